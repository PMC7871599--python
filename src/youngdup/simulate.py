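"""Synthetic multi-species genomes with planted duplication events.

The simulator evolves a set of ancestral coding sequences down a fixed
rooted species tree under a Jukes–Cantor substitution process and plants
duplication events (tandem, transposed, whole-genome-duplication segment)
on chosen branches. It emits per-species CDS FASTA + GFF3 and a truth
ledger recording every planted family and event, so the whole analysis
pipeline can be verified against known ground truth.

Design notes:

* Jukes–Cantor: per-site substitution probability for branch length ``t``
  (expected substitutions/site) is ``p = 3/4 (1 - exp(-4/3 t))``.
* An event with divergence ``d`` splits the divergence evenly: each of the
  two copies is mutated by ``d/2`` at the event, so the expected pairwise
  divergence between copies equals ``d`` (plus any post-event tree path).
* Events are placed at the end of their branch, after background mutation.
* Sequences are kept free of stop codons throughout (redraw on hit), so
  translation-guided alignment downstream always works.
* Gene layout: a fixed intergenic spacing between consecutive genes, the
  ancestral gene order shared by all species; tandem copies are inserted
  immediately after their template, transposed copies at a random locus on
  a random chromosome, and WGD segments are appended as a contiguous run at
  the end of a random chromosome, preserving gene order.
* Everything is driven by one ``numpy`` Generator seeded from the config;
  identical configs give byte-identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

from .genome_io import GeneModel, GenomeSet, write_genome, write_table

STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}

EVENT_TYPES = ("tandem", "transposed", "wgd_segment")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Event:
    """A planted duplication on one branch of the species tree.

    ``branch`` names the child node of the branch (a leaf name or an
    internal node label in the Newick string). ``divergence`` is the
    expected pairwise substitutions/site between the two copies at the
    moment of duplication. ``segment_length`` applies to ``wgd_segment``
    events only. ``gene_index`` optionally pins the event to a specific
    ancestral family (0-based); by default an unused family is drawn.
    """

    branch: str
    event_type: str
    divergence: float
    segment_length: int = 6
    gene_index: int | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ConfigError(f"unknown event type {self.event_type!r}")
        if self.divergence < 0:
            raise ConfigError("divergence must be >= 0")
        if self.event_type == "wgd_segment" and self.segment_length < 6:
            raise ConfigError("wgd_segment events duplicate a run of >= 6 genes")


@dataclass
class SimConfig:
    species: list[str]
    tree: str  # rooted Newick with branch lengths and internal node labels
    n_chromosomes: int = 4
    n_ancestral_genes: int = 200
    gene_length: int = 900
    events: list[Event] = field(default_factory=list)
    background_mutation_rate: float = 1.0
    intergenic_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= len(self.species) <= 6):
            raise ConfigError("between 2 and 6 species are supported")
        if self.gene_length % 3 != 0:
            raise ConfigError("gene_length must be a multiple of 3")


@dataclass
class LedgerEvent:
    event_id: str
    family_id: str
    event_type: str
    branch: str
    species: tuple[str, ...]  # species carrying both copies
    divergence: float
    # per species: (gene id descended from template, gene id descended from copy)
    members: dict[str, tuple[str, str]]


@dataclass
class TruthLedger:
    """Ground truth of a simulation: families, events, expected labels."""

    families: dict[str, dict[str, list[str]]]  # family -> species -> gene ids
    events: list[LedgerEvent]

    @property
    def expected_expansion(self) -> dict[str, tuple[str, tuple[str, ...]]]:
        """Per family: expected young-expansion label from member counts.

        A species "expands" a family when it carries >= 2 members; one such
        species gives ``species_specific``, several give ``lineage_specific``,
        none gives ``none``.
        """
        out = {}
        for fam, per_sp in self.families.items():
            expanded = tuple(sorted(s for s, g in per_sp.items() if len(g) >= 2))
            if not expanded:
                out[fam] = ("none", ())
            elif len(expanded) == 1:
                out[fam] = ("species_specific", expanded)
            else:
                out[fam] = ("lineage_specific", expanded)
        return out

    def family_member_sets(self) -> dict[str, frozenset[str]]:
        return {
            fam: frozenset(g for gl in per_sp.values() for g in gl)
            for fam, per_sp in self.families.items()
        }


# ---------------------------------------------------------------------------
# sequence evolution


def _fix_stops(codons: list[str], mutated: np.ndarray, rng: np.random.Generator) -> None:
    """Redraw mutated positions of any codon that became a stop codon.

    ``mutated`` holds the flat positions that were substituted. Codons that
    are stops without any mutated position are left alone (caller guarantees
    stop-free input, so this only happens on a final stop codon that is
    deliberately preserved).
    """
    by_codon: dict[int, list[int]] = {}
    for pos in mutated:
        by_codon.setdefault(pos // 3, []).append(int(pos))
    for ci, positions in by_codon.items():
        while codons[ci] in STOPS:
            c = list(codons[ci])
            for pos in positions:
                off = pos % 3
                orig = c[off]
                choices = [b for b in _BASES if b != orig]
                c[off] = choices[rng.integers(3)]
            codons[ci] = "".join(c)


def jc_p(branch_length: float) -> float:
    """Jukes–Cantor expected proportion of differing sites."""
    return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * branch_length))


def _mutate(seq: str, branch_length: float, rng: np.random.Generator) -> str:
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if len(seq) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    if branch_length == 0:
        return seq
    p = jc_p(branch_length)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < p)
    if hit.size == 0:
        return seq
    base_idx = np.array([_IDX[chr(b)] for b in arr[hit]])
    offs = rng.integers(1, 4, size=hit.size)
    new_idx = (base_idx + offs) % 4
    arr[hit] = np.frombuffer("".join(_BASES[i] for i in new_idx).encode(), dtype=np.uint8)
    out = arr.tobytes().decode()
    codons = [out[i : i + 3] for i in range(0, len(out), 3)]
    _fix_stops(codons, hit, rng)
    return "".join(codons)


def mutate_cds(seq: str, branch_length: float, seed: int) -> str:
    """Mutate a CDS under Jukes–Cantor; stop codons are redrawn.

    The per-site substitution probability is ``3/4 (1 - exp(-4/3 t))`` for
    branch length ``t``; substituted sites that would create a stop codon
    are redrawn so the output remains translatable.
    """
    return _mutate(seq, branch_length, np.random.default_rng(seed))


def random_cds(length: int, rng: np.random.Generator) -> str:
    """A stop-free random CDS beginning with ATG."""
    if length % 3 != 0:
        raise ValueError("length must be a multiple of 3")
    n_codons = length // 3
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in STOPS:
            codons.append(c)
    return "".join(codons)


# ---------------------------------------------------------------------------
# genome evolution along the tree


@dataclass
class _Lineage:
    """One gene copy being evolved; identified by a stable lineage id."""

    lineage_id: int
    family: str
    seq: str
    strand: str


def _parse_tree(newick: str) -> skbio.TreeNode:
    tree = skbio.TreeNode.read(io.StringIO(newick))
    return tree


def simulate(config: SimConfig) -> tuple[GenomeSet, TruthLedger]:
    """Run the simulation; returns the genomes and the truth ledger."""
    rng = np.random.default_rng(config.seed)
    tree = _parse_tree(config.tree)
    tips = sorted(t.name for t in tree.tips())
    if tips != sorted(config.species):
        raise ConfigError(f"tree tips {tips} do not match species {sorted(config.species)}")
    node_names = {n.name for n in tree.traverse() if n.name}
    for ev in config.events:
        if ev.branch not in node_names:
            raise ConfigError(f"event branch {ev.branch!r} not in tree")

    # ancestral genome: contiguous slices of families across chromosomes
    n = config.n_ancestral_genes
    per_chrom = int(np.ceil(n / config.n_chromosomes))
    fam_ids = [f"F{i:04d}" for i in range(n)]
    next_lineage = iter(range(10**9))
    chroms: dict[str, list[_Lineage]] = {}
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
    k = 0
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        chroms[name] = []
        for _ in range(min(per_chrom, n - k)):
            chroms[name].append(
                _Lineage(next(next_lineage), fam_ids[k], random_cds(config.gene_length, rng), strands[k])
            )
            k += 1

    events_by_branch: dict[str, list[Event]] = {}
    for ev in config.events:
        events_by_branch.setdefault(ev.branch, []).append(ev)

    used_families: set[str] = set()
    ledger_events: list[LedgerEvent] = []
    # lineage pairs per event, to be resolved to leaf gene ids at emission
    event_pairs: list[tuple[Event, str, list[tuple[str, int, int]]]] = []  # (event, event_id, [(family, orig_lin, copy_lin)])
    leaf_states: dict[str, dict[str, list[_Lineage]]] = {}

    def copy_state(state: dict[str, list[_Lineage]]) -> dict[str, list[_Lineage]]:
        return {c: [ _Lineage(l.lineage_id, l.family, l.seq, l.strand) for l in gl] for c, gl in state.items()}

    def apply_events(state: dict[str, list[_Lineage]], branch: str) -> None:
        for ev in events_by_branch.get(branch, []):
            chrom_names = sorted(state)
            all_genes = [(c, i) for c in chrom_names for i in range(len(state[c]))]
            if ev.event_type == "wgd_segment":
                # contiguous run of unused families
                candidates = []
                for c in chrom_names:
                    gl = state[c]
                    for i in range(0, len(gl) - ev.segment_length + 1):
                        fams = {gl[j].family for j in range(i, i + ev.segment_length)}
                        if len(fams) == ev.segment_length and not (fams & used_families):
                            candidates.append((c, i))
                if not candidates:
                    raise ConfigError("no unused contiguous segment left for wgd_segment event")
                c, i = candidates[rng.integers(len(candidates))]
                originals = state[c][i : i + ev.segment_length]
                pairs = []
                copies = []
                for lin in originals:
                    pre = lin.seq
                    lin.seq = _mutate(pre, ev.divergence / 2.0, rng)
                    cp = _Lineage(next(next_lineage), lin.family,
                                  _mutate(pre, ev.divergence / 2.0, rng), lin.strand)
                    copies.append(cp)
                    pairs.append((lin.family, lin.lineage_id, cp.lineage_id))
                    used_families.add(lin.family)
                target = chrom_names[rng.integers(len(chrom_names))]
                state[target].extend(copies)
                event_pairs.append((ev, f"E{len(event_pairs):03d}", pairs))
            else:
                if ev.gene_index is not None:
                    fam = fam_ids[ev.gene_index]
                    locs = [(c, i) for (c, i) in all_genes if state[c][i].family == fam]
                    if not locs:
                        raise ConfigError(f"family index {ev.gene_index} absent from branch {ev.branch}")
                    c, i = locs[0]
                else:
                    free = [(c, i) for (c, i) in all_genes if state[c][i].family not in used_families]
                    if not free:
                        raise ConfigError("no unused ancestral gene left for event")
                    c, i = free[rng.integers(len(free))]
                lin = state[c][i]
                used_families.add(lin.family)
                pre = lin.seq
                lin.seq = _mutate(pre, ev.divergence / 2.0, rng)
                cp = _Lineage(next(next_lineage), lin.family,
                              _mutate(pre, ev.divergence / 2.0, rng), lin.strand)
                if ev.event_type == "tandem":
                    state[c].insert(i + 1, cp)
                else:  # transposed
                    tc = chrom_names[rng.integers(len(chrom_names))]
                    pos = int(rng.integers(len(state[tc]) + 1))
                    state[tc].insert(pos, cp)
                event_pairs.append((ev, f"E{len(event_pairs):03d}", [(lin.family, lin.lineage_id, cp.lineage_id)]))

    def descend(node, state: dict[str, list[_Lineage]]) -> None:
        for child in node.children:
            cstate = copy_state(state)
            bl = (child.length or 0.0) * config.background_mutation_rate
            for c in sorted(cstate):
                for lin in cstate[c]:
                    lin.seq = _mutate(lin.seq, bl, rng)
            if child.name:
                apply_events(cstate, child.name)
            if child.is_tip():
                leaf_states[child.name] = cstate
            else:
                descend(child, cstate)

    descend(tree, chroms)

    # emit genomes with coordinates and gene ids
    genes: list[GeneModel] = []
    lineage_to_gene: dict[tuple[str, int], str] = {}
    gene_family: dict[str, str] = {}
    for sp in sorted(config.species):
        state = leaf_states[sp]
        counter = 0
        for chrom in sorted(state):
            pos = 0
            for lin in state[chrom]:
                gid = f"{sp}G{counter:05d}"
                counter += 1
                start = pos
                end = start + len(lin.seq)
                pos = end + config.intergenic_spacing
                genes.append(GeneModel(gid, sp, chrom, start, end, lin.strand, lin.seq))
                lineage_to_gene[(sp, lin.lineage_id)] = gid
                gene_family[gid] = lin.family

    families: dict[str, dict[str, list[str]]] = {f: {} for f in fam_ids}
    for g in genes:
        families[gene_family[g.gene_id]].setdefault(g.species, []).append(g.gene_id)

    # resolve event member pairs to leaf genes per descendant species
    for ev, eid, pairs in event_pairs:
        for fam, orig_lin, copy_lin in pairs:
            members: dict[str, tuple[str, str]] = {}
            for sp in sorted(config.species):
                a = lineage_to_gene.get((sp, orig_lin))
                b = lineage_to_gene.get((sp, copy_lin))
                if a is not None and b is not None:
                    members[sp] = (a, b)
            ledger_events.append(
                LedgerEvent(eid, fam, ev.event_type, ev.branch,
                            tuple(sorted(members)), ev.divergence, members)
            )

    return GenomeSet(genes), TruthLedger(families, ledger_events)


# ---------------------------------------------------------------------------
# file output


def write_simulation(genome: GenomeSet, ledger: TruthLedger, outdir: str | Path) -> dict[str, Path]:
    """Write per-species FASTA + GFF3 and the truth ledger TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sp in genome.species:
        fa, gff = outdir / f"{sp}.cds.fasta", outdir / f"{sp}.gff3"
        write_genome(genome, sp, fa, gff)
        paths[f"{sp}.fasta"] = fa
        paths[f"{sp}.gff"] = gff
    fam_rows = [
        {"family_id": fam, "species": sp, "gene_id": g}
        for fam, per_sp in sorted(ledger.families.items())
        for sp, gl in sorted(per_sp.items())
        for g in gl
    ]
    ev_rows = [
        {
            "event_id": e.event_id, "family_id": e.family_id, "event_type": e.event_type,
            "branch": e.branch, "species": ",".join(e.species), "divergence": e.divergence,
            "members": ";".join(f"{s}:{a}|{b}" for s, (a, b) in sorted(e.members.items())),
        }
        for e in ledger.events
    ]
    fpath, epath = outdir / "truth_families.tsv", outdir / "truth_events.tsv"
    write_table(pd.DataFrame(fam_rows, columns=["family_id", "species", "gene_id"]),
                fpath, sort_by=["family_id", "species", "gene_id"])
    write_table(pd.DataFrame(ev_rows, columns=["event_id", "family_id", "event_type",
                                               "branch", "species", "divergence", "members"]),
                epath, sort_by=["event_id", "family_id"])
    paths["families"] = fpath
    paths["events"] = epath
    return paths


# ---------------------------------------------------------------------------
# the standard study clade


DEMO_TREE = (
    "((((S1:0.01,S2:0.01)N12:0.01,S3:0.02)N123:0.01,"
    "(S4:0.015,S5:0.015)N45:0.015)N12345:0.005,S6:0.035)root;"
)


def make_demo_config(
    seed: int = 0,
    n_ancestral_genes: int = 200,
    gene_length: int = 900,
    n_chromosomes: int = 4,
) -> SimConfig:
    """The standard six-species study clade with 60 planted events.

    Emulates a clade of closely related genomes: six species, shallow
    divergences, and per-branch duplication events at divergences drawn
    uniformly from [0.005, 0.05] (so duplicate pairs keep > 90% identity).
    Each terminal branch carries 4 tandem, 3 transposed and 1 WGD-segment
    event; each of the two internal branches (N12, N45) carries 2 of each
    type — 60 events in total, touching 110 of the ancestral families.
    """
    rng = np.random.default_rng(seed)
    species = [f"S{i}" for i in range(1, 7)]
    events: list[Event] = []

    def d() -> float:
        return float(np.round(rng.uniform(0.005, 0.05), 4))

    for sp in species:
        events += [Event(sp, "tandem", d()) for _ in range(4)]
        events += [Event(sp, "transposed", d()) for _ in range(3)]
        events += [Event(sp, "wgd_segment", d(), segment_length=6)]
    for br in ("N12", "N45"):
        events += [Event(br, "tandem", d()) for _ in range(2)]
        events += [Event(br, "transposed", d()) for _ in range(2)]
        events += [Event(br, "wgd_segment", d(), segment_length=6) for _ in range(2)]
    return SimConfig(
        species=species, tree=DEMO_TREE, n_chromosomes=n_chromosomes,
        n_ancestral_genes=n_ancestral_genes, gene_length=gene_length,
        events=events, seed=seed,
    )


# ---------------------------------------------------------------------------
# synthetic domain table

_DOMAIN_VOCAB = [
    "PPR", "Pkinase", "LRR", "NB-ARC", "p450", "WD40", "Ribosomal", "Ank",
    "Peptidase", "Myb", "bHLH", "UDPGT", "FAR1", "B-lectin", "Vicilin",
    "Trigger", "ABC_tran", "GST", "HSP20", "zf-C3HC4",
]


def simulate_domains(genome: GenomeSet, ledger: TruthLedger, seed: int = 0) -> pd.DataFrame:
    """A synthetic protein-domain assignment table (gene_id, domain).

    Each planted family is assigned 1–2 domains from a small vocabulary;
    every member gene inherits the family's domains. Stands in for an
    external Pfam scan at test scale.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fam, per_sp in sorted(ledger.families.items()):
        k = 1 + int(rng.random() < 0.3)
        doms = sorted(rng.choice(_DOMAIN_VOCAB, size=k, replace=False))
        for sp, gl in sorted(per_sp.items()):
            for g in gl:
                for dom in doms:
                    rows.append({"gene_id": g, "domain": dom})
    return pd.DataFrame(rows, columns=["gene_id", "domain"])
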