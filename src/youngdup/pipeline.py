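"""End-to-end orchestration of the young-duplication analysis.

``run_pipeline`` chains every stage on an in-memory GenomeSet: similarity
search -> family building and young/expansion classification -> orthogroup
assignment and homolog-pair enumeration -> codon alignment and Ka/Ks/Pi ->
collinearity blocks and duplication typing -> chromosome windows ->
NJ trees with bootstrap for families spanning every species -> summary
tables. The result object keeps each stage's output so tests and the
command line can inspect any of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evometrics, families, orthology, report, similarity, synteny, trees, windows
from .config import PipelineConfig
from .evometrics import CodonAlignment, GenePairStats, SaturationError
from .families import GeneFamily
from .genome_io import GenomeSet, write_table
from .orthology import HomologPair, Orthogroup
from .similarity import SimilarityHit
from .synteny import CollinearBlock, DuplicationCall
from .trees import DuplicationEvent, FamilyTree
from .windows import WindowProfile

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    genomes: GenomeSet
    config: PipelineConfig
    hits: list[SimilarityHit]
    families: list[GeneFamily]
    orthogroups: list[Orthogroup]
    pairs: list[HomologPair]
    alignments: dict[str, CodonAlignment]  # per orthogroup id
    pair_stats: list[GenePairStats]
    dropped_pairs: list[tuple[str, str, str]]  # (gene_a, gene_b, reason)
    blocks: list[CollinearBlock]
    calls: list[DuplicationCall]
    type_summary: pd.DataFrame
    profiles: dict[tuple[str, str], list[WindowProfile]]  # (species, kind) -> profiles
    window_correlations: pd.DataFrame
    family_trees: list[FamilyTree]
    tree_events: list[DuplicationEvent]
    group_summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def young_families(self) -> list[GeneFamily]:
        return [f for f in self.families if f.is_young]

    def table1(self) -> dict:
        return report.table1(self.families)


def _class_genes(fams: list[GeneFamily], kind: str) -> dict[str, set[str]]:
    """Per species: young duplicate genes of one expansion kind."""
    out: dict[str, set[str]] = {}
    for fam in fams:
        if not fam.is_young or fam.expansion[0] != kind:
            continue
        for g, sp in fam.members.items():
            if sp in fam.expansion[1]:
                out.setdefault(sp, set()).add(g)
    return out


def _group_summary(
    fams: list[GeneFamily],
    pairs: list[HomologPair],
    stats: list[GenePairStats],
    alignments: dict[str, CodonAlignment],
    genomes: GenomeSet,
) -> pd.DataFrame:
    """Per species x expansion kind: mean Ks/Pi/omega for paralogs and
    orthologs, with Welch tests between the two relations.

    A cross-species (ortholog) pair contributes to both member species'
    summaries.
    """
    fam_kind = {f.family_id: f.expansion[0] for f in fams if f.is_young}
    og_family = {}
    for p in pairs:
        og_family[p.orthogroup_id] = p.orthogroup_id.rsplit(".og", 1)[0]
    stat_by_pair = {(s.gene_a, s.gene_b): s for s in stats}
    buckets: dict[tuple[str, str, str], dict[str, list[float]]] = {}

    def add(sp: str, kind: str, rel: str, metric: str, value: float | None) -> None:
        if value is None:
            return
        buckets.setdefault((sp, kind, rel), {}).setdefault(metric, []).append(value)

    for p in pairs:
        fam_id = og_family[p.orthogroup_id]
        kind = fam_kind.get(fam_id)
        if kind is None:
            continue
        s = stat_by_pair.get((p.gene_a, p.gene_b))
        if s is None:
            continue
        aln = alignments[p.orthogroup_id]
        pi_pair = evometrics.pair_p_distance(aln.row(p.gene_a), aln.row(p.gene_b))
        species = {genomes[p.gene_a].species, genomes[p.gene_b].species}
        for sp in species:
            add(sp, kind, p.relation, "pi", pi_pair)
            if s.retained:
                add(sp, kind, p.relation, "ks", s.ks)
            add(sp, kind, p.relation, "omega", s.omega)
    rows = []
    for (sp, kind) in sorted({(sp, kind) for (sp, kind, _) in buckets}):
        row: dict = {"species": sp, "expansion": kind}
        for rel in ("paralog", "ortholog"):
            b = buckets.get((sp, kind, rel), {})
            for metric in ("ks", "pi", "omega"):
                vals = b.get(metric, [])
                row[f"{rel}_{metric}_mean"] = float(np.mean(vals)) if vals else np.nan
                row[f"{rel}_{metric}_median"] = float(np.median(vals)) if vals else np.nan
                row[f"{rel}_{metric}_n"] = len(vals)
        for metric in ("pi", "omega"):
            a = buckets.get((sp, kind, "paralog"), {}).get(metric, [])
            b = buckets.get((sp, kind, "ortholog"), {}).get(metric, [])
            if len(a) >= 2 and len(b) >= 2:
                cmp = evometrics.compare_groups(a, b)
                row[f"{metric}_t"] = cmp.t_statistic
                row[f"{metric}_p"] = cmp.p_value
            else:
                row[f"{metric}_t"] = np.nan
                row[f"{metric}_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    genomes: GenomeSet,
    config: PipelineConfig | None = None,
    tree_seed: int = 0,
    with_trees: bool = True,
) -> PipelineResult:
    config = config or PipelineConfig()
    log.info("similarity search over %d genes", len(genomes))
    hits = similarity.all_vs_all(genomes, config)
    fams = families.annotate_families(hits, genomes, config)
    young = [f for f in fams if f.is_young]
    log.info("%d families, %d young", len(fams), len(young))

    orthogroups: list[Orthogroup] = []
    pairs: list[HomologPair] = []
    for fam in young:
        ogs = orthology.assign_orthogroups(fam, hits, genomes, config)
        orthogroups.extend(ogs)
        for og in ogs:
            pairs.extend(orthology.enumerate_pairs(og))

    alignments: dict[str, CodonAlignment] = {}
    pair_stats: list[GenePairStats] = []
    dropped: list[tuple[str, str, str]] = []
    for og in orthogroups:
        if len(og.members) < 2:
            continue
        aln = evometrics.codon_align({g: genomes[g].cds for g in og.members})
        alignments[og.orthogroup_id] = aln
    for p in pairs:
        aln = alignments[p.orthogroup_id]
        try:
            pair_stats.append(evometrics.ka_ks(aln, p.gene_a, p.gene_b, p.relation))
        except SaturationError:
            dropped.append((p.gene_a, p.gene_b, "saturated"))
            log.warning("pair %s-%s saturated; dropped", p.gene_a, p.gene_b)

    anchors = synteny.build_anchors(hits, genomes)
    blocks = synteny.detect_blocks(anchors, config.min_anchors, config.max_gap)
    calls = synteny.classify_pairs(pairs, genomes, blocks, config)
    tsummary = synteny.type_summary(calls, fams)

    profiles: dict[tuple[str, str], list[WindowProfile]] = {}
    for kind in ("species_specific", "lineage_specific"):
        per_sp = _class_genes(fams, kind)
        for sp, genes in sorted(per_sp.items()):
            profiles[(sp, kind)] = windows.window_profile(
                genomes, {g for g in genes}, config.window_size
            )
            profiles[(sp, kind)] = [p for p in profiles[(sp, kind)] if p.species == sp]
    corr_rows = []
    for sp in genomes.species:
        ss = profiles.get((sp, "species_specific"), [])
        ls = profiles.get((sp, "lineage_specific"), [])
        if ss and ls:
            corr_rows.append(windows.correlation_table(ss, ls))
    corr = pd.concat(corr_rows, ignore_index=True) if corr_rows else pd.DataFrame(
        columns=["species", "chromosome", "n_windows", "pearson_r"])

    family_trees: list[FamilyTree] = []
    tree_events: list[DuplicationEvent] = []
    if with_trees:
        all_species = set(genomes.species)
        for fam in young:
            counts = fam.species_counts()
            if set(counts) == all_species and all(v >= 2 for v in counts.values()):
                aln = evometrics.codon_align({g: genomes[g].cds for g in fam.members})
                ft = trees.bootstrap(aln, fam.family_id, config.bootstrap_reps, seed=tree_seed)
                family_trees.append(ft)
                tree_events.extend(
                    trees.count_events(ft, fam.members, config.min_support)
                )

    gsummary = _group_summary(fams, pairs, pair_stats, alignments, genomes)
    return PipelineResult(
        genomes=genomes, config=config, hits=hits, families=fams,
        orthogroups=orthogroups, pairs=pairs, alignments=alignments,
        pair_stats=pair_stats, dropped_pairs=dropped, blocks=blocks, calls=calls,
        type_summary=tsummary, profiles=profiles, window_correlations=corr,
        family_trees=family_trees, tree_events=tree_events, group_summary=gsummary,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write every stage's TSV (and Newick trees); returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, sort_by=None) -> None:
        path = outdir / f"{name}.tsv"
        write_table(df, path, sort_by=sort_by)
        manifest[name] = path

    emit("hits", similarity.hits_to_frame(result.hits), ["gene_a", "gene_b"])
    emit("families", families.families_to_frame(result.families), ["family_id", "gene_id"])
    emit("orthogroups", orthology.orthogroups_to_frame(result.orthogroups),
         ["orthogroup_id", "gene_id"])
    emit("pairs", orthology.pairs_to_frame(result.pairs), ["gene_a", "gene_b"])
    emit("pair_stats", evometrics.stats_to_frame(result.pair_stats), ["gene_a", "gene_b"])
    emit("blocks", synteny.blocks_to_frame(result.blocks), ["block_id", "anchor_index"])
    emit("duplication_calls", synteny.calls_to_frame(result.calls), ["gene_a", "gene_b"])
    emit("type_summary", result.type_summary, ["species", "expansion"])
    for (sp, kind), profs in sorted(result.profiles.items()):
        emit(f"windows_{sp}_{kind}", windows.profiles_to_frame(profs),
             ["species", "chromosome", "window"])
    emit("window_correlations", result.window_correlations, ["species", "chromosome"])
    emit("group_summary", result.group_summary, ["species", "expansion"])
    emit("table1", report.table1_frame(result.families), None)
    if result.family_trees:
        tree_path = outdir / "family_trees.nwk"
        tree_path.write_text("".join(ft.newick() + "\n" for ft in result.family_trees))
        manifest["family_trees"] = tree_path
        emit("tree_events", pd.DataFrame(
            [{"family_id": e.family_id, "species": e.species,
              "genes": ",".join(sorted(e.genes)), "support": e.support}
             for e in result.tree_events],
            columns=["family_id", "species", "genes", "support"]), ["family_id", "genes"])
    manifest_path = outdir / "MANIFEST.tsv"
    write_table(pd.DataFrame(
        [{"output": k, "path": str(v)} for k, v in sorted(manifest.items())],
        columns=["output", "path"]), manifest_path)
    manifest["manifest"] = manifest_path
    return manifest
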