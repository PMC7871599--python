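"""Collinearity blocks and duplication-type classification.

Anchors are homologous gene pairs (from the similarity hit list) placed in
gene-rank space. Per chromosome pair, collinear blocks are extracted by
longest-chain dynamic programming: chains of anchors strictly monotone in
both rank coordinates (same or inverted orientation), with the rank gap
between consecutive anchors bounded on both sides, of at least
``min_anchors`` anchors; non-overlapping top chains are taken greedily.

Each young intra-species paralog pair is then typed with priority
WGD > tandem > transposed > other:

* WGD: the pair itself is an anchor inside an intra-species block;
* tandem: same chromosome with at most ``tandem_max_gap`` intervening genes;
* transposed: the two genes have unequal cross-species block support (the
  number of partner species with which a gene sits in a collinear block);
  the better-supported gene marks the ancestral locus, the other the
  relocated copy. This generalises the "exactly one gene in a block" test:
  a copy transposed on an internal branch is inherited at the same locus
  by every descendant species and is therefore collinear with them, but
  remains non-collinear with the outgroup species — asymmetric support is
  the desk-scale proxy for outgroup-based ancestral-locus detection;
* other: everything else (including pairs a proximal-duplication category
  would absorb; set ``proximal_as_tandem`` to fold rank gaps up to
  ``proximal_max_gap`` into tandem).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .config import PipelineConfig
from .families import GeneFamily
from .genome_io import GenomeSet
from .orthology import HomologPair
from .similarity import SimilarityHit


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    key_a: tuple[str, str]  # (species, chromosome)
    key_b: tuple[str, str]
    rank_a: int
    rank_b: int


@dataclass
class CollinearBlock:
    block_id: str
    key_a: tuple[str, str]
    key_b: tuple[str, str]
    anchors: list[AnchorPair]  # ordered along key_a
    orientation: str  # "same" | "inverted"

    @property
    def intra_species(self) -> bool:
        return self.key_a[0] == self.key_b[0]

    def anchor_pairs(self) -> set[frozenset[str]]:
        return {frozenset((a.gene_a, a.gene_b)) for a in self.anchors}

    def genes(self) -> set[str]:
        return {g for a in self.anchors for g in (a.gene_a, a.gene_b)}


@dataclass(frozen=True)
class DuplicationCall:
    gene_a: str
    gene_b: str
    species: str
    dup_type: str  # wgd | tandem | transposed | other
    evidence: str


def build_anchors(hits: Sequence[SimilarityHit], genomes: GenomeSet) -> list[AnchorPair]:
    """Anchor pairs from hits between annotated genes, canonically ordered."""
    anchors = []
    for h in hits:
        if h.gene_a not in genomes or h.gene_b not in genomes:
            continue
        ga, gb = genomes[h.gene_a], genomes[h.gene_b]
        ka, kb = (ga.species, ga.chromosome), (gb.species, gb.chromosome)
        if (kb, gb.rank) < (ka, ga.rank):
            ga, gb, ka, kb = gb, ga, kb, ka
        anchors.append(AnchorPair(ga.gene_id, gb.gene_id, ka, kb, ga.rank, gb.rank))
    return anchors


def _best_chain(anchors: list[AnchorPair], sign: int, max_gap: int) -> list[int]:
    """Longest chain (as index list) monotone increasing in rank_a and, per
    ``sign``, increasing (+1) or decreasing (-1) in rank_b, gaps bounded."""
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))
    best_len = [1] * len(anchors)
    prev = [-1] * len(anchors)
    for oi, i in enumerate(order):
        ai = anchors[i]
        for j in order[:oi]:
            aj = anchors[j]
            if aj.rank_a >= ai.rank_a:
                continue
            if ai.rank_a - aj.rank_a > max_gap:
                continue
            if sign * (ai.rank_b - aj.rank_b) <= 0:
                continue
            if abs(ai.rank_b - aj.rank_b) > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(len(anchors)), key=lambda i: (best_len[i], -anchors[i].rank_a))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def detect_blocks(
    anchors: Sequence[AnchorPair],
    min_anchors: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """MCScanX-style chaining per chromosome pair, both orientations."""
    groups: dict[tuple[tuple[str, str], tuple[str, str]], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.key_a, a.key_b), []).append(a)
    blocks: list[CollinearBlock] = []
    for key in sorted(groups):
        pool = sorted(groups[key], key=lambda a: (a.rank_a, a.rank_b, a.gene_a, a.gene_b))
        while pool:
            candidates = []
            for sign, orientation in ((1, "same"), (-1, "inverted")):
                chain = _best_chain(pool, sign, max_gap)
                candidates.append((len(chain), orientation == "same", orientation, chain))
            candidates.sort(reverse=True)
            n, _, orientation, chain = candidates[0]
            if n < min_anchors:
                break
            chosen = [pool[i] for i in chain]
            blocks.append(CollinearBlock(f"blk{len(blocks):04d}", key[0], key[1], chosen, orientation))
            picked = set(chain)
            pool = [a for i, a in enumerate(pool) if i not in picked]
    return blocks


def block_species_support(blocks: Sequence[CollinearBlock]) -> dict[str, set[str]]:
    """Per gene: the set of *other* species it is block-collinear with.

    Intra-species blocks carry no ancestral-locus evidence and are ignored.
    """
    support: dict[str, set[str]] = {}
    for b in blocks:
        if b.intra_species:
            continue
        sp_a, sp_b = b.key_a[0], b.key_b[0]
        for a in b.anchors:
            support.setdefault(a.gene_a, set()).add(sp_b)
            support.setdefault(a.gene_b, set()).add(sp_a)
    return support


def classify_pair(
    pair: HomologPair,
    genomes: GenomeSet,
    blocks: Sequence[CollinearBlock],
    config: PipelineConfig | None = None,
) -> DuplicationCall:
    """Type one intra-species paralog pair (priority wgd > tandem > transposed)."""
    return classify_pairs([pair], genomes, blocks, config, _strict=True)[0]


def classify_pairs(
    pairs: Sequence[HomologPair],
    genomes: GenomeSet,
    blocks: Sequence[CollinearBlock],
    config: PipelineConfig | None = None,
    _strict: bool = False,
) -> list[DuplicationCall]:
    config = config or PipelineConfig()
    anchor_sets = [(b.block_id, b.anchor_pairs()) for b in blocks if b.intra_species]
    support = block_species_support(blocks)
    calls = []
    for pair in pairs:
        if pair.relation != "paralog":
            if _strict:
                raise ValueError("classify_pair requires an intra-species paralog pair")
            continue
        ga, gb = genomes[pair.gene_a], genomes[pair.gene_b]
        key = frozenset((pair.gene_a, pair.gene_b))
        blk_id = next((bid for bid, s in anchor_sets if key in s), None)
        if blk_id is not None:
            calls.append(DuplicationCall(pair.gene_a, pair.gene_b, ga.species, "wgd", blk_id))
            continue
        if ga.chromosome == gb.chromosome:
            gap = abs(ga.rank - gb.rank) - 1
            if gap <= config.tandem_max_gap or (config.proximal_as_tandem and gap <= config.proximal_max_gap):
                calls.append(DuplicationCall(pair.gene_a, pair.gene_b, ga.species, "tandem", f"rank_gap={gap}"))
                continue
        sa = len(support.get(pair.gene_a, ()))
        sb = len(support.get(pair.gene_b, ()))
        if sa != sb:
            anchored = pair.gene_a if sa > sb else pair.gene_b
            calls.append(DuplicationCall(pair.gene_a, pair.gene_b, ga.species, "transposed",
                                         f"ancestral={anchored};support={max(sa, sb)}v{min(sa, sb)}"))
        else:
            calls.append(DuplicationCall(pair.gene_a, pair.gene_b, ga.species, "other", ""))
    return calls


_PRIORITY = {"wgd": 0, "tandem": 1, "transposed": 2, "other": 3}


def type_summary(
    calls: Sequence[DuplicationCall],
    families: Sequence[GeneFamily],
) -> pd.DataFrame:
    """Gene-level counts and percentages per species x expansion class.

    A gene is typed once, by the highest-priority call among its pairs; the
    denominator is the number of young duplicate genes of that species in
    families of the given expansion class (genes of species in the family's
    expanded-species set). Genes with no call fall into "other", so
    tandem + transposed + wgd + other = total.
    """
    gene_type: dict[str, str] = {}
    for c in calls:
        for g in (c.gene_a, c.gene_b):
            cur = gene_type.get(g)
            if cur is None or _PRIORITY[c.dup_type] < _PRIORITY[cur]:
                gene_type[g] = c.dup_type
    rows = []
    class_genes: dict[tuple[str, str], set[str]] = {}
    for fam in families:
        if not fam.is_young:
            continue
        kind, expanded = fam.expansion
        for g, sp in fam.members.items():
            if sp in expanded:
                class_genes.setdefault((sp, kind), set()).add(g)
    for (sp, kind) in sorted(class_genes):
        genes = class_genes[(sp, kind)]
        counts = {t: 0 for t in ("tandem", "transposed", "wgd", "other")}
        for g in genes:
            counts[gene_type.get(g, "other")] += 1
        total = len(genes)
        row = {"species": sp, "expansion": kind, "total": total}
        for t in ("tandem", "transposed", "wgd", "other"):
            row[t] = counts[t]
            row[f"{t}_pct"] = 100.0 * counts[t] / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows, columns=["species", "expansion", "total",
                                       "tandem", "tandem_pct", "transposed", "transposed_pct",
                                       "wgd", "wgd_pct", "other", "other_pct"])


def blocks_to_frame(blocks: Iterable[CollinearBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        for i, a in enumerate(b.anchors):
            rows.append({
                "block_id": b.block_id, "orientation": b.orientation,
                "species_a": a.key_a[0], "chrom_a": a.key_a[1],
                "species_b": a.key_b[0], "chrom_b": a.key_b[1],
                "anchor_index": i, "gene_a": a.gene_a, "gene_b": a.gene_b,
                "rank_a": a.rank_a, "rank_b": a.rank_b,
            })
    return pd.DataFrame(rows, columns=["block_id", "orientation", "species_a", "chrom_a",
                                       "species_b", "chrom_b", "anchor_index",
                                       "gene_a", "gene_b", "rank_a", "rank_b"])


def calls_to_frame(calls: Iterable[DuplicationCall]) -> pd.DataFrame:
    rows = [
        {"gene_a": c.gene_a, "gene_b": c.gene_b, "species": c.species,
         "dup_type": c.dup_type, "evidence": c.evidence}
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "species", "dup_type", "evidence"])
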