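"""Gene families, young-duplication flags and expansion classes.

A gene family is a connected component (single linkage) of the similarity
graph restricted to hits whose coverage strictly exceeds the threshold
(default 0.60); singletons are not families. A family is a *young*
duplicate family when some species contributes at least two members and
the highest identity among same-species member pairs strictly exceeds the
identity threshold (default 0.90). Young families expand either in exactly
one species (species-specific) or in two or more (lineage-specific: the
set of species with >= 2 members).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .config import PipelineConfig
from .genome_io import GenomeSet
from .similarity import SimilarityHit


@dataclass
class GeneFamily:
    family_id: str
    members: dict[str, str]  # gene_id -> species
    is_young: bool = False
    max_intraspecies_identity: float = 0.0
    expansion: tuple[str, tuple[str, ...]] = ("none", ())

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(self.members)

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sp in self.members.values():
            counts[sp] = counts.get(sp, 0) + 1
        return counts


def build_families(
    hits: Sequence[SimilarityHit],
    genomes: GenomeSet,
    min_coverage: float = 0.60,
) -> list[GeneFamily]:
    """Single-linkage components over hits with coverage strictly > threshold."""
    graph = nx.Graph()
    for h in hits:
        if h.coverage > min_coverage:
            graph.add_edge(h.gene_a, h.gene_b)
    families = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph) if len(c) >= 2),
        key=lambda c: tuple(c),
    )
    for i, comp in enumerate(components):
        families.append(
            GeneFamily(f"fam{i:05d}", {g: genomes[g].species for g in comp})
        )
    return families


def flag_young(
    families: Iterable[GeneFamily],
    hits: Sequence[SimilarityHit],
    min_identity: float = 0.90,
    identity_scope: str = "intraspecies",
) -> None:
    """Set ``is_young`` and ``max_intraspecies_identity`` in place.

    ``identity_scope`` selects whether the "highest identity" is taken over
    same-species member pairs (the default: the young-duplication criterion
    concerns within-species duplicates) or over all member pairs.
    """
    ident: dict[tuple[str, str], float] = {(h.gene_a, h.gene_b): h.identity for h in hits}
    for fam in families:
        members = sorted(fam.members)
        best = 0.0
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if identity_scope == "intraspecies" and fam.members[a] != fam.members[b]:
                    continue
                best = max(best, ident.get((a, b), 0.0))
        if identity_scope == "intraspecies":
            fam.max_intraspecies_identity = best
        else:
            fam.max_intraspecies_identity = max(
                (ident.get((a, b), 0.0)
                 for i, a in enumerate(members) for b in members[i + 1 :]
                 if fam.members[a] == fam.members[b]),
                default=0.0,
            )
        has_pair = any(v >= 2 for v in fam.species_counts().values())
        fam.is_young = has_pair and best > min_identity


def classify_expansion(family: GeneFamily) -> tuple[str, tuple[str, ...]]:
    """Expansion label of a young family from per-species member counts.

    Exactly one species with >= 2 members: species-specific expansion of
    that species. Two or more species with >= 2 members: lineage-specific
    expansion of that species set (which may be the whole clade).
    """
    if not family.is_young:
        raise ValueError("classify_expansion requires a young family")
    expanded = tuple(sorted(sp for sp, n in family.species_counts().items() if n >= 2))
    if len(expanded) == 1:
        return ("species_specific", expanded)
    return ("lineage_specific", expanded)


def annotate_families(
    hits: Sequence[SimilarityHit],
    genomes: GenomeSet,
    config: PipelineConfig | None = None,
) -> list[GeneFamily]:
    """build -> flag_young -> classify, in one pass."""
    config = config or PipelineConfig()
    families = build_families(hits, genomes, min_coverage=config.min_coverage)
    flag_young(families, hits, min_identity=config.min_identity,
               identity_scope=config.identity_scope)
    for fam in families:
        if fam.is_young:
            fam.expansion = classify_expansion(fam)
    return families


def families_to_frame(families: Iterable[GeneFamily]) -> pd.DataFrame:
    rows = []
    for fam in families:
        kind, species = fam.expansion
        for g in sorted(fam.members):
            rows.append(
                {
                    "family_id": fam.family_id, "gene_id": g, "species": fam.members[g],
                    "is_young": fam.is_young,
                    "max_intraspecies_identity": fam.max_intraspecies_identity,
                    "expansion": kind, "expansion_species": ",".join(species),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["family_id", "gene_id", "species", "is_young",
                 "max_intraspecies_identity", "expansion", "expansion_species"],
    )


def frame_to_families(df: pd.DataFrame) -> list[GeneFamily]:
    out: dict[str, GeneFamily] = {}
    for r in df.itertuples():
        fam = out.get(r.family_id)
        if fam is None:
            species = tuple(str(r.expansion_species).split(",")) if isinstance(r.expansion_species, str) and r.expansion_species else ()
            fam = GeneFamily(r.family_id, {}, bool(r.is_young),
                             float(r.max_intraspecies_identity), (str(r.expansion), species))
            out[r.family_id] = fam
        fam.members[r.gene_id] = r.species
    return [out[k] for k in sorted(out)]
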