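"""Orthogroups within young families, and paralog/ortholog pairs.

Orthogroups partition a family's members by ancestral gene at the clade
root. Instead of running a full orthology inference tool, young families
(high identity, small size) are split with a length-normalised best-hit
surrogate: inter-species edges are kept when their normalised score is
within a factor of either endpoint's best inter-species score, all
intra-species edges above the young-identity threshold are kept, and
orthogroups are the connected components of the kept subgraph. Within an
orthogroup, same-species gene pairs are paralogs and cross-species pairs
are orthologs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .config import PipelineConfig
from .families import GeneFamily
from .genome_io import GenomeSet
from .similarity import SimilarityHit


@dataclass
class Orthogroup:
    orthogroup_id: str
    family_id: str
    members: dict[str, str]  # gene_id -> species


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    relation: str  # "paralog" | "ortholog"
    orthogroup_id: str


def assign_orthogroups(
    family: GeneFamily,
    hits: Sequence[SimilarityHit],
    genomes: GenomeSet,
    config: PipelineConfig | None = None,
) -> list[Orthogroup]:
    """Split one family into orthogroups with the best-hit surrogate."""
    config = config or PipelineConfig()
    members = sorted(family.members)
    member_set = set(members)
    norm: dict[tuple[str, str], float] = {}
    ident: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.gene_a in member_set and h.gene_b in member_set:
            la, lb = len(genomes[h.gene_a].cds), len(genomes[h.gene_b].cds)
            norm[(h.gene_a, h.gene_b)] = h.score / (la * lb) ** 0.5
            ident[(h.gene_a, h.gene_b)] = h.identity
    best_inter: dict[str, float] = {g: 0.0 for g in members}
    for (a, b), s in norm.items():
        if family.members[a] != family.members[b]:
            best_inter[a] = max(best_inter[a], s)
            best_inter[b] = max(best_inter[b], s)
    graph = nx.Graph()
    graph.add_nodes_from(members)
    for (a, b), s in norm.items():
        if family.members[a] == family.members[b]:
            if ident[(a, b)] > config.min_identity:
                graph.add_edge(a, b)
        elif s >= config.ortho_factor * best_inter[a] or s >= config.ortho_factor * best_inter[b]:
            graph.add_edge(a, b)
    groups = sorted((sorted(c) for c in nx.connected_components(graph)), key=tuple)
    return [
        Orthogroup(f"{family.family_id}.og{i}", family.family_id,
                   {g: family.members[g] for g in comp})
        for i, comp in enumerate(groups)
    ]


def enumerate_pairs(orthogroup: Orthogroup) -> list[HomologPair]:
    """All unordered member pairs; paralog iff same species."""
    pairs = []
    for a, b in combinations(sorted(orthogroup.members), 2):
        relation = "paralog" if orthogroup.members[a] == orthogroup.members[b] else "ortholog"
        pairs.append(HomologPair(a, b, relation, orthogroup.orthogroup_id))
    return pairs


def import_orthogroups(path: str, families: Sequence[GeneFamily]) -> list[Orthogroup]:
    """Adapter: read an external orthogroups TSV (orthogroup_id, gene_id).

    Members not belonging to any supplied family are ignored; each imported
    group is attached to the family containing its first member.
    """
    df = pd.read_csv(path, sep="\t")
    gene_to_family = {g: f for f in families for g in f.members}
    groups: list[Orthogroup] = []
    for og_id, sub in df.groupby(df.columns[0], sort=True):
        genes = [g for g in sub[df.columns[1]] if g in gene_to_family]
        if not genes:
            continue
        fam = gene_to_family[genes[0]]
        groups.append(Orthogroup(str(og_id), fam.family_id,
                                 {g: fam.members[g] for g in genes if g in fam.members}))
    return groups


def orthogroups_to_frame(groups: Iterable[Orthogroup]) -> pd.DataFrame:
    rows = [
        {"orthogroup_id": og.orthogroup_id, "family_id": og.family_id,
         "gene_id": g, "species": og.members[g]}
        for og in groups for g in sorted(og.members)
    ]
    return pd.DataFrame(rows, columns=["orthogroup_id", "family_id", "gene_id", "species"])


def pairs_to_frame(pairs: Iterable[HomologPair]) -> pd.DataFrame:
    rows = [
        {"gene_a": p.gene_a, "gene_b": p.gene_b, "relation": p.relation,
         "orthogroup_id": p.orthogroup_id}
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "relation", "orthogroup_id"])
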