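"""Neighbor-joining trees with bootstrap, and duplication-event counting.

Family trees are built from nucleotide p-distances (pairwise deletion of
gapped sites) on the family codon alignment with the Saitou–Nei
neighbor-joining algorithm (deterministic lexicographic tie-breaking).
Support values come from codon-column bootstrap resampling: the support of
an internal bipartition is the percentage of replicate trees containing
it. Trees are treated as unrooted throughout: a "clade" is a bipartition
side. A species-specific duplication event is a maximal bipartition side
whose tips are >= 2 genes of a single species, with support strictly above
the cutoff (default 50); maximal-first counting prevents nested clades
from being double-counted and counts each gene once.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import skbio

from .evometrics import CodonAlignment


def p_distance_matrix(alignment: CodonAlignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise nucleotide p-distances with pairwise deletion of gaps."""
    labels = list(alignment.ids)
    mat = np.array([[ord(c) for c in row] for row in alignment.rows], dtype=np.uint8)
    gap = ord("-")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != gap) & (mat[j] != gap)
            total = int(ok.sum())
            if total == 0:
                raise ValueError(f"all sites gapped between {labels[i]} and {labels[j]}")
            d[i, j] = d[j, i] = float(((mat[i] != mat[j]) & ok).sum()) / total
    return d, labels


def nj(distances: np.ndarray, labels: Sequence[str]) -> skbio.TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Requires a symmetric matrix with zero diagonal and n >= 3. Ties in the
    Q criterion are broken by the lexicographically smallest pair of
    subtree representative labels. The returned tree is unrooted in
    spirit: its root is the final 3-way (or the n = 3 star) junction.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.asarray(distances, dtype=float)
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes = [skbio.TreeNode(name=l) for l in labels]
    reps = [str(l) for l in labels]  # lexicographic representative per subtree
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = skbio.TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        # grow matrix with the new node's distances
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = (d[i, x] + d[j, x] - d[i, j]) / 2
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [x for x in active if x not in (i, j)] + [k]
    i, j, k = active
    root = skbio.TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length = float((d[i, j] + d[i, k] - d[j, k]) / 2)
    nodes[j].length = float((d[i, j] + d[j, k] - d[i, k]) / 2)
    nodes[k].length = float((d[i, k] + d[j, k] - d[i, j]) / 2)
    return root


def bipartitions(tree: skbio.TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as tip-name sets of the child side.

    Each internal edge is represented canonically by the smaller side (ties
    by sorted tip names) so identical splits compare equal across trees.
    """
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


@dataclass
class FamilyTree:
    """An unrooted NJ tree with bootstrap supports per internal bipartition."""

    family_id: str
    tree: skbio.TreeNode
    supports: dict[frozenset[str], float] = field(default_factory=dict)
    n_reps: int = 0

    def newick(self) -> str:
        """Newick with supports as internal node labels."""
        tips = frozenset(t.name for t in self.tree.tips())
        annotated = self.tree.copy()
        for node in annotated.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            canon = min(side, tips - side, key=lambda s: (len(s), tuple(sorted(s))))
            sup = self.supports.get(canon)
            node.name = "" if sup is None else f"{sup:g}"
        buf = io.StringIO()
        annotated.write(buf)
        return buf.getvalue().strip()


def _resample_codons(alignment: CodonAlignment, rng: np.random.Generator) -> CodonAlignment:
    nc = alignment.n_codon_columns
    idx = rng.integers(0, nc, size=nc)
    rows = ["".join(r[3 * i : 3 * i + 3] for i in idx) for r in alignment.rows]
    return CodonAlignment(list(alignment.ids), rows)


def bootstrap(
    alignment: CodonAlignment,
    family_id: str = "",
    n_reps: int = 1000,
    seed: int = 0,
) -> FamilyTree:
    """NJ tree with codon-column bootstrap supports (percent of replicates).

    With ``n_reps = 0`` the tree is returned without supports.
    """
    d, labels = p_distance_matrix(alignment)
    tree = nj(d, labels)
    original = bipartitions(tree)
    ft = FamilyTree(family_id, tree, {}, n_reps)
    if n_reps <= 0:
        return ft
    counts = {b: 0 for b in original}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = _resample_codons(alignment, rng)
        dr, _ = p_distance_matrix(rep)
        rep_bip = bipartitions(nj(dr, labels))
        for b in original:
            if b in rep_bip:
                counts[b] += 1
    ft.supports = {b: 100.0 * c / n_reps for b, c in counts.items()}
    return ft


@dataclass(frozen=True)
class DuplicationEvent:
    family_id: str
    species: str
    genes: frozenset[str]
    support: float


def count_events(
    family_tree: FamilyTree,
    gene_species: dict[str, str],
    min_support: float = 50.0,
) -> list[DuplicationEvent]:
    """Species-specific duplication events in one family tree.

    Candidate clades are bipartition sides whose tips are >= 2 genes all of
    one species with support strictly above ``min_support``; maximal-first
    greedy selection keeps only disjoint maximal clades, so nested
    duplications are counted once and each gene contributes to one event.
    For a bipartition, both sides are examined (the tree is unrooted).
    """
    tips = frozenset(t.name for t in family_tree.tree.tips())
    candidates = []
    for canon, sup in family_tree.supports.items():
        if sup <= min_support:
            continue
        for side in (canon, tips - canon):
            if len(side) < 2:
                continue
            species = {gene_species[g] for g in side}
            if len(species) == 1:
                candidates.append((side, next(iter(species)), sup))
    candidates.sort(key=lambda c: (-len(c[0]), tuple(sorted(c[0]))))
    events: list[DuplicationEvent] = []
    used: set[str] = set()
    for side, sp, sup in candidates:
        if side & used:
            continue
        used |= side
        events.append(DuplicationEvent(family_tree.family_id, sp, frozenset(side), sup))
    return sorted(events, key=lambda e: tuple(sorted(e.genes)))
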