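"""Codon alignment and evolutionary statistics.

* Protein-guided codon alignment: CDSs are translated, the proteins are
  multiply aligned (MAFFT), and codons are threaded back through the
  protein alignment, so every gap is a whole codon column.
* Ka/Ks: Nei–Gojobori (1986) counting. Synonymous site fractions per codon
  come from the three possible changes at each position (changes to stop
  codons count as nonsynonymous); differences in multi-hit codons are
  averaged over all mutational pathways that avoid stop codons (all
  pathways if every one passes through a stop). Both proportions receive
  the Jukes–Cantor correction d = -3/4 ln(1 - 4/3 p). Pairs at or beyond
  saturation (p >= 3/4) are undefined and reported as such.
* Pi: average pairwise nucleotide difference per site over columns where
  neither row of the pair is gapped.
* Ks values below 1 are "retained" (beyond that synonymous sites approach
  saturation and the clock reading is unreliable); Ks histograms use 0.1
  bins on [0, 1).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from itertools import combinations, permutations
from math import log
from pathlib import Path
from statistics import median

import numpy as np
import pandas as pd
from scipy import stats as sps
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_AA = {c: str(Seq(c).translate()) for c in _CODONS}


class SaturationError(ValueError):
    """Synonymous or nonsynonymous proportion at or beyond 3/4."""


# ---------------------------------------------------------------------------
# codon alignment


@dataclass
class CodonAlignment:
    """Gap-extended CDS rows in a fixed order; gaps come in codon triplets."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1 or (self.rows and len(self.rows[0]) % 3 != 0):
            raise ValueError("rows must share one length divisible by 3")

    def row(self, gene_id: str) -> str:
        return self.rows[self.ids.index(gene_id)]

    @property
    def n_codon_columns(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def ungapped(self, gene_id: str) -> str:
        return self.row(gene_id).replace("-", "")


def translate_cds(cds: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    prot = str(Seq(cds).translate())
    if "*" in prot[:-1]:
        raise ValueError("internal stop codon; upstream validation failed")
    return prot[:-1] if prot.endswith("*") else prot


def _mafft_align(proteins: dict[str, str]) -> dict[str, str]:
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        inp.write_text("".join(f">{k}\n{v}\n" for k, v in proteins.items()))
        res = subprocess.run(
            ["mafft", "--quiet", "--auto", "--amino", str(inp)],
            capture_output=True, text=True, check=True,
        )
        out: dict[str, list[str]] = {}
        name = None
        for line in res.stdout.splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif name is not None:
                out[name].append(line.strip())
        return {k: "".join(v) for k, v in out.items()}


def codon_align(cds_by_id: dict[str, str]) -> CodonAlignment:
    """Protein-guided codon alignment of a set of CDSs.

    Ungapping any output row recovers its input CDS exactly.
    """
    ids = sorted(cds_by_id)
    if not ids:
        raise ValueError("empty CDS set")
    proteins = {g: translate_cds(cds_by_id[g]) for g in ids}
    if len(ids) == 1 or len({proteins[g] for g in ids}) == 1 and len({len(cds_by_id[g]) for g in ids}) == 1:
        # identical proteins (or a single sequence): alignment is the stack
        rows = [cds_by_id[g] for g in ids]
        if len({len(r) for r in rows}) == 1:
            return CodonAlignment(ids, rows)
    aligned_prot = _mafft_align(proteins)
    rows = []
    for g in ids:
        cds = cds_by_id[g]
        has_final_stop = len(cds) // 3 == len(proteins[g]) + 1
        codons = iter(cds[i : i + 3] for i in range(0, len(cds) - (3 if has_final_stop else 0), 3))
        row = "".join("---" if aa == "-" else next(codons) for aa in aligned_prot[g])
        if has_final_stop:
            row += cds[-3:]
        rows.append(row)
    # final stop codons may make rows unequal when some sequences lack one;
    # pad such rows with a gap codon at the end
    width = max(len(r) for r in rows)
    rows = [r + "-" * (width - len(r)) for r in rows]
    return CodonAlignment(ids, rows)


# ---------------------------------------------------------------------------
# NG86


def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in one codon (0..3).

    At each position, the fraction of the three possible single-base
    changes that preserve the amino acid; changes to stop codons count as
    nonsynonymous.
    """
    aa = _AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _AA[alt] != "*" and _AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


_SYN_SITES = {c: _syn_fraction(c) for c in _CODONS if _AA[c] != "*"}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between codons.

    Averages over all orders of applying the differing positions, skipping
    pathways that pass through a stop codon (using all pathways when every
    one is blocked).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _AA[nxt] == "*":
                through_stop = True
            if _AA[nxt] == _AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else results).append((sd, nd))
    use = results or blocked
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC-corrected distance; raises SaturationError at p >= 3/4."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4")
    return -0.75 * log(1.0 - 4.0 / 3.0 * p)


@dataclass
class GenePairStats:
    gene_a: str
    gene_b: str
    relation: str
    ka: float
    ks: float
    omega: float | None  # None when Ks == 0
    n_codons: int
    s_sites: float
    n_sites: float

    @property
    def retained(self) -> bool:
        return self.ks < 1.0


def ng86_counts(row_a: str, row_b: str) -> tuple[float, float, float, float, int]:
    """NG86 site and difference counts for two aligned CDS rows.

    Returns (S, N, sd, nd, n_codons) over codon columns where neither row
    has a gap (stop/ambiguous codon columns are also excluded pairwise).
    Symmetric in argument order.
    """
    if len(row_a) != len(row_b) or len(row_a) % 3 != 0:
        raise ValueError("rows must share one length divisible by 3")
    S = N = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3], row_b[i : i + 3]
        if "-" in ca or "-" in cb:
            continue
        if ca not in _SYN_SITES or cb not in _SYN_SITES:
            continue  # stop or ambiguous codon: excluded pairwise
        n_codons += 1
        S += (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        N += 3.0 - (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        s_i, n_i = _pathway_counts(ca, cb)
        sd += s_i
        nd += n_i
    if n_codons == 0:
        raise ValueError("no comparable codon columns")
    return S, N, sd, nd, n_codons


def ng86(row_a: str, row_b: str) -> tuple[float, float, float, float, float, float, int]:
    """NG86 distances for two aligned CDS rows.

    Returns (Ka, Ks, S, N, sd, nd, n_codons); raises SaturationError when
    either difference proportion reaches the JC domain boundary (3/4).
    """
    S, N, sd, nd, n_codons = ng86_counts(row_a, row_b)
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    return ka, ks, S, N, sd, nd, n_codons


def ka_ks(alignment: CodonAlignment, gene_a: str, gene_b: str, relation: str = "") -> GenePairStats:
    """NG86 Ka, Ks and their ratio for one pair of alignment rows."""
    ka, ks, S, N, _, _, n_codons = ng86(alignment.row(gene_a), alignment.row(gene_b))
    omega = ka / ks if ks > 0 else None
    return GenePairStats(gene_a, gene_b, relation, ka, ks, omega, n_codons, S, N)


# ---------------------------------------------------------------------------
# nucleotide diversity


def pair_p_distance(row_a: str, row_b: str) -> float:
    """Difference proportion over columns where neither row is gapped."""
    total = diff = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        total += 1
        if x != y:
            diff += 1
    if total == 0:
        raise ValueError("all columns gapped for this pair")
    return diff / total


def pi(alignment: CodonAlignment, gene_ids: list[str] | None = None) -> float:
    """Nucleotide diversity: mean pairwise difference proportion.

    Pi = 2 / (n (n-1)) * sum_{i<j} d_ij / L_ij over the selected rows.
    """
    ids = sorted(gene_ids) if gene_ids is not None else list(alignment.ids)
    if len(ids) < 2:
        raise ValueError("Pi needs at least two rows")
    vals = [pair_p_distance(alignment.row(a), alignment.row(b)) for a, b in combinations(ids, 2)]
    return float(np.mean(vals))


def mean_pairwise_distance(alignment: CodonAlignment, pairs: list[tuple[str, str]]) -> float:
    """Mean difference proportion over an explicit list of row pairs."""
    if not pairs:
        raise ValueError("no pairs given")
    return float(np.mean([pair_p_distance(alignment.row(a), alignment.row(b)) for a, b in pairs]))


# ---------------------------------------------------------------------------
# aggregation


def ks_histogram(ks_values: list[float], bin_width: float = 0.1, max_ks: float = 1.0) -> np.ndarray:
    """Counts per [i*w, (i+1)*w) bin; input must be retained values (< max)."""
    n_bins = int(round(max_ks / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    for v in ks_values:
        if not (0.0 <= v < max_ks):
            raise ValueError(f"Ks value {v} outside [0, {max_ks}); pass retained values only")
        counts[min(int(v // bin_width), n_bins - 1)] += 1
    return counts


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float


def compare_groups(values_a: list[float], values_b: list[float]) -> GroupComparison:
    """Welch two-sample t-test between two groups of statistics."""
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("both groups need >= 2 values")
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(float(t), float(p), float(a.mean()), float(b.mean()),
                           float(median(a)), float(median(b)))


def stats_to_frame(stats: list[GenePairStats]) -> pd.DataFrame:
    rows = [
        {"gene_a": s.gene_a, "gene_b": s.gene_b, "relation": s.relation,
         "ka": s.ka, "ks": s.ks,
         "omega": s.omega if s.omega is not None else np.nan,
         "retained": s.retained}
        for s in stats
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "relation", "ka", "ks", "omega", "retained"])
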