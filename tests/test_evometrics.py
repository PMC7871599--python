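"""Codon alignment, NG86 vs a brute-force all-pathways oracle, Pi, Welch."""

from __future__ import annotations

import math
from itertools import permutations, product

import numpy as np
import pytest
from Bio.Data import CodonTable

from youngdup.evometrics import (
    CodonAlignment,
    SaturationError,
    codon_align,
    compare_groups,
    ka_ks,
    ks_histogram,
    ng86,
    ng86_counts,
    pair_p_distance,
    pi,
)
from youngdup.simulate import mutate_cds, random_cds

# ---------------------------------------------------------------------------
# independent NG86 oracle built from Biopython's standard codon table

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
for stop in _TABLE.stop_codons:
    _AA[stop] = "*"
_BASES = "ACGT"


def oracle_syn_sites(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _AA[alt] != "*" and _AA[alt] == _AA[codon]:
                syn += 1
        total += syn / 3.0
    return total


def oracle_pathways(c1: str, c2: str) -> tuple[float, float]:
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in permutations(diff):
        cur, sd, nd, through_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _AA[nxt] == "*":
                through_stop = True
            if _AA[nxt] == _AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (clean if not through_stop else blocked).append((sd, nd))
    use = clean or blocked
    return (sum(x[0] for x in use) / len(use), sum(x[1] for x in use) / len(use))


def oracle_ng86(seq1: str, seq2: str):
    S = N = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if "-" in c1 or "-" in c2 or _AA.get(c1) in (None, "*") or _AA.get(c2) in (None, "*"):
            continue
        S += (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2
        N += 3 - (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2
        s_i, n_i = oracle_pathways(c1, c2)
        sd += s_i
        nd += n_i
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else None
    return S, N, sd, nd, jc(ps), jc(pn)


SENSE_CODONS = sorted(c for c in map("".join, product(_BASES, repeat=3)) if _AA[c] != "*")


# ---------------------------------------------------------------------------
# codon alignment


class TestCodonAlign:
    def test_identical_sequences_align_without_gaps(self):
        s = random_cds(300, np.random.default_rng(0))
        aln = codon_align({"x": s, "y": s})
        assert aln.rows == [s, s]

    def test_deleted_codon_gives_single_triplet_gap(self):
        s = random_cds(300, np.random.default_rng(1))
        deleted = s[:150] + s[153:]
        aln = codon_align({"full": s, "del": deleted})
        row = aln.row("del")
        assert row.count("-") == 3
        gap_start = row.index("-")
        assert row[gap_start:gap_start + 3] == "---"
        assert gap_start % 3 == 0

    def test_ungapping_recovers_inputs(self):
        rng = np.random.default_rng(2)
        s = random_cds(300, rng)
        seqs = {"a": s, "b": mutate_cds(s, 0.1, 3), "c": s[:90] + s[96:]}
        aln = codon_align(seqs)
        for gid, seq in seqs.items():
            assert aln.ungapped(gid) == seq

    def test_planted_pair_aligns_ungapped(self):
        s = random_cds(300, np.random.default_rng(4))
        aln = codon_align({"a": s, "b": mutate_cds(s, 0.02, 5)})
        assert "-" not in "".join(aln.rows)


# ---------------------------------------------------------------------------
# NG86


class TestNG86:
    def test_identical_rows_zero_distances(self):
        s = random_cds(300, np.random.default_rng(5))
        aln = CodonAlignment(["a", "b"], [s, s])
        stats = ka_ks(aln, "a", "b")
        assert stats.ka == 0.0 and stats.ks == 0.0
        assert stats.omega is None  # undefined at Ks = 0

    def test_single_synonymous_difference_matches_site_count_oracle(self):
        # one GCT->GCC synonymous change in a long identical context
        ctx = random_cds(300, np.random.default_rng(6))
        a = ctx + "GCT"
        b = ctx + "GCC"
        S, N, sd, nd, ks_exp, ka_exp = oracle_ng86(a, b)
        assert (sd, nd) == (1.0, 0.0)
        stats = ka_ks(CodonAlignment(["a", "b"], [a, b]), "a", "b")
        assert stats.ka == 0.0
        assert stats.ks == pytest.approx(ks_exp, abs=1e-12)
        assert stats.ks == pytest.approx(-0.75 * math.log(1 - 4 / (3 * S)), abs=1e-12)

    def test_exhaustive_single_codon_counts_equal_oracle(self):
        # strided here to keep the unit test quick; the acceptance test
        # sweeps all 61 x 61 codon pairs
        for c1 in SENSE_CODONS[::7]:
            for c2 in SENSE_CODONS[::5]:
                S, N, sd, nd, _ = ng86_counts(c1, c2)
                So, No, sdo, ndo, *_ = oracle_ng86(c1, c2)
                assert S == pytest.approx(So, abs=1e-12)
                assert N == pytest.approx(No, abs=1e-12)
                assert sd == pytest.approx(sdo, abs=1e-12)
                assert nd == pytest.approx(ndo, abs=1e-12)

    def test_random_long_pairs_equal_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            s = random_cds(300, rng)
            t = mutate_cds(s, rng.uniform(0.01, 0.3), int(rng.integers(2**31)))
            ka, ks, S, N, sd, nd, _ = ng86(s, t)
            So, No, sdo, ndo, ks_o, ka_o = oracle_ng86(s, t)
            assert ks == pytest.approx(ks_o, abs=1e-12)
            assert ka == pytest.approx(ka_o, abs=1e-12)

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(8)
        s = random_cds(300, rng)
        t = mutate_cds(s, 0.15, 9)
        assert ng86(s, t)[:2] == ng86(t, s)[:2]

    def test_saturation_raises(self):
        rng = np.random.default_rng(9)
        s = random_cds(3000, rng)
        t = random_cds(3000, rng)  # unrelated: proportions near 3/4
        with pytest.raises(SaturationError):
            ng86(s, t)

    def test_gapped_codon_columns_excluded(self):
        s = random_cds(30, np.random.default_rng(10))
        a = s
        b = s[:15] + "---" + s[18:]
        *_, n_cod = ng86(a, b)
        assert n_cod == 9


# ---------------------------------------------------------------------------
# Pi and aggregation


class TestPi:
    def test_closed_form_two_rows(self):
        a = "A" * 300
        b = "C" * 9 + "A" * 291
        aln = CodonAlignment(["a", "b"], [a, b])
        assert pi(aln) == pytest.approx(0.03)

    def test_identical_rows_zero(self):
        s = random_cds(90, np.random.default_rng(11))
        aln = CodonAlignment(list("abcd"), [s] * 4)
        assert pi(aln) == 0.0

    def test_four_rows_match_brute_force(self):
        rng = np.random.default_rng(12)
        s = random_cds(120, rng)
        rows = [mutate_cds(s, 0.1, k) for k in range(4)]
        aln = CodonAlignment(list("abcd"), rows)
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        exp = np.mean([
            sum(x != y for x, y in zip(rows[i], rows[j])) / len(s) for i, j in pairs
        ])
        assert pi(aln) == pytest.approx(float(exp), abs=1e-12)

    def test_gap_columns_excluded_per_pair(self):
        a = "AAA" + "CCC"
        b = "AAA" + "---"
        assert pair_p_distance(a, b) == 0.0


class TestKsHistogram:
    def test_boundaries_and_totals(self):
        counts = ks_histogram([0.0, 0.05, 0.1, 0.95, 0.9999])
        assert counts[0] == 2 and counts[1] == 1 and counts[9] == 2
        assert counts.sum() == 5

    def test_unretained_value_rejected(self):
        with pytest.raises(ValueError):
            ks_histogram([1.0])

    def test_counts_match_sort_oracle(self):
        rng = np.random.default_rng(13)
        vals = rng.uniform(0, 1, size=200)
        vals = vals[vals < 1.0]
        counts = ks_histogram(list(vals))
        expected = [((vals >= lo) & (vals < lo + 0.1)).sum() for lo in np.arange(0, 1, 0.1)]
        assert list(counts) == [int(e) for e in expected]


class TestCompareGroups:
    def test_identical_degenerate_groups_p_one(self):
        res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_matches_closed_form_welch(self):
        a = [2.1, 2.5, 2.3, 2.7]
        b = [1.1, 1.4, 1.0]
        res = compare_groups(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t = (ma - mb) / math.sqrt(va / len(a) + vb / len(b))
        assert res.t_statistic == pytest.approx(t)
        assert res.mean_a == pytest.approx(ma) and res.median_b == pytest.approx(np.median(b))

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        assert compare_groups(list(a), list(b)).p_value < 0.01
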