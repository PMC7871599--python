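"""Collinear-block chaining vs exhaustive oracle; duplication typing rules."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from youngdup.config import PipelineConfig
from youngdup.families import GeneFamily
from youngdup.genome_io import GeneModel, GenomeSet
from youngdup.orthology import HomologPair
from youngdup.synteny import (
    AnchorPair,
    CollinearBlock,
    classify_pair,
    classify_pairs,
    detect_blocks,
    type_summary,
)

KA = ("A", "chr1")
KB = ("B", "chr1")


def _anchors(pairs: list[tuple[int, int]], key_a=KA, key_b=KB) -> list[AnchorPair]:
    return [
        AnchorPair(f"a{ra}", f"b{rb}", key_a, key_b, ra, rb) for ra, rb in pairs
    ]


def exhaustive_best_chain(anchors, max_gap=25) -> int:
    """Oracle: longest valid chain by explicit enumeration (<= 12 anchors)."""
    best = 1 if anchors else 0
    idx = list(range(len(anchors)))
    for sign in (1, -1):
        order = sorted(idx, key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))

        def extend(chain):
            nonlocal best
            best = max(best, len(chain))
            last = chain[-1]
            for j in order:
                aj, al = anchors[j], anchors[last]
                if (
                    aj.rank_a > al.rank_a
                    and aj.rank_a - al.rank_a <= max_gap
                    and sign * (aj.rank_b - al.rank_b) > 0
                    and abs(aj.rank_b - al.rank_b) <= max_gap
                ):
                    extend(chain + [j])

        for i in idx:
            extend([i])
    return best


class TestDetectBlocks:
    def test_six_consecutive_anchors_one_block_same_orientation(self):
        anchors = _anchors([(i, i) for i in range(6)])
        blocks = detect_blocks(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert len(blocks[0].anchors) == 6

    def test_four_anchors_below_min_no_block(self):
        assert detect_blocks(_anchors([(i, i) for i in range(4)])) == []

    def test_inverted_segment_detected(self):
        anchors = _anchors([(i, 100 - i) for i in range(8)])
        blocks = detect_blocks(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"
        assert len(blocks[0].anchors) == 8

    def test_gap_constraint_breaks_chain(self):
        anchors = _anchors([(i, i) for i in range(5)] + [(100 + i, 100 + i) for i in range(5)])
        blocks = detect_blocks(anchors, min_anchors=5, max_gap=25)
        assert len(blocks) == 2  # the 100-rank jump cannot be chained

    def test_anchors_strictly_monotone_within_block(self):
        rng = np.random.default_rng(0)
        pairs = [(int(a), int(b)) for a, b in zip(
            rng.choice(60, 20, replace=False), rng.choice(60, 20, replace=False))]
        for blk in detect_blocks(_anchors(pairs), min_anchors=3):
            ra = [a.rank_a for a in blk.anchors]
            rb = [a.rank_b for a in blk.anchors]
            assert ra == sorted(ra) and len(set(ra)) == len(ra)
            assert rb == sorted(rb) or rb == sorted(rb, reverse=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_chain_length_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        pairs = [(int(a), int(b)) for a, b in zip(
            rng.choice(40, n, replace=False), rng.choice(40, n, replace=False))]
        anchors = _anchors(pairs)
        blocks = detect_blocks(anchors, min_anchors=1)
        assert len(blocks[0].anchors) == exhaustive_best_chain(anchors)


# ---------------------------------------------------------------------------
# duplication typing


def _genome_line(n: int, species="A", chrom="chr1", offset=0) -> list[GeneModel]:
    return [
        GeneModel(f"{species}{chrom}g{i}", species, chrom,
                  (offset + i) * 1000, (offset + i) * 1000 + 300, "+", "ATG" * 100)
        for i in range(n)
    ]


def test_adjacent_pair_is_tandem():
    gs = GenomeSet(_genome_line(10))
    pair = HomologPair("Achr1g7", "Achr1g8", "paralog", "og0")
    call = classify_pair(pair, gs, [])
    assert call.dup_type == "tandem"


def test_anchor_pair_inside_intraspecies_block_is_wgd():
    genes = _genome_line(10, chrom="chr1") + _genome_line(10, chrom="chr2")
    gs = GenomeSet(genes)
    anchors = [
        AnchorPair(f"Achr1g{i}", f"Achr2g{i}", ("A", "chr1"), ("A", "chr2"), i, i)
        for i in range(6)
    ]
    blocks = detect_blocks(anchors)
    pair = HomologPair("Achr1g3", "Achr2g3", "paralog", "og0")
    call = classify_pair(pair, gs, blocks)
    assert call.dup_type == "wgd"
    assert call.evidence == blocks[0].block_id


def test_asymmetric_block_support_is_transposed():
    genes = _genome_line(10, "A", "chr1") + _genome_line(10, "A", "chr2") \
        + _genome_line(10, "B", "chr1")
    gs = GenomeSet(genes)
    # A chr1 collinear with B chr1; the copy on A chr2 is not in any block
    anchors = [
        AnchorPair(f"Achr1g{i}", f"Bchr1g{i}", ("A", "chr1"), ("B", "chr1"), i, i)
        for i in range(6)
    ]
    blocks = detect_blocks(anchors)
    pair = HomologPair("Achr1g3", "Achr2g5", "paralog", "og0")
    assert classify_pair(pair, gs, blocks).dup_type == "transposed"
    # equal support (neither in a block) falls through to other
    pair2 = HomologPair("Achr1g8", "Achr2g1", "paralog", "og0")
    blocks_without = [b for b in blocks if False]
    assert classify_pair(pair2, gs, blocks_without).dup_type == "other"


def test_priority_wgd_over_tandem():
    genes = _genome_line(12)
    gs = GenomeSet(genes)
    # adjacent pair that is also an anchor of an intra-species block
    anchors = [
        AnchorPair(f"Achr1g{i}", f"Achr1g{i + 6}", ("A", "chr1"), ("A", "chr1"), i, i + 6)
        for i in range(6)
    ]
    blocks = detect_blocks(anchors)
    pair = HomologPair("Achr1g5", "Achr1g6", "paralog", "og0")  # adjacent AND an anchor?
    call = classify_pair(HomologPair("Achr1g0", "Achr1g6", "paralog", "og0"), gs, blocks)
    assert call.dup_type == "wgd"


def test_type_summary_counts_and_percentages():
    genes = _genome_line(10)
    gs = GenomeSet(genes)
    members = {f"Achr1g{i}": "A" for i in range(10)}
    fam = GeneFamily("fam0", members, is_young=True,
                     expansion=("species_specific", ("A",)))
    pairs = [HomologPair(f"Achr1g{2 * i}", f"Achr1g{2 * i + 1}", "paralog", "og")
             for i in range(5)]
    calls = classify_pairs(pairs, gs, [])
    assert all(c.dup_type == "tandem" for c in calls)
    summary = type_summary(calls, [fam])
    row = summary.iloc[0]
    assert row["total"] == 10 and row["tandem"] == 10
    assert row["tandem_pct"] == pytest.approx(100.0)
    assert row["tandem"] + row["transposed"] + row["wgd"] + row["other"] == row["total"]


def test_classify_pair_rejects_cross_species_pair():
    gs = GenomeSet(_genome_line(2, "A") + _genome_line(2, "B"))
    with pytest.raises(ValueError):
        classify_pair(HomologPair("Achr1g0", "Bchr1g0", "ortholog", "og"), gs, [])
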