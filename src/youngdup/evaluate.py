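"""Scoring a pipeline run against a simulation's truth ledger.

Used by the test suite and the reproduction script to measure family
recovery, expansion-label agreement and duplication-type recall on
synthetic genomes with planted events.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import PipelineResult
from .simulate import TruthLedger

_EVENT_TO_CALL = {"tandem": "tandem", "transposed": "transposed", "wgd_segment": "wgd"}


@dataclass
class FamilyRecovery:
    n_truth: int
    n_exact: int  # truth families recovered as an identical component
    n_label_checked: int
    n_label_match: int

    @property
    def recovery_rate(self) -> float:
        return self.n_exact / self.n_truth if self.n_truth else float("nan")

    @property
    def label_accuracy(self) -> float:
        return self.n_label_match / self.n_label_checked if self.n_label_checked else float("nan")


def score_families(result: PipelineResult, ledger: TruthLedger) -> FamilyRecovery:
    """Exact member-set recovery of ledger families, and expansion labels.

    A ledger family counts as recovered when some detected family has
    exactly its member set. Labels are compared on recovered families whose
    ledger expectation is a young expansion (species_specific or
    lineage_specific): the detected family must be flagged young and carry
    the same (kind, species-set) label.
    """
    detected = {f.member_ids: f for f in result.families}
    expected = ledger.expected_expansion
    n_exact = label_checked = label_match = 0
    for fam_id, members in ledger.family_member_sets().items():
        hit = detected.get(members)
        if hit is None:
            continue
        n_exact += 1
        kind, species = expected[fam_id]
        if kind == "none":
            continue
        label_checked += 1
        if hit.is_young and hit.expansion == (kind, tuple(species)):
            label_match += 1
    return FamilyRecovery(len(ledger.families), n_exact, label_checked, label_match)


@dataclass
class TypeRecovery:
    # per planted class: (n_pairs, n_called_correctly)
    per_class: dict[str, tuple[int, int]]
    confusion: dict[tuple[str, str], int]  # (truth, called) -> n

    def recall(self, event_type: str) -> float:
        n, ok = self.per_class.get(event_type, (0, 0))
        return ok / n if n else float("nan")


def score_duplication_types(result: PipelineResult, ledger: TruthLedger) -> TypeRecovery:
    """Confusion of planted event types vs duplication calls.

    Every planted (template, copy) leaf pair of every event is looked up in
    the pipeline's duplication calls; a missing call counts as "none".
    """
    call_by_pair = {frozenset((c.gene_a, c.gene_b)): c.dup_type for c in result.calls}
    per_class: dict[str, list[int]] = {}
    confusion: dict[tuple[str, str], int] = {}
    for ev in ledger.events:
        truth = _EVENT_TO_CALL[ev.event_type]
        for sp, (a, b) in ev.members.items():
            called = call_by_pair.get(frozenset((a, b)), "none")
            confusion[(truth, called)] = confusion.get((truth, called), 0) + 1
            tally = per_class.setdefault(truth, [0, 0])
            tally[0] += 1
            tally[1] += int(called == truth)
    return TypeRecovery({k: (v[0], v[1]) for k, v in per_class.items()}, confusion)
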