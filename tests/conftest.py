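"""Shared fixtures: a tiny two-species simulation for unit tests and the
full six-species study clade (session-scoped; feeds the recovery and
invariant tests)."""

from __future__ import annotations

import pytest

from youngdup.config import PipelineConfig
from youngdup.pipeline import run_pipeline
from youngdup.simulate import Event, SimConfig, make_demo_config, simulate

TINY_TREE = "((A:0.01,B:0.01)AB:0.02,C:0.03)root;"


def tiny_config(seed: int = 0, events: list[Event] | None = None, **kw) -> SimConfig:
    defaults = dict(
        species=["A", "B", "C"],
        tree=TINY_TREE,
        n_chromosomes=2,
        n_ancestral_genes=24,
        gene_length=300,
        events=events or [],
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture
def tiny_sim():
    """24 ancestral genes, 3 species, a handful of planted events."""
    events = [
        Event("A", "tandem", 0.02),
        Event("B", "transposed", 0.03),
        Event("AB", "tandem", 0.02),
        Event("A", "wgd_segment", 0.02, segment_length=6),
    ]
    cfg = tiny_config(seed=3, events=events)
    genome, ledger = simulate(cfg)
    return cfg, genome, ledger


@pytest.fixture(scope="session")
def clade():
    """The standard six-species clade: 200 ancestral genes, 60 events."""
    cfg = make_demo_config(seed=1)
    genome, ledger = simulate(cfg)
    return cfg, genome, ledger


@pytest.fixture(scope="session")
def clade_result(clade):
    """Full pipeline run on the standard clade (computed once per session)."""
    _, genome, _ = clade
    return run_pipeline(genome, PipelineConfig())
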