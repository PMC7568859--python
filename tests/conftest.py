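"""Shared fixtures: small models, a synthetic plastome, one full
planted-conflict analysis reused by the signal and acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import plastosig as ps
from plastosig.fit import FreeParams
from plastosig.signal import locuswise_delta, sorted_by_magnitude


@pytest.fixture(scope="session")
def jc_model():
    """Jukes-Cantor: uniform rates/frequencies, single rate category."""
    return ps.SubstitutionModel(n_categories=1, alpha=1.0)


@pytest.fixture(scope="session")
def synth_plastome():
    """Deterministic synthetic plastome with its true structure."""
    return ps.synth_plastome_record(seed=3)


@dataclass
class ConflictAnalysis:
    config: ps.ConflictSimConfig
    alignment: object
    partition: object
    truth: object
    matrix: object
    fits: dict
    winner: str
    runner: str
    table: object          # locuswise delta winner-vs-runner
    planted: set
    top_by_magnitude: object


def run_conflict_analysis(seed: int) -> ConflictAnalysis:
    """One planted-conflict dataset taken through fit + dissection."""
    cfg = ps.default_conflict_config(seed=seed, preset="reduced")
    aln, partition, truth = ps.simulate_conflict_dataset(cfg)
    free = FreeParams(branch_lengths=True, alpha=False, p_inv=False)
    matrix, fits = ps.fit_topologies(aln, ps.candidate_topologies(),
                                     model=cfg.model, free=free)
    totals = matrix.totals().sort_values(ascending=False)
    winner, runner = totals.index[0], totals.index[1]
    table = locuswise_delta(matrix, winner, runner, partition)
    planted = set(truth.loc[truth.source == "minority", "locus"])
    return ConflictAnalysis(cfg, aln, partition, truth, matrix, fits,
                            winner, runner, table, planted,
                            sorted_by_magnitude(table))


@pytest.fixture(scope="session")
def conflict_analysis():
    return run_conflict_analysis(seed=11)
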