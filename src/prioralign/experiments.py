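"""Parameter-recovery experiments composing the generator and the pipeline.

The score's generative reading predicts that running the assessment on a
landscape simulated with influence ``s`` returns a national score of ``s``
(in the small-parcel limit).  These helpers run that loop; they are used by
the validation suite, the acceptance script, and the examples.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .simulate import SimulationConfig, simulate
from .strata import AssessmentConfig, run_assessment


def single_state_config(
    influence: float,
    coverage: float,
    n_parcels: int,
    seed: int,
    state_size: float = 2000.0,
) -> SimulationConfig:
    """One-state landscape with a single global influence parameter."""
    return SimulationConfig(
        n_states=1,
        state_size=state_size,
        coverage=coverage,
        n_parcels=n_parcels,
        influence=influence,
        influence_easement=None,
        influence_fee=None,
        seed=seed,
    )


def national_score(cfg: SimulationConfig) -> float:
    """Generate a landscape and return the pipeline's national score.

    Runs the genuine pipeline stages (clip → dissolve → intersect → score)
    with the stratum/state/centroid bookkeeping switched off, since only
    the all-records national score is consumed.
    """
    landscape = simulate(cfg)
    report = run_assessment(
        landscape.lands,
        landscape.priorities,
        landscape.states,
        AssessmentConfig(strata=(), per_state=False, centroid_test=False),
    )
    return report.national.score


def replicate_seeds(base_seed: int, n_replicates: int) -> list[int]:
    """Deterministic per-replicate seeds (< 2**31) derived from one seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(child.generate_state(1, np.uint32)[0] % (2**31)) for child in ss.spawn(n_replicates)]


def mean_recovered_score(
    influence: float,
    coverage: float,
    n_parcels: int,
    seeds: list[int],
) -> float:
    """Mean national score over replicate landscapes at fixed conditions."""
    scores = [
        national_score(single_state_config(influence, coverage, n_parcels, seed))
        for seed in seeds
    ]
    return float(np.mean(scores))


def tenure_scores(cfg: SimulationConfig) -> dict[str, float]:
    """Per-tenure national scores from a full stratified assessment."""
    landscape = simulate(cfg)
    report = run_assessment(
        landscape.lands,
        landscape.priorities,
        landscape.states,
        AssessmentConfig(strata=("tenure",), per_state=False, centroid_test=False),
    )
    return {t: report.strata[t].score for t in ("easement", "fee")}


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return dataclasses.replace(cfg, seed=seed)
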