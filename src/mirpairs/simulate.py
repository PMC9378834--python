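"""Synthetic cohorts with stable control orderings and planted case reversals.

The generator emulates the regime the pair-classifier method assumes: each
miRNA has a fixed baseline (log2 scale) well separated from its neighbours, so
between-miRNA orderings are near-deterministic in controls, plus independent
per-sample log-normal noise.  A configurable number of *planted* pairs — both
miRNA-disjoint and adjacent in baseline rank — have their two values swapped
in a Bernoulli fraction of case samples, reversing exactly that pair's
ordering while leaving the marginal value distribution and every other pair
untouched.  A background flip rate applies the same swap mechanism at a low
rate to the non-planted adjacent pairs in both cohorts, modelling the
occasional ordering violations real control cohorts show.

Everything is driven by one integer seed; identical configs produce
bit-identical matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    LabelMap,
    OrientedPair,
    write_expression_matrix,
    write_labels,
)

__all__ = ["SimConfig", "SimTruth", "generate_cohorts", "recount_truth", "write_simulation"]

# baselines must clear the noise by this many SDs of a pairwise difference,
# else near-neighbour orderings are not reliably stable and the config is rejected
_MIN_SEPARATION_SDS = 4.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated case/control pair of cohorts.

    Defaults are the recovery-benchmark conditions used throughout the test
    suite: 200 miRNAs, 200 controls, 100 cases, 20 planted reversed pairs at a
    case reversal rate of 0.9 with a 2% background ordering-flip rate.
    ``baseline_spread`` and ``noise_sd`` are on the log2 scale; the default
    gap of 0.5 is ten noise SDs, a well-separated microarray-like regime.
    """

    n_mirnas: int = 200
    n_controls: int = 200
    n_cases: int = 100
    baseline_spread: float = 0.5
    noise_sd: float = 0.05
    n_planted: int = 20
    reversal_rate_cases: float = 0.9
    background_flip_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_mirnas < 2 or self.n_controls < 1 or self.n_cases < 1:
            raise ValueError("need at least 2 miRNAs and 1 sample per cohort")
        if not (0 <= self.n_planted <= self.n_mirnas // 2):
            raise ValueError(
                "planted pairs are miRNA-disjoint: require n_planted <= n_mirnas/2"
            )
        for name in ("reversal_rate_cases", "background_flip_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_spread <= 0 or self.noise_sd < 0:
            raise ValueError("baseline_spread must be > 0 and noise_sd >= 0")
        min_spread = _MIN_SEPARATION_SDS * math.sqrt(2.0) * self.noise_sd
        if self.baseline_spread < min_spread:
            raise ValueError(
                "infeasible config: stable orderings require "
                f"baseline_spread >= {_MIN_SEPARATION_SDS}*sqrt(2)*noise_sd "
                f"({min_spread:.4g}), got {self.baseline_spread}"
            )


@dataclass(frozen=True)
class SimTruth:
    """Planted pairs (control orientation) and their realized reversal fractions."""

    planted_pairs: tuple[OrientedPair, ...]
    case_reversal: Mapping[tuple[str, str], float] = field(default_factory=dict)
    control_reversal: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "case_reversal", dict(self.case_reversal))
        object.__setattr__(self, "control_reversal", dict(self.control_reversal))

    @property
    def planted_keys(self) -> set[tuple[str, str]]:
        return {p.key for p in self.planted_pairs}


def _simulate_cohort(
    rng: np.random.Generator,
    mu: np.ndarray,
    n_samples: int,
    noise_sd: float,
    flip_rates: np.ndarray,
    slot_pairs: np.ndarray,
) -> np.ndarray:
    """Log2 matrix: baselines + noise, then per-sample swaps of slot pairs."""
    M = mu.shape[0]
    log2 = mu[:, None] + rng.normal(0.0, noise_sd, size=(M, n_samples))
    for (hi, lo), rate in zip(slot_pairs, flip_rates):
        if rate <= 0:
            continue
        flip = rng.random(n_samples) < rate
        if flip.any():
            tmp = log2[hi, flip].copy()
            log2[hi, flip] = log2[lo, flip]
            log2[lo, flip] = tmp
    return log2


def generate_cohorts(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Draw a control cohort, a case cohort, and the planted ground truth.

    Returns (controls, cases, truth).  The truth's reversal fractions are the
    *realized* per-pair fractions recounted directly from the emitted
    matrices, so :func:`recount_truth` reproduces them exactly.
    """
    rng = np.random.default_rng(config.seed)
    M = config.n_mirnas
    ids = [f"mir-{i + 1:04d}" for i in range(M)]

    # random assignment of miRNA ids to baseline ranks, so id order carries
    # no information about expression level
    rank_of = rng.permutation(M)  # rank_of[i] = baseline rank of miRNA i
    mu = rank_of * config.baseline_spread

    # disjoint adjacent-rank slot pairs (2k, 2k+1); planted ones drawn at random
    id_at_rank = np.argsort(rank_of)
    n_slots = M // 2
    slots = np.arange(n_slots)
    planted_slots = set(rng.choice(n_slots, size=config.n_planted, replace=False).tolist())

    slot_pairs = np.array(
        [[id_at_rank[2 * k + 1], id_at_rank[2 * k]] for k in slots]
    )  # (hi, lo) row indices per slot
    control_rates = np.full(n_slots, config.background_flip_rate)
    case_rates = np.array(
        [
            config.reversal_rate_cases if k in planted_slots else config.background_flip_rate
            for k in slots
        ]
    )

    log2_controls = _simulate_cohort(
        rng, mu, config.n_controls, config.noise_sd, control_rates, slot_pairs
    )
    log2_cases = _simulate_cohort(
        rng, mu, config.n_cases, config.noise_sd, case_rates, slot_pairs
    )

    controls = ExpressionMatrix.from_arrays(
        ids, [f"ctrl-{j + 1:04d}" for j in range(config.n_controls)], 2.0 ** log2_controls
    )
    cases = ExpressionMatrix.from_arrays(
        ids, [f"case-{j + 1:04d}" for j in range(config.n_cases)], 2.0 ** log2_cases
    )

    planted = tuple(
        sorted(
            (
                OrientedPair(ids[slot_pairs[k][0]], ids[slot_pairs[k][1]])
                for k in sorted(planted_slots)
            ),
            key=lambda p: (p.a, p.b),
        )
    )
    truth = recount_truth(controls, cases, SimTruth(planted))
    return controls, cases, truth


def _reversal_fraction(matrix: ExpressionMatrix, pair: OrientedPair) -> float:
    return float(np.mean(matrix.row(pair.a) < matrix.row(pair.b)))


def recount_truth(
    controls: ExpressionMatrix, cases: ExpressionMatrix, truth: SimTruth
) -> SimTruth:
    """Recompute realized reversal fractions of the planted pairs by direct count."""
    return SimTruth(
        planted_pairs=truth.planted_pairs,
        case_reversal={p.key: _reversal_fraction(cases, p) for p in truth.planted_pairs},
        control_reversal={p.key: _reversal_fraction(controls, p) for p in truth.planted_pairs},
    )


def write_simulation(
    config: SimConfig, out_dir: str | Path
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Generate cohorts and write controls/cases/labels/truth files to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    controls, cases, truth = generate_cohorts(config)
    write_expression_matrix(controls, out / "controls.tsv")
    write_expression_matrix(cases, out / "cases.tsv")
    labels = {sid: CONTROL for sid in controls.sample_ids}
    labels.update({sid: CASE for sid in cases.sample_ids})
    write_labels(LabelMap(labels), out / "labels.tsv")
    pd.DataFrame(
        {
            "a": [p.a for p in truth.planted_pairs],
            "b": [p.b for p in truth.planted_pairs],
            "case_reversal": [truth.case_reversal[p.key] for p in truth.planted_pairs],
            "control_reversal": [truth.control_reversal[p.key] for p in truth.planted_pairs],
        }
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    return controls, cases, truth
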