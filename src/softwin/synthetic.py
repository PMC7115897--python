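"""Synthetic phenotyping data.

Two generators drive every test and validation in the package:

* a piecewise-linear time series (a short signal whose slope is only active
  in a middle segment), used to demonstrate that windowed regression
  recovers a locally valid coefficient a global fit cannot see; and
* an IMPC-style longitudinal cohort: a large control group accumulating
  over months-to-years with day-level batch structure, optional eras with
  shifted mean or inflated variance, and a small mutant group measured in a
  couple of batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import PhenotypeDataset
from .errors import ConfigError

__all__ = [
    "PiecewiseSimConfig",
    "DriftSegment",
    "CohortSimConfig",
    "simulate_piecewise",
    "simulate_cohort",
    "inject_genotype_effect",
]


@dataclass(frozen=True)
class PiecewiseSimConfig:
    """Piecewise-linear simulation: ``y_t = t * beta_j + e`` per segment.

    Segment boundaries follow the convention ``t <= b1`` (segment 1),
    ``b1 < t < b2`` (segment 2), ``t >= b2`` (segment 3).  Defaults: 60 time
    points, breakpoints (20, 40), betas (0, 1, 0), unit noise.
    """

    n: int = 60
    breakpoints: tuple = (20, 40)
    betas: tuple = (0.0, 1.0, 0.0)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        b1, b2 = self.breakpoints
        if not (0 < b1 < b2 < self.n):
            raise ConfigError("breakpoints must satisfy 0 < b1 < b2 < n")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def simulate_piecewise(config: PiecewiseSimConfig | None = None):
    """Simulate the piecewise model; returns ``(t, y)`` with ``t = 1..n``."""
    config = config or PiecewiseSimConfig()
    rng = np.random.default_rng(config.seed)
    t = np.arange(1, config.n + 1, dtype=float)
    b1, b2 = config.breakpoints
    beta = np.where(t <= b1, config.betas[0], np.where(t < b2, config.betas[1], config.betas[2]))
    y = t * beta + rng.normal(0.0, config.noise_sd, size=config.n)
    return t, y


@dataclass(frozen=True)
class DriftSegment:
    """An era ``[start, end)`` (days) with altered control behaviour."""

    start: float
    end: float
    mean_shift: float = 0.0
    var_mult: float = 1.0

    def __post_init__(self):
        if not self.start < self.end:
            raise ConfigError("segment needs start < end")
        if self.var_mult <= 0:
            raise ConfigError("var_mult must be > 0")


@dataclass(frozen=True)
class CohortSimConfig:
    """IMPC-style cohort simulation.

    Defaults echo the production setting at desk-runnable cost: 1500
    controls accumulating over two years (one batch per calendar day,
    roughly two controls a day), 14 mutants measured in two batches a week
    apart, day-level random batch effects, a mild sex effect and a
    body-weight covariate that grows linearly with the measurement date.
    ``heavy_tails`` switches the noise to a t distribution (df 3) for
    procedures with outlier-prone parameters.
    """

    n_controls: int = 1500
    n_mutants: int = 14
    span_days: float = 730.0
    drift_segments: tuple = ()
    mutant_batch_days: tuple | None = None
    baseline: float = 10.0
    noise_sd: float = 1.0
    batch_sd: float = 0.25
    sex_effect: float = 0.25
    weight_effect: float = 0.05
    sex_ratio: float = 0.5
    heavy_tails: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 1 or self.n_mutants < 1:
            raise ConfigError("need at least one control and one mutant")
        days = self.resolved_mutant_days()
        if self.n_mutants < len(days):
            raise ConfigError(
                f"{self.n_mutants} mutants cannot fill {len(days)} mutant batches"
            )
        if any(d < 0 or d > self.span_days for d in days):
            raise ConfigError("mutant batch days must lie inside the time span")
        segs = [DriftSegment(*s) if not isinstance(s, DriftSegment) else s
                for s in self.drift_segments]
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ConfigError("drift segments must be non-overlapping and sorted")
        object.__setattr__(self, "drift_segments", tuple(segs))

    def resolved_mutant_days(self) -> tuple:
        """Mutant batch days; default two batches a week apart at ~60% of the span."""
        if self.mutant_batch_days is not None:
            return tuple(float(d) for d in self.mutant_batch_days)
        anchor = round(0.6 * self.span_days)
        return (float(anchor), float(min(anchor + 7, self.span_days)))


def _segment_adjust(days: np.ndarray, segments) -> tuple:
    shift = np.zeros(days.shape)
    scale = np.ones(days.shape)
    for seg in segments:
        inside = (days >= seg.start) & (days < seg.end)
        shift[inside] += seg.mean_shift
        scale[inside] *= np.sqrt(seg.var_mult)
    return shift, scale


def simulate_cohort(config: CohortSimConfig | None = None) -> PhenotypeDataset:
    """Simulate a control/mutant cohort as a :class:`PhenotypeDataset`."""
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed)
    span = int(round(config.span_days))

    control_days = rng.integers(0, span + 1, size=config.n_controls).astype(float)
    mutant_days_pool = config.resolved_mutant_days()
    # spread mutants as evenly as the group size allows over their batches
    reps = np.array_split(np.arange(config.n_mutants), len(mutant_days_pool))
    mutant_days = np.concatenate(
        [np.full(len(chunk), day) for chunk, day in zip(reps, mutant_days_pool)]
    )

    days = np.concatenate([control_days, mutant_days])
    n = len(days)
    group = np.array(["control"] * config.n_controls + ["mutant"] * config.n_mutants)
    sex = np.where(rng.random(n) < config.sex_ratio, "M", "F")

    body_weight = (
        25.0
        + 3.0 * (sex == "M")
        + 0.004 * days
        + rng.normal(0.0, 1.5, size=n)
    )

    all_days = np.unique(days)
    batch_effects = dict(zip(all_days, rng.normal(0.0, config.batch_sd, len(all_days))))
    batch_term = np.array([batch_effects[d] for d in days])

    if config.heavy_tails:
        noise = rng.standard_t(3, size=n) / np.sqrt(3.0)  # unit-variance t3
    else:
        noise = rng.normal(0.0, 1.0, size=n)

    shift, scale = _segment_adjust(days, config.drift_segments)
    response = (
        config.baseline
        + shift
        + batch_term
        + config.sex_effect * (sex == "M")
        + config.weight_effect * (body_weight - 27.0)
        + config.noise_sd * scale * noise
    )

    frame = pd.DataFrame(
        {
            "time": days,
            "response": response,
            "group": group,
            "sex": sex,
            "body_weight": body_weight,
            "batch": np.char.add("d", days.astype(int).astype(str)),
        }
    ).sort_values("time", kind="stable")
    return PhenotypeDataset(frame.reset_index(drop=True))


def control_residual_sd(data: PhenotypeDataset) -> float:
    """Pooled SD of control responses around their batch means.

    Depends only on the control rows, so shifting the mutant group leaves it
    unchanged.
    """
    ctrl = data.data[data.is_control]
    centered = ctrl["response"] - ctrl.groupby("batch")["response"].transform("mean")
    counts = ctrl.groupby("batch")["response"].transform("size")
    mask = counts > 1  # singleton batches carry no within-batch information
    if mask.sum() < 2:
        return float(ctrl["response"].std(ddof=1))
    n_obs = int(mask.sum())
    n_batches = ctrl.loc[mask, "batch"].nunique()
    dof = max(n_obs - n_batches, 1)
    return float(np.sqrt((centered[mask] ** 2).sum() / dof))


def inject_genotype_effect(data: PhenotypeDataset, delta: float) -> PhenotypeDataset:
    """Shift mutant responses by ``delta`` control residual SDs.

    Controls are untouched, so applying ``delta=a`` then ``delta=b`` equals a
    single ``delta=a+b`` injection.
    """
    out = data.copy()
    if delta == 0:
        return out
    sd = control_residual_sd(data)
    out.data.loc[out.is_mutant, "response"] += delta * sd
    return out
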