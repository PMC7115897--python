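"""Structured resampling and the false-positive comparison experiment.

Mutant groups in long-running phenotyping studies are not random draws in
time: littermates are phenotyped close together in a handful of batches.
Structured resampling preserves exactly that pattern when building
*artificial mutants* from the control pool — the true mutant measurement
offsets are slid to a uniformly random origin inside the control time span
and, for each shifted target time, the temporally closest unused control is
relabelled as mutant.  Because the relabelled animals are genuine controls,
every significant genotype effect on a resampled dataset is a false
positive, so comparing windowed against non-windowed analyses on many
resamples measures what the window buys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import PhenotypeDataset
from .errors import InfeasibleSlideError, MissingGroupError
from .tuning import GridConfig, soft_window_pipeline

logger = logging.getLogger("softwin.resampling")

__all__ = [
    "MutantStructure",
    "FPResult",
    "extract_structure",
    "structured_resample",
    "fp_experiment",
    "relative_change",
]


@dataclass(frozen=True)
class MutantStructure:
    """Temporal pattern of a mutant group.

    ``offsets`` are the measurement times relative to the first mutant
    measurement (sorted, starting at 0, one entry per animal).
    """

    offsets: np.ndarray

    def __post_init__(self):
        offsets = np.sort(np.asarray(self.offsets, dtype=float))
        if offsets.size < 1:
            raise MissingGroupError("a mutant structure needs at least one offset")
        offsets = offsets - offsets[0]
        object.__setattr__(self, "offsets", offsets)

    @property
    def group_size(self) -> int:
        return len(self.offsets)

    @property
    def span(self) -> float:
        return float(self.offsets[-1])

    def offset_counts(self) -> dict:
        vals, counts = np.unique(self.offsets, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def extract_structure(data: PhenotypeDataset) -> MutantStructure:
    """Read the mutant measurement-time pattern off a dataset."""
    data.require_mutants()
    return MutantStructure(offsets=data.mutant_times)


def structured_resample(
    data: PhenotypeDataset,
    structure: MutantStructure | None = None,
    rng: np.random.Generator | int | None = None,
) -> PhenotypeDataset:
    """Build an artificial-mutant dataset from the control pool.

    True mutants are excluded from the output.  A random origin is drawn
    uniformly so the whole shifted structure fits inside the control time
    span; each shifted target time claims the closest not-yet-taken control
    (distance ties broken uniformly at random), which is then relabelled
    ``mutant``.  Relabelled controls keep their true batch, so the day-level
    random-effect structure is replicated, not invented.
    """
    structure = structure or extract_structure(data)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    controls = data.controls_only()
    ctimes = controls.times
    t_lo, t_hi = float(ctimes.min()), float(ctimes.max())
    if structure.span > t_hi - t_lo:
        raise InfeasibleSlideError(
            f"structure span {structure.span:.1f} exceeds control span {t_hi - t_lo:.1f}"
        )
    if structure.group_size > len(controls):
        raise InfeasibleSlideError("not enough controls to relabel")

    origin = rng.uniform(t_lo, t_hi - structure.span)
    targets = origin + structure.offsets

    taken = np.zeros(len(controls), dtype=bool)
    chosen = []
    for target in targets:
        dist = np.abs(ctimes - target)
        dist[taken] = np.inf
        best = dist.min()
        candidates = np.flatnonzero(dist == best)
        pick = int(candidates[0]) if len(candidates) == 1 else int(rng.choice(candidates))
        taken[pick] = True
        chosen.append(pick)

    frame = controls.data.copy()
    frame.loc[frame.index[chosen], "group"] = "mutant"
    return PhenotypeDataset(frame)


def relative_change(nfp: int, wfp: int) -> float:
    """Relative percentage change of false positives, ``(WFP/(NFP+WFP))*100``.

    NaN when neither arm produced any false positive.
    """
    total = nfp + wfp
    if total == 0:
        return float("nan")
    return 100.0 * wfp / total


@dataclass
class FPResult:
    """Aggregate false-positive comparison between the two analysis arms."""

    n_tests: int
    nfp: int  # false positives, non-windowed arm
    wfp: int  # false positives, windowed arm
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def relative_change(self) -> float:
        return relative_change(self.nfp, self.wfp)


def fp_experiment(
    datasets,
    repeats: int = 5,
    alpha: float = 1e-4,
    rng_seed: int = 0,
    config: GridConfig | None = None,
) -> FPResult:
    """Run the windowed-vs-non-windowed false-positive comparison.

    For every dataset and every repeat, an artificial-mutant dataset is
    drawn by structured resampling and analysed twice — once non-windowed,
    once through the full soft-window pipeline — and a genotype p-value
    below ``alpha`` counts as a false positive for that arm.  Per-dataset
    failures are logged and skipped, never fatal.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    nfp = wfp = n_tests = 0
    for d_idx, data in enumerate(datasets):
        try:
            structure = extract_structure(data)
        except MissingGroupError as exc:
            logger.warning("dataset %d skipped: %s", d_idx, exc)
            continue
        for rep in range(repeats):
            try:
                artificial = structured_resample(data, structure, rng)
                result = soft_window_pipeline(artificial, config)
            except Exception as exc:  # noqa: BLE001 - robustness contract
                logger.warning("dataset %d repeat %d skipped: %s", d_idx, rep, exc)
                continue
            p_non = result.nonwindowed.genotype_p
            p_win = result.windowed.genotype_p
            fp_non = bool(np.isfinite(p_non) and p_non < alpha)
            fp_win = bool(np.isfinite(p_win) and p_win < alpha)
            nfp += fp_non
            wfp += fp_win
            n_tests += 1
            rows.append(
                {
                    "dataset": d_idx,
                    "repeat": rep,
                    "p_nonwindowed": p_non,
                    "p_windowed": p_win,
                    "fp_nonwindowed": fp_non,
                    "fp_windowed": fp_win,
                    "l_star": result.selection.l_star,
                    "k_star": result.selection.k_star,
                    "fallback": result.selection.fallback,
                }
            )
    return FPResult(n_tests=n_tests, nfp=nfp, wfp=wfp, records=pd.DataFrame(rows))
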