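"""Automatic selection of the window bandwidth and shape.

The bandwidth ``l`` is expanded along a logarithmic grid of admissible
candidates (sum-of-weights score at least ``T``).  At each expansion the
phenotyping model is refitted with the candidate weights; the residuals of
the newly admitted observations (accumulated across steps until at least
three are available) are compared against the residuals of the observations
admitted earlier — a Welch t-test for a mean change and a two-sided
variance-ratio F-test for a variance change, both computed from the current
fit.  The selected bandwidth is the grid value immediately before the
earliest change that survives a Bonferroni correction over all performed
tests; when no change is ever declared the largest admissible bandwidth is
kept (all data effectively included).

The shape ``k`` is then tuned at the fixed ``l*`` by scanning from the
hardest admissible shape towards softer ones and stopping before the first
significant change in the within-support residual set; if nothing fires the
admissible value nearest the geometric midpoint of the shape range is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import PhenotypeDataset
from .errors import InsufficientDataError, InvalidParameterError
from .models import (
    ALL_TERMS,
    ModelFit,
    build_design,
    weighted_mixed_fit,
)
from .windows import (
    WeightVector,
    count_hard,
    generate_weights,
    hard_window,
    merge_peak_days,
    sws,
    wgf,
)

logger = logging.getLogger("softwin.tuning")

__all__ = [
    "GridConfig",
    "SelectionResult",
    "PipelineResult",
    "SensitivityResult",
    "default_T",
    "log_spaced_grid",
    "change_scores",
    "select_bandwidth",
    "select_shape",
    "soft_window_pipeline",
    "sensitivity_over_T",
]


def default_T(n: int, p: int) -> float:
    """Default minimum sum-of-weights threshold.

    Single peak: ``max(35, pi * sqrt(n))``; multiple peaks: ``35 * p``.
    Inspired by the z-test minimal sample size (n > 30).  A threshold above
    the sample size is unsatisfiable; the pipeline then proceeds
    non-windowed with a warning rather than clipping the formula.
    """
    if n < 1 or p < 1:
        raise InvalidParameterError("n and p must be >= 1")
    if p == 1:
        return float(max(35.0, np.pi * np.sqrt(n)))
    return float(35.0 * p)


def log_spaced_grid(lo: float, hi: float, count: int) -> np.ndarray:
    """Strictly increasing geometric grid including both endpoints."""
    if not (0 < lo < hi):
        raise InvalidParameterError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if count < 2:
        raise InvalidParameterError("count must be >= 2")
    return np.geomspace(lo, hi, count)


def change_scores(prev_residuals, curr_residuals):
    """(t p-value, F p-value) for a change between consecutive residual sets.

    Mean change: Welch two-sample t-test.  Variance change: two-sided
    variance-ratio F-test.  Identical sets give p-values of 1.
    """
    prev = np.asarray(prev_residuals, dtype=float)
    curr = np.asarray(curr_residuals, dtype=float)
    if prev.size < 3 or curr.size < 3:
        raise InsufficientDataError("each residual set needs at least 3 values")
    v_prev, v_curr = np.var(prev, ddof=1), np.var(curr, ddof=1)
    if v_prev == 0 and v_curr == 0:
        t_p = 1.0 if np.mean(prev) == np.mean(curr) else 0.0
        return t_p, 1.0
    t_p = float(stats.ttest_ind(prev, curr, equal_var=False).pvalue)
    if v_prev == 0 or v_curr == 0:
        f_p = 0.0
    else:
        f = v_curr / v_prev
        cdf = stats.f.cdf(f, curr.size - 1, prev.size - 1)
        f_p = float(2 * min(cdf, 1 - cdf))
    if np.isnan(t_p):  # identical constant sets
        t_p = 1.0
    return t_p, f_p


@dataclass(frozen=True)
class GridConfig:
    """Grids, thresholds and options of the tuning search.

    ``n_l`` bandwidth candidates are log-spaced from ``l_min`` (days) to the
    total experiment time range; ``n_k`` shape candidates are log-spaced over
    ``(k_lo, k_hi)`` (1/days).  ``T`` overrides the default minimum
    sum-of-weights threshold.  ``k_during_l`` is the shape held fixed while
    the bandwidth is searched.  ``use_predictions`` switches the change tests
    from residuals to fitted values.
    """

    n_l: int = 500
    n_k: int = 50
    l_min: float = 1.0
    k_lo: float = 0.5
    k_hi: float = 10.0
    T: float | None = None
    test_alpha: float = 0.05
    k_during_l: float = 2.0
    direction: str = "expanding"
    use_predictions: bool = False
    family: str = "logistic"
    terms: tuple = ALL_TERMS
    #: peaks closer than this (days) count as one window when sizing T
    peak_cluster_gap: float = 7.0

    def l_grid(self, span: float) -> np.ndarray:
        return log_spaced_grid(min(self.l_min, span / 2), span, self.n_l)

    def k_grid(self) -> np.ndarray:
        return log_spaced_grid(self.k_lo, self.k_hi, self.n_k)


@dataclass
class SelectionResult:
    """Outcome of the (l, k) grid search."""

    l_star: float | None
    k_star: float | None
    scores: pd.DataFrame
    final_weights: WeightVector | None
    admissible_l: np.ndarray
    admissible_k: np.ndarray
    T: float
    peaks: np.ndarray
    fallback: bool = False
    notes: list = field(default_factory=list)


def _fast_weighted_residuals(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Residuals of the weighted least-squares fit, via lstsq on scaled rows."""
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return y - X @ beta


def _fast_weighted_fitted(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return X @ beta


_MIN_TEST_SIZE = 3  # smallest residual set a t/F test will accept


def _design_arrays(data: PhenotypeDataset, config: GridConfig):
    X, _, _ = build_design(data, config.terms)
    extract = _fast_weighted_fitted if config.use_predictions else _fast_weighted_residuals
    return X.to_numpy(), data.response, extract


def _scan_bandwidth(data, peaks, grid, T, config):
    """Expanding bandwidth scan with new-vs-admitted change tests.

    Returns ``(records DataFrame, admissible values, l_star)``.  Each test
    compares the residuals of observations newly entering the hard-window
    support (pooled across steps until at least three are available) against
    the residuals of the previously admitted support, both taken from the
    fit at the current step.  The stop point is the earliest test whose
    smaller p-value beats ``test_alpha`` Bonferroni-corrected over all
    performed tests (two per step); ``l*`` reverts to the last bandwidth
    before the offending admissions began.
    """
    Xm, y, extract = _design_arrays(data, config)
    times = data.times

    records, admissible = [], []
    base_mask = None  # admitted-and-vetted support
    pending_start = None  # index (into admissible) where untested admissions began
    tests = []  # (record row index, revert index into admissible, t_p, f_p)
    for v in grid:
        wv = wgf(times, v, config.k_during_l, peaks, config.family)
        score = sws(wv)
        ok = score >= T
        row = {
            "phase": "l",
            "value": float(v),
            "sws": score,
            "admissible": ok,
            "n_support": np.nan,
            "n_new": np.nan,
            "t_p": np.nan,
            "f_p": np.nan,
            "breakpoint": False,
        }
        if ok:
            idx = len(admissible)
            admissible.append(float(v))
            support = hard_window(times, peaks, v).astype(bool)
            row["n_support"] = int(support.sum())
            if base_mask is None:
                base_mask = support
            else:
                new_mask = support & ~base_mask
                if new_mask.any() and pending_start is None:
                    pending_start = idx
                # block size grows with the vetted support so each test keeps
                # power on fine grids where one step admits only a few points
                min_block = max(_MIN_TEST_SIZE, int(np.ceil(0.05 * base_mask.sum())))
                if new_mask.sum() >= min_block and base_mask.sum() >= _MIN_TEST_SIZE:
                    resid = extract(Xm, y, wv.weights)
                    row["n_new"] = int(new_mask.sum())
                    row["t_p"], row["f_p"] = change_scores(
                        resid[base_mask], resid[new_mask]
                    )
                    tests.append((len(records), pending_start, row["t_p"], row["f_p"]))
                    base_mask = support
                    pending_start = None
        records.append(row)
    df = pd.DataFrame.from_records(records)

    l_star = admissible[-1] if admissible else None
    if tests:
        threshold = config.test_alpha / (2 * len(tests))
        for rec_idx, revert_idx, t_p, f_p in tests:
            if min(t_p, f_p) < threshold:
                df.loc[rec_idx, "breakpoint"] = True
                l_star = admissible[max(revert_idx - 1, 0)]
                break
    return df, np.asarray(admissible), l_star


def _scan_shape(data, peaks, l_star, k_values, T, config):
    """Hard-to-soft shape scan with consecutive full-set change tests.

    ``k_values`` must be increasing; the scan walks them from the hardest
    end.  Returns ``(records DataFrame, admissible values, k_star)``;
    ``k_star`` is None when no admissible value exists.
    """
    Xm, y, extract = _design_arrays(data, config)
    times = data.times
    support = hard_window(times, peaks, l_star).astype(bool)

    admissible = []
    rows = {}
    for v in k_values:
        wv = wgf(times, l_star, v, peaks, config.family)
        score = sws(wv)
        rows[float(v)] = {
            "phase": "k",
            "value": float(v),
            "sws": score,
            "admissible": score >= T,
            "n_support": int(support.sum()),
            "n_new": np.nan,
            "t_p": np.nan,
            "f_p": np.nan,
            "breakpoint": False,
        }
        if score >= T:
            admissible.append(float(v))
    admissible = np.asarray(admissible)

    k_star = None
    tests = []
    if admissible.size:
        prev = None
        order = admissible[::-1]  # hardest first
        if support.sum() >= _MIN_TEST_SIZE:
            for v in order:
                wv = wgf(times, l_star, v, peaks, config.family)
                resid = extract(Xm, y, wv.weights)[support]
                if prev is not None:
                    t_p, f_p = change_scores(prev, resid)
                    rows[float(v)]["t_p"], rows[float(v)]["f_p"] = t_p, f_p
                    tests.append((float(v), t_p, f_p))
                prev = resid
        if tests:
            threshold = config.test_alpha / (2 * len(tests))
            for i, (v, t_p, f_p) in enumerate(tests):
                if min(t_p, f_p) < threshold:
                    rows[v]["breakpoint"] = True
                    k_star = float(order[i])  # value before the change
                    break
        if k_star is None:
            mid = float(np.sqrt(admissible[0] * admissible[-1]))
            k_star = float(
                admissible[np.argmin(np.abs(np.log(admissible) - np.log(mid)))]
            )
    df = pd.DataFrame.from_records([rows[float(v)] for v in k_values])
    return df, admissible, k_star


def _data_peaks(data: PhenotypeDataset) -> np.ndarray:
    data.require_mutants()
    return merge_peak_days(data.mutant_times)


def effective_peak_count(peaks, gap: float = 7.0) -> int:
    """Number of distinct windows the peaks will form.

    Peaks closer than ``gap`` belong to one cluster: their windows merge for
    any practical bandwidth, so the minimum-observation threshold should
    scale with the cluster count, not with the number of measurement days.
    """
    peaks = np.sort(np.atleast_1d(np.asarray(peaks, dtype=float)))
    if peaks.size == 0:
        return 0
    return int(1 + np.sum(np.diff(peaks) >= gap))


def select_bandwidth(
    data: PhenotypeDataset,
    config: GridConfig | None = None,
    peaks: np.ndarray | None = None,
) -> SelectionResult:
    """Select the bandwidth ``l*`` on the expanding log grid.

    The shape is held at ``config.k_during_l`` throughout.  With no
    admissible grid value the result is a flagged fallback (analysis should
    proceed non-windowed).
    """
    config = config or GridConfig()
    peaks = _data_peaks(data) if peaks is None else np.atleast_1d(peaks)
    times = data.times
    span = data.time_span
    if config.T is not None:
        T = config.T
    else:
        T = default_T(data.n, effective_peak_count(peaks, config.peak_cluster_gap))

    if span <= 0 or T > data.n:
        note = (
            "degenerate time span: non-windowed fallback"
            if span <= 0
            else f"T={T:.1f} exceeds n={data.n}: non-windowed fallback"
        )
        logger.warning(note)
        return SelectionResult(
            l_star=None,
            k_star=None,
            scores=pd.DataFrame(),
            final_weights=None,
            admissible_l=np.array([]),
            admissible_k=np.array([]),
            T=float(T),
            peaks=peaks,
            fallback=True,
            notes=[note],
        )

    grid = config.l_grid(span)
    df, admissible, l_star = _scan_bandwidth(data, peaks, grid, T, config)
    if admissible.size == 0 or l_star is None:
        note = "no bandwidth satisfies the minimum sum-of-weights: non-windowed fallback"
        logger.warning(note)
        return SelectionResult(
            l_star=None, k_star=None, scores=df, final_weights=None,
            admissible_l=admissible, admissible_k=np.array([]), T=float(T),
            peaks=peaks, fallback=True, notes=[note],
        )
    return SelectionResult(
        l_star=float(l_star),
        k_star=None,
        scores=df,
        final_weights=wgf(times, l_star, config.k_during_l, peaks, config.family),
        admissible_l=admissible,
        admissible_k=np.array([]),
        T=float(T),
        peaks=peaks,
    )


def select_shape(
    data: PhenotypeDataset,
    selection: SelectionResult,
    config: GridConfig | None = None,
) -> SelectionResult:
    """Tune the shape ``k*`` at the fixed ``l*`` by the same scan.

    When no change is declared the default is the admissible grid value
    closest to the geometric midpoint of the shape range (neither a hard nor
    a maximally diffuse window is forced on the data).
    """
    config = config or GridConfig()
    if selection.fallback or selection.l_star is None:
        return selection
    times = data.times
    peaks = selection.peaks
    l_star = selection.l_star
    df, admissible, k_star = _scan_shape(
        data, peaks, l_star, config.k_grid(), selection.T, config
    )
    if k_star is None:  # cannot happen when l* was admissible at k_during_l
        k_star = config.k_during_l
    scores = pd.concat([selection.scores, df], ignore_index=True)
    return replace(
        selection,
        k_star=float(k_star),
        scores=scores,
        admissible_k=admissible,
        final_weights=wgf(times, l_star, k_star, peaks, config.family),
    )


@dataclass
class PipelineResult:
    """End-to-end result: window selection plus both final model fits."""

    selection: SelectionResult
    windowed: ModelFit
    nonwindowed: ModelFit

    def __iter__(self):
        return iter((self.selection, self.windowed, self.nonwindowed))


def soft_window_pipeline(
    data: PhenotypeDataset, config: GridConfig | None = None
) -> PipelineResult:
    """Full analysis: peak construction, (l, k) selection, final fits.

    Peaks are the distinct mutant measurement days.  The final association
    model is a weighted linear mixed model (batch random intercept); a
    non-windowed reference fit with unit weights is always reported
    alongside.  Fallback paths (degenerate span, unsatisfiable threshold)
    proceed non-windowed with the selection flagged, never raise.
    """
    config = config or GridConfig()
    data.require_mutants()
    peaks = _data_peaks(data)
    selection = select_bandwidth(data, config, peaks)
    selection = select_shape(data, selection, config)
    unit = np.ones(data.n)
    if selection.fallback or selection.final_weights is None:
        weights = unit
    else:
        weights = selection.final_weights.weights
    windowed = weighted_mixed_fit(data, weights, config.terms)
    nonwindowed = weighted_mixed_fit(data, unit, config.terms)
    return PipelineResult(selection=selection, windowed=windowed, nonwindowed=nonwindowed)


@dataclass
class SensitivityResult:
    """Sensitivity of the final genotype p-value to the threshold ``T``.

    ``table`` has one row per candidate T (columns T, l_star, k_star,
    genotype_p); ``max_toleration_T`` is the T at the largest jump in
    ``-log10 p`` between consecutive rows — the largest threshold before a
    step change in the reported association.
    """

    table: pd.DataFrame
    max_toleration_T: float


def sensitivity_over_T(
    data: PhenotypeDataset,
    config: GridConfig | None = None,
    T_grid=None,
) -> SensitivityResult:
    """Re-run the pipeline across a grid of minimum-observation thresholds.

    Default grid: 25 log-spaced values from 14 to n.
    """
    config = config or GridConfig()
    if data.n <= 14:
        raise InsufficientDataError("sensitivity analysis needs n > 14")
    if T_grid is None:
        T_grid = log_spaced_grid(14.0, float(data.n), 25)
    rows = []
    for T in np.asarray(T_grid, dtype=float):
        result = soft_window_pipeline(data, replace(config, T=float(T)))
        rows.append(
            {
                "T": float(T),
                "l_star": result.selection.l_star,
                "k_star": result.selection.k_star,
                "genotype_p": result.windowed.genotype_p,
                "fallback": result.selection.fallback,
            }
        )
    table = pd.DataFrame(rows)
    logp = -np.log10(np.clip(table["genotype_p"].to_numpy(dtype=float), 1e-300, None))
    jumps = np.abs(np.diff(logp))
    idx = int(np.argmax(jumps)) if jumps.size else 0
    return SensitivityResult(table=table, max_toleration_T=float(table["T"].iloc[idx]))
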