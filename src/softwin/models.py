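"""Weighted regression and weighted linear mixed models.

The association model for one phenotype follows the high-throughput
phenotyping convention: fixed effects for genotype, sex, the genotype-sex
interaction and body weight, plus a random intercept per batch (measurement
day).  Soft-window weights enter as inverse residual-variance multipliers:
observation i contributes with residual variance ``sigma^2 / w_i``, which for
the mixed model is implemented by scaling the rows of the profiled problem by
``sqrt(w_i)``.  Inference on the genotype effect is a two-sided Wald test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datasets import PhenotypeDataset
from .errors import MissingGroupError, SingularDesignError
from .windows import WEIGHT_FLOOR

logger = logging.getLogger("softwin.models")

#: Default per-term significance reporting threshold used by large
#: phenotyping consortia; a reporting convention, not hard-coded logic.
DEFAULT_ALPHA = 1e-4

#: Weight above which a control observation counts as effectively included.
EFFECTIVE_WEIGHT_CUTOFF = 1e-7

#: Model terms, in design order.  ``genotype`` and the intercept are never
#: eliminated.
ALL_TERMS = ("genotype", "sex", "genotype:sex", "body_weight")
PROTECTED_TERMS = ("genotype",)


@dataclass
class ModelFit:
    """Result of a (weighted) regression or mixed-model fit.

    ``term_pvalues`` maps model terms (``genotype``, ``sex``, ...) to
    two-sided Wald p-values.  ``residuals`` are response minus fitted values
    on the original scale.  For mixed fits ``fitted`` uses the fixed effects
    only (marginal fit).
    """

    coefficients: pd.Series
    stderr: pd.Series
    term_pvalues: dict
    residuals: np.ndarray
    fitted: np.ndarray
    weights: np.ndarray
    model_kind: str  # {"wls", "weighted_mixed"}
    terms: tuple = ()
    data: PhenotypeDataset | None = None
    notes: list = field(default_factory=list)

    @property
    def genotype_p(self) -> float:
        return float(self.term_pvalues.get("genotype", np.nan))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(data: PhenotypeDataset, terms=ALL_TERMS):
    """Build the fixed-effect design matrix for ``data``.

    Returns ``(X, term_of_column)`` where ``X`` is a DataFrame with an
    intercept and one column per single-degree-of-freedom term.  Terms whose
    covariate is degenerate in the data (single sex level, missing body
    weight) are dropped with a logged note; body weight with at most 50%
    missing values is mean-imputed so no row is silently deleted.
    """
    df = data.data
    n = data.n
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    term_of: dict[str, str] = {}
    notes: list[str] = []

    geno = (df["group"] == "mutant").to_numpy(dtype=float)
    sex_m = (df["sex"] == "M").to_numpy(dtype=float)
    has_both_sexes = 0 < sex_m.sum() < n

    for term in terms:
        if term == "genotype":
            cols["genotype[mutant]"] = geno
            term_of["genotype[mutant]"] = "genotype"
        elif term == "sex":
            if not has_both_sexes:
                notes.append("sex term dropped: single sex level")
                continue
            cols["sex[M]"] = sex_m
            term_of["sex[M]"] = "sex"
        elif term == "genotype:sex":
            if not has_both_sexes or "sex" not in terms:
                continue
            inter = geno * sex_m
            # single-sex mutant groups make the interaction collinear with
            # genotype (or identically zero); drop it rather than fail
            if inter.std() == 0 or np.array_equal(inter, geno):
                notes.append("genotype:sex term dropped: mutants are single-sex")
                continue
            cols["genotype[mutant]:sex[M]"] = inter
            term_of["genotype[mutant]:sex[M]"] = "genotype:sex"
        elif term == "body_weight":
            bw = data.body_weight
            if bw is None:
                notes.append("body_weight term dropped: column absent or empty")
                continue
            n_missing = int(np.isnan(bw).sum())
            if n_missing > 0.5 * n:
                notes.append(
                    f"body_weight term dropped: {n_missing}/{n} values missing"
                )
                continue
            bw = bw.copy()
            if n_missing:
                bw[np.isnan(bw)] = np.nanmean(bw)
                notes.append(f"body_weight: {n_missing} missing values mean-imputed")
            if np.std(bw) == 0:
                notes.append("body_weight term dropped: constant covariate")
                continue
            cols["body_weight"] = bw - bw.mean()
            term_of["body_weight"] = "body_weight"
        else:
            raise ValueError(f"unknown model term {term!r}")

    X = pd.DataFrame(cols)
    for note in notes:
        logger.info(note)
    return X, term_of, notes


def _effective_rows(w: np.ndarray, rel_cutoff: float = EFFECTIVE_WEIGHT_CUTOFF) -> np.ndarray:
    """Rows whose weight is not effectively zero (relative to the maximum).

    Near-zero-weight rows carry no information but would still count towards
    the residual degrees of freedom (and, in the scaled mixed-model
    representation, towards the variance estimate), biasing every standard
    error downward; they are excluded from fitting.  The cutoff is relative
    so rescaling all weights leaves the selection unchanged.
    """
    w = np.asarray(w, dtype=float)
    return w > rel_cutoff * w.max()


def _check_rank(X: pd.DataFrame, w: np.ndarray) -> None:
    """Raise :class:`SingularDesignError` naming collinear columns."""
    sw = np.sqrt(np.asarray(w, dtype=float))
    mat = X.to_numpy() * sw[:, None]
    mat = mat[sw > 0]
    if np.linalg.matrix_rank(mat) >= X.shape[1]:
        return
    # identify offenders by greedy rank growth
    bad, kept = [], np.empty((mat.shape[0], 0))
    for j, name in enumerate(X.columns):
        cand = np.column_stack([kept, mat[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(name)
    raise SingularDesignError(bad)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def wls_fit(design, response, weights, term_of=None) -> ModelFit:
    """Weighted least squares with the closed form ``(X'WX)^{-1} X'Wy``.

    Unit weights reproduce ordinary least squares; rescaling all weights by
    a positive constant leaves the estimates unchanged.  ``design`` may be a
    DataFrame (column names kept) or a plain array.
    """
    X = design if isinstance(design, pd.DataFrame) else pd.DataFrame(
        np.asarray(design, dtype=float),
        columns=[f"x{j}" for j in range(np.asarray(design).shape[1])],
    )
    y = np.asarray(response, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    mask = _effective_rows(w)
    _check_rank(X[mask], w[mask])
    res = sm.WLS(y[mask], X[mask], weights=w[mask]).fit()
    fitted = X.to_numpy() @ np.asarray(res.params)
    term_of = term_of or {c: c for c in X.columns if c != "Intercept"}
    pvals = {term_of[c]: float(res.pvalues[c]) for c in X.columns if c in term_of}
    return ModelFit(
        coefficients=res.params,
        stderr=res.bse,
        term_pvalues=pvals,
        residuals=y - fitted,
        fitted=fitted,
        weights=w,
        model_kind="wls",
    )


def weighted_fixed_fit(data: PhenotypeDataset, weights, terms=ALL_TERMS) -> ModelFit:
    """Weighted fixed-effect fit of the phenotyping model (no random effect)."""
    X, term_of, notes = build_design(data, terms)
    fit = wls_fit(X, data.response, weights, term_of)
    fit.terms = tuple(dict.fromkeys(term_of.values()))
    fit.data = data
    fit.notes.extend(notes)
    return fit


class _WeightedRandomIntercept:
    """Exact REML machinery for ``y = Xb + Z u + e`` with one random
    intercept per batch and per-observation precision weights.

    The marginal covariance is ``sigma^2 * (W^{-1} + lam * Z Z')`` which is
    block diagonal over batches; each block is a diagonal plus a rank-one
    term, so its inverse is available in closed form (Sherman-Morrison) and
    the generalized least squares solution is exact for any variance ratio
    ``lam = tau^2 / sigma^2``.  The profiled REML criterion is then a
    function of the single scalar ``lam``, optimized by bounded search.
    This is the same likelihood lme4 maximizes for
    ``lmer(y ~ X + (1|batch), weights=w)``.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, w: np.ndarray, batch) -> None:
        self.X, self.y, self.w = X, y, w
        codes, _ = pd.factorize(pd.Series(batch).astype(str))
        self.codes = codes
        self.n_groups = codes.max() + 1
        self.n, self.p = X.shape
        # per-batch sums of weights: s_j = sum_i w_i
        self.s = np.bincount(codes, weights=w, minlength=self.n_groups)

    def _gls(self, lam: float):
        """X'O^{-1}X, X'O^{-1}y, y'O^{-1}y and log|O| for O = W^-1 + lam ZZ'."""
        X, y, w, codes = self.X, self.y, self.w, self.codes
        c = lam / (1.0 + lam * self.s)  # rank-one correction factor per batch
        wX = X * w[:, None]
        wy = y * w
        # per-batch aggregates of the weighted rows
        gX = np.zeros((self.n_groups, self.p))
        np.add.at(gX, codes, wX)
        gy = np.bincount(codes, weights=wy, minlength=self.n_groups)
        xtox = X.T @ wX - (gX * c[:, None]).T @ gX
        xtoy = X.T @ wy - gX.T @ (c * gy)
        ytoy = y @ wy - gy @ (c * gy)
        logdet = -np.sum(np.log(w)) + np.sum(np.log1p(lam * self.s))
        return xtox, xtoy, ytoy, logdet

    def reml(self, lam: float) -> float:
        """Negative restricted log-likelihood (constants dropped)."""
        xtox, xtoy, ytoy, logdet = self._gls(lam)
        beta = np.linalg.solve(xtox, xtoy)
        rss = ytoy - xtoy @ beta  # r' O^{-1} r at the GLS solution
        dof = self.n - self.p
        sigma2 = max(rss / dof, 1e-300)
        _, logdet_xox = np.linalg.slogdet(xtox)
        return 0.5 * (dof * np.log(sigma2) + logdet + logdet_xox)

    def fit(self):
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda u: self.reml(np.exp(u)),
            bounds=(np.log(1e-8), np.log(1e6)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(np.exp(res.x))
        if self.reml(0.0) <= res.fun:  # boundary: no between-batch variance
            lam = 0.0
        xtox, xtoy, ytoy, _ = self._gls(lam)
        beta = np.linalg.solve(xtox, xtoy)
        sigma2 = max((ytoy - xtoy @ beta) / (self.n - self.p), 1e-300)
        cov = sigma2 * np.linalg.inv(xtox)
        return beta, np.sqrt(np.diag(cov)), lam, sigma2


def weighted_mixed_fit(data: PhenotypeDataset, weights, terms=ALL_TERMS) -> ModelFit:
    """Weighted linear mixed model with a random intercept per batch.

    Observation weights act as precision weights (residual variance
    ``sigma^2 / w_i``), matching lme4's ``weights`` argument; the batch
    variance component is estimated by REML (exact profiled computation, see
    :class:`_WeightedRandomIntercept`) and the genotype effect is tested by
    a two-sided Wald test.  Rows with effectively zero weight are excluded
    from fitting; with fewer than two effectively included batches the
    random effect is unidentifiable and the fit degrades to
    :func:`weighted_fixed_fit` with a logged note.
    """
    if not data.is_mutant.any() or not data.is_control.any():
        raise MissingGroupError("mixed fit needs both control and mutant rows")
    w = np.clip(np.asarray(weights, dtype=float), WEIGHT_FLOOR, None)
    mask = _effective_rows(w)
    n_eff_batches = pd.Series(data.batch[mask]).nunique()
    if n_eff_batches < 2:
        logger.warning("single batch: falling back to weighted fixed-effect fit")
        fit = weighted_fixed_fit(data, w, terms)
        fit.notes.append("single batch: random effect dropped, WLS used")
        return fit

    X, term_of, notes = build_design(data, terms)
    _check_rank(X[mask], w[mask])
    y = data.response

    engine = _WeightedRandomIntercept(
        X[mask].to_numpy(), y[mask], w[mask], data.batch[mask]
    )
    beta, bse, lam, sigma2 = engine.fit()
    params = pd.Series(beta, index=X.columns)
    stderr = pd.Series(bse, index=X.columns)
    zvals = beta / bse
    pseries = pd.Series(2.0 * stats.norm.sf(np.abs(zvals)), index=X.columns)
    pvals = {term_of[c]: float(pseries[c]) for c in X.columns if c in term_of}

    fitted = X.to_numpy() @ beta
    return ModelFit(
        coefficients=params,
        stderr=stderr,
        term_pvalues=pvals,
        residuals=y - fitted,
        fitted=fitted,
        weights=w,
        model_kind="weighted_mixed",
        terms=tuple(dict.fromkeys(term_of.values())),
        data=data,
        notes=notes
        + [f"batch variance ratio lambda={lam:.4g}, residual variance {sigma2:.4g}"],
    )


def backward_eliminate(fit: ModelFit, alpha: float = 0.05) -> ModelFit:
    """Drop nonsignificant removable terms one at a time and refit.

    At each step the removable term with the largest p-value above ``alpha``
    is dropped (the genotype effect and intercept are never removed, and the
    sex main effect is only removable once the genotype-sex interaction is
    gone).  Stops when every remaining removable term has p <= alpha.
    """
    if fit.data is None:
        raise ValueError("fit must carry its dataset to support re-fitting")
    refit = weighted_mixed_fit if fit.model_kind == "weighted_mixed" else weighted_fixed_fit
    current = fit
    while True:
        removable = [
            t
            for t in current.terms
            if t not in PROTECTED_TERMS
            and not (t == "sex" and "genotype:sex" in current.terms)
        ]
        candidates = [
            (current.term_pvalues.get(t, np.nan), t)
            for t in removable
            if np.isfinite(current.term_pvalues.get(t, np.nan))
            and current.term_pvalues[t] > alpha
        ]
        if not candidates:
            return current
        _, worst = max(candidates)
        new_terms = tuple(t for t in current.terms if t != worst)
        logger.info("backward elimination drops %s", worst)
        nxt = refit(current.data, current.weights, new_terms)
        nxt.notes.append(f"backward elimination dropped {worst}")
        current = nxt


def effective_control_count(
    weights, groups, cutoff: float = EFFECTIVE_WEIGHT_CUTOFF
) -> int:
    """Number of control observations with weight strictly above ``cutoff``."""
    w = np.asarray(weights, dtype=float)
    is_control = np.asarray(groups) == "control"
    return int(np.sum(is_control & (w > cutoff)))
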