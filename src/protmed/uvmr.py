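"""Univariable two-sample MR estimators and directionality diagnostics.

Each estimator is a scikit-learn-style class: parameters are set in
``__init__``, ``fit(X, y, se_X=..., se_y=...)`` consumes per-variant
SNP-exposure effects ``X`` and SNP-outcome effects ``y`` with their
standard errors, and fitted quantities carry a trailing underscore
(``estimate_``, ``se_``, ``pval_`` ...).  Thin module-level functions accept
a :class:`~protmed.sumstats.HarmonizedSet` and return a frozen
:class:`MREstimate` record.

Implemented methods:

- Wald ratio (single variant), first-order delta-method standard error;
- inverse-variance-weighted regression through the origin with a
  multiplicative random-effects scale (IVW-MRE), the main model;
- MR-Egger weighted regression with intercept (directional pleiotropy);
- weighted median of per-variant ratio estimates (parametric bootstrap SE);
- weighted mode via a normal-kernel density over ratio estimates;
- leave-one-out IVW re-estimates and the Steiger directionality test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dataclass_replace
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateInstrumentError,
    DomainError,
    InsufficientSNPsError,
)
from .sumstats import HarmonizedSet, CASE_CONTROL

Z95 = float(stats.norm.ppf(0.975))

WALD = "wald"
IVW_MRE = "ivw_mre"
EGGER = "egger"
WEIGHTED_MEDIAN = "weighted_median"
WEIGHTED_MODE = "weighted_mode"

_MIN_SNPS = {WALD: 1, IVW_MRE: 2, EGGER: 3, WEIGHTED_MEDIAN: 3, WEIGHTED_MODE: 3}


@dataclass(frozen=True)
class MREstimate:
    """One MR point estimate with its uncertainty and heterogeneity."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    Q: float = float("nan")
    Q_pval: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_pval: float = float("nan")
    exposure: str = ""
    outcome: str = ""

    def with_labels(self, exposure, outcome):
        return dataclass_replace(self, exposure=exposure, outcome=outcome)


def _check_arrays(X, y, se_y, se_X=None):
    X = np.asarray(X, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    se_y = np.asarray(se_y, dtype=float).ravel()
    if not (len(X) == len(y) == len(se_y)):
        raise DomainError("X, y and se_y must have equal length")
    if np.any(se_y <= 0):
        raise DomainError("se_y must be > 0")
    if se_X is not None:
        se_X = np.asarray(se_X, dtype=float).ravel()
        if len(se_X) != len(X) or np.any(se_X <= 0):
            raise DomainError("se_X must be > 0 and match X")
    return X, y, se_y, se_X


class _MRBase(BaseEstimator):
    """Shared plumbing for the univariable estimators."""

    method: str = ""

    def _finish(self, estimate, se, n_snp, df=None):
        self.estimate_ = float(estimate)
        self.se_ = float(se)
        self.n_snp_ = int(n_snp)
        if np.isfinite(se) and se > 0:
            if df is None:
                z = estimate / se
                self.pval_ = float(2 * stats.norm.sf(abs(z)))
                half = Z95 * se
            else:
                t = estimate / se
                self.pval_ = float(2 * stats.t.sf(abs(t), df))
                half = float(stats.t.ppf(0.975, df)) * se
            self.ci_low_ = float(estimate - half)
            self.ci_high_ = float(estimate + half)
        else:
            self.pval_ = float("nan")
            self.ci_low_ = float("nan")
            self.ci_high_ = float("nan")

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method=self.method,
            estimate=self.estimate_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            pval=self.pval_,
            n_snp=self.n_snp_,
            Q=getattr(self, "q_", float("nan")),
            Q_pval=getattr(self, "q_pval_", float("nan")),
            egger_intercept=getattr(self, "intercept_", float("nan")),
            egger_intercept_se=getattr(self, "intercept_se_", float("nan")),
            egger_intercept_pval=getattr(self, "intercept_pval_", float("nan")),
        )


class WaldRatio(_MRBase):
    """Single-variant causal estimate ``beta_out / beta_exp``."""

    method = WALD

    def fit(self, X, y, se_y, se_X=None):
        X, y, se_y, _ = _check_arrays(X, y, se_y, se_X)
        if len(X) != 1:
            raise InsufficientSNPsError("Wald ratio requires exactly 1 variant")
        if X[0] == 0:
            raise DegenerateInstrumentError("beta_exp is zero")
        est = y[0] / X[0]
        se = se_y[0] / abs(X[0])
        self._finish(est, se, 1)
        return self


class IVWRandomEffects(_MRBase):
    """Weighted regression of outcome on exposure effects through the origin.

    Weights are ``1/se_y^2``; the residual (Cochran's Q) scale is applied
    multiplicatively, ``phi = Q/(k-1)``, unfloored by default.  ``floor_phi``
    floors the scale at 1 (the fixed-effects lower bound).
    """

    method = IVW_MRE

    def __init__(self, floor_phi: bool = False):
        self.floor_phi = floor_phi

    def fit(self, X, y, se_y, se_X=None):
        X, y, se_y, _ = _check_arrays(X, y, se_y, se_X)
        k = len(X)
        if k < 2:
            raise InsufficientSNPsError("IVW requires >= 2 variants")
        w = 1.0 / se_y ** 2
        sxx = float(np.sum(w * X * X))
        if sxx == 0:
            raise DegenerateInstrumentError("all beta_exp are zero")
        theta = float(np.sum(w * X * y)) / sxx
        q = float(np.sum(w * (y - theta * X) ** 2))
        phi = q / (k - 1)
        if self.floor_phi:
            phi = max(1.0, phi)
        se = float(np.sqrt(phi / sxx))
        self.q_ = q
        self.q_pval_ = float(stats.chi2.sf(q, k - 1))
        self._finish(theta, se, k)
        return self


class MREgger(_MRBase):
    """Weighted regression with intercept; the intercept estimates average
    directional pleiotropy.

    Pairs are oriented so every exposure effect is non-negative before
    fitting (Egger is not orientation-invariant).  Both standard errors are
    scaled by ``max(1, sigma_hat)`` and referred to a t distribution with
    ``k - 2`` degrees of freedom.
    """

    method = EGGER

    def fit(self, X, y, se_y, se_X=None):
        X, y, se_y, _ = _check_arrays(X, y, se_y, se_X)
        k = len(X)
        if k < 3:
            raise InsufficientSNPsError("MR-Egger requires >= 3 variants")
        sign = np.where(X < 0, -1.0, 1.0)
        bx = sign * X
        by = sign * y
        w = 1.0 / se_y ** 2
        sw = np.sqrt(w)
        design = np.column_stack([np.ones(k), bx])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], by * sw, rcond=None)
        resid = by - design @ coef
        rss = float(np.sum(w * resid ** 2))
        sigma = np.sqrt(rss / (k - 2))
        scale = max(1.0, sigma)
        xtwx_inv = np.linalg.inv(design.T @ (design * w[:, None]))
        ses = scale * np.sqrt(np.diag(xtwx_inv))
        self.intercept_ = float(coef[0])
        self.intercept_se_ = float(ses[0])
        self.intercept_pval_ = float(
            2 * stats.t.sf(abs(coef[0] / ses[0]), k - 2)
        )
        self.q_ = rss
        self.q_pval_ = float(stats.chi2.sf(rss, k - 2))
        self._finish(coef[1], ses[1], k, df=k - 2)
        return self


def _ratio_weights(X, y, se_y, se_X, second_order):
    theta = y / X
    var = se_y ** 2 / X ** 2
    if second_order and se_X is not None:
        var = var + (y ** 2) * (se_X ** 2) / X ** 4
    return theta, 1.0 / var


def _weighted_median(theta, w):
    """Weighted 50th percentile with linear interpolation over cumulative
    normalized weights ``s_j = sum_{i<=j} w'_i - w'_j / 2``."""
    order = np.argsort(theta, kind="mergesort")
    th = theta[order]
    wn = w[order] / np.sum(w[order])
    s = np.cumsum(wn) - wn / 2
    return float(np.interp(0.5, s, th))


class WeightedMedian(_MRBase):
    """Weighted median of per-variant ratio estimates.

    Consistent when at least half the weight comes from valid instruments.
    The standard error is the standard deviation of the estimate over
    ``boot_reps`` parametric-bootstrap resamples of the per-variant effects
    from their normal sampling distributions; ``boot_reps=0`` skips the
    bootstrap (SE reported as NaN).
    """

    method = WEIGHTED_MEDIAN

    def __init__(self, boot_reps: int = 1000, seed: Optional[int] = None,
                 second_order: bool = False):
        self.boot_reps = boot_reps
        self.seed = seed
        self.second_order = second_order

    def fit(self, X, y, se_y, se_X=None):
        X, y, se_y, se_X = _check_arrays(X, y, se_y, se_X)
        k = len(X)
        if k < 3:
            raise InsufficientSNPsError("weighted median requires >= 3 variants")
        theta, w = _ratio_weights(X, y, se_y, se_X, self.second_order)
        est = _weighted_median(theta, w)
        se = self._bootstrap(X, y, se_y, se_X)
        self._finish(est, se, k)
        return self

    def _bootstrap(self, X, y, se_y, se_X):
        if not self.boot_reps:
            return float("nan")
        rng = np.random.default_rng(self.seed)
        B, k = self.boot_reps, len(X)
        sx = se_X if se_X is not None else np.zeros_like(X)
        bx = X + sx * rng.standard_normal((B, k))
        by = y + se_y * rng.standard_normal((B, k))
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        theta = by / bx
        var = se_y ** 2 / bx ** 2
        if self.second_order and se_X is not None:
            var = var + (by ** 2) * (se_X ** 2) / bx ** 4
        w = 1.0 / var
        order = np.argsort(theta, axis=1, kind="mergesort")
        th = np.take_along_axis(theta, order, axis=1)
        wn = np.take_along_axis(w, order, axis=1)
        wn = wn / wn.sum(axis=1, keepdims=True)
        s = np.cumsum(wn, axis=1) - wn / 2
        ests = np.empty(B)
        for b in range(B):
            ests[b] = np.interp(0.5, s[b], th[b])
        return float(np.std(ests, ddof=1))


class WeightedMode(WeightedMedian):
    """Mode of the weighted normal-kernel density over ratio estimates.

    Bandwidth ``h = phi * 0.9 * min(sd, mad) * k^(-1/5)`` (mad scaled to be
    consistent for a normal distribution).  The estimate is the density
    argmax on a fixed evaluation grid; when all ratios coincide (zero
    bandwidth) the common ratio is returned.
    """

    method = WEIGHTED_MODE

    def __init__(self, phi: float = 1.0, boot_reps: int = 1000,
                 seed: Optional[int] = None, second_order: bool = False,
                 grid_size: int = 512):
        super().__init__(boot_reps=boot_reps, seed=seed,
                         second_order=second_order)
        self.phi = phi
        self.grid_size = grid_size

    _MAD_SCALE = 1.4826022185056018  # 1/Phi^{-1}(3/4): normal-consistent MAD

    def _mode(self, theta, w):
        sd = np.std(theta, ddof=1)
        mad = self._MAD_SCALE * np.median(np.abs(theta - np.median(theta)))
        h = self.phi * 0.9 * min(sd, mad) * len(theta) ** (-1 / 5)
        if h <= 0 or not np.isfinite(h):
            return float(theta[0])
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h,
                           self.grid_size)
        dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
        return float(grid[np.argmax(dens)])

    def _bootstrap(self, X, y, se_y, se_X):
        # fully vectorized over bootstrap replicates
        if not self.boot_reps:
            return float("nan")
        rng = np.random.default_rng(self.seed)
        B, k = self.boot_reps, len(X)
        sx = se_X if se_X is not None else np.zeros_like(X)
        bx = X + sx * rng.standard_normal((B, k))
        by = y + se_y * rng.standard_normal((B, k))
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        theta = by / bx
        var = se_y ** 2 / bx ** 2
        if self.second_order and se_X is not None:
            var = var + (by ** 2) * (se_X ** 2) / bx ** 4
        w = 1.0 / var
        w = w / w.sum(axis=1, keepdims=True)

        med = np.median(theta, axis=1, keepdims=True)
        mad = self._MAD_SCALE * np.median(np.abs(theta - med), axis=1)
        sd = np.std(theta, axis=1, ddof=1)
        h = self.phi * 0.9 * np.minimum(sd, mad) * k ** (-1 / 5)

        ests = np.empty(B)
        ok = (h > 0) & np.isfinite(h)
        ests[~ok] = theta[~ok, 0]
        idx = np.flatnonzero(ok)
        G = self.grid_size
        lo = theta[idx].min(axis=1) - 3 * h[idx]
        hi = theta[idx].max(axis=1) + 3 * h[idx]
        step = (hi - lo) / (G - 1)
        for start in range(0, len(idx), 64):
            rows = idx[start:start + 64]
            r = slice(start, start + len(rows))
            grid = lo[r, None] + step[r, None] * np.arange(G)[None, :]
            zs = (grid[:, :, None] - theta[rows, None, :]) / h[rows, None, None]
            dens = np.einsum("bgk,bk->bg", np.exp(-0.5 * zs ** 2), w[rows])
            ests[rows] = grid[np.arange(len(rows)), np.argmax(dens, axis=1)]
        return float(np.std(ests, ddof=1))

    def fit(self, X, y, se_y, se_X=None):
        X, y, se_y, se_X = _check_arrays(X, y, se_y, se_X)
        k = len(X)
        if k < 3:
            raise InsufficientSNPsError("weighted mode requires >= 3 variants")
        theta, w = _ratio_weights(X, y, se_y, se_X, self.second_order)
        est = self._mode(theta, w / np.sum(w))
        se = self._bootstrap(X, y, se_y, se_X)
        self._finish(est, se, k)
        return self


# ---------------------------------------------------------------------------
# HarmonizedSet-level wrappers


def wald_ratio(h: HarmonizedSet) -> MREstimate:
    est = WaldRatio().fit(h.beta_exp, h.beta_out, h.se_out)
    return est.to_estimate().with_labels(h.exposure_id, h.outcome_id)


def ivw_mre(h: HarmonizedSet, floor_phi: bool = False) -> MREstimate:
    est = IVWRandomEffects(floor_phi=floor_phi).fit(
        h.beta_exp, h.beta_out, h.se_out
    )
    return est.to_estimate().with_labels(h.exposure_id, h.outcome_id)


def mr_egger(h: HarmonizedSet) -> MREstimate:
    est = MREgger().fit(h.beta_exp, h.beta_out, h.se_out)
    return est.to_estimate().with_labels(h.exposure_id, h.outcome_id)


def weighted_median(h: HarmonizedSet, boot_reps: int = 1000,
                    seed: Optional[int] = None) -> MREstimate:
    est = WeightedMedian(boot_reps=boot_reps, seed=seed).fit(
        h.beta_exp, h.beta_out, h.se_out, se_X=h.se_exp
    )
    return est.to_estimate().with_labels(h.exposure_id, h.outcome_id)


def weighted_mode(h: HarmonizedSet, phi: float = 1.0, boot_reps: int = 1000,
                  seed: Optional[int] = None, grid_size: int = 512) -> MREstimate:
    est = WeightedMode(phi=phi, boot_reps=boot_reps, seed=seed,
                       grid_size=grid_size).fit(
        h.beta_exp, h.beta_out, h.se_out, se_X=h.se_exp
    )
    return est.to_estimate().with_labels(h.exposure_id, h.outcome_id)


@dataclass
class LeaveOneOut:
    """IVW re-estimates, one per omitted variant."""

    full: MREstimate
    results: list  # (omitted variant_id, MREstimate)
    sign_change_ids: list


def leave_one_out(h: HarmonizedSet) -> LeaveOneOut:
    """Re-estimate IVW-MRE omitting each variant in turn; flags variants
    whose omission changes the sign of the point estimate."""
    if h.n_snp < 3:
        raise InsufficientSNPsError("leave-one-out requires >= 3 variants")
    full = ivw_mre(h)
    results = []
    flips = []
    for i, vid in enumerate(h.variant_ids):
        idx = [j for j in range(h.n_snp) if j != i]
        est = ivw_mre(h.subset(idx))
        results.append((vid, est))
        if np.sign(est.estimate) != np.sign(full.estimate):
            flips.append(vid)
    return LeaveOneOut(full, results, flips)


@dataclass(frozen=True)
class SteigerResult:
    """Direction-of-causation diagnostic from variance explained."""

    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    z: float
    pval: float


def effective_n(n_case, n_control):
    """Effective sample size for a case-control GWAS, ``4/(1/ncase + 1/nctrl)``."""
    if n_case <= 0 or n_control <= 0:
        raise DomainError("case and control counts must be positive")
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def steiger(
    h: HarmonizedSet,
    n_exp: float,
    n_out: float,
    outcome_type: str = CASE_CONTROL,
    case_fraction: Optional[float] = None,
    r2_fn=None,
) -> SteigerResult:
    """Steiger directionality test on an instrument set.

    Per-variant variance explained is approximated as ``z^2/(z^2 + n)``; for
    a binary outcome ``n`` is the effective sample size derived from
    ``case_fraction``.  ``r2_fn(z, n) -> r2`` may supply an alternative
    (e.g. liability-scale) variance-explained formula.  The test statistic is
    the difference of Fisher-transformed multiple correlations with variance
    ``1/(n_exp - 3) + 1/(n_out - 3)``.
    """
    if n_exp <= 3 or n_out <= 3:
        raise DomainError("sample sizes must exceed 3")
    n_out_eff = n_out
    if outcome_type == CASE_CONTROL:
        if case_fraction is None or not 0 < case_fraction < 1:
            raise DomainError("case_fraction in (0,1) required for binary outcome")
        n_out_eff = effective_n(n_out * case_fraction, n_out * (1 - case_fraction))
    if n_out_eff <= 3:
        raise DomainError("effective outcome sample size must exceed 3")

    if r2_fn is None:
        r2_fn = lambda z, n: z ** 2 / (z ** 2 + n)  # noqa: E731
    z_exp = h.beta_exp / h.se_exp
    z_out = h.beta_out / h.se_out
    r2_exp = float(np.sum(r2_fn(z_exp, n_exp)))
    r2_out = float(np.sum(r2_fn(z_out, n_out_eff)))
    r2_exp_c = min(r2_exp, 1 - 1e-12)
    r2_out_c = min(r2_out, 1 - 1e-12)
    var = 1.0 / (n_exp - 3) + 1.0 / (n_out_eff - 3)
    z = (np.arctanh(np.sqrt(r2_exp_c)) - np.arctanh(np.sqrt(r2_out_c))) / np.sqrt(var)
    pval = float(2 * stats.norm.sf(abs(z)))
    return SteigerResult(r2_exp, r2_out, r2_exp > r2_out, float(z), pval)


def min_snps(method: str) -> int:
    return _MIN_SNPS[method]
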