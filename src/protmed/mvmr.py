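"""Multivariable MR: direct effects of an exposure adjusted for a mediator.

The estimator regresses SNP-outcome effects jointly on the SNP-exposure and
SNP-mediator effects (no intercept, inverse-variance weights), yielding the
direct effect of each exposure.  Diagnostics follow the generalized
Cochran's Q framework with pairwise effect covariances assumed zero:
``Q_a`` tests instrument validity of the joint model and the conditional
F-statistic measures the strength of each exposure's instruments given the
other exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import (
    CollinearityError,
    DomainError,
    InsufficientSNPsError,
    ProtmedError,
)
from .runlog import log_event
from .sumstats import HarmonizedSet, LDMatrix, SummaryTable, harmonize, ld_clump
from .uvmr import Z95

_COND_TOL = 1e8


@dataclass
class MVMRResult:
    """Direct effects and diagnostics from one multivariable fit."""

    exposures: list
    estimates: np.ndarray
    ses: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvals: np.ndarray
    conditional_f: np.ndarray
    q_a: float
    q_a_pval: float
    n_snp: int
    outcome: str = ""

    def estimate_for(self, exposure):
        i = self.exposures.index(exposure)
        return float(self.estimates[i])


class MVMRRegression(BaseEstimator):
    """Inverse-variance-weighted multivariable regression through the origin.

    ``fit(X, y, se_X=..., se_y=...)`` with ``X`` of shape ``(k, L)``.
    ``Q_a`` uses weights ``1/(se_y^2 + sum_l theta_l^2 se_{x,l}^2)``
    (zero pairwise covariance) against a chi-square with ``k - L`` degrees
    of freedom.  An exposure column that is exactly zero gets a zero direct
    effect (it drops out of the design); any other rank deficiency raises
    :class:`CollinearityError`.
    """

    def __init__(self, cond_tol: float = _COND_TOL):
        self.cond_tol = cond_tol

    def fit(self, X, y, se_X, se_y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 2:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        se_X = np.atleast_2d(np.asarray(se_X, dtype=float))
        if se_X.shape != X.shape:
            se_X = se_X.T
        se_y = np.asarray(se_y, dtype=float).ravel()
        k, L = X.shape
        if k <= L:
            raise InsufficientSNPsError(
                f"need more variants ({k}) than exposures ({L})"
            )
        if np.any(se_y <= 0):
            raise DomainError("se_y must be > 0")

        w = 1.0 / se_y ** 2
        sw = np.sqrt(w)
        nonzero = ~np.all(X == 0, axis=0)
        design = X[:, nonzero] * sw[:, None]
        if design.size:
            svals = np.linalg.svd(design, compute_uv=False)
            if svals[-1] == 0 or svals[0] / svals[-1] > self.cond_tol:
                raise CollinearityError(
                    "exposure effect columns are numerically collinear"
                )
            coef_nz, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
            cov_nz = np.linalg.inv(design.T @ design)
        else:
            raise CollinearityError("all exposure effect columns are zero")

        coef = np.zeros(L)
        coef[nonzero] = coef_nz
        resid = y - X @ coef
        # multiplicative random-effects scale, as in the univariable main model
        phi = float(np.sum(w * resid ** 2)) / (k - int(nonzero.sum()))
        ses = np.full(L, np.nan)
        ses[nonzero] = np.sqrt(phi * np.diag(cov_nz))
        w_q = 1.0 / (se_y ** 2 + (se_X ** 2) @ (coef ** 2))
        q_a = float(np.sum(w_q * resid ** 2))
        df = k - L
        self.estimates_ = coef
        self.ses_ = ses
        self.q_a_ = q_a
        self.q_a_pval_ = float(stats.chi2.sf(q_a, df))
        self.n_snp_ = k
        z = coef / ses
        self.pvals_ = 2 * stats.norm.sf(np.abs(z))
        self.ci_low_ = coef - Z95 * ses
        self.ci_high_ = coef + Z95 * ses
        return self


def _three_way_arrays(h: HarmonizedSet):
    if h.beta_med is None:
        raise DomainError("three-way HarmonizedSet (with mediator) required")
    X = np.column_stack([h.beta_exp, h.beta_med])
    se_X = np.column_stack([h.se_exp, h.se_med])
    return X, se_X


def mvmr_ivw(h: HarmonizedSet) -> MVMRResult:
    """Direct effects of the exposure and mediator on the outcome."""
    X, se_X = _three_way_arrays(h)
    fit = MVMRRegression().fit(X, h.beta_out, se_X, h.se_out)
    cond_f = np.array([conditional_f(h, 0), conditional_f(h, 1)])
    return MVMRResult(
        [h.exposure_id, h.mediator_id],
        fit.estimates_, fit.ses_, fit.ci_low_, fit.ci_high_, fit.pvals_,
        cond_f, fit.q_a_, fit.q_a_pval_, fit.n_snp_, h.outcome_id,
    )


def conditional_f(h: HarmonizedSet, exposure_index: int) -> float:
    """Conditional instrument strength of one exposure given the other.

    Profiles ``Q(delta) = sum_j (beta_a - delta*beta_b)^2 /
    (se_a^2 + delta^2 se_b^2)`` over the nuisance loading ``delta`` and
    reports ``Q_min / (k - 1)``.  When the other exposure carries no signal
    the profile has no interior minimum; the inverse-variance regression
    estimate of ``delta`` is used instead.
    """
    X, se_X = _three_way_arrays(h)
    a, b = exposure_index, 1 - exposure_index
    ba, bb = X[:, a], X[:, b]
    sa, sb = se_X[:, a], se_X[:, b]
    k = len(ba)
    if k < 3:
        raise InsufficientSNPsError("conditional F requires >= 3 variants")

    def q(delta):
        return np.sum((ba - delta * bb) ** 2 / (sa ** 2 + delta ** 2 * sb ** 2))

    denom = float(np.sum(bb ** 2 / sa ** 2))
    delta_reg = float(np.sum(ba * bb / sa ** 2)) / denom if denom > 0 else 0.0
    span = 10.0 * (abs(delta_reg) + 1.0)
    res = optimize.minimize_scalar(
        q, bounds=(delta_reg - span, delta_reg + span), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise ProtmedError(f"conditional-F profile failed: {res.message}")
    q_min = float(res.fun)
    # boundary solution => degenerate profile (no signal in the other
    # exposure); fall back to the regression value of delta
    if min(res.x - (delta_reg - span), (delta_reg + span) - res.x) < 1e-6 * span:
        q_min = float(q(delta_reg))
    return q_min / (k - 1)


def build_mvmr_set(
    exposure_instruments,
    mediator_instruments,
    exposure: SummaryTable,
    mediator: SummaryTable,
    outcome: SummaryTable,
    ld: LDMatrix,
    r2: float = 0.001,
    window_kb: int = 10_000,
) -> HarmonizedSet:
    """Combine exposure and mediator instruments into one three-way set.

    The union of instrument ids is de-duplicated, re-clumped at ``r2``
    prioritizing the smaller of each variant's exposure/mediator association
    p-values, and harmonized across the three summary tables.
    """
    union = list(dict.fromkeys(
        list(exposure_instruments.variant_ids)
        + list(mediator_instruments.variant_ids)
    ))
    exp_sub = exposure.subset(union)
    med_p = dict(zip(mediator.records["variant_id"], mediator.records["pval"]))
    combined = exp_sub.records.copy()
    combined["pval"] = [
        min(p, med_p.get(v, np.inf))
        for v, p in zip(combined["variant_id"], combined["pval"])
    ]
    ranked = SummaryTable(exposure.trait_id, exposure.trait_type, combined)
    clumped = ld_clump(ranked, ld, r2_threshold=r2, window_kb=window_kb)
    if len(clumped) == 0:
        raise InsufficientSNPsError("empty union after clumping")
    log_event(
        "build_mvmr_set", exposure=exposure.trait_id,
        mediator=mediator.trait_id, n_union=len(union), n_clumped=len(clumped),
    )
    return harmonize(
        exposure.subset(clumped.variant_ids), outcome, mediator=mediator
    )
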