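"""Single-causal-variant approximate-Bayes-factor colocalization.

For a genomic region shared by two traits, the method computes a
per-variant Wakefield log approximate Bayes factor (lABF) for each trait
and combines them into posterior probabilities over five hypotheses:

- h0: no association with either trait;
- h1/h2: association with trait 1/2 only;
- h3: both traits associated, distinct causal variants;
- h4: both traits associated, one shared causal variant.

Per-variant priors ``p1``, ``p2`` (trait-specific causality) and ``p12``
(shared causality) enter the hypothesis weights.  Robustness of an
``h4 >= 0.8`` call is probed over a grid of region windows and prior sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import DomainError
from .runlog import log_event
from .sumstats import CASE_CONTROL, SummaryTable

#: effect-scale prior standard deviations (per-SD scale for continuous
#: traits; log-odds scale for case-control traits)
PRIOR_SD_CONTINUOUS = 0.15
PRIOR_SD_CASE_CONTROL = 0.2

#: main priors, chosen for a region of ~5000 variants
DEFAULT_PRIORS = None  # set below


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of causality."""

    p1: float = 1e-6
    p2: float = 1e-6
    p12: float = 1e-7

    def __post_init__(self):
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DomainError(f"{name} must lie in (0, 1), got {v}")
        if self.p12 > min(self.p1, self.p2):
            log_event("coloc_prior_warning",
                      message="p12 exceeds min(p1, p2)", priors=str(self))


DEFAULT_PRIORS = ColocPriors()
#: the sensitivity prior sets probed alongside the main priors
SENSITIVITY_PRIORS = (ColocPriors(1e-5, 1e-5, 1e-6),)
#: region windows (bp) probed in the sensitivity grid; 1 Mb is the main cell
SENSITIVITY_WINDOWS_BP = (250_000, 500_000, 1_000_000, 2_000_000)
MAIN_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities over the five sharing hypotheses."""

    h0: float
    h1: float
    h2: float
    h3: float
    h4: float
    n_variants: int
    window_bp: int = 0
    priors: ColocPriors = DEFAULT_PRIORS

    @property
    def posteriors(self):
        return np.array([self.h0, self.h1, self.h2, self.h3, self.h4])


def prior_sd_for(trait_type: str) -> float:
    return (PRIOR_SD_CASE_CONTROL if trait_type == CASE_CONTROL
            else PRIOR_SD_CONTINUOUS)


def wakefield_labf(beta, se, prior_sd: float):
    """Wakefield log approximate Bayes factor for one association.

    With ``V = se^2``, ``W = prior_sd^2``, ``r = W/(V+W)`` and ``z = beta/se``:
    ``lABF = 0.5*(log(1 - r) + r*z^2)``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DomainError("se must be > 0")
    v = se ** 2
    r = prior_sd ** 2 / (v + prior_sd ** 2)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log1p(-r) + r * z2)


def _logdiffexp(a, b):
    """log(exp(a) - exp(b)) for a >= b, -inf when equal within rounding."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_region(
    trait1: SummaryTable,
    trait2: SummaryTable,
    priors: ColocPriors = DEFAULT_PRIORS,
    window_bp: int = 0,
) -> ColocResult:
    """Colocalization posteriors for the variants shared by two region slices.

    Orientation of effects is irrelevant (z enters squared).  With a single
    shared variant the distinct-causal-variant hypothesis h3 has no support
    and receives zero mass (logged).
    """
    df1 = trait1.records.set_index("variant_id")
    df2 = trait2.records.set_index("variant_id")
    shared = df1.index.intersection(df2.index)
    if len(shared) == 0:
        raise DomainError("no shared variants in the region")
    if len(shared) == 1:
        log_event("coloc_single_variant", trait1=trait1.trait_id,
                  trait2=trait2.trait_id)

    l1 = wakefield_labf(df1.loc[shared, "beta"], df1.loc[shared, "se"],
                        prior_sd_for(trait1.trait_type))
    l2 = wakefield_labf(df2.loc[shared, "beta"], df2.loc[shared, "se"],
                        prior_sd_for(trait2.trait_type))
    return _posteriors_from_labf(np.asarray(l1), np.asarray(l2), priors,
                                 window_bp)


def _posteriors_from_labf(l1, l2, priors: ColocPriors,
                          window_bp: int = 0) -> ColocResult:
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    log_l = np.array([
        0.0,
        np.log(priors.p1) + s1,
        np.log(priors.p2) + s2,
        np.log(priors.p1) + np.log(priors.p2) + _logdiffexp(s1 + s2, s12),
        np.log(priors.p12) + s12,
    ])
    post = np.exp(log_l - logsumexp(log_l))
    post = post / post.sum()
    return ColocResult(*post, n_variants=len(l1),
                       window_bp=window_bp, priors=priors)


def _slice_region(table: SummaryTable, chrom, center, half_window):
    df = table.records
    keep = (df["chrom"].astype(str) == str(chrom)) & (
        (df["pos"] - center).abs() <= half_window
    )
    return SummaryTable(table.trait_id, table.trait_type, df[keep].copy())


@dataclass
class SensitivityGrid:
    """Coloc posteriors across (window, priors) cells plus a robustness call.

    The verdict is True when h4 >= threshold in the main cell (1 Mb window,
    main priors), in at least two non-main windows under the main priors,
    and in at least one non-main prior set at the main window.
    """

    cells: list  # (window_bp, ColocPriors, ColocResult or None)
    robust: bool
    h4_main: float

    def to_rows(self, protein="", outcome=""):
        rows = []
        for window, priors, res in self.cells:
            if res is None:
                continue
            rows.append({
                "protein": protein, "outcome": outcome, "window": window,
                "p1": priors.p1, "p2": priors.p2, "p12": priors.p12,
                "n_variants": res.n_variants,
                "h0": res.h0, "h1": res.h1, "h2": res.h2,
                "h3": res.h3, "h4": res.h4, "robust": self.robust,
            })
        return rows


def sensitivity_grid(
    trait1: SummaryTable,
    trait2: SummaryTable,
    index_variant: str,
    windows_bp=SENSITIVITY_WINDOWS_BP,
    prior_sets=(DEFAULT_PRIORS,) + SENSITIVITY_PRIORS,
    h4_threshold: float = 0.8,
) -> SensitivityGrid:
    """Window/prior sensitivity analysis around a lead (index) cis variant."""
    lead = trait1.lookup(index_variant)
    chrom, center = lead["chrom"], int(lead["pos"])

    # slice the widest window once, compute per-variant lABFs once, and
    # re-use them for every narrower window and prior set
    max_half = max(windows_bp) // 2
    r1 = _slice_region(trait1, chrom, center, max_half)
    r2 = _slice_region(trait2, chrom, center, max_half)
    df1 = r1.records.set_index("variant_id")
    df2 = r2.records.set_index("variant_id")
    shared_all = df1.index.intersection(df2.index)
    cells = []
    if len(shared_all) == 0:
        cells = [(w, p, None) for w in windows_bp for p in prior_sets]
    else:
        pos = df1.loc[shared_all, "pos"].to_numpy()
        l1 = np.asarray(wakefield_labf(
            df1.loc[shared_all, "beta"], df1.loc[shared_all, "se"],
            prior_sd_for(trait1.trait_type)))
        l2 = np.asarray(wakefield_labf(
            df2.loc[shared_all, "beta"], df2.loc[shared_all, "se"],
            prior_sd_for(trait2.trait_type)))
        for window in windows_bp:
            mask = np.abs(pos - center) <= window // 2
            for priors in prior_sets:
                if not mask.any():
                    cells.append((window, priors, None))
                    continue
                cells.append((window, priors, _posteriors_from_labf(
                    l1[mask], l2[mask], priors, window)))

    def h4(window, priors):
        for w, p, res in cells:
            if w == window and p == priors and res is not None:
                return res.h4
        return float("nan")

    h4_main = h4(MAIN_WINDOW_BP, DEFAULT_PRIORS)
    non_main_windows = [w for w in windows_bp if w != MAIN_WINDOW_BP]
    n_windows_ok = sum(
        1 for w in non_main_windows
        if h4(w, DEFAULT_PRIORS) >= h4_threshold
    )
    n_priors_ok = sum(
        1 for p in prior_sets if p != DEFAULT_PRIORS
        and h4(MAIN_WINDOW_BP, p) >= h4_threshold
    )
    robust = (
        (h4_main >= h4_threshold)
        and n_windows_ok >= 2
        and n_priors_ok >= 1
    )
    return SensitivityGrid(cells, bool(robust), float(h4_main))
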