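"""Effective number of independent tests from a phenotype correlation matrix.

Screening thousands of correlated protein traits requires a multiple-testing
threshold that respects their correlation.  The phenotype correlation matrix
is estimated from summary statistics (correlation of z-scores over shared,
null-ish variants), spectrally decomposed, and the effective number of
independent tests (Meff) computed two ways:

- Nyholt: ``Meff = 1 + (m - 1) * (1 - var(lambda)/m)``;
- Li & Ji: ``Meff = sum_i [I(lambda_i >= 1) + (lambda_i - floor(lambda_i))]``.

The more conservative (larger) Meff sets the corrected per-test threshold
``alpha = 0.05 / Meff``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

Z_CAP_DEFAULT = 1.96
MIN_SHARED = 100


@dataclass(frozen=True)
class EffTests:
    """Effective-number-of-tests summary for m correlated traits."""

    m: int
    meff_nyholt: float
    meff_liji: float

    @property
    def meff_used(self) -> float:
        """The more conservative (larger) of the two estimates."""
        return max(self.meff_nyholt, self.meff_liji)

    @property
    def alpha_corrected(self) -> float:
        return 0.05 / self.meff_used


def estimate_pheno_corr(tables, z_cap: float = Z_CAP_DEFAULT) -> pd.DataFrame:
    """Pairwise phenotypic correlation of traits from summary z-scores.

    For each pair, Pearson correlation of z-scores over the variants shared
    by both tables whose |z| < ``z_cap`` in both traits (restricting to
    null-ish variants so genetic signal does not masquerade as phenotypic
    correlation).  Requires >= 100 qualifying variants per pair.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise DomainError("need at least two traits")
    ids = [t.trait_id for t in tables]
    zs = []
    for t in tables:
        df = t.records
        z = pd.Series(
            (df["beta"] / df["se"]).to_numpy(),
            index=df["variant_id"].to_numpy(),
        )
        zs.append(z)
    common = zs[0].index
    for z in zs[1:]:
        common = common.intersection(z.index)
    zmat = np.column_stack([z.loc[common].to_numpy() for z in zs])
    null_mask = np.abs(zmat) < z_cap

    m = len(tables)
    corr = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            both = null_mask[:, i] & null_mask[:, j]
            if both.sum() < MIN_SHARED:
                raise DomainError(
                    f"fewer than {MIN_SHARED} shared null variants for pair "
                    f"({ids[i]}, {ids[j]})"
                )
            r = np.corrcoef(zmat[both, i], zmat[both, j])[0, 1]
            corr[i, j] = corr[j, i] = r
    return pd.DataFrame(corr, index=ids, columns=ids)


def effective_tests(corr) -> EffTests:
    """Spectral-decomposition estimates of the effective number of tests."""
    mat = corr.to_numpy(dtype=float) if hasattr(corr, "to_numpy") else (
        np.asarray(corr, dtype=float)
    )
    m = mat.shape[0]
    if mat.shape != (m, m):
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValidationError("correlation matrix must have unit diagonal")

    lam = np.linalg.eigvalsh(mat)
    lam = np.clip(lam, 0.0, None)

    var_lam = float(np.var(lam, ddof=1)) if m > 1 else 0.0
    meff_nyholt = 1.0 + (m - 1) * (1.0 - var_lam / m)

    meff_liji = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))

    return EffTests(m, float(meff_nyholt), meff_liji)
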