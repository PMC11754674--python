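"""GWAS summary-statistic containers, I/O, harmonization, clumping, proxies.

The on-disk dialect is a tab-separated table with a fixed header::

    variant_id chrom pos effect_allele other_allele eaf beta se pval n n_case n_control

with ``NA`` as the missing-value token.  ``beta`` is on the
inverse-rank-normal (per-SD) scale for continuous traits and the log-odds
scale for case-control traits.  LD is consumed as a precomputed square
matrix of signed correlations ``r`` with a variant-id header row and column.

Two-sample MR requires every per-variant effect pair to refer to the same
effect allele; :func:`harmonize` aligns an outcome (and optionally a
mediator) table to the exposure's allele coding, resolving strand-ambiguous
(palindromic) variants by allele frequency or dropping them when the
frequency is uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    EmptyOverlapError,
    FormatError,
    ValidationError,
    VariantLookupError,
)
from .runlog import log_event

COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_case", "n_control",
]

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

CONTINUOUS = "continuous"
CASE_CONTROL = "case_control"

#: default half-width of the allele-frequency band around 0.5 inside which
#: palindromic variants are considered unresolvable and dropped
PALINDROME_EAF_BAND = 0.08


@dataclass(frozen=True)
class TraitMeta:
    """Identity and measurement scale of one GWAS trait."""

    trait_id: str
    trait_type: str = CONTINUOUS

    def __post_init__(self):
        if self.trait_type not in (CONTINUOUS, CASE_CONTROL):
            raise ValidationError(
                f"unknown trait_type {self.trait_type!r} for {self.trait_id}"
            )


@dataclass
class SummaryTable:
    """Per-variant association records for a single trait.

    ``records`` is a DataFrame with the dialect columns; ``variant_id`` is
    unique within the table.
    """

    trait_id: str
    trait_type: str
    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"missing columns {missing} in {self.trait_id}")
        if self.records["variant_id"].duplicated().any():
            dupes = self.records.loc[
                self.records["variant_id"].duplicated(), "variant_id"
            ].tolist()
            raise ValidationError(
                f"duplicate variant_id in {self.trait_id}: {dupes[:5]}"
            )
        self.records = self.records.reset_index(drop=True)

    def __len__(self):
        return len(self.records)

    @property
    def variant_ids(self):
        return self.records["variant_id"].tolist()

    def subset(self, variant_ids) -> "SummaryTable":
        keep = self.records[self.records["variant_id"].isin(set(variant_ids))]
        return SummaryTable(self.trait_id, self.trait_type, keep.copy())

    def lookup(self, variant_id) -> pd.Series:
        hit = self.records[self.records["variant_id"] == variant_id]
        if hit.empty:
            raise VariantLookupError(
                f"{variant_id} not in table {self.trait_id}"
            )
        return hit.iloc[0]


def _validate_rows(df: pd.DataFrame):
    """Return 1-based row numbers violating the record invariants."""
    bad = pd.Series(False, index=df.index)
    bad |= ~(df["se"] > 0)
    bad |= ~((df["pval"] > 0) & (df["pval"] <= 1))
    eaf = df["eaf"]
    bad |= eaf.notna() & ~((eaf >= 0) & (eaf <= 1))
    for col in ("effect_allele", "other_allele"):
        bad |= ~df[col].astype(str).isin(list(_VALID_ALLELES))
    both = df["n_case"].notna() & df["n_control"].notna() & df["n"].notna()
    bad |= both & (df["n_case"] + df["n_control"] != df["n"])
    bad |= ~(df["pos"] >= 1)
    return [int(i) + 1 for i in df.index[bad]]


def read_sumstats(path, trait_meta: TraitMeta, strict: bool = True) -> SummaryTable:
    """Read and validate one summary-statistic file.

    With ``strict`` (default) any row violating a record invariant raises
    :class:`ValidationError` naming the offending 1-based data rows; with
    ``strict=False`` offending rows are dropped and counted in the run log.
    """
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"variant_id": str, "chrom": str, "effect_allele": str,
               "other_allele": str},
    )
    if list(df.columns) != COLUMNS:
        raise FormatError(
            f"{path}: header {list(df.columns)} does not match dialect {COLUMNS}"
        )
    bad_rows = _validate_rows(df)
    if bad_rows and strict:
        raise ValidationError(
            f"{path}: invalid records on data rows {bad_rows}", rows=bad_rows
        )
    if bad_rows:
        df = df.drop(index=[r - 1 for r in bad_rows])
    log_event(
        "read_sumstats", path=str(path), trait=trait_meta.trait_id,
        n_records=len(df), n_rejected=len(bad_rows),
    )
    return SummaryTable(trait_meta.trait_id, trait_meta.trait_type, df)


def write_sumstats(table: SummaryTable, path):
    """Write a table in the package dialect (``NA`` for missing)."""
    out = table.records[COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class LDMatrix:
    """Signed LD correlations for an ordered panel of variants.

    ``validate=False`` skips the invariant checks for matrices constructed
    symmetric by design (e.g. by the simulator).
    """

    variant_ids: list
    r: np.ndarray
    validate: bool = True
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValidationError("LD matrix shape does not match variant ids")
        if self.validate:
            if not np.allclose(self.r, self.r.T, atol=1e-12):
                raise ValidationError("LD matrix is not symmetric")
            if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
                raise ValidationError("LD matrix diagonal is not 1")
            if np.any(np.abs(self.r) > 1 + 1e-9):
                raise ValidationError("LD correlations outside [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id):
        return variant_id in self._index

    def corr(self, a, b) -> float:
        try:
            return float(self.r[self._index[a], self._index[b]])
        except KeyError as exc:
            raise VariantLookupError(f"{exc.args[0]} not in LD matrix") from exc

    def submatrix(self, variant_ids) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


def read_ld_matrix(path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: LD row/column variant ids differ")
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path):
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


@dataclass(frozen=True)
class ProxyHit:
    """An outcome-present stand-in for a missing variant.

    ``r`` is the signed LD correlation between the coded (effect) alleles of
    the target and the proxy in the reference panel; its sign orients the
    proxy's effect during harmonization.
    """

    variant_id: str
    r: float

    @property
    def r2(self):
        return self.r ** 2


# harmonization action tags
KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"
PROXIED = "proxied"


@dataclass
class HarmonizedSet:
    """Exposure/outcome (optionally /mediator) effects on shared effect alleles."""

    variant_ids: list
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    beta_med: Optional[np.ndarray] = None
    se_med: Optional[np.ndarray] = None
    actions: list = field(default_factory=list)
    #: action tags for variants excluded during harmonization
    dropped: dict = field(default_factory=dict)
    exposure_id: str = ""
    outcome_id: str = ""
    mediator_id: str = ""

    def __post_init__(self):
        for arr in ("beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
        if self.beta_med is not None:
            self.beta_med = np.asarray(self.beta_med, dtype=float)
            self.se_med = np.asarray(self.se_med, dtype=float)
        k = len(self.variant_ids)
        if not (len(self.beta_exp) == len(self.beta_out) == k):
            raise ValidationError("harmonized arrays have unequal lengths")
        if not self.actions:
            self.actions = [KEPT] * k

    @property
    def n_snp(self):
        return len(self.variant_ids)

    def subset(self, idx) -> "HarmonizedSet":
        idx = np.asarray(idx)
        return HarmonizedSet(
            [self.variant_ids[i] for i in idx],
            self.beta_exp[idx], self.se_exp[idx],
            self.beta_out[idx], self.se_out[idx],
            None if self.beta_med is None else self.beta_med[idx],
            None if self.se_med is None else self.se_med[idx],
            [self.actions[i] for i in idx],
            dict(self.dropped),
            self.exposure_id, self.outcome_id, self.mediator_id,
        )


def _is_palindromic(ea, oa):
    return frozenset((ea, oa)) in _PALINDROMIC_PAIRS


def _orient_to(row_exp, ea, oa, beta, eaf):
    """Express (beta, eaf, ok_alleles) relative to the exposure's effect allele."""
    if ea == row_exp.effect_allele and oa == row_exp.other_allele:
        return beta, eaf, KEPT
    if ea == row_exp.other_allele and oa == row_exp.effect_allele:
        return -beta, None if eaf is None else 1.0 - eaf, FLIPPED
    return None, None, DROPPED_MISMATCH


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_eaf_band: float = PALINDROME_EAF_BAND,
    mediator: Optional[SummaryTable] = None,
    proxies: Optional[dict] = None,
) -> HarmonizedSet:
    """Align outcome (and mediator) effects to the exposure's effect alleles.

    Outcome rows with swapped effect/other alleles have their beta negated
    and eaf complemented.  Palindromic variants (A/T, C/G) with eaf within
    ``palindrome_eaf_band`` of 0.5 in either study, or with missing eaf, are
    dropped; otherwise they are oriented so that minor/major allele status
    agrees between the studies.  ``proxies`` maps exposure variant ids
    missing from the outcome to :class:`ProxyHit` substitutes.

    Raises :class:`EmptyOverlapError` when no variant survives.
    """
    proxies = proxies or {}
    out_idx = {v: i for i, v in enumerate(outcome.records["variant_id"])}
    med_idx = (
        {v: i for i, v in enumerate(mediator.records["variant_id"])}
        if mediator is not None else None
    )

    ids, b_exp, s_exp, b_out, s_out, b_med, s_med, actions = (
        [], [], [], [], [], [], [], []
    )
    dropped = {}

    for row in exposure.records.itertuples(index=False):
        vid = row.variant_id
        proxy_sign = 1.0
        proxied = False
        out_key = vid
        if vid not in out_idx:
            hit = proxies.get(vid)
            if hit is None or hit.variant_id not in out_idx:
                continue
            out_key = hit.variant_id
            proxy_sign = np.sign(hit.r) or 1.0
            proxied = True
        orow = outcome.records.iloc[out_idx[out_key]]

        if proxied:
            # proxy orientation comes from the signed LD r, not from alleles
            beta_o = proxy_sign * float(orow["beta"])
            eaf_o = None if pd.isna(orow["eaf"]) else (
                float(orow["eaf"]) if proxy_sign > 0 else 1.0 - float(orow["eaf"])
            )
            act = PROXIED
        else:
            eaf_raw = None if pd.isna(orow["eaf"]) else float(orow["eaf"])
            beta_o, eaf_o, act = _orient_to(
                row, str(orow["effect_allele"]), str(orow["other_allele"]),
                float(orow["beta"]), eaf_raw,
            )
            if act == DROPPED_MISMATCH:
                dropped[vid] = DROPPED_MISMATCH
                continue
            if _is_palindromic(row.effect_allele, row.other_allele):
                eaf_e = None if pd.isna(row.eaf) else float(row.eaf)
                ambiguous = (
                    eaf_e is None or eaf_o is None
                    or abs(eaf_e - 0.5) < palindrome_eaf_band
                    or abs(eaf_o - 0.5) < palindrome_eaf_band
                )
                if ambiguous:
                    dropped[vid] = DROPPED_PALINDROMIC
                    continue
                if (eaf_e - 0.5) * (eaf_o - 0.5) < 0:
                    # strand flip: same labels but opposite frequency side
                    beta_o = -beta_o
                    eaf_o = 1.0 - eaf_o
                    act = FLIPPED

        med_vals = (None, None)
        if med_idx is not None:
            if out_key not in med_idx if proxied else vid not in med_idx:
                dropped[vid] = DROPPED_MISMATCH
                continue
            mrow = mediator.records.iloc[med_idx[out_key if proxied else vid]]
            if proxied:
                beta_m = proxy_sign * float(mrow["beta"])
            else:
                eaf_m = None if pd.isna(mrow["eaf"]) else float(mrow["eaf"])
                beta_m, _, mact = _orient_to(
                    row, str(mrow["effect_allele"]), str(mrow["other_allele"]),
                    float(mrow["beta"]), eaf_m,
                )
                if mact == DROPPED_MISMATCH:
                    dropped[vid] = DROPPED_MISMATCH
                    continue
                if _is_palindromic(row.effect_allele, row.other_allele):
                    eaf_e = None if pd.isna(row.eaf) else float(row.eaf)
                    if eaf_m is None:
                        dropped[vid] = DROPPED_PALINDROMIC
                        continue
                    eaf_m_c = eaf_m if mact == KEPT else 1.0 - eaf_m
                    if abs(eaf_m_c - 0.5) < palindrome_eaf_band:
                        dropped[vid] = DROPPED_PALINDROMIC
                        continue
                    if (float(row.eaf) - 0.5) * (eaf_m_c - 0.5) < 0:
                        beta_m = -beta_m
            med_vals = (beta_m, float(mrow["se"]))

        ids.append(vid)
        b_exp.append(float(row.beta))
        s_exp.append(float(row.se))
        b_out.append(beta_o)
        s_out.append(float(orow["se"]))
        b_med.append(med_vals[0])
        s_med.append(med_vals[1])
        actions.append(act)

    if not ids:
        raise EmptyOverlapError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}"
        )
    log_event(
        "harmonize", exposure=exposure.trait_id, outcome=outcome.trait_id,
        n_kept=len(ids), n_dropped=len(dropped),
    )
    return HarmonizedSet(
        ids, b_exp, s_exp, b_out, s_out,
        np.array(b_med, dtype=float) if mediator is not None else None,
        np.array(s_med, dtype=float) if mediator is not None else None,
        actions, dropped,
        exposure.trait_id, outcome.trait_id,
        mediator.trait_id if mediator is not None else "",
    )


def ld_clump(
    table: SummaryTable,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> SummaryTable:
    """Greedy p-value-ordered LD clumping.

    Repeatedly keeps the remaining variant with the smallest p-value and
    removes every remaining variant with ``r^2 > r2_threshold`` to it within
    ``window_kb`` kilobases on the same chromosome.  Variants absent from
    the LD reference cannot be assessed and are dropped with a logged
    warning.  Output is ordered by p-value.
    """
    df = table.records
    in_ld = df["variant_id"].map(lambda v: v in ld).astype(bool)
    n_unassessable = int((~in_ld).sum())
    if n_unassessable:
        log_event(
            "ld_clump_dropped_unassessable", trait=table.trait_id,
            n_dropped=n_unassessable,
            variants=df.loc[~in_ld, "variant_id"].tolist(),
        )
    df = df[in_ld].sort_values("pval", kind="mergesort").reset_index(drop=True)
    if df.empty:
        return SummaryTable(table.trait_id, table.trait_type, df)

    vids = df["variant_id"].to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    idx = np.array([ld._index[v] for v in vids])
    window_bp = int(window_kb) * 1000

    alive = np.ones(len(df), dtype=bool)
    keep = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        keep.append(i)
        same = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        r_row = ld.r[idx[i], idx[same]]
        kill = np.zeros(len(df), dtype=bool)
        kill[np.flatnonzero(same)] = r_row ** 2 > r2_threshold
        kill[i] = False
        alive &= ~kill
        alive[i] = False
    out = df.iloc[keep].reset_index(drop=True)
    log_event(
        "ld_clump", trait=table.trait_id, n_in=len(table), n_out=len(out),
        r2_threshold=r2_threshold, window_kb=window_kb,
    )
    return SummaryTable(table.trait_id, table.trait_type, out)


def find_proxy(
    target: str,
    outcome: SummaryTable,
    ld: LDMatrix,
    min_r2: float = 0.8,
) -> Optional[ProxyHit]:
    """Best outcome-present stand-in for ``target`` at ``r^2 >= min_r2``.

    Returns the target itself (r = 1) when it is present in the outcome,
    otherwise the outcome variant with the highest ``r^2`` to the target
    among those passing the threshold, or ``None``.
    """
    if target not in ld:
        raise VariantLookupError(f"{target} not in LD matrix")
    present = set(outcome.records["variant_id"])
    if target in present:
        return ProxyHit(target, 1.0)
    best = None
    for vid in outcome.records["variant_id"]:
        if vid not in ld:
            continue
        r = ld.corr(target, vid)
        if r ** 2 >= min_r2 and (best is None or r ** 2 > best.r2):
            best = ProxyHit(vid, r)
    return best
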