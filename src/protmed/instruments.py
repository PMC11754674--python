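"""Instrument selection: genome-wide and cis sets, and instrument strength.

Genome-wide instruments pass the conventional ``P < 5e-8`` threshold and an
LD-independence clump at ``r^2 = 0.001``.  cis-pQTL instruments are
restricted to within 1 Mb of the protein-coding gene's transcription start
site and use the stricter proteome-wide ``P < 1.8e-9`` threshold.  Strength
is summarized by the per-variant F-statistic ``(beta/se)^2`` and its mean
over the set; mean F <= 10 flags a weak instrument but does not exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInstrumentError
from .runlog import log_event
from .sumstats import LDMatrix, SummaryTable, ld_clump

GENOME_WIDE_P = 5e-8
CIS_P = 1.8e-9
CIS_WINDOW_BP = 1_000_000
WEAK_F = 10.0

GENOME_WIDE = "genome_wide"
CIS = "cis"


@dataclass(frozen=True)
class GeneAnnotation:
    """Transcription start site of a protein-coding gene."""

    gene_id: str
    chrom: str
    tss: int

    def __post_init__(self):
        if self.tss < 1:
            raise DomainError(f"tss must be >= 1, got {self.tss}")


def read_gene_annotation(path) -> dict:
    """Read a ``gene_id chrom tss`` table into {gene_id: GeneAnnotation}."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return {
        r.gene_id: GeneAnnotation(r.gene_id, r.chrom, int(r.tss))
        for r in df.itertuples(index=False)
    }


@dataclass
class InstrumentSet:
    """LD-independent variants instrumenting one trait."""

    trait_id: str
    table: SummaryTable
    selection_mode: str
    f_per_variant: np.ndarray
    mean_f: float
    weak: bool

    @property
    def variant_ids(self):
        return self.table.variant_ids

    def __len__(self):
        return len(self.table)


def f_statistic(beta, se):
    """Per-variant instrument F-statistic, ``(beta/se)^2``."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DomainError("se must be > 0 for the F-statistic")
    return (beta / se) ** 2


def _build_set(trait_id, table, mode):
    if len(table) == 0:
        raise EmptyInstrumentError(f"no instruments for {trait_id} ({mode})")
    f = f_statistic(table.records["beta"], table.records["se"])
    mean_f = float(np.mean(f))
    weak = mean_f <= WEAK_F
    if weak:
        log_event("weak_instrument", trait=trait_id, mode=mode, mean_f=mean_f)
    return InstrumentSet(trait_id, table, mode, f, mean_f, weak)


def select_genome_wide(
    table: SummaryTable,
    ld: LDMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2: float = 0.001,
    window_kb: int = 10_000,
) -> InstrumentSet:
    """Genome-wide-significant, LD-clumped instrument set.

    Raises :class:`EmptyInstrumentError` when no variant passes; callers
    decide whether that is fatal.
    """
    passing = table.records[table.records["pval"] < p_threshold]
    sub = SummaryTable(table.trait_id, table.trait_type, passing.copy())
    clumped = ld_clump(sub, ld, r2_threshold=r2, window_kb=window_kb)
    return _build_set(table.trait_id, clumped, GENOME_WIDE)


def select_cis(
    table: SummaryTable,
    gene: GeneAnnotation,
    ld: LDMatrix,
    p_threshold: float = CIS_P,
    window_bp: int = CIS_WINDOW_BP,
    r2: float = 0.001,
) -> InstrumentSet:
    """cis instrument set: within ``window_bp`` of the gene TSS, ``P <
    p_threshold``, clumped within the cis region.

    Raises :class:`EmptyInstrumentError` when the protein has no cis
    instruments (such proteins are excluded from cis-MR, not from the study).
    """
    df = table.records
    in_cis = (df["chrom"].astype(str) == str(gene.chrom)) & (
        (df["pos"] - gene.tss).abs() <= window_bp
    )
    passing = df[in_cis & (df["pval"] < p_threshold)]
    sub = SummaryTable(table.trait_id, table.trait_type, passing.copy())
    # the 1 Mb region is its own clumping window
    clumped = ld_clump(
        sub, ld, r2_threshold=r2, window_kb=2 * window_bp // 1000
    )
    return _build_set(table.trait_id, clumped, CIS)
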