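"""Linked two-sample GWAS summary statistics with known causal structure.

The generator emulates the statistical shape of the study's three data
sources: inverse-rank-normal continuous adiposity and protein traits, a
case-control outcome on the log-odds scale, non-overlapping cohorts, and an
LD-structured variant panel organised in AR-1 blocks.  Summary statistics
are produced directly at the summary level: true per-variant joint effects
(on the standardized-genotype scale) are propagated through the regional LD
matrix to expected marginal effects, and each cohort adds its own
LD-correlated sampling noise with ``se = 1/sqrt(2 f (1-f) n)`` on the
per-allele scale (effective sample size ``4/(1/ncase + 1/nctrl)`` for the
binary outcome).

The causal structure is a configurable mediation graph: exposures affect a
subset of proteins (matrix ``alpha``), proteins affect outcomes (matrix
``gamma``), exposures may affect outcomes directly (``theta_direct``), and
a fraction of exposure instruments may carry direct (pleiotropic) outcome
effects.  Every planted quantity is returned in a :class:`GroundTruth`
record sufficient to recompute the expected value of any downstream
estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError
from .instruments import GeneAnnotation
from .sumstats import (
    CASE_CONTROL,
    CONTINUOUS,
    COLUMNS,
    LDMatrix,
    SummaryTable,
    write_ld_matrix,
    write_sumstats,
)

_PVAL_FLOOR = 1e-320

_ALLELE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]

_EXPOSURE_NAMES = ["BMI", "WHR", "BMI_F", "WHR_F", "BMI_M", "WHR_M"]
_OUTCOME_NAMES = ["CRC", "CRC_colon", "CRC_proximal", "CRC_distal", "CRC_rectal"]


@dataclass(frozen=True)
class SimConfig:
    """Study-generating parameters.

    Cohort sizes default to the scale of the emulated sources (a ~450k
    adiposity GWAS, a ~35k plasma-proteome GWAS, and a case-control cancer
    GWAS with ~58k cases and ~67k controls).  The default causal structure
    plants one fully mediated exposure->protein->outcome chain (protein 0,
    exposure 0, outcome 0) as a positive control, makes 40% of the
    remaining proteins adiposity-responsive and 10% outcome-associated,
    and leaves direct and pleiotropic paths off.
    """

    # panel geometry
    region_size_exposure: int = 11
    region_size_gene: int = 61
    region_size_outcome: int = 11
    variant_spacing_bp: int = 10_000
    rho: float = 0.9
    freq_bounds: tuple = (0.05, 0.95)
    # cohorts (two-sample: every trait has its own non-overlapping cohort)
    n_exposure: int = 450_000
    n_protein: int = 35_000
    n_case: int = 58_000
    n_control: int = 67_000
    # genetic architecture
    n_exposures: int = 1
    n_exposure_qtls: int = 30
    exposure_h2: float = 0.06
    n_proteins: int = 50
    n_cis_qtls: int = 2
    cis_h2: float = 0.10
    n_outcomes: int = 1
    n_outcome_qtls: int = 10
    outcome_qtl_beta: float = 0.04
    # causal structure
    n_mediators: int = 1
    mediator_alpha: float = 0.15
    mediator_gamma: float = 0.6
    theta_direct: float = 0.0
    frac_adiposity_assoc: float = 0.4
    alpha_other: float = 0.1
    frac_outcome_assoc: float = 0.1
    gamma_other: float = 0.3
    # directional pleiotropy on exposure instruments
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise DomainError("rho must lie in [0, 1)")
        for name in ("n_exposure", "n_protein", "n_case", "n_control"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.n_mediators > self.n_proteins:
            raise DomainError("more mediators than proteins")

    @property
    def exposure_ids(self):
        return _EXPOSURE_NAMES[: self.n_exposures]

    @property
    def protein_ids(self):
        return [f"P{j:03d}" for j in range(self.n_proteins)]

    @property
    def outcome_ids(self):
        return _OUTCOME_NAMES[: self.n_outcomes]

    @property
    def n_eff_outcome(self):
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)


def fixture_config(seed: int = 0) -> SimConfig:
    """A small default study (3 exposures x 50 proteins x 5 outcomes)
    that materializes in well under a minute."""
    return SimConfig(
        n_exposures=3, n_outcomes=5,
        n_exposure_qtls=10, region_size_exposure=5,
        region_size_gene=21, n_outcome_qtls=5, region_size_outcome=5,
        seed=seed,
    )


@lru_cache(maxsize=32)
def _ar1_corr(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@lru_cache(maxsize=32)
def _ar1_chol(size: int, rho: float) -> np.ndarray:
    return np.linalg.cholesky(_ar1_corr(size, rho) + 1e-12 * np.eye(size))


@dataclass
class _Region:
    kind: str          # "exposure" | "gene" | "outcome"
    owner: str         # trait id owning the region
    sl: slice          # slice into the global variant arrays
    size: int


@dataclass
class Panel:
    """Variant panel: ids, coordinates, alleles, frequencies, LD blocks."""

    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    freq: np.ndarray
    regions: list
    rho: float

    @property
    def n_variants(self):
        return len(self.variant_ids)

    def ld_matrix(self) -> LDMatrix:
        """Full block-diagonal signed-r matrix (cross-region LD is zero)."""
        r = np.zeros((self.n_variants, self.n_variants))
        for reg in self.regions:
            r[reg.sl, reg.sl] = _ar1_corr(reg.size, self.rho)
        return LDMatrix(list(self.variant_ids), r, validate=False)


def _build_panel(config: SimConfig, rng) -> Panel:
    regions = []
    specs = []
    for e in config.exposure_ids:
        for _ in range(config.n_exposure_qtls):
            specs.append(("exposure", e, config.region_size_exposure))
    for p in config.protein_ids:
        specs.append(("gene", p, config.region_size_gene))
    for o in config.outcome_ids:
        for _ in range(config.n_outcome_qtls):
            specs.append(("outcome", o, config.region_size_outcome))

    total = sum(s[2] for s in specs)
    ids = np.empty(total, dtype=object)
    chrom = np.empty(total, dtype=object)
    pos = np.zeros(total, dtype=np.int64)
    start = 0
    for i, (kind, owner, size) in enumerate(specs):
        sl = slice(start, start + size)
        c = str((i % 22) + 1)
        base = 1_000_000 + (i // 22) * 50_000_000
        for k in range(size):
            ids[start + k] = f"v{i:03d}_{k:03d}"
        chrom[sl] = c
        pos[sl] = base + np.arange(size) * config.variant_spacing_bp
        regions.append(_Region(kind, owner, sl, size))
        start += size

    lo, hi = config.freq_bounds
    freq = rng.uniform(lo, hi, size=total)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    return Panel(ids, chrom, pos, ea, oa, freq, regions, config.rho)


def simulate_panel(config: SimConfig, rng=None):
    """LD matrix (AR-1 per region, zero between regions) and frequencies."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    panel = _build_panel(config, rng)
    return panel.ld_matrix(), panel.freq


def sample_genotypes(panel: Panel, n: int, rng) -> np.ndarray:
    """Gaussian-dosage genotypes (n x variants) with the panel's LD.

    Dosages are continuous with mean ``2f`` and variance ``2f(1-f)`` —
    the same Gaussian approximation the summary-level generator assumes.
    """
    g = np.zeros((n, panel.n_variants))
    for reg in panel.regions:
        chol = _ar1_chol(reg.size, panel.rho)
        # two haplotype draws per individual
        h1 = rng.standard_normal((n, reg.size)) @ chol.T
        h2 = rng.standard_normal((n, reg.size)) @ chol.T
        f = panel.freq[reg.sl]
        sd1 = np.sqrt(f * (1 - f))
        g[:, reg.sl] = 2 * f + sd1 * (h1 + h2)
    return g


@dataclass
class GroundTruth:
    """Everything needed to recompute any expected downstream estimate."""

    alpha: np.ndarray          # (n_exposures, n_proteins) exposure -> protein
    gamma: np.ndarray          # (n_proteins, n_outcomes) protein -> outcome
    theta_direct: np.ndarray   # (n_exposures, n_outcomes)
    mediators: list            # (exposure_id, protein_id, outcome_id)
    causal_variants: dict      # trait_id -> {variant_id: joint std effect}
    genes: dict                # protein_id -> GeneAnnotation
    exposure_ids: list = field(default_factory=list)
    protein_ids: list = field(default_factory=list)
    outcome_ids: list = field(default_factory=list)

    def total_effect(self, e: int, o: int) -> float:
        """Planted total exposure->outcome effect (direct + mediated)."""
        return float(self.theta_direct[e, o] + self.alpha[e] @ self.gamma[:, o])

    def to_json(self, path):
        payload = {
            "alpha": self.alpha.tolist(),
            "gamma": self.gamma.tolist(),
            "theta_direct": self.theta_direct.tolist(),
            "mediators": self.mediators,
            "causal_variants": self.causal_variants,
            "genes": {k: asdict(v) for k, v in self.genes.items()},
            "exposure_ids": self.exposure_ids,
            "protein_ids": self.protein_ids,
            "outcome_ids": self.outcome_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SimStudy:
    """Generated summary tables plus panel and ground truth."""

    config: SimConfig
    panel: Panel
    tables: dict               # trait_id -> SummaryTable
    truth: GroundTruth

    @property
    def ld(self) -> LDMatrix:
        if not hasattr(self, "_ld"):
            self._ld = self.panel.ld_matrix()
        return self._ld


def _scaled_effects(rng, k, total_var):
    """k effect sizes with random shape, rescaled so sum of squares is exact."""
    if k == 0:
        return np.zeros(0)
    raw = rng.standard_normal(k)
    return raw * np.sqrt(total_var / np.sum(raw ** 2))


def _marginal_std(panel: Panel, joint_std: np.ndarray) -> np.ndarray:
    """Propagate joint standardized effects through regional LD."""
    marg = np.zeros_like(joint_std)
    for reg in panel.regions:
        block = joint_std[reg.sl]
        if np.any(block):
            marg[reg.sl] = _ar1_corr(reg.size, panel.rho) @ block
    return marg


def _noisy_z(panel: Panel, marg_std, n, rng) -> np.ndarray:
    """Marginal z-scores: expected value plus LD-correlated noise."""
    z = np.sqrt(n) * marg_std
    for reg in panel.regions:
        chol = _ar1_chol(reg.size, panel.rho)
        z[reg.sl] += chol @ rng.standard_normal(reg.size)
    return z


def _table_from_z(panel, trait_id, trait_type, z, n, n_case=None, n_control=None):
    denom = np.sqrt(2 * panel.freq * (1 - panel.freq))
    se = 1.0 / (denom * np.sqrt(n))
    beta = z * se
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), _PVAL_FLOOR, 1.0)
    df = pd.DataFrame({
        "variant_id": panel.variant_ids,
        "chrom": panel.chrom,
        "pos": panel.pos,
        "effect_allele": panel.effect_allele,
        "other_allele": panel.other_allele,
        "eaf": panel.freq,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": float(n if n_case is None else n_case + n_control),
        "n_case": np.nan if n_case is None else float(n_case),
        "n_control": np.nan if n_control is None else float(n_control),
    })
    return SummaryTable(trait_id, trait_type, df[COLUMNS])


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate the full linked study from one seeded configuration.

    Deterministic given ``config`` (including ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    panel = _build_panel(config, rng)
    E, P, O = config.n_exposures, config.n_proteins, config.n_outcomes
    exp_ids, prot_ids, out_ids = (
        config.exposure_ids, config.protein_ids, config.outcome_ids
    )

    # --- causal coefficient matrices -------------------------------------
    alpha = np.zeros((E, P))
    gamma = np.zeros((P, O))
    theta = np.full((E, O), config.theta_direct)
    mediators = []
    med_set = list(range(config.n_mediators))
    for j in med_set:
        alpha[0, j] = config.mediator_alpha
        gamma[j, 0] = config.mediator_gamma
        mediators.append((exp_ids[0], prot_ids[j], out_ids[0]))
    others = [j for j in range(P) if j not in med_set]
    n_adip = int(round(config.frac_adiposity_assoc * P))
    n_ocr = int(round(config.frac_outcome_assoc * P))
    adip = others[:n_adip]
    ocr = others[n_adip:n_adip + n_ocr]
    for e in range(E):
        signs = rng.choice([-1.0, 1.0], size=len(adip))
        alpha[e, adip] = config.alpha_other * signs
    for o in range(O):
        signs = rng.choice([-1.0, 1.0], size=len(ocr))
        gamma[ocr, o] = config.gamma_other * signs

    # --- per-variant joint effects (standardized-genotype scale) ---------
    V = panel.n_variants
    b_exp = np.zeros((E, V))
    b_prot_own = np.zeros((P, V))
    b_out_own = np.zeros((O, V))
    causal = {t: {} for t in exp_ids + prot_ids + out_ids}
    genes = {}

    exp_regions = {e: [] for e in exp_ids}
    for reg in panel.regions:
        if reg.kind == "exposure":
            exp_regions[reg.owner].append(reg)
    for e_i, e in enumerate(exp_ids):
        regions = exp_regions[e]
        effs = _scaled_effects(rng, len(regions), config.exposure_h2)
        for reg, eff in zip(regions, effs):
            c = reg.sl.start + reg.size // 2
            b_exp[e_i, c] = eff
            causal[e][str(panel.variant_ids[c])] = float(eff)

    gene_regions = [r for r in panel.regions if r.kind == "gene"]
    for j, (prot, reg) in enumerate(zip(prot_ids, gene_regions)):
        tss_idx = reg.sl.start + reg.size // 2
        genes[prot] = GeneAnnotation(
            prot, str(panel.chrom[tss_idx]), int(panel.pos[tss_idx])
        )
        effs = _scaled_effects(rng, config.n_cis_qtls, config.cis_h2)
        offsets = np.linspace(
            reg.size // 4, 3 * reg.size // 4, config.n_cis_qtls
        ).astype(int)
        for off, eff in zip(offsets, effs):
            c = reg.sl.start + off
            b_prot_own[j, c] = eff
            causal[prot][str(panel.variant_ids[c])] = float(eff)

    out_regions = {o: [] for o in out_ids}
    for reg in panel.regions:
        if reg.kind == "outcome":
            out_regions[reg.owner].append(reg)
    for o_i, o in enumerate(out_ids):
        for reg in out_regions[o]:
            c = reg.sl.start + reg.size // 2
            eff = config.outcome_qtl_beta * rng.choice([-1.0, 1.0])
            b_out_own[o_i, c] = eff
            causal[o][str(panel.variant_ids[c])] = float(eff)

    # directional pleiotropy: exposure instruments -> outcome directly
    pleio = np.zeros((E, V))
    if config.pleiotropy_frac > 0:
        for e_i, e in enumerate(exp_ids):
            qtl_idx = np.flatnonzero(b_exp[e_i])
            n_aff = int(round(config.pleiotropy_frac * len(qtl_idx)))
            affected = rng.choice(qtl_idx, size=n_aff, replace=False)
            pleio[e_i, affected] = (
                config.pleiotropy_mean
                + config.pleiotropy_sd * rng.standard_normal(n_aff)
            )

    # --- propagate through the graph --------------------------------------
    b_prot = b_prot_own + alpha.T @ b_exp                      # (P, V)
    b_out = (
        b_out_own + gamma.T @ b_prot + theta.T @ b_exp + pleio.sum(axis=0)
    )                                                          # (O, V)

    # --- summary tables ----------------------------------------------------
    tables = {}
    for e_i, e in enumerate(exp_ids):
        z = _noisy_z(panel, _marginal_std(panel, b_exp[e_i]),
                     config.n_exposure, rng)
        tables[e] = _table_from_z(panel, e, CONTINUOUS, z, config.n_exposure)
    for j, prot in enumerate(prot_ids):
        z = _noisy_z(panel, _marginal_std(panel, b_prot[j]),
                     config.n_protein, rng)
        tables[prot] = _table_from_z(panel, prot, CONTINUOUS, z,
                                     config.n_protein)
    for o_i, o in enumerate(out_ids):
        z = _noisy_z(panel, _marginal_std(panel, b_out[o_i]),
                     config.n_eff_outcome, rng)
        tables[o] = _table_from_z(
            panel, o, CASE_CONTROL, z, config.n_eff_outcome,
            n_case=config.n_case, n_control=config.n_control,
        )

    truth = GroundTruth(
        alpha, gamma, theta, mediators, causal, genes,
        list(exp_ids), list(prot_ids), list(out_ids),
    )
    return SimStudy(config, panel, tables, truth)


def write_study(study: SimStudy, outdir):
    """Materialize a study in the on-disk dialect plus truth.json and LD."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for trait_id, table in study.tables.items():
        write_sumstats(table, outdir / f"{trait_id}.tsv")
    write_ld_matrix(study.ld, outdir / "ld.tsv")
    study.truth.to_json(outdir / "truth.json")
    genes = pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss) for g in study.truth.genes.values()],
        columns=["gene_id", "chrom", "tss"],
    )
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# colocalization fixtures


@dataclass(frozen=True)
class ColocSimConfig:
    """One-region fixture for colocalization calibration."""

    n_variants: int = 500
    rho: float = 0.95
    z_causal: float = 8.0
    n1: float = 35_000
    n2: float = 35_000
    freq_bounds: tuple = (0.05, 0.95)
    spacing_bp: int = 2_000
    #: LD between the two causal variants in "distinct" mode
    distinct_r: float = 0.0
    seed: int = 0


def simulate_coloc_scenario(mode: str, config: ColocSimConfig = ColocSimConfig()):
    """Two summary-statistic regions with a known sharing structure.

    ``shared``: one causal variant drives both traits; ``distinct``: each
    trait has its own causal variant (with LD ``distinct_r`` between them);
    ``null``: no causal variant in either trait.
    """
    if mode not in ("shared", "distinct", "null"):
        raise DomainError(f"unknown coloc mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    panel = Panel(
        np.array([f"v000_{k:03d}" for k in range(m)], dtype=object),
        np.array(["1"] * m, dtype=object),
        1_000_000 + np.arange(m, dtype=np.int64) * config.spacing_bp,
        np.array(["A"] * m, dtype=object),
        np.array(["G"] * m, dtype=object),
        rng.uniform(*config.freq_bounds, size=m),
        [_Region("gene", "region", slice(0, m), m)],
        config.rho,
    )

    c1 = m // 2
    if mode == "distinct":
        if config.distinct_r > 0:
            d = max(1, int(round(np.log(config.distinct_r) / np.log(config.rho))))
        else:
            d = m // 4
        c2 = min(m - 1, c1 + d)
    else:
        c2 = c1

    b1 = np.zeros(m)
    b2 = np.zeros(m)
    if mode != "null":
        b1[c1] = config.z_causal / np.sqrt(config.n1)
        b2[c2] = config.z_causal / np.sqrt(config.n2)

    z1 = _noisy_z(panel, _marginal_std(panel, b1), config.n1, rng)
    z2 = _noisy_z(panel, _marginal_std(panel, b2), config.n2, rng)
    t1 = _table_from_z(panel, "trait1", CONTINUOUS, z1, config.n1)
    t2 = _table_from_z(panel, "trait2", CONTINUOUS, z2, config.n2)
    truth = {
        "mode": mode,
        "causal1": str(panel.variant_ids[c1]) if mode != "null" else None,
        "causal2": str(panel.variant_ids[c2]) if mode != "null" else None,
    }
    return t1, t2, truth


# ---------------------------------------------------------------------------
# inverse-rank-normal transform


def int_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset c = 3/8.

    ``Phi^{-1}((rank - c) / (n - 2c + 1))`` with ties sharing the average
    rank.  Raises for constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DomainError("need a 1-d array with at least 2 values")
    if np.all(x == x[0]):
        raise ValidationError("constant input cannot be rank-normalized")
    c = 3.0 / 8.0
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (len(x) - 2 * c + 1))
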