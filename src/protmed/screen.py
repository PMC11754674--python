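"""The four-step mediation screen and its decision rules.

Step i  — exposure-outcome UVMR both ways: an association is identified
when every computed MR model agrees in sign and the reverse direction shows
no corroborated conflict.
Step ii — exposure-protein UVMR both ways at the multiplicity-corrected
threshold; proteins associated in both directions are conflicted and
removed.
Step iii — cis-instrument protein-outcome UVMR at the corrected threshold,
a reverse screen, and corroboration by colocalization (robust h4 >= 0.8;
pairs with h4 < 0.5 are explicitly tagged not-corroborated).
Step iv — multivariable MR of the exposure adjusted for each surviving,
sign-consistent candidate mediator: a mediation flag requires the direct
effect to attenuate toward the null and its 95% CI to newly overlap the
null while the univariable CI excluded it.

Every verdict records an ordered rule trace so each decision can be
re-evaluated from its inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import EmptyInstrumentError, ProtmedError
from .instruments import (
    CIS_P,
    GENOME_WIDE_P,
    InstrumentSet,
    select_cis,
    select_genome_wide,
)
from .coloc import SensitivityGrid, sensitivity_grid
from .multitest import EffTests, effective_tests, estimate_pheno_corr
from .mvmr import MVMRResult, build_mvmr_set, mvmr_ivw
from .runlog import log_event
from .sumstats import CASE_CONTROL, HarmonizedSet, find_proxy, harmonize
from .uvmr import (
    MREstimate,
    SteigerResult,
    ivw_mre,
    mr_egger,
    steiger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds and knobs of the screening rules."""

    gw_p: float = GENOME_WIDE_P          # genome-wide significance
    protein_p: float = CIS_P             # stricter proteome-wide threshold
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    proxy_min_r2: float = 0.8
    cis_window_bp: int = 1_000_000
    #: reverse-conflict p threshold for step i (steps ii/iii use the
    #: PhenoSpD-corrected alpha)
    reverse_alpha_step_i: float = 0.05
    h4_identify: float = 0.8
    h4_reject: float = 0.5
    boot_reps: int = 100
    mode_grid_size: int = 256
    z_cap: float = 1.96
    #: floor the IVW multiplicative scale at the fixed-effects variance.
    #: With two instruments the unfloored scale has one residual degree of
    #: freedom and collapses the SE whenever the two ratios happen to agree,
    #: producing spurious reverse-direction "associations"; the floor is the
    #: standard guard.
    floor_phi: bool = True


@dataclass
class PairVerdict:
    """UVMR verdict for one exposure-outcome pair in one direction."""

    exposure: str
    outcome: str
    direction: str
    main: MREstimate
    sensitivity: dict
    consistent_direction: bool
    passes_threshold: Optional[bool] = None
    steiger: Optional[SteigerResult] = None
    models_used: list = field(default_factory=list)

    @property
    def all_estimates(self):
        return [self.main] + list(self.sensitivity.values())


@dataclass
class StepDecision:
    """Outcome of one screening rule, with a re-evaluable trace."""

    step: str
    ids: tuple
    identified: bool
    reasons: list = field(default_factory=list)
    forward: Optional[PairVerdict] = None
    reverse: Optional[PairVerdict] = None
    coloc: Optional[SensitivityGrid] = None
    tags: list = field(default_factory=list)


@dataclass
class MediationCall:
    """Step-iv verdict for one exposure/mediator/outcome triple."""

    exposure: str
    mediator: str
    outcome: str
    uvmr: MREstimate
    mvmr: MVMRResult
    attenuated: bool
    ci_now_overlaps_null: bool
    uvmr_excluded_null: bool
    mediation_flag: bool
    reasons: list = field(default_factory=list)


def consistent_direction(estimates) -> bool:
    """True when every point estimate has the same nonzero sign."""
    signs = {np.sign(e.estimate) for e in estimates}
    return len(signs) == 1 and 0.0 not in signs and signs != {np.nan}


def unconflicted_set(forward_ids, reverse_ids) -> set:
    """Forward associations minus those also identified in reverse."""
    forward_ids = set(forward_ids)
    return forward_ids - (forward_ids & set(reverse_ids))


def run_uvmr_models(h: HarmonizedSet, params: ScreenParams, seed: int):
    """Main model plus the sensitivity models computable at this SNP count.

    Wald ratio with 1 variant, IVW-MRE with 2, and additionally MR-Egger,
    weighted median and weighted mode with >= 3.
    """
    if h.n_snp == 1:
        return wald_ratio(h), {}
    main = ivw_mre(h, floor_phi=params.floor_phi)
    if h.n_snp < 3:
        return main, {}
    sens = {
        "egger": mr_egger(h),
        "weighted_median": weighted_median(h, boot_reps=params.boot_reps,
                                           seed=seed),
        "weighted_mode": weighted_mode(h, boot_reps=params.boot_reps,
                                       seed=seed + 1,
                                       grid_size=params.mode_grid_size),
    }
    return main, sens


def _proxies_for(instrument_ids, outcome, ld, min_r2):
    present = set(outcome.records["variant_id"])
    proxies = {}
    for vid in instrument_ids:
        if vid not in present and vid in ld:
            hit = find_proxy(vid, outcome, ld, min_r2=min_r2)
            if hit is not None:
                proxies[vid] = hit
    return proxies


def analyze_pair(
    exposure_table,
    outcome_table,
    instruments: InstrumentSet,
    ld,
    params: ScreenParams,
    seed: int,
    direction: str = FORWARD,
    alpha: Optional[float] = None,
    with_steiger: bool = False,
) -> PairVerdict:
    """Harmonize an instrument set against an outcome and run all models."""
    exp_sub = exposure_table.subset(instruments.variant_ids)
    proxies = _proxies_for(
        instruments.variant_ids, outcome_table, ld, params.proxy_min_r2
    )
    h = harmonize(exp_sub, outcome_table, proxies=proxies)
    main, sens = run_uvmr_models(h, params, seed)
    verdict = PairVerdict(
        exposure_table.trait_id, outcome_table.trait_id, direction,
        main, sens, consistent_direction([main] + list(sens.values())),
        passes_threshold=(main.pval < alpha) if alpha is not None else None,
        models_used=[main.method] + list(sens.keys()),
    )
    if with_steiger:
        verdict.steiger = _steiger_for(h, exposure_table, outcome_table)
    return verdict


def _steiger_for(h, exposure_table, outcome_table):
    n_exp = float(exposure_table.records["n"].iloc[0])
    n_out = float(outcome_table.records["n"].iloc[0])
    if outcome_table.trait_type == CASE_CONTROL:
        case_frac = float(
            outcome_table.records["n_case"].iloc[0] / n_out
        )
        return steiger(h, n_exp, n_out, CASE_CONTROL, case_frac)
    return steiger(h, n_exp, n_out, outcome_table.trait_type)


# ---------------------------------------------------------------------------
# step rules


def step_i(
    forward: PairVerdict,
    reverse: Optional[PairVerdict],
    params: ScreenParams,
) -> StepDecision:
    """Exposure-outcome identification rule.

    Identified when the forward models agree in sign and the reverse
    direction does not show a sign-consistent association at the nominal
    reverse threshold.  With no reverse instruments the reverse arm is
    untestable and the forward rule decides alone (logged caveat).
    """
    reasons = [f"forward consistent_direction={forward.consistent_direction}"]
    if reverse is None:
        reasons.append("reverse untestable (no instruments); forward rule only")
        identified = forward.consistent_direction
    else:
        conflict = (
            reverse.consistent_direction
            and reverse.main.pval < params.reverse_alpha_step_i
        )
        reasons.append(
            f"reverse consistent_direction={reverse.consistent_direction} "
            f"p={reverse.main.pval:.3g} conflict={conflict}"
        )
        identified = forward.consistent_direction and not conflict
    return StepDecision(
        "i", (forward.exposure, forward.outcome), identified, reasons,
        forward, reverse,
    )


def step_ii_protein(
    forward: PairVerdict,
    reverse: Optional[PairVerdict],
    alpha_corrected: float,
) -> StepDecision:
    """Adiposity-protein rule: consistent direction plus corrected threshold,
    with a reverse-conflict check at the same threshold."""
    fwd_ok = forward.consistent_direction and forward.main.pval < alpha_corrected
    rev_ok = (
        reverse is not None
        and reverse.consistent_direction
        and reverse.main.pval < alpha_corrected
    )
    reasons = [
        f"forward consistent={forward.consistent_direction} "
        f"p={forward.main.pval:.3g} alpha={alpha_corrected:.3g} -> {fwd_ok}",
        f"reverse association={rev_ok}",
    ]
    identified = fwd_ok and not rev_ok
    dec = StepDecision(
        "ii", (forward.exposure, forward.outcome), identified, reasons,
        forward, reverse,
    )
    if fwd_ok and rev_ok:
        dec.tags.append("conflicted")
    return dec


def step_iii_pair(
    forward: PairVerdict,
    reverse: Optional[PairVerdict],
    coloc: Optional[SensitivityGrid],
    alpha_corrected: float,
    params: ScreenParams,
) -> StepDecision:
    """Protein-outcome rule: corrected threshold on the cis UVMR, no
    reverse conflict, and a robust colocalization verdict."""
    fwd_ok = forward.main.pval < alpha_corrected
    rev_conflict = (
        reverse is not None
        and reverse.consistent_direction
        and reverse.main.pval < alpha_corrected
    )
    coloc_ok = coloc is not None and coloc.robust
    reasons = [
        f"cis UVMR p={forward.main.pval:.3g} alpha={alpha_corrected:.3g} -> {fwd_ok}",
        f"reverse conflict={rev_conflict}",
        f"coloc robust={coloc_ok} "
        f"h4_main={coloc.h4_main if coloc else float('nan'):.3g}",
    ]
    dec = StepDecision(
        "iii", (forward.exposure, forward.outcome),
        fwd_ok and not rev_conflict and coloc_ok, reasons,
        forward, reverse, coloc,
    )
    if coloc is not None and coloc.h4_main < params.h4_reject:
        dec.tags.append("not-corroborated")
    return dec


def step_iv(
    uvmr_estimate: MREstimate,
    mvmr_result: MVMRResult,
    exposure: str,
    mediator: str,
    outcome: str,
) -> MediationCall:
    """Attenuation rule on the log-odds scale.

    A mediation flag requires (a) the adjusted (direct) exposure estimate
    to be smaller in magnitude than the univariable estimate, (b) the
    adjusted 95% CI to overlap the null, and (c) the univariable CI to
    exclude the null.
    """
    i = mvmr_result.exposures.index(exposure)
    direct = float(mvmr_result.estimates[i])
    attenuated = abs(direct) < abs(uvmr_estimate.estimate)
    overlaps = mvmr_result.ci_low[i] <= 0.0 <= mvmr_result.ci_high[i]
    uvmr_excl = not (uvmr_estimate.ci_low <= 0.0 <= uvmr_estimate.ci_high)
    flag = attenuated and overlaps and uvmr_excl
    reasons = [
        f"|direct|={abs(direct):.4g} < |total|={abs(uvmr_estimate.estimate):.4g}"
        f" -> attenuated={attenuated}",
        f"mvmr CI [{mvmr_result.ci_low[i]:.4g}, {mvmr_result.ci_high[i]:.4g}]"
        f" overlaps null={overlaps}",
        f"uvmr CI [{uvmr_estimate.ci_low:.4g}, {uvmr_estimate.ci_high:.4g}]"
        f" excluded null={uvmr_excl}",
    ]
    return MediationCall(
        exposure, mediator, outcome, uvmr_estimate, mvmr_result,
        attenuated, overlaps, uvmr_excl, flag, reasons,
    )


# ---------------------------------------------------------------------------
# full screen


@dataclass
class ScreenResults:
    """Bundle of every decision from one screen run."""

    params: ScreenParams
    seed: int
    eff_tests: EffTests
    step_i: dict          # (exposure, outcome) -> StepDecision
    step_ii: dict         # (exposure, protein) -> StepDecision
    unconflicted: dict    # exposure -> set of protein ids
    step_iii: dict        # (protein, outcome) -> StepDecision
    step_iv: list         # MediationCall
    failures: list        # (stage, ids, message)

    @property
    def mediation_flags(self):
        return [c for c in self.step_iv if c.mediation_flag]

    def uvmr_table(self) -> pd.DataFrame:
        rows = []
        decisions = (
            list(self.step_i.values()) + list(self.step_ii.values())
            + list(self.step_iii.values())
        )
        for dec in decisions:
            for verdict in (dec.forward, dec.reverse):
                if verdict is None:
                    continue
                for est in verdict.all_estimates:
                    rows.append({
                        "exposure": verdict.exposure,
                        "outcome": verdict.outcome,
                        "direction": verdict.direction,
                        "step": dec.step,
                        "method": est.method,
                        "n_snp": est.n_snp,
                        "estimate": est.estimate, "se": est.se,
                        "ci_low": est.ci_low, "ci_high": est.ci_high,
                        "pval": est.pval, "Q": est.Q, "Q_pval": est.Q_pval,
                        "egger_intercept": est.egger_intercept,
                        "egger_intercept_pval": est.egger_intercept_pval,
                    })
        return pd.DataFrame(rows)

    def mvmr_table(self) -> pd.DataFrame:
        rows = []
        for call in self.step_iv:
            m = call.mvmr
            i = m.exposures.index(call.exposure)
            j = 1 - i
            rows.append({
                "exposure": call.exposure, "mediator": call.mediator,
                "outcome": call.outcome, "n_snp": m.n_snp,
                "est_exposure": m.estimates[i], "se_exposure": m.ses[i],
                "est_mediator": m.estimates[j], "se_mediator": m.ses[j],
                "cond_F_exposure": m.conditional_f[i],
                "cond_F_mediator": m.conditional_f[j],
                "Q_a": m.q_a, "Q_a_pval": m.q_a_pval,
                "attenuated": call.attenuated,
                "mediation_flag": call.mediation_flag,
            })
        return pd.DataFrame(rows)

    def decisions_table(self) -> pd.DataFrame:
        rows = []
        all_decs = (
            list(self.step_i.values()) + list(self.step_ii.values())
            + list(self.step_iii.values())
        )
        for dec in all_decs:
            rows.append({
                "step": dec.step, "ids": "|".join(dec.ids),
                "identified": dec.identified,
                "tags": ";".join(dec.tags),
                "trace": " ;; ".join(dec.reasons),
            })
        for call in self.step_iv:
            rows.append({
                "step": "iv",
                "ids": "|".join((call.exposure, call.mediator, call.outcome)),
                "identified": call.mediation_flag,
                "tags": "",
                "trace": " ;; ".join(call.reasons),
            })
        return pd.DataFrame(rows)

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.uvmr_table().to_csv(outdir / "uvmr.tsv", sep="\t", index=False,
                                 na_rep="NA")
        self.mvmr_table().to_csv(outdir / "mvmr.tsv", sep="\t", index=False,
                                 na_rep="NA")
        self.decisions_table().to_csv(outdir / "decisions.tsv", sep="\t",
                                      index=False, na_rep="NA")
        coloc_rows = []
        for (prot, out), dec in self.step_iii.items():
            if dec.coloc is not None:
                coloc_rows.extend(dec.coloc.to_rows(prot, out))
        pd.DataFrame(coloc_rows).to_csv(outdir / "coloc.tsv", sep="\t",
                                        index=False, na_rep="NA")
        run = {
            "package_version": __version__,
            "seed": self.seed,
            "params": asdict(self.params),
            "meff": {
                "m": self.eff_tests.m,
                "nyholt": self.eff_tests.meff_nyholt,
                "liji": self.eff_tests.meff_liji,
                "alpha_corrected": self.eff_tests.alpha_corrected,
            },
            "n_failures": len(self.failures),
        }
        (outdir / "run.json").write_text(json.dumps(run, indent=1))


def run_screen(
    tables: dict,
    exposures: list,
    proteins: list,
    outcomes: list,
    genes: dict,
    ld,
    params: ScreenParams = ScreenParams(),
    seed: int = 0,
) -> ScreenResults:
    """Execute steps i-iv over every exposure/protein/outcome combination.

    ``tables`` maps trait ids to summary tables; ``genes`` maps protein ids
    to their gene annotations.  Fully deterministic given ``seed``; partial
    failures are isolated per pair and tabulated in ``results.failures``.
    """
    failures = []
    seed = int(seed)

    def instruments_or_none(stage, trait_id, select):
        try:
            return select()
        except (EmptyInstrumentError, ProtmedError) as exc:
            failures.append((stage, trait_id, str(exc)))
            return None

    exp_inst = {
        e: instruments_or_none(
            "instruments", e,
            lambda e=e: select_genome_wide(
                tables[e], ld, p_threshold=params.gw_p,
                r2=params.clump_r2, window_kb=params.clump_window_kb),
        )
        for e in exposures
    }
    out_inst = {
        o: instruments_or_none(
            "instruments", o,
            lambda o=o: select_genome_wide(
                tables[o], ld, p_threshold=params.gw_p,
                r2=params.clump_r2, window_kb=params.clump_window_kb),
        )
        for o in outcomes
    }

    # multiplicity correction over the protein panel
    eff = effective_tests(
        estimate_pheno_corr([tables[p] for p in proteins], z_cap=params.z_cap)
    )
    alpha_c = eff.alpha_corrected
    log_event("meff", m=eff.m, nyholt=eff.meff_nyholt, liji=eff.meff_liji,
              alpha_corrected=alpha_c)

    # --- step i ----------------------------------------------------------
    step_i_dec = {}
    pair_seed = seed
    for e in exposures:
        for o in outcomes:
            pair_seed += 10
            if exp_inst[e] is None:
                failures.append(("step_i", (e, o), "no forward instruments"))
                continue
            try:
                fwd = analyze_pair(tables[e], tables[o], exp_inst[e], ld,
                                   params, pair_seed, FORWARD,
                                   with_steiger=True)
                rev = None
                if out_inst[o] is not None:
                    rev = analyze_pair(tables[o], tables[e], out_inst[o], ld,
                                       params, pair_seed + 1, REVERSE,
                                       with_steiger=True)
                step_i_dec[(e, o)] = step_i(fwd, rev, params)
            except ProtmedError as exc:
                failures.append(("step_i", (e, o), str(exc)))

    # --- step ii ---------------------------------------------------------
    step_ii_dec = {}
    unconflicted = {}
    prot_inst = {
        p: instruments_or_none(
            "instruments", p,
            lambda p=p: select_genome_wide(
                tables[p], ld, p_threshold=params.protein_p,
                r2=params.clump_r2, window_kb=params.clump_window_kb),
        )
        for p in proteins
    }
    for e in exposures:
        fwd_set, rev_set = set(), set()
        for p in proteins:
            pair_seed += 10
            if exp_inst[e] is None:
                continue
            try:
                fwd = analyze_pair(tables[e], tables[p], exp_inst[e], ld,
                                   params, pair_seed, FORWARD, alpha=alpha_c)
                rev = None
                if prot_inst[p] is not None:
                    rev = analyze_pair(tables[p], tables[e], prot_inst[p], ld,
                                       params, pair_seed + 1, REVERSE,
                                       alpha=alpha_c)
                dec = step_ii_protein(fwd, rev, alpha_c)
                step_ii_dec[(e, p)] = dec
                fwd_ok = (fwd.consistent_direction
                          and fwd.main.pval < alpha_c)
                if fwd_ok:
                    fwd_set.add(p)
                if rev is not None and rev.consistent_direction \
                        and rev.main.pval < alpha_c:
                    rev_set.add(p)
            except ProtmedError as exc:
                failures.append(("step_ii", (e, p), str(exc)))
        unconflicted[e] = unconflicted_set(fwd_set, rev_set)

    # --- step iii --------------------------------------------------------
    step_iii_dec = {}
    cis_inst = {}
    for p in proteins:
        gene = genes.get(p)
        if gene is None:
            failures.append(("step_iii", p, "no gene annotation"))
            continue
        cis_inst[p] = instruments_or_none(
            "cis_instruments", p,
            lambda p=p, gene=gene: select_cis(
                tables[p], gene, ld, p_threshold=params.protein_p,
                window_bp=params.cis_window_bp, r2=params.clump_r2),
        )
    for p in proteins:
        for o in outcomes:
            pair_seed += 10
            inst = cis_inst.get(p)
            if inst is None:
                continue  # protein untested in cis-MR
            try:
                fwd = analyze_pair(tables[p], tables[o], inst, ld,
                                   params, pair_seed, FORWARD, alpha=alpha_c)
                rev = None
                if out_inst[o] is not None:
                    rev = analyze_pair(tables[o], tables[p], out_inst[o], ld,
                                       params, pair_seed + 1, REVERSE,
                                       alpha=alpha_c)
                lead = inst.table.records.iloc[0]["variant_id"]
                grid = sensitivity_grid(
                    tables[p], tables[o], lead,
                    h4_threshold=params.h4_identify,
                )
                step_iii_dec[(p, o)] = step_iii_pair(
                    fwd, rev, grid, alpha_c, params
                )
            except ProtmedError as exc:
                failures.append(("step_iii", (p, o), str(exc)))

    # --- step iv ---------------------------------------------------------
    calls = []
    for e in exposures:
        for o in outcomes:
            dec_i = step_i_dec.get((e, o))
            if dec_i is None or not dec_i.identified:
                continue
            uv = dec_i.forward.main
            for p in sorted(unconflicted[e]):
                dec_iii = step_iii_dec.get((p, o))
                if dec_iii is None or not dec_iii.identified:
                    continue
                dec_ii = step_ii_dec[(e, p)]
                s_ep = np.sign(dec_ii.forward.main.estimate)
                s_po = np.sign(dec_iii.forward.main.estimate)
                s_eo = np.sign(uv.estimate)
                if s_ep * s_po != s_eo:
                    log_event("step_iv_sign_inconsistent", exposure=e,
                              mediator=p, outcome=o)
                    continue
                try:
                    h3 = build_mvmr_set(
                        exp_inst[e], cis_inst[p], tables[e], tables[p],
                        tables[o], ld, r2=params.clump_r2,
                        window_kb=params.clump_window_kb,
                    )
                    mv = mvmr_ivw(h3)
                    calls.append(step_iv(uv, mv, e, p, o))
                except ProtmedError as exc:
                    failures.append(("step_iv", (e, p, o), str(exc)))

    return ScreenResults(
        params, seed, eff, step_i_dec, step_ii_dec, unconflicted,
        step_iii_dec, calls, failures,
    )


def run_screen_study(study, params: ScreenParams = ScreenParams(),
                     seed: int = 0) -> ScreenResults:
    """Run the screen on a simulated study object."""
    cfg = study.config
    return run_screen(
        study.tables, cfg.exposure_ids, cfg.protein_ids, cfg.outcome_ids,
        study.truth.genes, study.ld, params=params, seed=seed,
    )
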