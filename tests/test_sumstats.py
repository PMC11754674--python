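"""I/O dialect, harmonization, LD clumping and proxy search."""

import numpy as np
import pandas as pd
import pytest

from protmed import (
    LDMatrix,
    SimConfig,
    TraitMeta,
    find_proxy,
    harmonize,
    ld_clump,
    read_sumstats,
    simulate_study,
    write_sumstats,
)
from protmed.errors import (
    EmptyOverlapError,
    FormatError,
    ValidationError,
    VariantLookupError,
)
from protmed.sumstats import (
    DROPPED_PALINDROMIC,
    FLIPPED,
    KEPT,
    PROXIED,
    SummaryTable,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# reading and writing


def test_read_write_roundtrip(tmp_path):
    study = simulate_study(SimConfig(
        n_proteins=2, n_exposure_qtls=3, seed=3,
        frac_adiposity_assoc=0.0, frac_outcome_assoc=0.0,
    ))
    table = study.tables["BMI"]
    path = tmp_path / "bmi.tsv"
    write_sumstats(table, path)
    back = read_sumstats(path, TraitMeta("BMI", "continuous"))
    pd.testing.assert_frame_equal(
        back.records, table.records.reset_index(drop=True),
        check_dtype=False,
    )


def test_read_small_well_formed_file(tmp_path, mk_table):
    t = mk_table("x", [{}, {}, {}])
    path = tmp_path / "x.tsv"
    write_sumstats(t, path)
    assert len(read_sumstats(path, TraitMeta("x"))) == 3


def test_invalid_rows_named(tmp_path, mk_table):
    t = mk_table("x", [{}, {"se": 0.0}, {"pval": 1.5}])
    path = tmp_path / "x.tsv"
    t.records.to_csv(path, sep="\t", index=False, na_rep="NA")
    with pytest.raises(ValidationError) as err:
        read_sumstats(path, TraitMeta("x"))
    assert err.value.rows == [2, 3]


def test_nonstrict_read_drops_bad_rows(tmp_path, mk_table):
    t = mk_table("x", [{}, {"se": -1.0}])
    path = tmp_path / "x.tsv"
    t.records.to_csv(path, sep="\t", index=False, na_rep="NA")
    back = read_sumstats(path, TraitMeta("x"), strict=False)
    assert len(back) == 1


def test_missing_column_is_format_error(tmp_path, mk_table):
    t = mk_table("x", [{}])
    path = tmp_path / "x.tsv"
    t.records.drop(columns=["se"]).to_csv(path, sep="\t", index=False)
    with pytest.raises(FormatError):
        read_sumstats(path, TraitMeta("x"))


def test_duplicate_variant_id_rejected(mk_table):
    with pytest.raises(ValidationError):
        make_table("x", [{"variant_id": "rs1"}, {"variant_id": "rs1"}])


# ---------------------------------------------------------------------------
# harmonization


def test_harmonize_identity_coding(mk_table):
    exp = mk_table("e", [{"beta": 0.1}, {"beta": -0.2}])
    out = mk_table("o", [{"beta": 0.3}, {"beta": 0.4}])
    h = harmonize(exp, out)
    assert h.actions == [KEPT, KEPT]
    np.testing.assert_allclose(h.beta_out, [0.3, 0.4])


def test_harmonize_swapped_alleles_flip_beta_and_eaf(mk_table):
    exp = mk_table("e", [{"effect_allele": "A", "other_allele": "G",
                          "eaf": 0.3}])
    out = mk_table("o", [{"effect_allele": "G", "other_allele": "A",
                          "beta": 0.2, "eaf": 0.7}])
    h = harmonize(exp, out)
    assert h.actions == [FLIPPED]
    np.testing.assert_allclose(h.beta_out, [-0.2])


def test_palindromic_near_half_dropped(mk_table):
    exp = mk_table("e", [{"effect_allele": "A", "other_allele": "T",
                          "eaf": 0.50}])
    out = mk_table("o", [{"effect_allele": "A", "other_allele": "T",
                          "eaf": 0.50}, {"variant_id": "rs99"}])
    # rs0 is palindromic and ambiguous; the only other variant is unshared
    with pytest.raises(EmptyOverlapError):
        harmonize(exp, out)


def test_palindromic_resolved_by_frequency(mk_table):
    exp = mk_table("e", [{"effect_allele": "A", "other_allele": "T",
                          "eaf": 0.2, "beta": 0.1}])
    same = mk_table("o", [{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.22, "beta": 0.5}])
    flipped = mk_table("o", [{"effect_allele": "A", "other_allele": "T",
                              "eaf": 0.8, "beta": 0.5}])
    assert harmonize(exp, same).beta_out[0] == 0.5
    h = harmonize(exp, flipped)
    assert h.actions == [FLIPPED]
    assert h.beta_out[0] == -0.5


def test_harmonize_involution(small_study):
    """Recoding every outcome record to the opposite allele orientation
    leaves the harmonized set identical."""
    exp = small_study.tables["BMI"]
    out = small_study.tables["CRC"]
    recoded_df = out.records.copy()
    recoded_df[["effect_allele", "other_allele"]] = (
        recoded_df[["other_allele", "effect_allele"]].to_numpy()
    )
    recoded_df["beta"] = -recoded_df["beta"]
    recoded_df["eaf"] = 1 - recoded_df["eaf"]
    recoded = SummaryTable("CRC", out.trait_type, recoded_df)

    h1 = harmonize(exp, out)
    h2 = harmonize(exp, recoded)
    assert h1.variant_ids == h2.variant_ids
    np.testing.assert_array_equal(h1.beta_out, h2.beta_out)
    np.testing.assert_array_equal(h1.se_out, h2.se_out)


def test_harmonize_with_proxy(mk_table):
    exp = mk_table("e", [{"variant_id": "rs0", "beta": 0.1}])
    out = mk_table("o", [{"variant_id": "rs1", "beta": 0.4}])
    ld = LDMatrix(["rs0", "rs1"], np.array([[1.0, -0.95], [-0.95, 1.0]]))
    hit = find_proxy("rs0", out, ld)
    h = harmonize(exp, out, proxies={"rs0": hit})
    assert h.actions == [PROXIED]
    np.testing.assert_allclose(h.beta_out, [-0.4])  # oriented by sign(r)


# ---------------------------------------------------------------------------
# clumping


def _random_instance(rng, m=50):
    ids = [f"rs{i}" for i in range(m)]
    a = rng.standard_normal((m, m))
    corr = np.corrcoef(a @ a.T)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2
    ld = LDMatrix(ids, corr, validate=False)
    table = make_table("t", [
        {"variant_id": ids[i], "pos": 1000 + i,
         "pval": float(rng.uniform(1e-12, 1e-2))}
        for i in range(m)
    ])
    return table, ld


def _brute_force_clump(table, ld, r2, window_bp):
    """Independent greedy reference implementation."""
    df = table.records.sort_values("pval")
    remaining = list(df.itertuples(index=False))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best.variant_id)
        survivors = []
        for other in remaining:
            near = (other.chrom == best.chrom
                    and abs(other.pos - best.pos) <= window_bp)
            if near and ld.corr(best.variant_id, other.variant_id) ** 2 > r2:
                continue
            survivors.append(other)
        remaining = survivors
    return kept


@pytest.mark.parametrize("r2", [0.001, 0.1, 0.5])
def test_clump_matches_brute_force(rng, r2):
    table, ld = _random_instance(rng)
    out = ld_clump(table, ld, r2_threshold=r2, window_kb=10)
    assert out.variant_ids == _brute_force_clump(table, ld, r2, 10_000)


def test_clump_survivors_ld_independent(rng):
    table, ld = _random_instance(rng)
    out = ld_clump(table, ld, r2_threshold=0.1, window_kb=10)
    ids = out.variant_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            assert ld.corr(a, b) ** 2 <= 0.1


def test_clump_idempotent(rng):
    table, ld = _random_instance(rng)
    once = ld_clump(table, ld, r2_threshold=0.05, window_kb=10)
    twice = ld_clump(once, ld, r2_threshold=0.05, window_kb=10)
    assert once.variant_ids == twice.variant_ids


def test_clump_single_variant_kept(mk_table):
    t = mk_table("t", [{"variant_id": "rs0"}])
    ld = LDMatrix(["rs0"], np.eye(1))
    assert ld_clump(t, ld).variant_ids == ["rs0"]


def test_clump_keeps_best_of_correlated_pair(mk_table):
    t = mk_table("t", [
        {"variant_id": "rs0", "pval": 1e-9, "pos": 1000},
        {"variant_id": "rs1", "pval": 1e-10, "pos": 2000},
    ])
    r = np.sqrt(0.5)
    ld = LDMatrix(["rs0", "rs1"], np.array([[1, r], [r, 1]]))
    assert ld_clump(t, ld, r2_threshold=0.001).variant_ids == ["rs1"]


def test_clump_drops_variants_missing_from_ld(mk_table):
    t = mk_table("t", [{"variant_id": "rs0"}, {"variant_id": "rsX"}])
    ld = LDMatrix(["rs0"], np.eye(1))
    assert ld_clump(t, ld).variant_ids == ["rs0"]


def test_clump_empty_table(mk_table):
    t = mk_table("t", [])
    ld = LDMatrix(["rs0"], np.eye(1))
    assert len(ld_clump(t, ld)) == 0


# ---------------------------------------------------------------------------
# proxies


def test_proxy_target_present_is_itself(mk_table):
    out = mk_table("o", [{"variant_id": "rs0"}])
    ld = LDMatrix(["rs0"], np.eye(1))
    hit = find_proxy("rs0", out, ld)
    assert hit.variant_id == "rs0" and hit.r == 1.0


def test_proxy_below_threshold_is_none(mk_table):
    out = mk_table("o", [{"variant_id": "rs1"}])
    r = np.sqrt(0.5)
    ld = LDMatrix(["rs0", "rs1"], np.array([[1, r], [r, 1]]))
    assert find_proxy("rs0", out, ld, min_r2=0.64) is None


def test_proxy_argmax_over_candidates(mk_table):
    out = mk_table("o", [{"variant_id": "rs1"}, {"variant_id": "rs2"}])
    r1, r2 = np.sqrt(0.7), -np.sqrt(0.9)
    mat = np.eye(3)
    mat[0, 1] = mat[1, 0] = r1
    mat[0, 2] = mat[2, 0] = r2
    ld = LDMatrix(["rs0", "rs1", "rs2"], mat, validate=False)
    hit = find_proxy("rs0", out, ld, min_r2=0.64)
    assert hit.variant_id == "rs2"


def test_proxy_target_absent_from_ld(mk_table):
    out = mk_table("o", [{"variant_id": "rs1"}])
    ld = LDMatrix(["rs1"], np.eye(1))
    with pytest.raises(VariantLookupError):
        find_proxy("rsX", out, ld)
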