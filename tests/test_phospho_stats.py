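"""Class-I filtering, variance stabilization, batch correction, s0-test,
fraction profiles and translocation calls."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pafskit.phospho_stats import (
    CalibrationError,
    ConfoundingError,
    DifferentialConfig,
    batch_correct,
    call_translocation,
    count_regulated,
    filter_class1,
    glog2,
    sam_test,
    scale_profiles,
    vsn_transform,
)
from pafskit.simulate import gen_phospho_dataset

from conftest import make_table


# --- class-I filter -----------------------------------------------------------


def test_filter_class1_inclusive_boundary_and_counts():
    table = make_table(
        np.ones((5, 2)), ["treated", "control"], loc_prob=[0.9, 0.8, 0.75, 0.5, 0.2]
    )
    out, report = filter_class1(table)
    assert report.retained == 3 and report.dropped == 2
    assert out.sites["localization_prob"].min() == 0.75  # "at least" is inclusive
    assert report.by_residue == {"S": 3}
    sub, rep749 = filter_class1(make_table(np.ones((1, 2)), ["treated", "control"], loc_prob=[0.749]))
    assert rep749.retained == 0


def test_filter_class1_idempotent():
    table, _ = gen_phospho_dataset(n_sites=100, seed=11)
    once, _ = filter_class1(table)
    twice, rep = filter_class1(once)
    pd.testing.assert_frame_equal(once.values, twice.values)
    assert rep.dropped == 0


# --- variance stabilization ---------------------------------------------------


def test_glog2_asymptotic_log_behavior():
    x = np.array([1e4, 1e6, 1e8])
    assert np.abs(glog2(x, 10.0) - np.log2(x)).max() < 1e-6
    np.testing.assert_allclose(glog2(x, 0.0), np.log2(x))


def test_vsn_scale_invariance_between_samples():
    """Two samples identical up to a scale factor calibrate to equal outputs."""
    rng = np.random.default_rng(1)
    base = rng.lognormal(mean=12, sigma=1.5, size=300)
    table = make_table(
        np.column_stack([base, 3.7 * base, base * 0.4]),
        ["treated", "control", "control"],
        log2=False,
    )
    out = vsn_transform(table)
    v = out.values.to_numpy()
    assert np.abs(v[:, 0] - v[:, 1]).max() < 1e-6
    assert np.abs(v[:, 0] - v[:, 2]).max() < 1e-6


def test_vsn_flattens_sd_vs_mean_trend():
    """Additive + multiplicative noise: after the transform the replicate SD
    must not trend upward with mean intensity (regression oracle)."""
    rng = np.random.default_rng(2)
    n_sites, n_rep = 600, 6
    mu = rng.lognormal(10, 1.8, size=n_sites)
    raw = mu[:, None] * np.exp(rng.normal(0, 0.15, (n_sites, n_rep))) + rng.normal(
        0, 200, (n_sites, n_rep)
    )
    raw = np.clip(raw, 1.0, None)
    table = make_table(raw, ["treated"] * 3 + ["control"] * 3, log2=False)
    out = vsn_transform(table).values.to_numpy()
    sd = out.std(axis=1, ddof=1)
    mean = out.mean(axis=1)
    slope, _, _, pval, _ = stats.linregress(mean, sd)
    assert not (slope > 0 and pval < 0.01)
    # and the raw data do show the trend the transform removed
    slope_raw, *_ = stats.linregress(raw.mean(axis=1), raw.std(axis=1, ddof=1))
    assert slope_raw > 0


def test_vsn_monotone_per_sample():
    table, _ = gen_phospho_dataset(n_sites=200, seed=4)
    out = vsn_transform(table)
    for col in table.values.columns:
        order = np.argsort(table.values[col].to_numpy())
        transformed = out.values[col].to_numpy()[order]
        assert np.all(np.diff(transformed) >= 0)


def test_vsn_rejects_sparse_sample():
    rng = np.random.default_rng(7)
    vals = rng.lognormal(10, 1, size=(12, 2))
    vals[3:, 1] = np.nan
    table = make_table(vals, ["treated", "control"], log2=False)
    with pytest.raises(CalibrationError, match="s1"):
        vsn_transform(table)


# --- batch correction ---------------------------------------------------------


def test_batch_correct_single_batch_identity():
    table = make_table(np.arange(8.0).reshape(2, 4), ["treated", "treated", "control", "control"])
    out = batch_correct(table)
    pd.testing.assert_frame_equal(out.values, table.values)


def test_batch_correct_removes_pure_batch_offset():
    rng = np.random.default_rng(3)
    base = rng.normal(20, 1, size=(50, 1))
    vals = np.tile(base, (1, 8)) + np.r_[[0.0] * 4, [2.0] * 4]  # +2 log2 in batch 2
    table = make_table(
        vals,
        ["treated", "control"] * 4,
        batches=["B1"] * 4 + ["B2"] * 4,
    )
    out = batch_correct(table).values.to_numpy()
    b1 = out[:, :4].mean(axis=1)
    b2 = out[:, 4:].mean(axis=1)
    assert np.abs(b1 - b2).max() < 1e-9


def test_batch_correct_preserves_condition_effect():
    rng = np.random.default_rng(4)
    n = 40
    vals = rng.normal(20, 1, size=(n, 8))
    cond = ["treated", "control"] * 4
    batch = ["B1"] * 4 + ["B2"] * 4
    effect = 1.0
    for j, c in enumerate(cond):
        if c == "treated":
            vals[:, j] += effect
    vals[:, 4:] += 3.0
    table = make_table(vals, cond, batches=batch)
    out = batch_correct(table).values.to_numpy()
    treated = [j for j, c in enumerate(cond) if c == "treated"]
    control = [j for j, c in enumerate(cond) if c == "control"]
    before = vals[:, treated].mean() - vals[:, control].mean()
    after = out[:, treated].mean() - out[:, control].mean()
    assert after == pytest.approx(before, abs=1e-9)
    assert after == pytest.approx(effect, abs=0.4)  # sampling noise of the mean


def test_batch_correct_confounded_design_raises():
    table = make_table(
        np.ones((3, 4)),
        ["treated", "treated", "control", "control"],
        batches=["B1", "B1", "B2", "B2"],
    )
    with pytest.raises(ConfoundingError):
        batch_correct(table)


def test_batch_correct_matches_limma_oracle():
    """Independent cross-check against limma::removeBatchEffect."""
    rng = np.random.default_rng(5)
    vals = rng.normal(20, 1, size=(12, 8))
    cond = ["treated", "control"] * 4
    batch = ["B1"] * 4 + ["B2"] * 4
    table = make_table(vals, cond, batches=batch)
    ours = batch_correct(table).values.to_numpy()
    with tempfile.TemporaryDirectory() as td:
        inp, outp = Path(td) / "m.csv", Path(td) / "o.csv"
        pd.DataFrame(vals).to_csv(inp, index=False)
        script = (
            "suppressMessages(library(limma));"
            f"m <- as.matrix(read.csv('{inp}'));"
            f"batch <- c({','.join(repr(b) for b in batch)});"
            f"cond <- c({','.join(repr(c) for c in cond)});"
            "design <- model.matrix(~cond);"
            "out <- removeBatchEffect(m, batch=batch, design=design);"
            f"write.csv(out, '{outp}', row.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        theirs = pd.read_csv(outp).to_numpy()
    np.testing.assert_allclose(ours, theirs, atol=1e-8)


# --- differential test --------------------------------------------------------


def test_sam_worked_example_moderated_statistic():
    """Groups (4,5,6) vs (1,2,3): delta 3, se sqrt(2/3), t' = 3/(0.8165+0.1)."""
    table = make_table([[4, 5, 6, 1, 2, 3]], ["treated"] * 3 + ["control"] * 3)
    res = sam_test(table, config=DifferentialConfig(s0=0.1))
    assert res["log2fc"].iloc[0] == pytest.approx(3.0)
    assert res["t_mod"].iloc[0] == pytest.approx(3.0 / (np.sqrt(2 / 3) + 0.1), rel=1e-12)
    assert res["t_mod"].iloc[0] == pytest.approx(3.273, abs=5e-4)


def test_sam_s0_zero_equals_welch_oracle(rng):
    """At s0 = 0 with unpooled variances the statistic and p-value are the
    Welch t-test, site by site."""
    vals = rng.normal(0, 1, size=(300, 9))
    table = make_table(vals, ["treated"] * 4 + ["control"] * 5)
    res = sam_test(table, config=DifferentialConfig(s0=0.0, equal_var=False))
    t_ref, p_ref = stats.ttest_ind(vals[:, :4], vals[:, 4:], axis=1, equal_var=False)
    np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-12)
    np.testing.assert_allclose(res["p"], p_ref, atol=1e-12)


def test_sam_pooled_matches_student_oracle(rng):
    vals = rng.normal(0, 1, size=(200, 8))
    table = make_table(vals, ["treated"] * 4 + ["control"] * 4)
    res = sam_test(table, config=DifferentialConfig(s0=0.0, equal_var=True))
    t_ref, p_ref = stats.ttest_ind(vals[:, :4], vals[:, 4:], axis=1, equal_var=True)
    np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-12)
    np.testing.assert_allclose(res["p"], p_ref, atol=1e-12)


def test_sam_identical_groups_never_significant():
    table = make_table([[1, 2, 3, 1, 2, 3]], ["treated"] * 3 + ["control"] * 3)
    for s0 in (0.0, 0.1, 1.0):
        res = sam_test(table, config=DifferentialConfig(s0=s0))
        assert res["log2fc"].iloc[0] == 0.0
        assert not res["significant"].iloc[0]


def test_sam_zero_variance_handling():
    vals = [[5, 5, 5, 5, 5, 5], [5, 5, 5, 3, 3, 3]]
    table = make_table(vals, ["treated"] * 3 + ["control"] * 3)
    res = sam_test(table, config=DifferentialConfig(s0=0.1))
    assert not res["tested"].iloc[0]  # constant with delta = 0: untested
    assert res["tested"].iloc[1]  # delta != 0 with s0 > 0: finite t'
    assert np.isfinite(res["t_mod"].iloc[1])
    assert res["t_mod"].iloc[1] == pytest.approx(2.0 / 0.1)


def test_sam_insufficient_group_size_flagged_untested():
    vals = np.array([[1.0, np.nan, np.nan, 2.0, 2.5, 3.0]])
    table = make_table(vals, ["treated"] * 3 + ["control"] * 3)
    res = sam_test(table)
    assert not res["tested"].iloc[0]
    assert not res["significant"].iloc[0]


def test_sam_permutation_mode_agrees_on_strong_effects(rng):
    # few planted sites: the permutation null pool is dominated by true
    # nulls, so the empirical p floor stays below the BH cut
    vals = rng.normal(0, 0.3, size=(300, 8))
    vals[:5, :4] += 3.0
    table = make_table(vals, ["treated"] * 4 + ["control"] * 4)
    analytic = sam_test(table)
    perm = sam_test(
        table, config=DifferentialConfig(s0=0.1, fdr=0.1), permute_fdr=True,
        n_permutations=100, seed=1,
    )
    assert analytic["significant"].iloc[:5].all()
    # permutation p-values rank every planted site ahead of all nulls; the
    # achievable p floor is limited by the planted sites' own relabelings
    assert set(perm["p"].nsmallest(5).index) == set(perm.index[:5])
    assert perm["significant"].iloc[:5].all()
    assert perm["significant"].iloc[5:].sum() <= 3


def test_count_regulated_recovers_planted_up_sites():
    table, truth = gen_phospho_dataset(
        n_sites=500,
        frac_regulated=0.2,
        effect_size=3.0,
        residual_sd=0.1,
        direction="up",
        n_batches=1,
        batch_sd=0.0,
        scale="log2",
        seed=8,
    )
    res = sam_test(table)
    n_up, n_down = count_regulated(res)
    assert n_up == 100
    assert n_down == 0


def test_batch_correction_leaves_balanced_contrast_unchanged():
    """With batches balanced over conditions, correction does not move the
    per-site group difference."""
    table, _ = gen_phospho_dataset(n_sites=200, n_batches=2, scale="log2", seed=9)
    raw = sam_test(table)
    corrected = sam_test(batch_correct(table))
    np.testing.assert_allclose(raw["log2fc"], corrected["log2fc"], atol=1e-9)


# --- fraction profiles and translocation -------------------------------------


def test_scale_profiles_known_values():
    vals = [[10, 20, 40, 10, 10, 10]]
    table = make_table(
        vals, ["treated"] * 6, log2=False, fractions=[1, 2, 3, 4, 5, 6]
    )
    prof = scale_profiles(table)
    np.testing.assert_allclose(
        prof.to_numpy()[0], [0.25, 0.5, 1.0, 0.25, 0.25, 0.25]
    )


def test_scale_profiles_indicator_and_uniform():
    vals = np.array([[np.nan, 50, np.nan], [7.0, 7.0, 7.0]])
    table = make_table(vals, ["treated"] * 3, log2=False, fractions=[1, 2, 3])
    prof = scale_profiles(table)
    row0 = prof.to_numpy()[0]
    assert row0[1] == 1.0 and np.isnan(row0[0]) and np.isnan(row0[2])
    np.testing.assert_allclose(prof.to_numpy()[1], [1.0, 1.0, 1.0])


def test_call_translocation_requires_opposite_directions():
    prot = pd.Index(["A", "B", "C"], name="protein")
    dep = pd.DataFrame(
        {"significant": [True, True, False], "direction": ["down", "up", "down"]}, index=prot
    )
    acc = pd.DataFrame(
        {"significant": [True, True, True], "direction": ["up", "up", "up"]}, index=prot
    )
    calls, summary = call_translocation(dep, acc)
    assert [c.protein for c in calls] == ["A"]  # B is up in both, C not significant in f1
    assert summary == {"n_down_depleted": 1, "n_up_accumulated": 3, "n_called": 1}


def test_call_translocation_disjoint_sets_warns_empty():
    dep = pd.DataFrame(
        {"significant": [True], "direction": ["down"]}, index=pd.Index(["A"], name="protein")
    )
    acc = pd.DataFrame(
        {"significant": [True], "direction": ["up"]}, index=pd.Index(["B"], name="protein")
    )
    with pytest.warns(UserWarning, match="disjoint"):
        calls, summary = call_translocation(dep, acc)
    assert calls == [] and summary["n_called"] == 0
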