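import numpy as np
import pandas as pd
import pytest
from scipy import stats

import straindiff as sd
from straindiff.de import (
    Contrast,
    ModeratedStats,
    apply_contrast,
    build_design,
    call_degs,
    compute_precision_weights,
    empirical_bayes_moderate,
    fit_linear_models,
    global_fdr,
    low_average_contrasts,
    pairwise_contrasts,
    treat_test,
    trigamma_inverse,
)
from straindiff.preprocess import NormalizedMatrix


def _samples(n_per, strains, extra=None):
    rows = []
    for s in strains:
        for i in range(n_per):
            rows.append({"sample_id": f"{s}{i}", "strain": s,
                         **(extra or {})})
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def _gaussian_fit(y, samples, factors=("strain",), weights=None):
    design = build_design(samples, factors)
    fits = fit_linear_models(y, design, weights)
    return design, fits


# ---------------------------------------------------------------- design

def test_design_is_cell_means_for_strain_plus_adjustments():
    samples = _samples(2, ["A", "B"])
    samples["sex"] = ["F", "M"] * 2
    design = build_design(samples, ("strain", "sex"))
    assert list(design.columns) == ["strain_A", "strain_B", "sex_M"]
    assert design[["strain_A", "strain_B"]].sum(axis=1).eq(1).all()


def test_confounded_batch_raises_rank_error():
    samples = _samples(3, ["A", "B"])
    samples["batch"] = np.where(samples["strain"] == "A", "b1", "b2")
    with pytest.raises(ValueError, match="rank deficient"):
        build_design(samples, ("strain", "batch"))


# ---------------------------------------------------------------- fitting

def test_two_group_fit_recovers_group_means_and_pooled_variance(rng):
    samples = _samples(3, ["A", "B"])
    y = pd.DataFrame([rng.normal([1, 1, 1, 4, 4, 4], 1.0)],
                     index=["g"], columns=samples.index)
    _, fits = _gaussian_fit(y, samples)
    a = y.iloc[0, :3].mean()
    b = y.iloc[0, 3:].mean()
    assert fits.coefficients.loc["g", "strain_A"] == pytest.approx(a)
    assert fits.coefficients.loc["g", "strain_B"] == pytest.approx(b)
    pooled = (((y.iloc[0, :3] - a) ** 2).sum() + ((y.iloc[0, 3:] - b) ** 2).sum()) / 4
    assert fits.sigma2["g"] == pytest.approx(pooled)
    assert fits.df_residual == 4


def test_batch_shift_leaves_strain_contrast_unchanged(rng):
    samples = _samples(4, ["A", "B"])
    samples["batch"] = (["b1", "b2"] * 4)
    y = pd.DataFrame(rng.normal(5, 1, size=(20, 8)),
                     index=[f"g{i}" for i in range(20)], columns=samples.index)
    design = build_design(samples, ("strain", "batch"))
    con = Contrast("A_vs_B", {"A": 1.0, "B": -1.0})
    fits1 = fit_linear_models(y, design)
    shifted = y.copy()
    shifted.loc[:, samples.index[samples.batch == "b2"]] += 7.0
    fits2 = fit_linear_models(shifted, design)
    mod1 = empirical_bayes_moderate(fits1)
    mod2 = empirical_bayes_moderate(fits2)
    t1 = apply_contrast(fits1, mod1, con)
    t2 = apply_contrast(fits2, mod2, con)
    assert np.allclose(t1["log2FC"], t2["log2FC"])


def test_weighted_fit_matches_brute_force_normal_equations(rng):
    samples = _samples(3, ["A", "B", "C"])
    samples["sex"] = ["F", "M", "F"] * 3
    design = build_design(samples, ("strain", "sex"))
    y = pd.DataFrame(rng.normal(size=(15, len(samples))),
                     index=[f"g{i}" for i in range(15)], columns=samples.index)
    w = pd.DataFrame(rng.uniform(0.2, 3.0, size=y.shape),
                     index=y.index, columns=y.columns)
    fits = fit_linear_models(y, design, w)
    x = design.to_numpy()
    for g in y.index:
        wg = np.diag(w.loc[g].to_numpy())
        beta = np.linalg.solve(x.T @ wg @ x, x.T @ wg @ y.loc[g].to_numpy())
        assert np.allclose(fits.coefficients.loc[g].to_numpy(), beta)


def test_unit_weights_equal_unweighted_fit(rng):
    samples = _samples(4, ["A", "B"])
    y = pd.DataFrame(rng.normal(size=(10, 8)),
                     index=[f"g{i}" for i in range(10)], columns=samples.index)
    design = build_design(samples, ("strain",))
    ones = pd.DataFrame(1.0, index=y.index, columns=y.columns)
    f1 = fit_linear_models(y, design)
    f2 = fit_linear_models(y, design, ones)
    assert np.allclose(f1.coefficients, f2.coefficients)
    assert np.allclose(f1.sigma2, f2.sigma2)


# ---------------------------------------------------------------- moderation

def test_shrinkage_formula_hand_values():
    samples = _samples(3, ["A", "B"])
    fits = fit_linear_models(
        pd.DataFrame(np.zeros((4, 6)), index=list("wxyz"),
                     columns=samples.index),
        build_design(samples, ("strain",)),
    )
    fits.sigma2 = pd.Series([1.0, 2.0, 4.0, 8.0], index=list("wxyz"))
    mod = empirical_bayes_moderate(fits, d0=4.0, s02=2.0)
    assert mod.s2_post.tolist() == [1.5, 2.0, 3.0, 5.0]
    assert mod.df_total == 8.0


def test_d0_limits_match_pooled_and_ordinary_t(rng):
    samples = _samples(3, ["A", "B"])
    y = pd.DataFrame(rng.normal(size=(50, 6)),
                     index=[f"g{i}" for i in range(50)], columns=samples.index)
    design, fits = _gaussian_fit(y, samples)
    con = Contrast("A_vs_B", {"A": 1.0, "B": -1.0})

    mod_inf = empirical_bayes_moderate(fits, d0=np.inf, s02=1.7)
    assert np.allclose(mod_inf.s2_post, 1.7)
    t_inf = apply_contrast(fits, mod_inf, con)
    # pooled-variance z statistic
    se = np.sqrt(1.7 * (1 / 3 + 1 / 3))
    expected = (fits.coefficients["strain_A"] - fits.coefficients["strain_B"]) / se
    assert np.allclose(t_inf["t"], expected)

    mod0 = empirical_bayes_moderate(fits, d0=0.0, s02=1.0)
    assert np.allclose(mod0.s2_post, fits.sigma2)
    t0 = apply_contrast(fits, mod0, con)
    a = y.iloc[:, :3].to_numpy()
    b = y.iloc[:, 3:].to_numpy()
    t_ref = stats.ttest_ind(a, b, axis=1).statistic
    assert np.allclose(t0["t"], t_ref)


def test_estimated_prior_matches_limma_on_frozen_sim():
    """Hyperparameters and contrast stats agree with a reference
    moderated-statistics implementation (limma voom/eBayes) run once on
    this exact seeded simulation."""
    cfg = sd.SimConfig(n_genes=400, strains=("A", "B"), regions=("R",),
                       replicates_per_cell=3, seed=7,
                       frac_unique_per_strain=0.05, frac_shared_signature=0.0,
                       region_effect_sd=0.0, batch_effect_sd=0.1)
    counts, samples, _, _ = sd.simulate_counts(cfg)
    norm = sd.tmm_normalize(counts)
    design = build_design(samples, ("strain", "sex", "batch"))
    w = compute_precision_weights(counts, norm, design)
    fits = fit_linear_models(norm.log2_cpm, design, w)
    mod = empirical_bayes_moderate(fits)
    assert mod.d0 == pytest.approx(27.006855, rel=0.02)
    assert mod.s02 == pytest.approx(1.075801, rel=0.02)
    tab = apply_contrast(fits, mod, Contrast("A_vs_B", {"A": 1.0, "B": -1.0}))
    frozen_logfc = {"G00000": 0.266681, "G00001": -0.740775,
                    "G00003": 1.985064, "G00005": 0.182823}
    frozen_t = {"G00000": 1.015521, "G00001": -2.906150,
                "G00003": 8.075990, "G00005": 0.701909}
    for g, v in frozen_logfc.items():
        assert tab.loc[g, "log2FC"] == pytest.approx(v, abs=5e-3)
    for g, v in frozen_t.items():
        assert tab.loc[g, "t"] == pytest.approx(v, rel=0.02)


def test_trigamma_inverse_roundtrip():
    from scipy.special import polygamma
    for y in (0.1, 1.0, 5.0, 40.0):
        assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-5)


# ---------------------------------------------------------------- contrasts

def test_self_contrast_is_null():
    samples = _samples(3, ["A", "B"])
    y = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 6)),
                     index=[f"g{i}" for i in range(5)], columns=samples.index)
    _, fits = _gaussian_fit(y, samples)
    mod = empirical_bayes_moderate(fits)
    tab = apply_contrast(fits, mod, Contrast("A_vs_A", {"A": 0.0}))
    assert (tab["log2FC"] == 0).all()
    assert (tab["p"] == 1).all()


def test_constructed_unit_shift_gives_unit_logfc(rng):
    samples = _samples(3, ["A", "B"])
    base = rng.normal(size=(10, 3))
    y = pd.DataFrame(np.hstack([base + 1.0, base]),
                     index=[f"g{i}" for i in range(10)], columns=samples.index)
    _, fits = _gaussian_fit(y, samples)
    mod = empirical_bayes_moderate(fits)
    tab = apply_contrast(fits, mod, Contrast("A_vs_B", {"A": 1.0, "B": -1.0}))
    assert np.allclose(tab["log2FC"], 1.0)


def test_low_average_contrast_arithmetic(rng):
    strains = ["B6", "AJ", "CAST", "NOD", "NZO", "S129", "WSB", "PWK"]
    samples = _samples(3, strains)
    m = rng.normal(5, 1, size=(8, 3))
    # B6 sits 2 log2 units above every low strain; PWK matches the lows
    offsets = {s: 0.0 for s in strains}
    offsets["B6"] = 2.0
    y = pd.DataFrame(
        np.hstack([np.full((8, 3), offsets[s]) + m for s in strains]),
        index=[f"g{i}" for i in range(8)], columns=samples.index)
    _, fits = _gaussian_fit(y, samples)
    mod = empirical_bayes_moderate(fits)
    cons = low_average_contrasts(strains)
    b6 = apply_contrast(fits, mod, cons[0])
    pwk = apply_contrast(fits, mod, cons[1])
    assert np.allclose(b6["log2FC"], 2.0)
    assert np.allclose(pwk["log2FC"], 0.0)


def test_contrast_antisymmetry(rng):
    samples = _samples(3, ["A", "B", "C"])
    y = pd.DataFrame(rng.normal(size=(30, 9)),
                     index=[f"g{i}" for i in range(30)], columns=samples.index)
    _, fits = _gaussian_fit(y, samples)
    mod = empirical_bayes_moderate(fits)
    fwd = apply_contrast(fits, mod, Contrast("A_vs_B", {"A": 1.0, "B": -1.0}))
    rev = apply_contrast(fits, mod, Contrast("B_vs_A", {"B": 1.0, "A": -1.0}))
    assert np.allclose(fwd["log2FC"], -rev["log2FC"])
    assert np.allclose(fwd["p"], rev["p"])


def test_contrast_validation():
    with pytest.raises(ValueError, match="sum"):
        Contrast("bad", {"A": 1.0, "B": -0.5})
    with pytest.raises(KeyError):
        Contrast("A_vs_Z", {"A": 1.0, "Z": -1.0}).vector(
            pd.Index(["strain_A", "strain_B"]))
    assert len(pairwise_contrasts(list("ABCDEFGH"))) == 28


# ---------------------------------------------------------------- TREAT

def test_treat_at_zero_threshold_equals_ordinary_p(rng):
    samples = _samples(3, ["A", "B"])
    y = pd.DataFrame(rng.normal(size=(40, 6)),
                     index=[f"g{i}" for i in range(40)], columns=samples.index)
    _, fits = _gaussian_fit(y, samples)
    mod = empirical_bayes_moderate(fits)
    con = Contrast("A_vs_B", {"A": 1.0, "B": -1.0})
    plain = apply_contrast(fits, mod, con)
    tr = treat_test(fits, mod, con, lfc_threshold=0.0)
    assert np.allclose(tr["p_treat"], plain["p"])


def test_treat_boundary_and_strong_effect_cases():
    # gene at logFC 0.5 with near-zero SE: cannot exceed a threshold of 1
    mod = ModeratedStats(d0=10.0, s02=1.0,
                         s2_post=pd.Series([1e-8, 1e-8], index=["near", "big"]),
                         df_total=14.0, df_residual=4.0)
    samples = _samples(3, ["A", "B"])
    design = build_design(samples, ("strain",))
    base = np.random.default_rng(2).normal(0, 1e-5, size=(2, 3))
    y = pd.DataFrame(np.hstack([base + [[0.5], [3.0]], base]),
                     index=["near", "big"], columns=samples.index)
    fits = fit_linear_models(y, design)
    tr = treat_test(fits, mod, Contrast("A_vs_B", {"A": 1.0, "B": -1.0}),
                    lfc_threshold=1.0)
    assert tr.loc["near", "p_treat"] > 0.95
    assert tr.loc["big", "p_treat"] < 1e-6


def test_treat_p_monotone_in_threshold(rng):
    samples = _samples(3, ["A", "B"])
    y = pd.DataFrame(rng.normal(size=(20, 6)),
                     index=[f"g{i}" for i in range(20)], columns=samples.index)
    _, fits = _gaussian_fit(y, samples)
    mod = empirical_bayes_moderate(fits)
    con = Contrast("A_vs_B", {"A": 1.0, "B": -1.0})
    prev = treat_test(fits, mod, con, 0.0)["p_treat"]
    for thr in (0.5, 1.0, 2.0):
        cur = treat_test(fits, mod, con, thr)["p_treat"]
        assert (cur >= prev - 1e-12).all()
        prev = cur
    with pytest.raises(ValueError):
        treat_test(fits, mod, con, -1.0)


# ---------------------------------------------------------------- FDR + calls

def test_bh_hand_arithmetic():
    adj = global_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(adj, 0.04)
    assert np.allclose(global_fdr(np.ones(5)), 1.0)


def test_global_pooling_equals_concatenation(rng):
    p1 = rng.uniform(size=40)
    p2 = rng.uniform(size=60)
    pooled = global_fdr(np.concatenate([p1, p2]))
    assert np.allclose(pooled, global_fdr(np.r_[p1, p2]))
    with pytest.raises(ValueError):
        global_fdr(np.array([]))


def test_deg_flags_at_thresholds():
    tab = pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "log2FC": [2.0, 0.99, -1.5, 0.2],
        "t": [5.0, 5.0, -5.0, 1.0],
        "p": [1e-6, 1e-6, 1e-6, 0.5],
        "p_treat": [1e-4, 1e-4, 1e-4, 0.9],
    })
    out = call_degs({"A_vs_B": tab}, region="R")
    out = out.set_index("gene")
    assert out.loc["a", "is_deg"] and out.loc["a", "is_hdeg"]
    # |log2FC| = 0.99 < 1: significant but not an hDEG
    assert out.loc["b", "is_deg"] and not out.loc["b", "is_hdeg"]
    assert out.loc["c", "direction"] == "down"
    assert not out.loc["d", "is_deg"]
    assert (out.loc[out["is_hdeg"], "is_deg"]).all()
    with pytest.raises(ValueError):
        call_degs({"A_vs_B": tab}, region="R", fdr_threshold=1.5)


def test_fdr_threshold_boundary_is_strict():
    n = 10
    tab = pd.DataFrame({
        "gene": [f"g{i}" for i in range(n)],
        "log2FC": np.ones(n), "t": np.ones(n),
        "p": np.linspace(0.001, 0.9, n), "p_treat": np.ones(n),
    })
    out = call_degs({"c": tab}, region="R")
    assert (out["is_deg"] == (out["fdr_global"] < 0.05)).all()


def test_null_gaussian_p_values_are_uniform(rng):
    samples = _samples(3, ["A", "B"])
    y = pd.DataFrame(rng.normal(size=(5000, 6)),
                     index=[f"g{i}" for i in range(5000)],
                     columns=samples.index)
    _, fits = _gaussian_fit(y, samples)
    mod = empirical_bayes_moderate(fits)
    tab = apply_contrast(fits, mod, Contrast("A_vs_B", {"A": 1.0, "B": -1.0}))
    ks = stats.kstest(tab["p"], "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------- voom

def _norm_from(y, counts):
    lib = counts.sum(axis=0).astype(float)
    return NormalizedMatrix(log2_cpm=y, norm_factors=pd.Series(1.0, index=y.columns),
                            lib_sizes=lib)


def test_constant_variance_gives_flat_weights(rng):
    samples = _samples(6, ["A", "B"])
    n = len(samples)
    mean = np.linspace(2, 12, 300)
    y = pd.DataFrame(mean[:, None] + rng.normal(0, 0.5, size=(300, n)),
                     index=[f"g{i}" for i in range(300)], columns=samples.index)
    counts = pd.DataFrame(np.round(2 ** y), index=y.index, columns=y.columns)
    design = build_design(samples, ("strain",))
    w = compute_precision_weights(counts, _norm_from(y, counts), design)
    spread = w.to_numpy().max() / w.to_numpy().min()
    assert spread < 3.0  # flat trend up to smoother wiggle


def test_decreasing_sd_trend_gives_increasing_weights(rng):
    samples = _samples(6, ["A", "B"])
    n = len(samples)
    mean = np.linspace(2, 12, 400)
    sds = np.interp(mean, [2, 12], [1.2, 0.2])
    y = pd.DataFrame(mean[:, None] + rng.normal(0, 1, size=(400, n)) * sds[:, None],
                     index=[f"g{i}" for i in range(400)], columns=samples.index)
    counts = pd.DataFrame(np.round(2 ** y), index=y.index, columns=y.columns)
    design = build_design(samples, ("strain",))
    w = compute_precision_weights(counts, _norm_from(y, counts), design)
    mean_w = w.mean(axis=1)
    lo = mean_w[mean < 4].mean()
    hi = mean_w[mean > 10].mean()
    assert hi > 2 * lo
    assert (w.to_numpy() > 0).all()


def test_weight_computation_needs_residual_df():
    samples = _samples(1, ["A", "B"])
    y = pd.DataFrame(np.ones((5, 2)), columns=samples.index)
    counts = y.copy()
    design = build_design(samples, ("strain",))
    with pytest.raises(ValueError, match="more samples"):
        compute_precision_weights(counts, _norm_from(y, counts), design)
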