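"""Transformations, correlations, PERMANOVA/PERMDISP, SIMPER, OPLS-DA,
ROC and volcano contrasts, each checked against an independent oracle or a
closed-form identity where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from adductomics.stats import (
    SiteMetadata,
    VolcanoParams,
    correlation_sign_test,
    log_half_min,
    oplsda,
    pareto_scale,
    pearson_matrix,
    permanova,
    roc,
    simper,
    transform,
    volcano,
    zscore,
)

RNG = np.random.default_rng(20260925)


# ---------------------------------------------------------------------------
# transformations


def test_zscore_centered_example():
    z = zscore(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
    assert z["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])


def test_pareto_scaled_variance_equals_pre_scaling_sd():
    """Algebraic identity of Pareto scaling: var(x/sqrt(s)) = s."""
    df = pd.DataFrame(RNG.lognormal(0, 1, (30, 4)), columns=list("abcd"))
    scaled = pareto_scale(df)
    assert np.allclose(scaled.var(ddof=1), df.std(ddof=1))


def test_log_half_min_replaces_zeros():
    df = pd.DataFrame({"x": [0.0, 2.0, 4.0]})
    out = log_half_min(df)
    assert out["x"].iloc[0] == pytest.approx(np.log(1.0))  # half of min positive (2)
    assert out["x"].iloc[1] == pytest.approx(np.log(2.0))


def _toy_meta(n=6):
    idx = [f"s{i}" for i in range(n)]
    return SiteMetadata(
        station=pd.Series(["st"] * n, index=idx),
        basin=pd.Series(["BS"] * n, index=idx),
        status=pd.Series(["C"] * (n // 2) + ["R"] * (n - n // 2), index=idx),
        contaminants=pd.DataFrame(
            {"Cu": RNG.lognormal(1, 0.5, n), "flat": np.ones(n)}, index=idx
        ),
    )


def test_transform_drops_invariant_columns():
    meta = _toy_meta()
    norm = pd.DataFrame(
        {"A1": RNG.lognormal(0, 0.5, 6), "const": np.full(6, 3.0)},
        index=meta.samples,
    )
    with pytest.warns(UserWarning, match="invariant"):
        X, Z = transform(norm, meta)
    assert list(X.columns) == ["A1"]
    assert list(Z.columns) == ["Cu"]


def test_status_label_validation():
    with pytest.raises(ValueError):
        SiteMetadata(
            station=pd.Series(["a"]),
            basin=pd.Series(["BS"]),
            status=pd.Series(["bad"]),
            contaminants=pd.DataFrame({"Cu": [1.0]}),
        )


# ---------------------------------------------------------------------------
# correlations


def test_pearson_self_and_sign():
    x = pd.DataFrame({"x": RNG.normal(size=20)})
    r, p = pearson_matrix(x, x)
    assert r.iloc[0, 0] == pytest.approx(1.0)
    assert p.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)
    r2, _ = pearson_matrix(x, -x)
    assert r2.iloc[0, 0] == pytest.approx(-1.0)


def test_pearson_matches_scipy_pairwise():
    """r and p agree with scipy.stats.pearsonr (the t-transform oracle)."""
    X = pd.DataFrame(RNG.normal(size=(15, 3)), columns=list("abc"))
    Z = pd.DataFrame(RNG.normal(size=(15, 2)), columns=list("uv"))
    r, p = pearson_matrix(X, Z)
    for a in X.columns:
        for u in Z.columns:
            ref = sps.pearsonr(X[a], Z[u])
            assert r.loc[a, u] == pytest.approx(ref.statistic, abs=1e-12)
            assert p.loc[a, u] == pytest.approx(ref.pvalue, rel=1e-9)


def test_pearson_zero_variance_is_missing():
    X = pd.DataFrame({"x": np.ones(5)})
    Z = pd.DataFrame({"z": RNG.normal(size=5)})
    r, p = pearson_matrix(X, Z)
    assert np.isnan(r.iloc[0, 0]) and np.isnan(p.iloc[0, 0])


def test_correlation_sign_test_identical_groups():
    vals = np.array([0.1, 0.2, 0.3, 0.4])
    _, p = correlation_sign_test(vals, vals)
    assert p == pytest.approx(1.0)


def test_correlation_sign_test_detects_planted_shift():
    high = RNG.normal(0.4, 0.1, 30)
    low = RNG.normal(0.0, 0.1, 30)
    _, p = correlation_sign_test(high, low)
    assert p < 0.01


def test_correlation_sign_test_matches_hand_welch():
    """3+3 toy vs a hand-computed Welch statistic."""
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 4.0, 6.0])
    t, p = correlation_sign_test(a, b)
    se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
    t_hand = (a.mean() - b.mean()) / se
    df = (a.var(ddof=1) / 3 + b.var(ddof=1) / 3) ** 2 / (
        (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2
    )
    assert t == pytest.approx(t_hand)
    assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), df), rel=1e-9)

    with pytest.raises(ValueError):
        correlation_sign_test([0.1], [0.2, 0.3])


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP


def _factors(status, basin=None, index=None):
    idx = index or [f"s{i}" for i in range(len(status))]
    d = {"status": pd.Series(status, index=idx)}
    if basin is not None:
        d["basin"] = pd.Series(basin, index=idx)
    return pd.DataFrame(d)


def test_permanova_separated_groups_hit_permutation_floor():
    X = np.vstack([RNG.normal(0, 1, (10, 5)), RNG.normal(8, 1, (10, 5))])
    factors = _factors(["C"] * 10 + ["R"] * 10)
    res = permanova(X, factors, terms=("status",), n_perm=999, seed=1,
                    run_permdisp=False)
    assert res.terms.loc["status", "p"] == pytest.approx(1 / 1000)


def test_permanova_r2_partition_sums_to_one():
    X = RNG.normal(size=(16, 6))
    factors = _factors(["C"] * 8 + ["R"] * 8, ["BS"] * 4 + ["NBP"] * 4 + ["BS"] * 4 + ["NBP"] * 4)
    res = permanova(X, factors, n_perm=99, seed=2, run_permdisp=False)
    total_r2 = res.terms["R2"].sum() + res.residual_ss / res.total_ss
    assert total_r2 == pytest.approx(1.0, abs=1e-9)


def test_permanova_singleton_level_is_an_error():
    X = RNG.normal(size=(5, 3))
    factors = _factors(["C", "C", "C", "C", "R"])
    with pytest.raises(ValueError, match="singleton"):
        permanova(X, factors, terms=("status",))


def _brute_force_permanova_p(X, labels):
    """Independent oracle: classic one-factor pseudo-F from the distance
    matrix, enumerated over every permutation of the observations."""
    D = squareform(pdist(X))
    n = len(labels)

    def pseudo_f(lab):
        d2 = D**2
        ss_total = d2.sum() / (2 * n)
        ss_within = 0.0
        for lev in set(lab):
            idx = [i for i, l in enumerate(lab) if l == lev]
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        a = len(set(lab))
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    count = 0
    perms = list(itertools.permutations(range(n)))
    for perm in perms:
        if pseudo_f([labels[i] for i in perm]) >= f_obs - 1e-12:
            count += 1
    return count / len(perms)


def test_permanova_exact_p_matches_brute_force_enumeration():
    """Exhaustive enumeration over all 720 relabelings of a 6-sample toy."""
    X = np.array([[0.0, 0.1], [0.2, 0.0], [0.1, 0.3], [2.0, 2.1], [2.2, 1.9], [1.9, 2.2]])
    labels = ["C", "C", "C", "R", "R", "R"]
    res = permanova(X, _factors(labels), terms=("status",), n_perm="exact",
                    run_permdisp=False)
    assert res.terms.loc["status", "p"] == pytest.approx(
        _brute_force_permanova_p(X, labels), abs=1e-12
    )


def test_permanova_invariant_to_rotation_and_reordering():
    """Euclidean PERMANOVA depends on X only through distances, which are
    preserved by orthogonal rotation; reordering samples with their labels
    leaves p unchanged."""
    X = RNG.normal(size=(12, 4))
    labels = ["C"] * 6 + ["R"] * 6
    res1 = permanova(X, _factors(labels), terms=("status",), n_perm=199, seed=5,
                     run_permdisp=False)
    Q, _ = np.linalg.qr(RNG.normal(size=(4, 4)))
    res2 = permanova(X @ Q, _factors(labels), terms=("status",), n_perm=199, seed=5,
                     run_permdisp=False)
    assert res2.terms.loc["status", "pseudo_F"] == pytest.approx(
        res1.terms.loc["status", "pseudo_F"]
    )
    assert res2.terms.loc["status", "p"] == res1.terms.loc["status", "p"]
    order = RNG.permutation(12)
    res3 = permanova(X[order], _factors([labels[i] for i in order]),
                     terms=("status",), n_perm=199, seed=5, run_permdisp=False)
    assert res3.terms.loc["status", "pseudo_F"] == pytest.approx(
        res1.terms.loc["status", "pseudo_F"]
    )


def test_permdisp_reported_alongside():
    X = np.vstack([RNG.normal(0, 1, (8, 4)), RNG.normal(0, 5, (8, 4))])
    res = permanova(X, _factors(["C"] * 8 + ["R"] * 8), terms=("status",),
                    n_perm=199, seed=3)
    assert "status" in res.dispersion_p
    assert res.dispersion_p["status"] <= 0.05  # dispersions differ by design


# ---------------------------------------------------------------------------
# SIMPER


def test_simper_hand_computed_two_sample_case():
    """A=(1,0) vs B=(0,1): Bray-Curtis dissimilarity 1, each variable 50%."""
    abund = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], columns=["x", "y"],
                         index=["a", "b"])
    groups = pd.Series(["A", "B"], index=["a", "b"])
    res = simper(abund, groups)
    assert res.attrs["average_dissimilarity"] == pytest.approx(1.0)
    assert res["contribution_pct"].tolist() == pytest.approx([50.0, 50.0])


def test_simper_identical_groups_warns_and_selects_nothing():
    abund = pd.DataFrame([[1.0, 2.0]] * 4, columns=["x", "y"])
    groups = pd.Series(["A", "A", "B", "B"])
    with pytest.warns(UserWarning, match="identical"):
        res = simper(abund, groups)
    assert not res["selected"].any()


def test_simper_contributions_sum_to_100():
    abund = pd.DataFrame(RNG.lognormal(0, 1, (10, 7)))
    groups = pd.Series(["A"] * 5 + ["B"] * 5)
    res = simper(abund, groups)
    assert res["contribution_pct"].sum() == pytest.approx(100.0)
    assert res["cumulative_pct"].is_monotonic_increasing


def test_simper_selection_monotone_in_cutoff():
    abund = pd.DataFrame(RNG.lognormal(0, 1, (10, 9)))
    groups = pd.Series(["A"] * 5 + ["B"] * 5)
    n_sel = [int(simper(abund, groups, cutoff=c)["selected"].sum())
             for c in (40.0, 60.0, 80.0, 95.0)]
    assert n_sel == sorted(n_sel)


def test_simper_rejects_all_zero_samples_and_negative_values():
    abund = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["bad", "ok"])
    with pytest.raises(ValueError, match="bad"):
        simper(abund, pd.Series(["A", "B"], index=["bad", "ok"]))
    with pytest.raises(ValueError):
        simper(pd.DataFrame([[-1.0], [1.0]]), pd.Series(["A", "B"]))


# ---------------------------------------------------------------------------
# OPLS-DA


def _planted_X(n=40, p_noise=50, seed=11):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.normal(size=(n, p_noise + 1))
    X[:, 0] = y * 4.0 + rng.normal(0, 0.2, n)  # one perfectly separating variable
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(p_noise + 1)]), y


def test_oplsda_recovers_planted_variable_with_max_vip():
    X, y = _planted_X()
    model = oplsda(X, y, n_orth=1, folds=10, seed=1)
    assert int(np.argmax(model.vip)) == 0
    # training misclassification zero at the 0.5 score cut
    pred = (model.predict(X) > 0.5).astype(int)
    assert (pred == y).all()
    assert model.q2 <= model.r2y <= 1.0


def test_vip_mean_square_is_one():
    X, y = _planted_X(seed=2)
    model = oplsda(X, y, seed=2)
    assert np.mean(model.vip**2) == pytest.approx(1.0, abs=1e-12)


def test_oplsda_permuted_labels_give_nonpositive_median_q2():
    X, y = _planted_X(n=30, p_noise=20, seed=4)
    rng = np.random.default_rng(9)
    q2s = [oplsda(X, rng.permutation(y), seed=s).q2 for s in range(20)]
    assert np.median(q2s) <= 0.0


def test_oplsda_zero_orthogonal_equals_pls1_component():
    """With no orthogonal filtering the predictive scores equal the first
    NIPALS PLS component (sklearn oracle), up to sign."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    X, y = _planted_X(n=24, p_noise=10, seed=6)
    model = oplsda(X, y, n_orth=0, folds=5, seed=1)
    pls = sklearn.PLSRegression(n_components=1, scale=False).fit(
        X.to_numpy() - X.to_numpy().mean(axis=0), y - y.mean()
    )
    ref = pls.x_scores_[:, 0]
    sign = np.sign(np.dot(ref, model.scores))
    assert np.allclose(model.scores * sign, ref, atol=1e-8)


def test_oplsda_rejects_degenerate_inputs():
    X, y = _planted_X(n=10, p_noise=4)
    with pytest.raises(ValueError):
        oplsda(X, np.zeros(10, dtype=int))
    X2 = X.copy()
    X2["v1"] = 1.0
    with pytest.raises(ValueError, match="zero-variance"):
        oplsda(X2, y)


# ---------------------------------------------------------------------------
# ROC


def test_roc_perfect_and_tied_scores():
    labels = np.array([0, 0, 1, 1])
    assert roc(np.array([0.0, 0.0, 1.0, 1.0]), labels, n_boot=50, seed=1).auc == 1.0
    assert roc(np.ones(4), labels, n_boot=50, seed=1).auc == 0.5


def test_roc_concordant_pair_counting():
    res = roc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]),
              n_boot=100, seed=1)
    assert res.auc == pytest.approx(0.75)
    assert res.ci_lo <= res.auc <= res.ci_hi


def test_roc_equals_normalized_mann_whitney_u():
    """AUC == U / (n+ x n-) on arbitrary tied inputs (scipy oracle)."""
    rng = np.random.default_rng(13)
    scores = np.round(rng.normal(size=40), 1)  # coarse rounding forces ties
    labels = rng.integers(0, 2, 40)
    while len(set(labels)) < 2:
        labels = rng.integers(0, 2, 40)
    u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                         alternative="two-sided").statistic
    expected = u / ((labels == 1).sum() * (labels == 0).sum())
    assert roc(scores, labels, n_boot=10, seed=1).auc == pytest.approx(expected)


def test_roc_requires_two_classes():
    with pytest.raises(ValueError):
        roc(np.array([0.1, 0.2]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# volcano


def _norm_table(c_vals, r_vals, name="A1"):
    idx = [f"c{i}" for i in range(len(c_vals))] + [f"r{i}" for i in range(len(r_vals))]
    table = pd.DataFrame({name: list(c_vals) + list(r_vals)}, index=idx)
    groups = pd.Series(["C"] * len(c_vals) + ["R"] * len(r_vals), index=idx)
    return table, groups


def test_volcano_identical_groups_not_significant():
    table, groups = _norm_table([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    res = volcano(table, groups)
    assert (res["flag"] == "ns").all()


def test_volcano_planted_fourfold_change_flagged_symmetrically():
    rng = np.random.default_rng(21)
    up_c = 40.0 * (1 + rng.normal(0, 0.01, 6))
    base = 10.0 * (1 + rng.normal(0, 0.01, 6))
    table, groups = _norm_table(up_c, base)
    res = volcano(table, groups)
    assert res["flag"].iloc[0] == "up"
    assert res["log2_fc"].iloc[0] == pytest.approx(2.0, abs=0.05)
    table2, groups2 = _norm_table(base, up_c)
    res2 = volcano(table2, groups2)
    assert res2["flag"].iloc[0] == "down"
    assert res2["log2_fc"].iloc[0] == pytest.approx(-res["log2_fc"].iloc[0], abs=0.05)


def test_volcano_zero_group_mean_substituted_and_flagged():
    table, groups = _norm_table([8.0, 9.0, 10.0], [0.0, 0.0, 0.0])
    res = volcano(table, groups)
    assert bool(res["substituted"].iloc[0])
    assert np.isfinite(res["log2_fc"].iloc[0])


def test_volcano_requires_two_per_group():
    table, groups = _norm_table([1.0], [2.0, 3.0])
    with pytest.raises(ValueError):
        volcano(table, groups)
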