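import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from umamikit.datatypes import ValidationError
from umamikit.simulate import GeneratorConfig, generate_expression_and_compounds
from umamikit.stats import (
    anova_oneway,
    compact_letter_display,
    pearson_matrix,
    strong_associations,
    tukey_hsd,
)


# ---------------------------------------------------------------- ANOVA

def test_anova_identical_groups_degenerate():
    g = [np.array([5.0, 5.0, 5.0])] * 3
    res = anova_oneway(g)
    assert res.f_statistic == 0.0
    assert res.p_value == 1.0
    assert (res.df_between, res.df_within) == (2, 6)


def test_anova_matches_manual_sums_of_squares():
    groups = [np.array([6.0, 8.0, 4.0]), np.array([5.0, 4.0, 3.0]), np.array([9.0, 10.0, 8.0])]
    res = anova_oneway(groups)
    # manual decomposition
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f = (ssb / 2) / (ssw / 6)
    assert res.f_statistic == pytest.approx(f, rel=1e-12)
    assert res.p_value == pytest.approx(sps.f.sf(f, 2, 6), rel=1e-12)


def test_two_group_anova_equals_squared_pooled_t():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 8)
    res = anova_oneway([a, b])
    t, p = sps.ttest_ind(a, b)
    assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
    assert res.p_value == pytest.approx(p, rel=1e-10)


def test_anova_parametric_agrees_with_permutation():
    rng = np.random.default_rng(7)
    groups = [rng.normal(mu, 1.0, 6) for mu in (0.0, 0.6, 1.0)]
    res = anova_oneway(groups)

    # permutation oracle: reshuffle group labels, recompute F
    allv = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    cuts = np.cumsum(sizes)[:-1]

    def fstat(v):
        parts = np.split(v, cuts)
        grand = v.mean()
        ssb = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
        ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
        return (ssb / (len(parts) - 1)) / (ssw / (len(v) - len(parts)))

    n_perm = 10000
    count = sum(
        fstat(rng.permutation(allv)) >= res.f_statistic for _ in range(n_perm)
    )
    p_perm = (count + 1) / (n_perm + 1)
    # binomial MC error ~ sqrt(p(1-p)/n) ~ 0.004 here; allow parametric slack
    assert abs(p_perm - res.p_value) < 0.03


def test_anova_needs_enough_data():
    with pytest.raises(ValidationError):
        anova_oneway([[1.0, 2.0]])
    with pytest.raises(ValidationError):
        anova_oneway([[1.0], [2.0, 3.0]])


# ------------------------------------------------------------- Tukey HSD

def test_tukey_identical_groups_all_one():
    g = [np.array([5.0, 5.0, 5.0])] * 3
    p = tukey_hsd(g)
    assert np.all(p == 1.0)


def test_tukey_separated_groups_tiny_p():
    g = [
        np.array([0.0, 0.1, -0.1, 0.05]),
        np.array([100.0, 100.1, 99.9, 100.05]),
        np.array([200.0, 200.1, 199.9, 200.05]),
    ]
    p = tukey_hsd(g)
    off = p[~np.eye(3, dtype=bool)]
    assert np.all(off < 1e-6)
    assert np.allclose(p, p.T)
    assert np.all(np.diag(p) == 1.0)


def test_tukey_matches_statsmodels_oracle():
    rng = np.random.default_rng(12)
    groups = [rng.normal(mu, 1.0, n) for mu, n in ((0.0, 5), (1.2, 7), (2.0, 6))]
    p = tukey_hsd(groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(groups)
    labels = np.repeat(["g0", "g1", "g2"], [len(g) for g in groups])
    sm = pairwise_tukeyhsd(values, labels)
    # statsmodels rows are (0,1), (0,2), (1,2)
    expected = dict(zip([(0, 1), (0, 2), (1, 2)], sm.pvalues))
    for (i, j), pv in expected.items():
        assert p[i, j] == pytest.approx(pv, abs=1e-6)


# -------------------------------------------------- compact letter display

def test_cld_no_significant_pairs():
    p = np.ones((4, 4))
    out = compact_letter_display(p, labels=list("WXYZ"))
    assert set(out.values()) == {"a"}


def test_cld_all_pairs_significant():
    p = np.full((3, 3), 1e-6)
    np.fill_diagonal(p, 1.0)
    out = compact_letter_display(p, labels=list("ABC"), means=[3.0, 2.0, 1.0])
    assert out == {"A": "a", "B": "b", "C": "c"}


def test_cld_chain_pattern():
    # A differs from C; B differs from neither -> A:a, B:ab, C:b
    p = np.array([[1.0, 0.5, 0.01], [0.5, 1.0, 0.5], [0.01, 0.5, 1.0]])
    out = compact_letter_display(p, labels=list("ABC"), means=[3.0, 2.0, 1.0])
    assert out == {"A": "a", "B": "ab", "C": "b"}


def test_cld_rejects_asymmetric_matrix():
    p = np.array([[1.0, 0.2], [0.8, 1.0]])
    with pytest.raises(ValidationError):
        compact_letter_display(p)


def test_cld_letters_follow_descending_means():
    p = np.full((3, 3), 1e-9)
    np.fill_diagonal(p, 1.0)
    out = compact_letter_display(p, labels=["lo", "hi", "mid"], means=[1.0, 9.0, 5.0])
    assert out == {"hi": "a", "mid": "b", "lo": "c"}


@settings(max_examples=200, derandomize=True)
@given(seed=st.integers(0, 10**6), k=st.integers(2, 6))
def test_cld_sharing_invariant_on_random_matrices(seed, k):
    """Groups share a letter iff their pairwise p >= alpha, for any matrix."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, (k, k))
    p = np.triu(p, 1)
    p = p + p.T + np.eye(k)
    alpha = 0.05 if seed % 2 else 0.5  # exercise both sparse and dense splits
    letters = compact_letter_display(p, alpha=alpha)
    for i in range(k):
        for j in range(i + 1, k):
            shared = set(letters[str(i)]) & set(letters[str(j)])
            if p[i, j] < alpha:
                assert not shared, (i, j, letters, p[i, j])
            else:
                assert shared, (i, j, letters, p[i, j])


# ------------------------------------------------------------- Pearson

def test_pearson_collinear_limits():
    x = pd.DataFrame({"g": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
    up = pd.DataFrame({"v": [2.0, 4.0, 6.0, 8.0]}, index=list("abcd"))
    down = pd.DataFrame({"v": [8.0, 6.0, 4.0, 2.0]}, index=list("abcd"))
    assert pearson_matrix(x, up).loc[0, "r"] == pytest.approx(1.0)
    assert pearson_matrix(x, down).loc[0, "r"] == pytest.approx(-1.0)


def test_pearson_matches_product_moment_oracle():
    rng = np.random.default_rng(9)
    idx = [f"s{i}" for i in range(20)]
    x = pd.DataFrame({"g": rng.normal(size=20)}, index=idx)
    y = pd.DataFrame({"v": rng.normal(size=20)}, index=idx)
    row = pearson_matrix(x, y).iloc[0]
    xv, yv = x["g"].to_numpy(), y["v"].to_numpy()
    r = np.sum((xv - xv.mean()) * (yv - yv.mean())) / np.sqrt(
        np.sum((xv - xv.mean()) ** 2) * np.sum((yv - yv.mean()) ** 2)
    )
    assert row["r"] == pytest.approx(r, rel=1e-12)
    t = r * np.sqrt(18 / (1 - r**2))
    assert row["p_value"] == pytest.approx(2 * sps.t.sf(abs(t), 18), rel=1e-9)


def test_pearson_affine_invariance():
    rng = np.random.default_rng(10)
    idx = [f"s{i}" for i in range(15)]
    x = pd.DataFrame({"g": rng.normal(size=15)}, index=idx)
    y = pd.DataFrame({"v": rng.normal(size=15)}, index=idx)
    base = pearson_matrix(x, y).loc[0, "r"]
    scaled = pearson_matrix(x * 7.0 + 3.0, y * 0.2 - 11.0).loc[0, "r"]
    assert scaled == pytest.approx(base, rel=1e-12)


def test_pearson_zero_variance_is_absent():
    x = pd.DataFrame({"g": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
    y = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
    row = pearson_matrix(x, y).iloc[0]
    assert np.isnan(row["r"]) and np.isnan(row["p_value"]) and row["stars"] == ""


def test_pearson_stars_and_strong_filter():
    rng = np.random.default_rng(30)
    n = 40
    idx = [f"s{i}" for i in range(n)]
    z = rng.normal(size=n)
    x = pd.DataFrame({"g": z}, index=idx)
    y = pd.DataFrame(
        {"tight": z + rng.normal(0, 0.1, n), "noise": rng.normal(size=n)}, index=idx
    )
    m = pearson_matrix(x, y)
    tight = m[m["variable"] == "tight"].iloc[0]
    assert tight["stars"] == "***"
    strong = strong_associations(m, r_min=0.8, alpha=0.05)
    assert list(strong["variable"]) == ["tight"]


def test_pearson_requires_min_overlap():
    x = pd.DataFrame({"g": [1.0, 2.0]}, index=["a", "b"])
    y = pd.DataFrame({"v": [1.0, 2.0]}, index=["a", "b"])
    with pytest.raises(ValidationError):
        pearson_matrix(x, y)


@pytest.mark.parametrize("rho", [-0.9, 0.0, 0.5, 0.9])
def test_latent_correlation_recovery(rho):
    """Estimated r converges to the generating rho within 3/sqrt(n)."""
    n = 2000
    cfg = GeneratorConfig(couplings={"GLUD1": ("Glu", rho)}, n_replicates=2)
    study = generate_expression_and_compounds(cfg, seed=abs(int(rho * 100)) + 3, n_species=n)
    m = pearson_matrix(study.expression_truth, study.compound_truth[["Glu"]])
    r_hat = m.loc[m["variable"] == "Glu", "r"].iloc[0]
    assert abs(r_hat - rho) < 3 / np.sqrt(n)
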