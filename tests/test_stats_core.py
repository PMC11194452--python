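"""Unit and property tests for the self-implemented statistics.

Every statistic is checked against an independent oracle: closed forms,
exhaustive enumeration on tiny instances, scipy/scikit-bio/vegan
reference implementations, or Monte-Carlo calibration.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from leachresp import stats_core as sc


# ---------------------------------------------------------------------------
# diversity indices


@pytest.mark.parametrize(
    "counts, expected",
    [
        ([5, 5, 5, 5], np.log(4)),
        ([9, 0, 0], 0.0),
        ([1, 2, 3], np.log(6) - (2 * np.log(2) + 3 * np.log(3)) / 6),
    ],
)
def test_shannon_closed_forms(counts, expected):
    assert sc.shannon_index(counts) == pytest.approx(expected, abs=1e-12)


def test_shannon_rejects_empty_community():
    with pytest.raises(sc.DegenerateInputError):
        sc.shannon_index([0, 0, 0])


def test_pielou_uniform_is_one_and_single_taxon_is_undefined():
    assert sc.pielou_evenness([3, 3, 3]) == pytest.approx(1.0)
    assert sc.pielou_evenness([1, 2, 3]) == pytest.approx(
        sc.shannon_index([1, 2, 3]) / np.log(3)
    )
    with pytest.raises(sc.DegenerateInputError):
        sc.pielou_evenness([1, 0, 0])


def test_pielou_bounded_on_random_communities():
    rng = np.random.default_rng(0)
    for _ in range(50):
        c = rng.integers(0, 50, size=12)
        if (c > 0).sum() < 2:
            continue
        assert 0.0 <= sc.pielou_evenness(c) <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _gv(values, labels):
    return sc.GroupedValues(np.asarray(values, float), np.asarray(labels))


def test_kruskal_wallis_all_tied_is_zero():
    r = sc.kruskal_wallis(_gv([2, 2, 2, 2], ["a", "a", "b", "b"]))
    assert r.statistic == 0.0
    assert r.p_value == 1.0


def test_kruskal_wallis_matches_scipy_with_ties():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a = rng.integers(0, 5, 7).astype(float)
        b = rng.integers(0, 5, 5).astype(float)
        c = rng.integers(0, 5, 6).astype(float)
        if len(set(np.concatenate([a, b, c]))) < 2:
            continue
        ours = sc.kruskal_wallis(_gv(np.concatenate([a, b, c]),
                                     ["a"] * 7 + ["b"] * 5 + ["c"] * 6))
        ref = scipy.stats.kruskal(a, b, c)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_kruskal_wallis_extreme_separation_is_exhaustive_maximum():
    """[1,2,3] vs [4,5,6] has the largest H of all 20 label assignments."""
    from itertools import combinations

    values = np.array([1, 2, 3, 4, 5, 6], float)
    h_obs = sc.kruskal_wallis(_gv(values, ["a"] * 3 + ["b"] * 3)).statistic
    h_all = []
    for idx in combinations(range(6), 3):
        labels = np.array(["b"] * 6, dtype=object)
        labels[list(idx)] = "a"
        h_all.append(sc.kruskal_wallis(_gv(values, labels)).statistic)
    assert h_obs == pytest.approx(max(h_all), abs=1e-12)
    # exactly the two extreme splits attain it
    assert sum(h == pytest.approx(h_obs) for h in h_all) == 2


def test_kruskal_wallis_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    x = rng.normal(size=18)
    labels = np.repeat(["a", "b", "c"], 6)
    h1 = sc.kruskal_wallis(_gv(x, labels)).statistic
    h2 = sc.kruskal_wallis(_gv(np.exp(x), labels)).statistic
    h3 = sc.kruskal_wallis(_gv(x**3, labels)).statistic
    assert h1 == pytest.approx(h2, rel=1e-12)
    assert h1 == pytest.approx(h3, rel=1e-12)


def test_kruskal_wallis_single_group_rejected():
    with pytest.raises(sc.DegenerateInputError):
        sc.kruskal_wallis(_gv([1, 2, 3], ["a", "a", "a"]))


def test_kruskal_wallis_type_one_error_calibrated():
    """Null rejection rate at alpha=0.05 within 3 binomial SE (600 sims)."""
    rng = np.random.default_rng(3)
    n_sims, alpha = 600, 0.05
    labels = np.repeat(["a", "b", "c"], 6)
    hits = sum(
        sc.kruskal_wallis(_gv(rng.normal(size=18), labels)).p_value < alpha
        for _ in range(n_sims)
    )
    se = np.sqrt(alpha * (1 - alpha) / n_sims)
    assert abs(hits / n_sims - alpha) < 3 * se


# ---------------------------------------------------------------------------
# Dunn post hoc


def test_dunn_identical_groups_z_zero_p_one():
    r = sc.dunn_posthoc(_gv([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3))
    row = r.pairwise.iloc[0]
    assert row["z"] == pytest.approx(0.0)
    assert row["p_raw"] == pytest.approx(1.0)


def test_dunn_hand_computed_mean_ranks():
    """A=[1,2], B=[3,4], C=[5,6]: mean ranks 1.5/3.5/5.5, sigma2=3.5."""
    g = _gv([1, 2, 3, 4, 5, 6], ["A", "A", "B", "B", "C", "C"])
    r = sc.dunn_posthoc(g, adjust="none")
    tab = r.pairwise.set_index(["group_a", "group_b"])
    z_ab = (1.5 - 3.5) / np.sqrt(3.5 * (1 / 2 + 1 / 2))
    z_ac = (1.5 - 5.5) / np.sqrt(3.5 * (1 / 2 + 1 / 2))
    assert tab.loc[("A", "B"), "z"] == pytest.approx(z_ab, abs=1e-12)
    assert tab.loc[("A", "C"), "z"] == pytest.approx(z_ac, abs=1e-12)
    assert tab.loc[("A", "B"), "p_raw"] == pytest.approx(
        2 * scipy.stats.norm.sf(abs(z_ab)), abs=1e-12
    )


def test_dunn_holm_never_below_raw():
    rng = np.random.default_rng(4)
    g = _gv(rng.normal(size=20), rng.choice(["a", "b", "c", "d"], 20))
    r = sc.dunn_posthoc(g, adjust="holm")
    assert (r.pairwise["p_adj"] >= r.pairwise["p_raw"] - 1e-15).all()


def test_holm_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.random(9)
    ours = sc.holm_adjust(p)
    _, ref, _, _ = multipletests(p, method="holm")
    assert np.allclose(ours, ref)


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_monotone_extremes():
    assert sc.spearman([1, 2, 3], [10, 20, 30], n_perm=99, seed=0).statistic == pytest.approx(1.0)
    assert sc.spearman([1, 2, 3], [3, 2, 1], n_perm=99, seed=0).statistic == pytest.approx(-1.0)


def test_spearman_ties_equal_pearson_on_midranks():
    x, y = [1, 1, 2, 3], [1, 2, 2, 2]
    rho = sc.spearman(x, y, n_perm=99, seed=0).statistic
    rx, ry = scipy.stats.rankdata(x), scipy.stats.rankdata(y)
    assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
    assert rho == pytest.approx(scipy.stats.spearmanr(x, y).statistic, abs=1e-12)


def test_spearman_constant_vector_rejected():
    with pytest.raises(sc.DegenerateInputError):
        sc.spearman([1, 1, 1], [1, 2, 3], n_perm=9, seed=0)


def test_spearman_permutation_p_reproducible_and_bounded():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=10), rng.normal(size=10)
    r1 = sc.spearman(x, y, n_perm=499, seed=42)
    r2 = sc.spearman(x, y, n_perm=499, seed=42)
    assert r1.p_value == r2.p_value
    assert 1 / 500 <= r1.p_value <= 1.0


# ---------------------------------------------------------------------------
# Bray-Curtis


def test_bray_curtis_closed_forms():
    d = sc.bray_curtis(pd.DataFrame([[1, 1], [1, 1], [2, 0], [0, 2], [1, 1]]))
    assert d.d[0, 1] == pytest.approx(0.0)
    assert d.d[2, 3] == pytest.approx(1.0)  # disjoint supports
    # [1,1] vs [0,2]: |1-0|+|1-2| over 1+0+1+2 = 2/4
    assert d.d[0, 3] == pytest.approx(0.5)


def test_bray_curtis_matches_scipy_on_random_tables():
    rng = np.random.default_rng(7)
    x = rng.random((8, 15))
    ours = sc.bray_curtis(pd.DataFrame(x)).d
    ref = squareform(pdist(x, metric="braycurtis"))
    assert np.allclose(ours, ref)


def test_bray_curtis_two_empty_samples_rejected():
    with pytest.raises(sc.DegenerateInputError):
        sc.bray_curtis(pd.DataFrame([[0, 0], [0, 0]]))


# ---------------------------------------------------------------------------
# PERMANOVA


def _random_distance(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.random((n, 6))
    return sc.DistanceMatrix(
        [f"s{i}" for i in range(n)], squareform(pdist(x, "braycurtis"))
    )


def _two_factor_design(n):
    # 3 plastic levels x 2 light levels, balanced
    per = n // 6
    return pd.DataFrame(
        {
            "plastic": np.repeat(["a", "b", "c"], 2 * per),
            "light": np.tile(np.repeat(["x", "y"], per), 3),
        },
        index=[f"s{i}" for i in range(n)],
    )


def test_permanova_r2_partition_sums_to_one():
    d = _random_distance(12, 8)
    r = sc.permanova(d, _two_factor_design(12), n_perm=49, seed=0)
    assert r.table["R2"].iloc[:4].sum() == pytest.approx(1.0, abs=1e-9)
    assert r.table.loc["Total", "SS"] == pytest.approx(
        r.table["SS"].iloc[:4].sum(), rel=1e-9
    )


def _oneway_permanova_oracle(d, labels, perms):
    """Independent one-way pseudo-F from group-wise squared distances."""
    labels = np.asarray(labels)
    n = len(labels)
    k = len(set(labels))
    d2 = d**2

    def f_stat(lab):
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in set(lab):
            idx = np.flatnonzero(lab == g)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = f_stat(labels)
    hits = sum(f_stat(labels[list(p)]) >= f_obs - 1e-12 for p in perms)
    return f_obs, (hits + 1) / (len(perms) + 1)


def test_permanova_p_equals_exhaustive_enumeration_oracle():
    """6 samples, 2 groups: full 720-permutation p matches the oracle."""
    d = _random_distance(6, 9)
    design = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3}, index=d.labels)
    perms = sc.all_label_permutations(6)
    ours = sc.permanova(d, design, factors=("group",), permutations=perms)
    f_oracle, p_oracle = _oneway_permanova_oracle(
        d.d, design["group"].to_numpy(), perms
    )
    assert ours.table.loc["group", "F"] == pytest.approx(f_oracle, rel=1e-9)
    assert ours.p("group") == pytest.approx(p_oracle, abs=1e-12)


def test_permanova_oneway_matches_skbio():
    import skbio

    d = _random_distance(10, 10)
    design = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5}, index=d.labels)
    ours = sc.permanova(d, design, factors=("group",), n_perm=99, seed=1)
    ref = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(d.d, ids=list(d.labels)),
        design, column="group", permutations=99,
    )
    assert ours.table.loc["group", "F"] == pytest.approx(ref["test statistic"], rel=1e-9)


def test_permanova_two_factor_matches_vegan_adonis2(tmp_path):
    """Sequential SS/R2/F agree with vegan's adonis2 on a fixed table."""
    rng = np.random.default_rng(3)
    x = rng.random((12, 5))
    x = x / x.sum(1, keepdims=True)
    labels = [f"s{i}" for i in range(12)]
    design = pd.DataFrame(
        {"plastic": ["a"] * 4 + ["b"] * 4 + ["c"] * 4, "light": ["x", "y"] * 6},
        index=labels,
    )
    pd.DataFrame(x, index=labels).to_csv(tmp_path / "abund.csv")
    design.to_csv(tmp_path / "design.csv")
    script = textwrap.dedent("""
        suppressMessages(library(vegan))
        x <- read.csv('abund.csv', row.names=1)
        d <- read.csv('design.csv', row.names=1)
        res <- adonis2(x ~ plastic * light, data=d, permutations=29,
                       method='bray', by='terms')
        write.csv(as.data.frame(res), 'out.csv')
    """)
    (tmp_path / "oracle.R").write_text(script)
    subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path, check=True,
                   capture_output=True)
    ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
    dm = sc.bray_curtis(pd.DataFrame(x, index=labels))
    ours = sc.permanova(dm, design, n_perm=29, seed=0)
    for term, rterm in [("plastic", "plastic"), ("light", "light"),
                        ("plastic:light", "plastic:light"), ("Residual", "Residual")]:
        assert ours.table.loc[term, "SS"] == pytest.approx(
            ref.loc[rterm, "SumOfSqs"], rel=1e-6
        )
        assert ours.table.loc[term, "R2"] == pytest.approx(ref.loc[rterm, "R2"], rel=1e-6)


def test_permanova_invariant_to_joint_relabeling():
    d = _random_distance(12, 11)
    design = _two_factor_design(12)
    r1 = sc.permanova(d, design, n_perm=9, seed=0)
    perm = np.random.default_rng(0).permutation(12)
    d2 = sc.DistanceMatrix([d.labels[i] for i in perm], d.d[np.ix_(perm, perm)])
    r2 = sc.permanova(d2, design, n_perm=9, seed=0)
    assert np.allclose(r1.table["R2"].iloc[:4], r2.table["R2"].iloc[:4])


def test_permanova_p_reproducible_and_bounded():
    d = _random_distance(12, 12)
    design = _two_factor_design(12)
    r1 = sc.permanova(d, design, n_perm=199, seed=5)
    r2 = sc.permanova(d, design, n_perm=199, seed=5)
    assert r1.table["p_perm"].iloc[:3].equals(r2.table["p_perm"].iloc[:3])
    assert (r1.table["p_perm"].iloc[:3] >= 1 / 200).all()
    assert (r1.table["p_perm"].iloc[:3] <= 1.0).all()


def test_permanova_degenerate_distances_rejected():
    d = sc.DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
    design = pd.DataFrame({"plastic": ["a", "a", "b", "b"], "light": ["x", "y", "x", "y"]},
                          index=list("abcd"))
    with pytest.raises(sc.DegenerateInputError):
        sc.permanova(d, design, n_perm=9, seed=0)
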