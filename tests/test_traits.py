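"""Brownian-motion trait models: covariances, likelihoods, LRT."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastid_erosion.scenarios import random_tree
from plastid_erosion.synth import simulate_traits
from plastid_erosion.traits import (
    bm_loglik,
    fit_bm,
    lrt_correlation,
    tree_covariance,
)


def _df(x, y, index=None):
    return pd.DataFrame({"x": x, "y": y}, index=index)


# -- tree covariance ---------------------------------------------------

def test_star_tree_gives_diagonal_covariance():
    tree = dendropy.Tree.get(data="(a:1,b:1,c:1,d:1);", schema="newick")
    labels, C = tree_covariance(tree)
    assert np.allclose(C, np.eye(4))


def test_two_tip_closed_form():
    tree = dendropy.Tree.get(data="(a:2.0,b:3.5);", schema="newick")
    labels, C = tree_covariance(tree)
    expect = {"a": 2.0, "b": 3.5}
    assert C[0, 1] == 0.0
    for lab, d in zip(labels, np.diag(C)):
        assert d == expect[lab]


def test_covariance_matches_path_enumeration_oracle():
    tree = random_tree(6, seed=3)
    labels, C = tree_covariance(tree)
    pdm = tree.phylogenetic_distance_matrix()
    depth = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth[leaf.taxon.label] = d
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                assert C[i, i] == pytest.approx(depth[a])
            else:
                patristic = pdm.patristic_distance(taxa[a], taxa[b])
                mrca_depth = (depth[a] + depth[b] - patristic) / 2
                assert C[i, j] == pytest.approx(mrca_depth)


def test_negative_branch_length_rejected():
    tree = dendropy.Tree.get(data="(a:1,b:-0.5);", schema="newick")
    with pytest.raises(ValueError, match="negative"):
        tree_covariance(tree)


# -- likelihood --------------------------------------------------------

def test_two_tip_independent_loglik_equals_univariate_sum():
    C = np.diag([2.0, 3.0])
    x, y = np.array([0.4, -1.0]), np.array([1.2, 0.3])
    params = dict(mu_x=0.1, mu_y=-0.2, sigma2_x=1.5, sigma2_y=0.7,
                  sigma_xy=0.0)
    ll = bm_loglik(C, _df(x, y), params)
    direct = (
        stats.norm.logpdf(x, 0.1, np.sqrt(1.5 * np.diag(C))).sum()
        + stats.norm.logpdf(y, -0.2, np.sqrt(0.7 * np.diag(C))).sum()
    )
    assert ll == pytest.approx(direct, abs=1e-10)


def test_correlated_flag_off_equals_zero_covariance():
    tree = random_tree(6, seed=1)
    df = simulate_traits(tree, np.eye(2), seed=0)
    params = dict(mu_x=0.0, mu_y=0.0, sigma2_x=1.0, sigma2_y=1.0,
                  sigma_xy=0.0)
    assert bm_loglik(tree, df, params, correlated=True) == \
        bm_loglik(tree, df, params, correlated=False)


def test_loglik_matches_dense_multivariate_normal():
    rng = np.random.default_rng(5)
    for rep in range(20):
        n = int(rng.integers(3, 9))
        tree = random_tree(n, seed=100 + rep)
        _, C = tree_covariance(tree)
        params = dict(
            mu_x=float(rng.normal()), mu_y=float(rng.normal()),
            sigma2_x=float(rng.uniform(0.3, 2.0)),
            sigma2_y=float(rng.uniform(0.3, 2.0)),
        )
        r = float(rng.uniform(-0.9, 0.9))
        params["sigma_xy"] = r * np.sqrt(
            params["sigma2_x"] * params["sigma2_y"])
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        R = np.array([[params["sigma2_x"], params["sigma_xy"]],
                      [params["sigma_xy"], params["sigma2_y"]]])
        dense = stats.multivariate_normal.logpdf(
            np.concatenate([x, y]),
            np.concatenate([np.full(n, params["mu_x"]),
                            np.full(n, params["mu_y"])]),
            np.kron(R, C),
        )
        assert bm_loglik(C, _df(x, y), params) == pytest.approx(
            dense, abs=1e-8)


def test_singular_rate_matrix_raises_with_diagnostic():
    C = np.eye(3)
    params = dict(mu_x=0, mu_y=0, sigma2_x=1.0, sigma2_y=1.0, sigma_xy=1.0)
    with pytest.raises(ValueError, match="singular"):
        bm_loglik(C, _df(np.zeros(3), np.zeros(3)), params)


# -- fitting -----------------------------------------------------------

def test_free_fit_never_below_null_fit():
    rng = np.random.default_rng(2)
    tree = random_tree(10, seed=7)
    for rep in range(20):
        df = simulate_traits(tree, np.eye(2), seed=rep)
        free = fit_bm(tree, df, correlated=True)
        null = fit_bm(tree, df, correlated=False)
        assert free.loglik >= null.loglik - 1e-9
        assert abs(free.sigma_xy) <= np.sqrt(
            free.sigma2_x * free.sigma2_y) + 1e-12


def test_identical_traits_give_unit_correlation():
    tree = random_tree(8, seed=9)
    labels, _ = tree_covariance(tree)
    x = np.random.default_rng(0).standard_normal(8)
    df = _df(x, x, index=labels)
    fit = fit_bm(tree, df)
    assert fit.correlation >= 0.999


def test_rate_recovery_bias_small_at_n64():
    tree = random_tree(64, seed=11)
    _, C = tree_covariance(tree)
    est = []
    for rep in range(500):
        df = simulate_traits(tree, np.diag([1.0, 1.0]), seed=1000 + rep)
        est.append(fit_bm(C, df).sigma2_x)
    assert abs(np.mean(est) - 1.0) < 0.10


def test_uncorrelated_data_recover_near_zero_correlation():
    tree = random_tree(16, seed=13)
    _, C = tree_covariance(tree)
    rs = []
    for rep in range(500):
        df = simulate_traits(tree, np.eye(2), seed=2000 + rep)
        rs.append(fit_bm(C, df).correlation)
    assert abs(np.median(rs)) < 0.05


# -- LRT ---------------------------------------------------------------

def test_identical_traits_reject_overwhelmingly():
    tree = random_tree(10, seed=17)
    labels, _ = tree_covariance(tree)
    x = np.random.default_rng(1).standard_normal(10)
    res = lrt_correlation(tree, _df(x, x, index=labels))
    assert res.p_value < 1e-6


def test_star_tree_lrt_equals_ordinary_bivariate_lrt():
    n = 12
    tree = dendropy.Tree.get(
        data="(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");",
        schema="newick")
    labels, C = tree_covariance(tree)
    assert np.allclose(C, np.eye(n))
    rng = np.random.default_rng(3)
    x, y = rng.standard_normal(n), rng.standard_normal(n)
    res = lrt_correlation(tree, _df(x, y, index=labels))
    # ordinary bivariate normal LRT: -n log(1 - r^2) with ML (biased) r
    xc, yc = x - x.mean(), y - y.mean()
    r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
    assert res.lr == pytest.approx(-n * np.log(1 - r2), abs=1e-6)


def test_binary_trait_emits_caveat():
    tree = random_tree(8, seed=23)
    labels, _ = tree_covariance(tree)
    rng = np.random.default_rng(0)
    df = _df(rng.standard_normal(8), rng.integers(0, 2, 8).astype(float),
             index=labels)
    res = lrt_correlation(tree, df)
    assert "binary" in res.caveat
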