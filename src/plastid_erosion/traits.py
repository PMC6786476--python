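"""Correlated vs independent Brownian-motion trait models on a fixed tree.

Two continuous traits evolving by Brownian motion on a rooted tree with
branch lengths have tip values distributed as multivariate normal with
covariance R (x) C, where C[i,j] is the shared root-to-tip path length of
tips i and j and R = [[sx2, sxy], [sxy, sy2]] is the evolutionary rate
matrix.  The free model estimates sxy; the null fixes sxy = 0.  Both are
fitted by maximum likelihood — available in closed form: root states by
generalized least squares, R-hat = D' C^-1 D / n — and compared by a
likelihood-ratio test against chi-square with 1 df.

Binary traits (IR presence, heterotrophy) are coded 0/1 and analyzed
under the same continuous random-walk model; results for such traits
carry an explicit caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

_LOG2PI = np.log(2.0 * np.pi)


def tree_covariance(tree) -> tuple[list[str], np.ndarray]:
    """Shared root-to-tip path-length matrix of a dendropy tree.

    Returns (taxon labels, C) with C[i,i] the depth of tip i and C[i,j]
    the depth of the MRCA of tips i and j.
    """
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError("negative branch length")
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    index = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[id(parent)]
        if node.edge.length is not None and parent is not None:
            d += node.edge.length
        depth[id(node)] = d
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            kids = [below[id(ch)] for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = d
            below[id(node)] = [i for k in kids for i in k]
    return labels, C


@dataclass
class BMModelFit:
    mu_x: float
    mu_y: float
    sigma2_x: float
    sigma2_y: float
    sigma_xy: float
    loglik: float
    correlated: bool
    converged: bool = True

    @property
    def correlation(self) -> float:
        denom = np.sqrt(self.sigma2_x * self.sigma2_y)
        return self.sigma_xy / denom if denom > 0 else 0.0


def _prep(tree_or_C, traits: pd.DataFrame):
    """Align traits with the tree and return (C, x, y)."""
    if isinstance(tree_or_C, np.ndarray):
        C = np.array(tree_or_C, float)
        x = traits.iloc[:, 0].to_numpy(float)
        y = traits.iloc[:, 1].to_numpy(float)
    else:
        labels, C = tree_covariance(tree_or_C)
        missing = set(labels) - set(traits.index)
        if missing:
            raise ValueError(f"traits missing for tips: {sorted(missing)}")
        sub = traits.loc[labels]
        x = sub.iloc[:, 0].to_numpy(float)
        y = sub.iloc[:, 1].to_numpy(float)
    n = len(x)
    if C.shape != (n, n):
        raise ValueError("covariance / trait dimension mismatch")
    return C, x, y


def _chol(C: np.ndarray):
    """Cholesky factor; floors the diagonal only if C is singular
    (e.g. zero-length terminal branches)."""
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        floor = 1e-8 * float(np.max(np.diag(C)))
        if floor <= 0:
            raise ValueError("tree covariance is identically zero")
        return cho_factor(C + floor * np.eye(len(C)), lower=True)


def _loglik_arrays(C, x, y, mu_x, mu_y, sx2, sy2, sxy) -> float:
    n = len(x)
    if sx2 <= 0 or sy2 <= 0:
        raise ValueError("rate parameters must be positive")
    det_r = sx2 * sy2 - sxy * sxy
    if det_r <= 0:
        raise ValueError(
            f"singular rate matrix (det={det_r:.3g}); |sigma_xy| must be "
            "strictly below sqrt(sigma2_x * sigma2_y)"
        )
    cf = _chol(C)
    logdet_c = 2.0 * float(np.log(np.diag(cf[0])).sum())
    xw = cho_solve(cf, x - mu_x)
    yw = cho_solve(cf, y - mu_y)
    xx = float((x - mu_x) @ xw)
    yy = float((y - mu_y) @ yw)
    xy = float((x - mu_x) @ yw)
    r11, r22, r12 = sy2 / det_r, sx2 / det_r, -sxy / det_r
    quad = r11 * xx + 2.0 * r12 * xy + r22 * yy
    return float(
        -n * _LOG2PI - logdet_c - 0.5 * n * np.log(det_r) - 0.5 * quad
    )


def bm_loglik(
    tree_or_C,
    traits: pd.DataFrame,
    params: dict,
    correlated: bool = True,
) -> float:
    """Log-likelihood of a bivariate BM model.

    Equivalent to the dense 2n-dimensional multivariate normal with
    covariance R (x) C, evaluated through the Kronecker structure.
    ``sigma_xy`` is treated as 0 when ``correlated`` is False.
    """
    C, x, y = _prep(tree_or_C, traits)
    sxy = float(params.get("sigma_xy", 0.0)) if correlated else 0.0
    return _loglik_arrays(
        C, x, y,
        float(params["mu_x"]), float(params["mu_y"]),
        float(params["sigma2_x"]), float(params["sigma2_y"]), sxy,
    )


def fit_bm(tree_or_C, traits: pd.DataFrame, correlated: bool = True) -> BMModelFit:
    """Closed-form ML fit of the bivariate BM model.

    Root states are the GLS means given C; the rate-matrix MLE is
    R-hat = D' C^-1 D / n (its diagonal for the uncorrelated null).
    """
    C, x, y = _prep(tree_or_C, traits)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 tips")
    cf = _chol(C)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    denom = float(ones @ Ci1)
    mu_x = float(x @ Ci1) / denom
    mu_y = float(y @ Ci1) / denom
    dx, dy = x - mu_x, y - mu_y
    Cix = cho_solve(cf, dx)
    Ciy = cho_solve(cf, dy)
    sxx = max(float(dx @ Cix) / n, 1e-300)
    syy = max(float(dy @ Ciy) / n, 1e-300)
    sxy = float(dx @ Ciy) / n if correlated else 0.0
    if correlated:
        # keep R-hat strictly positive definite (degenerate Y = X case)
        cap = (1.0 - 1e-12) * np.sqrt(sxx * syy)
        sxy = float(np.clip(sxy, -cap, cap))
    ll = _loglik_arrays(C, x, y, mu_x, mu_y, sxx, syy, sxy)
    return BMModelFit(mu_x, mu_y, sxx, syy, sxy, ll, correlated)


@dataclass
class LRTResult:
    lr: float
    df: int
    p_value: float
    fit_free: BMModelFit
    fit_null: BMModelFit
    caveat: str = ""

    def to_dict(self) -> dict:
        return {
            "LR": self.lr,
            "df": self.df,
            "p": self.p_value,
            "correlation": self.fit_free.correlation,
            "free_loglik": self.fit_free.loglik,
            "null_loglik": self.fit_null.loglik,
            "caveat": self.caveat,
        }


def lrt_correlation(tree_or_C, traits: pd.DataFrame) -> LRTResult:
    """LRT of trait correlation: 2(lnL_free - lnL_null) vs chi-square(1)."""
    free = fit_bm(tree_or_C, traits, correlated=True)
    null = fit_bm(tree_or_C, traits, correlated=False)
    lr = max(0.0, 2.0 * (free.loglik - null.loglik))
    p = float(stats.chi2.sf(lr, df=1))
    caveat = ""
    for col in traits.columns[:2]:
        vals = set(np.unique(traits[col].to_numpy(float)))
        if vals <= {0.0, 1.0}:
            caveat = (
                "binary trait analyzed under a continuous random-walk "
                "model; interpret the correlation qualitatively"
            )
    return LRTResult(lr, 1, p, free, null, caveat)
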