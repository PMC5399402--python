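"""PCA and MB-PLS against independent oracles; VIP normalization and selection."""

import numpy as np
import pandas as pd
import pytest

from scaldnet import (
    SizingError,
    ValidationError,
    compute_vip,
    fit_mbpls,
    fit_pca,
    select_vips,
    split_by_sign,
)
from scaldnet.data import OmicsBlock
from scaldnet.multivariate import assign_signs


def nipals_pls2(X, Y, n_components, tol=1e-12, max_iter=2000):
    """Textbook NIPALS PLS2 oracle, written independently of the package."""
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    W, T, Q = [], [], []
    for _ in range(n_components):
        u = Y[:, int(np.argmax((Y**2).sum(axis=0)))].copy()
        for _ in range(max_iter):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            q = Y.T @ t / (t @ t)
            u_new = Y @ q / (q @ q)
            if np.linalg.norm(u_new - u) <= tol * np.linalg.norm(u_new):
                u = u_new
                break
            u = u_new
        p = X.T @ t / (t @ t)
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, q)
        W.append(w)
        T.append(t)
        Q.append(q)
    return np.column_stack(W), np.column_stack(T), np.column_stack(Q)


def _scaled(rng, n, p):
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    X /= X.std(axis=0, ddof=1)
    return X


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_first_component_explains_everything():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([2.0, -1.0, 0.5])
    X = np.outer(a, b)
    model = fit_pca(X, 1)
    assert model.explained_variance_ratio[0] == pytest.approx(1.0)
    assert np.abs(model.reconstruct() - X).max() < 1e-10


def test_pca_full_reconstruction():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((8, 5))
    model = fit_pca(X, 5)
    assert np.abs(model.reconstruct() - X).max() < 1e-8


def test_pca_explained_variance_matches_eigendecomposition():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((3, 3))
    Xc = X - X.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
    model = fit_pca(X, 2)
    expected = eig / eig.sum()
    assert np.allclose(model.explained_variance_ratio, expected[:2], atol=1e-10)


def test_pca_rejects_too_many_components():
    with pytest.raises(SizingError):
        fit_pca(np.eye(4), 4)  # A must be <= n-1


# ---------------------------------------------------------------------------
# MB-PLS
# ---------------------------------------------------------------------------

def test_single_block_equals_ordinary_pls():
    """With one block the consensus model reduces to NIPALS PLS2."""
    rng = np.random.default_rng(2)
    X = _scaled(rng, 20, 12)
    Y = _scaled(rng, 20, 3)
    model = fit_mbpls([X], Y, n_components=3, block_scale=False)
    W, T, _ = nipals_pls2(X, Y, 3)
    for a in range(3):
        w_m = model.block_weights[0][:, a]
        t_m = model.super_scores[:, a]
        sign = np.sign(w_m @ W[:, a])
        assert np.abs(w_m - sign * W[:, a]).max() < 1e-6
        assert np.abs(t_m - sign * T[:, a]).max() < 1e-6


def test_two_identical_blocks_get_equal_super_weights():
    rng = np.random.default_rng(3)
    X = _scaled(rng, 15, 6)
    y = _scaled(rng, 15, 1)
    model = fit_mbpls([X, X.copy()], y, n_components=2)
    assert np.abs(model.super_weights[0] - model.super_weights[1]).max() < 1e-8


def test_super_scores_orthogonal(scaled):
    expr_s, metab_s, resp, _ = scaled
    model = fit_mbpls([expr_s.block, metab_s.block], resp, n_components=3)
    T = model.super_scores
    gram = T.T @ T
    off = np.abs(gram - np.diag(np.diag(gram))).max()
    assert off < 1e-8 * np.diag(gram).max()


def test_block_weights_unit_norm(scaled):
    expr_s, metab_s, resp, _ = scaled
    model = fit_mbpls([expr_s.block, metab_s.block], resp, n_components=3)
    for W in model.block_weights:
        assert np.allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-10)


def test_misaligned_blocks_rejected():
    rng = np.random.default_rng(4)
    with pytest.raises(Exception):
        fit_mbpls([rng.standard_normal((10, 3)), rng.standard_normal((9, 3))],
                  rng.standard_normal(10), n_components=1)


def test_components_beyond_rank_rejected():
    rng = np.random.default_rng(5)
    X = _scaled(rng, 5, 3)
    y = _scaled(rng, 5, 1)
    with pytest.raises(SizingError):
        fit_mbpls([X], y, n_components=5)


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def test_raw_vip_sum_of_squares_equals_block_size(scaled):
    expr_s, metab_s, resp, _ = scaled
    model = fit_mbpls([expr_s.block, metab_s.block], resp, n_components=3)
    vip = compute_vip(model, "scald")
    for block, p in zip(model.block_names, model.p_b):
        ss = (vip.loc[vip["block"] == block, "raw_vip"] ** 2).sum()
        assert ss == pytest.approx(p, rel=1e-6)


def test_rescaled_vip_grand_mean_is_one(scaled):
    expr_s, metab_s, resp, _ = scaled
    model = fit_mbpls([expr_s.block, metab_s.block], resp, n_components=3)
    vip = compute_vip(model, "scald")
    assert vip["vip"].mean() == pytest.approx(1.0, abs=1e-9)
    # equal block totals
    totals = vip.groupby("block")["vip"].sum()
    assert totals.iloc[0] == pytest.approx(totals.iloc[1], rel=1e-9)


def test_single_variable_block_raw_vip_is_one():
    rng = np.random.default_rng(6)
    X1 = _scaled(rng, 12, 1)
    X2 = _scaled(rng, 12, 4)
    y = _scaled(rng, 12, 1)
    model = fit_mbpls([X1, X2], y, n_components=1)
    vip = compute_vip(model, "y0")
    assert vip.loc[vip["block"] == "block0", "raw_vip"].iloc[0] == pytest.approx(1.0)


def test_vip_requires_explained_variance():
    rng = np.random.default_rng(7)
    X = _scaled(rng, 10, 4)
    Y = np.column_stack([_scaled(rng, 10, 1)[:, 0], np.zeros(10)])
    model = fit_mbpls([X], Y, n_components=1)
    with pytest.raises(ValidationError, match="no variance"):
        compute_vip(model, "y1")


# ---------------------------------------------------------------------------
# selection and sign splitting
# ---------------------------------------------------------------------------

def _vip_frame(values, block="b"):
    return pd.DataFrame(
        {"variable": [f"v{i}" for i in range(len(values))],
         "block": block, "raw_vip": values, "vip": values}
    )


def test_selection_quantile_value():
    from scipy.stats import norm
    assert norm.ppf(1 - 0.33) == pytest.approx(0.4399, abs=5e-5)


def test_selection_threshold_arithmetic():
    out = select_vips(_vip_frame([0.5, 1.0, 1.5]), p=0.33)
    assert out["threshold"].iloc[0] == pytest.approx(1.0 + 0.4399 * 0.5, abs=1e-4)
    assert list(out["selected"]) == [False, False, True]


def test_no_selection_when_all_vips_equal():
    out = select_vips(_vip_frame([1.0, 1.0, 1.0]), p=0.33)
    assert not out["selected"].any()


def test_single_variable_block_warns_and_selects_nothing():
    with pytest.warns(UserWarning, match="single variable"):
        out = select_vips(_vip_frame([2.0]), p=0.33)
    assert not out["selected"].any()


def test_sign_split_partitions_selected():
    rng = np.random.default_rng(8)
    y = np.linspace(1, 4, 12) + 0 * rng.standard_normal(12)
    data = pd.DataFrame(
        {"up": y, "down": -y, "flat": rng.standard_normal(12)},
        index=[f"s{i}" for i in range(12)],
    )
    blk = OmicsBlock("b", data)
    vip = _vip_frame([2.0, 2.0, 0.1])
    vip["variable"] = ["up", "down", "flat"]
    vip = select_vips(vip, p=0.33)
    vip.loc[:, "selected"] = [True, True, False]  # focus the partition property
    pos, neg = split_by_sign(vip, [blk], y)
    assert pos == ["up"] and neg == ["down"]
    assert len(pos) + len(neg) == int(vip["selected"].sum())


def test_sign_split_rejects_constant_response():
    blk = OmicsBlock("b", pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=list("abc")))
    vip = select_vips(_vip_frame([1.0, 2.0, 3.0]))
    with pytest.raises(ValidationError, match="constant"):
        assign_signs(vip, [blk], np.ones(3))
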