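"""PCA, multi-block PLS-DA, and VIP scoring.

The multi-block model follows the consensus NIPALS formulation: per
latent component, every block computes its own unit-norm weight vector
and block score against the current Y residual; a unit-norm super-weight
vector combines the block scores into a super score; Y is regressed on
the super score and both the blocks and Y are deflated by it.  With one
block this reduces to ordinary NIPALS PLS2.

VIP (variable importance in projection) per response r, for variable j
in block b with block-normalized weights w and per-component explained
response variance SSY:

    VIP_j = sqrt( p_b * sum_a SSY_ar * w_ja^2 / sum_a SSY_ar )

so that sum_{j in b} VIP_j^2 = p_b within every block.  Block-rescaled
VIPs multiply each block by a constant giving every block the same total
contribution (sum over block = P_total / B); their grand mean is then
exactly one, and the ratio of block-mean VIP between two blocks equals
the inverse ratio of their variable counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import OmicsBlock, check_aligned
from .errors import AlignmentError, SizingError, ValidationError
from .preprocess import ResponseDesign

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAModel:
    """SVD principal-component model of a centred/scaled matrix."""

    loadings: np.ndarray  # variables x A, orthonormal columns
    scores: np.ndarray  # samples x A
    mean: np.ndarray  # variables,
    explained_variance_ratio: np.ndarray  # A,
    n_components: int

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T + self.mean


def fit_pca(X: np.ndarray | pd.DataFrame, n_components: int) -> PCAModel:
    """Fit PCA by singular value decomposition.

    Component sign is fixed by making the largest-magnitude loading of
    each component positive, so results are fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components < 1 or n_components > min(n - 1, p):
        raise SizingError(
            f"n_components={n_components} outside 1..min(n-1={n - 1}, p={p})"
        )
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    for a in range(n_components):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    total = float((s**2).sum())
    evr = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAModel(
        loadings=Vt[:n_components].T.copy(),
        scores=(U[:, :n_components] * s[:n_components]).copy(),
        mean=mean,
        explained_variance_ratio=evr,
        n_components=n_components,
    )


# --------------------------------------------------------------------------
# MB-PLS
# --------------------------------------------------------------------------

@dataclass
class MBPLSModel:
    """Fitted multi-block PLS model.

    Per component a and block b: unit-norm block weights ``w_ba``, block
    scores ``t_ba``; unit-norm super weights (block importance); super
    scores ``T_a`` (mutually orthogonal); Y-weights ``q_a`` (regression
    of Y on the super score); ``ssy[a, r]`` the explained sum of squares
    of response r by component a.
    """

    block_names: list[str]
    variable_ids: list[list[str]]
    p_b: list[int]
    block_weights: list[np.ndarray]  # each p_b x A
    block_scores: list[np.ndarray]  # each n x A
    super_weights: np.ndarray  # B x A
    super_scores: np.ndarray  # n x A
    y_weights: np.ndarray  # R x A
    y_names: list[str]
    ssy: np.ndarray  # A x R
    total_y_ss: np.ndarray  # R,
    block_scale_factors: list[float]
    n_components: int
    n_samples: int

    @property
    def n_blocks(self) -> int:
        return len(self.block_names)

    @property
    def explained_y_fraction(self) -> np.ndarray:
        """Per-response fraction of Y sum of squares explained (R,)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.ssy.sum(axis=0) / self.total_y_ss

    def summary(self) -> dict:
        return {
            "n_components": self.n_components,
            "n_samples": self.n_samples,
            "blocks": {
                name: {"n_variables": p, "scale_factor": f}
                for name, p, f in zip(
                    self.block_names, self.p_b, self.block_scale_factors
                )
            },
            "super_weights": self.super_weights.tolist(),
            "explained_y_fraction": {
                r: float(v)
                for r, v in zip(self.y_names, self.explained_y_fraction)
            },
            "ssy_per_component": {
                r: self.ssy[:, i].tolist() for i, r in enumerate(self.y_names)
            },
        }


def _coerce_blocks(blocks) -> tuple[list[str], list[list[str]], list[np.ndarray]]:
    names, ids, mats = [], [], []
    for i, blk in enumerate(blocks):
        if isinstance(blk, OmicsBlock):
            names.append(blk.name)
            ids.append(blk.variable_ids)
            mats.append(blk.values)
        else:
            arr = np.asarray(blk, dtype=float)
            names.append(f"block{i}")
            ids.append([f"block{i}_v{j}" for j in range(arr.shape[1])])
            mats.append(arr)
    return names, ids, mats


def _coerce_y(Y) -> tuple[np.ndarray, list[str]]:
    if isinstance(Y, ResponseDesign):
        return Y.data.to_numpy(dtype=float), Y.names
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), list(Y.columns)
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"y{j}" for j in range(arr.shape[1])]


def fit_mbpls(
    blocks,
    Y,
    n_components: int = 3,
    block_scale: bool = True,
    max_iter: int = 1000,
    tol: float = 1e-12,
) -> MBPLSModel:
    """Fit the consensus (super-score) multi-block PLS model.

    Parameters
    ----------
    blocks:
        Autoscaled :class:`OmicsBlock` objects (or raw samples x
        variables arrays) sharing the same samples in the same order.
    Y:
        Autoscaled response matrix (``ResponseDesign``, DataFrame or
        array).
    n_components:
        Number of latent components A.
    block_scale:
        Divide each block by sqrt(p_b) before fitting so large blocks
        do not overshadow small ones at the super level (standard
        multi-block practice).  Weight normalization makes VIPs
        invariant to this factor.
    """
    if not blocks:
        raise ValidationError("at least one block required")
    names, var_ids, mats = _coerce_blocks(blocks)
    if all(isinstance(b, OmicsBlock) for b in blocks):
        check_aligned(blocks)
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise AlignmentError("blocks have differing sample counts")
    Ymat, y_names = _coerce_y(Y)
    if Ymat.shape[0] != n:
        raise AlignmentError("Y sample count differs from blocks")
    if n_components < 1:
        raise SizingError("n_components must be >= 1")

    factors = [np.sqrt(m.shape[1]) if block_scale else 1.0 for m in mats]
    Xres = [m / f for m, f in zip(mats, factors)]
    Yres = Ymat.copy()
    total_y_ss = (Ymat**2).sum(axis=0)

    B = len(Xres)
    p_b = [m.shape[1] for m in mats]
    W = [np.zeros((p, n_components)) for p in p_b]
    Tb = [np.zeros((n, n_components)) for _ in range(B)]
    Ws = np.zeros((B, n_components))
    Tsup = np.zeros((n, n_components))
    Q = np.zeros((Ymat.shape[1], n_components))
    ssy = np.zeros((n_components, Ymat.shape[1]))
    x_ss0 = sum(float((m**2).sum()) for m in Xres)

    for a in range(n_components):
        y_col_ss = (Yres**2).sum(axis=0)
        x_ss = sum(float((m**2).sum()) for m in Xres)
        if y_col_ss.max() <= 1e-12 * max(total_y_ss.max(), 1.0) or (
            x_ss <= 1e-12 * max(x_ss0, 1.0)
        ):
            raise SizingError(
                f"n_components={n_components} exceeds the informative rank "
                f"(residual exhausted at component {a + 1})"
            )
        u = Yres[:, int(np.argmax(y_col_ss))].copy()
        wbs = [np.zeros(p) for p in p_b]
        tbs = [np.zeros(n) for _ in range(B)]
        ws = np.zeros(B)
        tT = np.zeros(n)
        q = np.zeros(Ymat.shape[1])
        for _ in range(max_iter):
            for b in range(B):
                wb = Xres[b].T @ u
                nw = np.linalg.norm(wb)
                if nw <= _EPS:
                    raise SizingError(
                        f"block '{names[b]}' residual orthogonal to Y at "
                        f"component {a + 1}; reduce n_components"
                    )
                wbs[b] = wb / nw
                tbs[b] = Xres[b] @ wbs[b]
            Tmat = np.column_stack(tbs)
            ws = Tmat.T @ u
            ws /= np.linalg.norm(ws)
            tT = Tmat @ ws
            q = Yres.T @ tT / float(tT @ tT)
            u_new = Yres @ q / float(q @ q)
            if np.linalg.norm(u_new - u) <= tol * max(np.linalg.norm(u_new), _EPS):
                u = u_new
                break
            u = u_new
        # deterministic sign: largest-|q| response weight positive
        j = int(np.argmax(np.abs(q)))
        if q[j] < 0:
            wbs = [-w for w in wbs]
            tbs = [-t for t in tbs]
            tT = -tT
            q = -q
        tt = float(tT @ tT)
        for b in range(B):
            W[b][:, a] = wbs[b]
            Tb[b][:, a] = tbs[b]
            pb = Xres[b].T @ tT / tt
            Xres[b] = Xres[b] - np.outer(tT, pb)
        Ws[:, a] = ws
        Tsup[:, a] = tT
        Q[:, a] = q
        Yres = Yres - np.outer(tT, q)
        ssy[a] = tt * q**2

    # deflation guarantees mutually orthogonal super scores
    gram = Tsup.T @ Tsup
    off = np.abs(gram - np.diag(np.diag(gram))).max() if n_components > 1 else 0.0
    if off > 1e-8 * max(np.diag(gram).max(), 1.0):
        raise RuntimeError("super scores lost orthogonality; ill-conditioned fit")

    return MBPLSModel(
        block_names=names,
        variable_ids=var_ids,
        p_b=p_b,
        block_weights=W,
        block_scores=Tb,
        super_weights=Ws,
        super_scores=Tsup,
        y_weights=Q,
        y_names=y_names,
        ssy=ssy,
        total_y_ss=total_y_ss,
        block_scale_factors=factors,
        n_components=n_components,
        n_samples=n,
    )


# --------------------------------------------------------------------------
# VIP
# --------------------------------------------------------------------------

def compute_vip(model: MBPLSModel, response: str) -> pd.DataFrame:
    """Per-variable VIP scores with respect to one response.

    Returns a table with columns ``variable``, ``block``, ``raw_vip``
    (Wold VIP, block-normalized: sum of squares = p_b per block) and
    ``vip`` (block-rescaled: equal block totals, grand mean exactly 1).
    """
    if response not in model.y_names:
        raise ValidationError(
            f"response '{response}' not in model responses {model.y_names}"
        )
    r = model.y_names.index(response)
    ssy_r = model.ssy[:, r]
    tot = float(ssy_r.sum())
    if tot <= 0:
        raise ValidationError(
            f"model explains no variance of response '{response}'"
        )
    P_total = sum(model.p_b)
    B = model.n_blocks
    frames = []
    for b in range(B):
        w = model.block_weights[b]  # p_b x A, unit columns
        raw = np.sqrt(model.p_b[b] * (w**2 @ ssy_r) / tot)
        scale = (P_total / B) / float(raw.sum())
        frames.append(
            pd.DataFrame(
                {
                    "variable": model.variable_ids[b],
                    "block": model.block_names[b],
                    "raw_vip": raw,
                    "vip": raw * scale,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.attrs["response"] = response
    return table


def select_vips(vip: pd.DataFrame, p: float = 0.33) -> pd.DataFrame:
    """Flag high-VIP variables per block: VIP > mu + z_p * sigma.

    ``z_p`` is the upper-p quantile of the standard normal (a t with
    infinite degrees of freedom); mu and sigma (n-1 denominator) are
    computed within each block on the block-rescaled VIPs.
    """
    if not 0.0 < p <= 0.5:
        raise ValidationError("p must be in (0, 0.5]")
    z = float(stats.norm.ppf(1.0 - p))
    out = vip.copy()
    out["selected"] = False
    out["threshold"] = np.nan
    for block, grp in out.groupby("block", sort=False):
        if len(grp) < 2:
            warnings.warn(
                f"block '{block}' has a single variable; sigma undefined, "
                "nothing selected",
                stacklevel=2,
            )
            continue
        mu = float(grp["vip"].mean())
        sd = float(grp["vip"].std(ddof=1))
        thr = mu + z * sd
        out.loc[grp.index, "threshold"] = thr
        out.loc[grp.index, "selected"] = grp["vip"] > thr
    out.attrs.update(vip.attrs)
    out.attrs["p"] = p
    out.attrs["z"] = z
    return out


def _pearson_with(y: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r of each column of M against y (vectorized)."""
    yc = y - y.mean()
    Mc = M - M.mean(axis=0)
    denom = np.sqrt((yc**2).sum() * (Mc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Mc.T @ yc / denom, 0.0)
    return r


def assign_signs(
    vip: pd.DataFrame, blocks, response_values: np.ndarray
) -> pd.DataFrame:
    """Attach the sign of each selected variable's Pearson correlation
    with the response; zero correlation falls to '+' by convention."""
    y = np.asarray(response_values, dtype=float)
    if np.allclose(y, y[0]):
        raise ValidationError("response is constant; sign undefined")
    lookup: dict[tuple[str, str], float] = {}
    for blk in blocks:
        r = _pearson_with(y, blk.values)
        for var, rv in zip(blk.variable_ids, r):
            lookup[(blk.name, var)] = float(rv)
    out = vip.copy()
    signs = []
    for _, row in out.iterrows():
        if not row.get("selected", False):
            signs.append("")
            continue
        rv = lookup.get((row["block"], row["variable"]))
        if rv is None:
            raise ValidationError(
                f"selected variable '{row['variable']}' not found in data blocks"
            )
        if rv == 0.0:
            logger.info(
                "variable %s has zero correlation with response; "
                "assigned positive by convention",
                row["variable"],
            )
        signs.append("+" if rv >= 0 else "-")
    out["sign"] = signs
    out.attrs.update(vip.attrs)
    return out


def split_by_sign(
    vip: pd.DataFrame, blocks, response_values: np.ndarray
) -> tuple[list[str], list[str]]:
    """Partition the selected variables by correlation sign with the
    response; returns (positive ids, negative ids)."""
    signed = assign_signs(vip, blocks, response_values)
    sel = signed[signed["selected"]]
    if sel.empty:
        raise ValidationError("no variables selected; nothing to split")
    pos = list(sel.loc[sel["sign"] == "+", "variable"])
    neg = list(sel.loc[sel["sign"] == "-", "variable"])
    return pos, neg
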