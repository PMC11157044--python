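"""Construction of the spatial three-layer FCN and its temporal stack.

Per sliding window the spatial network has three layers:

1. a hypergraph over the M GM MRSNs, encoded by a binary incidence matrix
   ``H`` (M x M, rows = MRSN nodes, columns = hyperedges, one hyperedge
   centered on each MRSN) estimated by L1-regularized (Lasso) regression
   of each MRSN's representative signal on all others;
2. a binary within-MRSN adjacency ``A1`` (N_GM x N_GM, block diagonal in
   MRSN blocks) from thresholded Pearson correlations;
3. a binary WM-GM bipartite adjacency ``A2`` (N_WM x N_GM), likewise
   thresholded.

The binarization threshold is adaptive: mean plus one standard deviation
of the functional-connectivity strengths of the matrix being thresholded
(per MRSN block for A1, the whole WM x GM matrix for A2), keeping only
connections stronger than typical for that matrix.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .parcellation import Parcellation
from .timeseries import RoiTimeSeries, WindowSpec, mrsn_series, sliding_windows

__all__ = [
    "SpatialMultilayerFCN",
    "TemporalMultilayerFCN",
    "threshold_adjacency",
    "lasso_hyperedges",
    "build_spatial_fcn",
    "build_temporal_fcn",
    "save_network_archive",
    "load_network_archive",
]

log = logging.getLogger(__name__)

#: Default Lasso regularization strength on standardized MRSN signals.
DEFAULT_LAM = 0.1


@dataclass
class SpatialMultilayerFCN:
    """Three-layer spatial network for one time window."""

    H: np.ndarray          # (M, M) binary incidence, H[i, i] = 0
    A1: np.ndarray         # (N_GM, N_GM) binary, symmetric, block diagonal
    A2: np.ndarray         # (N_WM, N_GM) binary bipartite
    window_index: int = 0
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        H, A1, A2 = (np.asarray(x, dtype=np.uint8) for x in (self.H, self.A1, self.A2))
        if np.any(np.diag(H)):
            raise ValueError("H must have a zero diagonal (no self-membership)")
        if not np.array_equal(A1, A1.T) or np.any(np.diag(A1)):
            raise ValueError("A1 must be symmetric with a zero diagonal")
        self.H, self.A1, self.A2 = H, A1, A2


@dataclass
class TemporalMultilayerFCN:
    """Ordered stack of spatial networks over the sliding windows."""

    layers: list[SpatialMultilayerFCN]
    window_spec: WindowSpec
    parcellation: Parcellation

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("temporal network needs at least 2 layers")
        shapes = {(l.H.shape, l.A1.shape, l.A2.shape) for l in self.layers}
        if len(shapes) != 1:
            raise ValueError("all layers must share matrix shapes")

    @property
    def n_windows(self) -> int:
        return len(self.layers)


def threshold_adjacency(
    corr: np.ndarray,
    symmetric: bool | None = None,
    return_threshold: bool = False,
) -> np.ndarray | tuple[np.ndarray, float]:
    """Binarize a correlation matrix at its mean-plus-one-SD threshold.

    The threshold is computed from the relevant functional-connectivity
    strengths of *this* matrix: the off-diagonal upper-triangle values for
    a square symmetric matrix, all entries for a rectangular (bipartite)
    one.  Entries strictly greater than the threshold become 1.  The SD is
    the sample standard deviation; with a single value, or all values
    identical, nothing can exceed mean + SD and the result is all zeros.
    """
    corr = np.asarray(corr, dtype=float)
    if symmetric is None:
        symmetric = corr.ndim == 2 and corr.shape[0] == corr.shape[1]
    if symmetric:
        iu = np.triu_indices(corr.shape[0], k=1)
        vals = corr[iu]
    else:
        vals = corr.ravel()
    if vals.size == 0:
        empty = np.zeros_like(corr, dtype=np.uint8)
        return (empty, float("nan")) if return_threshold else empty
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    theta = vals.mean() + sd
    if sd == 0.0:
        warnings.warn(
            "degenerate correlation matrix (zero spread); adjacency is empty",
            stacklevel=2,
        )
    out = (corr > theta).astype(np.uint8)
    if symmetric:
        np.fill_diagonal(out, 0)
        out = np.maximum(out, out.T)  # symmetric by construction; keep exact
    if return_threshold:
        return out, float(theta)
    return out


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize (zero mean, unit population SD); flag dead columns."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd < 1e-12
    sd_safe = np.where(dead, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, dead] = 0.0
    return Z, dead


def lasso_hyperedges(mrsn_ts: np.ndarray, lam: float = DEFAULT_LAM) -> np.ndarray:
    """Estimate the hypergraph incidence matrix by sparse regression.

    For each central MRSN ``i`` the standardized signal ``X_i`` is
    regressed on the standardized signals of all other MRSNs with an L1
    penalty (objective ``(1/2w)||X_i - B_i a||^2 + lam * ||a||_1``, the
    per-sample-normalized Lasso).  MRSN ``j`` joins hyperedge ``e_i`` iff
    its coefficient is strictly positive; the central node itself is never
    a member of its own hyperedge (``H[i, i] = 0``).

    Returns the binary ``(M, M)`` incidence matrix with rows = nodes,
    columns = hyperedges.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    Z, dead = _standardize(mrsn_ts)
    w, M = Z.shape
    if M < 2:
        raise ValueError("need at least 2 MRSN signals")
    if dead.any():
        warnings.warn(
            f"zero-variance MRSN signals at positions {np.flatnonzero(dead).tolist()}; "
            "their hyperedges are empty",
            stacklevel=2,
        )
    H = np.zeros((M, M), dtype=np.uint8)
    others = np.arange(M)
    for i in range(M):
        if dead[i]:
            continue
        cols = others[others != i]
        B = Z[:, cols]
        y = Z[:, i]
        model = Lasso(alpha=lam, fit_intercept=False, max_iter=50_000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(B, y)
            except ConvergenceWarning as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"Lasso failed to converge for central MRSN {i}: {exc}"
                ) from exc
        members = cols[model.coef_ > 0.0]
        H[members, i] = 1
    return H


def build_spatial_fcn(
    ts_window: np.ndarray,
    parc: Parcellation,
    lam: float = DEFAULT_LAM,
    window_index: int = 0,
    abs_corr: bool = False,
    mrsn_method: Literal["mean", "pc1"] = "mean",
) -> SpatialMultilayerFCN:
    """Build the three-layer spatial network for one window slice.

    ``ts_window`` is the ``(w, N_roi)`` windowed ROI series.  FC strength
    is the signed Pearson correlation by default; ``abs_corr=True``
    thresholds absolute correlations instead.
    """
    ts_window = np.asarray(ts_window, dtype=float)
    if ts_window.shape[0] < 3:
        raise ValueError("window must contain at least 3 time points")
    if ts_window.shape[1] != parc.n_roi:
        raise ValueError("window column count does not match parcellation")

    # layer 1: hypergraph over MRSN representative signals
    X = mrsn_series(ts_window, parc, method=mrsn_method)
    H = lasso_hyperedges(X, lam)

    thresholds: dict[str, float] = {}
    gm = ts_window[:, parc.gm_mask]
    wm = ts_window[:, parc.wm_mask]

    # layer 2: within-MRSN adjacency, thresholded per block
    n_gm = gm.shape[1]
    A1 = np.zeros((n_gm, n_gm), dtype=np.uint8)
    for m in parc.gm_mrsns:
        pos = parc.gm_block_slices()[m.mrsn_id]
        if pos.size < 2:
            continue
        block_corr = _pearson(gm[:, pos])
        if abs_corr:
            block_corr = np.abs(block_corr)
        block, theta = threshold_adjacency(
            block_corr, symmetric=True, return_threshold=True
        )
        A1[np.ix_(pos, pos)] = block
        thresholds[f"A1:{m.name}"] = theta
    # layer 3: WM-GM bipartite adjacency, one threshold for the whole matrix
    cross = _cross_corr(wm, gm)
    if abs_corr:
        cross = np.abs(cross)
    A2, theta2 = threshold_adjacency(cross, symmetric=False, return_threshold=True)
    thresholds["A2"] = theta2

    return SpatialMultilayerFCN(H, A1, A2, window_index, thresholds)


def _pearson(X: np.ndarray) -> np.ndarray:
    """Pearson correlations among columns; zero-variance columns give 0."""
    Z, dead = _standardize(X)
    C = Z.T @ Z / X.shape[0]
    C[dead, :] = 0.0
    C[:, dead] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def _cross_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of A (rows) and B (columns)."""
    Za, dead_a = _standardize(A)
    Zb, dead_b = _standardize(B)
    C = Za.T @ Zb / A.shape[0]
    C[dead_a, :] = 0.0
    C[:, dead_b] = 0.0
    return np.clip(C, -1.0, 1.0)


def build_temporal_fcn(
    ts: RoiTimeSeries,
    parc: Parcellation,
    spec: WindowSpec,
    lam: float = DEFAULT_LAM,
    abs_corr: bool = False,
    mrsn_method: Literal["mean", "pc1"] = "mean",
) -> TemporalMultilayerFCN:
    """Stack spatial networks over all sliding windows of the series."""
    ranges = sliding_windows(ts.n_timepoints, spec)
    layers = [
        build_spatial_fcn(
            ts.data[a:b], parc, lam, window_index=t,
            abs_corr=abs_corr, mrsn_method=mrsn_method,
        )
        for t, (a, b) in enumerate(ranges)
    ]
    return TemporalMultilayerFCN(layers, spec, parc)


# ---------------------------------------------------------------------------
# Archive IO: sparse triplet TSVs + JSON manifest
# ---------------------------------------------------------------------------

def _to_triplets(mat: np.ndarray, name: str) -> pd.DataFrame:
    r, c = np.nonzero(mat)
    return pd.DataFrame({"matrix": name, "row": r, "col": c})


def save_network_archive(
    tfcn: TemporalMultilayerFCN, outdir: str | Path, **manifest_extra
) -> Path:
    """Write one triplet TSV per window plus a JSON manifest; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer in tfcn.layers:
        frames = [
            _to_triplets(layer.H, "H"),
            _to_triplets(layer.A1, "A1"),
            _to_triplets(layer.A2, "A2"),
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / f"window_{layer.window_index:03d}.tsv", sep="\t", index=False
        )
    first = tfcn.layers[0]
    manifest = {
        "n_windows": tfcn.n_windows,
        "window_W": tfcn.window_spec.W,
        "window_S": tfcn.window_spec.S,
        "shapes": {
            "H": list(first.H.shape),
            "A1": list(first.A1.shape),
            "A2": list(first.A2.shape),
        },
        **manifest_extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_network_archive(
    indir: str | Path, parc: Parcellation
) -> TemporalMultilayerFCN:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    shapes = {k: tuple(v) for k, v in manifest["shapes"].items()}
    layers = []
    for t in range(manifest["n_windows"]):
        df = pd.read_csv(indir / f"window_{t:03d}.tsv", sep="\t")
        mats = {}
        for name in ("H", "A1", "A2"):
            mat = np.zeros(shapes[name], dtype=np.uint8)
            sub = df[df["matrix"] == name]
            mat[sub["row"].to_numpy(), sub["col"].to_numpy()] = 1
            mats[name] = mat
        layers.append(SpatialMultilayerFCN(mats["H"], mats["A1"], mats["A2"], t))
    spec = WindowSpec(manifest["window_W"], manifest["window_S"])
    return TemporalMultilayerFCN(layers, spec, parc)
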