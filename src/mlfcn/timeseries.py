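"""ROI time-series IO, sliding windows, and MRSN representative signals.

Time series enter as an ``L x N_roi`` real matrix (one column per ROI, in
parcellation order), either from delimited text or extracted from a 4D
NIfTI volume with integer label atlases.  Sliding windows of length ``W``
and stride ``S`` partition the series into ``T = (L - W) // S + 1``
overlapping temporal segments; each segment yields one spatial network
layer downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .parcellation import Parcellation

__all__ = [
    "RoiTimeSeries",
    "WindowSpec",
    "load_timeseries",
    "extract_timeseries",
    "sliding_windows",
    "mrsn_series",
]

log = logging.getLogger(__name__)


@dataclass
class RoiTimeSeries:
    """BOLD time series for one subject/session.

    ``data`` is ``(L, N_roi)`` float64 with columns in parcellation ROI
    order; ``zero_variance`` flags columns with (numerically) no signal.
    """

    data: np.ndarray
    subject_id: str = ""
    session_id: str = ""
    tr_seconds: float = 1.0
    zero_variance: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D (time x ROI) matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        self.zero_variance = self.data.std(axis=0) < 1e-12
        if self.zero_variance.any():
            cols = np.flatnonzero(self.zero_variance) + 1
            warnings.warn(
                f"zero-variance ROI columns (1-based): {cols.tolist()}",
                stacklevel=2,
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: window length ``W``, stride ``S`` (in TR)."""

    W: int
    S: int

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("stride S must be >= 1")
        if self.W < self.S:
            raise ValueError("window length W must be >= stride S")

    def n_windows(self, L: int) -> int:
        """T = (L - W) // S + 1 for a series of length L."""
        if self.W > L:
            raise ValueError(f"window W={self.W} exceeds series length L={L}")
        return (L - self.W) // self.S + 1


def load_timeseries(
    path: str | Path,
    parc: Parcellation,
    subject_id: str = "",
    session_id: str = "",
    tr_seconds: float = 1.0,
) -> RoiTimeSeries:
    """Read an ``L x N_roi`` delimited-text matrix (TSV/CSV, optional header).

    The column count must equal the parcellation's ROI count and columns
    must follow parcellation order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    # tolerate a single header row of column names
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = df.iloc[1:].reset_index(drop=True)
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if data.shape[1] != parc.n_roi:
        raise ValueError(
            f"{path}: expected {parc.n_roi} ROI columns, found {data.shape[1]}"
        )
    sid = subject_id or path.stem
    return RoiTimeSeries(data, sid, session_id, tr_seconds)


def extract_timeseries(
    bold_path: str | Path,
    atlas_paths: list[str | Path],
    label_maps: list[Mapping[int, int]],
    parc: Parcellation,
    subject_id: str = "",
    session_id: str = "",
) -> RoiTimeSeries:
    """Extract ROI means from a 4D NIfTI volume using integer label atlases.

    Each atlas (e.g. one GM, one WM) is a 3-D integer volume on the same
    voxel grid as the BOLD data; its ``label_map`` sends atlas labels to
    1-based ROI indices.  The ROI signal is the unweighted mean over the
    labeled voxels at each time point.  Every ROI of the parcellation must
    be covered by exactly one atlas label.
    """
    import nibabel as nib

    img = nib.load(str(bold_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("BOLD volume must be 4-D (x, y, z, time)")
    L = data.shape[3]
    flat = data.reshape(-1, L)
    out = np.full((L, parc.n_roi), np.nan)
    covered: set[int] = set()
    for atlas_path, label_map in zip(atlas_paths, label_maps):
        atlas = np.asanyarray(nib.load(str(atlas_path)).dataobj).astype(int)
        if atlas.shape != data.shape[:3]:
            raise ValueError(
                f"atlas {atlas_path} grid {atlas.shape} does not match "
                f"BOLD grid {data.shape[:3]}"
            )
        aflat = atlas.reshape(-1)
        for label, roi_index in label_map.items():
            if roi_index in covered:
                raise ValueError(f"ROI {roi_index} labeled by multiple atlases")
            mask = aflat == label
            if not mask.any():
                raise ValueError(f"label {label} absent from atlas {atlas_path}")
            out[:, roi_index - 1] = flat[mask].mean(axis=0)
            covered.add(roi_index)
    missing = set(range(1, parc.n_roi + 1)) - covered
    if missing:
        raise ValueError(f"ROIs without atlas labels: {sorted(missing)}")
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return RoiTimeSeries(out, subject_id, session_id, tr)


def sliding_windows(L: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open ``[start, end)`` index ranges of the sliding windows.

    Window ``t`` (0-based) covers ``[t*S, t*S + W)``; consecutive windows
    overlap by ``W - S`` points.  When ``L - W`` is not divisible by ``S``
    the trailing points are dropped (with a warning); the standard
    parameter sets divide evenly.
    """
    T = spec.n_windows(L)
    last_end = (T - 1) * spec.S + spec.W
    if last_end < L:
        warnings.warn(
            f"{L - last_end} trailing time points not covered by any window",
            stacklevel=2,
        )
    return [(t * spec.S, t * spec.S + spec.W) for t in range(T)]


def mrsn_series(
    window_data: np.ndarray,
    parc: Parcellation,
    method: Literal["mean", "pc1"] = "mean",
) -> np.ndarray:
    """MRSN-level representative signals for a (windowed) GM series.

    ``window_data`` is ``(w, N_roi)`` (full ROI set, parcellation order).
    Returns ``(w, M)`` with one column per GM MRSN, in hypergraph node
    order.  ``method="mean"`` takes the unweighted mean over member ROI
    columns; ``"pc1"`` projects members onto their first principal
    component (sign-fixed to correlate positively with the member mean).
    """
    window_data = np.asarray(window_data, dtype=float)
    if window_data.ndim != 2 or window_data.shape[0] == 0:
        raise ValueError("window slice must be a nonempty 2-D matrix")
    M = parc.n_mrsn_gm
    out = np.empty((window_data.shape[0], M))
    for m in parc.gm_mrsns:
        cols = np.array(m.member_roi_indices) - 1
        block = window_data[:, cols]
        k = parc.mrsn_pos[m.mrsn_id]
        if method == "mean" or block.shape[1] == 1:
            out[:, k] = block.mean(axis=1)
        elif method == "pc1":
            centered = block - block.mean(axis=0)
            u, s, vt = np.linalg.svd(centered, full_matrices=False)
            pc = u[:, 0] * s[0]
            ref = block.mean(axis=1)
            if np.dot(pc - pc.mean(), ref - ref.mean()) < 0:
                pc = -pc
            out[:, k] = pc + block.mean()
        else:
            raise ValueError(f"unknown MRSN series method {method!r}")
    return out
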