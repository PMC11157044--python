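"""Shared fixtures: parcellations and random small network instances."""

from __future__ import annotations

import numpy as np
import pytest

from mlfcn import (
    CoreAssignment,
    SpatialMultilayerFCN,
    TemporalMultilayerFCN,
    WindowSpec,
    default_parcellation,
    toy_parcellation,
)
from mlfcn.parcellation import Parcellation, Roi


@pytest.fixture(scope="session")
def default_parc():
    return default_parcellation()


@pytest.fixture(scope="session")
def toy_parc():
    return toy_parcellation()


def random_parcellation(rng: np.random.Generator) -> Parcellation:
    """Random small parcellation: <= 3 GM MRSNs, <= 8 ROIs total.

    Guarantees at least 2 MRSNs (joint functionality needs another
    network) and at least one GM ROI per MRSN.
    """
    n_mrsn = int(rng.integers(2, 4))
    sizes = [int(rng.integers(1, 3)) for _ in range(n_mrsn)]
    n_wm = int(rng.integers(0, max(1, 9 - sum(sizes))))
    rois = []
    idx = 1
    for mid in range(1, n_mrsn + 1):
        for k in range(sizes[mid - 1]):
            rois.append(Roi(idx, f"G{idx}", "GM", mid))
            idx += 1
    for _ in range(n_wm):
        rois.append(Roi(idx, f"W{idx}", "WM", 0))
        idx += 1
    return Parcellation(tuple(rois))


def random_spatial_fcn(
    rng: np.random.Generator, parc: Parcellation, window_index: int = 0,
    density: float = 0.4,
) -> SpatialMultilayerFCN:
    """Random binary three-layer network respecting all structural invariants."""
    M, n_gm, n_wm = parc.n_mrsn_gm, parc.n_gm, parc.n_wm
    H = (rng.random((M, M)) < density).astype(np.uint8)
    np.fill_diagonal(H, 0)
    A1 = np.zeros((n_gm, n_gm), dtype=np.uint8)
    for pos in parc.gm_block_slices().values():
        b = (rng.random((pos.size, pos.size)) < density).astype(np.uint8)
        b = np.triu(b, 1)
        b = b + b.T
        A1[np.ix_(pos, pos)] = b
    A2 = (rng.random((n_wm, n_gm)) < density).astype(np.uint8)
    return SpatialMultilayerFCN(H, A1, A2, window_index)


def random_temporal_fcn(
    rng: np.random.Generator, parc: Parcellation, T: int
) -> TemporalMultilayerFCN:
    layers = [random_spatial_fcn(rng, parc, t) for t in range(T)]
    return TemporalMultilayerFCN(layers, WindowSpec(10, 5), parc)


def random_core_assignment(
    rng: np.random.Generator, n_roi: int, T: int, n_core: int
) -> CoreAssignment:
    R = np.zeros((n_roi, T), dtype=np.uint8)
    for t in range(T):
        R[rng.choice(n_roi, size=n_core, replace=False), t] = 1
    return CoreAssignment(R, n_core)


def parc_lookup_tables(parc: Parcellation):
    """0-based lookup tables in the form the brute-force oracle expects."""
    tissue = [r.tissue for r in parc.rois]
    mrsn_of_roi = [r.mrsn_id for r in parc.rois]
    gm_order = {r.index - 1: k for k, r in enumerate(
        [x for x in parc.rois if x.tissue == "GM"])}
    wm_order = {r.index - 1: k for k, r in enumerate(
        [x for x in parc.rois if x.tissue == "WM"])}
    mrsn_sizes = {m.mrsn_id: m.size for m in parc.mrsns}
    return tissue, mrsn_of_roi, parc.mrsn_pos, gm_order, wm_order, mrsn_sizes
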