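"""Dynamic rich-club organization of the temporal multilayer network.

Per temporal layer, every ROI gets a multilayer degree — the sum of its
degrees in the hypergraph, within-MRSN, and WM-GM layers — normalized by
its theoretical maximum, and the top ``n_core`` ROIs (default 15, one per
MRSN of the default layout) form the rich-club core; the rest are
peripheral.  Four metrics summarize the core's dynamics per node:

* temporal centrality (TC): fraction of layers in which the node is core;
* temporal stability (TS): persistence of the node's core/peripheral
  identity between consecutive layers.  The ``"prose"`` reading scores a
  never-switching node 1; the ``"literal"`` reading is its complement
  (1 - prose), scoring frequent switchers high;
* local functionality (LF): normalized frequency of sharing core-node
  neighbors with nodes of the node's own MRSN;
* joint functionality (JF): the same with nodes of all other MRSNs.

LF and JF rest on the pairwise shared-core matrix ``P``: per layer,
``beta_ij`` counts the core nodes to which peripheral nodes i and j are
both connected, and ``P = sum_t beta / (T * n_R)``.  "Connected" is
evaluated on a per-layer union graph over all ROIs that combines the
three layers (see :func:`union_graph`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .construction import SpatialMultilayerFCN, TemporalMultilayerFCN
from .parcellation import WM_MRSN_ID, Parcellation, max_degrees

__all__ = [
    "CoreAssignment",
    "RichClubMetrics",
    "multilayer_degrees",
    "normalized_degree",
    "select_core",
    "core_assignment",
    "temporal_centrality",
    "temporal_stability",
    "union_graph",
    "shared_core_matrix",
    "local_functionality",
    "joint_functionality",
    "aggregate",
    "compute_metrics",
]

log = logging.getLogger(__name__)

DEFAULT_N_CORE = 15


@dataclass
class CoreAssignment:
    """Binary core membership R (N_roi x T): R[i, t] = 1 iff ROI i is core
    at layer t.  Every column has exactly ``n_core`` ones."""

    R: np.ndarray
    n_core: int = DEFAULT_N_CORE

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.uint8)
        if self.R.ndim != 2:
            raise ValueError("R must be 2-D (ROI x time layer)")
        if not np.all(self.R.sum(axis=0) == self.n_core):
            raise ValueError("every layer must have exactly n_core core nodes")

    @property
    def n_layers(self) -> int:
        return self.R.shape[1]


@dataclass
class RichClubMetrics:
    """Per-node rich-club metric vectors plus the shared-core matrix."""

    tc: np.ndarray
    ts_literal: np.ndarray
    ts_prose: np.ndarray
    lf: np.ndarray
    jf: np.ndarray
    P: np.ndarray
    core: CoreAssignment

    def to_frame(self, parc: Parcellation) -> pd.DataFrame:
        names = {m.mrsn_id: m.name for m in parc.mrsns}
        return pd.DataFrame(
            {
                "roi_index": [r.index for r in parc.rois],
                "label": [r.label for r in parc.rois],
                "tissue": [r.tissue for r in parc.rois],
                "mrsn": [names[r.mrsn_id] for r in parc.rois],
                "tc": self.tc,
                "ts_literal": self.ts_literal,
                "ts_prose": self.ts_prose,
                "lf": self.lf,
                "jf": self.jf,
            }
        )


# ---------------------------------------------------------------------------
# Degrees and core selection
# ---------------------------------------------------------------------------

def multilayer_degrees(
    net: SpatialMultilayerFCN, parc: Parcellation
) -> np.ndarray:
    """Per-ROI degree triple (D1, D2, D3) in one spatial network.

    A GM ROI inherits its layer-1 degree from its MRSN (the number of
    hyperedges the MRSN belongs to); its layer-2 degree is its within-MRSN
    adjacency row sum, and its layer-3 degree the number of WM ROIs it
    connects to.  A WM ROI participates only in layer 3, with degree equal
    to the number of GM ROIs it connects to.
    """
    n = parc.n_roi
    out = np.zeros((n, 3), dtype=int)
    hyper_deg = net.H.sum(axis=1)  # hyperedge-membership count per MRSN
    a1_deg = net.A1.sum(axis=1)
    gm_from_wm = net.A2.sum(axis=0)  # per GM ROI
    wm_from_gm = net.A2.sum(axis=1)  # per WM ROI
    gm_positions = {idx: k for k, idx in enumerate(parc.gm_roi_indices)}
    wm_positions = {idx: k for k, idx in enumerate(parc.wm_roi_indices)}
    for r in parc.rois:
        i = r.index - 1
        if r.tissue == "GM":
            k = gm_positions[r.index]
            out[i, 0] = hyper_deg[parc.mrsn_pos[r.mrsn_id]]
            out[i, 1] = a1_deg[k]
            out[i, 2] = gm_from_wm[k]
        else:
            out[i, 2] = wm_from_gm[wm_positions[r.index]]
    return out


def normalized_degree(degrees: np.ndarray, dmax: np.ndarray) -> np.ndarray:
    """Normalized multilayer degree: layer-summed degree over its maximum."""
    degrees = np.asarray(degrees)
    dmax = np.asarray(dmax)
    denom = dmax.sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError(
            "degenerate parcellation: some ROI has zero theoretical maximum degree"
        )
    return degrees.sum(axis=1) / denom


def select_core(norm_deg: np.ndarray, n_core: int = DEFAULT_N_CORE) -> np.ndarray:
    """Binary top-``n_core`` indicator over ROIs, ranked by normalized degree.

    Ties at the cutoff are broken by ascending ROI index, making the
    selection deterministic and reportable.
    """
    norm_deg = np.asarray(norm_deg, dtype=float)
    n = norm_deg.size
    if n_core > n:
        raise ValueError("n_core exceeds the number of ROIs")
    # primary key: descending degree; secondary: ascending ROI index
    order = np.lexsort((np.arange(n), -norm_deg))
    out = np.zeros(n, dtype=np.uint8)
    out[order[:n_core]] = 1
    return out


def core_assignment(
    tfcn: TemporalMultilayerFCN,
    parc: Parcellation,
    n_core: int = DEFAULT_N_CORE,
) -> CoreAssignment:
    """Select the rich-club core independently in every temporal layer."""
    dmax = max_degrees(parc)
    cols = []
    for layer in tfcn.layers:
        deg = multilayer_degrees(layer, parc)
        cols.append(select_core(normalized_degree(deg, dmax), n_core))
    return CoreAssignment(np.column_stack(cols), n_core)


# ---------------------------------------------------------------------------
# Temporal metrics
# ---------------------------------------------------------------------------

def temporal_centrality(core: CoreAssignment) -> np.ndarray:
    """Fraction of temporal layers in which each node is core."""
    return core.R.mean(axis=1)


def temporal_stability(
    core: CoreAssignment, interpretation: Literal["prose", "literal"] = "prose"
) -> np.ndarray:
    """Persistence of core/peripheral identity across consecutive layers.

    Over the ``T - 1`` consecutive layer pairs, the identity-consistency
    indicator is 1 when the node keeps its core/peripheral status.  The
    ``"literal"`` reading returns one minus the mean consistency (0 for a
    node that never switches); the default ``"prose"`` reading returns the
    mean consistency itself (1 for a node that never switches), matching
    the intent of a *stability* measure.  The two always sum to 1.
    """
    R = core.R
    if R.shape[1] < 2:
        raise ValueError("temporal stability needs at least 2 layers")
    consistent = (R[:, :-1] == R[:, 1:]).mean(axis=1)
    if interpretation == "prose":
        return consistent
    if interpretation == "literal":
        return 1.0 - consistent
    raise ValueError(f"unknown interpretation {interpretation!r}")


# ---------------------------------------------------------------------------
# Shared-core matrix and functionalities
# ---------------------------------------------------------------------------

def union_graph(
    layer: SpatialMultilayerFCN,
    parc: Parcellation,
    policy: Literal["union", "adjacency_only"] = "union",
) -> np.ndarray:
    """Per-layer connectivity over all ROIs, combining the three layers.

    Edges (symmetric, zero diagonal):

    * GM-GM, same MRSN: the within-MRSN adjacency A1;
    * GM-GM, different MRSNs (``policy="union"`` only): present when the
      two MRSNs co-occur in at least one hyperedge — the clique expansion
      of the hypergraph at MRSN level, each hyperedge's node set taken as
      its members plus its central MRSN;
    * WM-GM: the bipartite adjacency A2;
    * WM-WM: never (no layer relates WM regions to each other).

    ``policy="adjacency_only"`` drops the hypergraph-derived edges.
    """
    n = parc.n_roi
    U = np.zeros((n, n), dtype=bool)
    gm_idx = parc.gm_roi_indices - 1
    wm_idx = parc.wm_roi_indices - 1
    U[np.ix_(gm_idx, gm_idx)] = layer.A1.astype(bool)
    U[np.ix_(wm_idx, gm_idx)] = layer.A2.astype(bool)
    U[np.ix_(gm_idx, wm_idx)] = layer.A2.T.astype(bool)
    if policy == "union":
        Hc = layer.H.astype(bool).copy()
        np.fill_diagonal(Hc, True)  # central MRSN counts as hyperedge member
        mrsn_conn = Hc @ Hc.T
        np.fill_diagonal(mrsn_conn, False)
        # node-level MRSN membership matrix over GM ROIs
        gm_mrsn_pos = np.array(
            [parc.mrsn_pos[mid] for mid in parc.mrsn_id[parc.gm_mask]]
        )
        cross = mrsn_conn[np.ix_(gm_mrsn_pos, gm_mrsn_pos)]
        # different-MRSN pairs only; same-MRSN connectivity is A1's job
        same = gm_mrsn_pos[:, None] == gm_mrsn_pos[None, :]
        cross = cross & ~same
        U[np.ix_(gm_idx, gm_idx)] |= cross
    elif policy != "adjacency_only":
        raise ValueError(f"unknown connectivity policy {policy!r}")
    np.fill_diagonal(U, False)
    return U


def shared_core_matrix(
    tfcn: TemporalMultilayerFCN,
    core: CoreAssignment,
    parc: Parcellation | None = None,
    policy: Literal["union", "adjacency_only"] = "union",
    sum_mode: Literal["all", "t_minus_1"] = "all",
    core_only_pairs: bool = True,
) -> np.ndarray:
    """Pairwise shared-core-neighbor matrix P (N_roi x N_roi).

    Per layer t, ``beta_ij`` counts core nodes connected (in the layer's
    union graph) to both i and j, provided both are peripheral at t; the
    contribution is 0 otherwise (``core_only_pairs=False`` counts all
    pairs).  ``P = sum_t beta_ij / (T * n_R)``, symmetric with a zero
    diagonal, every entry in [0, 1].  ``sum_mode="t_minus_1"`` drops the
    last layer from the sum while keeping the ``T * n_R`` normalizer.
    """
    parc = parc or tfcn.parcellation
    R = core.R
    T = tfcn.n_windows
    if R.shape[1] != T:
        raise ValueError("core assignment layer count does not match network")
    n = parc.n_roi
    P = np.zeros((n, n))
    layers = tfcn.layers[:-1] if sum_mode == "t_minus_1" else tfcn.layers
    for t, layer in enumerate(layers):
        U = union_graph(layer, parc, policy)
        core_idx = np.flatnonzero(R[:, t])
        Uc = U[:, core_idx].astype(np.int64)
        beta = Uc @ Uc.T
        if core_only_pairs:
            periph = R[:, t] == 0
            beta = beta * periph[:, None] * periph[None, :]
        P += beta
    P /= T * core.n_core
    np.fill_diagonal(P, 0.0)
    return P


def _mrsn_membership_masks(parc: Parcellation) -> dict[int, np.ndarray]:
    return {
        mid: parc.mrsn_id == mid
        for mid in {r.mrsn_id for r in parc.rois}
    }


def local_functionality(P: np.ndarray, parc: Parcellation) -> np.ndarray:
    """LF_i = (1/n_S) * sum of P_ij over same-MRSN peers j != i.

    WM ROIs use the WM MRSN as their network S.  The denominator is the
    full member count n_S (the sum has n_S - 1 terms since j = i is
    excluded by P's zero diagonal).
    """
    masks = _mrsn_membership_masks(parc)
    out = np.zeros(parc.n_roi)
    for r in parc.rois:
        i = r.index - 1
        mask = masks[r.mrsn_id]
        n_s = mask.sum()
        out[i] = P[i, mask].sum() / n_s
    return out


def joint_functionality(P: np.ndarray, parc: Parcellation) -> np.ndarray:
    """JF_i = (1/(N - n_S)) * sum of P_ij over ROIs outside i's MRSN."""
    masks = _mrsn_membership_masks(parc)
    n = parc.n_roi
    out = np.zeros(n)
    for r in parc.rois:
        i = r.index - 1
        mask = masks[r.mrsn_id]
        n_s = mask.sum()
        if n_s == n:
            raise ValueError(
                "joint functionality undefined with a single network"
            )
        out[i] = P[i, ~mask].sum() / (n - n_s)
    return out


# ---------------------------------------------------------------------------
# Aggregation and the full pipeline step
# ---------------------------------------------------------------------------

def aggregate(
    values: np.ndarray,
    parc: Parcellation,
    scale: Literal["roi", "mrsn", "whole_brain"],
    metric_name: str = "metric",
) -> pd.DataFrame:
    """Unweighted means of a per-ROI metric at the requested scale.

    Whole-brain TC is reported like any other aggregate but is constant by
    construction (the core has fixed size, so the ROI-mean of TC is
    n_core / N for every subject); it is flagged in the output so callers
    can exclude it from difference analyses.
    """
    values = np.asarray(values, dtype=float)
    names = {m.mrsn_id: m.name for m in parc.mrsns}
    if scale == "roi":
        return pd.DataFrame(
            {
                "unit": [str(r.index) for r in parc.rois],
                "metric": metric_name,
                "value": values,
            }
        )
    if scale == "mrsn":
        rows = []
        for m in parc.mrsns:
            members = np.array(m.member_roi_indices) - 1
            rows.append(
                {"unit": names[m.mrsn_id], "metric": metric_name,
                 "value": values[members].mean()}
            )
        return pd.DataFrame(rows)
    if scale == "whole_brain":
        df = pd.DataFrame(
            {"unit": ["whole_brain"], "metric": metric_name,
             "value": [values.mean()]}
        )
        if metric_name == "tc":
            df["constant_by_construction"] = True
        return df
    raise ValueError(f"unknown scale {scale!r}")


def compute_metrics(
    tfcn: TemporalMultilayerFCN,
    parc: Parcellation | None = None,
    n_core: int = DEFAULT_N_CORE,
    policy: Literal["union", "adjacency_only"] = "union",
    sum_mode: Literal["all", "t_minus_1"] = "all",
) -> RichClubMetrics:
    """Core selection plus all four rich-club metrics for one subject."""
    parc = parc or tfcn.parcellation
    core = core_assignment(tfcn, parc, n_core)
    P = shared_core_matrix(tfcn, core, parc, policy=policy, sum_mode=sum_mode)
    return RichClubMetrics(
        tc=temporal_centrality(core),
        ts_literal=temporal_stability(core, "literal"),
        ts_prose=temporal_stability(core, "prose"),
        lf=local_functionality(P, parc),
        jf=joint_functionality(P, parc),
        P=P,
        core=core,
    )
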