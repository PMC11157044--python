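"""Multi-scale brain parcellation: ROIs, tissue classes, and macroscale networks.

The node sets of every layer of the multilayer functional connectivity
network (FCN) are defined by a parcellation that assigns each region of
interest (ROI) a tissue class (gray matter, GM, or white matter, WM) and,
for GM ROIs, membership in exactly one macroscale resting-state network
(MRSN).  The default layout has 90 GM ROIs grouped into 14 MRSNs plus 48 WM
tracts treated as a single WM MRSN, i.e. 138 ROIs and 15 MRSNs in total.

The hypergraph layer is built over the 14 GM MRSNs only; the WM MRSN is
represented by the reserved id :data:`WM_MRSN_ID` and excluded from the
hypergraph node set.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WM_MRSN_ID",
    "WM_MRSN_NAME",
    "Roi",
    "Mrsn",
    "Parcellation",
    "ParcellationError",
    "load_parcellation",
    "write_parcellation",
    "default_parcellation",
    "toy_parcellation",
    "max_degrees",
]

#: Reserved MRSN id for the single white-matter network.
WM_MRSN_ID = 0
WM_MRSN_NAME = "WM"

GM = "GM"
WM = "WM"


class ParcellationError(ValueError):
    """Raised when a parcellation specification violates an invariant."""


@dataclass(frozen=True)
class Roi:
    """A single region of interest.

    Attributes
    ----------
    index:
        1-based ROI index, unique and contiguous across the parcellation.
    label:
        Human-readable region name.
    tissue:
        ``"GM"`` or ``"WM"``.
    mrsn_id:
        Id of the MRSN the ROI belongs to; WM ROIs carry :data:`WM_MRSN_ID`.
    """

    index: int
    label: str
    tissue: str
    mrsn_id: int


@dataclass(frozen=True)
class Mrsn:
    mrsn_id: int
    name: str
    member_roi_indices: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.member_roi_indices)


@dataclass
class Parcellation:
    """Validated multi-scale parcellation.

    Holds the ordered ROI list and the MRSN partition, and exposes the
    derived index arrays used throughout network construction: GM/WM masks,
    the GM-block and WM-block orderings of the adjacency matrices, and the
    hypergraph node order over GM MRSNs.
    """

    rois: tuple[Roi, ...]
    mrsns: tuple[Mrsn, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.mrsns:
            self.mrsns = _mrsns_from_rois(self.rois)
        self._validate()
        idx = np.array([r.index for r in self.rois])
        self.tissue = np.array([r.tissue for r in self.rois])
        self.mrsn_id = np.array([r.mrsn_id for r in self.rois])
        self.gm_mask = self.tissue == GM
        self.wm_mask = self.tissue == WM
        # ROI indices (1-based) in GM-block / WM-block order
        self.gm_roi_indices = idx[self.gm_mask]
        self.wm_roi_indices = idx[self.wm_mask]
        gm_networks = [m for m in self.mrsns if m.mrsn_id != WM_MRSN_ID]
        self.gm_mrsns = tuple(sorted(gm_networks, key=lambda m: m.mrsn_id))
        # hypergraph node position of each GM MRSN id
        self.mrsn_pos = {m.mrsn_id: k for k, m in enumerate(self.gm_mrsns)}

    # -- basic counts -----------------------------------------------------

    @property
    def n_roi(self) -> int:
        return len(self.rois)

    @property
    def n_gm(self) -> int:
        return int(self.gm_mask.sum())

    @property
    def n_wm(self) -> int:
        return int(self.wm_mask.sum())

    @property
    def n_mrsn_gm(self) -> int:
        """Number of GM MRSNs (hypergraph nodes), M."""
        return len(self.gm_mrsns)

    def mrsn_size(self, mrsn_id: int) -> int:
        """Member count n_S of an MRSN (WM id gives the WM tract count)."""
        for m in self.mrsns:
            if m.mrsn_id == mrsn_id:
                return m.size
        raise KeyError(f"unknown MRSN id {mrsn_id}")

    def mrsn_by_name(self, name: str) -> Mrsn:
        for m in self.mrsns:
            if m.name == name:
                return m
        raise KeyError(f"unknown MRSN name {name!r}")

    def roi(self, index: int) -> Roi:
        return self.rois[index - 1]

    # -- derived orderings ------------------------------------------------

    def gm_block_slices(self) -> dict[int, np.ndarray]:
        """Positions (0-based, GM-block order) of each GM MRSN's members."""
        gm_ids = self.mrsn_id[self.gm_mask]
        return {
            m.mrsn_id: np.flatnonzero(gm_ids == m.mrsn_id)
            for m in self.gm_mrsns
        }

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        indices = [r.index for r in self.rois]
        if len(set(indices)) != len(indices):
            raise ParcellationError("duplicate ROI indices")
        if sorted(indices) != list(range(1, len(indices) + 1)):
            raise ParcellationError(
                "ROI indices must be contiguous from 1 to N_roi"
            )
        if list(indices) != sorted(indices):
            raise ParcellationError("ROIs must be listed in index order")
        seen: dict[int, int] = {}
        for m in self.mrsns:
            if m.size < 1:
                raise ParcellationError(f"empty MRSN {m.name!r}")
            for ri in m.member_roi_indices:
                if ri in seen:
                    raise ParcellationError(
                        f"ROI {ri} assigned to more than one MRSN"
                    )
                seen[ri] = m.mrsn_id
        for r in self.rois:
            if r.tissue not in (GM, WM):
                raise ParcellationError(
                    f"ROI {r.index}: tissue must be GM or WM, got {r.tissue!r}"
                )
            if r.tissue == GM and r.mrsn_id == WM_MRSN_ID:
                raise ParcellationError(f"GM ROI {r.index} without an MRSN")
            if r.tissue == WM and r.mrsn_id != WM_MRSN_ID:
                raise ParcellationError(
                    f"WM ROI {r.index} must belong to the WM MRSN"
                )
            if seen.get(r.index) != r.mrsn_id:
                raise ParcellationError(
                    f"ROI {r.index}: MRSN membership inconsistent"
                )


def _mrsns_from_rois(rois: Sequence[Roi]) -> tuple[Mrsn, ...]:
    members: dict[int, list[int]] = {}
    names: dict[int, str] = {}
    for r in rois:
        members.setdefault(r.mrsn_id, []).append(r.index)
        names.setdefault(
            r.mrsn_id,
            WM_MRSN_NAME if r.mrsn_id == WM_MRSN_ID else f"MRSN{r.mrsn_id}",
        )
    return tuple(
        Mrsn(mid, names[mid], tuple(members[mid])) for mid in sorted(members)
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["roi_index", "label", "tissue", "mrsn_name"]


def load_parcellation(spec_path: str | Path) -> Parcellation:
    """Load a parcellation from its TSV specification.

    The file has columns ``roi_index, label, tissue, mrsn_name`` (tab
    separated, header row required).  WM ROIs may leave ``mrsn_name`` blank
    or use ``"WM"``; GM ROIs must name their MRSN.
    """
    spec_path = Path(spec_path)
    if not spec_path.exists():
        raise FileNotFoundError(spec_path)
    df = pd.read_csv(spec_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParcellationError(f"missing columns: {missing}")
    return _parcellation_from_frame(df)


def _parcellation_from_frame(df: pd.DataFrame) -> Parcellation:
    gm_names: list[str] = []
    for _, row in df.iterrows():
        if row["tissue"] == GM and row["mrsn_name"] not in ("", WM_MRSN_NAME):
            if row["mrsn_name"] not in gm_names:
                gm_names.append(row["mrsn_name"])
        elif row["tissue"] == GM:
            raise ParcellationError(
                f"GM ROI {row['roi_index']} without an MRSN name"
            )
    name_to_id = {n: i + 1 for i, n in enumerate(gm_names)}
    rois = []
    for _, row in df.iterrows():
        try:
            index = int(row["roi_index"])
        except ValueError as exc:
            raise ParcellationError(
                f"non-integer roi_index {row['roi_index']!r}"
            ) from exc
        if row["tissue"] == WM:
            mid = WM_MRSN_ID
        else:
            mid = name_to_id[row["mrsn_name"]]
        rois.append(Roi(index, row["label"], row["tissue"], mid))
    id_to_name = {v: k for k, v in name_to_id.items()}
    id_to_name[WM_MRSN_ID] = WM_MRSN_NAME
    mrsns = tuple(
        Mrsn(m.mrsn_id, id_to_name[m.mrsn_id], m.member_roi_indices)
        for m in _mrsns_from_rois(rois)
    )
    return Parcellation(tuple(rois), mrsns)


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    """Write the TSV specification; inverse of :func:`load_parcellation`."""
    names = {m.mrsn_id: m.name for m in parc.mrsns}
    rows = [
        {
            "roi_index": r.index,
            "label": r.label,
            "tissue": r.tissue,
            "mrsn_name": names[r.mrsn_id] if r.tissue == GM else WM_MRSN_NAME,
        }
        for r in parc.rois
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Default and toy layouts
# ---------------------------------------------------------------------------

# 14 GM MRSNs of the Stanford FIND 90-ROI functional atlas with their
# published member counts (90 ROIs total; the auditory network has 3).
_DEFAULT_GM_NETWORKS: tuple[tuple[str, int], ...] = (
    ("ASN", 7),   # anterior salience
    ("PSN", 12),  # posterior salience
    ("AN", 3),    # auditory
    ("BGN", 5),   # basal ganglia
    ("DDMN", 9),  # dorsal default mode
    ("VDMN", 10), # ventral default mode
    ("PVN", 2),   # primary visual
    ("HVN", 2),   # higher visual
    ("LN", 7),    # language
    ("LECN", 6),  # left executive control
    ("RECN", 6),  # right executive control
    ("PN", 4),    # precuneus
    ("SMN", 6),   # sensorimotor
    ("VSN", 11),  # visuospatial
)

# The 48 JHU probabilistic white-matter tract labels.
_JHU_WM_TRACTS: tuple[str, ...] = (
    "Middle cerebellar peduncle",
    "Pontine crossing tract",
    "Genu of corpus callosum",
    "Body of corpus callosum",
    "Splenium of corpus callosum",
    "Fornix (column and body)",
    "Corticospinal tract R",
    "Corticospinal tract L",
    "Medial lemniscus R",
    "Medial lemniscus L",
    "Inferior cerebellar peduncle R",
    "Inferior cerebellar peduncle L",
    "Superior cerebellar peduncle R",
    "Superior cerebellar peduncle L",
    "Cerebral peduncle R",
    "Cerebral peduncle L",
    "Anterior limb of internal capsule R",
    "Anterior limb of internal capsule L",
    "Posterior limb of internal capsule R",
    "Posterior limb of internal capsule L",
    "Retrolenticular part of internal capsule R",
    "Retrolenticular part of internal capsule L",
    "Anterior corona radiata R",
    "Anterior corona radiata L",
    "Superior corona radiata R",
    "Superior corona radiata L",
    "Posterior corona radiata R",
    "Posterior corona radiata L",
    "Posterior thalamic radiation R",
    "Posterior thalamic radiation L",
    "Sagittal stratum R",
    "Sagittal stratum L",
    "External capsule R",
    "External capsule L",
    "Cingulum (cingulate gyrus) R",
    "Cingulum (cingulate gyrus) L",
    "Cingulum (hippocampus) R",
    "Cingulum (hippocampus) L",
    "Fornix (cres) / Stria terminalis R",
    "Fornix (cres) / Stria terminalis L",
    "Superior longitudinal fasciculus R",
    "Superior longitudinal fasciculus L",
    "Superior fronto-occipital fasciculus R",
    "Superior fronto-occipital fasciculus L",
    "Uncinate fasciculus R",
    "Uncinate fasciculus L",
    "Tapetum R",
    "Tapetum L",
)


def default_parcellation() -> Parcellation:
    """The default 138-ROI layout: 90 GM ROIs in 14 MRSNs + 48 WM tracts.

    GM member counts follow the Stanford FIND functional atlas; GM ROI
    labels are generic placeholders (``"AN 1"``), since only the network
    partition — not individual region identity — enters the network
    construction.  Real region names can be supplied via a custom TSV.
    """
    rois: list[Roi] = []
    idx = 1
    for mid, (name, size) in enumerate(_DEFAULT_GM_NETWORKS, start=1):
        for k in range(1, size + 1):
            rois.append(Roi(idx, f"{name} {k}", GM, mid))
            idx += 1
    for tract in _JHU_WM_TRACTS:
        rois.append(Roi(idx, tract, WM, WM_MRSN_ID))
        idx += 1
    names = {mid: name for mid, (name, _) in
             enumerate(_DEFAULT_GM_NETWORKS, start=1)}
    names[WM_MRSN_ID] = WM_MRSN_NAME
    mrsns = tuple(
        Mrsn(m.mrsn_id, names[m.mrsn_id], m.member_roi_indices)
        for m in _mrsns_from_rois(rois)
    )
    return Parcellation(tuple(rois), mrsns)


def toy_parcellation(
    n_mrsn: int = 5, gm_per_mrsn: int = 4, n_wm: int = 6
) -> Parcellation:
    """Small parcellation for simulation and brute-force testing.

    Defaults give 5 MRSNs x 4 GM ROIs + 6 WM ROIs = 26 nodes, small enough
    that exhaustive oracles over nodes, layers and windows stay feasible.
    """
    rois: list[Roi] = []
    idx = 1
    for mid in range(1, n_mrsn + 1):
        for k in range(1, gm_per_mrsn + 1):
            rois.append(Roi(idx, f"N{mid} {k}", GM, mid))
            idx += 1
    for k in range(1, n_wm + 1):
        rois.append(Roi(idx, f"WM {k}", WM, WM_MRSN_ID))
        idx += 1
    return Parcellation(tuple(rois))


# ---------------------------------------------------------------------------
# Theoretical maximum degrees
# ---------------------------------------------------------------------------

def max_degrees(parc: Parcellation) -> np.ndarray:
    """Per-ROI theoretical maximum degree in each of the three layers.

    Returns an ``(N_roi, 3)`` integer array.  For a GM ROI in MRSN S:

    * layer 1 (hypergraph): M - 1 — its MRSN can belong to every hyperedge
      except its own central one;
    * layer 2 (within-MRSN adjacency): n_S - 1;
    * layer 3 (WM-GM adjacency): the number of WM ROIs.

    For a WM ROI, layers 1 and 2 are 0 and layer 3 is the number of GM
    ROIs.  The row sums are the normalization denominators of the
    normalized multilayer degree.
    """
    n = parc.n_roi
    out = np.zeros((n, 3), dtype=int)
    m = parc.n_mrsn_gm
    for r in parc.rois:
        i = r.index - 1
        if r.tissue == GM:
            n_s = parc.mrsn_size(r.mrsn_id)
            out[i] = (m - 1, n_s - 1, parc.n_wm)
        else:
            out[i] = (0, 0, parc.n_gm)
    return out
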