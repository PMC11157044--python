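"""Seeded synthetic cohorts with the structure the pipeline assumes.

The generator is a Gaussian latent-factor model chosen so the implied
correlation structure is positive semidefinite by construction and every
knob maps directly to a pipeline assumption:

* one latent factor per MRSN; a global factor couples MRSN factors to one
  another, strongly for designated *hub* MRSNs (``cross_block_corr``) and
  weakly for the rest (``background_cross_corr``);
* GM ROI series = sqrt(w) * own-MRSN factor + sqrt(1-w) * idiosyncratic
  noise, giving within-block Pearson correlation w = ``within_block_corr``;
* designated WM ROIs couple to the active hub MRSN's factor with weight
  ``wm_gm_corr``; remaining WM ROIs are pure noise;
* regime switches rotate which MRSN is the hub at stated window starts,
  so hub identity — and hence core membership — flips there;
* group "B" hubs get ``group_effect_size`` added to their cross-block
  coupling, planting a detectable group difference;
* a retest session re-uses a fraction ``retest_reliability`` of the
  session-1 innovations (blended at the level of the underlying standard
  normals), so reliability 1 reproduces session 1 exactly.

All draws descend from a single ``numpy.random.SeedSequence``; one seed
fully determines the cohort, bit for bit.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import Parcellation, toy_parcellation
from .timeseries import RoiTimeSeries, WindowSpec

__all__ = [
    "SimulationConfig",
    "Cohort",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
]

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters (defaults define the study
    conditions used throughout the test suite)."""

    parcellation: Parcellation = field(default_factory=toy_parcellation)
    L: int = 120
    W: int = 40
    S: int = 20
    n_subjects: int = 6          # per group
    n_sessions: int = 1
    within_block_corr: float = 0.6
    cross_block_corr: float = 0.7       # hub MRSN <-> global factor
    background_cross_corr: float = 0.15  # non-hub MRSN <-> global factor
    wm_gm_corr: float = 0.7
    hub_mrsn_ids: tuple[int, ...] = (1,)
    n_wm_coupled: int = 4        # WM ROIs tracking the active hub factor
    regime_switch_windows: tuple[int, ...] = ()
    group_effect_size: float = 0.0
    retest_reliability: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.parcellation
        for name in ("within_block_corr", "background_cross_corr"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        hub_cross = self.cross_block_corr + abs(self.group_effect_size)
        if not 0.0 <= hub_cross <= 1.0:
            raise ValueError(
                "cross_block_corr + |group_effect_size| must stay in [0, 1] "
                f"for hub MRSNs {self.hub_mrsn_ids}"
            )
        if not 0.0 <= self.wm_gm_corr < 1.0:
            raise ValueError("wm_gm_corr must be in [0, 1)")
        if not 0.0 <= self.retest_reliability <= 1.0:
            raise ValueError("retest_reliability must be in [0, 1]")
        gm_ids = {m.mrsn_id for m in p.gm_mrsns}
        if not set(self.hub_mrsn_ids) <= gm_ids:
            raise ValueError("hub_mrsn_ids must name GM MRSNs")
        if self.n_wm_coupled > p.n_wm:
            raise ValueError("n_wm_coupled exceeds the WM ROI count")
        self.window_spec = WindowSpec(self.W, self.S)
        if self.window_spec.n_windows(self.L) < 2:
            raise ValueError("configuration yields fewer than 2 windows")

    # -- ground truth -----------------------------------------------------

    @property
    def hub_roi_indices(self) -> tuple[int, ...]:
        """1-based ROI indices planted as hubs (hub-MRSN GM members plus
        the coupled WM ROIs)."""
        p = self.parcellation
        gm = [
            ri
            for m in p.gm_mrsns
            if m.mrsn_id in self.hub_mrsn_ids
            for ri in m.member_roi_indices
        ]
        wm = [int(x) for x in p.wm_roi_indices[: self.n_wm_coupled]]
        return tuple(gm + wm)

    def active_hubs(self, window: int) -> tuple[int, ...]:
        """Hub MRSN ids active at a given window, after regime rotation."""
        shift = sum(1 for s in self.regime_switch_windows if window >= s)
        M = self.parcellation.n_mrsn_gm
        ids = sorted(m.mrsn_id for m in self.parcellation.gm_mrsns)
        return tuple(ids[(ids.index(h) + shift) % M] for h in self.hub_mrsn_ids)


@dataclass
class Cohort:
    timeseries: list[RoiTimeSeries]
    manifest: pd.DataFrame        # subject_id, session_id, group
    ground_truth: dict


def _innovations(rng: np.random.Generator, L: int, n_cols: int) -> np.ndarray:
    return rng.standard_normal((L, n_cols))


def _mix(cfg: SimulationConfig, E: np.ndarray, group: str) -> np.ndarray:
    """Deterministically map innovation draws to the observed ROI series."""
    p = cfg.parcellation
    M, n_gm, n_wm = p.n_mrsn_gm, p.n_gm, p.n_wm
    g = E[:, 0]
    eta = E[:, 1 : 1 + M]
    eps_gm = E[:, 1 + M : 1 + M + n_gm]
    eps_wm = E[:, 1 + M + n_gm : 1 + M + n_gm + n_wm]
    obs = E[:, 1 + M + n_gm + n_wm :]

    L = cfg.L
    hub_cross = cfg.cross_block_corr + (
        cfg.group_effect_size if group == "B" else 0.0
    )
    # per-timepoint regime: a window's regime applies from its start onward
    starts = [s * cfg.S for s in cfg.regime_switch_windows]
    regime_of_t = np.zeros(L, dtype=int)
    for s in starts:
        regime_of_t[s:] += 1

    mrsn_ids = sorted(m.mrsn_id for m in p.gm_mrsns)
    out = np.empty((L, p.n_roi))
    for reg in np.unique(regime_of_t):
        tmask = regime_of_t == reg
        window_for_reg = 0 if reg == 0 else cfg.regime_switch_windows[reg - 1]
        hubs = set(cfg.active_hubs(window_for_reg))
        # MRSN factors
        f = np.empty((tmask.sum(), M))
        for k, mid in enumerate(mrsn_ids):
            c = hub_cross if mid in hubs else cfg.background_cross_corr
            f[:, k] = np.sqrt(c) * g[tmask] + np.sqrt(1 - c) * eta[tmask, k]
        # GM ROIs
        w = cfg.within_block_corr
        for j, ri in enumerate(p.gm_roi_indices):
            k = p.mrsn_pos[p.mrsn_id[ri - 1]]
            out[tmask, ri - 1] = (
                np.sqrt(w) * f[:, k] + np.sqrt(1 - w) * eps_gm[tmask, j]
            )
        # WM ROIs: the first n_wm_coupled track the first active hub factor
        hub_k = p.mrsn_pos[cfg.active_hubs(window_for_reg)[0]]
        a = cfg.wm_gm_corr
        for j, ri in enumerate(p.wm_roi_indices):
            if j < cfg.n_wm_coupled:
                out[tmask, ri - 1] = (
                    np.sqrt(a) * f[:, hub_k] + np.sqrt(1 - a) * eps_wm[tmask, j]
                )
            else:
                out[tmask, ri - 1] = eps_wm[tmask, j]
    if cfg.noise_sd > 0:
        out = out + cfg.noise_sd * obs
    return out


def _n_innovation_cols(cfg: SimulationConfig) -> int:
    p = cfg.parcellation
    base = 1 + p.n_mrsn_gm + p.n_gm + p.n_wm
    return base + (p.n_roi if cfg.noise_sd > 0 else 0)


def generate_subject(
    cfg: SimulationConfig,
    subject_id: str,
    session_id: str = "s1",
    group: str = "A",
    seed_seq: np.random.SeedSequence | None = None,
) -> RoiTimeSeries:
    """One subject/session series under the factor model.

    When called directly (outside :func:`generate_cohort`) the subject's
    random stream is derived from ``cfg.seed`` and the subject id, so the
    same (config, subject, session) triple always reproduces the same
    series.  Session ids other than ``"s1"`` yield the reliability-blended
    retest series.
    """
    if seed_seq is None:
        sid_key = zlib.crc32(subject_id.encode()) % (2**31)
        seed_seq = np.random.SeedSequence([cfg.seed, sid_key])
    # stateless children: both sessions of a subject must see the same pair
    ss1 = np.random.SeedSequence(
        entropy=seed_seq.entropy, spawn_key=seed_seq.spawn_key + (0,)
    )
    ss_fresh = np.random.SeedSequence(
        entropy=seed_seq.entropy, spawn_key=seed_seq.spawn_key + (1,)
    )
    n_cols = _n_innovation_cols(cfg)
    E1 = _innovations(np.random.default_rng(ss1), cfg.L, n_cols)
    if session_id == "s1":
        E = E1
    else:
        rho = cfg.retest_reliability
        E_fresh = _innovations(np.random.default_rng(ss_fresh), cfg.L, n_cols)
        E = np.sqrt(rho) * E1 + np.sqrt(1 - rho) * E_fresh
    data = _mix(cfg, E, group)
    return RoiTimeSeries(data, subject_id, session_id)


def generate_cohort(cfg: SimulationConfig) -> Cohort:
    """Two groups x ``n_sessions`` sessions of ``n_subjects`` subjects each.

    The manifest records subject, session and group; ground truth (planted
    hub ids, switch windows, effect size) rides along for recovery tests.
    """
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    series: list[RoiTimeSeries] = []
    groups = ("A", "B")
    subject_seeds = root.spawn(len(groups) * cfg.n_subjects)
    k = 0
    for group in groups:
        for s in range(cfg.n_subjects):
            subject_id = f"{group}{s + 1:03d}"
            subj_seq = subject_seeds[k]
            k += 1
            # one innovation pair per subject, shared across sessions
            session_seqs = [subj_seq] * cfg.n_sessions
            for sess in range(cfg.n_sessions):
                session_id = f"s{sess + 1}"
                ts = generate_subject(
                    cfg, subject_id, session_id, group, session_seqs[sess]
                )
                series.append(ts)
                rows.append(
                    {"subject_id": subject_id, "session_id": session_id,
                     "group": group}
                )
    manifest = pd.DataFrame(rows)
    ground_truth = {
        "hub_mrsn_ids": list(cfg.hub_mrsn_ids),
        "hub_roi_indices": list(cfg.hub_roi_indices),
        "regime_switch_windows": list(cfg.regime_switch_windows),
        "group_effect_size": cfg.group_effect_size,
        "retest_reliability": cfg.retest_reliability,
        "seed": cfg.seed,
    }
    return Cohort(series, manifest, ground_truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-subject time-series TSVs plus the samples manifest."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ts in cohort.timeseries:
        name = f"{ts.subject_id}_{ts.session_id}.tsv"
        pd.DataFrame(ts.data).to_csv(
            outdir / name, sep="\t", index=False, header=False
        )
    cohort.manifest.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    (outdir / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=2)
    )
    return outdir
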