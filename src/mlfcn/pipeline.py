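"""End-to-end orchestration: construct -> metrics -> group analyses.

A run is fully described by a :class:`RunConfig`; the resolved config and
per-stage output checksums are serialized into ``run_manifest.json`` so a
rerun from the same manifest reproduces outputs byte for byte (all stages
are deterministic given the config and the recorded seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .construction import DEFAULT_LAM, build_temporal_fcn
from .group_analysis import group_diff_table, icc_table
from .parcellation import (
    Parcellation,
    default_parcellation,
    load_parcellation,
    toy_parcellation,
)
from .richclub import DEFAULT_N_CORE, RichClubMetrics, aggregate, compute_metrics
from .timeseries import RoiTimeSeries, WindowSpec, load_timeseries

__all__ = ["RunConfig", "run_pipeline", "metrics_long", "resolve_parcellation"]

log = logging.getLogger(__name__)

METRIC_NAMES = ("tc", "ts_literal", "ts_prose", "lf", "jf")


@dataclass
class RunConfig:
    parcellation: str = "default"   # "default" | "toy" | path to TSV
    timeseries_dir: str = ""
    samples_manifest: str = ""      # TSV: subject_id, session_id, group
    out_dir: str = "mlfcn_out"
    W: int = 200
    S: int = 100
    lam: float = DEFAULT_LAM
    n_core: int = DEFAULT_N_CORE
    ts_mode: Literal["prose", "literal"] = "prose"
    connectivity_policy: Literal["union", "adjacency_only"] = "union"
    analyses: tuple[str, ...] = ()  # subset of {"icc", "groupdiff"}
    scales: tuple[str, ...] = ("roi", "mrsn", "whole_brain")
    seed: int = 0


def resolve_parcellation(spec: str) -> Parcellation:
    if spec == "default":
        return default_parcellation()
    if spec == "toy":
        return toy_parcellation()
    return load_parcellation(spec)


def metrics_long(
    metrics: RichClubMetrics,
    parc: Parcellation,
    scales: Sequence[str] = ("roi", "mrsn", "whole_brain"),
) -> pd.DataFrame:
    """Long-format (unit, metric, value, scale) table of all five vectors."""
    frames = []
    vectors = {
        "tc": metrics.tc,
        "ts_literal": metrics.ts_literal,
        "ts_prose": metrics.ts_prose,
        "lf": metrics.lf,
        "jf": metrics.jf,
    }
    for scale in scales:
        for name, vec in vectors.items():
            df = aggregate(vec, parc, scale, metric_name=name)
            df["scale"] = scale
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns a dict with the manifest and key frames.

    Per subject/session: sliding-window network construction and rich-club
    metrics, written to ``metrics/<subject>_<session>.tsv``.  Afterwards the
    selected group analyses run over the collected long-format tables.  Any
    stage error aborts with the failing subject identified; outputs written
    so far are retained alongside a ``FAILED`` marker file.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parc = resolve_parcellation(cfg.parcellation)
    spec = WindowSpec(cfg.W, cfg.S)
    samples = pd.read_csv(cfg.samples_manifest, sep="\t", dtype=str)
    required = {"subject_id", "session_id", "group"}
    if not required <= set(samples.columns):
        raise ValueError(f"samples manifest needs columns {sorted(required)}")

    metrics_dir = out / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    long_tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    checksums: dict[str, str] = {}
    warnings_log: list[str] = []

    for _, row in samples.iterrows():
        sid, sess, group = row["subject_id"], row["session_id"], row["group"]
        ts_path = Path(cfg.timeseries_dir) / f"{sid}_{sess}.tsv"
        try:
            ts = load_timeseries(ts_path, parc, subject_id=sid, session_id=sess)
            if ts.zero_variance.any():
                warnings_log.append(
                    f"{sid}/{sess}: zero-variance ROIs "
                    f"{(np.flatnonzero(ts.zero_variance) + 1).tolist()}"
                )
            tfcn = build_temporal_fcn(ts, parc, spec, cfg.lam)
            m = compute_metrics(
                tfcn, parc, cfg.n_core, policy=cfg.connectivity_policy
            )
        except Exception as exc:
            (out / "FAILED").write_text(
                f"subject {sid} session {sess}: {exc}\n"
            )
            raise RuntimeError(
                f"pipeline failed at subject {sid} session {sess}: {exc}"
            ) from exc
        roi_frame = m.to_frame(parc)
        path = metrics_dir / f"{sid}_{sess}.tsv"
        roi_frame.to_csv(path, sep="\t", index=False)
        checksums[str(path.relative_to(out))] = _sha256(path)
        long = metrics_long(m, parc, cfg.scales)
        long.insert(0, "subject_id", sid)
        long_tables[(sid, sess, group)] = long

    results: dict[str, pd.DataFrame] = {}
    tissue_of_unit = {str(r.index): r.tissue for r in parc.rois}
    for m_ in parc.mrsns:
        tissue_of_unit[m_.name] = "WM" if m_.mrsn_id == 0 else "GM"

    if "icc" in cfg.analyses:
        sessions = sorted({k[1] for k in long_tables})
        if len(sessions) < 2:
            raise ValueError("ICC analysis needs two sessions per subject")
        s1 = pd.concat(
            [v for (sid, sess, g), v in long_tables.items() if sess == sessions[0]]
        )
        s2 = pd.concat(
            [v for (sid, sess, g), v in long_tables.items() if sess == sessions[1]]
        )
        icc_df = icc_table(s1, s2, tissue_of_unit)
        icc_path = out / "icc.tsv"
        icc_df.to_csv(icc_path, sep="\t", index=False)
        checksums["icc.tsv"] = _sha256(icc_path)
        results["icc"] = icc_df

    if "groupdiff" in cfg.analyses:
        groups = sorted({k[2] for k in long_tables})
        if len(groups) != 2:
            raise ValueError("group difference analysis needs exactly 2 groups")
        first_session = sorted({k[1] for k in long_tables})[0]
        ga = pd.concat(
            [v for (sid, sess, g), v in long_tables.items()
             if g == groups[0] and sess == first_session]
        )
        gb = pd.concat(
            [v for (sid, sess, g), v in long_tables.items()
             if g == groups[1] and sess == first_session]
        )
        diff_df = group_diff_table(ga, gb)
        diff_path = out / "groupdiff.tsv"
        diff_df.to_csv(diff_path, sep="\t", index=False)
        checksums["groupdiff.tsv"] = _sha256(diff_path)
        results["groupdiff"] = diff_df

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "n_windows": spec.n_windows(_series_length(cfg, samples, parc)),
        "checksums": checksums,
        "warnings": warnings_log,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


def _series_length(cfg: RunConfig, samples: pd.DataFrame, parc) -> int:
    row = samples.iloc[0]
    path = Path(cfg.timeseries_dir) / f"{row['subject_id']}_{row['session_id']}.tsv"
    ts = load_timeseries(path, parc)
    return ts.n_timepoints
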