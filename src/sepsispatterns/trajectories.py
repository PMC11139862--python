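"""Movement of subjects and groups through pattern space over time.

Coordinates are two chosen pattern rows (or any two per-sample scalars).
Group trajectories are per-(group, timepoint) means over the samples
actually observed — missing timepoints are omitted, never imputed — with
the healthy-donor centroid as the recovery reference. The recovery index
summarises each subject's approach to the healthy mean as the slope of the
standardised distance against log(hours + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CANONICAL_TIMEPOINTS


class TrajectoryError(ValueError):
    pass


@dataclass
class TrajectorySummary:
    """Mean group trajectories over two pattern axes."""

    axes: tuple[str, str]
    means: pd.DataFrame        # columns: group, timepoint, hours, mean_x, mean_y, n
    healthy_centroid: np.ndarray

    def group_path(self, group: str) -> pd.DataFrame:
        path = self.means[self.means["group"] == group]
        if path.empty:
            raise TrajectoryError(f"no samples for group {group!r}")
        return path.sort_values("hours")


def _resolve_axes(P: pd.DataFrame, axes) -> tuple[str, str]:
    out = []
    for a in axes:
        if isinstance(a, (int, np.integer)):
            if not 1 <= a <= P.shape[0]:
                raise TrajectoryError(f"pattern index {a} outside 1..{P.shape[0]}")
            out.append(P.index[a - 1])
        elif a in P.index:
            out.append(a)
        else:
            raise TrajectoryError(f"unknown pattern axis {a!r}")
    return tuple(out)


def _sample_groups(meta: pd.DataFrame) -> pd.Series:
    """healthy | survived | died | unknown per sample."""
    grp = meta["outcome"].where(meta["group"] == "sepsis", "healthy")
    return pd.Series(grp.to_numpy(), index=meta["sample_id"].to_numpy())


def group_mean_trajectory(
    P: pd.DataFrame,
    meta: pd.DataFrame,
    axes=(1, 2),
    groups: tuple[str, ...] = ("survived", "died"),
) -> TrajectorySummary:
    """Per-(group, timepoint) mean coordinates over two pattern axes.

    ``groups`` are outcome groups among sepsis subjects ("survived",
    "died", "unknown"); the healthy centroid is always computed from all
    healthy samples. Timepoints with no samples for a group are omitted.
    """
    ax = _resolve_axes(P, axes)
    sample_group = _sample_groups(meta)
    shared = [s for s in meta["sample_id"] if s in P.columns]
    if not shared:
        raise TrajectoryError("no metadata samples found in the pattern matrix")
    coords = P.loc[list(ax), shared].T  # samples x 2
    m = meta.set_index("sample_id").loc[shared]

    healthy = sample_group.loc[shared] == "healthy"
    if not healthy.any():
        raise TrajectoryError("no healthy samples to define the centroid")
    centroid = coords[healthy.to_numpy()].mean(axis=0).to_numpy()

    rows = []
    for g in groups:
        sel = (sample_group.loc[shared] == g).to_numpy()
        if not sel.any():
            raise TrajectoryError(f"no samples for group {g!r}")
        sub = m[sel]
        for tp in CANONICAL_TIMEPOINTS:
            at = (sub["timepoint"] == tp).to_numpy()
            if not at.any():
                continue
            xy = coords[sel][at]
            rows.append({
                "group": g, "timepoint": tp,
                "hours": float(sub.loc[at, "hours"].iloc[0]),
                "mean_x": float(xy.iloc[:, 0].mean()),
                "mean_y": float(xy.iloc[:, 1].mean()),
                "n": int(at.sum()),
            })
    means = pd.DataFrame(rows)
    return TrajectorySummary(axes=ax, means=means, healthy_centroid=centroid)


def net_displacement(traj: TrajectorySummary, group: str) -> float:
    """Euclidean distance between a group's first and last observed mean
    coordinates (0 for a single observed timepoint)."""
    path = traj.group_path(group)
    first = path.iloc[0][["mean_x", "mean_y"]].to_numpy(dtype=float)
    last = path.iloc[-1][["mean_x", "mean_y"]].to_numpy(dtype=float)
    return float(np.linalg.norm(last - first))


def subject_paths(P: pd.DataFrame, meta: pd.DataFrame, axes=(1, 2)
                  ) -> dict[str, pd.DataFrame]:
    """Per-subject coordinates ordered by hours (file order irrelevant)."""
    ax = _resolve_axes(P, axes)
    shared = meta[meta["sample_id"].isin(P.columns)]
    paths: dict[str, pd.DataFrame] = {}
    for subj, sub in shared.groupby("subject_id", sort=True):
        sub = sub.sort_values("hours")
        coords = P.loc[list(ax), sub["sample_id"]].T
        paths[subj] = pd.DataFrame({
            "timepoint": sub["timepoint"].to_numpy(),
            "hours": sub["hours"].to_numpy(dtype=float),
            "x": coords.iloc[:, 0].to_numpy(),
            "y": coords.iloc[:, 1].to_numpy(),
        })
    return paths


def recovery_index(
    values: pd.Series,
    meta: pd.DataFrame,
    log_time: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject recovery slope of the standardised distance to healthy.

    ``values`` is a per-sample scalar (a pattern row or a PC score). Each
    sample's signed distance to the healthy mean is expressed in healthy-SD
    units; per subject the slope of that distance against log(hours + 1)
    (or raw hours) is reported — negative slope = movement toward healthy.
    Subjects with fewer than 2 timepoints get a missing slope.

    Returns (per_subject, per_group) DataFrames.
    """
    shared = meta[meta["sample_id"].isin(values.index)]
    sample_group = _sample_groups(shared)
    healthy_vals = values.loc[
        sample_group.index[(sample_group == "healthy").to_numpy()]]
    if healthy_vals.empty:
        raise TrajectoryError("no healthy samples to define the reference")
    mu = float(healthy_vals.mean())
    sd = float(healthy_vals.std(ddof=1)) if len(healthy_vals) > 1 else 0.0
    if sd == 0:
        raise TrajectoryError("healthy reference has zero SD")

    rows = []
    sepsis = shared[shared["group"] == "sepsis"]
    for subj, sub in sepsis.groupby("subject_id", sort=True):
        sub = sub.sort_values("hours")
        d = (values.loc[sub["sample_id"]].to_numpy(dtype=float) - mu) / sd
        t = sub["hours"].to_numpy(dtype=float)
        t = np.log(t + 1.0) if log_time else t
        if len(sub) < 2 or np.ptp(t) == 0:
            slope = np.nan
        else:
            slope = float(np.polyfit(t, d, 1)[0])
        rows.append({
            "subject_id": subj,
            "outcome": sub["outcome"].iloc[0],
            "n_timepoints": len(sub),
            "mean_distance": float(d.mean()),
            "slope": slope,
        })
    per_subject = pd.DataFrame(rows)
    per_group = (per_subject.dropna(subset=["slope"])
                 .groupby("outcome")["slope"]
                 .agg(mean_slope="mean", sd_slope="std", n="count")
                 .reset_index())
    return per_subject, per_group
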