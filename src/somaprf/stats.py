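"""Somatotopy and quality-control statistics.

Covers the bespoke statistical procedures of the analysis: per-ROI rigid
rotation of flattened coordinates so the leg-to-face axis points north,
subject-level regressions of pRF center (or size) on the rotated vertical
coordinate with a group t-test of the slopes (the somatotopy/size gradient
test), correlations between vertex maps, the task-design bias test on
same-run versus other-run body-part distances, and head-motion scoring of
cued movements from rigid-body realignment traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .aggregation import dx_columns
from .task_design import (
    BodyPartSet,
    EventSchedule,
    DEFAULT_TR,
    DEFAULT_VOLUMES_PER_RUN,
)

__all__ = [
    "GradientTestResult",
    "MotionTrace",
    "LEG_GROUP",
    "FACE_GROUP",
    "rotate_roi",
    "gradient_test",
    "map_correlation",
    "design_bias_test",
    "head_motion_score",
]

#: pRF centers anchoring the south (leg) and north (face) ends of the
#: somatotopic axis: toes/ankle/knee and lips/jaw/tongue.
LEG_GROUP: tuple[int, ...] = (1, 2, 3)
FACE_GROUP: tuple[int, ...] = (16, 17, 18)


@dataclass(frozen=True)
class GradientTestResult:
    roi: str
    quantity: str
    slopes: np.ndarray  # one per subject
    t_stat: float
    p_one_sided: float
    p_two_sided: float
    angles: np.ndarray  # rotation applied per subject, radians
    degenerate: bool = False


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-body realignment parameters, one row per volume.

    ``params`` has six columns: translations in mm (x, y, z) then rotations
    in radians (pitch, roll, yaw).
    """

    params: np.ndarray
    tr: float = DEFAULT_TR

    def __post_init__(self) -> None:
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must have six columns")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


def _rotation_to_north(v: np.ndarray) -> tuple[np.ndarray, float]:
    """Proper rotation matrix sending direction v to +y, and its angle."""
    angle = np.arctan2(v[1], v[0])
    theta = np.pi / 2.0 - angle  # rotate so the vector points along +y
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]]), theta


def rotate_roi(
    table: pd.DataFrame, roi: str, inplace_columns: bool = True
) -> pd.DataFrame | None:
    """Rotate one ROI's flattened coordinates so the somatotopy runs south
    to north.

    The rigid rotation (determinant +1, about the ROI centroid) aligns the
    vector from the leg-group centroid (vertices preferring toes/ankle/knee)
    to the face-group centroid (lips/jaw/tongue) with the +y axis.  Returns
    the ROI's rows with ``x_rot``/``y_rot``/``rotation_angle`` columns
    added, or None (with a warning) when either anchor group is empty.
    """
    sub = table[table["roi"] == roi]
    if "selected" in sub.columns:
        sub = sub[sub["selected"].astype(bool)]
    centers = sub["center"].to_numpy()
    leg = sub[np.isin(centers, LEG_GROUP)]
    face = sub[np.isin(centers, FACE_GROUP)]
    if len(leg) == 0 or len(face) == 0:
        warnings.warn(
            f"ROI {roi!r} lacks {'leg' if len(leg) == 0 else 'face'}-group "
            "centers; skipping rotation"
        )
        return None
    xy = sub[["x", "y"]].to_numpy(dtype=float)
    centroid = xy.mean(axis=0)
    v = face[["x", "y"]].to_numpy(dtype=float).mean(axis=0) - leg[
        ["x", "y"]
    ].to_numpy(dtype=float).mean(axis=0)
    R, theta = _rotation_to_north(v)
    rotated = (xy - centroid) @ R.T + centroid
    out = sub.copy()
    out["x_rot"] = rotated[:, 0]
    out["y_rot"] = rotated[:, 1]
    out["rotation_angle"] = theta
    return out


def gradient_test(
    table: pd.DataFrame, quantity: str = "center", rois: list[str] | None = None
) -> list[GradientTestResult]:
    """Somatotopy (or size) gradient test per ROI.

    Per subject and ROI, the quantity is regressed on the rotated vertical
    coordinate; the per-subject slopes are then tested against zero with a
    one-sample t-test across subjects (one-sided 'greater' is the headline,
    the two-sided p is reported alongside).  Requires at least two subjects.
    """
    if quantity not in ("center", "size"):
        raise ValueError("quantity must be 'center' or 'size'")
    subjects = sorted(table["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("gradient_test requires at least 2 subjects")
    if rois is None:
        rois = sorted(table["roi"].unique())
    results = []
    for roi in rois:
        slopes, angles = [], []
        degenerate = False
        for subj in subjects:
            rot = rotate_roi(table[table["subject"] == subj], roi)
            if rot is None or len(rot) < 3:
                continue
            yv = rot["y_rot"].to_numpy(dtype=float)
            qv = rot[quantity].to_numpy(dtype=float)
            if np.ptp(qv) == 0 or np.ptp(yv) == 0:
                slopes.append(0.0)
                degenerate = True
            else:
                slope, _ = np.polyfit(yv, qv, 1)
                slopes.append(float(slope))
            angles.append(float(rot["rotation_angle"].iloc[0]))
        if len(slopes) < 2:
            warnings.warn(f"ROI {roi!r}: fewer than 2 usable subjects; skipped")
            continue
        slopes_arr = np.asarray(slopes)
        t, p_two = sps.ttest_1samp(slopes_arr, 0.0)
        _, p_one = sps.ttest_1samp(slopes_arr, 0.0, alternative="greater")
        results.append(
            GradientTestResult(
                roi=roi,
                quantity=quantity,
                slopes=slopes_arr,
                t_stat=float(t),
                p_one_sided=float(p_one),
                p_two_sided=float(p_two),
                angles=np.asarray(angles),
                degenerate=degenerate,
            )
        )
    return results


def map_correlation(
    map_a: np.ndarray, map_b: np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation between two vertex maps over their non-zero
    overlap; degrees of freedom are the overlap count minus 2."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share the vertex index")
    mask = (a != 0) & (b != 0)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"only {n} vertices are non-zero in both maps (need >= 3)")
    r, p = sps.pearsonr(a[mask], b[mask])
    return float(r), float(p), n - 2


def design_bias_test(
    table: pd.DataFrame, parts: BodyPartSet | None = None, n_parts: int = 18
) -> tuple[float, float, float]:
    """Welch t-test for coupling of body parts cued in the same run.

    For every selected vertex, the non-center body-part distances are split
    by whether the part was presented in the same run-part as the vertex's
    pRF center or in the other one; the two pooled distance distributions
    are compared with a Welch t-test.  Returns (t, df, p); |t| near zero
    means no evidence that the split-run design coupled the estimates.
    """
    if parts is None:
        parts = BodyPartSet()
    sub = table[table["selected"].astype(bool)] if "selected" in table.columns else table
    if len(sub) == 0:
        raise ValueError("no selected vertices")
    run_of = np.array([parts.run_assignment[lab] for lab in parts.labels])
    dx = sub[dx_columns(n_parts)].to_numpy(dtype=float)
    centers = sub["center"].to_numpy(dtype=int)
    same_run, other_run = [], []
    for v in range(dx.shape[0]):
        c = centers[v]
        mask = np.arange(1, n_parts + 1) != c
        same = run_of == run_of[c - 1]
        same_run.append(dx[v, mask & same])
        other_run.append(dx[v, mask & ~same])
    same_all = np.concatenate(same_run)
    other_all = np.concatenate(other_run)
    if same_all.size == 0 or other_all.size == 0:
        raise ValueError("one of the run groups is empty")
    t, p = sps.ttest_ind(same_all, other_all, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    v1 = same_all.var(ddof=1) / same_all.size
    v2 = other_all.var(ddof=1) / other_all.size
    if v1 + v2 == 0:
        return 0.0, float(same_all.size + other_all.size - 2), 1.0
    df = (v1 + v2) ** 2 / (
        v1**2 / (same_all.size - 1) + v2**2 / (other_all.size - 1)
    )
    return float(t), float(df), float(p)


def head_motion_score(
    trace: MotionTrace,
    schedule: EventSchedule,
    window: float = 3.0,
    rotation_radius: float = 50.0,
    volumes_per_run: tuple[int, ...] = DEFAULT_VOLUMES_PER_RUN,
) -> pd.DataFrame:
    """Score head displacement following each motor cue.

    The six realignment parameters are differentiated over volumes
    (restarting at run boundaries) and their absolute first differences are
    summed over the volumes whose acquisition onset falls within ``window``
    seconds of the cue; rotations are converted to arc displacement at
    ``rotation_radius`` mm.  Returns a per-event table with a
    ``displacement`` column (mm) plus, per condition, the Welch t-test of
    that condition's event scores against all other conditions pooled
    (columns ``cond_mean``, ``t_vs_rest``, ``p_vs_rest``).
    """
    if window < trace.tr:
        warnings.warn(
            f"window {window}s is shorter than one TR ({trace.tr}s); "
            "falling back to the nearest volume per cue"
        )
    offsets = np.concatenate([[0], np.cumsum(volumes_per_run)])
    if trace.n_volumes < offsets[-1]:
        raise ValueError(
            f"motion trace has {trace.n_volumes} volumes; protocol needs {offsets[-1]}"
        )
    deriv = np.abs(np.diff(trace.params, axis=0, prepend=trace.params[:1]))
    for start in offsets[:-1]:
        deriv[start] = 0.0  # realignment restarts per run
    # mm-equivalent framewise displacement per volume
    fd = deriv[:, :3].sum(axis=1) + rotation_radius * deriv[:, 3:].sum(axis=1)

    rows = []
    for ev in schedule.events.itertuples():
        run0 = ev.run - 1
        n_vol = volumes_per_run[run0]
        vol_onsets = np.arange(n_vol) * trace.tr
        in_win = (vol_onsets >= ev.onset) & (vol_onsets < ev.onset + window)
        if not in_win.any():
            in_win = np.zeros(n_vol, dtype=bool)
            in_win[int(np.argmin(np.abs(vol_onsets - ev.onset)))] = True
        score = float(fd[offsets[run0] : offsets[run0] + n_vol][in_win].sum())
        rows.append({"condition": ev.condition, "run": ev.run, "onset": ev.onset,
                     "displacement": score})
    events = pd.DataFrame(rows)
    out = []
    for cond, grp in events.groupby("condition"):
        rest = events.loc[events["condition"] != cond, "displacement"]
        a = grp["displacement"].to_numpy()
        b = rest.to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        out.append(
            {"condition": cond, "cond_mean": float(a.mean()),
             "t_vs_rest": float(t), "p_vs_rest": float(p)}
        )
    summary = pd.DataFrame(out)
    return events.merge(summary, on="condition")
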