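"""Movement-task protocol: body parts, event schedules, design matrix, HRF.

The task cues 18 body parts spanning the classical homunculus ordering
(toes ... tongue).  Cueing is split into two run-parts -- one presenting the
torso/arm/hand conditions, the other the leg and face conditions -- each
recorded in two scanner runs.  This module generates pseudo-randomized event
schedules for that protocol, rasterizes them into a binary condition x volume
design matrix, and samples the canonical double-gamma hemodynamic response
function used by the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "BODY_PART_LABELS",
    "BodyPartSet",
    "EventSchedule",
    "DesignMatrix",
    "HRFKernel",
    "DEFAULT_VOLUMES_PER_RUN",
    "DEFAULT_TR",
    "build_event_schedule",
    "design_matrix",
    "canonical_hrf",
]

#: Homunculus order, toes (1) to tongue (18).
BODY_PART_LABELS: tuple[str, ...] = (
    "toes",
    "ankle",
    "knee",
    "abdomen",
    "shoulder",
    "elbow",
    "wrist",
    "little_finger",
    "ring_finger",
    "middle_finger",
    "index_finger",
    "thumb",
    "forehead",
    "eyelid",
    "nose",
    "lips",
    "jaw",
    "tongue",
)

# Run-part 1 presents torso/arm/hand (abdomen..thumb), run-part 2 the
# leg (toes/ankle/knee) and face conditions.
_DEFAULT_RUN_ASSIGNMENT: dict[str, int] = {
    label: (1 if 4 <= i <= 12 else 2) for i, label in enumerate(BODY_PART_LABELS, start=1)
}

#: Scanner-run lengths (volumes) of the full protocol: each of the two task
#: parts was recorded in two runs of 237 and 191 volumes (856 in total).
DEFAULT_VOLUMES_PER_RUN: tuple[int, ...] = (237, 191, 237, 191)

#: Repetition time of the protocol, seconds.
DEFAULT_TR: float = 2.1


@dataclass(frozen=True)
class BodyPartSet:
    """Ordered body-part conditions and their run-part assignment."""

    labels: tuple[str, ...] = BODY_PART_LABELS
    run_assignment: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_RUN_ASSIGNMENT)
    )

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("body-part labels must be unique")
        missing = set(self.labels) - set(self.run_assignment)
        if missing:
            raise ValueError(f"labels without run assignment: {sorted(missing)}")
        parts = set(self.run_assignment[lab] for lab in self.labels)
        if not parts <= {1, 2}:
            raise ValueError("run-part ids must be 1 or 2")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """1-based condition index of *label*."""
        return self.labels.index(label) + 1

    def conditions_in_part(self, part: int) -> list[int]:
        """1-based condition indices assigned to run-part *part*."""
        return [
            i
            for i, lab in enumerate(self.labels, start=1)
            if self.run_assignment[lab] == part
        ]


@dataclass(frozen=True)
class EventSchedule:
    """A realized task schedule.

    ``events`` is a DataFrame with one row per cue and columns

    condition
        1-based body-part index.
    onset
        seconds from the start of the event's scanner run.
    duration
        movement-window length in seconds.
    interval
        inter-cue interval owned by this event: time from the previous cue
        onset in the same run (run start for the first event of a run).
    part, run
        run-part id (1/2) and global scanner-run index (1-based, protocol
        order).
    """

    events: pd.DataFrame
    base_iti: float
    long_iti: float
    seed: int

    @property
    def n_events(self) -> int:
        return len(self.events)

    def events_per_condition(self) -> pd.Series:
        return self.events.groupby("condition").size()

    def to_bids(self) -> pd.DataFrame:
        """BIDS-events-style table (onset, duration, trial_type, run)."""
        ev = self.events
        return pd.DataFrame(
            {
                "onset": ev["onset"].to_numpy(),
                "duration": ev["duration"].to_numpy(),
                "trial_type": [BODY_PART_LABELS[c - 1] for c in ev["condition"]],
                "run": ev["run"].to_numpy(),
            }
        )


@dataclass(frozen=True)
class DesignMatrix:
    """Binary condition x volume stimulus matrix with run bookkeeping."""

    s: np.ndarray  # (n_conditions, T), entries in {0, 1}
    tr: float
    run_boundaries: tuple[int, ...]  # cumulative volume counts, ends at T

    @property
    def n_volumes(self) -> int:
        return self.s.shape[1]

    @property
    def n_conditions(self) -> int:
        return self.s.shape[0]

    def run_slices(self) -> list[slice]:
        starts = (0,) + self.run_boundaries[:-1]
        return [slice(a, b) for a, b in zip(starts, self.run_boundaries)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.s.T, columns=list(BODY_PART_LABELS[: self.n_conditions]))


@dataclass(frozen=True)
class HRFKernel:
    """Canonical HRF sampled at the repetition time."""

    values: np.ndarray
    tr: float
    duration: float
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    @property
    def peak_time(self) -> float:
        return float(np.argmax(self.values) * self.tr)


def _greedy_no_repeat_order(
    conditions: list[int], repetitions: int, rng: np.random.Generator
) -> np.ndarray:
    conds = np.asarray(conditions)
    for _ in range(1000):
        counts = np.full(len(conds), repetitions)
        seq: list[int] = []
        while counts.sum() > 0:
            avail = counts > 0
            if seq:
                avail &= conds != seq[-1]
            if not avail.any():
                break
            w = counts[avail].astype(float)
            pick = rng.choice(np.flatnonzero(avail), p=w / w.sum())
            seq.append(int(conds[pick]))
            counts[pick] -= 1
        if counts.sum() == 0:
            return np.asarray(seq)
    raise RuntimeError("no non-repeating condition order exists for this design")


def _schedule_one_part(
    conditions: list[int],
    repetitions: int,
    base_iti: float,
    long_iti: float,
    movement_duration: float,
    run_durations: tuple[float, ...],
    rng: np.random.Generator,
) -> list[tuple[int, float, float, int]]:
    """Place one run-part's events; returns (condition, onset, interval, run#).

    Order is a uniform shuffle resampled until no condition immediately
    repeats (waived when the part has a single condition).  Each event owns
    the interval preceding its onset -- the first event of a run measures it
    from the run start -- and one repetition per condition carries the
    lengthened interval, its position drawn by the seeded generator.  Events
    fill the part's runs greedily: when the next event would overrun the
    current run's scan window it rolls over to the next run.
    """
    order = np.repeat(conditions, repetitions)
    if len(conditions) > 1:
        for _ in range(50_000):
            rng.shuffle(order)
            if not np.any(order[1:] == order[:-1]):
                break
        else:
            # rejection sampling is hopeless when repeats are highly likely
            # (few conditions, many repetitions); build the order greedily,
            # drawing each cue from the remaining counts excluding the
            # previous condition, weighted by count to avoid dead ends
            order = _greedy_no_repeat_order(conditions, repetitions, rng)
    # which repetition (per condition) owns the long interval
    long_pick = {c: rng.integers(repetitions) for c in conditions}

    placed: list[tuple[int, float, float, int]] = []
    seen: dict[int, int] = {c: 0 for c in conditions}
    run_idx = 0
    prev_onset: float | None = None
    for cond in order:
        iti = long_iti if seen[cond] == long_pick[cond] else base_iti
        seen[cond] += 1
        onset = iti if prev_onset is None else prev_onset + iti
        if onset + movement_duration > run_durations[run_idx]:
            run_idx += 1
            if run_idx >= len(run_durations):
                raise ValueError(
                    "schedule does not fit the scan windows; "
                    "increase run durations or reduce repetitions"
                )
            onset = iti
            prev_onset = None
        placed.append((int(cond), onset, iti, run_idx))
        prev_onset = onset
    return placed


def build_event_schedule(
    parts: BodyPartSet | None = None,
    repetitions: int = 9,
    base_iti: float = 10.0,
    long_iti: float = 14.7,
    seed: int = 0,
    *,
    movement_duration: float = 3.0,
    run_durations: tuple[tuple[float, ...], tuple[float, ...]] | None = None,
) -> EventSchedule:
    """Generate a pseudo-randomized movement schedule for both run-parts.

    Each condition is cued ``repetitions`` times within its assigned
    run-part; inter-cue intervals are ``base_iti`` seconds except one
    randomly chosen repetition per condition, which is lengthened to
    ``long_iti``.  ``run_durations`` gives the scan-window lengths (seconds)
    of each part's scanner runs; by default the full-protocol windows
    (237- and 191-volume runs at TR 2.1 s) are used.

    The schedule is bit-reproducible for a fixed seed.
    """
    if parts is None:
        parts = BodyPartSet()
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if long_iti <= base_iti:
        raise ValueError("long_iti must exceed base_iti")
    if run_durations is None:
        d1 = DEFAULT_VOLUMES_PER_RUN[0] * DEFAULT_TR
        d2 = DEFAULT_VOLUMES_PER_RUN[1] * DEFAULT_TR
        run_durations = ((d1, d2), (d1, d2))

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    global_run = 0
    for part in (1, 2):
        conds = parts.conditions_in_part(part)
        if not conds:
            continue
        placed = _schedule_one_part(
            conds,
            repetitions,
            base_iti,
            long_iti,
            movement_duration,
            run_durations[part - 1],
            rng,
        )
        for cond, onset, interval, run_in_part in placed:
            rows.append(
                {
                    "condition": cond,
                    "onset": onset,
                    "duration": movement_duration,
                    "interval": interval,
                    "part": part,
                    "run": global_run + run_in_part + 1,
                }
            )
        global_run += len(run_durations[part - 1])

    events = pd.DataFrame(rows)
    # onsets strictly increasing within every run, by construction
    for _, grp in events.groupby("run"):
        d = np.diff(grp["onset"].to_numpy())
        assert np.all(d > 0)
    return EventSchedule(events=events, base_iti=base_iti, long_iti=long_iti, seed=seed)


def design_matrix(
    schedule: EventSchedule,
    volumes_per_run: tuple[int, ...] = DEFAULT_VOLUMES_PER_RUN,
    tr: float = DEFAULT_TR,
    boxcar: float = 3.0,
    n_conditions: int = 18,
) -> DesignMatrix:
    """Rasterize a schedule into the binary stimulus matrix s(x_i, t).

    A volume is "on" for condition i when its half-open acquisition window
    ``[t, t + tr)`` intersects the event window ``[onset, onset + boxcar)``.
    Runs are concatenated in protocol order.  Setting ``boxcar`` to 0 is not
    supported; impulse regressors are obtained with ``boxcar <= tr``.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if boxcar <= 0:
        raise ValueError("boxcar must be positive")
    runs_present = sorted(schedule.events["run"].unique())
    if runs_present and max(runs_present) > len(volumes_per_run):
        raise ValueError(
            f"schedule references run {max(runs_present)} but only "
            f"{len(volumes_per_run)} runs were given"
        )
    T = int(sum(volumes_per_run))
    s = np.zeros((n_conditions, T), dtype=np.int8)
    offsets = np.concatenate([[0], np.cumsum(volumes_per_run)])
    for row in schedule.events.itertuples():
        run0 = row.run - 1
        n_vol = volumes_per_run[run0]
        if row.onset + boxcar > n_vol * tr:
            raise ValueError(
                f"event at {row.onset:.1f}s (+{boxcar}s boxcar) exceeds the "
                f"{n_vol * tr:.1f}s scan window of run {row.run}"
            )
        first = int(np.floor(row.onset / tr))
        last = int(np.ceil((row.onset + boxcar) / tr))  # exclusive
        s[row.condition - 1, offsets[run0] + first : offsets[run0] + last] = 1
    return DesignMatrix(s=s, tr=tr, run_boundaries=tuple(np.cumsum(volumes_per_run)))


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1.0) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def canonical_hrf(
    tr: float = DEFAULT_TR,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> HRFKernel:
    """Sample the canonical double-gamma HRF at the repetition time.

    The kernel is the standard difference of two gamma densities (positive
    peak near ``peak_delay`` seconds, late undershoot scaled by
    ``undershoot_ratio``), rescaled to unit peak so that the fitted
    amplitude carries the percent-signal units.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = max(1, int(np.ceil(duration / tr)))
    t = np.arange(n) * tr
    # shape = delay/dispersion, scale = dispersion (gamma mode at delay - dispersion)
    peak = _gamma_pdf(t, peak_delay / peak_dispersion, peak_dispersion)
    under = _gamma_pdf(t, undershoot_delay / undershoot_dispersion, undershoot_dispersion)
    h = peak - undershoot_ratio * under
    m = np.max(np.abs(h))
    if m > 0:
        h = h / m
    return HRFKernel(
        values=h,
        tr=tr,
        duration=duration,
        peak_delay=peak_delay,
        undershoot_delay=undershoot_delay,
        peak_dispersion=peak_dispersion,
        undershoot_dispersion=undershoot_dispersion,
        undershoot_ratio=undershoot_ratio,
    )
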