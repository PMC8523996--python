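"""Frame schedules, time-activity curves and cohort I/O.

Time convention used throughout the package: frame timing is stored in
seconds (as on disk), all kinetic-model mathematics is carried out in
minutes (rate constants in min^-1), and late-phase slopes are reported in
per-hour units.  Frame SUV values are treated as frame-averaged activity
conventionally assigned to the frame midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PROTOCOL_INPUT_FUNCTION",
    "PROTOCOL_UNIFORM",
    "REGION_TUMOR",
    "REGION_BRAIN",
    "REGION_BLOOD",
    "REGIONS",
    "FrameSchedule",
    "TAC",
    "SubjectRecord",
    "make_schedule",
    "frame_midpoints",
    "dense_grid_minutes",
    "tac_ratio",
    "read_cohort",
    "write_cohort",
]

PROTOCOL_INPUT_FUNCTION = "input_function"
PROTOCOL_UNIFORM = "uniform"
PROTOCOLS = (PROTOCOL_INPUT_FUNCTION, PROTOCOL_UNIFORM)

REGION_TUMOR = "tumor"
REGION_BRAIN = "brain_reference"
REGION_BLOOD = "blood"
REGIONS = (REGION_TUMOR, REGION_BRAIN, REGION_BLOOD)

#: resolution of the dense evaluation grid for fitted curves, seconds
DENSE_DT_S = 1.0
#: total acquisition length, seconds
ACQUISITION_S = 1800.0


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-PET frame grid.

    Parameters
    ----------
    frame_start : array of float
        Frame start times, seconds from injection, strictly increasing.
    frame_duration : array of float
        Frame durations in seconds, all positive.  Frames must tile the
        acquisition without gaps or overlap.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValueError("frame_start and frame_duration must be equal-length 1-d arrays")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def total_duration_s(self) -> float:
        return float(self.frame_end[-1] - self.frame_start[0])

    def midpoints_min(self) -> np.ndarray:
        """Frame midpoints in minutes, strictly increasing."""
        return (self.frame_start + 0.5 * self.frame_duration) / 60.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.frame_start.shape == other.frame_start.shape
            and np.array_equal(self.frame_start, other.frame_start)
            and np.array_equal(self.frame_duration, other.frame_duration)
        )

    def __hash__(self) -> int:
        return hash((self.frame_start.tobytes(), self.frame_duration.tobytes()))


def make_schedule(protocol: str) -> FrameSchedule:
    """Build one of the two acquisition frame schedules.

    ``input_function``: 12 x 5 s, 6 x 10 s, 6 x 30 s, 5 x 60 s, 4 x 300 s
    (33 frames; fine early sampling for the vascular phase).
    ``uniform``: 30 x 60 s frames.  Both span 0-1800 s.
    """
    if protocol == PROTOCOL_INPUT_FUNCTION:
        durations = np.concatenate(
            [np.full(12, 5.0), np.full(6, 10.0), np.full(6, 30.0), np.full(5, 60.0), np.full(4, 300.0)]
        )
    elif protocol == PROTOCOL_UNIFORM:
        durations = np.full(30, 60.0)
    else:
        raise ValueError(
            f"unknown protocol {protocol!r}: expected {PROTOCOL_INPUT_FUNCTION!r} or {PROTOCOL_UNIFORM!r}"
        )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoints of *schedule* in minutes."""
    return schedule.midpoints_min()


def _infer_protocol(schedule: FrameSchedule) -> str | None:
    for protocol in PROTOCOLS:
        if schedule == make_schedule(protocol):
            return protocol
    return None


@dataclass(frozen=True)
class TAC:
    """Region time-activity curve: one SUV value per frame.

    Noisy values may dip below zero and are preserved as measured;
    clipping would bias late-phase slope estimates.
    """

    schedule: FrameSchedule
    values: np.ndarray
    region_label: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != self.schedule.frame_start.shape:
            raise ValueError("TAC needs exactly one value per frame")
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")
        if self.region_label not in REGIONS:
            raise ValueError(f"unknown region label {self.region_label!r}")

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.schedule.midpoints_min()


@dataclass
class SubjectRecord:
    """One subject: TACs per (region, protocol) plus the binary IDH label."""

    subject_id: str
    idh_mutant: bool
    tacs: dict = field(default_factory=dict)  # (region, protocol) -> TAC

    def __post_init__(self) -> None:
        if not any(region == REGION_TUMOR for region, _ in self.tacs):
            raise ValueError(f"subject {self.subject_id!r}: tumor TAC is required")

    def tac(self, region: str, protocol: str) -> TAC:
        try:
            return self.tacs[(region, protocol)]
        except KeyError:
            raise KeyError(
                f"subject {self.subject_id!r} has no {region!r} TAC under the {protocol!r} protocol"
            ) from None

    def has(self, region: str, protocol: str) -> bool:
        return (region, protocol) in self.tacs


def dense_grid_minutes(dt_s: float = DENSE_DT_S, end_s: float = ACQUISITION_S) -> np.ndarray:
    """Dense curve-evaluation grid in minutes (default 1-s resolution)."""
    n = int(round(end_s / dt_s))
    return np.arange(n + 1) * (dt_s / 60.0)


def tac_ratio(
    tumor: Callable[[np.ndarray], np.ndarray],
    reference: Callable[[np.ndarray], np.ndarray],
    grid_min: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise tumor/reference ratio of two fitted (continuous) curves.

    Both curves are evaluated on a common dense grid (minutes); the
    reference must be strictly positive everywhere on that grid.

    Returns
    -------
    (t_min, ratio) : pair of arrays
    """
    t = dense_grid_minutes() if grid_min is None else np.asarray(grid_min, dtype=float)
    num = np.asarray(tumor(t), dtype=float)
    den = np.asarray(reference(t), dtype=float)
    if np.any(den <= 0):
        bad = t[np.argmax(den <= 0)]
        raise ValueError(f"reference curve is non-positive on the evaluation grid (first at t = {bad:.3f} min)")
    return t, num / den


# ---------------------------------------------------------------------------
# cohort I/O

TAC_COLUMNS = ["subject_id", "region", "protocol", "frame_start_s", "frame_duration_s", "suv_mean"]
LABEL_COLUMNS = ["subject_id", "idh_mutant"]


def write_cohort(records: Iterable[SubjectRecord], tac_path, label_path) -> None:
    """Write a cohort as two delimited-text files (TAC rows + labels)."""
    rows = []
    labels = []
    for rec in records:
        labels.append({"subject_id": rec.subject_id, "idh_mutant": int(rec.idh_mutant)})
        for (region, protocol), tac in sorted(rec.tacs.items()):
            for start, dur, value in zip(tac.schedule.frame_start, tac.schedule.frame_duration, tac.values):
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "region": region,
                        "protocol": protocol,
                        "frame_start_s": start,
                        "frame_duration_s": dur,
                        "suv_mean": value,
                    }
                )
    pd.DataFrame(rows, columns=TAC_COLUMNS).to_csv(tac_path, index=False)
    pd.DataFrame(labels, columns=LABEL_COLUMNS).to_csv(label_path, index=False)


def read_cohort(tac_path, label_path) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort`.

    Frame rows may appear in any order on disk; each (subject, region,
    protocol) group is sorted by frame start before the schedule is
    validated.  Errors name the offending subject/row.
    """
    tac_df = pd.read_csv(tac_path)
    label_df = pd.read_csv(label_path)

    missing = [c for c in TAC_COLUMNS if c not in tac_df.columns and c != "protocol"]
    if missing:
        raise ValueError(f"cohort TAC file is missing required columns: {missing}")
    if any(c not in label_df.columns for c in LABEL_COLUMNS):
        raise ValueError(f"label file must have columns {LABEL_COLUMNS}")
    has_protocol = "protocol" in tac_df.columns

    bad_region = ~tac_df["region"].isin(REGIONS)
    if bad_region.any():
        row = tac_df.index[bad_region][0]
        raise ValueError(f"row {row}: unknown region {tac_df.loc[row, 'region']!r}")

    key_cols = ["subject_id", "region", "frame_start_s", "frame_duration_s"]
    if has_protocol:
        key_cols.insert(2, "protocol")
    dup = tac_df.duplicated(subset=key_cols)
    if dup.any():
        row = tac_df.index[dup][0]
        raise ValueError(f"duplicate frame key at row {row}: {tac_df.loc[row, key_cols].to_dict()}")

    labels: Mapping[str, bool] = {
        str(r.subject_id): bool(r.idh_mutant) for r in label_df.itertuples(index=False)
    }

    records = []
    group_cols = ["subject_id", "region", "protocol"] if has_protocol else ["subject_id", "region"]
    for subject_id, sub_df in tac_df.groupby("subject_id", sort=True):
        subject_id = str(subject_id)
        if subject_id not in labels:
            raise ValueError(f"subject {subject_id!r} has TAC rows but no label row")
        tacs = {}
        for keys, grp in sub_df.groupby(group_cols[1:], sort=True):
            region = keys[0] if isinstance(keys, tuple) else keys
            grp = grp.sort_values("frame_start_s")
            try:
                schedule = FrameSchedule(
                    grp["frame_start_s"].to_numpy(), grp["frame_duration_s"].to_numpy()
                )
            except ValueError as exc:
                raise ValueError(f"subject {subject_id!r}, region {region!r}: {exc}") from exc
            if has_protocol:
                protocol = keys[1]
                if protocol not in PROTOCOLS:
                    raise ValueError(f"subject {subject_id!r}: unknown protocol {protocol!r}")
            else:
                protocol = _infer_protocol(schedule)
                if protocol is None:
                    raise ValueError(
                        f"subject {subject_id!r}, region {region!r}: frame grid matches neither "
                        "built-in protocol and no protocol column is present"
                    )
            tacs[(region, protocol)] = TAC(schedule, grp["suv_mean"].to_numpy(), region)
        if not any(region == REGION_TUMOR for region, _ in tacs):
            raise ValueError(f"subject {subject_id!r} is missing the tumor region")
        records.append(SubjectRecord(subject_id, labels[subject_id], tacs))
    return records
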