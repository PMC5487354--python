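"""Trial-level 3D trajectory container and plain-text I/O.

A :class:`TrajectorySeries` holds one trial's index-finger positions sampled
at a uniform rate, together with named event timestamps (stimulus onset,
home-key release/return, addressee events).  Coordinates follow the task
frame: x lateral (positive rightward from the communicator), y depth
(positive toward the screen), z altitude (positive up); origin at the
home-key; units are meters and seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical event names recognized throughout the pipeline
EVENT_NAMES = (
    "stimulus",
    "home_release",
    "home_return",
    "addressee_release",
    "addressee_select",
)


class TooShortError(ValueError):
    """Series has too few samples for the requested operation."""


@dataclass
class TrajectorySeries:
    """One trial's timestamped 3D positions plus event marks.

    Parameters
    ----------
    time:
        Strictly increasing sample times in seconds, uniformly spaced at
        ``sampling_rate`` (checked to a relative tolerance of 1e-3).
    position:
        ``(n, 3)`` array of x/y/z positions in meters.
    sampling_rate:
        Declared sampling rate in Hz.
    events:
        Mapping of event name to timestamp (seconds, same clock as ``time``).
    """

    time: np.ndarray
    position: np.ndarray
    sampling_rate: float
    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.time.ndim != 1:
            raise ValueError("time must be one-dimensional")
        if self.position.shape != (self.time.size, 3):
            raise ValueError(
                f"position must have shape (n, 3); got {self.position.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            nominal = 1.0 / self.sampling_rate
            if np.any(np.abs(dt - nominal) > 1e-3 * nominal):
                raise ValueError("time must be uniformly sampled at sampling_rate")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def with_position(self, position: np.ndarray) -> "TrajectorySeries":
        """Return a copy with positions replaced (events untouched)."""
        return replace(self, position=np.asarray(position, dtype=float))

    def index_at(self, t: float) -> int:
        """Index of the first sample at or after time ``t``."""
        return int(np.searchsorted(self.time, t - 1e-12))


# ---------------------------------------------------------------------------
# Long-form delimited text I/O
# ---------------------------------------------------------------------------

_HEADER = (
    "# pointkin trajectory file\n"
    "# columns: trial_id,time_s,x_m,y_m,z_m\n"
    "# units: seconds, meters; frame: x lateral, y depth, z altitude\n"
)


def write_trajectories(
    path,
    trials: dict[str, TrajectorySeries],
) -> None:
    """Write trials to one long-form delimited text file.

    The format is CSV with ``#`` comment lines declaring units, one row per
    sample: ``trial_id,time_s,x_m,y_m,z_m``.  Event marks are not stored
    here; they live in the trial table.
    """
    frames = []
    rate = None
    for trial_id, series in trials.items():
        rate = series.sampling_rate
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": trial_id,
                    "time_s": series.time,
                    "x_m": series.position[:, 0],
                    "y_m": series.position[:, 1],
                    "z_m": series.position[:, 2],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write(f"# sampling_rate_hz: {rate}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trajectories(
    path,
    events: dict[str, dict[str, float]] | None = None,
) -> dict[str, TrajectorySeries]:
    """Read a long-form trajectory file written by :func:`write_trajectories`.

    Comment lines (``#``) are tolerated anywhere before the header row.
    ``events`` optionally maps trial_id -> event dict to attach.
    """
    rate = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# sampling_rate_hz:"):
                rate = float(line.split(":", 1)[1])
            elif not line.startswith("#"):
                break
    df = pd.read_csv(
        path, comment="#", dtype={"trial_id": str}, float_precision="round_trip"
    )
    out: dict[str, TrajectorySeries] = {}
    for trial_id, grp in df.groupby("trial_id", sort=False):
        t = grp["time_s"].to_numpy()
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(t)))
        out[trial_id] = TrajectorySeries(
            time=t,
            position=grp[["x_m", "y_m", "z_m"]].to_numpy(),
            sampling_rate=rate,
            events=dict(events.get(trial_id, {})) if events else {},
        )
    return out
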