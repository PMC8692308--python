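"""Beat-to-beat RR-interval series container and plain-text file I/O.

The on-disk format is one interval in milliseconds per line (UTF-8,
``#`` comment lines allowed).  A Polar-HRM-style dialect is supported in
which intervals follow an ``[HRData]`` section marker, as exported by
Polar heart-rate monitors in R-R recording mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RRSeries", "read_rr_file", "write_rr_file", "RRFileError"]


class RRFileError(ValueError):
    """Raised for malformed or empty RR-interval files."""


@dataclass(frozen=True)
class RRSeries:
    """A sequence of successive RR intervals in milliseconds.

    Parameters
    ----------
    intervals
        Beat-to-beat intervals, ms.  All values must be strictly positive.
    subject, condition, context
        Optional recording metadata (e.g. subject id, supplementation
        condition PP/PC/CC, recording context such as ``tt_final``).
    """

    intervals: np.ndarray
    subject: str | None = None
    condition: str | None = None
    context: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if arr.size and not np.all(arr > 0):
            raise ValueError("all RR intervals must be strictly positive")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def beat_times(self) -> np.ndarray:
        """Beat occurrence times in seconds; the first beat is at t = 0.

        ``beat_times[i]`` is the cumulative sum of the preceding
        intervals, so the series of beat times is strictly increasing.
        """
        t = np.empty(len(self), dtype=float)
        if len(self):
            t[0] = 0.0
            np.cumsum(self.intervals[:-1] / 1000.0, out=t[1:])
        return t

    @property
    def duration_s(self) -> float:
        """Total recorded time: the sum of all intervals, seconds."""
        return float(self.intervals.sum() / 1000.0)

    def slice(self, start: int, stop: int) -> "RRSeries":
        """Contiguous sub-series ``[start, stop)`` keeping metadata."""
        return replace(self, intervals=self.intervals[start:stop])


def write_rr_file(series: RRSeries, path: str | Path, *, hrm: bool = False) -> None:
    """Write an RR series as text, one interval (ms) per line.

    With ``hrm=True`` a minimal Polar-HRM-style layout is produced: a
    ``[Params]`` section followed by the intervals under ``[HRData]``.
    """
    path = Path(path)
    lines: list[str] = []
    if hrm:
        lines.append("[Params]")
        lines.append("Mode=3 0 0 0")  # R-R recording mode
        if series.subject is not None:
            lines.append(f"Note={series.subject}")
        lines.append("")
        lines.append("[HRData]")
    else:
        meta = [
            f"# {k}: {v}"
            for k, v in (
                ("subject", series.subject),
                ("condition", series.condition),
                ("context", series.context),
            )
            if v is not None
        ]
        lines.extend(meta)
    fmt = "%d" if np.allclose(series.intervals, np.round(series.intervals)) else "%.3f"
    lines.extend(fmt % v for v in series.intervals)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rr_file(
    path: str | Path,
    *,
    subject: str | None = None,
    condition: str | None = None,
    context: str | None = None,
) -> RRSeries:
    """Read an RR-interval text file.

    Accepts the plain dialect (one ms value per line, ``#`` comments)
    and the Polar-HRM dialect: if an ``[HRData]`` marker is present only
    lines after it are parsed as intervals; any other ``[Section]``
    lines are ignored.

    Raises
    ------
    RRFileError
        On an empty file or a non-numeric data line (the message names
        the 1-based line number).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    in_hrdata = any(ln.strip().lower() == "[hrdata]" for ln in lines)
    active = not in_hrdata  # HRM dialect: parse only after the marker
    values: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            active = line.lower() == "[hrdata]"
            continue
        if not active:
            continue
        if in_hrdata and "=" in line:
            continue  # section key=value pairs
        try:
            # HRM files may carry extra columns; the RR interval is first
            values.append(float(line.split()[0]))
        except ValueError:
            raise RRFileError(
                f"{path}: non-numeric RR value on line {lineno}: {line!r}"
            ) from None
    if not values:
        raise RRFileError(f"{path}: no RR intervals found (empty input)")
    return RRSeries(
        np.asarray(values), subject=subject, condition=condition, context=context
    )
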