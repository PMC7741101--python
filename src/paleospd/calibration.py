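"""Radiocarbon calibration against an IntCal-style curve.

A radiocarbon determination (an uncalibrated ¹⁴C age with a 1σ measurement
error) is mapped onto the calendar scale by evaluating, for every calendar
year t on an annual grid, the Normal likelihood of the measured age given
the curve mean μ(t) and the combined error √(σ_meas² + σ_curve(t)²).  The
resulting per-year masses form a :class:`CalibratedDensity`; highest-density
regions of that density drive the study-window overlap filter.

All calendar ages are integer years cal BP (before AD 1950), with BP
increasing into the past.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
from scipy.stats import norm

__all__ = [
    "CalendarWindow",
    "CalibrationCurve",
    "RadiocarbonDetermination",
    "CalibratedDensity",
    "CalibrationError",
    "CurveParseError",
    "read_calibration_curve",
    "interpolate_curve",
    "calibrate",
    "hpd_region",
    "overlaps_window",
]


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs (bad curve, off-curve date...)."""


class CurveParseError(CalibrationError):
    """Raised when a calibration-curve file cannot be parsed."""


@dataclass(frozen=True, order=True)
class CalendarWindow:
    """Closed interval of calendar years, bounds in cal BP.

    ``start_bp`` is the older (larger) bound, ``end_bp`` the younger one;
    both are inclusive, so the window 1750–150 BP contains 1750 and 150.
    """

    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < self.end_bp:
            raise ValueError(
                f"start_bp ({self.start_bp}) must be >= end_bp ({self.end_bp})"
            )

    @property
    def n_years(self) -> int:
        return self.start_bp - self.end_bp + 1

    def contains(self, year_bp: int) -> bool:
        return self.end_bp <= year_bp <= self.start_bp

    def intersects(self, other: "CalendarWindow") -> bool:
        """Closed-interval intersection: shared endpoints count."""
        return max(self.end_bp, other.end_bp) <= min(self.start_bp, other.start_bp)


@dataclass
class CalibrationCurve:
    """Gridded mapping from calendar age (cal BP) to ¹⁴C age with 1σ error.

    The grid is canonicalized to strictly increasing cal BP on construction.
    """

    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma_curve: np.ndarray
    name: str = "curve"

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.sigma_curve = np.asarray(self.sigma_curve, dtype=float)
        n = self.cal_bp.size
        if not (self.c14_age.size == n and self.sigma_curve.size == n):
            raise CalibrationError("curve arrays must have equal length")
        if n < 2:
            raise CalibrationError("calibration curve needs at least 2 grid points")
        d = np.diff(self.cal_bp)
        if np.all(d < 0):  # decreasing on disk (IntCal convention) -> flip
            self.cal_bp = self.cal_bp[::-1].copy()
            self.c14_age = self.c14_age[::-1].copy()
            self.sigma_curve = self.sigma_curve[::-1].copy()
        elif not np.all(d > 0):
            raise CalibrationError("cal_bp grid must be strictly monotone")
        if np.any(self.sigma_curve < 0):
            raise CalibrationError("sigma_curve must be non-negative")

    @property
    def is_annual(self) -> bool:
        return bool(np.all(np.diff(self.cal_bp) == 1))

    @property
    def span(self) -> CalendarWindow:
        return CalendarWindow(int(self.cal_bp[-1]), int(self.cal_bp[0]))

    def mu_sigma_at(self, cal_bp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated curve mean and 1σ error at given cal BP years."""
        cal_bp = np.asarray(cal_bp, dtype=float)
        lo, hi = self.cal_bp[0], self.cal_bp[-1]
        if np.any(cal_bp < lo) or np.any(cal_bp > hi):
            raise CalibrationError(
                f"requested years outside curve span [{lo}, {hi}] cal BP"
            )
        mu = np.interp(cal_bp, self.cal_bp, self.c14_age)
        sig = np.interp(cal_bp, self.cal_bp, self.sigma_curve)
        return mu, sig


def identity_curve(
    start_bp: int, end_bp: int, sigma_curve: float = 0.0, name: str = "identity"
) -> CalibrationCurve:
    """Annual curve with μ(t) = t: ¹⁴C age equals calendar age exactly.

    Useful as a neutral reference: calibration against it collapses to the
    measurement density itself.
    """
    grid = np.arange(min(start_bp, end_bp), max(start_bp, end_bp) + 1)
    return CalibrationCurve(
        cal_bp=grid,
        c14_age=grid.astype(float),
        sigma_curve=np.full(grid.size, float(sigma_curve)),
        name=name,
    )


@dataclass(frozen=True)
class RadiocarbonDetermination:
    """One laboratory ¹⁴C measurement: uncalibrated age BP and 1σ error."""

    c14_age: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.c14_age):
            raise ValueError("c14_age must be finite")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")


@dataclass
class CalibratedDensity:
    """Discrete probability mass over a contiguous annual calendar grid.

    ``grid`` holds integer cal BP years in increasing order; ``mass[i]`` is
    the probability (or unnormalized density) assigned to ``grid[i]``.
    """

    grid: np.ndarray
    mass: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.size != self.mass.size:
            raise ValueError("grid and mass must have equal length")
        if self.grid.size == 0:
            raise ValueError("empty density")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) == 1):
            raise ValueError("grid must be annual and contiguous")
        if np.any(self.mass < 0):
            raise ValueError("mass must be non-negative")

    @property
    def total(self) -> float:
        return float(self.mass.sum())

    @property
    def is_normalized(self) -> bool:
        return abs(self.total - 1.0) <= 1e-6

    def argmax_bp(self) -> int:
        """Grid year of maximum mass (ties broken toward the older year)."""
        m = self.mass.max()
        return int(self.grid[np.nonzero(self.mass == m)[0][-1]])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"cal_bp": self.grid, "mass": self.mass})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


_Source = Union[str, Path, TextIO]


def _open_lines(source: _Source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r") as fh:
            yield from fh
    else:
        yield from source


def read_calibration_curve(source: _Source, dialect: str = "intcal") -> CalibrationCurve:
    """Parse an IntCal-style curve file into a :class:`CalibrationCurve`.

    Both dialects hold at least three numeric columns (cal BP, ¹⁴C age BP,
    1σ error), comma- or whitespace-separated; ``#`` lines are comments and
    extra columns are ignored.  Duplicate cal BP rows are rejected.
    """
    if dialect not in ("intcal", "plain"):
        raise ValueError(f"unknown curve dialect: {dialect!r}")
    name = source if isinstance(source, str) else getattr(source, "name", "curve")
    cal, age, sig = [], [], []
    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"[,\s]+", line)
        if len(fields) < 3:
            raise CurveParseError(f"line {lineno}: expected >= 3 columns, got {len(fields)}")
        try:
            vals = [float(fields[i]) for i in range(3)]
        except ValueError as exc:
            raise CurveParseError(f"line {lineno}: non-numeric field ({exc})") from None
        cal.append(vals[0])
        age.append(vals[1])
        sig.append(vals[2])
    if len(cal) < 2:
        raise CurveParseError("insufficient curve: fewer than 2 data rows")
    cal_arr = np.asarray(cal)
    if np.unique(cal_arr).size != cal_arr.size:
        dupes = cal_arr[np.nonzero(np.diff(np.sort(cal_arr)) == 0)[0]]
        raise CurveParseError(f"duplicate cal_bp rows: {sorted(set(dupes.tolist()))}")
    order = np.argsort(cal_arr)
    return CalibrationCurve(
        cal_bp=cal_arr[order],
        c14_age=np.asarray(age)[order],
        sigma_curve=np.asarray(sig)[order],
        name=str(Path(name).name) if isinstance(name, (str, Path)) else "curve",
    )


def interpolate_curve(curve: CalibrationCurve, resolution: int = 1) -> CalibrationCurve:
    """Linearly interpolate the curve onto a regular (default annual) grid.

    Endpoints of the input span are preserved exactly; an input already on
    the requested grid is returned unchanged.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1 year")
    span = curve.cal_bp[-1] - curve.cal_bp[0]
    if resolution > span:
        raise CalibrationError(
            f"resolution {resolution} coarser than curve span {span:g} years"
        )
    grid = np.arange(curve.cal_bp[0], curve.cal_bp[-1] + 1, resolution)
    if grid.size == curve.cal_bp.size and np.array_equal(grid, curve.cal_bp):
        return curve
    return CalibrationCurve(
        cal_bp=grid,
        c14_age=np.interp(grid, curve.cal_bp, curve.c14_age),
        sigma_curve=np.interp(grid, curve.cal_bp, curve.sigma_curve),
        name=curve.name,
    )


#: calibrated mass outside this cumulative fraction is trimmed from each tail
TAIL_TRIM = 5e-7


def calibrate(
    det: RadiocarbonDetermination,
    curve: CalibrationCurve,
    normalize: bool = True,
) -> CalibratedDensity:
    """Calibrate one determination against an annual-grid curve.

    For each grid year t the mass is the Normal density of ``det.c14_age``
    with mean μ(t) and standard deviation √(det.sigma² + σ_curve(t)²).
    The support is trimmed where the two cumulative tails each hold less
    than 5e-7 of the total (so ≥ 1 − 1e-6 of the mass is kept; the trim
    bounds are recorded in ``meta``).  With ``normalize`` the trimmed
    density is rescaled to sum to exactly 1; otherwise the raw per-year
    Normal density values are kept.
    """
    if not curve.is_annual:
        raise CalibrationError("curve must be interpolated to an annual grid first")
    tau = np.sqrt(det.sigma**2 + curve.sigma_curve**2)
    z = np.abs(det.c14_age - curve.c14_age) / tau
    if z.min() > 10.0:
        raise CalibrationError(
            f"determination {det.c14_age}±{det.sigma} lies >10 combined sigma "
            f"outside curve {curve.name!r} everywhere"
        )
    dens = norm.pdf(det.c14_age, loc=curve.c14_age, scale=tau)
    total = dens.sum()
    if total <= 0:
        raise CalibrationError("calibrated density vanished (curve too far from date)")
    frac = dens / total
    csum = np.cumsum(frac)
    lo = int(np.searchsorted(csum, TAIL_TRIM, side="right"))
    hi = int(np.searchsorted(csum, 1.0 - TAIL_TRIM, side="left"))
    lo = min(lo, hi)  # degenerate guard
    grid = curve.cal_bp[lo : hi + 1].astype(int)
    mass = (frac if normalize else dens)[lo : hi + 1].copy()
    if normalize:
        mass /= mass.sum()
    meta = {
        "normalized": normalize,
        "trimmed_to": (int(grid[0]), int(grid[-1])),
        "curve": curve.name,
        "c14_age": float(det.c14_age),
        "sigma": float(det.sigma),
    }
    return CalibratedDensity(grid=grid, mass=mass, meta=meta)


def hpd_region(density: CalibratedDensity, level: float = 0.95) -> list[CalendarWindow]:
    """Highest-density region of a normalized calibrated density.

    Returns the smallest set of grid years (selected by descending mass,
    ties broken toward older years) whose cumulative mass reaches ``level``,
    merged into maximal contiguous :class:`CalendarWindow` intervals and
    ordered oldest first.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if not density.is_normalized:
        raise CalibrationError("hpd_region requires a normalized density")
    # stable sort on (-mass, -grid year): heavier first, older wins ties
    order = np.lexsort((-density.grid, -density.mass))
    csum = np.cumsum(density.mass[order])
    k = int(np.searchsorted(csum, level - 1e-12, side="left")) + 1
    years = np.sort(density.grid[order[:k]])
    windows: list[CalendarWindow] = []
    start = prev = int(years[0])
    for y in years[1:]:
        y = int(y)
        if y == prev + 1:
            prev = y
        else:
            windows.append(CalendarWindow(start_bp=prev, end_bp=start))
            start = prev = y
    windows.append(CalendarWindow(start_bp=prev, end_bp=start))
    windows.sort(key=lambda w: -w.start_bp)
    return windows


def overlaps_window(region: Sequence[CalendarWindow], window: CalendarWindow) -> bool:
    """True iff any interval of ``region`` intersects ``window`` (closed)."""
    return any(w.intersects(window) for w in region)
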