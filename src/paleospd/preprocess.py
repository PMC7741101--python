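"""Cleaning and harmonization of radiocarbon and tree-ring date tables.

Implements the dates-as-data hygiene rules used to prepare the two
chronometric archives for summed-probability analysis:

* radiocarbon: drop non-archaeological dates, imprecise dates (1σ error
  over 300 ¹⁴C years or over 25% of the uncalibrated age), conflicting
  duplicate laboratory numbers, out-of-area counties, and dates whose 95%
  calibrated mass misses the study window;
* tree-ring: keep only cutting and near-cutting dates, in-area counties,
  and dates inside the study window.

Every filter run produces a :class:`FilterReport` audit trail whose counts
always reconcile with the input size.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .calibration import (
    CalendarWindow,
    CalibrationCurve,
    RadiocarbonDetermination,
    calibrate,
    hpd_region,
    interpolate_curve,
    overlaps_window,
)

log = logging.getLogger(__name__)

__all__ = [
    "RadiocarbonRecord",
    "TreeRingRecord",
    "FilterReport",
    "RegionConfig",
    "ad_to_bp",
    "bp_to_ad",
    "classify_treering_symbol",
    "normalize_county",
    "filter_radiocarbon",
    "filter_treering",
    "assign_region",
    "DEFAULT_REGIONS",
    "DEFAULT_STUDY_WINDOW",
    "DEFAULT_PERIOD_AD",
]


def ad_to_bp(year_ad: int) -> int:
    """Calendar year AD -> cal BP (years before AD 1950).

    Uses astronomical year numbering for BC dates (year 0 exists), so
    AD 201 -> 1749 BP and 1 BC (= year 0) -> 1950 BP.
    """
    return 1950 - year_ad


def bp_to_ad(year_bp: int) -> int:
    """Inverse of :func:`ad_to_bp`."""
    return 1950 - year_bp


#: outer-ring symbols marking the year the tree died exactly
CUTTING_SYMBOLS = frozenset("BGLcr")
#: symbols within 0-3 years of the true outer-ring date
NEAR_CUTTING_SYMBOLS = frozenset({"v", "v+"})


def classify_treering_symbol(symbol: str) -> str:
    """Classify a tree-ring date symbol as cutting / near_cutting / other.

    Cutting symbols are 'B', 'G', 'L', 'c' or 'r', with or without a
    trailing '+'; near-cutting symbols are 'v' and 'v+'.  Every string
    maps to exactly one class (unknown symbols are 'other').
    """
    s = symbol.strip()
    if s in NEAR_CUTTING_SYMBOLS:
        return "near_cutting"
    base = s[:-1] if s.endswith("+") else s
    if base in CUTTING_SYMBOLS:
        return "cutting"
    return "other"


_COUNTY_RE = re.compile(r"^\s*(?P<county>[^,]+?)\s*,\s*(?P<state>[A-Za-z]{2})\s*$")


def normalize_county(county: str) -> Optional[str]:
    """Canonicalize a "County, ST" string for deterministic joins.

    Whitespace is collapsed, the county name case-folded and the two-letter
    state suffix upper-cased.  Strings without a state suffix are invalid
    and return None.
    """
    if not county:
        return None
    m = _COUNTY_RE.match(county)
    if m is None:
        return None
    name = re.sub(r"\s+", " ", m.group("county")).casefold()
    return f"{name}, {m.group('state').upper()}"


@dataclass(frozen=True)
class RadiocarbonRecord:
    """One laboratory determination with provenance fields."""

    lab_number: str
    site_id: str
    county: str
    c14_age: float
    sigma: float
    is_archaeological: bool = True

    def __post_init__(self) -> None:
        if not self.lab_number:
            raise ValueError("lab_number must be non-empty")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")

    @property
    def determination(self) -> RadiocarbonDetermination:
        return RadiocarbonDetermination(self.c14_age, self.sigma)


@dataclass(frozen=True)
class TreeRingRecord:
    """One dated tree-ring specimen."""

    site_id: str
    county: str
    year_ad: int
    symbol: str

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("symbol must be non-empty")

    @property
    def year_bp(self) -> int:
        return ad_to_bp(self.year_ad)


#: study window 1750-150 cal BP (AD 200-1800)
DEFAULT_STUDY_WINDOW = CalendarWindow(start_bp=1750, end_bp=150)
DEFAULT_PERIOD_AD = (200, 1800)

# Region -> county roster.  CMV conforms to Montezuma county, CO; the NRG
# overlaps five New Mexico counties; the UUSW roster is the full study-area
# county list (a superset of both) and is configuration, not inference.
DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "UUSW": (
        "Montezuma, CO",
        "La Plata, CO",
        "Dolores, CO",
        "Los Alamos, NM",
        "Rio Arriba, NM",
        "Sandoval, NM",
        "Santa Fe, NM",
        "Taos, NM",
        "San Juan, NM",
        "McKinley, NM",
        "Cibola, NM",
        "Apache, AZ",
        "Navajo, AZ",
        "Coconino, AZ",
    ),
    "CMV": ("Montezuma, CO",),
    "NRG": (
        "Los Alamos, NM",
        "Rio Arriba, NM",
        "Sandoval, NM",
        "Santa Fe, NM",
        "Taos, NM",
    ),
}


@dataclass
class RegionConfig:
    """Study-area configuration: named regions as county rosters."""

    regions: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    study_window: CalendarWindow = DEFAULT_STUDY_WINDOW
    period_ad: tuple[int, int] = DEFAULT_PERIOD_AD

    def __post_init__(self) -> None:
        norm: dict[str, frozenset[str]] = {}
        for region, counties in self.regions.items():
            if not counties:
                raise ValueError(f"region {region!r} has an empty county list")
            keys = set()
            for c in counties:
                key = normalize_county(c)
                if key is None:
                    raise ValueError(f"region {region!r}: bad county string {c!r}")
                keys.add(key)
            norm[region] = frozenset(keys)
        self._normalized = norm
        self._study_counties = frozenset().union(*norm.values())

    def region_counties(self, region: str) -> frozenset[str]:
        return self._normalized[region]

    @property
    def study_counties(self) -> frozenset[str]:
        """Union of all region rosters: the full study-area county list."""
        return self._study_counties


Record = Union[RadiocarbonRecord, TreeRingRecord]


def assign_region(record: Record, config: RegionConfig) -> set[str]:
    """Region names whose county roster contains the record's county.

    Regions may nest (a Montezuma, CO date belongs to both UUSW and CMV).
    An unknown or malformed county belongs to no region; a warning is logged.
    """
    key = normalize_county(record.county)
    if key is None:
        log.warning("unparseable county %r; record assigned to no region", record.county)
        return set()
    out = {r for r, counties in config._normalized.items() if key in counties}
    if not out:
        log.warning("county %r outside all configured regions", record.county)
    return out


@dataclass
class FilterReport:
    """Audit trail of one filter run: removals per rule, in order applied."""

    n_input: int
    removed: dict[str, int]
    deduplicated: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_retained + sum(self.removed.values()) + self.deduplicated != self.n_input:
            raise ValueError("filter report does not conserve record counts")
        if self.n_input < 0 or self.n_retained < 0 or self.deduplicated < 0:
            raise ValueError("negative counts in filter report")
        if any(v < 0 for v in self.removed.values()):
            raise ValueError("negative removal count")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "deduplicated": self.deduplicated,
            "n_retained": self.n_retained,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _error_rule_hits(rec: RadiocarbonRecord, mode: str) -> bool:
    absolute = rec.sigma > 300.0
    relative = rec.sigma > 0.25 * rec.c14_age
    if mode == "either":
        return absolute or relative
    if mode == "both":
        return absolute and relative
    raise ValueError(f"error_rule must be 'either' or 'both', got {mode!r}")


def filter_radiocarbon(
    records: Sequence[RadiocarbonRecord],
    curve: CalibrationCurve,
    config: RegionConfig,
    error_rule: str = "either",
    hpd_level: float = 0.95,
) -> tuple[list[RadiocarbonRecord], FilterReport]:
    """Apply the radiocarbon cleaning rules in their fixed order.

    Order: non-archaeological -> error thresholds -> duplicate-lab handling
    -> county trim -> calibrated-window overlap.  Duplicate lab numbers with
    fully matching (age, sigma, county) collapse to one record (counted as
    deduplicated); any mismatch removes every record bearing that number.
    """
    n_input = len(records)
    removed = {
        "non_archaeological": 0,
        "error_threshold": 0,
        "duplicate_conflict": 0,
        "county": 0,
        "window_overlap": 0,
    }
    stage = [r for r in records if r.is_archaeological]
    removed["non_archaeological"] = n_input - len(stage)

    kept = [r for r in stage if not _error_rule_hits(r, error_rule)]
    removed["error_threshold"] = len(stage) - len(kept)
    stage = kept

    by_lab: dict[str, list[RadiocarbonRecord]] = {}
    for r in stage:
        by_lab.setdefault(r.lab_number, []).append(r)
    deduplicated = 0
    kept = []
    # iterate in input order so output order is stable
    seen: set[str] = set()
    for r in stage:
        if r.lab_number in seen:
            continue
        seen.add(r.lab_number)
        group = by_lab[r.lab_number]
        sigs = {(g.c14_age, g.sigma, normalize_county(g.county)) for g in group}
        if len(sigs) == 1:
            # order-independent representative so permuting input is a no-op
            rep = min(group, key=lambda g: (g.site_id, g.county, g.c14_age, g.sigma))
            kept.append(rep)
            deduplicated += len(group) - 1
        else:
            removed["duplicate_conflict"] += len(group)
    stage = kept

    kept = [r for r in stage if normalize_county(r.county) in config.study_counties]
    removed["county"] = len(stage) - len(kept)
    stage = kept

    annual = interpolate_curve(curve)
    kept = []
    for r in stage:
        density = calibrate(r.determination, annual)
        region = hpd_region(density, level=hpd_level)
        if overlaps_window(region, config.study_window):
            kept.append(r)
    removed["window_overlap"] = len(stage) - len(kept)

    report = FilterReport(
        n_input=n_input,
        removed=removed,
        deduplicated=deduplicated,
        n_retained=len(kept),
    )
    for rule, n in removed.items():
        log.info("radiocarbon filter %-18s removed %d", rule, n)
    return kept, report


def filter_treering(
    records: Sequence[TreeRingRecord],
    config: RegionConfig,
) -> tuple[list[TreeRingRecord], FilterReport]:
    """Apply the tree-ring cleaning rules: symbol -> county -> window."""
    n_input = len(records)
    removed = {"symbol": 0, "county": 0, "window": 0}

    stage = [r for r in records if classify_treering_symbol(r.symbol) != "other"]
    removed["symbol"] = n_input - len(stage)

    kept = [r for r in stage if normalize_county(r.county) in config.study_counties]
    removed["county"] = len(stage) - len(kept)
    stage = kept

    win = config.study_window
    kept = [r for r in stage if win.contains(r.year_bp)]
    removed["window"] = len(stage) - len(kept)

    report = FilterReport(
        n_input=n_input, removed=removed, deduplicated=0, n_retained=len(kept)
    )
    for rule, n in removed.items():
        log.info("tree-ring filter %-8s removed %d", rule, n)
    return kept, report
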