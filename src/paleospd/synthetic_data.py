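"""Synthetic date archives with known demographic truth.

The generator adopts the dates-as-data premise as its simulation law:
datable events are deposited in proportion to population size.  A
boom-bust trajectory (rise to a peak near AD 1300, then sustained
decline) emulates the demographic history the pipeline is meant to
recover; events are turned into radiocarbon determinations by inverting
calibration against a chosen curve (identity or "wiggly", the latter
mimicking plateaus and cliffs in real curves) and into tree-ring records
with cutting or near-cutting symbols (near-cutting dates sit 0-3 years
before the true event year).

``generate_study`` additionally injects contaminants — over-error dates,
duplicate laboratory numbers, out-of-area counties, non-cutting symbols,
out-of-window dates — at exactly known counts, so filter audit trails
have exact expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .binning_spd import PopulationSeries
from .calibration import CalendarWindow, CalibrationCurve, identity_curve
from .preprocess import (
    DEFAULT_REGIONS,
    RadiocarbonRecord,
    RegionConfig,
    TreeRingRecord,
    ad_to_bp,
    classify_treering_symbol,
)

__all__ = [
    "PopulationModel",
    "SimulationConfig",
    "SyntheticStudy",
    "population_curve",
    "sample_event_years",
    "uncalibrate",
    "make_treering_records",
    "make_curve",
    "generate_study",
]

RngLike = Union[int, np.random.Generator]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class PopulationModel:
    """Parametric population trajectory used as simulation truth.

    boom_bust rises polynomially (degree ``rise_exponent``) from
    ``floor_level`` at ``rise_start_ad`` to ``peak_level`` at ``peak_ad``,
    then decays exponentially at ``decline_rate`` per year toward
    ``floor_level``.  The defaults give a sharply peaked trajectory —
    an accelerating build-up to the peak followed by a collapse that
    halves the population roughly every 46 years — the kind of history
    the ancestral Pueblo reconstructions describe.  ``constant`` holds
    ``peak_level`` everywhere; ``custom`` passes ``table`` through.
    """

    shape: str = "boom_bust"
    rise_start_ad: int = 600
    peak_ad: int = 1300
    peak_level: float = 10_000.0
    decline_rate: float = 0.015
    floor_level: float = 100.0
    rise_exponent: float = 3.0
    table: Optional[Sequence[tuple[int, int, float]]] = None

    def level(self, year_ad: np.ndarray) -> np.ndarray:
        year_ad = np.asarray(year_ad, dtype=float)
        if self.shape == "constant":
            return np.full(year_ad.shape, self.peak_level)
        if self.shape == "boom_bust":
            out = np.full(year_ad.shape, self.floor_level)
            rising = (year_ad > self.rise_start_ad) & (year_ad <= self.peak_ad)
            frac = (year_ad[rising] - self.rise_start_ad) / (
                self.peak_ad - self.rise_start_ad
            )
            out[rising] = (
                self.floor_level
                + (self.peak_level - self.floor_level) * frac**self.rise_exponent
            )
            falling = year_ad > self.peak_ad
            out[falling] = np.maximum(
                self.floor_level,
                self.peak_level * np.exp(-self.decline_rate * (year_ad[falling] - self.peak_ad)),
            )
            return out
        raise ValueError(f"unknown population model shape: {self.shape!r}")


def population_curve(model: PopulationModel, span: CalendarWindow) -> PopulationSeries:
    """Annual piecewise-constant truth series over a calendar window."""
    lo_ad = 1950 - span.start_bp
    hi_ad = 1950 - span.end_bp
    if model.shape == "custom":
        if model.table is None:
            raise ValueError("custom population model requires a table")
        return PopulationSeries(list(model.table))
    years = np.arange(lo_ad, hi_ad + 1)
    levels = model.level(years)
    return PopulationSeries([(int(y), int(y) + 1, float(v)) for y, v in zip(years, levels)])


def sample_event_years(pop: PopulationSeries, n: int, rng: RngLike) -> np.ndarray:
    """Draw event years AD i.i.d. with probability proportional to population."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = _as_rng(rng)
    years, vals = pop.annualize()
    total = vals.sum()
    if total <= 0:
        raise ValueError("population series is identically zero")
    return rng.choice(years, size=n, p=vals / total)


def uncalibrate(
    year_ad: int, curve: CalibrationCurve, sigma_meas: float, rng: RngLike
) -> tuple[int, float]:
    """Simulate a radiocarbon measurement of an event in ``year_ad``.

    The ¹⁴C age is drawn from Normal(μ(t), √(σ_meas² + σ_curve(t)²)) with
    t = 1950 − year_ad, then rounded to the integer year a laboratory
    would report; the recorded error is ``sigma_meas`` alone.
    """
    rng = _as_rng(rng)
    bp = ad_to_bp(year_ad)
    mu, sc = curve.mu_sigma_at(np.array([bp]))
    sd = float(np.sqrt(sigma_meas**2 + sc[0] ** 2))
    c14 = float(mu[0]) if sd == 0 else float(rng.normal(mu[0], sd))
    return int(round(c14)), float(sigma_meas)


def make_curve(
    kind: str = "identity",
    span_bp: tuple[int, int] = (-150, 2600),
    amplitude: float = 0.0,
    period: float = 500.0,
    sigma_curve: float = 0.0,
) -> CalibrationCurve:
    """Synthetic annual calibration curve.

    ``identity`` has μ(t) = t; ``wiggly`` adds A·sin(2πt/P) to mimic the
    plateaus and cliffs of real calibration curves.
    """
    lo, hi = min(span_bp), max(span_bp)
    grid = np.arange(lo, hi + 1)
    if kind == "identity":
        mu = grid.astype(float)
    elif kind == "wiggly":
        mu = grid + amplitude * np.sin(2 * np.pi * grid / period)
    else:
        raise ValueError(f"unknown curve kind: {kind!r}")
    return CalibrationCurve(
        cal_bp=grid,
        c14_age=mu,
        sigma_curve=np.full(grid.size, float(sigma_curve)),
        name=f"synthetic-{kind}",
    )


@dataclass
class SimulationConfig:
    """Knobs of one synthetic study; everything derives from ``seed``."""

    seed: int = 0
    n_radiocarbon: int = 500
    n_treering: int = 500
    n_sites: int = 150
    county_roster: tuple[str, ...] = DEFAULT_REGIONS["UUSW"]
    span_ad: tuple[int, int] = (600, 1600)
    population: PopulationModel = field(default_factory=PopulationModel)
    sigma_range: tuple[int, int] = (20, 60)
    symbol_mix: dict = field(
        default_factory=lambda: {"r": 0.45, "B": 0.15, "v": 0.30, "v+": 0.10}
    )
    near_cutting_offset: tuple[int, int] = (0, 3)
    curve_kind: str = "identity"
    curve_amplitude: float = 0.0
    curve_period: float = 500.0
    curve_sigma: float = 0.0
    # contaminant injection counts (exact, for filter audits)
    n_non_archaeological: int = 0
    n_sigma_outliers: int = 0
    n_duplicate_conflict_pairs: int = 0
    n_duplicate_matching_pairs: int = 0
    n_out_of_area: int = 0
    n_out_of_window: int = 0
    n_tr_noncutting: int = 0
    n_tr_out_of_area: int = 0
    n_tr_out_of_window: int = 0

    def __post_init__(self) -> None:
        if self.n_radiocarbon <= 0 or self.n_treering <= 0 or self.n_sites <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.near_cutting_offset
        if not (0 <= lo <= hi <= 3):
            raise ValueError("near-cutting offset range must lie within [0, 3]")
        if abs(sum(self.symbol_mix.values()) - 1.0) > 1e-9:
            raise ValueError("symbol mix must sum to 1")


@dataclass
class SyntheticStudy:
    """One generated study: tables, truth, curve, and audit expectations."""

    radiocarbon: list[RadiocarbonRecord]
    treering: list[TreeRingRecord]
    population: PopulationSeries
    curve: CalibrationCurve
    region_config: RegionConfig
    expected: dict
    config: SimulationConfig

    def write(self, outdir) -> dict:
        """Write the CSV dialects consumed by the pipeline; returns paths."""
        from pathlib import Path

        from . import io as pio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "radiocarbon": outdir / "radiocarbon.csv",
            "treering": outdir / "treering.csv",
            "population": outdir / "population.csv",
            "curve": outdir / "curve.txt",
        }
        pio.write_radiocarbon_csv(self.radiocarbon, paths["radiocarbon"])
        pio.write_treering_csv(self.treering, paths["treering"])
        pio.write_population_csv(self.population, paths["population"])
        pio.write_curve(self.curve, paths["curve"])
        return paths


def _site_roster(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    """(site_id, county) roster; counties drawn uniformly from the config."""
    counties = list(config.county_roster)
    idx = rng.integers(0, len(counties), size=config.n_sites)
    return [(f"S{i:04d}", counties[j]) for i, j in enumerate(idx)]


def make_treering_records(
    events: Sequence[int],
    config: SimulationConfig,
    rng: RngLike,
    sites: Optional[Sequence[tuple[str, str]]] = None,
) -> list[TreeRingRecord]:
    """Tree-ring records for event years, honouring the symbol mix.

    Cutting symbols date the event year exactly; near-cutting symbols are
    offset 0-3 years earlier (the dated ring predates the tree's death);
    'other' symbols, if present in the mix, get no offset — they exist to
    exercise the symbol filter.
    """
    rng = _as_rng(rng)
    if sites is None:
        sites = _site_roster(config, rng)
    symbols = list(config.symbol_mix)
    probs = np.array([config.symbol_mix[s] for s in symbols])
    lo, hi = config.near_cutting_offset
    records = []
    for year in events:
        sym = symbols[int(rng.choice(len(symbols), p=probs))]
        offset = int(rng.integers(lo, hi + 1)) if classify_treering_symbol(sym) == "near_cutting" else 0
        site_id, county = sites[int(rng.integers(0, len(sites)))]
        records.append(
            TreeRingRecord(
                site_id=site_id, county=county, year_ad=int(year) - offset, symbol=sym
            )
        )
    return records


def _clean_radiocarbon(
    events: Sequence[int],
    config: SimulationConfig,
    curve: CalibrationCurve,
    sites: Sequence[tuple[str, str]],
    rng: np.random.Generator,
    start_index: int = 0,
) -> list[RadiocarbonRecord]:
    """Records guaranteed to survive every cleaning rule.

    Measurement draws are rejection-sampled (deterministically from the
    rng stream) so sigma <= 0.25 * c14 and 150 <= c14 <= 1750 hold; this
    conditioning keeps the filter audit exact, because removals are then
    governed solely by the injected contaminants.
    """
    lo_s, hi_s = config.sigma_range
    out = []
    for k, year in enumerate(events):
        site_id, county = sites[int(rng.integers(0, len(sites)))]
        for _ in range(1000):
            sigma = float(rng.integers(lo_s, hi_s + 1))
            c14, _ = uncalibrate(int(year), curve, sigma, rng)
            if sigma <= 0.25 * c14 and 150 <= c14 <= 1750:
                break
        out.append(
            RadiocarbonRecord(
                lab_number=f"SYN-{start_index + k:05d}",
                site_id=site_id,
                county=county,
                c14_age=float(c14),
                sigma=sigma,
            )
        )
    return out


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a fully reproducible synthetic study from ``config.seed``.

    Contaminants are appended at exactly the configured counts and each is
    constructed to fail precisely one cleaning rule (the first one it
    reaches), so the returned ``expected`` dict gives the exact per-rule
    removal counts a filter audit must report.
    """
    rng = np.random.default_rng(config.seed)
    curve = make_curve(
        config.curve_kind,
        amplitude=config.curve_amplitude,
        period=config.curve_period,
        sigma_curve=config.curve_sigma,
    )
    lo_ad, hi_ad = config.span_ad
    span = CalendarWindow(start_bp=ad_to_bp(lo_ad), end_bp=ad_to_bp(hi_ad))
    pop = population_curve(config.population, span)
    sites = _site_roster(config, rng)
    in_area = [s for s in sites]

    rc_events = sample_event_years(pop, config.n_radiocarbon, rng)
    tr_events = sample_event_years(pop, config.n_treering, rng)

    radiocarbon = _clean_radiocarbon(rc_events, config, curve, in_area, rng)
    # tree-ring clean records: restrict the mix to cutting/near-cutting
    clean_mix = {
        s: p for s, p in config.symbol_mix.items()
        if classify_treering_symbol(s) != "other"
    }
    norm = sum(clean_mix.values())
    clean_cfg_mix = {s: p / norm for s, p in clean_mix.items()}
    tr_cfg = SimulationConfig(**{**config.__dict__, "symbol_mix": clean_cfg_mix})
    treering = make_treering_records(tr_events, tr_cfg, rng, sites=in_area)

    extra_events = sample_event_years(
        pop,
        max(
            1,
            config.n_non_archaeological
            + config.n_sigma_outliers
            + 2 * config.n_duplicate_conflict_pairs
            + 2 * config.n_duplicate_matching_pairs
            + config.n_out_of_area,
        ),
        rng,
    )
    it = iter(extra_events.tolist())

    def _contaminant_base(lab: str, county: Optional[str] = None) -> RadiocarbonRecord:
        site_id, site_county = in_area[int(rng.integers(0, len(in_area)))]
        rec = _clean_radiocarbon([next(it)], config, curve, [(site_id, site_county)], rng)[0]
        return RadiocarbonRecord(
            lab_number=lab,
            site_id=rec.site_id,
            county=county or rec.county,
            c14_age=rec.c14_age,
            sigma=rec.sigma,
        )

    for k in range(config.n_non_archaeological):
        base = _contaminant_base(f"NONARCH-{k:03d}")
        radiocarbon.append(
            RadiocarbonRecord(
                base.lab_number, base.site_id, base.county, base.c14_age, base.sigma,
                is_archaeological=False,
            )
        )
    for k in range(config.n_sigma_outliers):
        base = _contaminant_base(f"BIGSIG-{k:03d}")
        # sigma 350 trips both the 300-year and the 25% threshold for any
        # in-window age, so the record is removed under either error mode
        radiocarbon.append(
            RadiocarbonRecord(
                base.lab_number, base.site_id, base.county, min(base.c14_age, 1350.0), 350.0
            )
        )
    counties_pool = sorted({c for _, c in in_area})
    for k in range(config.n_duplicate_conflict_pairs):
        base = _contaminant_base(f"DUPCON-{k:03d}")
        other_county = next(c for c in counties_pool if c != base.county)
        radiocarbon.append(base)
        radiocarbon.append(
            RadiocarbonRecord(
                base.lab_number, base.site_id, other_county, base.c14_age, base.sigma
            )
        )
        next(it)  # keep the event stream aligned with the pair
    for k in range(config.n_duplicate_matching_pairs):
        base = _contaminant_base(f"DUPMAT-{k:03d}")
        radiocarbon.append(base)
        radiocarbon.append(base)
        next(it)
    for k in range(config.n_out_of_area):
        base = _contaminant_base(f"OUTAREA-{k:03d}", county="Maricopa, AZ")
        radiocarbon.append(base)
    for k in range(config.n_out_of_window):
        # 60 +/- 12 BP: the 95% mass sits wholly below 150 BP, and
        # sigma = 12 <= 0.25 * 60 so the error rule is not tripped first
        site_id, county = in_area[int(rng.integers(0, len(in_area)))]
        radiocarbon.append(
            RadiocarbonRecord(f"OUTWIN-{k:03d}", site_id, county, 60.0, 12.0)
        )

    for k in range(config.n_tr_noncutting):
        site_id, county = in_area[int(rng.integers(0, len(in_area)))]
        year = int(rng.integers(lo_ad, hi_ad + 1))
        treering.append(TreeRingRecord(site_id, county, year, "vv"))
    for k in range(config.n_tr_out_of_area):
        year = int(rng.integers(lo_ad, hi_ad + 1))
        treering.append(TreeRingRecord("SOUT", "Maricopa, AZ", year, "r"))
    for k in range(config.n_tr_out_of_window):
        site_id, county = in_area[int(rng.integers(0, len(in_area)))]
        treering.append(TreeRingRecord(site_id, county, 1850, "r"))

    # deterministic shuffle so contaminants are interleaved with clean rows
    radiocarbon = [radiocarbon[i] for i in rng.permutation(len(radiocarbon))]
    treering = [treering[i] for i in rng.permutation(len(treering))]

    expected = {
        "radiocarbon": {
            "removed": {
                "non_archaeological": config.n_non_archaeological,
                "error_threshold": config.n_sigma_outliers,
                "duplicate_conflict": 2 * config.n_duplicate_conflict_pairs,
                "county": config.n_out_of_area,
                "window_overlap": config.n_out_of_window,
            },
            "deduplicated": config.n_duplicate_matching_pairs,
            "n_retained": len(radiocarbon)
            - config.n_non_archaeological
            - config.n_sigma_outliers
            - 2 * config.n_duplicate_conflict_pairs
            - config.n_duplicate_matching_pairs
            - config.n_out_of_area
            - config.n_out_of_window,
        },
        "tree_ring": {
            "removed": {
                "symbol": config.n_tr_noncutting,
                "county": config.n_tr_out_of_area,
                "window": config.n_tr_out_of_window,
            },
            "deduplicated": 0,
            "n_retained": len(treering)
            - config.n_tr_noncutting
            - config.n_tr_out_of_area
            - config.n_tr_out_of_window,
        },
    }
    region_config = RegionConfig()
    return SyntheticStudy(
        radiocarbon=radiocarbon,
        treering=treering,
        population=pop,
        curve=curve,
        region_config=region_config,
        expected=expected,
        config=config,
    )
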