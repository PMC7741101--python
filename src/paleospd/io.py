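"""CSV dialects for the pipeline's tabular inputs and outputs.

Counties are held internally as a single ``"County, ST"`` string but the
on-disk dialects keep county and state in separate columns, matching how
county-resolved archaeological databases are usually distributed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .binning_spd import PopulationSeries
from .calibration import CalibrationCurve
from .preprocess import RadiocarbonRecord, TreeRingRecord

__all__ = [
    "read_radiocarbon_csv",
    "write_radiocarbon_csv",
    "read_treering_csv",
    "write_treering_csv",
    "read_population_csv",
    "write_population_csv",
    "write_curve",
]

PathLike = Union[str, Path]


def _split_county(county: str) -> tuple[str, str]:
    if "," in county:
        name, state = county.rsplit(",", 1)
        return name.strip(), state.strip()
    return county.strip(), ""


def _join_county(name: str, state: str) -> str:
    name = str(name).strip()
    state = str(state).strip()
    return f"{name}, {state}" if state else name


RADIOCARBON_COLUMNS = [
    "lab_number",
    "site_id",
    "county",
    "state",
    "c14_age_bp",
    "sigma",
    "is_archaeological",
]

TREERING_COLUMNS = ["site_id", "county", "state", "year_ad", "symbol"]


def write_radiocarbon_csv(records: Sequence[RadiocarbonRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        county, state = _split_county(r.county)
        rows.append(
            {
                "lab_number": r.lab_number,
                "site_id": r.site_id,
                "county": county,
                "state": state,
                "c14_age_bp": r.c14_age,
                "sigma": r.sigma,
                "is_archaeological": r.is_archaeological,
            }
        )
    pd.DataFrame(rows, columns=RADIOCARBON_COLUMNS).to_csv(path, index=False)


def read_radiocarbon_csv(path: PathLike) -> list[RadiocarbonRecord]:
    df = pd.read_csv(path, dtype={"lab_number": str, "site_id": str, "state": str})
    return [
        RadiocarbonRecord(
            lab_number=str(row.lab_number),
            site_id=str(row.site_id),
            county=_join_county(row.county, row.state),
            c14_age=float(row.c14_age_bp),
            sigma=float(row.sigma),
            is_archaeological=bool(row.is_archaeological),
        )
        for row in df.itertuples()
    ]


def write_treering_csv(records: Sequence[TreeRingRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        county, state = _split_county(r.county)
        rows.append(
            {
                "site_id": r.site_id,
                "county": county,
                "state": state,
                "year_ad": r.year_ad,
                "symbol": r.symbol,
            }
        )
    pd.DataFrame(rows, columns=TREERING_COLUMNS).to_csv(path, index=False)


def read_treering_csv(path: PathLike) -> list[TreeRingRecord]:
    df = pd.read_csv(path, dtype={"site_id": str, "state": str, "symbol": str})
    return [
        TreeRingRecord(
            site_id=str(row.site_id),
            county=_join_county(row.county, row.state),
            year_ad=int(row.year_ad),
            symbol=str(row.symbol),
        )
        for row in df.itertuples()
    ]


def write_population_csv(pop: PopulationSeries, path: PathLike) -> None:
    pop.to_frame().to_csv(path, index=False)


def read_population_csv(path: PathLike) -> PopulationSeries:
    df = pd.read_csv(path)
    return PopulationSeries(
        [(int(r.start_ad), int(r.end_ad), float(r.estimate)) for r in df.itertuples()]
    )


def write_curve(curve: CalibrationCurve, path: PathLike) -> None:
    """Write an IntCal-style three-column curve file (oldest first)."""
    with open(path, "w") as fh:
        fh.write(f"# {curve.name}\n# cal_bp,c14_age_bp,sigma\n")
        for bp, age, sig in zip(
            curve.cal_bp[::-1], curve.c14_age[::-1], curve.sigma_curve[::-1]
        ):
            fh.write(f"{bp:g},{age:g},{sig:g}\n")
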