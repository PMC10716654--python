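"""Fossil and historical-sighting occurrence records.

Each record ties a grid cell to a calibrated age (years BP) with a dating
standard deviation and an integer quality score from the dating-reliability
audit. Historical sightings carry no dating uncertainty (age_sd = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

FOSSIL_KINDS = ("fossil", "historical_sighting")
CSV_COLUMNS = ["cell_id", "lon", "lat", "age_bp", "age_sd", "quality", "kind"]


@dataclass(frozen=True)
class FossilRecord:
    cell_id: int
    age_bp: float
    age_sd: float
    quality_score: int
    kind: str = "fossil"
    lon: float = float("nan")
    lat: float = float("nan")

    def __post_init__(self) -> None:
        if self.age_sd < 0:
            raise ValueError("age_sd must be nonnegative")
        if self.kind not in FOSSIL_KINDS:
            raise ValueError(f"kind must be one of {FOSSIL_KINDS}")
        if self.kind == "historical_sighting" and self.age_sd != 0:
            raise ValueError("historical sightings must have age_sd = 0")


def filter_fossils(
    records: Sequence[FossilRecord], min_quality: int = 10
) -> list[FossilRecord]:
    """Keep records whose quality score is strictly greater than ``min_quality``.

    The dating-reliability audit assigns each date an integer score; only
    scores above 10 are considered reliable enough to inform the niche.
    Order is preserved.
    """
    return [r for r in records if r.quality_score > min_quality]


def fossils_to_frame(records: Iterable[FossilRecord]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": r.cell_id,
            "lon": r.lon,
            "lat": r.lat,
            "age_bp": r.age_bp,
            "age_sd": r.age_sd,
            "quality": r.quality_score,
            "kind": r.kind,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_fossils(df: pd.DataFrame) -> list[FossilRecord]:
    return [
        FossilRecord(
            cell_id=int(row.cell_id),
            age_bp=float(row.age_bp),
            age_sd=float(row.age_sd),
            quality_score=int(row.quality),
            kind=str(row.kind),
            lon=float(row.lon),
            lat=float(row.lat),
        )
        for row in df.itertuples()
    ]


def write_fossils_csv(records: Iterable[FossilRecord], path: str | Path) -> None:
    fossils_to_frame(records).to_csv(path, index=False)


def read_fossils_csv(path: str | Path) -> list[FossilRecord]:
    return frame_to_fossils(pd.read_csv(path))
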