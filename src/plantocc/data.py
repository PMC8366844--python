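"""Record and species tables: reading, validation, covariate preparation.

A record is one study-level observation: N diet samples examined, of which y
contained (non-fruit) plant material.  Many studies never report y; a subset
of those mention plants were present without giving the count ("mentioned"
records).  Environmental covariates travel with the record; body mass and
phylogenetic eigenvector scores are species-level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "DietRecord",
    "SpeciesCovariates",
    "ENV_COLUMNS",
    "load_records",
    "write_records",
    "records_to_frame",
    "frame_to_records",
    "load_species",
    "normalize_minmax",
    "collinearity_screen",
]

#: Record-level covariates entering Model 2's environmental design matrix,
#: in the fixed column order used throughout (sample type is a record-level
#: binary and is carried in the same design block).
ENV_COLUMNS = [
    "island",
    "precip",
    "tmax",
    "tmin",
    "ndvi",
    "spring",
    "summer",
    "autumn",
    "winter",
    "dry",
    "wet",
    "sample_type",
]

_SEASONS = ["spring", "summer", "autumn", "winter", "dry", "wet"]


@dataclass
class DietRecord:
    """One study-record of plant occurrence in diet samples.

    ``y`` is None when the study did not report the count; ``mentioned`` marks
    unreported records whose study nonetheless states plants were present.
    """

    record_id: str
    species_id: str
    N: int
    y: int | None = None
    mentioned: bool = False
    sample_type: int = 0  # 0 = scat, 1 = digestive tract
    island: int = 0
    spring: int = 0
    summer: int = 0
    autumn: int = 0
    winter: int = 0
    dry: int = 0
    wet: int = 0
    precip: float = 0.0  # mean monthly precipitation, mm
    tmax: float = 0.0  # mean daily maximum temperature, deg C
    tmin: float = 0.0  # mean daily minimum temperature, deg C
    ndvi: float = 0.0  # mean monthly NDVI, unitless in [-1, 1]

    @property
    def reported(self) -> bool:
        return self.y is not None

    def validate(self, row: int | str = "?") -> None:
        if self.N < 1:
            raise ValueError(f"record {row}: sample size N={self.N} < 1")
        if self.y is not None and not (0 <= self.y <= self.N):
            raise ValueError(
                f"record {row}: reported count y={self.y} outside [0, N={self.N}]"
            )
        if self.mentioned and self.reported:
            raise ValueError(
                f"record {row}: 'mentioned' flag is only valid for unreported records"
            )


@dataclass
class SpeciesCovariates:
    """Species-level predictors: body mass (kg) and PV scores."""

    species_id: str
    body_mass: float
    pv_scores: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError(f"{self.species_id}: body mass must be positive")
        self.pv_scores = np.asarray(self.pv_scores, dtype=float)

    @property
    def log_body_mass(self) -> float:
        # natural log; the base only rescales the coefficient
        return math.log(self.body_mass)


def records_to_frame(records: list[DietRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name: getattr(r, f.name) for f in fields(DietRecord)}
        d["mentioned"] = int(r.mentioned)
        rows.append(d)
    frame = pd.DataFrame(rows)
    frame["y"] = frame["y"].astype("Int64")  # empty cell for missing on write
    return frame


def frame_to_records(frame: pd.DataFrame, validate: bool = True) -> list[DietRecord]:
    records = []
    for idx, row in frame.iterrows():
        y = row["y"]
        y = None if pd.isna(y) else int(y)
        known = {f.name for f in fields(DietRecord)}
        rec = DietRecord(
            record_id=str(row["record_id"]),
            species_id=str(row["species_id"]),
            N=int(row["N"]),
            y=y,
            mentioned=bool(int(row.get("mentioned", 0))),
            **{
                k: (float(row[k]) if k in ("precip", "tmax", "tmin", "ndvi") else int(row[k]))
                for k in known - {"record_id", "species_id", "N", "y", "mentioned"}
                if k in row.index
            },
        )
        if validate:
            rec.validate(row=idx)
        records.append(rec)
    return records


def load_records(path: str, known_species: set[str] | None = None) -> list[DietRecord]:
    """Read and validate a record CSV.

    Missing y is an empty cell.  A reported row with y outside [0, N] or an
    unknown species raises ``ValueError`` naming the offending row.
    """
    frame = pd.read_csv(
        path,
        dtype={"record_id": str, "species_id": str},
        float_precision="round_trip",
    )
    required = {"record_id", "species_id", "N", "y"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"record CSV lacks required columns: {sorted(missing)}")
    records = frame_to_records(frame)
    if known_species is not None:
        for idx, rec in enumerate(records):
            if rec.species_id not in known_species:
                raise ValueError(f"record {idx}: unknown species {rec.species_id!r}")
    return records


def write_records(records: list[DietRecord], path: str) -> None:
    frame = records_to_frame(records)
    for col in ("precip", "tmax", "tmin", "ndvi"):
        # shortest exact decimal representation: the round trip is lossless
        frame[col] = frame[col].map(lambda v: repr(float(v)))
    frame.to_csv(path, index=False)


def load_species(path: str) -> pd.DataFrame:
    """Read the species CSV (species_id, body_mass[, PV1, PV2, ...])."""
    frame = pd.read_csv(path, dtype={"species_id": str}).set_index("species_id")
    if "body_mass" not in frame.columns:
        raise ValueError("species CSV lacks a body_mass column")
    if (frame["body_mass"] <= 0).any():
        bad = frame.index[frame["body_mass"] <= 0].tolist()
        raise ValueError(f"non-positive body mass for species: {bad}")
    return frame


def normalize_minmax(values: np.ndarray) -> np.ndarray:
    """Affine rescale of a covariate into [0, 1]."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant vector")
    return (v - lo) / (hi - lo)


def collinearity_screen(
    x: pd.DataFrame | np.ndarray,
    threshold: float = 0.80,
) -> list[tuple[str, str, float]]:
    """Pairwise Pearson correlations at or above ``threshold`` (absolute value).

    Returns one (name_a, name_b, r) triple per flagged unordered pair.  An
    empty list means the screen passes.  A zero-variance column is reported
    with r = nan rather than silently skipped.
    """
    if isinstance(x, np.ndarray):
        x = pd.DataFrame(x, columns=[f"x{i}" for i in range(x.shape[1])])
    if len(x) < 3:
        raise ValueError("collinearity screen needs at least 3 rows")
    cols = list(x.columns)
    arr = x.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    flagged: list[tuple[str, str, float]] = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if sd[i] == 0 or sd[j] == 0:
                flagged.append((cols[i], cols[j], float("nan")))
                continue
            r = float(np.corrcoef(arr[:, i], arr[:, j])[0, 1])
            if abs(r) >= threshold:
                flagged.append((cols[i], cols[j], r))
    return flagged


def env_design(records: list[DietRecord], normalize_precip: bool = True) -> pd.DataFrame:
    """Record-level design matrix in the fixed ENV_COLUMNS order.

    Precipitation is min-max normalized into [0, 1] (an MCMC-conditioning
    choice); all other columns pass through.
    """
    frame = records_to_frame(records)[ENV_COLUMNS].astype(float)
    if normalize_precip and frame["precip"].nunique() > 1:
        frame["precip"] = normalize_minmax(frame["precip"].to_numpy())
    return frame


def species_design(
    species: pd.DataFrame,
    pv: pd.DataFrame | None = None,
    center: bool = False,
) -> pd.DataFrame:
    """Species-level design: log body mass first, then PV axes.

    ``center`` subtracts column means (off by default; the choice is recorded
    in run metadata since it only shifts the intercept).
    """
    design = pd.DataFrame(
        {"log_body_mass": np.log(species["body_mass"].to_numpy(dtype=float))},
        index=species.index,
    )
    if pv is not None and pv.shape[1] > 0:
        design = design.join(pv.loc[design.index])
    if center:
        design = design - design.mean(axis=0)
    return design
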