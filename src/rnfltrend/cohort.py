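"""Domain types, validation and I/O for paired-device RNFL cohorts.

A cohort is a long-format table: one row per (eye, device, visit time, sector)
thickness observation in micrometers. Sectors follow the clock-hour convention
in right-eye format — 12 superior, numbering clockwise — plus ``G`` for the
global average over the full peripapillary circle. Spectralis circle scans are
exported as 768-point profiles; :func:`aggregate_profile` collapses them to the
12 clock hours (64 pixels each) plus the global mean.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SPECTRALIS = "spectralis"
CIRRUS = "cirrus"
DEVICES = (SPECTRALIS, CIRRUS)

#: Admissible sector labels: global average then clock hours 1..12 (right-eye format).
SECTORS: tuple[str, ...] = ("G",) + tuple(str(h) for h in range(1, 13))

N_PROFILE = 768
PIXELS_PER_HOUR = 64

#: Default visit-pairing tolerance when matching cross-device sessions, years (~14 days).
PAIRING_TOL_YEARS = 0.0383

REQUIRED_COLUMNS = ("eye_id", "device", "t", "sector", "thickness")


class SchemaError(ValueError):
    """Input table is missing required columns or uses unknown labels."""


class IntegrityError(ValueError):
    """Input rows violate a dataset invariant (duplicates, bad values)."""


def validate_sector(sector: object) -> str:
    s = str(sector)
    if s not in SECTORS:
        raise SchemaError(f"unknown sector {sector!r}; expected one of {SECTORS}")
    return s


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    out = frame.copy()
    out["eye_id"] = out["eye_id"].astype(str)
    out["device"] = out["device"].astype(str).str.lower()
    bad_dev = sorted(set(out["device"]) - set(DEVICES))
    if bad_dev:
        raise SchemaError(f"unknown device labels {bad_dev}; expected {DEVICES}")
    out["sector"] = out["sector"].astype(str)
    bad_sec = sorted(set(out["sector"]) - set(SECTORS))
    if bad_sec:
        raise SchemaError(f"unknown sector labels {bad_sec}; expected {SECTORS}")
    out["t"] = pd.to_numeric(out["t"])
    out["thickness"] = pd.to_numeric(out["thickness"])
    if "quality_ok" not in out.columns:
        out["quality_ok"] = True
    out["quality_ok"] = out["quality_ok"].astype(bool)

    problems = []
    t = out["t"].to_numpy(float)
    y = out["thickness"].to_numpy(float)
    bad_t = ~np.isfinite(t) | (t < 0)
    bad_y = ~np.isfinite(y) | (y <= 0)
    for idx in out.index[bad_t]:
        problems.append(f"row {idx}: visit time t={out.at[idx, 't']!r} must be finite and >= 0")
    for idx in out.index[bad_y]:
        problems.append(
            f"row {idx}: thickness={out.at[idx, 'thickness']!r} must be finite and > 0"
        )
    if problems:
        raise IntegrityError("invalid rows:\n" + "\n".join(problems))

    out = out[["eye_id", "device", "t", "sector", "thickness", "quality_ok"]]
    dup = out.duplicated(subset=["eye_id", "device", "t", "sector"], keep=False)
    if dup.any():
        keys = (
            out.loc[dup, ["eye_id", "device", "t", "sector"]]
            .drop_duplicates()
            .to_records(index=False)
        )
        raise IntegrityError(
            "duplicate (eye_id, device, t, sector) keys: "
            + "; ".join(str(tuple(k)) for k in keys[:10])
        )
    return out


def _sort_frame(frame: pd.DataFrame) -> pd.DataFrame:
    # Deterministic row order: eye, device, t, sector (G first, then clock hours).
    order = {s: i for i, s in enumerate(SECTORS)}
    key = frame["sector"].map(order)
    return (
        frame.assign(_s=key)
        .sort_values(["eye_id", "device", "t", "_s"], kind="mergesort")
        .drop(columns="_s")
        .reset_index(drop=True)
    )


@dataclass
class PairedCohort:
    """Validated long-format collection of thickness observations for both devices.

    Parameters
    ----------
    frame
        Columns ``eye_id, device, t, sector, thickness, quality_ok``; one row
        per observation; ``t`` in years since the eye's first scan.
    metadata
        Free-form provenance map carried through I/O round trips.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = _sort_frame(_validate_frame(self.frame))

    @property
    def eyes(self) -> list[str]:
        return sorted(self.frame["eye_id"].unique())

    @property
    def sectors(self) -> list[str]:
        present = set(self.frame["sector"])
        return [s for s in SECTORS if s in present]

    def n_visits(self, eye_id: str) -> int:
        sub = self.frame[self.frame["eye_id"] == eye_id]
        return sub["t"].nunique()

    def sector_frame(self, sector: str) -> pd.DataFrame:
        validate_sector(sector)
        return self.frame[self.frame["sector"] == sector].reset_index(drop=True)

    def check_min_visits(self, minimum: int = 4) -> None:
        """Enforce the study design's minimum number of visits per eye."""
        low = [e for e in self.eyes if self.n_visits(e) < minimum]
        if low:
            raise IntegrityError(
                f"eyes with fewer than {minimum} visits: {low[:10]}"
                + ("..." if len(low) > 10 else "")
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairedCohort):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass(frozen=True)
class CircleScanProfile:
    """One Spectralis circle-scan export: 768 thickness values around the disc.

    ``start_anchor`` declares the clock-hour position (right-eye format) of
    pixel index 0; the default 9.0 places index 0 at the temporal midline.
    Pixels advance clockwise in right-eye orientation.
    """

    eye_id: str
    t: float
    values: np.ndarray
    start_anchor: float = 9.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (N_PROFILE,):
            raise IntegrityError(
                f"profile must have exactly {N_PROFILE} values, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise IntegrityError("profile values must be finite and >= 0")
        object.__setattr__(self, "values", vals)


def aggregate_profile(profile: CircleScanProfile) -> dict[str, float]:
    """Collapse a 768-point circle-scan profile to clock-hour means plus global.

    Each clock hour averages its contiguous 64 pixels under the profile's
    declared anchor/direction convention; ``G`` is the mean of all 768 values,
    which equals the mean of the 12 sector means because the blocks tile the
    circle evenly.
    """
    vals = profile.values
    idx = np.arange(N_PROFILE)
    # Clock-hour position of each pixel center, then nearest-hour assignment.
    hour_pos = profile.start_anchor + (idx + 0.5) / PIXELS_PER_HOUR
    hour = (np.floor(hour_pos + 0.5).astype(int) - 1) % 12 + 1
    out: dict[str, float] = {"G": float(vals.mean())}
    for h in range(1, 13):
        out[str(h)] = float(vals[hour == h].mean())
    return out


def align_time_axis(cohort: PairedCohort) -> PairedCohort:
    """Re-express each eye's visit times as years since its first retained visit.

    Idempotent: a cohort whose eyes already start at t=0 is returned unchanged.
    """
    frame = cohort.frame.copy()
    t0 = frame.groupby("eye_id")["t"].transform("min")
    frame["t"] = frame["t"] - t0
    return PairedCohort(frame, metadata=dict(cohort.metadata))


DEFAULT_SCHEMA = {
    "eye_id": "eye_id",
    "device": "device",
    "t": "t_years",
    "sector": "sector",
    "thickness": "thickness_um",
    "quality_ok": "quality_ok",
}


def read_cohort(path, schema: Mapping[str, str] | None = None) -> PairedCohort:
    """Read a long-format cohort CSV into a validated :class:`PairedCohort`.

    ``schema`` maps internal field names to the file's column names; defaults
    to the package's own export schema (``t_years``, ``thickness_um``, ...).
    A ``visit_date`` ISO-8601 column may stand in for ``t_years``; it is
    converted to years since each eye's first visit.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path)
    frame = pd.DataFrame()
    for internal in ("eye_id", "device", "sector", "thickness"):
        col = colmap[internal]
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r} (field {internal})")
        frame[internal] = raw[col]
    tcol = colmap["t"]
    if tcol in raw.columns:
        frame["t"] = raw[tcol]
    elif "visit_date" in raw.columns:
        dates = pd.to_datetime(raw["visit_date"])
        frame["eye_id"] = frame["eye_id"].astype(str)
        t0 = dates.groupby(frame["eye_id"]).transform("min")
        frame["t"] = (dates - t0).dt.days / 365.25
    else:
        raise SchemaError(f"missing time column {tcol!r} (or a visit_date column)")
    qcol = colmap["quality_ok"]
    if qcol in raw.columns:
        frame["quality_ok"] = raw[qcol]
    return PairedCohort(frame)


def write_cohort(cohort: PairedCohort, path) -> None:
    """Write a cohort as long-format CSV with the package's export schema."""
    out = cohort.frame.rename(
        columns={"t": "t_years", "thickness": "thickness_um"}
    )[["eye_id", "device", "t_years", "sector", "thickness_um", "quality_ok"]]
    out.to_csv(path, index=False)


def read_profiles(path, start_anchor: float = 9.0) -> list[CircleScanProfile]:
    """Read 768-point circle-scan profiles from a wide CSV/TSV.

    Expected columns: ``eye_id``, ``t_years`` (or ``visit_date``), then 768
    value columns in pixel order.
    """
    raw = pd.read_csv(path, sep=None, engine="python")
    if "eye_id" not in raw.columns:
        raise SchemaError("profile table must have an eye_id column")
    if "t_years" in raw.columns:
        tvals = pd.to_numeric(raw["t_years"])
    elif "visit_date" in raw.columns:
        dates = pd.to_datetime(raw["visit_date"])
        t0 = dates.groupby(raw["eye_id"].astype(str)).transform("min")
        tvals = (dates - t0).dt.days / 365.25
    else:
        raise SchemaError("profile table must have a t_years or visit_date column")
    value_cols = [c for c in raw.columns if c not in ("eye_id", "t_years", "visit_date")]
    if len(value_cols) != N_PROFILE:
        raise SchemaError(
            f"expected {N_PROFILE} profile value columns, found {len(value_cols)}"
        )
    return [
        CircleScanProfile(
            eye_id=str(row["eye_id"]),
            t=float(tvals.iloc[i]),
            values=row[value_cols].to_numpy(dtype=float),
            start_anchor=start_anchor,
        )
        for i, (_, row) in enumerate(raw.iterrows())
    ]


def profiles_to_cohort(
    profiles: Sequence[CircleScanProfile], device: str = SPECTRALIS
) -> PairedCohort:
    """Aggregate circle-scan profiles into a long-format single-device cohort."""
    rows = []
    for p in profiles:
        for sector, value in aggregate_profile(p).items():
            rows.append(
                {
                    "eye_id": p.eye_id,
                    "device": device,
                    "t": p.t,
                    "sector": sector,
                    "thickness": value,
                    "quality_ok": True,
                }
            )
    return PairedCohort(pd.DataFrame(rows))
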