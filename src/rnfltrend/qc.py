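"""Outlier screening for longitudinal thickness series and paired removal.

Each (eye, sector, device) series is screened against a robust linear trend:
a Theil-Sen slope with median intercept, residuals scaled by 1.4826 x MAD.
Observations whose absolute residual exceeds ``k`` times that robust scale are
flagged. Because the two devices image the same session, a visit-sector cell
flagged on either device is removed from both — retained data keep identical
(eye, t, sector) support across devices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from rnfltrend.cohort import CIRRUS, SPECTRALIS, IntegrityError, PairedCohort

#: Default robustness multiplier: "obvious" outliers only.
DEFAULT_K = 4.0
#: Below this many observations a series is never screened.
MIN_SERIES_LEN = 4
#: Floor on the robust residual scale, um. On 4-7 visits the Theil-Sen line
#: interpolates much of the series and the residual MAD can collapse toward
#: zero, which would flag ordinary measurement noise (or integer rounding) as
#: outliers. RNFL test-retest variability is on the order of 2 um, so a
#: deviation smaller than k x 2 um is never an "obvious" outlier.
SCALE_FLOOR_UM = 2.0

#: A flag identifies one observation: (eye_id, t, sector, device).
Flag = tuple[str, float, str, str]


@dataclass
class OutlierReport:
    """Audit record of the screening and paired-removal step."""

    flags: set[Flag] = field(default_factory=set)
    removed_pairs: set[tuple[str, float, str]] = field(default_factory=set)
    n_spectralis_only: int = 0
    n_cirrus_only: int = 0
    n_both: int = 0

    @property
    def n_removed(self) -> int:
        return len(self.removed_pairs)

    def to_frame(self) -> pd.DataFrame:
        """One row per flag with device attribution, deterministic order."""
        rows = sorted(self.flags)
        return pd.DataFrame(rows, columns=["eye_id", "t", "sector", "device"])


def flag_series(
    t: np.ndarray,
    y: np.ndarray,
    k: float = DEFAULT_K,
    min_len: int = MIN_SERIES_LEN,
    scale_floor: float = SCALE_FLOOR_UM,
) -> np.ndarray:
    """Boolean mask of outliers in a single time series.

    Fits a Theil-Sen slope with median intercept, then flags points whose
    absolute residual exceeds ``k * max(1.4826 * MAD(residuals), scale_floor)``.
    Series shorter than ``min_len`` are never flagged. Deterministic.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
        raise IntegrityError("series contains non-finite values")
    if y.size < min_len:
        return np.zeros(y.size, dtype=bool)
    if np.ptp(t) == 0:
        raise IntegrityError("series has no time spread")
    slope, _, _, _ = stats.theilslopes(y, t)
    intercept = float(np.median(y - slope * t))
    resid = y - (intercept + slope * t)
    scale = stats.median_abs_deviation(resid, scale="normal")
    threshold = k * max(float(scale), scale_floor)
    return np.abs(resid) > threshold


def flag_outliers(
    cohort: PairedCohort,
    k: float = DEFAULT_K,
    min_len: int = MIN_SERIES_LEN,
    scale_floor: float = SCALE_FLOOR_UM,
    manual_exclusions: Iterable[Flag] | None = None,
) -> set[Flag]:
    """Screen every (eye, sector, device) series in the cohort.

    Sector series and the global series are screened independently, each on
    its own values. ``manual_exclusions`` adds user-curated flags (the manual
    arm of a semiautomated review); they must refer to observations present in
    the cohort.
    """
    flags: set[Flag] = set()
    for (eye, sector, device), grp in cohort.frame.groupby(
        ["eye_id", "sector", "device"], sort=True
    ):
        grp = grp.sort_values("t")
        mask = flag_series(
            grp["t"].to_numpy(), grp["thickness"].to_numpy(),
            k=k, min_len=min_len, scale_floor=scale_floor,
        )
        for t in grp["t"].to_numpy()[mask]:
            flags.add((str(eye), float(t), str(sector), str(device)))
    if manual_exclusions:
        present = {
            (r.eye_id, float(r.t), r.sector, r.device)
            for r in cohort.frame.itertuples()
        }
        for fl in manual_exclusions:
            fl = (str(fl[0]), float(fl[1]), str(fl[2]), str(fl[3]))
            if fl not in present:
                raise IntegrityError(f"manual exclusion {fl} not present in cohort")
            flags.add(fl)
    return flags


def apply_paired_removal(
    cohort: PairedCohort, flags: Iterable[Flag]
) -> tuple[PairedCohort, OutlierReport]:
    """Remove every flagged (eye, t, sector) cell from BOTH devices.

    Returns the cleaned cohort and a report partitioning flags into
    Spectralis-only / Cirrus-only / both-device detections.
    """
    flags = {(str(e), float(t), str(s), str(d)) for e, t, s, d in flags}
    frame = cohort.frame
    present = {
        (r.eye_id, float(r.t), r.sector, r.device) for r in frame.itertuples()
    }
    missing = flags - present
    if missing:
        raise IntegrityError(
            f"flags reference observations absent from the cohort: {sorted(missing)[:5]}"
        )

    pairs = {(e, t, s) for e, t, s, _ in flags}
    by_dev: dict[tuple[str, float, str], set[str]] = {}
    for e, t, s, d in flags:
        by_dev.setdefault((e, t, s), set()).add(d)
    n_s = sum(1 for devs in by_dev.values() if devs == {SPECTRALIS})
    n_c = sum(1 for devs in by_dev.values() if devs == {CIRRUS})
    n_b = sum(1 for devs in by_dev.values() if len(devs) == 2)

    key = list(zip(frame["eye_id"], frame["t"].astype(float), frame["sector"]))
    keep = np.array([kk not in pairs for kk in key])
    cleaned = PairedCohort(frame[keep], metadata=dict(cohort.metadata))
    report = OutlierReport(
        flags=flags,
        removed_pairs=pairs,
        n_spectralis_only=n_s,
        n_cirrus_only=n_c,
        n_both=n_b,
    )
    return cleaned, report


def screen_cohort(
    cohort: PairedCohort,
    k: float = DEFAULT_K,
    min_len: int = MIN_SERIES_LEN,
    scale_floor: float = SCALE_FLOOR_UM,
    manual_exclusions: Iterable[Flag] | None = None,
) -> tuple[PairedCohort, OutlierReport]:
    """Convenience wrapper: flag, then apply paired removal."""
    flags = flag_outliers(
        cohort, k=k, min_len=min_len, scale_floor=scale_floor,
        manual_exclusions=manual_exclusions,
    )
    return apply_paired_removal(cohort, flags)
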