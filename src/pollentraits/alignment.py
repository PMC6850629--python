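"""Align irregular proxy series onto pollen sample ages.

Produces the year x environment matrix the regressions and ordinations use:

* precipitation — piecewise-linear interpolation of d18O onto pollen ages,
  then multiplied by -1 (higher = wetter);
* erosion rate — interpolated band width (mm/yr), with the unlaminated oldest
  section imputed at a fixed fill value (0.22 mm/yr, the band width at the
  onset of lamination);
* fire_prev — the closest previous charcoal measurement (a measurement exactly
  at the pollen age counts as previous);
* fire_max — the maximum charcoal value inside the inter-sample window
  (previous pollen age, current pollen age] in calendar time.

Charcoal is deliberately *not* interpolated: interpolation would smooth away
the extreme values that carry the fire signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PollenRecord, ProxySeries, ValidationError

logger = logging.getLogger("pollentraits")

__all__ = [
    "AlignedEnvironment",
    "interpolate_to_ages",
    "precipitation_proxy",
    "fire_closest_previous",
    "fire_max_preceding",
    "impute_erosion",
    "build_environment",
]

ENV_COLUMNS = ("precipitation", "erosion_rate", "fire_prev", "fire_max")


@dataclass
class AlignedEnvironment:
    """Per-pollen-sample environmental values (one row per sample, oldest first)."""

    ages: np.ndarray
    data: pd.DataFrame  # columns: precipitation, erosion_rate, fire_prev, fire_max
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(ENV_COLUMNS):
            raise ValidationError(f"environment columns must be {ENV_COLUMNS}")
        if self.data.isna().any().any():
            raise ValidationError("aligned environment contains missing cells")
        for col in ("erosion_rate", "fire_prev", "fire_max"):
            if (self.data[col] < 0).any():
                raise ValidationError(f"{col} contains negative values")

    def predictors(self, fire_index: str = "prev") -> pd.DataFrame:
        """Three-column predictor matrix with the chosen fire index."""
        fire = {"prev": "fire_prev", "max": "fire_max"}[fire_index]
        out = self.data[["precipitation", "erosion_rate", fire]].copy()
        out.columns = ["precipitation", "erosion_rate", "fire"]
        return out


def interpolate_to_ages(
    series: ProxySeries, target_ages, extrapolation: str = "missing"
) -> np.ndarray:
    """Piecewise-linear interpolation of a proxy series at target ages (BP).

    Targets outside the measured age range are NaN (``extrapolation='missing'``)
    or held at the nearest endpoint (``'nearest'``, logged).  Exact knot hits
    return the measured value.
    """
    if len(series) < 2:
        raise ValidationError(f"{series.kind}: interpolation needs at least 2 points")
    t_series = -series.ages  # ages are descending BP, so this is ascending calendar time
    v_series = series.values
    t_targets = -np.asarray(target_ages, dtype=float)
    out = np.interp(t_targets, t_series, v_series)
    outside = (t_targets < t_series[0]) | (t_targets > t_series[-1])
    if outside.any():
        if extrapolation == "missing":
            out[outside] = np.nan
        elif extrapolation == "nearest":
            logger.warning(
                "%s: %d target ages outside the measured range held at nearest endpoint",
                series.kind,
                int(outside.sum()),
            )
        else:
            raise ValueError(f"unknown extrapolation policy {extrapolation!r}")
    return out


def precipitation_proxy(d18o_values) -> np.ndarray:
    """Precipitation proxy: elementwise -1 x d18O (higher = wetter)."""
    return -np.asarray(d18o_values, dtype=float)


def fire_closest_previous(
    charcoal: ProxySeries, target_ages, backfill: bool = True
) -> np.ndarray:
    """Value of the most recent charcoal measurement at or before each target.

    "Previous" means older in calendar time: the measurement with the smallest
    age BP >= the target age.  A target older than every measurement has no
    previous value; with ``backfill=True`` (logged) it takes the oldest
    measurement, otherwise NaN.
    """
    if len(charcoal) == 0:
        raise ValidationError("charcoal series is empty")
    ages_asc = charcoal.ages[::-1]  # ascending BP
    vals_asc = charcoal.values[::-1]
    targets = np.asarray(target_ages, dtype=float)
    # first measurement with age BP >= target
    idx = np.searchsorted(ages_asc, targets, side="left")
    out = np.empty(len(targets))
    missing = idx >= len(ages_asc)
    out[~missing] = vals_asc[idx[~missing]]
    if missing.any():
        if backfill:
            logger.warning(
                "fire_closest_previous: %d targets older than the oldest charcoal "
                "measurement backfilled with it",
                int(missing.sum()),
            )
            out[missing] = vals_asc[-1]
        else:
            out[missing] = np.nan
    return out


def fire_max_preceding(charcoal: ProxySeries, target_ages) -> np.ndarray:
    """Maximum charcoal value in each inter-sample window.

    For sample j the window is (age of sample j-1, age of sample j] in calendar
    time, i.e. measurements with BP in [age_j, age_{j-1}).  The oldest sample's
    window extends back to the oldest charcoal measurement.  An empty window
    falls back to the closest-previous value (logged).
    """
    if len(charcoal) == 0:
        raise ValidationError("charcoal series is empty")
    targets = np.asarray(target_ages, dtype=float)
    if np.any(np.diff(targets) >= 0):
        raise ValidationError("target ages must be strictly decreasing in BP (oldest first)")
    ages_asc = charcoal.ages[::-1]
    vals_asc = charcoal.values[::-1]
    out = np.empty(len(targets))
    fallback = None
    for j, age in enumerate(targets):
        upper = np.inf if j == 0 else targets[j - 1]  # exclusive older bound (BP)
        in_window = (ages_asc >= age) & (ages_asc < upper)
        if in_window.any():
            out[j] = vals_asc[in_window].max()
        else:
            if fallback is None:
                fallback = fire_closest_previous(charcoal, targets)
            logger.warning(
                "fire_max_preceding: empty charcoal window at %s BP; using closest-previous value",
                age,
            )
            out[j] = fallback[j]
    return out


def impute_erosion(values, ages_bp, fill_value: float = 0.22) -> np.ndarray:
    """Complete an interpolated band-width series.

    The leading (oldest) missing stretch — the unlaminated core section — is
    set to ``fill_value`` (default 0.22 mm/yr, the band width at the onset of
    lamination).  Interior gaps are linearly interpolated in time and a
    trailing (youngest) missing stretch is held at the last observed value.
    """
    values = np.asarray(values, dtype=float).copy()
    ages_bp = np.asarray(ages_bp, dtype=float)
    missing = np.isnan(values)
    if not missing.any():
        return values
    if missing.all():
        return np.full_like(values, fill_value)
    first_obs = int(np.argmax(~missing))
    if first_obs > 0:
        values[:first_obs] = fill_value
        logger.info(
            "impute_erosion: %d leading (oldest) values set to %.3g mm/yr", first_obs, fill_value
        )
    obs = ~np.isnan(values)
    t = -ages_bp
    values = np.interp(t, t[obs], values[obs])  # interior gaps linear, trailing held
    return values


def build_environment(
    record: PollenRecord,
    d18o: ProxySeries,
    charcoal: ProxySeries,
    bandwidth: ProxySeries,
    erosion_fill: float = 0.22,
) -> AlignedEnvironment:
    """Compose the full year x environment matrix at the pollen sample ages.

    Reports Pearson correlations between the two fire indices and between
    erosion and each fire index as diagnostics; these describe the aligned
    matrix and never gate the pipeline.
    """
    ages = record.ages
    precip = precipitation_proxy(interpolate_to_ages(d18o, ages, extrapolation="nearest"))
    bw = interpolate_to_ages(bandwidth, ages, extrapolation="missing")
    erosion = impute_erosion(bw, ages, fill_value=erosion_fill)
    prev = fire_closest_previous(charcoal, ages)
    fmax = fire_max_preceding(charcoal, ages)
    data = pd.DataFrame(
        {
            "precipitation": precip,
            "erosion_rate": erosion,
            "fire_prev": prev,
            "fire_max": fmax,
        },
        index=pd.Index(ages, name="age_bp"),
    )
    diagnostics = {
        "r_fire_prev_fire_max": float(np.corrcoef(prev, fmax)[0, 1]),
        "r_erosion_fire_prev": float(np.corrcoef(erosion, prev)[0, 1]),
        "r_erosion_fire_max": float(np.corrcoef(erosion, fmax)[0, 1]),
    }
    logger.info("aligned environment diagnostics: %s", diagnostics)
    return AlignedEnvironment(ages=ages, data=data, diagnostics=diagnostics)
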