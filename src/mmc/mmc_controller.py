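"""The metabolic-model-control loop: OD → growth rate → minimized uptake → feed.

Every feed interval the controller (i) estimates the specific growth rate from
the last two optical-density readings, mu = ln(OD_t / OD_{t-1}) / Δt,
(ii) pins the model's biomass flux to that rate and minimizes nutrient uptake
(nitrate under autotrophy; glucose then nitrate lexicographically under
heterotrophy, optionally with the empirical glucose-uptake cap applied first),
and (iii) converts the minimized uptake flux into the nutrient mass to add for
the next interval, assuming biomass grows exponentially at mu over it:

    mass [mg/L] = flux · MW · X0 · (e^{mu·dt} − 1) / mu

with the continuous limit flux·MW·X0·dt at mu = 0. A feed-scaling factor
(0.8/1.0/1.2 in under/exact/over-feeding studies) multiplies the final mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fba_engine
from .model_core import ModelVariant
from .uptake_kinetics import UptakeCapModel, apply_uptake_cap

__all__ = [
    "ODSeries",
    "GrowthEstimate",
    "NutrientSpec",
    "FeedPrediction",
    "FeedSchedule",
    "NITRATE",
    "GLUCOSE",
    "estimate_growth_rate",
    "flux_to_feed_mass",
    "predict_feed_autotrophic",
    "predict_feeds_heterotrophic",
    "feasible_growth",
    "run_schedule",
]

logger = logging.getLogger(__name__)

#: default OD750 → dry weight conversion, gDW·L⁻¹ per OD unit (approximate,
#: derived from pairing OD750 ≈ 1.3 with ~520 mg/L dry biomass; overridable)
DEFAULT_OD_TO_GDW = 0.4

_MU_ZERO = 1e-9


@dataclass
class ODSeries:
    """OD750 observations with the conversion factor to dry-weight biomass."""

    times: np.ndarray
    od750: np.ndarray
    od_to_gdw: float = DEFAULT_OD_TO_GDW

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od750 = np.asarray(self.od750, dtype=float)
        if self.times.shape != self.od750.shape or self.times.ndim != 1:
            raise ValueError("times and od750 must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od750 <= 0):
            raise ValueError("od750 values must be positive")
        if self.od_to_gdw <= 0:
            raise ValueError("od_to_gdw must be positive")

    @classmethod
    def from_csv(cls, path, od_to_gdw: float = DEFAULT_OD_TO_GDW) -> "ODSeries":
        df = pd.read_csv(path)
        return cls(df["time_h"].to_numpy(), df["od750"].to_numpy(), od_to_gdw)

    def od_at(self, t: float, atol: float = 1e-6) -> float:
        i = np.argmin(np.abs(self.times - t))
        if abs(self.times[i] - t) > atol:
            raise KeyError(f"no observation at t={t} h")
        return float(self.od750[i])

    def biomass_at(self, t: float) -> float:
        """gDW·L⁻¹ at an observed time point."""
        return self.od_at(t) * self.od_to_gdw

    def integrated_biomass(self, t_end: float | None = None) -> float:
        """Trapezoidal integral of biomass concentration, gDW·L⁻¹·h."""
        mask = self.times <= (t_end if t_end is not None else self.times[-1]) + 1e-9
        return float(np.trapezoid(self.od750[mask] * self.od_to_gdw, self.times[mask]))


@dataclass
class GrowthEstimate:
    mu: float  # h^-1
    window: tuple[float, float]
    negative: bool = False


@dataclass
class NutrientSpec:
    """Nutrient identity: molecular weight (mg/mmol) and uptake reaction id."""

    name: str
    molecular_weight: float
    uptake_rxn: str

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")


NITRATE = NutrientSpec("nitrate", 62.00, "EX_no3")
GLUCOSE = NutrientSpec("glucose", 180.16, "EX_glc")


@dataclass
class FeedPrediction:
    nutrient: str
    interval: tuple[float, float]
    uptake_flux: float  # mmol gDW^-1 h^-1
    feed_mass_conc: float  # mg/L to add
    scale_factor: float
    mu: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feed_mass_conc < 0:
            raise ValueError("feed mass cannot be negative")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def estimate_growth_rate(series: ODSeries, t_prev: float, t_now: float) -> GrowthEstimate:
    """mu = ln(OD_t / OD_{t-1}) / (t_now − t_prev). Negative mu is flagged."""
    if t_now <= t_prev:
        raise ValueError("t_now must be after t_prev")
    od_prev = series.od_at(t_prev)
    od_now = series.od_at(t_now)
    mu = math.log(od_now / od_prev) / (t_now - t_prev)
    return GrowthEstimate(mu=mu, window=(t_prev, t_now), negative=mu < 0)


def flux_to_feed_mass(
    flux: float,
    nutrient: NutrientSpec,
    X0: float,
    mu: float,
    dt: float,
    biomass_model: str = "exponential",
) -> float:
    """Convert an uptake flux into the nutrient mass consumed over an interval.

    Integrates flux·MW·X(t) over the interval with X(t) = X0·e^{mu·t}
    (``biomass_model="constant"`` holds X at X0 instead). mu = 0 and negative
    mu use the same closed form; |mu| < 1e-9 switches to the limit to avoid
    cancellation.
    """
    if flux < 0 or X0 < 0 or dt < 0:
        raise ValueError("flux, X0 and dt must be nonnegative")
    if biomass_model == "constant" or abs(mu) < _MU_ZERO:
        return flux * nutrient.molecular_weight * X0 * dt
    if biomass_model != "exponential":
        raise ValueError(f"unknown biomass_model {biomass_model!r}")
    return flux * nutrient.molecular_weight * X0 * (math.exp(mu * dt) - 1.0) / mu


def feasible_growth(variant: ModelVariant, mu_target: float) -> float:
    """Largest growth rate the model supports, capped at ``mu_target``."""
    cap = fba_engine.maximize_growth(variant)
    mu_max = cap.objective_value if cap.ok else 0.0
    return min(mu_target, mu_max)


def _resolved_mu(variant: ModelVariant, estimate: GrowthEstimate, flags: list[str]) -> float:
    """Apply the nonnegative-feed floor and model feasibility to an estimate."""
    if estimate.negative:
        flags.append("negative_mu_floored")
        return 0.0
    mu = feasible_growth(variant, estimate.mu)
    if mu < estimate.mu - 1e-12:
        flags.append("mu_capped_to_feasible")
    return mu


def predict_feed_autotrophic(
    variant: ModelVariant,
    series: ODSeries,
    t_prev: float,
    t_now: float,
    dt_next: float,
    nutrient: NutrientSpec = NITRATE,
    scale: float = 1.0,
) -> FeedPrediction:
    """One autotrophic MMC step: nitrate mass to add for the next interval."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    est = estimate_growth_rate(series, t_prev, t_now)
    flags: list[str] = []
    mu = _resolved_mu(variant, est, flags)
    sol = fba_engine.minimize_uptake_at_growth(variant, nutrient.name, mu)
    if not sol.ok:
        # mu was already feasibility-capped; residual infeasibility is numeric
        flags.append(f"fba_{sol.status}")
        flux = 0.0
    else:
        flux = max(0.0, sol.objective_value)
    X0 = series.biomass_at(t_now)
    mass = scale * flux_to_feed_mass(flux, nutrient, X0, mu, dt_next)
    return FeedPrediction(
        nutrient=nutrient.name,
        interval=(t_now, t_now + dt_next),
        uptake_flux=flux,
        feed_mass_conc=mass,
        scale_factor=scale,
        mu=mu,
        flags=flags,
    )


def predict_feeds_heterotrophic(
    variant: ModelVariant,
    series: ODSeries,
    t_prev: float,
    t_now: float,
    dt_next: float,
    nutrients: list[NutrientSpec] | None = None,
    cap: UptakeCapModel | None = None,
    scale: float = 1.0,
) -> list[FeedPrediction]:
    """One heterotrophic MMC step: glucose then nitrate, lexicographically.

    If ``cap`` is given, the glucose uptake bound is first set from the cap
    evaluated at the current accumulated biomass (integrated biomass or
    concentration, per the cap's regressor); growth is then capped to what the
    bounded model supports before the lexicographic minimization.
    """
    if nutrients is None:
        nutrients = [GLUCOSE, NITRATE]
    if variant.trophic_mode != "heterotrophic":
        raise ValueError("heterotrophic prediction requires a heterotrophic variant")
    working = variant
    flags: list[str] = []
    if cap is not None:
        axis_value = (
            series.integrated_biomass(t_now)
            if cap.regressor == "integrated_biomass"
            else series.biomass_at(t_now)
        )
        working = apply_uptake_cap(variant, cap, axis_value)
        flags.append("uptake_cap_applied")
    est = estimate_growth_rate(series, t_prev, t_now)
    mu = _resolved_mu(working, est, flags)
    order = [n.name for n in nutrients]
    fluxes = fba_engine.lexicographic_minimize(working, mu, order)
    X0 = series.biomass_at(t_now)
    out = []
    for spec in nutrients:
        flux = max(0.0, fluxes[spec.name])
        mass = scale * flux_to_feed_mass(flux, spec, X0, mu, dt_next)
        out.append(
            FeedPrediction(
                nutrient=spec.name,
                interval=(t_now, t_now + dt_next),
                uptake_flux=flux,
                feed_mass_conc=mass,
                scale_factor=scale,
                mu=mu,
                flags=list(flags),
            )
        )
    return out


@dataclass
class FeedSchedule:
    """Ordered feed predictions plus exact cumulative accounting."""

    predictions: list[FeedPrediction] = field(default_factory=list)
    failures: list[tuple[float, str]] = field(default_factory=list)

    def total(self, nutrient: str | None = None) -> float:
        masses = [
            p.feed_mass_conc
            for p in self.predictions
            if nutrient is None or p.nutrient == nutrient
        ]
        return math.fsum(masses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": [p.interval[0] for p in self.predictions],
                "nutrient": [p.nutrient for p in self.predictions],
                "feed_mg_L": [p.feed_mass_conc for p in self.predictions],
                "uptake_flux": [p.uptake_flux for p in self.predictions],
                "mu": [p.mu for p in self.predictions],
                "flags": [";".join(p.flags) for p in self.predictions],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_schedule(
    variant: ModelVariant,
    series: ODSeries,
    feed_times: list[float],
    nutrient: NutrientSpec = NITRATE,
    nutrients: list[NutrientSpec] | None = None,
    cap: UptakeCapModel | None = None,
    scale: float = 1.0,
    dt_next: float | None = None,
) -> FeedSchedule:
    """Predict a feed at each feed time using the latest two observations.

    Per-time-point failures are recorded and skipped rather than aborting the
    whole schedule. ``dt_next`` defaults to the gap to the following feed time
    (the last interval reuses the preceding gap).
    """
    schedule = FeedSchedule()
    feed_times = sorted(feed_times)
    for k, t in enumerate(feed_times):
        try:
            past = series.times[series.times <= t + 1e-9]
            if len(past) < 2:
                raise ValueError(f"need two observations at or before t={t} h")
            t_prev, t_now = float(past[-2]), float(past[-1])
            if dt_next is not None:
                dt = dt_next
            elif k + 1 < len(feed_times):
                dt = feed_times[k + 1] - t
            elif k > 0:
                dt = t - feed_times[k - 1]
            else:
                dt = t_now - t_prev
            if variant.trophic_mode == "heterotrophic":
                preds = predict_feeds_heterotrophic(
                    variant, series, t_prev, t_now, dt, nutrients, cap, scale
                )
                schedule.predictions.extend(preds)
            else:
                schedule.predictions.append(
                    predict_feed_autotrophic(variant, series, t_prev, t_now, dt, nutrient, scale)
                )
        except Exception as exc:
            logger.warning("feed prediction at t=%s h failed: %s", t, exc)
            schedule.failures.append((t, str(exc)))
    return schedule
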