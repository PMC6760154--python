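"""Virtual Chlorella culture: a discrete-time nitrogen-quota model.

The simulator is the closed-loop test bed for the feed controller. It
reproduces the phenomenology the controller relies on without being the
controller's own model:

* exponential growth at ``mu_max`` while the internal nitrogen quota is replete;
* luxury nitrate uptake into an internal quota (storage), so cells can keep
  growing after the medium runs dry and can absorb over-feeding without
  growing faster;
* growth slow-down as the quota dilutes a few percent below the replete level, and a
  hard cessation once the protein fraction falls below ``p_min`` (~10%);
* under heterotrophy, glucose-limited growth with an optional polynomial
  uptake-capacity cap in accumulated biomass, emulating the high-density
  uptake bottleneck.

State tracks biomass X (gDW/L), medium nitrate and glucose pools (mg/L), and
the protein mass fraction p. The quota q (mmol N per gDW) maps to p by
proportional scaling from the replete point: p = p_target · q / q_target.
Nutrient mass is conserved exactly each step: pool_out = pool_in + feed − uptake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import mmc_controller as ctrl
from .model_core import ModelVariant

__all__ = [
    "CultureState",
    "CellParams",
    "step",
    "run_closed_loop",
    "generate_observations",
]

MW_NITRATE = 62.00
MW_GLUCOSE = 180.16


@dataclass
class CellParams:
    """Virtual-cell parameters.

    ``Y_N`` (gDW per mmol nitrate) sets the replete quota q_target = 1/Y_N;
    ``Y_G`` is gDW per mmol glucose. ``p_target`` and ``p_min`` delimit the
    protein fraction between nitrogen-replete growth and cessation.
    """

    mu_max: float = 0.0137  # h^-1, replete autotrophic growth rate
    Y_N: float = 1.0 / 5.665  # gDW per mmol nitrate (replete autotrophic N demand)
    Y_G: float = 0.09  # gDW per mmol glucose
    p_min: float = 0.10  # protein fraction below which growth stops
    p_target: float = 0.45  # nitrogen-replete protein fraction
    vmax_N: float = 0.5  # mmol nitrate gDW^-1 h^-1 maximal uptake
    vmax_G: float = 2.0  # mmol glucose gDW^-1 h^-1 maximal uptake
    require_glucose: bool = False  # heterotrophic mode
    glc_cap_coeffs: tuple[float, ...] | None = None  # poly(integrated biomass), ascending
    od_to_gdw: float = ctrl.DEFAULT_OD_TO_GDW
    sigma: float = 0.0  # measurement noise (lognormal on OD, relative on conc.)
    seed: int = 0
    # quota-ramp shape factors (fractions of q_target / q_min)
    q_sat_frac: float = 0.95  # growth saturates at q >= 0.95 q_target
    q_floor_frac: float = 0.8  # ramp extrapolates to zero at 0.8 q_min
    q_max_frac: float = 1.1  # luxury storage headroom above q_target

    def __post_init__(self) -> None:
        for name in ("mu_max", "Y_N", "Y_G", "p_min", "p_target", "vmax_N", "vmax_G"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p_min >= self.p_target:
            raise ValueError("p_min must be below p_target")

    @property
    def q_target(self) -> float:
        """Replete internal quota, mmol N per gDW."""
        return 1.0 / self.Y_N

    @property
    def q_min(self) -> float:
        return self.q_target * self.p_min / self.p_target

    @property
    def q_max(self) -> float:
        return self.q_target * self.q_max_frac

    def p_of_q(self, q: float) -> float:
        return self.p_target * q / self.q_target

    def q_of_p(self, p: float) -> float:
        return self.q_target * p / self.p_target

    def growth_factor(self, q: float) -> float:
        """Quota-availability multiplier on mu_max, in [0, 1].

        Zero below q_min (protein < p_min); linear ramp up to saturation at
        q_sat = q_sat_frac * q_target.
        """
        if q < self.q_min:
            return 0.0
        q_floor = self.q_floor_frac * self.q_min
        q_sat = self.q_sat_frac * self.q_target
        return float(np.clip((q - q_floor) / (q_sat - q_floor), 0.0, 1.0))

    def glc_cap_flux(self, integrated_biomass: float) -> float:
        if self.glc_cap_coeffs is None:
            return math.inf
        val = np.polynomial.polynomial.polyval(integrated_biomass, np.asarray(self.glc_cap_coeffs))
        return max(0.0, float(val))


@dataclass
class CultureState:
    t: float  # h
    X: float  # gDW/L
    S_N: float  # nitrate, mg/L
    S_G: float = 0.0  # glucose, mg/L
    p: float = 0.45  # protein mass fraction
    B_int: float = 0.0  # integrated biomass, gDW L^-1 h

    def __post_init__(self) -> None:
        if self.X <= 0:
            raise ValueError("X must be positive")
        if self.S_N < 0 or self.S_G < 0:
            raise ValueError("nutrient pools cannot be negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be a fraction in [0, 1]")

    def od750(self, od_to_gdw: float = ctrl.DEFAULT_OD_TO_GDW) -> float:
        return self.X / od_to_gdw


def step(
    state: CultureState,
    params: CellParams,
    dt: float,
    feeds: dict[str, float] | None = None,
) -> CultureState:
    """Advance the culture one time step.

    Feeds (mg/L) enter the pools first; nitrate uptake then refills the quota
    (limited by the pool, the uptake rate vmax_N, and the storage headroom);
    growth proceeds at mu_max scaled by the quota ramp and, under heterotrophy,
    limited by available glucose; finally the quota is diluted by the new
    biomass. Deterministic; all randomness lives in observation noise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    feeds = feeds or {}
    S_N = state.S_N + feeds.get("nitrate", 0.0)
    S_G = state.S_G + feeds.get("glucose", 0.0)
    X = state.X
    q = params.q_of_p(state.p)

    # nitrate uptake into the quota (luxury uptake up to q_max)
    avail = S_N / MW_NITRATE  # mmol/L
    headroom = max(0.0, params.q_max - q) * X
    upt_N = min(avail, params.vmax_N * X * dt, headroom)
    S_N -= upt_N * MW_NITRATE
    S_N = max(0.0, S_N)  # guard float dust only; conservation is exact in mmol
    q = q + upt_N / X

    # growth
    mu_d = params.mu_max * params.growth_factor(q)
    dX = X * (math.exp(mu_d * dt) - 1.0)
    if params.require_glucose:
        need_G = dX / params.Y_G  # mmol/L
        cap = params.glc_cap_flux(state.B_int)
        upt_G = min(need_G, S_G / MW_GLUCOSE, params.vmax_G * X * dt, cap * X * dt)
        dX = upt_G * params.Y_G
        S_G -= upt_G * MW_GLUCOSE
        S_G = max(0.0, S_G)
    X_new = X + dX
    q_new = q * X / X_new  # cellular N conserved, diluted by growth

    return replace(
        state,
        t=state.t + dt,
        X=X_new,
        S_N=S_N,
        S_G=S_G,
        p=params.p_of_q(q_new),
        B_int=state.B_int + X * dt,
    )


@dataclass
class ClosedLoopResult:
    trajectory: pd.DataFrame
    schedule: ctrl.FeedSchedule
    ledger: "FeedLedger"  # noqa: F821 - imported lazily to avoid a cycle

    @property
    def final_biomass(self) -> float:
        return float(self.trajectory["X_gDW_L"].iloc[-1])


def run_closed_loop(
    params: CellParams,
    variant: ModelVariant | None,
    horizon: float,
    X0: float = 0.1,
    initial_nitrate: float = 25.0,
    initial_glucose: float = 0.0,
    feed_every: float = 24.0,
    feed_start: float | None = None,
    scale: float = 1.0,
    strategy: str = "mmc",
    fixed_mu: float = 0.0137,
    cap=None,
    sim_dt: float = 0.5,
) -> ClosedLoopResult:
    """Alternate simulator steps with controller feed predictions.

    Strategies: ``mmc`` (growth estimated from the simulated OD, feeds from
    the FBA uptake minimization), ``biorule`` (feeds computed from a fixed
    assumed growth rate instead of measurements), ``bulk`` (no feeding beyond
    the initial charge). Observations passed to the controller are the exact
    simulated ODs; use :func:`generate_observations` for noisy re-estimation
    studies.
    """
    from .ledger_io import FeedLedger

    if strategy not in ("mmc", "biorule", "bulk"):
        raise ValueError(f"unknown strategy {strategy!r}")
    state = CultureState(
        t=0.0, X=X0, S_N=initial_nitrate, S_G=initial_glucose, p=params.p_target
    )
    ledger = FeedLedger(
        initial_charges={"nitrate": initial_nitrate, "glucose": initial_glucose}
    )
    schedule = ctrl.FeedSchedule()
    heterotrophic = variant is not None and variant.trophic_mode == "heterotrophic"

    if feed_start is None:
        feed_start = feed_every
    feed_times = (
        [] if strategy == "bulk" else list(np.arange(feed_start, horizon - 1e-9, feed_every))
    )

    rows = [_row(state, params)]
    obs_t = [0.0]
    obs_od = [state.od750(params.od_to_gdw)]
    pending: dict[str, float] = {}
    n_steps = int(round(horizon / sim_dt))
    next_feed = 0

    for _ in range(n_steps):
        state = step(state, params, sim_dt, pending)
        pending = {}
        rows.append(_row(state, params))
        if next_feed < len(feed_times) and state.t >= feed_times[next_feed] - 1e-9:
            t_now = state.t
            obs_t.append(t_now)
            obs_od.append(state.od750(params.od_to_gdw))
            series = ctrl.ODSeries(np.array(obs_t), np.array(obs_od), params.od_to_gdw)
            t_prev = obs_t[-2]
            try:
                preds = _predict(
                    variant, series, t_prev, t_now, feed_every, scale, strategy,
                    fixed_mu, heterotrophic, cap,
                )
                for p in preds:
                    schedule.predictions.append(p)
                    pending[p.nutrient] = pending.get(p.nutrient, 0.0) + p.feed_mass_conc
                    ledger.add_feed(p.interval[0], p.nutrient, p.feed_mass_conc)
            except Exception as exc:  # per-point failures do not abort the run
                schedule.failures.append((t_now, str(exc)))
            next_feed += 1

    trajectory = pd.DataFrame(rows)
    return ClosedLoopResult(trajectory=trajectory, schedule=schedule, ledger=ledger)


def _predict(
    variant, series, t_prev, t_now, dt_next, scale, strategy, fixed_mu, heterotrophic, cap
) -> list[ctrl.FeedPrediction]:
    if strategy == "biorule":
        # fixed assumed growth rate; feed covers that growth regardless of OD
        X0 = series.biomass_at(t_now)
        demand = variant.composition.nitrogen_demand
        flux = demand * fixed_mu
        mass = scale * ctrl.flux_to_feed_mass(flux, ctrl.NITRATE, X0, fixed_mu, dt_next)
        return [
            ctrl.FeedPrediction(
                nutrient="nitrate",
                interval=(t_now, t_now + dt_next),
                uptake_flux=flux,
                feed_mass_conc=mass,
                scale_factor=scale,
                mu=fixed_mu,
                flags=["biorule"],
            )
        ]
    if heterotrophic:
        return ctrl.predict_feeds_heterotrophic(
            variant, series, t_prev, t_now, dt_next, cap=cap, scale=scale
        )
    return [
        ctrl.predict_feed_autotrophic(variant, series, t_prev, t_now, dt_next, scale=scale)
    ]


def _row(state: CultureState, params: CellParams) -> dict:
    return {
        "time_h": state.t,
        "od750": state.od750(params.od_to_gdw),
        "X_gDW_L": state.X,
        "nitrate_mg_L": state.S_N,
        "glucose_mg_L": state.S_G,
        "protein_frac": state.p,
        "integrated_biomass": state.B_int,
    }


def generate_observations(
    trajectory: pd.DataFrame,
    sigma: float = 0.0,
    seed: int = 0,
    od_to_gdw: float = ctrl.DEFAULT_OD_TO_GDW,
    every: float | None = None,
) -> tuple[ctrl.ODSeries, pd.DataFrame]:
    """Turn a simulated trajectory into noisy observations.

    OD gets multiplicative lognormal noise exp(N(0, sigma)); nutrient
    concentrations get relative truncated-normal noise (clipped at zero).
    Reproducible given ``seed``. ``every`` subsamples to a measurement cadence
    in hours.
    """
    df = trajectory
    if every is not None:
        keep = np.isclose(np.mod(df["time_h"], every), 0.0) | np.isclose(
            np.mod(df["time_h"], every), every
        )
        df = df[keep]
    rng = np.random.default_rng(seed)
    od = df["od750"].to_numpy() * np.exp(rng.normal(0.0, sigma, len(df)))
    series = ctrl.ODSeries(df["time_h"].to_numpy(), od, od_to_gdw)
    conc = df[["time_h", "nitrate_mg_L", "glucose_mg_L"]].copy()
    for col in ("nitrate_mg_L", "glucose_mg_L"):
        vals = conc[col].to_numpy()
        noisy = vals * (1.0 + rng.normal(0.0, sigma, len(vals)))
        conc[col] = np.maximum(noisy, 0.0)
    return series, conc.reset_index(drop=True)
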