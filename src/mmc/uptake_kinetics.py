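"""Empirical glucose-uptake capacity as a function of accumulated biomass.

At high cell densities the observed glucose consumption rate decouples from
FBA demand — the culture cannot take glucose up as fast as a growth-pinned
model asks for. The remedy is phenomenological: fit a polynomial to measured
uptake rate against accumulated biomass and impose the fitted curve as the
glucose uptake bound, which in turn caps the achievable growth rate that the
controller may assume.

The regressor axis is either the time-integral of biomass concentration
(gDW·L⁻¹·h, default) or the instantaneous biomass concentration; the choice is
recorded on the fitted model so a cap is never evaluated on the wrong axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model_core import ModelVariant

__all__ = ["UptakeCapModel", "fit_uptake_cap", "apply_uptake_cap"]

REGRESSORS = ("integrated_biomass", "biomass_concentration")


@dataclass
class UptakeCapModel:
    """Polynomial uptake capacity, clipped below at zero.

    ``coeffs`` are in ascending-power order (numpy polynomial convention):
    ``cap(x) = max(0, sum_k coeffs[k] * x**k)``.
    """

    coeffs: np.ndarray
    degree: int
    r_squared: float
    regressor: str = "integrated_biomass"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")
        if len(self.coeffs) != self.degree + 1:
            raise ValueError("need degree+1 coefficients")
        if self.regressor not in REGRESSORS:
            raise ValueError(f"regressor must be one of {REGRESSORS}")

    def __call__(self, x):
        return self.predict(x)

    def predict(self, x):
        """Evaluate the cap; uptake capacity is never negative."""
        y = np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coeffs)
        return np.maximum(y, 0.0)

    def to_json_dict(self) -> dict:
        return {
            "coeffs": self.coeffs.tolist(),
            "degree": self.degree,
            "r_squared": self.r_squared,
            "regressor": self.regressor,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json_dict(cls, d: dict) -> "UptakeCapModel":
        return cls(np.asarray(d["coeffs"]), d["degree"], d["r_squared"], d["regressor"])

    @classmethod
    def from_json(cls, path) -> "UptakeCapModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def fit_uptake_cap(
    biomass_axis,
    uptake_rate,
    degree: int = 2,
    regressor: str = "integrated_biomass",
) -> UptakeCapModel:
    """Least-squares polynomial fit of uptake rate against accumulated biomass.

    Parameters
    ----------
    biomass_axis
        Accumulated biomass (units per ``regressor``).
    uptake_rate
        Specific glucose uptake rate, mmol·gDW⁻¹·h⁻¹. Volumetric rates must be
        divided by the prevailing biomass concentration before fitting.
    degree
        Polynomial degree (default 2, the lowest degree capturing saturation
        followed by decline).

    R² is computed as 1 − SS_res/SS_tot.
    """
    x = np.asarray(biomass_axis, dtype=float)
    y = np.asarray(uptake_rate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("biomass_axis and uptake_rate must be equal-length 1-D series")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if len(x) < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: biomass axis is constant")
    # Polynomial.fit uses a scaled domain for conditioning; convert back
    poly = np.polynomial.Polynomial.fit(x, y, degree).convert()
    coeffs = np.zeros(degree + 1)
    coeffs[: len(poly.coef)] = poly.coef
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return UptakeCapModel(coeffs, degree, r2, regressor)


def apply_uptake_cap(
    variant: ModelVariant, cap: UptakeCapModel, biomass_axis_value: float
) -> ModelVariant:
    """Return a copy of ``variant`` with glucose uptake bounded by the cap.

    The glucose uptake upper bound becomes ``max(0, cap(biomass_axis_value))``,
    never exceeding the bound already in place (a capacity limit only
    restricts); all other bounds are untouched.
    """
    if "glucose" not in variant.network.uptake_rxns:
        raise KeyError("variant has no mapped glucose uptake reaction")
    out = variant.copy()
    limit = float(cap.predict(biomass_axis_value))
    rxn = out.network.uptake_rxns["glucose"]
    j = out.network.reaction_index(rxn)
    limit = min(limit, out.network.ub[j])
    out.network.lb[j] = min(out.network.lb[j], limit)
    out.network.ub[j] = limit
    return out
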