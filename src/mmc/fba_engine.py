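"""FBA linear programs with switchable objectives.

Flux balance analysis solves ``optimize c·v subject to S v = 0, lb <= v <= ub``.
Three entry points match how the feed controller uses the model:

* :func:`maximize_growth` — the conventional biomass-maximization FBA;
* :func:`minimize_uptake_at_growth` — the objective inversion at the heart of
  metabolic model control: the biomass flux is pinned to the observed growth
  rate mu and the uptake flux of one nutrient is minimized, yielding the
  smallest supply consistent with that growth;
* :func:`lexicographic_minimize` — sequential minimization (glucose then
  nitrate under heterotrophy): each stage fixes the previously minimized
  uptakes at their optima before minimizing the next.

All LPs are solved with scipy's HiGHS backend. Only objective *values* are
consumed downstream; degenerate alternate flux vectors are left as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_core import MetabolicNetwork, ModelVariant

__all__ = [
    "ObjectiveSpec",
    "FluxSolution",
    "solve",
    "maximize_growth",
    "minimize_uptake_at_growth",
    "lexicographic_minimize",
]

logger = logging.getLogger(__name__)

#: slack used when "fixing" a flux to a previously obtained optimum
FIX_TOL = 1e-9

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass
class ObjectiveSpec:
    reaction_id: str
    sense: str  # "maximize" | "minimize"

    def __post_init__(self) -> None:
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"sense must be maximize or minimize, got {self.sense!r}")


@dataclass
class FluxSolution:
    """Outcome of one FBA solve.

    ``objective_value`` is the signed flux of the objective reaction (not the
    LP's internal sign-flipped objective). ``meta`` carries diagnostics such as
    the maximum achievable growth when a growth-constrained solve is infeasible.
    """

    v: np.ndarray | None
    objective_id: str
    objective_value: float | None
    status: str
    reaction_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        if self.v is None:
            raise ValueError(f"no flux vector (status={self.status})")
        return float(self.v[self.reaction_ids.index(rxn_id)])

    def fluxes(self) -> dict[str, float]:
        if self.v is None:
            return {}
        return {r: float(x) for r, x in zip(self.reaction_ids, self.v)}


def solve(network: MetabolicNetwork, objective: ObjectiveSpec) -> FluxSolution:
    """Solve one FBA LP. Solver failures surface in ``status``, never silently."""
    j = network.reaction_index(objective.reaction_id)
    c = np.zeros(network.n_reactions)
    c[j] = -1.0 if objective.sense == "maximize" else 1.0
    res = linprog(
        c,
        A_eq=network.S if network.n_metabolites else None,
        b_eq=np.zeros(network.n_metabolites) if network.n_metabolites else None,
        bounds=list(zip(network.lb, network.ub)),
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    v = np.asarray(res.x) if res.status == 0 else None
    value = float(v[j]) if v is not None else None
    logger.info(
        "LP %s %s: status=%s value=%s",
        objective.sense,
        objective.reaction_id,
        status,
        value,
    )
    return FluxSolution(
        v=v,
        objective_id=objective.reaction_id,
        objective_value=value,
        status=status,
        reaction_ids=list(network.reaction_ids),
    )


def maximize_growth(variant: ModelVariant) -> FluxSolution:
    """Conventional FBA: maximize the biomass flux under current bounds."""
    net = variant.network
    return solve(net, ObjectiveSpec(net.biomass_rxn, "maximize"))


def _with_growth_fixed(
    network: MetabolicNetwork, mu: float, growth_tolerance: float = 0.0
) -> MetabolicNetwork:
    net = network.copy()
    net.set_bounds(net.biomass_rxn, lb=mu, ub=mu * (1.0 + growth_tolerance) if mu else mu)
    return net


def minimize_uptake_at_growth(
    variant: ModelVariant,
    nutrient: str,
    mu: float,
    growth_tolerance: float = 0.0,
) -> FluxSolution:
    """Minimize one nutrient's uptake flux with growth pinned to ``mu``.

    The biomass reaction is constrained to lb = ub = mu (``growth_tolerance``
    relaxes the upper bound to mu*(1+eps) for numerically brittle models). If
    mu exceeds the network's capacity the solve is infeasible; the returned
    solution then carries the maximum achievable growth in
    ``meta["max_growth"]`` for diagnostics.
    """
    if mu < 0:
        raise ValueError(f"growth rate must be >= 0, got {mu}")
    net = variant.network
    rxn = net.uptake_rxns[nutrient] if nutrient in net.uptake_rxns else None
    if rxn is None:
        raise KeyError(
            f"nutrient {nutrient!r} has no mapped uptake reaction "
            f"(available: {sorted(net.uptake_rxns)})"
        )
    fixed = _with_growth_fixed(net, mu, growth_tolerance)
    sol = solve(fixed, ObjectiveSpec(rxn, "minimize"))
    if not sol.ok:
        cap = maximize_growth(variant)
        sol.meta["max_growth"] = cap.objective_value if cap.ok else 0.0
        logger.warning(
            "uptake minimization infeasible at mu=%.6g (max achievable %.6g)",
            mu,
            sol.meta["max_growth"] or 0.0,
        )
    return sol


def lexicographic_minimize(
    variant: ModelVariant,
    mu: float,
    order: list[str] | None = None,
    growth_tolerance: float = 0.0,
) -> dict[str, float]:
    """Sequentially minimize uptakes in ``order`` at fixed growth ``mu``.

    After each stage the minimized uptake is fixed (equality within
    ``FIX_TOL``) before the next nutrient is minimized, so earlier optima are
    never degraded by later stages. Raises :class:`InfeasibleStage` naming the
    failing stage on infeasibility.
    """
    if order is None:
        order = ["glucose", "nitrate"]
    if not order:
        raise ValueError("order must be a nonempty nutrient list")
    net = _with_growth_fixed(variant.network, mu, growth_tolerance)
    result: dict[str, float] = {}
    for nutrient in order:
        rxn = variant.network.uptake_rxns.get(nutrient)
        if rxn is None:
            raise KeyError(f"nutrient {nutrient!r} has no mapped uptake reaction")
        sol = solve(net, ObjectiveSpec(rxn, "minimize"))
        if not sol.ok:
            raise InfeasibleStage(nutrient, sol.status)
        opt = sol.objective_value
        result[nutrient] = opt
        j = net.reaction_index(rxn)
        net.lb[j] = opt - FIX_TOL
        net.ub[j] = opt + FIX_TOL
    return result


class InfeasibleStage(RuntimeError):
    """A lexicographic stage's LP was infeasible or failed."""

    def __init__(self, nutrient: str, status: str):
        self.nutrient = nutrient
        self.status = status
        super().__init__(f"lexicographic stage {nutrient!r} failed: {status}")
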