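"""Flux Balance Analysis and flux unfolding.

FBA computes a flux vector ``v*`` maximising the objective ``c^T v`` subject
to the steady-state mass balance ``S v = 0`` and box bounds
``lb <= v <= ub``. The LP is solved with scipy's HiGHS dual simplex so that
repeated runs return the same vertex solution.

The solution is *unfolded* into non-negative forward/backward components
``v2m = [v+; v-]`` with ``v+ = (|v| + v)/2`` and ``v- = (|v| - v)/2``; the
metabolite flux vector ``j`` (production flux of each metabolite, equal to
its consumption flux at steady state) feeds the mass flow graph construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse

from .model_io import MetabolicModel

__all__ = [
    "Scenario",
    "FluxSolution",
    "ConfigurationError",
    "SteadyStateError",
    "solve_fba",
    "unfold_fluxes",
    "builtin_scenarios",
    "load_scenario_file",
]


class ConfigurationError(ValueError):
    """A scenario references reactions absent from the model."""


class SteadyStateError(ValueError):
    """A flux vector claimed balanced violates S v = 0 beyond tolerance."""


@dataclass
class Scenario:
    """Growth-condition encoding: per-reaction bound overrides in mmol/gDW/h."""

    name: str
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective_reaction: str | None = None

    def validate(self, model: MetabolicModel) -> None:
        missing = [rid for rid in self.bound_overrides if rid not in model.reaction_ids]
        if self.objective_reaction is not None and \
                self.objective_reaction not in model.reaction_ids:
            missing.append(self.objective_reaction)
        if missing:
            raise ConfigurationError(
                f"scenario {self.name!r}: unknown reactions {missing}"
            )
        for rid, (lo, hi) in self.bound_overrides.items():
            if lo > hi:
                raise ConfigurationError(
                    f"scenario {self.name!r}: lb > ub for {rid}"
                )


@dataclass
class FluxSolution:
    """An FBA solution with its unfolded flux bookkeeping.

    ``status`` is one of ``optimal``, ``infeasible`` or ``unbounded``; the
    flux fields are only populated for optimal solutions. ``mode`` records
    whether the plain LP or the minimum-total-flux second stage produced v.
    """

    status: str
    objective_value: float | None = None
    v: np.ndarray | None = None
    v2m: np.ndarray | None = None
    j: np.ndarray | None = None
    mode: str = "single_stage"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _apply_scenario(model: MetabolicModel, scenario: Scenario | None):
    lb, ub, c = model.lb.copy(), model.ub.copy(), model.c.copy()
    if scenario is not None:
        scenario.validate(model)
        for rid, (lo, hi) in scenario.bound_overrides.items():
            j = model.reaction_index(rid)
            lb[j], ub[j] = lo, hi
        if scenario.objective_reaction is not None:
            c[:] = 0.0
            c[model.reaction_index(scenario.objective_reaction)] = 1.0
    return lb, ub, c


def solve_fba(
    model: MetabolicModel,
    scenario: Scenario | None = None,
    *,
    minimize_total_flux: bool = False,
    tol: float = 1e-9,
) -> FluxSolution:
    """Maximise ``c^T v`` subject to ``S v = 0`` and ``lb <= v <= ub``.

    With ``minimize_total_flux=True`` a second LP minimises the total
    absolute flux at the fixed optimal objective, selecting a reproducible
    representative among degenerate optima (off by default).
    """
    lb, ub, c = _apply_scenario(model, scenario)
    A = scipy.sparse.csr_matrix(model.S)
    opts = {"primal_feasibility_tolerance": tol, "dual_feasibility_tolerance": tol}
    res = scipy.optimize.linprog(
        -c, A_eq=A, b_eq=np.zeros(model.n), bounds=np.column_stack([lb, ub]),
        method="highs-ds", options=opts,
    )
    if res.status == 2:
        return FluxSolution(status="infeasible")
    if res.status == 3:
        return FluxSolution(status="unbounded")
    if res.status != 0:
        return FluxSolution(status=f"solver_failure:{res.status}")
    v = res.x
    objective = float(c @ v)
    mode = "single_stage"
    if minimize_total_flux:
        # minimise sum(u) with u >= |v|, at fixed objective value
        m = model.m
        ones = np.ones(m)
        A_eq = scipy.sparse.hstack([A, scipy.sparse.csr_matrix((model.n, m))])
        A_eq = scipy.sparse.vstack(
            [A_eq, scipy.sparse.csr_matrix(np.concatenate([c, np.zeros(m)]))]
        )
        b_eq = np.concatenate([np.zeros(model.n), [objective]])
        eye = scipy.sparse.eye(m)
        A_ub = scipy.sparse.vstack(
            [scipy.sparse.hstack([eye, -eye]), scipy.sparse.hstack([-eye, -eye])]
        )
        b_ub = np.zeros(2 * m)
        big = max(1.0, np.max(np.abs(v))) * 1e3
        bounds2 = np.vstack([
            np.column_stack([lb, ub]),
            np.column_stack([np.zeros(m), np.full(m, big)]),
        ])
        res2 = scipy.optimize.linprog(
            np.concatenate([np.zeros(m), ones]), A_ub=A_ub, b_ub=b_ub,
            A_eq=A_eq, b_eq=b_eq, bounds=bounds2, method="highs-ds", options=opts,
        )
        if res2.status == 0:
            v = res2.x[:m]
            mode = "min_total_flux"
    v2m, j = unfold_fluxes(v, model, atol=1e-5)
    return FluxSolution(
        status="optimal", objective_value=objective, v=v, v2m=v2m, j=j, mode=mode
    )


def unfold_fluxes(
    v: np.ndarray, model: MetabolicModel, atol: float | None = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``v`` into ``v2m = [v+; v-] >= 0`` and compute metabolite fluxes.

    ``j[k]`` is the flux at which metabolite ``k`` is produced, computed from
    the production split. When ``atol`` is not None the consumption-based
    computation must agree to ``atol`` (scaled by max|v|), otherwise a
    :class:`SteadyStateError` is raised — production and consumption fluxes
    coincide exactly only for balanced vectors.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("flux vector contains non-finite entries")
    vplus = (np.abs(v) + v) / 2.0
    vminus = (np.abs(v) - v) / 2.0
    v2m = np.concatenate([vplus, vminus])
    from .graph_construction import unfold  # lazy: avoids import cycle

    sys = unfold(model)
    j_prod = sys.Splus @ v2m
    j_cons = sys.Sminus @ v2m
    if atol is not None:
        scale = max(1.0, float(np.max(np.abs(v), initial=0.0)))
        gap = np.abs(j_prod - j_cons)
        worst = int(np.argmax(gap))
        if gap[worst] > atol * scale:
            raise SteadyStateError(
                f"production/consumption flux mismatch {gap[worst]:.3g} at "
                f"metabolite {model.metabolite_ids[worst]!r}"
            )
    return v2m, j_prod


# --- built-in growth scenarios for the E. coli core model -------------------

_CARBON_UPTAKE = 18.5     # mmol/gDW/h, every available carbon source
_NH4_LIMIT = 4.5          # mmol/gDW/h
_PI_LIMIT = 3.04          # mmol/gDW/h

_GLC, _ETOH, _O2, _NH4, _PI = (
    "EX_glc__D_e", "EX_etoh_e", "EX_o2_e", "EX_nh4_e", "EX_pi_e"
)


def builtin_scenarios(model: MetabolicModel) -> list[Scenario]:
    """The four standard growth conditions for the *E. coli* core model.

    All scenarios keep the distributed defaults for every exchange not
    explicitly constrained (rich media) and set each available carbon uptake
    to 18.5 mmol/gDW/h:

    * ``aerobic_glucose`` — glucose at 18.5, oxygen unconstrained;
    * ``aerobic_ethanol`` — glucose shut off, ethanol at 18.5;
    * ``anaerobic_glucose`` — glucose at 18.5, oxygen intake capped at 0;
    * ``limited_phosphate_ammonium`` — glucose at 18.5, NH4 and phosphate
      intakes capped at 4.5 and 3.04 (half the unrestricted aerobic levels).

    Uptake is a negative exchange flux, so an intake cap of ``u`` becomes an
    exchange lower bound of ``-u``.
    """
    ub_of = {rid: model.ub[j] for j, rid in enumerate(model.reaction_ids)}
    missing = [rid for rid in (_GLC, _ETOH, _O2, _NH4, _PI) if rid not in ub_of]
    if missing:
        raise ConfigurationError(f"model lacks exchange reactions: {missing}")
    return [
        Scenario("aerobic_glucose", {_GLC: (-_CARBON_UPTAKE, ub_of[_GLC])}),
        Scenario("aerobic_ethanol", {
            _GLC: (0.0, ub_of[_GLC]),
            _ETOH: (-_CARBON_UPTAKE, ub_of[_ETOH]),
        }),
        Scenario("anaerobic_glucose", {
            _GLC: (-_CARBON_UPTAKE, ub_of[_GLC]),
            _O2: (0.0, ub_of[_O2]),
        }),
        Scenario("limited_phosphate_ammonium", {
            _GLC: (-_CARBON_UPTAKE, ub_of[_GLC]),
            _NH4: (-_NH4_LIMIT, ub_of[_NH4]),
            _PI: (-_PI_LIMIT, ub_of[_PI]),
        }),
    ]


def load_scenario_file(path, name: str | None = None) -> Scenario:
    """Read a flat scenario config: ``reaction_id = lb,ub`` per line."""
    from pathlib import Path

    path = Path(path)
    overrides: dict[str, tuple[float, float]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            rid, rest = line.split("=", 1)
            lo, hi = rest.split(",")
            overrides[rid.strip()] = (float(lo), float(hi))
        except ValueError as exc:
            raise ConfigurationError(
                f"{path.name}:{lineno}: cannot parse {line!r}"
            ) from exc
    return Scenario(name or path.stem, overrides)
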