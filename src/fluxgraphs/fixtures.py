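"""Synthetic metabolic models and balanced fluxes for tests and examples.

Provides a small hand-written toy network (uptake, biosynthesis, waste
secretion, biomass) and a parametric generator of random sparse
stoichiometries with guaranteed producer/consumer coverage, plus balanced
flux vectors drawn from the null space of S. Everything is deterministic
given a seed, so no external model files are ever required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model_io import MetabolicModel

__all__ = ["FixtureSpec", "toy_network", "chain_model", "random_model",
           "random_balanced_flux"]


@dataclass
class FixtureSpec:
    """Parameters of the random model generator.

    ``density`` is the expected fraction of non-zero entries per reaction
    column beyond the guaranteed ones; ``flux_mode`` records how fluxes are
    meant to be generated for the fixture (a null-space draw or an FBA
    solve). Defaults give a small, well-connected network in which every
    metabolite has at least one producer and one consumer, the regime the
    probabilistic graphs are designed for.
    """

    n_metabolites: int = 6
    n_reactions: int = 10
    fraction_reversible: float = 0.3
    density: float = 0.3
    seed: int = 0
    flux_mode: str = "null_space_random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_reversible <= 1.0:
            raise ValueError("fraction_reversible must be in [0, 1]")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if self.flux_mode not in ("null_space_random", "fba"):
            raise ValueError(f"unknown flux_mode {self.flux_mode!r}")


def chain_model() -> MetabolicModel:
    """Two-reaction chain: R1 imports X1, R2 exports it (both irreversible)."""
    return MetabolicModel(
        metabolite_ids=["X1"],
        reaction_ids=["R1", "R2"],
        S=np.array([[1.0, -1.0]]),
        r=np.zeros(2, dtype=int),
        lb=np.zeros(2),
        ub=np.full(2, 1000.0),
        c=np.array([0.0, 1.0]),
    )


def toy_network() -> MetabolicModel:
    """Eight-reaction toy metabolic network over metabolites X1..X5.

    A synthetic minimal network with the canonical anatomy of a metabolic
    model: nutrient uptake (R1), biosynthesis of intermediates (R2, R3, R5,
    R6), a reversible interconversion (R4), secretion of a waste product
    (R7), and a biomass reaction R8 consuming X3 + 2 X4 + X5. R4 is the only
    reversible reaction. (The stoichiometry beyond these anchoring facts is
    this package's own construction.)

        R1: -> X1            R2: X1 -> X2         R3: X1 -> X3
        R4: X2 <-> X4        R5: X2 -> X5         R6: X3 -> X4
        R7: X4 ->            R8: X3 + 2 X4 + X5 ->  (biomass)
    """
    mets = ["X1", "X2", "X3", "X4", "X5"]
    rxns = ["R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8"]
    S = np.array([
        #  R1   R2   R3   R4   R5   R6   R7   R8
        [1.0, -1., -1.,  0.,  0.,  0.,  0.,  0.],   # X1
        [0.0,  1.,  0., -1., -1.,  0.,  0.,  0.],   # X2
        [0.0,  0.,  1.,  0.,  0., -1.,  0., -1.],   # X3
        [0.0,  0.,  0.,  1.,  0.,  1., -1., -2.],   # X4
        [0.0,  0.,  0.,  0.,  1.,  0.,  0., -1.],   # X5
    ])
    r = np.array([0, 0, 0, 1, 0, 0, 0, 0])
    lb = np.where(r == 1, -1000.0, 0.0)
    lb[0] = 0.0
    ub = np.full(8, 1000.0)
    ub[0] = 10.0  # uptake capacity
    c = np.zeros(8)
    c[7] = 1.0
    subsystem = {
        "R1": "Uptake", "R2": "Biosynthesis", "R3": "Biosynthesis",
        "R4": "Biosynthesis", "R5": "Biosynthesis", "R6": "Biosynthesis",
        "R7": "Secretion", "R8": "Biomass",
    }
    return MetabolicModel(mets, rxns, S, r, lb, ub, c,
                          subsystem=subsystem, name="toy")


def random_model(spec: FixtureSpec, ensure_mass_flow: bool = True) -> MetabolicModel:
    """Random sparse stoichiometry with small integer coefficients.

    With ``ensure_mass_flow`` every metabolite is guaranteed at least one
    producing and one consuming column after unfolding, the regime in which
    the normalised flow graph weights sum to one. Deterministic: the same
    spec yields byte-identical models.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_metabolites, spec.n_reactions
    S = np.zeros((n, m))
    # each reaction consumes and produces at least one metabolite
    for j in range(m):
        consumed = rng.integers(n)
        produced = rng.integers(n)
        while produced == consumed:
            produced = rng.integers(n)
        S[consumed, j] = -float(rng.integers(1, 3))
        S[produced, j] = float(rng.integers(1, 3))
        extra = rng.random(n) < spec.density
        for i in np.flatnonzero(extra):
            if S[i, j] == 0:
                S[i, j] = float(rng.choice([-2, -1, 1, 2]))
    r = (rng.random(m) < spec.fraction_reversible).astype(int)
    if ensure_mass_flow:
        # a metabolite touched by a reversible reaction is both produced and
        # consumed by it, so marking one touching reaction reversible is an
        # always-safe fix for a missing producer or consumer
        for i in range(n):
            touched = np.flatnonzero(S[i] != 0)
            if len(touched) == 0:
                j = int(rng.integers(m))
                S[i, j] = float(rng.choice([-1, 1]))
                touched = np.array([j])
            if r[touched].any():
                continue
            if not (S[i] > 0).any() or not (S[i] < 0).any():
                r[int(rng.choice(touched))] = 1
    lb = np.where(r == 1, -10.0, 0.0)
    ub = np.full(m, 10.0)
    c = np.zeros(m)
    if spec.flux_mode == "fba":
        c[rng.integers(m)] = 1.0
    return MetabolicModel(
        metabolite_ids=[f"X{i + 1}" for i in range(n)],
        reaction_ids=[f"R{j + 1}" for j in range(m)],
        S=S, r=r, lb=lb, ub=ub, c=c,
        name=f"random_n{n}_m{m}_seed{spec.seed}",
    )


def random_balanced_flux(
    model: MetabolicModel, seed: int = 0, respect_bounds: bool = True
) -> np.ndarray:
    """Draw a non-trivial flux vector from the null space of S (S v = 0).

    With ``respect_bounds`` the draw is a random vertex of the steady-state
    flux polytope {S v = 0, lb <= v <= ub} (a linear programme with a random
    seeded objective), so the result is balanced *and* feasible even when
    irreversibility makes naive null-space sampling infeasible. Without
    bounds, a random combination of null-space basis vectors is returned.
    Raises if the null space is trivial or only the zero flux is feasible.
    """
    import scipy.optimize

    rng = np.random.default_rng(seed)
    Z = scipy.linalg.null_space(model.S)
    if Z.shape[1] == 0:
        raise ValueError("stoichiometric matrix has a trivial null space")
    if not respect_bounds:
        for _ in range(50):
            v = Z @ rng.standard_normal(Z.shape[1])
            if np.max(np.abs(v)) > 1e-9:
                return v
        raise ValueError("null-space draw degenerate")
    bounds = np.column_stack([model.lb, model.ub])
    for _ in range(50):
        c = rng.standard_normal(model.m)
        res = scipy.optimize.linprog(
            -c, A_eq=model.S, b_eq=np.zeros(model.n), bounds=bounds,
            method="highs",
        )
        if res.status == 0 and np.max(np.abs(res.x)) > 1e-9:
            return res.x
    raise ValueError("could not draw a bounded null-space flux for this model")
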