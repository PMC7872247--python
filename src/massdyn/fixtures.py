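"""Built-in toy networks with thermodynamically consistent reference states.

Both generators construct a flux-balanced steady state first, draw
strictly positive concentrations, then choose each reversible Keq as
the reference mass-action ratio times a positive margin, so the
reference state is feasible by construction.  Rate constants are then
back-calculated (PERCs), which makes the reference state an exact
steady state of the returned model.
"""

from __future__ import annotations

import math

import numpy as np

from .core import Model, Reaction, Species, mass_action_ratio
from .parameterize import SteadyStateData, check_direction_consistency, parameterize

__all__ = ["make_linear_chain", "make_toy_glycolysis"]


def _assign_keqs(model: Model, ss: SteadyStateData, margins) -> None:
    """Set Keq = Gamma * exp(margin) per reversible reaction (forward flux)."""
    k = 0
    for rxn in model.reactions:
        if not rxn.reversible:
            continue
        gamma = mass_action_ratio(rxn, ss.concentrations)
        sign = 1.0 if ss.fluxes[rxn.id] >= 0 else -1.0
        rxn.Keq = gamma * math.exp(sign * margins[k])
        k += 1


def _finalize(model: Model, ss: SteadyStateData):
    model = parameterize(model, ss)
    if check_direction_consistency(model, ss):
        raise AssertionError("fixture reference state is not feasible")
    return model, ss


def make_linear_chain(n: int = 3, seed: int = 0):
    """Open chain src -> X1 -> ... -> Xn -> snk with n internal species.

    All n+1 reactions are reversible, carry unit flux at the reference
    state, and have randomized concentrations and thermodynamic margins.
    Returns (model, steady-state data).
    """
    if n < 2:
        raise ValueError("chain needs at least 2 internal species")
    rng = np.random.default_rng(seed)
    xs = {f"x{i + 1}": float(v) for i, v in enumerate(rng.uniform(1e-4, 1e-3, n))}
    species = [Species("src", x0=2e-3, fixed=True)]
    species += [Species(sid, x0=x) for sid, x in xs.items()]
    species.append(Species("snk", x0=1e-4, fixed=True))
    ids = ["src"] + list(xs) + ["snk"]
    reactions = [
        Reaction(f"r{j}", {ids[j]: 1}, {ids[j + 1]: 1}, Keq=1.0)
        for j in range(n + 1)
    ]
    model = Model("linear_chain", species, reactions)
    conc = {s.id: s.x0 for s in species}
    fluxes = {r.id: 1.0 for r in reactions}
    ss = SteadyStateData(fluxes=fluxes, concentrations=conc)
    _assign_keqs(model, ss, rng.uniform(0.5, 2.0, n + 1))
    return _finalize(model, ss)


def make_toy_glycolysis(seed: int = 0):
    """A small glycolysis-like network with an adenylate subsystem.

    Upper/lower glycolysis are lumped into a few reactions; the network
    carries an irreversible PFK/FBPase futile-cycle pair (each leg
    inflated by 10% of the net flux through the pair), an irreversible
    ATP-utilization reaction, and ATP/ADP/AMP with a small adenylate
    turnover so the energy charge responds to perturbations.  The
    reference flux state is balanced exactly and the reference
    concentrations are jittered by the seed.
    """
    rng = np.random.default_rng(seed)

    def jitter(v):
        return float(v * math.exp(rng.uniform(-0.1, 0.1)))

    conc = {
        # boundary
        "glc_x": 5e-3, "lac_x": 1e-3, "ade_x": 1e-6, "ino_x": 1e-6,
        # interior
        "g6p": jitter(5e-4), "fdp": jitter(2e-4), "pyr": jitter(1e-4),
        "atp": jitter(1.6e-3), "adp": jitter(4e-4), "amp": jitter(1e-4),
    }
    fixed = {"glc_x", "lac_x", "ade_x", "ino_x"}
    species = [
        Species(sid, x0=x, fixed=sid in fixed) for sid, x in conc.items()
    ]
    reactions = [
        Reaction("HEX", {"glc_x": 1, "atp": 1}, {"g6p": 1, "adp": 1}, Keq=1.0),
        Reaction("PFK", {"g6p": 1, "atp": 1}, {"fdp": 1, "adp": 1},
                 reversible=False),
        Reaction("FBP", {"fdp": 1}, {"g6p": 1}, reversible=False),
        Reaction("LOW", {"fdp": 1, "adp": 4}, {"pyr": 2, "atp": 4}, Keq=1.0),
        Reaction("LDH", {"pyr": 1}, {"lac_x": 1}, Keq=1.0),
        Reaction("ATPASE", {"atp": 1}, {"adp": 1}, reversible=False),
        Reaction("AK", {"adp": 2}, {"atp": 1, "amp": 1}, Keq=1.0),
        Reaction("ADPS", {"ade_x": 1}, {"adp": 1}, reversible=False),
        Reaction("AMPD", {"amp": 1}, {"ino_x": 1}, reversible=False),
    ]
    # balanced reference flux state (M/h); PFK/FBP is the futile pair:
    # net 1.0 through the pair, each leg carrying +10% of the net.
    fluxes = {
        "HEX": 1.0,
        "PFK": 1.1,
        "FBP": 0.1,
        "LOW": 1.0,
        "LDH": 2.0,
        "ATPASE": 1.95,
        "AK": 0.05,
        "ADPS": 0.05,
        "AMPD": 0.05,
    }
    model = Model("toy_glycolysis", species, reactions)
    ss = SteadyStateData(fluxes=fluxes, concentrations=conc)
    n_rev = sum(r.reversible for r in reactions)
    _assign_keqs(model, ss, rng.uniform(0.5, 2.5, n_rev))
    return _finalize(model, ss)
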