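"""Parameterization from steady-state data.

The central operation is the computation of pseudo-elementary rate
constants (PERCs): given a steady-state flux v_ss and concentration
state x_ss, each reaction's forward constant is back-calculated as

    kf = v_ss / (prod x_s**a - Keq**-1 * prod x_p**b)

so that the mass-action model reproduces v_ss exactly at x_ss.  The
denominator must carry the sign of the flux (flux never runs against
its thermodynamic driving force); violations are hard errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import (
    Model,
    ModelError,
    Reaction,
    mass_action_ratio,
    stoichiometric_matrix,
)

__all__ = [
    "SteadyStateData",
    "DirectionViolation",
    "compute_percs",
    "parameterize",
    "check_direction_consistency",
    "gibbs_energy",
    "convert_flux_units",
    "GAS_CONSTANT_KJ",
]

logger = logging.getLogger(__name__)

#: Gas constant in kJ/(mol K).
GAS_CONSTANT_KJ = 8.314e-3


@dataclass
class SteadyStateData:
    """A steady-state flux/concentration data set.

    fluxes : reaction id -> v_ss (M/h, signed)
    concentrations : species id -> x_ss (M, > 0)
    temperature : K (default physiological 310.15)
    """

    fluxes: dict[str, float] = field(default_factory=dict)
    concentrations: dict[str, float] = field(default_factory=dict)
    temperature: float = 310.15
    gas_constant: float = GAS_CONSTANT_KJ

    def __post_init__(self) -> None:
        for sid, x in self.concentrations.items():
            if not x > 0:
                raise ModelError(f"steady-state concentration for {sid!r} must be > 0")

    @property
    def rt(self) -> float:
        """R*T in kJ/mol."""
        return self.gas_constant * self.temperature

    def check_balance(
        self, model: Model, rtol: float = 1e-6
    ) -> float:
        """Return ||S v_ss||_inf over dynamic species; warn above rtol*max|v|."""
        S = stoichiometric_matrix(model)[~model.fixed_mask, :]
        v = np.array([self.fluxes.get(r.id, 0.0) for r in model.reactions])
        resid = float(np.max(np.abs(S @ v))) if S.size else 0.0
        scale = float(np.max(np.abs(v))) if v.size else 0.0
        if scale and resid > rtol * scale:
            logger.warning(
                "steady-state flux imbalance: ||S v||_inf = %.3e (max|v| = %.3e)",
                resid,
                scale,
            )
        return resid


@dataclass
class DirectionViolation:
    """A reaction whose flux runs against its thermodynamic driving force."""

    reaction_id: str
    flux: float
    gamma: float
    keq: float

    def __str__(self) -> str:  # pragma: no cover
        return (
            f"{self.reaction_id}: v = {self.flux:g} but Gamma = {self.gamma:g} "
            f"vs Keq = {self.keq:g}"
        )


def _perc_denominator(rxn: Reaction, x: Mapping[str, float]) -> float:
    fwd = 1.0
    for sid, c in rxn.reactants.items():
        fwd *= x[sid] ** c
    if not rxn.reversible:
        return fwd
    rev = 1.0
    for sid, c in rxn.products.items():
        rev *= x[sid] ** c
    return fwd - rev / rxn.Keq


def compute_percs(
    model: Model,
    ss: SteadyStateData,
    zero_flux_kf: float = 0.0,
) -> dict[str, float]:
    """Back-calculate the forward rate constant of every reaction.

    Reactions carrying zero flux at zero driving force get
    ``zero_flux_kf`` (default 0) with a warning; a nonzero flux with a
    vanishing or wrong-signed denominator is a hard error naming the
    reaction.  Reactions with custom rate laws are skipped (their
    parameters are not PERCs).
    """
    ss.check_balance(model)
    x = ss.concentrations
    percs: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.id in model.custom_rates:
            logger.info("skipping custom-rate reaction %s", rxn.id)
            continue
        if rxn.id not in ss.fluxes:
            raise ModelError(f"no steady-state flux provided for reaction {rxn.id!r}")
        v = ss.fluxes[rxn.id]
        D = _perc_denominator(rxn, x)
        if v == 0.0:
            percs[rxn.id] = zero_flux_kf
            if D == 0.0:
                logger.warning(
                    "reaction %s: zero flux at zero driving force; kf set to %g",
                    rxn.id,
                    zero_flux_kf,
                )
            else:
                logger.warning(
                    "reaction %s: zero flux; kf set to %g", rxn.id, zero_flux_kf
                )
            continue
        if D == 0.0:
            raise ModelError(
                f"reaction {rxn.id!r}: nonzero flux {v:g} at zero thermodynamic "
                "driving force (mass-action ratio equals Keq)"
            )
        if math.copysign(1.0, D) != math.copysign(1.0, v):
            raise ModelError(
                f"reaction {rxn.id!r}: flux {v:g} runs against its driving force "
                f"(rate-law denominator {D:g})"
            )
        percs[rxn.id] = v / D
    return percs


def parameterize(model: Model, ss: SteadyStateData, **kwargs) -> Model:
    """Return a copy of ``model`` with PERCs installed and x0 set to x_ss."""
    percs = compute_percs(model, ss, **kwargs)
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id in percs:
            rxn.kf = percs[rxn.id]
    for s in out.species:
        if s.id in ss.concentrations:
            s.x0 = ss.concentrations[s.id]
    return out


def check_direction_consistency(
    model: Model, ss: SteadyStateData
) -> list[DirectionViolation]:
    """Reactions where v_ss * (ln Keq - ln Gamma) < 0.

    An empty list means the (flux, concentration) pair is
    thermodynamically feasible.  Irreversible reactions violate only
    when run backwards (their ln Keq is +inf).
    """
    x = ss.concentrations
    out: list[DirectionViolation] = []
    for rxn in model.reactions:
        v = ss.fluxes.get(rxn.id, 0.0)
        if v == 0.0:
            continue
        gamma = mass_action_ratio(rxn, x)
        if not rxn.reversible:
            if v < 0:
                out.append(DirectionViolation(rxn.id, v, gamma, math.inf))
            continue
        if v * (math.log(rxn.Keq) - math.log(gamma)) < 0:
            out.append(DirectionViolation(rxn.id, v, gamma, rxn.Keq))
    return out


def gibbs_energy(
    rxn: Reaction,
    x: Mapping[str, float],
    temperature: float = 310.15,
    gas_constant: float = GAS_CONSTANT_KJ,
) -> float:
    """Gibbs free energy of reaction, dG = R T ln(Gamma / Keq), in kJ/mol.

    Negative iff the forward direction is thermodynamically favored.
    Irreversible reactions have no finite Keq; -inf is returned as the
    sentinel for an unbounded forward driving force.
    """
    gamma = mass_action_ratio(rxn, x)
    if not rxn.reversible:
        return -math.inf
    if gamma <= 0:
        raise ModelError(
            f"reaction {rxn.id!r}: Gibbs energy undefined at zero product "
            "concentration (Gamma = 0)"
        )
    return gas_constant * temperature * math.log(gamma / rxn.Keq)


def convert_flux_units(v: float, density: float) -> float:
    """Convert mmol/gDW/h to molar/h using cell density in gDW per litre.

    v_molar = v * density / 1000; the sign of v is preserved.
    """
    if not density > 0:
        raise ModelError(f"cell density must be > 0, got {density!r}")
    return v * density / 1000.0
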