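"""Network representation and mass-action kinetics.

A :class:`Model` holds an ordered list of :class:`Species` and
:class:`Reaction` objects.  Every reaction carries a forward
pseudo-elementary rate constant ``kf`` and an equilibrium constant
``Keq``; the default rate law is net mass action,

    v = kf * (prod x_s**a  -  (1/Keq) * prod x_p**b),

with the reverse term dropped for irreversible reactions (``Keq`` is
stored as ``inf`` and never evaluated).  Concentrations are molar and
time is in hours throughout; ``kf`` consequently has units
M**(1-order)/h where *order* is the sum of reactant coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "Species",
    "Reaction",
    "Model",
    "ModelError",
    "stoichiometric_matrix",
    "mass_action_rate",
    "mass_action_ratio",
    "build_odes",
    "conserved_pools",
    "compile_kernel",
]


class ModelError(ValueError):
    """Raised for structurally invalid models, reactions, or states."""


@dataclass
class Species:
    """A metabolite or enzyme form.

    Parameters
    ----------
    id : str
        Short unique identifier.
    name : str
        Free-text name.
    compartment : str
        Compartment label (no volume bookkeeping is attached to it).
    x0 : float
        Reference / initial concentration in molar.
    fixed : bool
        Boundary species: held constant, contributes no ODE.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    x0: float = 0.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("species id must be non-empty")
        if self.x0 < 0:
            raise ModelError(f"species {self.id!r}: x0 must be >= 0")


def _check_coeffs(side: Mapping[str, int], rid: str, label: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for sid, c in side.items():
        if c != int(c) or c <= 0:
            raise ModelError(
                f"reaction {rid!r}: {label} coefficient for {sid!r} must be a "
                f"positive integer, got {c!r}"
            )
        out[sid] = int(c)
    return out


@dataclass
class Reaction:
    """A (possibly reversible) reaction with a net mass-action rate law.

    Species appearing on both sides are net-cancelled at construction so
    the rate-law exponents are well defined.  ``reversible=False`` forces
    ``Keq = inf`` (the sentinel for an infinite driving force); a finite
    positive ``Keq`` is required otherwise.
    """

    id: str
    reactants: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    kf: float = 0.0
    Keq: float = math.inf
    reversible: bool = True
    subsystem: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        reac = _check_coeffs(self.reactants, self.id, "reactant")
        prod = _check_coeffs(self.products, self.id, "product")
        # net-cancel species occurring on both sides
        for sid in set(reac) & set(prod):
            c = min(reac[sid], prod[sid])
            reac[sid] -= c
            prod[sid] -= c
            if reac[sid] == 0:
                del reac[sid]
            if prod[sid] == 0:
                del prod[sid]
        self.reactants = reac
        self.products = prod
        if self.kf < 0:
            raise ModelError(f"reaction {self.id!r}: kf must be >= 0")
        if not self.reversible:
            self.Keq = math.inf
        else:
            if not (self.Keq > 0):
                raise ModelError(
                    f"reaction {self.id!r}: reversible reaction needs Keq > 0"
                )
            if math.isinf(self.Keq):
                self.reversible = False

    @property
    def order(self) -> int:
        """Kinetic order of the forward term (sum of reactant coefficients)."""
        return sum(self.reactants.values())

    @property
    def species_ids(self) -> set[str]:
        return set(self.reactants) | set(self.products)

    def stoichiometry(self, sid: str) -> int:
        """Net stoichiometric coefficient b - a of species ``sid``."""
        return self.products.get(sid, 0) - self.reactants.get(sid, 0)


class Model:
    """Ordered species + reactions; exposes S and the ODE right-hand side."""

    def __init__(
        self,
        id: str = "model",
        species: Sequence[Species] = (),
        reactions: Sequence[Reaction] = (),
        custom_rates: Mapping[str, sp.Expr] | None = None,
    ) -> None:
        self.id = id
        self.species: list[Species] = list(species)
        self.reactions: list[Reaction] = list(reactions)
        self.custom_rates: dict[str, sp.Expr] = dict(custom_rates or {})
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        sids = [s.id for s in self.species]
        if len(set(sids)) != len(sids):
            dup = sorted({x for x in sids if sids.count(x) > 1})
            raise ModelError(f"duplicate species ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        known = set(sids)
        for r in self.reactions:
            missing = r.species_ids - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references unknown species {sorted(missing)}"
                )
        allowed = {sp.Symbol(s) for s in sids}
        for rid, expr in self.custom_rates.items():
            if rid not in set(rids):
                raise ModelError(f"custom rate for unknown reaction {rid!r}")
            extra = sp.sympify(expr).free_symbols - allowed
            if extra:
                raise ModelError(
                    f"custom rate for {rid!r} has unresolved symbols {sorted(map(str, extra))}"
                )

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def fixed_mask(self) -> np.ndarray:
        return np.array([s.fixed for s in self.species], dtype=bool)

    def x0_vector(self) -> np.ndarray:
        return np.array([s.x0 for s in self.species], dtype=float)

    def x0_dict(self) -> dict[str, float]:
        return {s.id: s.x0 for s in self.species}

    def copy(self) -> "Model":
        import copy as _copy

        m = Model.__new__(Model)
        m.id = self.id
        m.species = [_copy.copy(s) for s in self.species]
        m.reactions = [
            Reaction(
                id=r.id,
                reactants=dict(r.reactants),
                products=dict(r.products),
                kf=r.kf,
                Keq=r.Keq,
                reversible=r.reversible,
                subsystem=r.subsystem,
            )
            for r in self.reactions
        ]
        m.custom_rates = dict(self.custom_rates)
        return m

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Model {self.id!r}: {len(self.species)} species, "
            f"{len(self.reactions)} reactions>"
        )


# -- operations -------------------------------------------------------------


def stoichiometric_matrix(model: Model) -> np.ndarray:
    """Net stoichiometric matrix S (n_species x n_reactions), S[i,j] = b - a.

    Rows for fixed (boundary) species are present; callers that need the
    dynamic part mask them with ``model.fixed_mask``.
    """
    n, m = len(model.species), len(model.reactions)
    S = np.zeros((n, m))
    idx = model.species_index()
    for j, r in enumerate(model.reactions):
        for sid, c in r.reactants.items():
            S[idx[sid], j] -= c
        for sid, c in r.products.items():
            S[idx[sid], j] += c
    return S


def _side_product(side: Mapping[str, int], x: Mapping[str, float]) -> float:
    p = 1.0
    for sid, c in side.items():
        p *= x[sid] ** c
    return p


def mass_action_rate(rxn: Reaction, x: Mapping[str, float]) -> float:
    """Net mass-action rate v = kf (prod x_s^a - Keq^-1 prod x_p^b).

    For an irreversible reaction the reverse term is absent.  The rate is
    exactly zero when the mass-action ratio equals Keq.
    """
    for sid in rxn.species_ids:
        if sid not in x:
            raise ModelError(f"reaction {rxn.id!r}: missing concentration for {sid!r}")
        if x[sid] < 0:
            raise ModelError(f"reaction {rxn.id!r}: negative concentration for {sid!r}")
    fwd = _side_product(rxn.reactants, x)
    if not rxn.reversible:
        return rxn.kf * fwd
    return rxn.kf * (fwd - _side_product(rxn.products, x) / rxn.Keq)


def mass_action_ratio(rxn: Reaction, x: Mapping[str, float]) -> float:
    """Mass-action ratio Gamma = prod x_p^b / prod x_s^a."""
    for sid, c in rxn.reactants.items():
        if x[sid] <= 0:
            raise ModelError(
                f"reaction {rxn.id!r}: mass-action ratio undefined, "
                f"reactant {sid!r} has zero concentration"
            )
    return _side_product(rxn.products, x) / _side_product(rxn.reactants, x)


def rate_expression(model: Model, rxn: Reaction) -> sp.Expr:
    """Symbolic rate law of one reaction (custom expression if assigned)."""
    if rxn.id in model.custom_rates:
        return sp.sympify(model.custom_rates[rxn.id])
    fwd = sp.Integer(1)
    for sid, c in rxn.reactants.items():
        fwd *= sp.Symbol(sid) ** c
    if not rxn.reversible:
        return sp.Float(rxn.kf) * fwd
    rev = sp.Integer(1)
    for sid, c in rxn.products.items():
        rev *= sp.Symbol(sid) ** c
    return sp.Float(rxn.kf) * (fwd - rev / sp.Float(rxn.Keq))


def build_odes(model: Model) -> dict[str, sp.Expr]:
    """Symbolic ODE right-hand sides dx_i/dt = sum_j S[i,j] v_j.

    Fixed species map to 0.
    """
    rates = {r.id: rate_expression(model, r) for r in model.reactions}
    odes: dict[str, sp.Expr] = {}
    for s in model.species:
        if s.fixed:
            odes[s.id] = sp.Integer(0)
            continue
        expr = sp.Integer(0)
        for r in model.reactions:
            c = r.stoichiometry(s.id)
            if c:
                expr += c * rates[r.id]
        odes[s.id] = sp.expand(expr)
    return odes


def conserved_pools(model: Model) -> list[dict[str, Fraction]]:
    """Left-nullspace basis of S restricted to dynamic (non-fixed) species.

    Each returned mapping l satisfies l.S = 0, so sum_i l_i x_i(t) is a
    conserved moiety total along any trajectory.  Entries are rational
    with the minimal integer scaling.
    """
    free = [s.id for s in model.species if not s.fixed]
    if not free:
        return []
    S = stoichiometric_matrix(model)
    keep = ~model.fixed_mask
    Sf = sp.Matrix(S[keep, :].astype(int) if np.all(S == S.astype(int)) else S[keep, :])
    basis = Sf.T.nullspace()
    pools: list[dict[str, Fraction]] = []
    for vec in basis:
        fracs = [Fraction(sp.Rational(v)) for v in vec]
        denom = math.lcm(*(f.denominator for f in fracs)) if fracs else 1
        ints = [f * denom for f in fracs]
        g = math.gcd(*(abs(int(v)) for v in ints if v != 0)) or 1
        ints = [Fraction(int(v), g) for v in ints]
        if sum(1 for v in ints if v < 0) > sum(1 for v in ints if v > 0):
            ints = [-v for v in ints]
        pools.append({sid: v for sid, v in zip(free, ints) if v != 0})
    return pools


# -- compiled numeric kernel -------------------------------------------------


class ModelKernel:
    """Vectorized evaluation of rates, RHS and Jacobian for one model.

    Parameter values (kf, Keq) are frozen in at compile time; recompile
    after changing them.  Custom symbolic rate laws are lambdified; the
    mass-action default is evaluated with pure numpy.
    """

    def __init__(self, model: Model) -> None:
        self.model = model
        self.sids = model.species_ids
        self.rids = model.reaction_ids
        n, m = len(self.sids), len(self.rids)
        self.n, self.m = n, m
        idx = model.species_index()
        self.A = np.zeros((m, n))  # reactant coefficients
        self.B = np.zeros((m, n))  # product coefficients
        self.kf = np.zeros(m)
        self.inv_keq = np.zeros(m)
        for j, r in enumerate(model.reactions):
            self.kf[j] = r.kf
            if r.reversible:
                self.inv_keq[j] = 1.0 / r.Keq
            for sid, c in r.reactants.items():
                self.A[j, idx[sid]] = c
            for sid, c in r.products.items():
                self.B[j, idx[sid]] = c
        self.S = stoichiometric_matrix(model)
        self.free = ~model.fixed_mask
        self.S_dyn = self.S.copy()
        self.S_dyn[model.fixed_mask, :] = 0.0
        self._custom: dict[int, object] = {}
        self._custom_grad: dict[int, object] = {}
        syms = [sp.Symbol(s) for s in self.sids]
        jidx = model.reaction_index()
        for rid, expr in model.custom_rates.items():
            j = jidx[rid]
            e = sp.sympify(expr)
            self._custom[j] = sp.lambdify(syms, e, "numpy")
            self._custom_grad[j] = sp.lambdify(
                syms, [sp.diff(e, s) for s in syms], "numpy"
            )

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Reaction rate vector v(x); negative x is clipped to 0 first."""
        xc = np.maximum(np.asarray(x, dtype=float), 0.0)
        with np.errstate(divide="ignore"):
            fwd = np.prod(np.power(xc[None, :], self.A), axis=1)
            rev = np.prod(np.power(xc[None, :], self.B), axis=1)
        v = self.kf * (fwd - self.inv_keq * rev)
        for j, f in self._custom.items():
            v[j] = f(*xc)
        return v

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """dx/dt = S v(x) with fixed-species rows zeroed."""
        return self.S_dyn @ self.rates(x)

    def rate_jacobian(self, x: np.ndarray) -> np.ndarray:
        """G[j, i] = dv_j / dx_i."""
        xc = np.maximum(np.asarray(x, dtype=float), 0.0)
        G = np.zeros((self.m, self.n))
        for j in range(self.m):
            if j in self._custom_grad:
                G[j, :] = np.asarray(self._custom_grad[j](*xc), dtype=float)
                continue
            for i in np.nonzero(self.A[j])[0]:
                a = self.A[j, i]
                term = a * xc[i] ** (a - 1)  # 0**0 == 1, so a==1 is safe at x==0
                for k in np.nonzero(self.A[j])[0]:
                    if k != i:
                        term *= xc[k] ** self.A[j, k]
                G[j, i] += self.kf[j] * term
            if self.inv_keq[j]:
                for i in np.nonzero(self.B[j])[0]:
                    b = self.B[j, i]
                    term = b * xc[i] ** (b - 1)
                    for k in np.nonzero(self.B[j])[0]:
                        if k != i:
                            term *= xc[k] ** self.B[j, k]
                    G[j, i] -= self.kf[j] * self.inv_keq[j] * term
        return G

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """J = S G, rows of fixed species zeroed (their ODE is 0)."""
        return self.S_dyn @ self.rate_jacobian(x)


def compile_kernel(model: Model) -> ModelKernel:
    """Build the numeric evaluation kernel for ``model``."""
    return ModelKernel(model)
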