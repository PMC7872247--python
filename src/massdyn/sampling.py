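"""Thermodynamically feasible state sampling.

Concentration states are sampled in log space from the polytope

    s_j * (ln Keq_j - sum_i (b-a)_ij y_i) >= eps_thermo      (per reaction)
    box bounds around a reference state,

where s_j is the sign of the flux carried by reaction j; the margin
``eps_thermo`` keeps every sampled state strictly away from equilibrium
so the back-calculated rate constants have nonvanishing denominators.
Flux states are sampled from {v : S v = 0, lb <= v <= ub} in nullspace
coordinates.  Both use the same hit-and-run Markov chain core.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import LinearConstraint, linprog, minimize

from .core import Model, ModelError, stoichiometric_matrix

__all__ = [
    "Polytope",
    "SampleSet",
    "SamplingError",
    "EmptyPolytopeError",
    "build_concentration_polytope",
    "find_interior_point",
    "hit_and_run",
    "sample_fluxes",
    "default_flux_bounds",
    "adjust_concentrations_min",
    "fit_fluxes",
    "futile_cycle_inflate",
]

logger = logging.getLogger(__name__)

EPS_THERMO = 1e-6
FEAS_SLACK = 1e-9


class SamplingError(RuntimeError):
    pass


class EmptyPolytopeError(SamplingError):
    """The constraint system has no feasible point."""


@dataclass
class Polytope:
    """Linear constraint system A y <= b plus box bounds lb <= y <= ub.

    ``space`` records the coordinate system: ``"log-concentration"``
    (variables are ln of molar concentrations) or ``"flux"``.
    """

    A: np.ndarray
    b: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    variable_ids: list[str]
    space: str = "log-concentration"

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.A.size == 0:
            self.A = self.A.reshape(0, len(self.variable_ids))
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.lb = np.asarray(self.lb, dtype=float).ravel()
        self.ub = np.asarray(self.ub, dtype=float).ravel()
        k = len(self.variable_ids)
        if self.A.shape[1] != k or len(self.lb) != k or len(self.ub) != k:
            raise ModelError("polytope dimensions are inconsistent")
        if self.A.shape[0] != len(self.b):
            raise ModelError("A and b row counts differ")
        if np.any(self.lb > self.ub + 1e-15):
            raise EmptyPolytopeError("box bounds cross (lb > ub)")

    @property
    def dim(self) -> int:
        return len(self.variable_ids)

    def slack(self, y: np.ndarray) -> float:
        """Minimal constraint slack at y (negative means infeasible)."""
        s = [float(np.min(y - self.lb)), float(np.min(self.ub - y))]
        if self.A.shape[0]:
            s.append(float(np.min(self.b - self.A @ y)))
        return min(s)

    def contains(self, y: np.ndarray, tol: float = FEAS_SLACK) -> bool:
        return self.slack(np.asarray(y, dtype=float)) >= -tol

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "space": self.space,
                    "variable_ids": self.variable_ids,
                    "A": self.A.tolist(),
                    "b": self.b.tolist(),
                    "lb": self.lb.tolist(),
                    "ub": self.ub.tolist(),
                },
                fh,
                indent=1,
            )


@dataclass
class SampleSet:
    """Rows of feasible states on the natural (linear) scale."""

    samples: np.ndarray
    variable_ids: list[str]
    seed: int
    polytope: Polytope | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def row_dict(self, i: int) -> dict[str, float]:
        return dict(zip(self.variable_ids, self.samples[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.variable_ids)


def build_concentration_polytope(
    model: Model,
    directions: Mapping[str, int],
    x_ref: Mapping[str, float],
    bound_mode: str = "deviation",
    d: float = 0.8,
    eps_thermo: float = EPS_THERMO,
) -> Polytope:
    """Constraint system for thermodynamically feasible concentrations.

    ``directions`` maps reaction id -> sign of the flux it must carry
    (0 entries impose no constraint).  ``bound_mode="deviation"`` allows
    each free concentration in [(1-d) x_ref, (1+d) x_ref]; ``"magnitude"``
    allows [x_ref/10**d, x_ref * 10**d].  Fixed species stay at their
    reference value and are folded into the constraint constants.
    """
    free = [s for s in model.species if not s.fixed]
    ids = [s.id for s in free]
    pos = {sid: i for i, sid in enumerate(ids)}
    for sid in ids:
        if not x_ref.get(sid, 0) > 0:
            raise ModelError(f"reference concentration for {sid!r} must be > 0")
    rows, rhs = [], []
    for rxn in model.reactions:
        s = int(np.sign(directions.get(rxn.id, 0)))
        if s == 0:
            continue
        if not rxn.reversible:
            if s < 0:
                raise ModelError(
                    f"reaction {rxn.id!r} is irreversible but direction is negative"
                )
            continue  # ln Keq = +inf: forward direction is unconstrained
        row = np.zeros(len(ids))
        const = math.log(rxn.Keq)
        for sid in rxn.species_ids:
            c = rxn.stoichiometry(sid)
            if sid in pos:
                row[pos[sid]] += s * c
            else:
                const -= c * math.log(x_ref[sid])
        rows.append(row)
        rhs.append(s * const - eps_thermo)
    xr = np.array([x_ref[sid] for sid in ids])
    if bound_mode == "deviation":
        if not 0 <= d:
            raise ModelError("deviation fraction d must be >= 0")
        lb = np.log(np.maximum((1.0 - d) * xr, 1e-300))
        ub = np.log((1.0 + d) * xr)
    elif bound_mode == "magnitude":
        lb = np.log(xr) - d * math.log(10.0)
        ub = np.log(xr) + d * math.log(10.0)
    else:
        raise ValueError(f"unknown bound_mode {bound_mode!r}")
    p = Polytope(np.array(rows).reshape(len(rows), len(ids)), np.array(rhs),
                 lb, ub, ids, space="log-concentration")
    _assert_feasible(p)
    return p


def _chebyshev_lp(p: Polytope):
    """LP for the Chebyshev center: maximize the inscribed-ball radius."""
    k = p.dim
    n_ineq = p.A.shape[0]
    # variables (y, r)
    c = np.zeros(k + 1)
    c[-1] = -1.0
    A_ub, b_ub = [], []
    for i in range(n_ineq):
        A_ub.append(np.append(p.A[i], np.linalg.norm(p.A[i])))
        b_ub.append(p.b[i])
    bounds = [(lo, hi) for lo, hi in zip(p.lb, p.ub)] + [(0, None)]
    for i in range(k):
        if np.isfinite(p.ub[i]):
            e = np.zeros(k + 1)
            e[i], e[-1] = 1.0, 1.0
            A_ub.append(e)
            b_ub.append(p.ub[i])
        if np.isfinite(p.lb[i]):
            e = np.zeros(k + 1)
            e[i], e[-1] = -1.0, 1.0
            A_ub.append(e)
            b_ub.append(-p.lb[i])
    return linprog(
        c,
        A_ub=np.array(A_ub).reshape(len(b_ub), k + 1),
        b_ub=np.array(b_ub),
        bounds=bounds,
        method="highs",
    )


def _assert_feasible(p: Polytope) -> None:
    res = _chebyshev_lp(p)
    if not res.success:
        tight = []
        if p.A.shape[0]:
            tight = [f"row {i}" for i in range(p.A.shape[0])]
        raise EmptyPolytopeError(
            "constraint system is infeasible"
            + (f" (inequality rows: {', '.join(tight)})" if tight else "")
        )


def find_interior_point(p: Polytope) -> np.ndarray:
    """Chebyshev center of the polytope (strictly interior when radius > 0)."""
    res = _chebyshev_lp(p)
    if not res.success:
        raise EmptyPolytopeError("cannot find an interior point: polytope is empty")
    return res.x[:-1]


def _hit_and_run_chain(
    p: Polytope, n: int, thin: int, rng: np.random.Generator,
    start: np.ndarray,
) -> np.ndarray:
    y = np.asarray(start, dtype=float).copy()
    if not p.contains(y, tol=1e-7):
        raise SamplingError("hit-and-run start point is not feasible")
    k = p.dim
    frozen = p.ub - p.lb < 1e-14
    out = np.empty((n, k))
    for i in range(n):
        for _ in range(thin):
            for _retry in range(64):
                d = rng.standard_normal(k)
                d[frozen] = 0.0
                nrm = np.linalg.norm(d)
                if nrm == 0.0:
                    if frozen.all():
                        break
                    continue
                d /= nrm
                t_lo, t_hi = -np.inf, np.inf
                with np.errstate(divide="ignore", invalid="ignore"):
                    for lim, sense in ((p.ub - y, 1.0), (p.lb - y, -1.0)):
                        tt = lim / d
                        pos = d * sense > 1e-300
                        neg = d * sense < -1e-300
                        if pos.any():
                            t_hi = min(t_hi, np.min(tt[pos]))
                        if neg.any():
                            t_lo = max(t_lo, np.max(tt[neg]))
                    if p.A.shape[0]:
                        Ad = p.A @ d
                        gap = p.b - p.A @ y
                        pos = Ad > 1e-300
                        neg = Ad < -1e-300
                        if pos.any():
                            t_hi = min(t_hi, np.min(gap[pos] / Ad[pos]))
                        if neg.any():
                            t_lo = max(t_lo, np.max(gap[neg] / Ad[neg]))
                if t_hi - t_lo > 1e-12:
                    y = y + (t_lo + (t_hi - t_lo) * rng.random()) * d
                    break
                if frozen.all():
                    break
            else:
                raise SamplingError(
                    "chord length collapsed repeatedly; polytope may have "
                    "empty interior"
                )
        if p.slack(y) < -FEAS_SLACK:
            raise SamplingError("hit-and-run produced an infeasible point")
        out[i] = y
    return out


def hit_and_run(
    p: Polytope,
    n: int,
    thin: int = 100,
    seed: int = 0,
    start: np.ndarray | None = None,
) -> SampleSet:
    """Uniform hit-and-run sampling of the polytope.

    Directions are isotropic Gaussian; the step is uniform along the
    feasible chord.  Deterministic for a fixed (polytope, n, thin, seed).
    Samples are returned on the natural scale (exponentiated for
    log-concentration polytopes).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    y0 = find_interior_point(p) if start is None else np.asarray(start, float)
    ys = _hit_and_run_chain(p, n, thin, rng, y0)
    samples = np.exp(ys) if p.space == "log-concentration" else ys
    return SampleSet(samples, list(p.variable_ids), seed, p)


def default_flux_bounds(model: Model, big: float = 1e3) -> dict[str, tuple[float, float]]:
    """(-big, big) for reversible reactions, (0, big) for irreversible."""
    return {
        r.id: ((0.0, big) if not r.reversible else (-big, big))
        for r in model.reactions
    }


def _equality_system(model: Model, bounds: Mapping[str, tuple[float, float]]):
    """Stack S v = 0 (dynamic species) with pinned coordinates lb == ub."""
    S = stoichiometric_matrix(model)[~model.fixed_mask, :]
    m = len(model.reactions)
    lb = np.array([bounds[r.id][0] for r in model.reactions], dtype=float)
    ub = np.array([bounds[r.id][1] for r in model.reactions], dtype=float)
    rows, rhs = [S], [np.zeros(S.shape[0])]
    pinned = np.isclose(lb, ub, rtol=0, atol=1e-12)
    for j in np.nonzero(pinned)[0]:
        e = np.zeros(m)
        e[j] = 1.0
        rows.append(e[None, :])
        rhs.append(np.array([lb[j]]))
    E = np.vstack(rows)
    f = np.concatenate(rhs)
    return E, f, lb, ub, pinned


def _flux_particular_and_nullspace(model, bounds):
    E, f, lb, ub, pinned = _equality_system(model, bounds)
    v0, *_ = np.linalg.lstsq(E, f, rcond=None)
    if np.max(np.abs(E @ v0 - f)) > 1e-8:
        raise EmptyPolytopeError("flux equality system S v = 0 is inconsistent")
    K = null_space(E)
    return v0, K, lb, ub, pinned


def sample_fluxes(
    model: Model,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n: int = 100,
    thin: int = 100,
    seed: int = 0,
) -> SampleSet:
    """Hit-and-run sampling of the steady-state flux polytope.

    Sampling runs in nullspace coordinates of S (restricted to dynamic
    species), so every sample satisfies S v = 0 to numerical precision;
    box bounds on v become inequalities on the nullspace coordinates.
    """
    bounds = dict(bounds) if bounds is not None else default_flux_bounds(model)
    rids = model.reaction_ids
    v0, K, lb, ub, _ = _flux_particular_and_nullspace(model, bounds)
    if K.shape[1] == 0:
        if np.any(v0 < lb - 1e-9) or np.any(v0 > ub + 1e-9):
            raise EmptyPolytopeError("unique flux state violates bounds")
        return SampleSet(np.tile(v0, (n, 1)), rids, seed, None)
    kdim = K.shape[1]
    A = np.vstack([K, -K])
    b = np.concatenate([ub - v0, v0 - lb])
    # drop numerically-zero rows (pinned coordinates already live in the
    # equality system); a zero row with negative slack means infeasible
    norms = np.linalg.norm(A, axis=1)
    degenerate = norms < 1e-10
    if np.any(b[degenerate] < -1e-9):
        raise EmptyPolytopeError("flux bounds contradict the equality system")
    A, b = A[~degenerate], b[~degenerate]
    zp = Polytope(A, b, np.full(kdim, -np.inf), np.full(kdim, np.inf),
                  [f"z{i}" for i in range(kdim)], space="flux")
    zs = hit_and_run(zp, n, thin, seed)
    V = v0[None, :] + zs.samples @ K.T
    S = stoichiometric_matrix(model)[~model.fixed_mask, :]
    resid = float(np.max(np.abs(S @ V.T))) if S.size else 0.0
    if resid > 1e-9:
        raise SamplingError(f"flux samples violate S v = 0 (residual {resid:.2e})")
    return SampleSet(V, rids, seed, zp)


def adjust_concentrations_min(
    model: Model,
    x_init: Mapping[str, float],
    directions: Mapping[str, int],
    bound_mode: str = "magnitude",
    d: float = 6.0,
    eps_thermo: float = EPS_THERMO,
) -> dict[str, float]:
    """Minimal thermodynamic repair of a concentration state.

    Returns argmin ||y - ln x_init||_2 subject to the feasibility
    polytope (a QP in log space).  Already-feasible input is returned
    unchanged.  The default box is deliberately wide (six orders of
    magnitude) so the thermodynamic constraints dominate.
    """
    p = build_concentration_polytope(
        model, directions, x_init, bound_mode=bound_mode, d=d,
        eps_thermo=eps_thermo,
    )
    y0 = np.log(np.array([x_init[sid] for sid in p.variable_ids]))
    if p.contains(y0, tol=0.0):
        return {sid: float(x_init[sid]) for sid in p.variable_ids}
    cons = []
    if p.A.shape[0]:
        cons.append(LinearConstraint(p.A, -np.inf, p.b))
    res = minimize(
        lambda y: float(np.sum((y - y0) ** 2)),
        np.clip(find_interior_point(p), p.lb, p.ub),
        jac=lambda y: 2.0 * (y - y0),
        bounds=list(zip(p.lb, p.ub)),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise SamplingError(f"minimal adjustment QP failed: {res.message}")
    y = res.x
    if p.slack(y) < -1e-7:
        raise SamplingError("adjusted state violates the feasibility polytope")
    return dict(zip(p.variable_ids, np.exp(y)))


def fit_fluxes(
    model: Model,
    measured: Mapping[str, float],
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Least-squares fit of a steady-state flux state to measurements.

    Minimizes sum_j (v_j - measured_j)^2 over the measured reactions
    subject to S v = 0 and box bounds (quadratic program).  When the
    unconstrained stationary point respects the bounds it is returned
    exactly (linear least squares in nullspace coordinates).
    """
    bounds = dict(bounds) if bounds is not None else default_flux_bounds(model)
    rids = model.reaction_ids
    jidx = model.reaction_index()
    for rid in measured:
        if rid not in jidx:
            raise ModelError(f"measured flux for unknown reaction {rid!r}")
    v0, K, lb, ub, _ = _flux_particular_and_nullspace(model, bounds)
    if K.shape[1] == 0:
        if np.any(v0 < lb - 1e-9) or np.any(v0 > ub + 1e-9):
            raise EmptyPolytopeError("unique flux state violates bounds")
        return dict(zip(rids, v0))
    rows = np.array([jidx[rid] for rid in measured])
    m_vec = np.array([measured[rid] for rid in measured])
    M = K[rows, :]
    z, *_ = np.linalg.lstsq(M, m_vec - v0[rows], rcond=None)
    v = v0 + K @ z
    if np.all(v >= lb - 1e-12) and np.all(v <= ub + 1e-12):
        return dict(zip(rids, np.clip(v, lb, ub)))
    res = minimize(
        lambda zz: float(np.sum((v0[rows] + M @ zz - m_vec) ** 2)),
        z,
        jac=lambda zz: 2.0 * M.T @ (v0[rows] + M @ zz - m_vec),
        constraints=[LinearConstraint(K, lb - v0, ub - v0)],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-16},
    )
    if not res.success:
        raise SamplingError(f"flux-fitting QP failed: {res.message}")
    v = v0 + K @ res.x
    return dict(zip(rids, np.clip(v, lb, ub)))


def futile_cycle_inflate(v_fwd, v_rev, frac):
    """Inflate both legs of a futile pair by ``frac`` of the net flux.

    Each leg grows by frac * |v_fwd - v_rev|; the net flux is preserved
    exactly (the same increment is added to both legs).  Exact for exact
    (e.g. Fraction) inputs.
    """
    if frac < 0:
        raise ModelError("inflation fraction must be >= 0")
    net = v_fwd - v_rev
    inc = frac * (net if net >= 0 else -net)
    return v_fwd + inc, v_rev + inc
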