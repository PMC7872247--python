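"""Deterministic simulation of mass-action models.

Integration uses a stiff-capable adaptive solver (LSODA) with the
analytic Jacobian supplied by the model kernel.  Steady states can be
found by plain integration, by a damped Newton iteration on the
conserved-pool-reduced system, or by a hybrid of the two (the default:
integrate toward the attractor, then polish with Newton).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.linalg import null_space

from .core import Model, ModelError, compile_kernel, conserved_pools

__all__ = [
    "Trajectory",
    "Perturbation",
    "SimulationError",
    "SteadyStateError",
    "integrate",
    "find_steady_state",
    "jacobian",
    "reduced_jacobian",
    "is_stable",
    "timescales",
    "interpolate",
]

logger = logging.getLogger(__name__)

#: default steady-state tolerances: ||dx/dt||_inf < max(ATOL_SS, RTOL_SS * ||v||_inf)
ATOL_SS = 1e-9
RTOL_SS = 1e-6
#: zero-eigenvalue tolerance after conserved-pool reduction
EPS_ZERO = 1e-9


class SimulationError(RuntimeError):
    """Integrator failure (step-size collapse, non-finite states)."""


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge within budget."""

    def __init__(self, msg: str, residual: float = math.nan):
        super().__init__(msg)
        self.residual = residual


@dataclass
class Trajectory:
    """Time course of concentrations and fluxes.

    times are hours, states molar (time x species), fluxes M/h
    (time x reactions).  Row 0 holds the initial condition.
    """

    times: np.ndarray
    states: np.ndarray
    fluxes: np.ndarray
    species_ids: list[str]
    reaction_ids: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ModelError("trajectory times must be strictly increasing")

    def state_at(self, t_index: int) -> dict[str, float]:
        return dict(zip(self.species_ids, self.states[t_index]))

    def series(self, sid: str) -> np.ndarray:
        """Concentration (or flux, if ``sid`` is a reaction id) time series."""
        if sid in self.species_ids:
            return self.states[:, self.species_ids.index(sid)]
        if sid in self.reaction_ids:
            return self.fluxes[:, self.reaction_ids.index(sid)]
        raise KeyError(sid)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (time, id, kind in {conc, flux}, value)."""
        rows = []
        for k, sid in enumerate(self.species_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "id": sid,
                        "kind": "conc",
                        "value": self.states[:, k],
                    }
                )
            )
        for k, rid in enumerate(self.reaction_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "id": rid,
                        "kind": "flux",
                        "value": self.fluxes[:, k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class Perturbation:
    """Parameter changes applied at a single instant.

    scale : reference -> multiplicative factor (> 0)
    set : reference -> absolute value

    A reference is ``"<reaction id>.kf"``, ``"<reaction id>.Keq"``, or the
    id of a *fixed* (boundary) species.  Dynamic species cannot be
    targeted: the state trajectory stays continuous, only parameters jump.
    """

    scale: dict[str, float] = field(default_factory=dict)
    set: dict[str, float] = field(default_factory=dict)
    time: float = 0.0

    def __post_init__(self) -> None:
        for ref, f in self.scale.items():
            if not f > 0:
                raise ModelError(f"perturbation factor for {ref!r} must be > 0")

    def apply(self, model: Model) -> Model:
        """Return a perturbed copy of ``model``."""
        out = model.copy()
        for ref, val in list(self.scale.items()) + list(self.set.items()):
            is_scale = ref in self.scale
            if "." in ref:
                rid, attr = ref.rsplit(".", 1)
                if attr not in ("kf", "Keq"):
                    raise ModelError(f"unknown parameter reference {ref!r}")
                rxn = out.get_reaction(rid)
                old = getattr(rxn, attr)
                setattr(rxn, attr, old * val if is_scale else val)
            else:
                s = out.get_species(ref)
                if not s.fixed:
                    raise ModelError(
                        f"perturbation target {ref!r} is a dynamic species; only "
                        "fixed species and reaction parameters can jump"
                    )
                s.x0 = s.x0 * val if is_scale else val
        return out


def _x0_vector(model: Model, x0) -> np.ndarray:
    if x0 is None:
        return model.x0_vector()
    if isinstance(x0, Mapping):
        vec = model.x0_vector()
        idx = model.species_index()
        for sid, v in x0.items():
            vec[idx[sid]] = v
        return vec
    return np.asarray(x0, dtype=float)


def _solve_segment(model, x0, t0, t1, n_points, rtol, atol):
    kern = compile_kernel(model)
    t_eval = np.linspace(t0, t1, n_points)
    sol = solve_ivp(
        lambda t, y: kern.rhs(y),
        (t0, t1),
        x0,
        method="LSODA",
        jac=lambda t, y: kern.jacobian(y),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        r = kern.rates(sol.y[:, -1]) if sol.y.size else np.zeros(kern.m)
        worst = (
            model.reaction_ids[int(np.argmax(np.abs(r)))] if len(r) else "<none>"
        )
        raise SimulationError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else t0:g}: "
            f"{sol.message} (largest-rate reaction: {worst})"
        )
    return sol.t, sol.y.T, kern


def integrate(
    model: Model,
    x0: Mapping[str, float] | np.ndarray | None = None,
    t_span: tuple[float, float] = (0.0, 10.0),
    perturbation: Perturbation | None = None,
    n_points: int = 201,
    rtol: float = 1e-9,
    atol: float = 1e-15,
) -> Trajectory:
    """Integrate the ODE system over ``t_span``.

    If a perturbation is given with a time inside the span, parameters
    jump at that instant; the concentration state carries over
    continuously.  Fluxes are recomputed from the stored states.
    """
    x0v = _x0_vector(model, x0)
    if np.any(x0v < 0):
        raise ModelError("initial concentrations must be >= 0")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if perturbation is not None and t0 < perturbation.time < t1:
        tp = perturbation.time
        n1 = max(2, int(n_points * (tp - t0) / (t1 - t0)))
        ta, ya, ka = _solve_segment(model, x0v, t0, tp, n1 + 1, rtol, atol)
        pert_model = perturbation.apply(model)
        # a fixed-species target changes the boundary value, not the state
        xb = ya[-1].copy()
        idx = model.species_index()
        for ref in list(perturbation.scale) + list(perturbation.set):
            if "." not in ref:
                xb[idx[ref]] = pert_model.get_species(ref).x0
        nb = max(2, n_points - n1)
        tb, yb, kb = _solve_segment(pert_model, xb, tp, t1, nb + 1, rtol, atol)
        times = np.concatenate([ta, tb[1:]])
        states = np.vstack([ya, yb[1:]])
        fluxes = np.vstack(
            [
                np.array([ka.rates(y) for y in ya]),
                np.array([kb.rates(y) for y in yb[1:]]),
            ]
        )
    else:
        m = model if perturbation is None else perturbation.apply(model)
        if perturbation is not None:
            idx = m.species_index()
            for ref in list(perturbation.scale) + list(perturbation.set):
                if "." not in ref:
                    x0v = x0v.copy()
                    x0v[idx[ref]] = m.get_species(ref).x0
        times, states, kern = _solve_segment(m, x0v, t0, t1, n_points, rtol, atol)
        fluxes = np.array([kern.rates(y) for y in states])
    states = np.where((states < 0) & (states > -atol * 10), 0.0, states)
    return Trajectory(times, states, fluxes, model.species_ids, model.reaction_ids)


def _ss_criterion(kern, x, atol_ss, rtol_ss) -> tuple[bool, float]:
    f = kern.rhs(x)
    v = kern.rates(x)
    resid = float(np.max(np.abs(f))) if f.size else 0.0
    thresh = max(atol_ss, rtol_ss * (float(np.max(np.abs(v))) if v.size else 0.0))
    return resid < thresh, resid


def _reduction_basis(model: Model) -> np.ndarray:
    """Orthonormal basis of the pool-free subspace of dynamic species."""
    free_ids = [s.id for s in model.species if not s.fixed]
    pools = conserved_pools(model)
    nf = len(free_ids)
    if not pools:
        return np.eye(nf)
    L = np.zeros((len(pools), nf))
    for k, pool in enumerate(pools):
        for sid, c in pool.items():
            L[k, free_ids.index(sid)] = float(c)
    N = null_space(L)
    return N


def _newton_polish(model, x_start, atol_ss, rtol_ss, max_iter=60):
    kern = compile_kernel(model)
    free = ~model.fixed_mask
    N = _reduction_basis(model)
    x = x_start.copy()

    def full(xf):
        out = x_start.copy()
        out[free] = xf
        return out

    xf = x[free].copy()
    for _ in range(max_iter):
        ok, resid = _ss_criterion(kern, full(xf), atol_ss, rtol_ss)
        if ok:
            return full(xf), resid
        f = kern.rhs(full(xf))[free]
        g = N.T @ f
        J = N.T @ kern.jacobian(full(xf))[np.ix_(free, free)] @ N
        try:
            du = np.linalg.solve(J, -g)
        except np.linalg.LinAlgError:
            raise SteadyStateError("singular reduced Jacobian in Newton polish",
                                   residual=resid)
        lam, g0 = 1.0, float(np.linalg.norm(g))
        for _bt in range(40):
            cand = xf + lam * (N @ du)
            if np.all(cand[np.abs(N @ du) > 0] > 0) or np.all(cand >= 0):
                gn = float(np.linalg.norm(N.T @ kern.rhs(full(np.maximum(cand, 0.0)))[free]))
                if gn < (1 - 1e-4 * lam) * g0 or gn < atol_ss:
                    xf = np.maximum(cand, 0.0)
                    break
            lam *= 0.5
        else:
            _, resid = _ss_criterion(kern, full(xf), atol_ss, rtol_ss)
            raise SteadyStateError(
                "Newton line search stalled", residual=resid
            )
    _, resid = _ss_criterion(kern, full(xf), atol_ss, rtol_ss)
    raise SteadyStateError("Newton did not converge", residual=resid)


def find_steady_state(
    model: Model,
    x0: Mapping[str, float] | np.ndarray | None = None,
    strategy: str = "hybrid",
    atol_ss: float = ATOL_SS,
    rtol_ss: float = RTOL_SS,
    max_time: float = 1e6,
) -> dict[str, float]:
    """Find x* with ||dx/dt||_inf < max(atol_ss, rtol_ss ||v||_inf).

    ``integrate`` simulates over geometrically growing horizons until the
    criterion holds; ``newton`` runs a damped Newton iteration on the
    conserved-pool-reduced system seeded at x0; ``hybrid`` integrates
    briefly, then polishes with Newton (falling back to further
    integration if the polish fails).
    """
    if strategy not in ("integrate", "newton", "hybrid"):
        raise ValueError(f"unknown strategy {strategy!r}")
    x = _x0_vector(model, x0)
    kern = compile_kernel(model)
    ok, resid = _ss_criterion(kern, x, atol_ss, rtol_ss)
    if ok:
        return dict(zip(model.species_ids, x))

    if strategy == "newton":
        xs, resid = _newton_polish(model, x, atol_ss, rtol_ss)
        return dict(zip(model.species_ids, xs))

    horizon, best = 10.0, resid
    while horizon <= max_time:
        traj = integrate(model, x, (0.0, horizon), n_points=11)
        x = traj.states[-1]
        ok, resid = _ss_criterion(kern, x, atol_ss, rtol_ss)
        best = min(best, resid)
        if ok:
            return dict(zip(model.species_ids, x))
        if strategy == "hybrid":
            try:
                xs, resid = _newton_polish(model, x, atol_ss, rtol_ss)
                return dict(zip(model.species_ids, xs))
            except SteadyStateError:
                pass
        horizon *= 10.0
    raise SteadyStateError(
        f"no steady state within t = {max_time:g} h "
        f"(best ||dx/dt||_inf = {best:.3e})",
        residual=best,
    )


def jacobian(model: Model, x: Mapping[str, float] | np.ndarray) -> np.ndarray:
    """Jacobian J = S G of the full system at x (fixed-species rows are 0)."""
    return compile_kernel(model).jacobian(_x0_vector(model, x))


def reduced_jacobian(model: Model, x) -> np.ndarray:
    """Jacobian projected onto the pool-free subspace of dynamic species.

    Conserved pools contribute structural zero eigenvalues; projecting
    them out (rather than thresholding eigenvalues) leaves the spectrum
    that decides asymptotic stability.
    """
    free = ~model.fixed_mask
    J = jacobian(model, x)[np.ix_(free, free)]
    N = _reduction_basis(model)
    return N.T @ J @ N


def is_stable(
    model: Model,
    x_star: Mapping[str, float] | np.ndarray,
    method: str = "eigen",
    eps_zero: float = EPS_ZERO,
    kick: float = 0.05,
    horizon: float = 1e4,
) -> tuple[bool, dict]:
    """Decide asymptotic stability of a steady state.

    ``eigen``: every eigenvalue of the reduced Jacobian has
    Re(lambda) < eps_zero.  ``simulate``: nudge each concentration by
    ``kick`` (relative), integrate up to ``horizon`` hours and require
    the steady-state criterion to be re-satisfied.
    """
    x = _x0_vector(model, x_star)
    if method == "eigen":
        lam = np.linalg.eigvals(reduced_jacobian(model, x))
        stable = bool(np.all(lam.real < eps_zero))
        return stable, {"eigenvalues": lam, "max_real": float(np.max(lam.real)) if lam.size else 0.0}
    if method == "simulate":
        kicked = x.copy()
        freei = np.nonzero(~model.fixed_mask)[0]
        kicked[freei] *= 1.0 + kick
        try:
            xs = find_steady_state(model, kicked, strategy="integrate",
                                   max_time=horizon)
        except (SteadyStateError, SimulationError) as exc:
            return False, {"reason": str(exc)}
        return True, {"steady_state": xs}
    raise ValueError(f"unknown stability method {method!r}")


def timescales(model: Model, x_star) -> np.ndarray:
    """Dynamic timescales tau = -1/Re(lambda), ascending; zero modes omitted."""
    lam = np.linalg.eigvals(reduced_jacobian(model, _x0_vector(model, x_star)))
    neg = lam.real[lam.real < -EPS_ZERO]
    return np.sort(-1.0 / neg)


def interpolate(traj: Trajectory, times: Sequence[float]) -> Trajectory:
    """Resample a trajectory on a new grid by monotone (PCHIP) interpolation."""
    t = np.asarray(times, dtype=float)
    if t.min() < traj.times[0] - 1e-12 or t.max() > traj.times[-1] + 1e-12:
        raise ModelError(
            f"requested times [{t.min():g}, {t.max():g}] extend beyond the "
            f"trajectory range [{traj.times[0]:g}, {traj.times[-1]:g}]"
        )
    t = np.clip(t, traj.times[0], traj.times[-1])
    states = PchipInterpolator(traj.times, traj.states, axis=0)(t)
    fluxes = PchipInterpolator(traj.times, traj.fluxes, axis=0)(t)
    return Trajectory(t, states, fluxes, traj.species_ids, traj.reaction_ids)
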