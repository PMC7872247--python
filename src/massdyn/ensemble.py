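"""Ensemble assembly, stability filtering, simulation and aggregation.

The workflow: sampled flux states and concentration states are combined
pairwise into candidate models (each parameterized by PERCs so its
sampled state is an exact steady state), candidates are filtered by
their ability to reach a steady state after a perturbation, and the
surviving ensemble is simulated on a common time grid and summarized
distributionally (mean / 95% CI / median / IQR across candidates at
each time point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Model, ModelError
from .parameterize import SteadyStateData, check_direction_consistency, parameterize
from .sampling import SampleSet
from .simulate import (
    Perturbation,
    SimulationError,
    SteadyStateError,
    Trajectory,
    find_steady_state,
    integrate,
    interpolate,
    is_stable,
)

__all__ = [
    "Candidate",
    "Ensemble",
    "assemble",
    "filter_stable",
    "simulate_ensemble",
    "aggregate",
    "energy_charge",
]

logger = logging.getLogger(__name__)

_STATUS = ("untested", "stable", "unstable", "infeasible")


@dataclass
class Candidate:
    """One parameterized model tagged by its (flux, concentration) origin."""

    flux_state_id: int
    conc_state_id: int
    model: Model | None
    status: str = "untested"
    diagnostics: str = ""

    def set_status(self, status: str, diagnostics: str = "") -> None:
        if status not in _STATUS:
            raise ValueError(f"unknown status {status!r}")
        if self.status != "untested" and status != self.status:
            raise ModelError(
                f"candidate ({self.flux_state_id},{self.conc_state_id}): status "
                f"transition {self.status} -> {status} is not allowed"
            )
        self.status = status
        if diagnostics:
            self.diagnostics = diagnostics


@dataclass
class Ensemble:
    """Candidates plus (optionally) stacked trajectories for the stable ones."""

    candidates: list[Candidate]
    times: np.ndarray | None = None
    trajectories: list[Trajectory] = field(default_factory=list)

    @property
    def stable(self) -> list[Candidate]:
        return [c for c in self.candidates if c.status == "stable"]

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in _STATUS}
        for c in self.candidates:
            out[c.status] += 1
        return out


def assemble(
    base_model: Model,
    flux_states: SampleSet,
    conc_states: SampleSet,
) -> list[Candidate]:
    """One candidate per (flux state, concentration state) pair.

    Every combination of the two sample sets yields a candidate
    (count = n_flux * n_conc).  Pairs that fail direction consistency
    or PERC computation are kept with status ``infeasible`` rather than
    dropped, so candidate accounting stays exact.
    """
    if flux_states.n == 0 or conc_states.n == 0:
        raise ModelError("both sample sets must be non-empty")
    fixed_conc = {s.id: s.x0 for s in base_model.species if s.fixed}
    out: list[Candidate] = []
    for i in range(flux_states.n):
        fluxes = flux_states.row_dict(i)
        for j in range(conc_states.n):
            conc = dict(fixed_conc)
            conc.update(conc_states.row_dict(j))
            cand = Candidate(i, j, None)
            try:
                ss = SteadyStateData(fluxes=fluxes, concentrations=conc)
                violations = check_direction_consistency(base_model, ss)
                if violations:
                    cand.set_status(
                        "infeasible",
                        "direction violations: "
                        + "; ".join(str(v) for v in violations),
                    )
                else:
                    cand.model = parameterize(base_model, ss)
            except ModelError as exc:
                cand.set_status("infeasible", str(exc))
            out.append(cand)
    logger.info(
        "assembled %d candidates (%d flux x %d conc states)",
        len(out), flux_states.n, conc_states.n,
    )
    return out


def filter_stable(
    candidates: Sequence[Candidate],
    perturbation: Perturbation | None = None,
    strategy: str = "simulate",
    max_time: float = 1e6,
) -> tuple[Ensemble, pd.DataFrame]:
    """Filter candidates by stability; returns (ensemble, discard log).

    ``simulate`` (default): each candidate is driven to a steady state,
    the perturbation is applied, and the candidate must reach a steady
    state again by simulation; an inability to do so discards it.
    ``eigen``: eigenvalue pre-screen of the reduced Jacobian at the
    candidate steady state.
    """
    if strategy not in ("simulate", "eigen"):
        raise ValueError(f"unknown stability strategy {strategy!r}")
    discard: list[dict] = []
    for cand in candidates:
        if cand.status == "infeasible":
            discard.append(
                {
                    "flux_state_id": cand.flux_state_id,
                    "conc_state_id": cand.conc_state_id,
                    "reason": cand.diagnostics or "infeasible",
                }
            )
            continue
        model = cand.model
        try:
            x_star = find_steady_state(model, strategy="hybrid", max_time=max_time)
            if strategy == "eigen":
                ok, diag = is_stable(model, x_star, method="eigen")
                if not ok:
                    raise SteadyStateError(
                        f"positive eigenvalue (max Re = {diag['max_real']:.3e})"
                    )
            else:
                target = perturbation.apply(model) if perturbation else model
                find_steady_state(
                    target,
                    np.array([x_star[s] for s in model.species_ids]),
                    strategy="integrate",
                    max_time=max_time,
                )
            cand.set_status("stable")
        except (SteadyStateError, SimulationError, ModelError) as exc:
            cand.set_status("unstable", str(exc))
            discard.append(
                {
                    "flux_state_id": cand.flux_state_id,
                    "conc_state_id": cand.conc_state_id,
                    "reason": str(exc),
                }
            )
    ens = Ensemble(list(candidates))
    log = pd.DataFrame(discard, columns=["flux_state_id", "conc_state_id", "reason"])
    c = ens.counts()
    logger.info(
        "stability filter: %d stable, %d unstable, %d infeasible",
        c["stable"], c["unstable"], c["infeasible"],
    )
    return ens, log


def _log_grid(t_span: tuple[float, float], grid_n: int) -> np.ndarray:
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t0 > 0:
        return np.geomspace(t0, t1, grid_n)
    return np.concatenate([[0.0], np.geomspace(t1 * 1e-6, t1, grid_n - 1)])


def simulate_ensemble(
    ens: Ensemble,
    perturbation: Perturbation | None,
    t_span: tuple[float, float] = (0.0, 10.0),
    grid_n: int = 100,
    n_points: int = 400,
) -> Ensemble:
    """Integrate every stable candidate and stack on a shared log grid.

    Each candidate starts from its own steady state; the shared
    perturbation is applied inside the span.  A per-candidate
    integration failure downgrades that candidate with a diagnostic
    instead of aborting the ensemble.
    """
    stable = ens.stable
    if not stable:
        raise ModelError("no stable candidates to simulate")
    grid = _log_grid(t_span, grid_n)
    times, trajs = None, []
    for cand in stable:
        try:
            traj = integrate(
                cand.model, None, t_span, perturbation, n_points=n_points
            )
            trajs.append(interpolate(traj, grid))
        except (SimulationError, ModelError) as exc:
            cand.status = "unstable"
            cand.diagnostics = f"ensemble simulation failed: {exc}"
            logger.warning(
                "candidate (%d,%d) failed during ensemble simulation: %s",
                cand.flux_state_id, cand.conc_state_id, exc,
            )
    ens.times = grid
    ens.trajectories = trajs
    return ens


def energy_charge(x_atp, x_adp, x_amp):
    """Adenylate energy charge EC = (ATP + ADP/2) / (ATP + ADP + AMP).

    A 0-1 index of the cellular energy state; 1 when all adenylate is
    ATP, 0.5 when all is ADP.  Accepts scalars or arrays.
    """
    atp = np.asarray(x_atp, dtype=float)
    adp = np.asarray(x_adp, dtype=float)
    amp = np.asarray(x_amp, dtype=float)
    total = atp + adp + amp
    if np.any(total <= 0):
        raise ModelError("energy charge undefined: total adenylate pool is zero")
    out = (atp + adp / 2.0) / total
    return float(out) if out.ndim == 0 else out


def _series(traj: Trajectory, quantity) -> np.ndarray:
    if callable(quantity):
        return np.asarray(quantity(traj), dtype=float)
    if quantity == "energy_charge":
        return energy_charge(
            traj.series("atp"), traj.series("adp"), traj.series("amp")
        )
    return traj.series(quantity)


def aggregate(
    ens: Ensemble,
    quantity,
    stats: Sequence[str] = ("mean", "ci95"),
) -> pd.DataFrame:
    """Per-time-point ensemble statistics of a quantity.

    ``quantity`` is a species id, a reaction id, the string
    ``"energy_charge"``, or a callable mapping a Trajectory to a time
    series.  ``ci95`` is the normal-theory mean +/- 1.96 sd/sqrt(n);
    median/IQR use empirical percentiles with linear interpolation.
    """
    if ens.times is None or not ens.trajectories:
        raise ModelError("ensemble has no stacked trajectories; simulate first")
    known = {"mean", "ci95", "median", "iqr"}
    bad = set(stats) - known
    if bad:
        raise ValueError(f"unknown statistics: {sorted(bad)}")
    Y = np.vstack([_series(t, quantity) for t in ens.trajectories])
    n = Y.shape[0]
    if n < 2 and ({"ci95", "iqr"} & set(stats)):
        raise ModelError("dispersion statistics need at least 2 stable candidates")
    out = {"time": ens.times, "n_candidates": n}
    if "mean" in stats or "ci95" in stats:
        mean = Y.mean(axis=0)
        out["mean"] = mean
    if "ci95" in stats:
        half = 1.96 * Y.std(axis=0, ddof=1) / np.sqrt(n)
        out["ci95_lo"] = mean - half
        out["ci95_hi"] = mean + half
    if "median" in stats:
        out["median"] = np.percentile(Y, 50, axis=0, method="linear")
    if "iqr" in stats:
        out["iqr_lo"] = np.percentile(Y, 25, axis=0, method="linear")
        out["iqr_hi"] = np.percentile(Y, 75, axis=0, method="linear")
    return pd.DataFrame(out)
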