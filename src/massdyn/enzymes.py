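"""Mechanistic enzyme modules.

An enzyme module expands one net enzymatic reaction into its elementary
binding/catalysis/release steps, with the enzyme forms (free enzyme,
complexes, allosteric states) as explicit mass-action species.  Because
every elementary step converts exactly one enzyme form into another
(ligand concentrations held fixed), the internal steady state of a
module is a linear problem in the form concentrations; the net catalytic
flux is therefore cheap to evaluate and to fit.

Elementary rate constants are fitted in log space (positivity by
construction) with the Haldane constraint - the product of equilibrium
constants along the catalytic path equals the net Keq - enforced by
eliminating one step Keq, never by penalty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import Model, ModelError, Reaction, Species, mass_action_rate

__all__ = [
    "EnzymeForm",
    "EnzymeModule",
    "build_uni_uni",
    "build_ordered_bi_bi",
    "build_mwc_uni_uni",
    "fit_rate_constants",
    "steady_state_net_flux",
    "form_distribution",
    "merge_module",
    "remove_module",
    "fractional_abundance",
    "split_flux",
]

logger = logging.getLogger(__name__)

#: default total enzyme concentration (molar) when the caller gives none
E_TOTAL_DEFAULT = 1e-6


@dataclass
class EnzymeForm(Species):
    """A microscopic enzyme state (free, ligand-bound, R/T, ...)."""

    enzyme_id: str = ""
    bound_ligands: dict[str, int] = field(default_factory=dict)
    categories: set[str] = field(default_factory=set)


@dataclass
class EnzymeModule:
    """Elementary-step description of one net enzymatic reaction.

    ``path_step_ids`` lists the steps along the net catalytic route; the
    Haldane relation constrains the product of their equilibrium
    constants to ``keq_net``.  ``replaces`` names the host-model reaction
    the module stands in for.
    """

    enzyme_id: str
    forms: list[EnzymeForm]
    steps: list[Reaction]
    net_reactants: dict[str, int]
    net_products: dict[str, int]
    keq_net: float
    path_step_ids: list[str]
    e_total: float = E_TOTAL_DEFAULT
    target_net_flux: float = 0.0
    replaces: str | None = None
    e_total_defaulted: bool = False
    fitted: bool = False
    form_x0: dict[str, float] = field(default_factory=dict)
    _replaced_reaction: Reaction | None = field(default=None, repr=False)

    @property
    def form_ids(self) -> list[str]:
        return [f.id for f in self.forms]

    @property
    def ligand_ids(self) -> set[str]:
        forms = set(self.form_ids)
        out: set[str] = set()
        for st in self.steps:
            out |= st.species_ids - forms
        return out

    def haldane_product(self) -> float:
        """Product of step equilibrium constants along the catalytic path."""
        p = 1.0
        for st in self.steps:
            if st.id in self.path_step_ids:
                p *= st.Keq
        return p

    def step_form_map(self) -> list[tuple[int, int]]:
        """(reactant-form index, product-form index) per step."""
        fidx = {f: i for i, f in enumerate(self.form_ids)}
        out = []
        for st in self.steps:
            r = [s for s in st.reactants if s in fidx]
            p = [s for s in st.products if s in fidx]
            if len(r) != 1 or len(p) != 1 or st.reactants[r[0]] != 1 or st.products[p[0]] != 1:
                raise ModelError(
                    f"step {st.id!r} must convert exactly one enzyme form into "
                    "another with unit stoichiometry"
                )
            out.append((fidx[r[0]], fidx[p[0]]))
        return out


def _form(eid: str, suffix: str, ligands: dict[str, int], cats: set[str]) -> EnzymeForm:
    fid = eid if not suffix else f"{eid}_{suffix}"
    return EnzymeForm(
        id=fid, name=fid, compartment="c", x0=0.0, fixed=False,
        enzyme_id=eid, bound_ligands=dict(ligands), categories=set(cats),
    )


def build_uni_uni(
    enzyme_id: str,
    substrate: str,
    product: str,
    keq_net: float,
    n_steps: int = 2,
    replaces: str | None = None,
    e_total: float | None = None,
) -> EnzymeModule:
    """Uni-uni mechanism: E + S <=> ES (<=> EP) <=> E + P.

    ``n_steps=2`` merges catalysis and release; ``n_steps=3`` keeps a
    distinct product-bound form.  Step Keq values are placeholders until
    :func:`fit_rate_constants` assigns them (their product is constrained
    to ``keq_net``).
    """
    if substrate == product:
        raise ModelError("substrate and product must differ")
    if not keq_net > 0:
        raise ModelError("keq_net must be > 0")
    if n_steps not in (2, 3):
        raise ModelError("uni-uni template supports 2 or 3 steps")
    eid = enzyme_id
    E = _form(eid, "", {}, {"active", "free"})
    ES = _form(eid, substrate, {substrate: 1}, {"active"})
    if n_steps == 2:
        forms = [E, ES]
        steps = [
            Reaction(f"{eid}_bind", {eid: 1, substrate: 1}, {ES.id: 1}, Keq=1.0),
            Reaction(f"{eid}_cat", {ES.id: 1}, {eid: 1, product: 1}, Keq=1.0),
        ]
    else:
        EP = _form(eid, product, {product: 1}, {"active"})
        forms = [E, ES, EP]
        steps = [
            Reaction(f"{eid}_bind", {eid: 1, substrate: 1}, {ES.id: 1}, Keq=1.0),
            Reaction(f"{eid}_cat", {ES.id: 1}, {EP.id: 1}, Keq=1.0),
            Reaction(f"{eid}_rel", {EP.id: 1}, {eid: 1, product: 1}, Keq=1.0),
        ]
    return EnzymeModule(
        enzyme_id=eid,
        forms=forms,
        steps=steps,
        net_reactants={substrate: 1},
        net_products={product: 1},
        keq_net=keq_net,
        path_step_ids=[s.id for s in steps],
        e_total=e_total if e_total is not None else E_TOTAL_DEFAULT,
        replaces=replaces,
        e_total_defaulted=e_total is None,
    )


def build_ordered_bi_bi(
    enzyme_id: str,
    substrate_a: str,
    substrate_b: str,
    product_p: str,
    product_q: str,
    keq_net: float,
    replaces: str | None = None,
    e_total: float | None = None,
) -> EnzymeModule:
    """Ordered bi-bi mechanism: E+A <=> EA, EA+B <=> EAB, EAB <=> EQ+P, EQ <=> E+Q."""
    if not keq_net > 0:
        raise ModelError("keq_net must be > 0")
    eid = enzyme_id
    E = _form(eid, "", {}, {"active", "free"})
    EA = _form(eid, substrate_a, {substrate_a: 1}, {"active"})
    EAB = _form(eid, f"{substrate_a}_{substrate_b}",
                {substrate_a: 1, substrate_b: 1}, {"active"})
    EQ = _form(eid, product_q, {product_q: 1}, {"active"})
    steps = [
        Reaction(f"{eid}_bind_a", {eid: 1, substrate_a: 1}, {EA.id: 1}, Keq=1.0),
        Reaction(f"{eid}_bind_b", {EA.id: 1, substrate_b: 1}, {EAB.id: 1}, Keq=1.0),
        Reaction(f"{eid}_cat", {EAB.id: 1}, {EQ.id: 1, product_p: 1}, Keq=1.0),
        Reaction(f"{eid}_rel", {EQ.id: 1}, {eid: 1, product_q: 1}, Keq=1.0),
    ]
    return EnzymeModule(
        enzyme_id=eid,
        forms=[E, EA, EAB, EQ],
        steps=steps,
        net_reactants={substrate_a: 1, substrate_b: 1},
        net_products={product_p: 1, product_q: 1},
        keq_net=keq_net,
        path_step_ids=[s.id for s in steps],
        e_total=e_total if e_total is not None else E_TOTAL_DEFAULT,
        replaces=replaces,
        e_total_defaulted=e_total is None,
    )


def build_mwc_uni_uni(
    enzyme_id: str,
    substrate: str,
    product: str,
    keq_net: float,
    inhibitor: str | None = None,
    replaces: str | None = None,
    e_total: float | None = None,
) -> EnzymeModule:
    """MWC-style R/T template around a uni-uni catalytic core.

    The active R state carries the catalytic path R+S <=> RS <=> R+P; the
    inactive T state is reached by the allosteric transition R <=> T and,
    if an inhibitor is given, sequestered as TI.  The T branch is a
    dead end, so the only thermodynamic cycle constraint is the Haldane
    relation on the R path.
    """
    eid = enzyme_id
    R = _form(eid, "R", {}, {"active", "R-state", "free"})
    RS = _form(eid, f"R_{substrate}", {substrate: 1}, {"active", "R-state"})
    T = _form(eid, "T", {}, {"inactive", "T-state"})
    forms = [R, RS, T]
    steps = [
        Reaction(f"{eid}_bind", {R.id: 1, substrate: 1}, {RS.id: 1}, Keq=1.0),
        Reaction(f"{eid}_cat", {RS.id: 1}, {R.id: 1, product: 1}, Keq=1.0),
        Reaction(f"{eid}_rt", {R.id: 1}, {T.id: 1}, Keq=1.0),
    ]
    if inhibitor is not None:
        TI = _form(eid, f"T_{inhibitor}", {inhibitor: 1}, {"inactive", "T-state"})
        forms.append(TI)
        steps.append(
            Reaction(f"{eid}_seq", {T.id: 1, inhibitor: 1}, {TI.id: 1}, Keq=1.0)
        )
    return EnzymeModule(
        enzyme_id=eid,
        forms=forms,
        steps=steps,
        net_reactants={substrate: 1},
        net_products={product: 1},
        keq_net=keq_net,
        path_step_ids=[f"{eid}_bind", f"{eid}_cat"],
        e_total=e_total if e_total is not None else E_TOTAL_DEFAULT,
        replaces=replaces,
        e_total_defaulted=e_total is None,
    )


# -- internal steady state ---------------------------------------------------


def _ligand_products(step: Reaction, forms: set[str], x: Mapping[str, float]):
    lf = lb = 1.0
    for sid, c in step.reactants.items():
        if sid not in forms:
            lf *= x[sid] ** c
    for sid, c in step.products.items():
        if sid not in forms:
            lb *= x[sid] ** c
    return lf, lb


def form_distribution(
    module: EnzymeModule, ligand_conc: Mapping[str, float]
) -> dict[str, float]:
    """Internal steady-state concentrations of all enzyme forms.

    With ligands fixed, each step rate is linear in the form
    concentrations; the distribution solves the linear balance system
    closed by the conservation sum_forms e = e_total.
    """
    forms = module.form_ids
    fset = set(forms)
    nf = len(forms)
    pairs = module.step_form_map()
    M = np.zeros((nf, nf))
    for st, (ir, ip) in zip(module.steps, pairs):
        lf, lbp = _ligand_products(st, fset, ligand_conc)
        alpha = st.kf * lf
        beta = 0.0 if not st.reversible else st.kf / st.Keq * lbp
        # v = alpha e_r - beta e_p; d e_r/dt -= v; d e_p/dt += v
        M[ir, ir] -= alpha
        M[ir, ip] += beta
        M[ip, ir] += alpha
        M[ip, ip] -= beta
    A = np.vstack([M[:-1, :], np.ones(nf)])
    rhs = np.zeros(nf)
    rhs[-1] = module.e_total
    try:
        e = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        raise ModelError(
            f"enzyme module {module.enzyme_id!r}: singular internal system"
        )
    return dict(zip(forms, e))


def steady_state_net_flux(
    module: EnzymeModule, ligand_conc: Mapping[str, float]
) -> float:
    """Net catalytic flux at the module's internal steady state.

    Measured as the net production rate of the net-reaction product(s),
    normalized per unit of net stoichiometry.
    """
    e = form_distribution(module, ligand_conc)
    x = dict(ligand_conc)
    x.update(e)
    pid, pstoich = next(iter(module.net_products.items()))
    flux = 0.0
    for st in module.steps:
        c = st.stoichiometry(pid)
        if c:
            flux += c * mass_action_rate(st, x)
    return flux / pstoich


def _net_gamma(module: EnzymeModule, x: Mapping[str, float]) -> float:
    num = den = 1.0
    for sid, c in module.net_products.items():
        num *= x[sid] ** c
    for sid, c in module.net_reactants.items():
        den *= x[sid] ** c
    return num / den


def fit_rate_constants(
    module: EnzymeModule,
    x_ss: Mapping[str, float],
    target_flux: float,
    kinetic_constraints: Mapping[str, float] | None = None,
    seed: int = 0,
) -> EnzymeModule:
    """Fit elementary rate constants so the module carries ``target_flux``.

    Decision variables are the logs of the step forward constants and of
    all but one path-step Keq; the last path Keq is eliminated through
    the Haldane relation, so the constraint holds exactly.  The residual
    (relative net-flux mismatch, plus optional Km/kcat mismatches for
    the 2-step uni-uni template) is minimized with a trust-region
    least-squares method.  A target whose sign opposes the net
    thermodynamic driving force is rejected before optimization.
    """
    gamma = _net_gamma(module, x_ss)
    drive = math.log(module.keq_net) - math.log(gamma)
    if target_flux != 0.0 and drive != 0.0 and np.sign(target_flux) != np.sign(drive):
        raise ModelError(
            f"enzyme module {module.enzyme_id!r}: target flux {target_flux:g} "
            f"opposes the net driving force (ln Keq - ln Gamma = {drive:g})"
        )
    if target_flux != 0.0 and drive == 0.0:
        raise ModelError(
            f"enzyme module {module.enzyme_id!r}: nonzero target flux at "
            "equilibrium is thermodynamically impossible"
        )
    steps = module.steps
    path = [i for i, st in enumerate(steps) if st.id in module.path_step_ids]
    off_path = [i for i in range(len(steps)) if i not in path]
    n_kf = len(steps)
    n_keq = len(path) - 1 + len(off_path)
    scale = max(abs(target_flux), 1e-12)
    kin = dict(kinetic_constraints or {})

    def unpack(theta):
        kfs = np.exp(theta[:n_kf])
        keqs = np.ones(len(steps))
        k = n_kf
        for i in path[:-1]:
            keqs[i] = math.exp(theta[k])
            k += 1
        for i in off_path:
            keqs[i] = math.exp(theta[k])
            k += 1
        prod_others = np.prod([keqs[i] for i in path[:-1]]) if len(path) > 1 else 1.0
        keqs[path[-1]] = module.keq_net / prod_others
        return kfs, keqs

    def install(theta):
        kfs, keqs = unpack(theta)
        for st, kf, keq in zip(steps, kfs, keqs):
            st.kf = float(kf)
            st.Keq = float(keq)
            st.reversible = True

    def residuals(theta):
        install(theta)
        r = [(steady_state_net_flux(module, x_ss) - target_flux) / scale]
        if kin:
            kfs, keqs = unpack(theta)
            if "kcat" in kin:
                r.append((kfs[1] - kin["kcat"]) / kin["kcat"])
            if "Km" in kin:
                k1, k2 = kfs[0], kfs[1]
                km = (k1 / keqs[0] + k2) / k1
                r.append((km - kin["Km"]) / kin["Km"])
        return np.array(r)

    if kin and not (len(steps) == 2 and len(path) == 2):
        raise ModelError(
            "Km/kcat constraints are supported for the 2-step uni-uni template"
        )
    # heuristic initial point: rate constants sized so a well-occupied
    # enzyme could carry the target flux, Keq spread evenly over the path
    lig = max((x_ss[s] for s in module.net_reactants), default=1.0)
    k0 = max(abs(target_flux), 1e-9) / max(module.e_total, 1e-30)
    theta0 = np.concatenate(
        [
            np.log(np.full(n_kf, max(k0 / max(lig, 1e-12), 1e-6))),
            np.zeros(n_keq),
        ]
    )
    k = n_kf
    for i in path[:-1]:
        theta0[k] = math.log(module.keq_net) / len(path)
        if steps[i].order > 1 or len(steps[i].reactants) > 1:
            theta0[k] -= math.log(max(lig, 1e-12))
        k += 1
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(8):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 2.0, theta0.size)
        res = least_squares(
            residuals, start, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
            max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-20:
            break
    install(best.x)
    achieved = steady_state_net_flux(module, x_ss)
    rel = abs(achieved - target_flux) / scale
    if rel > 1e-6:
        logger.warning(
            "module %s: fitted net flux %.6g misses target %.6g (rel %.2e)",
            module.enzyme_id, achieved, target_flux, rel,
        )
    module.target_net_flux = target_flux
    module.fitted = True
    module.form_x0 = form_distribution(module, x_ss)
    return module


# -- merging -----------------------------------------------------------------


def merge_module(model: Model, module: EnzymeModule) -> Model:
    """Replace the host reaction with the module's microscopic steps.

    The module must be fitted; the host reaction named by
    ``module.replaces`` is removed, the enzyme forms (initialized at the
    fitted internal steady state) and elementary steps are added, and
    the net module flux at the reference state is checked against the
    flux the removed reaction carried.
    """
    if not module.fitted:
        raise ModelError(f"enzyme module {module.enzyme_id!r} is not fitted")
    if module.replaces is None:
        raise ModelError("module.replaces must name a host reaction")
    rids = set(model.reaction_ids)
    if module.replaces not in rids:
        raise ModelError(f"host reaction {module.replaces!r} not in model")
    sids = set(model.species_ids)
    clash = (sids & set(module.form_ids)) | (rids & {s.id for s in module.steps})
    if clash:
        raise ModelError(f"id collision when merging module: {sorted(clash)}")
    host = model.get_reaction(module.replaces)
    x_ref = model.x0_dict()
    v_host = mass_action_rate(host, x_ref)
    ligands = {sid: x_ref[sid] for sid in module.ligand_ids}
    v_mod = steady_state_net_flux(module, ligands)
    if abs(v_host) > 0 and abs(v_mod - v_host) > 1e-6 * abs(v_host):
        raise ModelError(
            f"module {module.enzyme_id!r} net flux {v_mod:g} does not match the "
            f"host reaction flux {v_host:g} at the reference state"
        )
    out = model.copy()
    out.reactions = [r for r in out.reactions if r.id != module.replaces]
    for f in module.forms:
        s = EnzymeForm(
            id=f.id, name=f.name, compartment=f.compartment,
            x0=module.form_x0.get(f.id, 0.0), fixed=False,
            enzyme_id=f.enzyme_id, bound_ligands=dict(f.bound_ligands),
            categories=set(f.categories),
        )
        out.species.append(s)
    for st in module.steps:
        out.reactions.append(
            Reaction(
                id=st.id, reactants=dict(st.reactants), products=dict(st.products),
                kf=st.kf, Keq=st.Keq, reversible=st.reversible,
                subsystem=f"enzyme:{module.enzyme_id}",
            )
        )
    out.validate()
    module._replaced_reaction = host
    return out


def remove_module(model: Model, module: EnzymeModule) -> Model:
    """Undo a merge: drop forms and steps, restore the host reaction."""
    if module._replaced_reaction is None:
        raise ModelError("module was never merged into this model")
    out = model.copy()
    fids = set(module.form_ids)
    stids = {s.id for s in module.steps}
    out.species = [s for s in out.species if s.id not in fids]
    out.reactions = [r for r in out.reactions if r.id not in stids]
    host = module._replaced_reaction
    out.reactions.append(
        Reaction(
            id=host.id, reactants=dict(host.reactants), products=dict(host.products),
            kf=host.kf, Keq=host.Keq, reversible=host.reversible,
            subsystem=host.subsystem,
        )
    )
    out.validate()
    return out


def fractional_abundance(
    module: EnzymeModule, x: Mapping[str, float]
) -> dict[str, float]:
    """Fraction of total enzyme in each form; sums to 1 exactly."""
    conc = np.array([x[f] for f in module.form_ids], dtype=float)
    total = conc.sum()
    if not total > 0:
        raise ModelError("all enzyme forms have zero concentration")
    frac = conc / total
    return dict(zip(module.form_ids, frac))


def split_flux(net_flux: float, fractions: Sequence[float]) -> list[float]:
    """Split a net flux across isozymes by fractional assignment.

    Fractions must be nonnegative and sum to 1 (tolerance 1e-9); the
    per-isozyme fluxes sum back to the net flux.
    """
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ModelError("flux-split fractions must be >= 0")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ModelError(f"flux-split fractions sum to {f.sum()!r}, expected 1")
    return [float(net_flux * fi) for fi in f]
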