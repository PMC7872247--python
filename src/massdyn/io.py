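"""Model and data input/output.

JSON (schema version 1) is the source-of-truth model format; SBML Level
3 Version 1 core is export-only (import is limited to documents this
package wrote).  Steady-state data travel as two-column CSV (id, value)
with a header.  Unknown JSON fields are preserved verbatim on
round-trip for forward compatibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import Model, ModelError, Reaction, Species
from .enzymes import EnzymeForm, EnzymeModule
from .parameterize import SteadyStateData
from .sampling import SampleSet

__all__ = [
    "SchemaError",
    "read_model_json",
    "write_model_json",
    "export_sbml",
    "read_steady_state_csv",
    "write_steady_state_csv",
    "write_samples_csv",
    "enzyme_module_to_dict",
    "enzyme_module_from_dict",
    "RunConfig",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_SPECIES_FIELDS = {"id", "name", "compartment", "x0", "fixed"}
_REACTION_FIELDS = {"id", "reactants", "products", "kf", "Keq", "reversible",
                    "subsystem"}


class SchemaError(ModelError):
    """A model document violates the JSON schema."""


def _species_from_dict(d: dict) -> tuple[Species, dict]:
    if "id" not in d:
        raise SchemaError("species entry missing 'id'")
    extra = {k: v for k, v in d.items() if k not in _SPECIES_FIELDS}
    try:
        sp = Species(
            id=d["id"],
            name=d.get("name", ""),
            compartment=d.get("compartment", "c"),
            x0=float(d.get("x0", 0.0)),
            fixed=bool(d.get("fixed", False)),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"species {d['id']!r}: {exc}")
    return sp, extra


def _reaction_from_dict(d: dict) -> tuple[Reaction, dict]:
    if "id" not in d:
        raise SchemaError("reaction entry missing 'id'")
    rid = d["id"]
    extra = {k: v for k, v in d.items() if k not in _REACTION_FIELDS}
    reversible = bool(d.get("reversible", True))
    keq = d.get("Keq", None)
    if reversible:
        if keq is None:
            raise SchemaError(
                f"reaction {rid!r}: reversible reaction requires a finite 'Keq'"
            )
        keq = float(keq)
    else:
        keq = math.inf
    try:
        rxn = Reaction(
            id=rid,
            reactants={str(k): int(v) for k, v in d.get("reactants", {}).items()},
            products={str(k): int(v) for k, v in d.get("products", {}).items()},
            kf=float(d.get("kf", 0.0)),
            Keq=keq,
            reversible=reversible,
            subsystem=d.get("subsystem"),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"reaction {rid!r}: {exc}")
    return rxn, extra


def read_model_json(path) -> Model:
    """Read a model document; unknown fields are kept for re-export."""
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {version!r}")
    species, reactions = [], []
    extras = {"species": {}, "reactions": {}}
    for d in doc.get("species", []):
        sp, ex = _species_from_dict(d)
        species.append(sp)
        if ex:
            extras["species"][sp.id] = ex
    for d in doc.get("reactions", []):
        rxn, ex = _reaction_from_dict(d)
        reactions.append(rxn)
        if ex:
            extras["reactions"][rxn.id] = ex
    extras["top"] = {
        k: v
        for k, v in doc.items()
        if k not in ("version", "units", "id", "species", "reactions",
                     "enzyme_modules")
    }
    try:
        model = Model(id=doc.get("id", "model"), species=species,
                      reactions=reactions)
    except ModelError as exc:
        raise SchemaError(str(exc))
    model._json_extras = extras
    model._enzyme_module_docs = doc.get("enzyme_modules", [])
    return model


def write_model_json(
    model: Model, path, enzyme_modules: list[EnzymeModule] | None = None
) -> None:
    """Write a model (and optional enzyme-module blocks) as schema-v1 JSON."""
    extras = getattr(model, "_json_extras", {"species": {}, "reactions": {},
                                             "top": {}})
    doc = {
        "version": SCHEMA_VERSION,
        "id": model.id,
        "units": {"concentration": "M", "time": "h",
                  "kf": "M^(1-order)/h (order = sum of reactant coefficients)"},
        "species": [],
        "reactions": [],
    }
    doc.update(extras.get("top", {}))
    for s in model.species:
        d = {"id": s.id, "name": s.name, "compartment": s.compartment,
             "x0": s.x0, "fixed": s.fixed}
        d.update(extras.get("species", {}).get(s.id, {}))
        doc["species"].append(d)
    for r in model.reactions:
        d = {
            "id": r.id,
            "reactants": r.reactants,
            "products": r.products,
            "kf": r.kf,
            "Keq": None if not r.reversible else r.Keq,
            "reversible": r.reversible,
            "subsystem": r.subsystem,
        }
        d.update(extras.get("reactions", {}).get(r.id, {}))
        doc["reactions"].append(d)
    mods = enzyme_modules or []
    if mods:
        doc["enzyme_modules"] = [enzyme_module_to_dict(m) for m in mods]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def enzyme_module_to_dict(m: EnzymeModule) -> dict:
    return {
        "enzyme_id": m.enzyme_id,
        "e_total": m.e_total,
        "e_total_defaulted": m.e_total_defaulted,
        "replaces": m.replaces,
        "keq_net": m.keq_net,
        "target_net_flux": m.target_net_flux,
        "fitted": m.fitted,
        "net_reactants": m.net_reactants,
        "net_products": m.net_products,
        "path_step_ids": m.path_step_ids,
        "forms": [
            {
                "id": f.id,
                "bound_ligands": f.bound_ligands,
                "categories": sorted(f.categories),
                "x0": m.form_x0.get(f.id, 0.0),
            }
            for f in m.forms
        ],
        "steps": [
            {
                "id": s.id,
                "reactants": s.reactants,
                "products": s.products,
                "kf": s.kf,
                "Keq": None if not s.reversible else s.Keq,
                "reversible": s.reversible,
            }
            for s in m.steps
        ],
    }


def enzyme_module_from_dict(d: dict) -> EnzymeModule:
    eid = d["enzyme_id"]
    forms = [
        EnzymeForm(
            id=f["id"], name=f["id"], x0=float(f.get("x0", 0.0)),
            enzyme_id=eid, bound_ligands=dict(f.get("bound_ligands", {})),
            categories=set(f.get("categories", [])),
        )
        for f in d["forms"]
    ]
    steps = [_reaction_from_dict(s)[0] for s in d["steps"]]
    mod = EnzymeModule(
        enzyme_id=eid,
        forms=forms,
        steps=steps,
        net_reactants=dict(d["net_reactants"]),
        net_products=dict(d["net_products"]),
        keq_net=float(d["keq_net"]),
        path_step_ids=list(d["path_step_ids"]),
        e_total=float(d["e_total"]),
        target_net_flux=float(d.get("target_net_flux", 0.0)),
        replaces=d.get("replaces"),
        e_total_defaulted=bool(d.get("e_total_defaulted", False)),
        fitted=bool(d.get("fitted", False)),
        form_x0={f["id"]: float(f.get("x0", 0.0)) for f in d["forms"]},
    )
    return mod


# -- SBML --------------------------------------------------------------------


def _kinetic_formula(model: Model, rxn: Reaction) -> str:
    if rxn.id in model.custom_rates:
        return str(model.custom_rates[rxn.id])
    fwd = " * ".join(
        [f"kf_{rxn.id}"]
        + [f"pow({sid}, {c})" if c > 1 else sid
           for sid, c in rxn.reactants.items()]
    )
    if not rxn.reversible:
        return fwd
    rev = " * ".join(
        [f"kf_{rxn.id} / Keq_{rxn.id}"]
        + [f"pow({sid}, {c})" if c > 1 else sid
           for sid, c in rxn.products.items()]
    )
    return f"{fwd} - {rev}"


def export_sbml(model: Model, path) -> None:
    """Export as SBML Level 3 Version 1 core with explicit kinetic laws.

    Each reaction gets a MathML kinetic law of the net mass-action form
    with local parameters kf (and Keq when reversible); fixed species
    are flagged as boundary species.  The document is checked for
    consistency before writing.
    """
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1)
    doc = libsbml.SBMLDocument(ns)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    sbml_model.setTimeUnits("hour")
    compartments = sorted({s.compartment for s in model.species}) or ["c"]
    for cid in compartments:
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
        comp.setSize(1.0)
        comp.setSpatialDimensions(3)
    for s in model.species:
        sp = sbml_model.createSpecies()
        sp.setId(s.id)
        sp.setName(s.name or s.id)
        sp.setCompartment(s.compartment)
        sp.setInitialConcentration(s.x0)
        sp.setConstant(False)
        sp.setBoundaryCondition(bool(s.fixed))
        sp.setHasOnlySubstanceUnits(False)
    for r in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId(r.id)
        rx.setReversible(bool(r.reversible))
        rx.setFast(False)
        for sid, c in r.reactants.items():
            ref = rx.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(c))
            ref.setConstant(True)
        for sid, c in r.products.items():
            ref = rx.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(c))
            ref.setConstant(True)
        kl = rx.createKineticLaw()
        formula = _kinetic_formula(model, r)
        ast = libsbml.parseL3Formula(formula)
        if ast is None:
            raise ModelError(
                f"reaction {r.id!r}: rate law {formula!r} is not serializable "
                "to SBML MathML"
            )
        kl.setMath(ast)
        p = kl.createLocalParameter()
        p.setId(f"kf_{r.id}")
        p.setValue(r.kf)
        if r.reversible:
            p = kl.createLocalParameter()
            p.setId(f"Keq_{r.id}")
            p.setValue(r.Keq)
    doc.checkInternalConsistency()
    n_err = doc.getNumErrors()
    serious = [
        doc.getError(i).getMessage()
        for i in range(n_err)
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if serious:
        raise ModelError("SBML export failed validation: " + "; ".join(serious))
    libsbml.writeSBMLToFile(doc, str(path))


# -- CSV ---------------------------------------------------------------------


def read_steady_state_csv(
    flux_path, conc_path, temperature: float = 310.15
) -> SteadyStateData:
    """Read fluxes and concentrations from two-column (id, value) CSVs."""
    def _read(p) -> dict[str, float]:
        df = pd.read_csv(p)
        if df.shape[1] < 2:
            raise SchemaError(f"{p}: expected two columns (id, value)")
        return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))

    return SteadyStateData(
        fluxes=_read(flux_path),
        concentrations=_read(conc_path),
        temperature=temperature,
    )


def write_steady_state_csv(ss: SteadyStateData, flux_path, conc_path) -> None:
    pd.DataFrame(
        {"id": list(ss.fluxes), "value": list(ss.fluxes.values())}
    ).to_csv(flux_path, index=False)
    pd.DataFrame(
        {"id": list(ss.concentrations), "value": list(ss.concentrations.values())}
    ).to_csv(conc_path, index=False)


def write_samples_csv(samples: SampleSet, path) -> None:
    df = samples.to_frame()
    df.insert(0, "sample", range(samples.n))
    df.to_csv(path, index=False)


# -- run configuration -------------------------------------------------------


@dataclass
class RunConfig:
    """Seeds, tolerances, sampler settings and the perturbation spec."""

    seed: int = 0
    rtol: float = 1e-9
    atol: float = 1e-15
    atol_ss: float = 1e-9
    rtol_ss: float = 1e-6
    n_flux: int = 15
    n_conc: int = 15
    thin: int = 100
    bound_mode: str = "deviation"
    d: float = 0.8
    perturbation: dict = field(
        default_factory=lambda: {"scale": {}, "set": {}, "time": 0.0}
    )
    t_span: tuple[float, float] = (0.0, 10.0)
    grid_n: int = 100
    outdir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("rtol", "atol", "atol_ss", "rtol_ss"):
            if not getattr(self, name) > 0:
                raise ModelError(f"tolerance {name} must be > 0")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            yaml.safe_load(text)
            if str(path).endswith((".yml", ".yaml"))
            else json.loads(text)
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "t_span" in data:
            data["t_span"] = tuple(data["t_span"])
        return cls(**data)

    def to_file(self, path) -> None:
        d = dataclasses.asdict(self)
        d["t_span"] = list(d["t_span"])
        with open(path, "w") as fh:
            if str(path).endswith((".yml", ".yaml")):
                yaml.safe_dump(d, fh)
            else:
                json.dump(d, fh, indent=1)

    def make_perturbation(self):
        from .simulate import Perturbation

        p = self.perturbation or {}
        if not p.get("scale") and not p.get("set"):
            return None
        return Perturbation(
            scale=dict(p.get("scale", {})),
            set=dict(p.get("set", {})),
            time=float(p.get("time", 0.0)),
        )
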