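"""Core metabolic-model structures: species, reactions, bounds, GPRs.

The model is a plain stoichiometric network: an M x N matrix S over
species (rows) and reactions (columns), per-reaction flux bounds, and
optional general linear constraints a.v in [lo, hi] used to encode
exchange-flux ratios and the growth-yield bracket, which the SBML format
cannot embed (they travel in a JSON sidecar).

SBML Level 3 + fbc reading/writing is delegated to COBRApy; everything
downstream operates on the lightweight containers defined here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .gpr import GprExpression, parse_gpr

logger = logging.getLogger(__name__)

__all__ = [
    "Species",
    "Reaction",
    "LinearConstraint",
    "MetabolicModel",
    "ModelError",
    "read_sbml",
    "write_sbml",
    "make_irreversible",
    "net_flux",
    "REVERSE_SUFFIX",
]

#: suffix appended to the id of the reverse partner of a split reversible
#: reaction; stable because downstream tables key on it.
REVERSE_SUFFIX = "_reverse"

#: compartment ids/names recognized as extracellular for structural
#: exchange detection (single-species boundary reactions).
EXTRACELLULAR_IDS = frozenset({"e", "c_e", "extracellular", "extracellular space", "s"})


class ModelError(ValueError):
    """Raised for structurally invalid models or failed lookups."""


@dataclass
class Species:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self):
        if not self.compartment:
            raise ModelError(f"species {self.id!r} has an empty compartment")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[GprExpression] = None
    reversible: Optional[bool] = None
    is_exchange: bool = False
    pathway: Optional[str] = None

    def __post_init__(self):
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if np.isnan(self.lower_bound) or np.isnan(self.upper_bound):
            raise ModelError(f"reaction {self.id!r} has missing bounds")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.reversible is None:
            # captured at construction; deliberately not re-derived when
            # bounds are later tightened, so that the irreversible split
            # stays structurally identical across per-group model variants
            self.reversible = self.lower_bound < 0

    @property
    def substrates(self) -> dict[str, float]:
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {s: c for s, c in self.stoichiometry.items() if c > 0}

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes if self.gpr is not None else frozenset()


@dataclass
class LinearConstraint:
    """A general linear constraint lo <= sum_i a_i * v_i <= hi."""

    name: str
    coefficients: dict[str, float]
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.lower > self.upper:
            raise ModelError(f"constraint {self.name!r}: lower > upper")


@dataclass
class MetabolicModel:
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    extra_constraints: list[LinearConstraint] = field(default_factory=list)
    id: str = "model"
    #: original id -> (forward id, reverse id or None); set by make_irreversible
    split_map: Optional[dict[str, tuple[str, Optional[str]]]] = None

    # ------------------------------------------------------------------ #
    def species_by_id(self) -> dict[str, Species]:
        return {s.id: s for s in self.species}

    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ModelError(f"unknown reaction id {rid!r}")

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return sorted(out)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def reverse_of(self) -> dict[str, str]:
        """Map forward/reverse split ids back to the original reaction id."""
        out: dict[str, str] = {}
        if self.split_map:
            for orig, (fwd, rev) in self.split_map.items():
                out[fwd] = orig
                if rev is not None:
                    out[rev] = orig
        return out

    # ------------------------------------------------------------------ #
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S matrix of shape (n_species, n_reactions)."""
        sp_index = {s.id: i for i, s in enumerate(self.species)}
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sid, coeff in r.stoichiometry.items():
                S[sp_index[sid], j] = coeff
        return S, [s.id for s in self.species], [r.id for r in self.reactions]

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], float)
        ub = np.array([r.upper_bound for r in self.reactions], float)
        return lb, ub

    def validate(self) -> None:
        sids = [s.id for s in self.species]
        if len(set(sids)) != len(sids):
            raise ModelError("duplicate species ids")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            raise ModelError("duplicate reaction ids")
        known = set(sids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references unknown species {sorted(missing)}"
                )
        rid_set = set(rids)
        for c in self.extra_constraints:
            unknown = set(c.coefficients) - rid_set
            if unknown:
                raise ModelError(
                    f"constraint {c.name!r} references unknown reactions {sorted(unknown)}"
                )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            species=[replace(s) for s in self.species],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions
            ],
            extra_constraints=[
                replace(c, coefficients=dict(c.coefficients))
                for c in self.extra_constraints
            ],
            id=self.id,
            split_map=dict(self.split_map) if self.split_map else None,
        )

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_for_species(self, sid: str) -> Reaction:
        for r in self.exchanges:
            if sid in r.stoichiometry:
                return r
        raise ModelError(f"no exchange reaction found for species {sid!r}")


# ---------------------------------------------------------------------- #
# exchange detection
# ---------------------------------------------------------------------- #
def flag_exchanges(
    model: MetabolicModel,
    explicit: Optional[Iterable[str]] = None,
    extracellular: Optional[Iterable[str]] = None,
) -> None:
    """Mark exchange reactions in-place.

    Detection is structural: a reaction touching a single species located
    in an extracellular compartment.  ``explicit`` overrides detection
    with a literal list of reaction ids.
    """
    if explicit is not None:
        explicit = set(explicit)
        for r in model.reactions:
            r.is_exchange = r.id in explicit
        return
    extra = {c.lower() for c in (extracellular or EXTRACELLULAR_IDS)}
    compartments = model.species_by_id()
    for r in model.reactions:
        if len(r.stoichiometry) != 1:
            r.is_exchange = False
            continue
        (sid,) = r.stoichiometry
        r.is_exchange = compartments[sid].compartment.lower() in extra


# ---------------------------------------------------------------------- #
# SBML I/O (via COBRApy)
# ---------------------------------------------------------------------- #
def read_sbml(
    path: str | Path,
    exchange_ids: Optional[Iterable[str]] = None,
) -> MetabolicModel:
    """Read an SBML Level 3 (fbc) model file.

    GPR association strings are re-parsed with the tolerant grammar of
    :func:`fluxcord.gpr.parse_gpr`, which accepts both gene-symbol and
    numeric-id leaves.  A load summary (reaction/species/gene counts) is
    logged at INFO level.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra wraps libsbml errors
        raise ModelError(f"failed to parse SBML file {path}: {exc}") from exc

    species = [
        Species(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cmodel.metabolites
    ]
    reactions = []
    for rxn in cmodel.reactions:
        if rxn.lower_bound is None or rxn.upper_bound is None:
            raise ModelError(f"reaction {rxn.id!r} has missing flux bounds")
        rule = rxn.gene_reaction_rule
        gpr = parse_gpr(rule) if rule and rule.strip() else None
        reactions.append(
            Reaction(
                id=rxn.id,
                stoichiometry={m.id: c for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gpr=gpr,
                pathway=rxn.subsystem or None,
            )
        )
    model = MetabolicModel(species=species, reactions=reactions, id=cmodel.id or path.stem)
    flag_exchanges(model, explicit=exchange_ids)
    model.validate()

    sidecar = path.with_suffix(path.suffix + ".constraints.json")
    if sidecar.exists():
        model.extra_constraints = _read_constraint_sidecar(sidecar)
        model.validate()

    logger.info(
        "loaded model %s: %d reactions, %d species, %d genes, %d exchanges",
        model.id,
        len(model.reactions),
        len(model.species),
        len(model.genes),
        len(model.exchanges),
    )
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML L3+fbc, with extra linear constraints in a
    ``<path>.constraints.json`` sidecar (SBML cannot embed them)."""
    import cobra

    path = Path(path)
    cmodel = cobra.Model(model.id)
    mets = {
        s.id: cobra.Metabolite(s.id, name=s.name, compartment=s.compartment)
        for s in model.species
    }
    crxns = []
    for r in model.reactions:
        crxn = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        crxn.subsystem = r.pathway or ""
        crxns.append(crxn)
    cmodel.add_reactions(crxns)
    for r, crxn in zip(model.reactions, crxns):
        crxn.add_metabolites({mets[s]: c for s, c in r.stoichiometry.items()})
        if r.gpr is not None:
            crxn.gene_reaction_rule = r.gpr.to_string().strip("()")
    cobra.io.write_sbml_model(cmodel, str(path))
    if model.extra_constraints:
        _write_constraint_sidecar(
            model.extra_constraints, path.with_suffix(path.suffix + ".constraints.json")
        )


def _write_constraint_sidecar(constraints: Sequence[LinearConstraint], path: Path) -> None:
    payload = [
        {
            "name": c.name,
            "coefficients": c.coefficients,
            "lower": None if np.isneginf(c.lower) else c.lower,
            "upper": None if np.isposinf(c.upper) else c.upper,
        }
        for c in constraints
    ]
    path.write_text(json.dumps(payload, indent=1))


def _read_constraint_sidecar(path: Path) -> list[LinearConstraint]:
    payload = json.loads(path.read_text())
    return [
        LinearConstraint(
            name=c["name"],
            coefficients={k: float(v) for k, v in c["coefficients"].items()},
            lower=-np.inf if c["lower"] is None else float(c["lower"]),
            upper=np.inf if c["upper"] is None else float(c["upper"]),
        )
        for c in payload
    ]


# ---------------------------------------------------------------------- #
# irreversible form
# ---------------------------------------------------------------------- #
def make_irreversible(model: MetabolicModel, require_ratio_rows: bool = False) -> MetabolicModel:
    """Split every reversible reaction into complementary forward/reverse
    irreversible reactions.

    A reversible reaction ``r`` with bounds [lb, ub] (lb < 0) becomes
    ``r`` with bounds [max(lb, 0), max(ub, 0)] and ``r_reverse`` with
    bounds [max(-ub, 0), -lb]; the GPR is copied to both.  Extra linear
    constraints are rewritten onto the split variables (coefficient a on
    v becomes +a on forward, -a on reverse, since v = v_fwd - v_rev).
    A back-map from split ids to original ids is retained on the result.

    Exchange-flux ratio rows must be attached before this step, never
    after: ratio constraints stated on net exchange fluxes are only
    meaningful on the reversible model.  Set ``require_ratio_rows`` to
    enforce that at least one extra constraint is present.
    """
    if model.split_map is not None:
        raise ModelError("model is already irreversible")
    if require_ratio_rows and not model.extra_constraints:
        raise ModelError(
            "make_irreversible called before ratio constraints were attached; "
            "type 2 rows must be defined on the reversible model first"
        )

    reactions: list[Reaction] = []
    split_map: dict[str, tuple[str, Optional[str]]] = {}
    for r in model.reactions:
        if not r.reversible:
            if r.lower_bound < 0:
                raise ModelError(f"reaction {r.id!r} marked irreversible but lb < 0")
            reactions.append(replace(r, stoichiometry=dict(r.stoichiometry)))
            split_map[r.id] = (r.id, None)
            continue
        rev_id = r.id + REVERSE_SUFFIX
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=dict(r.stoichiometry),
                lower_bound=max(r.lower_bound, 0.0),
                upper_bound=max(r.upper_bound, 0.0),
                gpr=r.gpr,
                reversible=False,
                is_exchange=r.is_exchange,
                pathway=r.pathway,
            )
        )
        reactions.append(
            Reaction(
                id=rev_id,
                stoichiometry={s: -c for s, c in r.stoichiometry.items()},
                lower_bound=max(-r.upper_bound, 0.0),
                upper_bound=-r.lower_bound,
                gpr=r.gpr,
                reversible=False,
                is_exchange=r.is_exchange,
                pathway=r.pathway,
            )
        )
        split_map[r.id] = (r.id, rev_id)

    constraints = []
    for c in model.extra_constraints:
        coeffs: dict[str, float] = {}
        for rid, a in c.coefficients.items():
            fwd, rev = split_map[rid]
            coeffs[fwd] = coeffs.get(fwd, 0.0) + a
            if rev is not None:
                coeffs[rev] = coeffs.get(rev, 0.0) - a
        constraints.append(LinearConstraint(c.name, coeffs, c.lower, c.upper))

    out = MetabolicModel(
        species=[replace(s) for s in model.species],
        reactions=reactions,
        extra_constraints=constraints,
        id=model.id,
        split_map=split_map,
    )
    out.validate()
    return out


def net_flux(samples, reaction_id: str) -> np.ndarray:
    """Per-sample net flux (forward minus reverse) of an original-model
    reaction, given a sampled flux set from the irreversible model.

    ``samples`` is any object with a ``fluxes`` DataFrame (reactions x
    samples) and a ``split_map`` attribute; for irreversible reactions
    the net flux equals the forward flux.
    """
    split_map = samples.split_map or {}
    fwd, rev = split_map.get(reaction_id, (reaction_id, None))
    fluxes = samples.fluxes
    if fwd not in fluxes.index:
        raise ModelError(f"unknown reaction id {reaction_id!r} in sample set")
    values = fluxes.loc[fwd].to_numpy(float)
    if rev is not None:
        values = values - fluxes.loc[rev].to_numpy(float)
    return values
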