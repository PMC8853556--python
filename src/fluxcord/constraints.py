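"""Cell-relative model construction.

Three incremental constraint layers turn one generic metabolic network
into per-group models that encode only *relative* differences between
the groups:

- type 1 (medium): the uptake bound of each medium metabolite scales
  with its concentration relative to the group with the highest
  concentration; metabolites absent from a group's medium cannot be
  internalized.
- type 2 (extracellular ratios): secreted-over-consumed flux ratios
  measured in spent medium become two-sided linear rows
  ``-sigma <= v_secretion - xbar * v_uptake <= sigma``; a growth-yield
  bracket ties the biomass flux to the glucose uptake flux in gram
  units.
- type 3 (transcriptomics): per-group flux-variability bounds, computed
  under layers 1 + 2 with the yield bracket retained, are scaled by the
  normalized RAS of each GPR-bearing reaction.

Layer order matters: ratio rows must be stated on the reversible model
(before the irreversible split), and FVA must run on the irreversible
model so that the RAS scaling acts on non-negative per-direction bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._lp import fva as _fva
from .model import (
    LinearConstraint,
    MetabolicModel,
    ModelError,
    make_irreversible,
)
from .ras import RasTable

logger = logging.getLogger(__name__)

__all__ = [
    "MediumDefinition",
    "RatioConstraint",
    "GrowthYieldConstraint",
    "LayerConfig",
    "CellModel",
    "apply_medium_constraints",
    "derive_ratio_constraints",
    "attach_constraints",
    "run_fva",
    "apply_ras_bounds",
    "build_cell_relative_models",
]

#: glucose molecular weight, g/mol
MW_GLUCOSE = 180.16

#: default produced-over-consumed ratio pairs, as (numerator, denominator)
DEFAULT_RATIO_PAIRS = (
    ("lactate", "glucose"),
    ("lactate", "glutamine"),
    ("glutamate", "glutamine"),
)


@dataclass
class MediumDefinition:
    """Per-group medium composition: species id -> concentration (mM)."""

    concentrations: dict[str, dict[str, float]]   # group -> species -> mM

    def __post_init__(self):
        for group, conc in self.concentrations.items():
            for sid, value in conc.items():
                if value < 0:
                    raise ValueError(
                        f"negative medium concentration for {sid!r} in group {group!r}"
                    )

    @property
    def groups(self) -> list[str]:
        return list(self.concentrations)

    @property
    def species(self) -> set[str]:
        out: set[str] = set()
        for conc in self.concentrations.values():
            out |= set(conc)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MediumDefinition":
        df = pd.read_csv(path, sep="\t")
        out: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            out.setdefault(str(row["group"]), {})[str(row["species"])] = float(row["mM"])
        return cls(out)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"species": sid, "group": group, "mM": value}
            for group, conc in self.concentrations.items()
            for sid, value in conc.items()
        ]
        pd.DataFrame(rows, columns=["species", "group", "mM"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class RatioConstraint:
    """Secretion-over-uptake flux ratio with replicate spread.

    ``numerator`` is the exchange reaction of the secreted byproduct,
    ``denominator`` the exchange of the consumed nutrient; ``mean`` and
    ``sigma`` are statistics of the measured concentration-difference
    ratio across biological replicates.
    """

    numerator: str
    denominator: str
    mean: float
    sigma: float
    name: str = ""

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("ratio sigma must be non-negative")
        if not self.name:
            self.name = f"ratio_{self.numerator}_over_{self.denominator}"


@dataclass
class GrowthYieldConstraint:
    """Bracket on the growth yield on glucose.

    With uptake u = -v_glc (mmol/gDW/h) and glucose mass u * mw * 0.001
    (g), the protein output of biomass is kept within the experimentally
    observed yield range:
    ``min_yield * u * mw * 0.001 <= protein_fraction * v_biomass
    <= max_yield * u * mw * 0.001``.
    """

    biomass_id: str
    glucose_exchange_id: str
    min_yield: float = 3.90762e-5
    max_yield: float = 1.67998e-4
    protein_fraction: float = 0.131972
    mw_glc: float = MW_GLUCOSE

    def __post_init__(self):
        if not (0 < self.min_yield <= self.max_yield):
            raise ValueError("require 0 < min_yield <= max_yield")

    def rows(self) -> list[LinearConstraint]:
        # uptake = -v_glc, so  pf*v_bio - y*mw*1e-3*(-v_glc) >= / <= 0
        # becomes pf*v_bio + y*mw*1e-3*v_glc with the exchange flux itself
        scale = self.mw_glc * 0.001
        return [
            LinearConstraint(
                "growth_yield_min",
                {
                    self.biomass_id: self.protein_fraction,
                    self.glucose_exchange_id: self.min_yield * scale,
                },
                lower=0.0,
            ),
            LinearConstraint(
                "growth_yield_max",
                {
                    self.biomass_id: self.protein_fraction,
                    self.glucose_exchange_id: self.max_yield * scale,
                },
                upper=0.0,
            ),
        ]


# ---------------------------------------------------------------------- #
# type 1: medium
# ---------------------------------------------------------------------- #
def apply_medium_constraints(
    model: MetabolicModel,
    medium: MediumDefinition,
    base_uptake: float = 10.0,
) -> dict[str, MetabolicModel]:
    """Per-group copies of the model with medium-scaled uptake bounds.

    For each exchanged metabolite, the group with the highest medium
    concentration gets uptake bound ``base_uptake`` and the others get a
    proportionally reduced bound (concentration ratios are the only
    meaningful quantity; the absolute scale is arbitrary).  Metabolites
    absent from a group's medium get uptake bound 0.  Secretion bounds
    are untouched.
    """
    for sid in medium.species:
        model.exchange_for_species(sid)  # raises ModelError naming the species

    max_conc = {
        sid: max(medium.concentrations[g].get(sid, 0.0) for g in medium.groups)
        for sid in medium.species
    }
    out: dict[str, MetabolicModel] = {}
    for group in medium.groups:
        copy = model.copy()
        copy.id = f"{model.id}__{group}"
        conc = medium.concentrations[group]
        for rxn in copy.reactions:
            if not rxn.is_exchange:
                continue
            (sid,) = rxn.stoichiometry
            coeff = rxn.stoichiometry[sid]
            # uptake is the direction that consumes the extracellular
            # species: negative flux for the conventional X_e -> (nothing)
            # encoding, positive flux if the exchange is written reversed
            if sid not in medium.species:
                if coeff < 0:
                    rxn.lower_bound = max(rxn.lower_bound, 0.0)
                else:
                    rxn.upper_bound = min(rxn.upper_bound, 0.0)
                continue
            ratio = conc.get(sid, 0.0) / max_conc[sid] if max_conc[sid] > 0 else 0.0
            if coeff < 0:
                rxn.lower_bound = -base_uptake * ratio
            else:
                rxn.upper_bound = base_uptake * ratio
        out[group] = copy
    return out


# ---------------------------------------------------------------------- #
# type 2: extracellular flux ratios + growth yield
# ---------------------------------------------------------------------- #
def derive_ratio_constraints(
    spent: pd.DataFrame,
    exchange_map: Mapping[str, str],
    pairs: Sequence[tuple[str, str]] = DEFAULT_RATIO_PAIRS,
    sigma_default: Optional[float] = None,
) -> dict[str, list[RatioConstraint]]:
    """Ratio constraints from spent-medium concentration measurements.

    ``spent`` has columns ``group, metabolite, bio_rep, tech_rep, t0,
    t48`` (concentrations at seeding and after the growth window).  For
    each (numerator, denominator) pair the produced amount (t48 - t0 of
    the byproduct) over the consumed amount (t0 - t48 of the nutrient)
    is computed per sample; ratios are averaged over technical replicates
    within each biological replicate, and the mean and sample standard
    deviation (ddof=1) over biological replicates become the constraint.
    Dividing the concentration differences by a cell-number integral is
    unnecessary since it cancels in the ratio.

    With fewer than two biological replicates the spread is undefined and
    an error is raised unless ``sigma_default`` supplies it.
    """
    required = {"group", "metabolite", "bio_rep", "tech_rep", "t0", "t48"}
    if not required <= set(spent.columns):
        raise ValueError(f"spent-medium table must have columns {sorted(required)}")

    out: dict[str, list[RatioConstraint]] = {}
    for group, gdf in spent.groupby("group", sort=False):
        wide = gdf.set_index(["bio_rep", "tech_rep", "metabolite"])[["t0", "t48"]]
        constraints = []
        for num, den in pairs:
            for met in (num, den):
                if met not in exchange_map:
                    raise ModelError(f"no exchange reaction mapped for {met!r}")
            per_bio: dict[object, list[float]] = {}
            for (bio, tech), sub in wide.groupby(level=["bio_rep", "tech_rep"]):
                sub = sub.droplevel(["bio_rep", "tech_rep"])
                produced = sub.loc[num, "t48"] - sub.loc[num, "t0"]
                consumed = sub.loc[den, "t0"] - sub.loc[den, "t48"]
                if consumed == 0:
                    raise ValueError(
                        f"zero consumption of {den!r} in group {group!r} "
                        f"(bio {bio}, tech {tech}); ratio undefined"
                    )
                per_bio.setdefault(bio, []).append(produced / consumed)
            bio_means = np.array([np.mean(v) for v in per_bio.values()])
            mean = float(bio_means.mean())
            if len(bio_means) >= 2:
                sigma = float(bio_means.std(ddof=1))
            elif sigma_default is not None:
                sigma = sigma_default
            else:
                raise ValueError(
                    f"group {group!r} has fewer than 2 biological replicates; "
                    "supply sigma_default"
                )
            constraints.append(
                RatioConstraint(
                    numerator=exchange_map[num],
                    denominator=exchange_map[den],
                    mean=mean,
                    sigma=sigma,
                    name=f"ratio_{num}_over_{den}",
                )
            )
        out[str(group)] = constraints
    return out


def attach_constraints(
    model: MetabolicModel,
    ratios: Iterable[RatioConstraint] = (),
    yield_constraint: Optional[GrowthYieldConstraint] = None,
) -> MetabolicModel:
    """Attach ratio rows and the growth-yield bracket as linear rows.

    Must be called on the reversible model, before the irreversible
    split.  With the conventional exchange encoding (positive flux =
    secretion, negative = uptake), a produced-over-consumed ratio
    ``v_num_secreted / (-v_den) ~ xbar`` becomes the two-sided row
    ``-sigma <= v_num + xbar * v_den <= sigma``.
    """
    out = model.copy()
    known = set(out.reaction_ids)
    for ratio in ratios:
        for rid in (ratio.numerator, ratio.denominator):
            if rid not in known:
                raise ModelError(f"ratio constraint references unknown flux {rid!r}")
        out.extra_constraints.append(
            LinearConstraint(
                ratio.name,
                {ratio.numerator: 1.0, ratio.denominator: ratio.mean},
                lower=-ratio.sigma,
                upper=ratio.sigma,
            )
        )
    if yield_constraint is not None:
        for rid in (yield_constraint.biomass_id, yield_constraint.glucose_exchange_id):
            if rid not in known:
                raise ModelError(f"yield constraint references unknown flux {rid!r}")
        out.extra_constraints.extend(yield_constraint.rows())
    return out


# ---------------------------------------------------------------------- #
# type 3: RAS-scaled FVA bounds
# ---------------------------------------------------------------------- #
def run_fva(
    model: MetabolicModel,
    reaction_ids: Optional[list[str]] = None,
    zero_tol: float = 1e-9,
) -> pd.DataFrame:
    """Per-reaction flux variability bounds over the feasible region,
    with no biomass objective imposed (all extra rows, including the
    yield bracket, stay active)."""
    return _fva(model, reaction_ids, zero_tol=zero_tol)


def apply_ras_bounds(
    model: MetabolicModel,
    ras_normalized: pd.Series,
    fva_bounds: pd.DataFrame,
    exempt_list: Iterable[str] = (),
    gprless: Iterable[str] = (),
) -> MetabolicModel:
    """Scale each GPR-bearing reaction's FVA interval by its normalized
    RAS: bounds become [RAS * v_L, RAS * v_U], so the group with the top
    score spans the full type-1+2 range and the others are
    proportionally narrowed.

    GPR-less reactions, reactions listed in ``gprless`` (undefined GPR),
    and ``exempt_list`` entries keep the plain [v_L, v_U] interval; the
    exemption mirrors cases where a null score would wrongly block
    growth.  ``ras_normalized`` is indexed by original (pre-split)
    reaction ids; split partners share their original's score.
    """
    values = ras_normalized.dropna()
    if ((values < 0) | (values > 1)).any():
        raise ValueError("normalized RAS values must lie in [0, 1]")
    exempt = set(exempt_list)
    skip_gpr = set(gprless)
    back = model.reverse_of
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id not in fva_bounds.index:
            continue
        lo = float(fva_bounds.loc[rxn.id, "minimum"])
        hi = float(fva_bounds.loc[rxn.id, "maximum"])
        orig = back.get(rxn.id, rxn.id)
        scalable = (
            rxn.gpr is not None
            and orig not in exempt
            and rxn.id not in exempt
            and orig not in skip_gpr
            and orig in ras_normalized.index
            and np.isfinite(ras_normalized.loc[orig])
        )
        if scalable:
            score = float(ras_normalized.loc[orig])
            rxn.lower_bound, rxn.upper_bound = score * lo, score * hi
        else:
            rxn.lower_bound, rxn.upper_bound = lo, hi
    return out


# ---------------------------------------------------------------------- #
# orchestration
# ---------------------------------------------------------------------- #
@dataclass
class LayerConfig:
    """Which constraint layers to apply, and their knobs."""

    type1: bool = True
    type2: bool = True
    type3: bool = True
    base_uptake: float = 10.0
    exempt_list: tuple[str, ...] = ()

    def __post_init__(self):
        if self.base_uptake <= 0:
            raise ValueError("base_uptake must be positive")


@dataclass
class CellModel:
    """A group's cell-relative model in irreversible form, with the FVA
    bounds used for the transcriptomic layer."""

    group: str
    model: MetabolicModel
    fva_bounds: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_cell_relative_models(
    model: MetabolicModel,
    groups: Sequence[str],
    medium: Optional[MediumDefinition] = None,
    ratio_constraints: Optional[Mapping[str, Sequence[RatioConstraint]]] = None,
    yield_constraint: Optional[GrowthYieldConstraint] = None,
    ras_table: Optional[RasTable] = None,
    config: LayerConfig = LayerConfig(),
) -> dict[str, CellModel]:
    """Compose the constraint layers into one irreversible model per group.

    Pipeline order: type 1 (medium) -> type 2 (ratio rows + yield
    bracket) -> irreversible split -> FVA (yield row retained) -> type 3
    (RAS-scaled bounds).  Any layer can be toggled off; omitting type 2
    and applying type 3 directly after type 1 is supported.
    """
    if config.type1:
        if medium is None:
            raise ValueError("type 1 requested but no medium definition given")
        per_group = apply_medium_constraints(model, medium, config.base_uptake)
        missing = [g for g in groups if g not in per_group]
        if missing:
            raise ValueError(f"medium defines no composition for groups {missing}")
    else:
        per_group = {g: model.copy() for g in groups}

    out: dict[str, CellModel] = {}
    for group in groups:
        m = per_group[group]
        if config.type2:
            ratios = (ratio_constraints or {}).get(group, [])
            m = attach_constraints(m, ratios, yield_constraint)
        irr = make_irreversible(m)
        bounds = run_fva(irr)
        if config.type3:
            if ras_table is None or ras_table.normalized is None:
                raise ValueError("type 3 requested but no normalized RAS table given")
            irr = apply_ras_bounds(
                irr,
                ras_table.normalized[group],
                bounds,
                exempt_list=config.exempt_list,
                gprless=ras_table.gprless,
            )
        else:
            irr = apply_ras_bounds(
                irr, pd.Series(dtype=float), bounds, exempt_list=irr.reaction_ids
            )
        out[group] = CellModel(group=group, model=irr, fva_bounds=bounds)
        logger.info("built cell-relative model for group %s", group)
    return out
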