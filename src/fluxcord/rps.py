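"""Reaction Propensity Scores (RPS): mass-action products of substrate
abundances.

Under mass-action kinetics the rate of an irreversible reaction is
proportional to the product of its substrate concentrations, each raised
to its stoichiometric coefficient; the kinetic constant cancels in any
ratio between two states, so the bare product serves as a proxy for how
substrate availability alone would move the flux.  A reaction enters the
RPS dataset only if *every* substrate (optionally excluding ubiquitous
species such as water or protons) has a measured abundance; one missing
substrate omits the reaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .model import MetabolicModel
from .ras import _read_grouped_tsv, _write_grouped_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolomicsDataset",
    "RpsTable",
    "map_metabolites",
    "eligible_reactions",
    "compute_rps_table",
    "COFACTOR_PRESET",
]

#: documented preset of ubiquitous species commonly left out of the
#: substrate product (matched against the species id stripped of its
#: compartment suffix); the default exclusion list is empty.
COFACTOR_PRESET = frozenset({"h2o", "h", "pi"})


@dataclass
class MetabolomicsDataset:
    """Measured-metabolite x sample abundance matrix plus the mapping
    from measured names to model species ids (one measurement may map to
    the same metabolite in several compartments)."""

    data: pd.DataFrame                                  # names x (group, sample)
    name_map: Optional[dict[str, set[str]]] = None      # measured name -> species ids

    def __post_init__(self):
        if (self.data.to_numpy(float) < 0).any():
            raise ValueError("metabolite abundances must be non-negative")
        self.data.index.name = "metabolite"

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values("group")))

    @classmethod
    def from_tsv(
        cls, path: str | Path, name_map_path: str | Path | None = None
    ) -> "MetabolomicsDataset":
        data = _read_grouped_tsv(path, "metabolite")
        name_map = None
        if name_map_path is not None:
            pairs = pd.read_csv(name_map_path, sep="\t")
            name_map = {}
            for name, sid in zip(pairs.iloc[:, 0], pairs.iloc[:, 1]):
                name_map.setdefault(str(name), set()).add(str(sid))
        return cls(data, name_map)

    def to_tsv(self, path: str | Path) -> None:
        _write_grouped_tsv(self.data, path)


@dataclass
class RpsTable:
    """Per-sample RPS values for eligible reactions, with group means."""

    per_sample: pd.DataFrame      # eligible reactions x (group, sample)
    mean: pd.DataFrame            # eligible reactions x group
    eligible: frozenset[str] = field(default_factory=frozenset)

    def group_samples(self, group: str) -> pd.DataFrame:
        return self.per_sample[group]

    def to_tsv(self, path: str | Path) -> None:
        out = self.per_sample.copy()
        out.columns = [f"{g}__{s}" for g, s in out.columns]
        for g in self.mean.columns:
            out[f"mean__{g}"] = self.mean[g]
        out.index.name = "reaction"
        out.to_csv(path, sep="\t")


def _strip_compartment(species_id: str) -> str:
    for suffix in ("_c", "_m", "_e", "_x", "_n", "_r", "_g", "_l"):
        if species_id.endswith(suffix):
            return species_id[: -len(suffix)]
    return species_id


def map_metabolites(
    model: MetabolicModel,
    metabolomics: MetabolomicsDataset,
    name_map: Optional[Mapping[str, Iterable[str]]] = None,
) -> pd.DataFrame:
    """Assign each measured abundance to its model species.

    A measurement mapping to several compartmental species (e.g.
    "citrate" -> cytosolic and mitochondrial citrate) is copied
    identically to each of them: bulk metabolomics cannot resolve
    compartments, the network structure does.  When no mapping is given,
    names are matched case-insensitively against species ids stripped of
    their compartment suffix (and against exact ids).  Names mapping to
    no species are ignored with a warning.

    Returns a species x (group, sample) abundance frame.
    """
    name_map = dict(name_map or metabolomics.name_map or {})
    by_base: dict[str, set[str]] = {}
    species_ids = {s.id for s in model.species}
    for sp in model.species:
        by_base.setdefault(_strip_compartment(sp.id).lower(), set()).add(sp.id)
        if sp.name:
            by_base.setdefault(sp.name.lower(), set()).add(sp.id)

    rows: dict[str, pd.Series] = {}
    for name in metabolomics.data.index:
        if name in name_map:
            targets = {t for t in name_map[name] if t in species_ids}
        elif name in species_ids:
            targets = {name}
        else:
            targets = by_base.get(str(name).lower(), set())
        if not targets:
            warnings.warn(
                f"measured metabolite {name!r} maps to no model species; ignored"
            )
            continue
        for sid in targets:
            if sid in rows:
                warnings.warn(
                    f"species {sid!r} already assigned; keeping the first "
                    f"measurement and ignoring {name!r}"
                )
                continue
            rows[sid] = metabolomics.data.loc[name]
    if not rows:
        return pd.DataFrame(columns=metabolomics.data.columns)
    return pd.DataFrame(rows).T


def eligible_reactions(
    model: MetabolicModel,
    assignment: pd.DataFrame,
    exclusion_list: Iterable[str] = (),
    exclude_reactions: Iterable[str] = (),
) -> set[str]:
    """Reactions whose every substrate has a measured abundance.

    Substrates are the negative-stoichiometry species of the (directional)
    reaction, minus ``exclusion_list`` entries, which may be given either
    as full species ids or as compartment-less base names (cofactor
    preset).  Exchange reactions, reactions left with no substrates, and
    ids in ``exclude_reactions`` (typically the biomass reaction, whose
    substrate pool has no meaningful measurement) are never eligible.
    """
    exclusion = {e.lower() for e in exclusion_list}
    excluded_rxns = set(exclude_reactions)
    measured = set(assignment.index)
    out: set[str] = set()
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.id in excluded_rxns:
            continue
        substrates = [
            sid
            for sid in rxn.substrates
            if sid.lower() not in exclusion
            and _strip_compartment(sid).lower() not in exclusion
        ]
        if substrates and all(sid in measured for sid in substrates):
            out.add(rxn.id)
    return out


def compute_rps_table(
    model: MetabolicModel,
    assignment: pd.DataFrame,
    eligible: Optional[set[str]] = None,
    exclusion_list: Iterable[str] = (),
    exclude_reactions: Iterable[str] = (),
) -> RpsTable:
    """RPS per eligible reaction and sample: the product over substrates
    of abundance raised to |stoichiometric coefficient|.

    Products never enter the score; the substrate set is taken from the
    directional (irreversible) reaction, so forward and reverse partners
    of a split reversible reaction are scored independently.
    """
    if (assignment.to_numpy(float) < 0).any():
        raise ValueError("metabolite abundances must be non-negative")
    if eligible is None:
        eligible = eligible_reactions(
            model, assignment, exclusion_list, exclude_reactions
        )
    exclusion = {e.lower() for e in exclusion_list}

    order = [r.id for r in model.reactions if r.id in eligible]
    rows = np.empty((len(order), assignment.shape[1]))
    by_id = model.reactions_by_id()
    for i, rid in enumerate(order):
        rxn = by_id[rid]
        value = np.ones(assignment.shape[1])
        for sid, coeff in rxn.substrates.items():
            if sid.lower() in exclusion or _strip_compartment(sid).lower() in exclusion:
                continue
            value = value * assignment.loc[sid].to_numpy(float) ** abs(coeff)
        rows[i] = value
    per_sample = pd.DataFrame(rows, index=order, columns=assignment.columns)
    mean = per_sample.T.groupby(level="group", sort=False).mean().T
    groups = list(dict.fromkeys(assignment.columns.get_level_values("group")))
    return RpsTable(per_sample=per_sample, mean=mean[groups], eligible=frozenset(order))
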