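"""Synthetic toy models and matched multi-omics with planted regulation.

The toy network mimics, at miniature scale, the situation the pipeline
is built for: a glucose/glutamine core with lactate and glutamate
secretion (so spent-medium ratio constraints and the growth-yield
bracket apply), a reversible reaction, GPRs mixing AND/OR, a GPR-less
transporter, a cytosol/mitochondrion duplicated metabolite, and a set of
independent substrate->product branches onto which regulation classes
are planted:

- metabolic control: the branch substrate's medium concentration and
  measured abundance co-vary across groups while enzyme expression stays
  flat -- the flux tracks substrate availability;
- transcriptional control: enzyme expression varies while substrate
  levels and medium stay flat -- the flux tracks the activity score
  through the transcriptomic bounds;
- concerted control: both move together.

Group-level means follow the planted multipliers; per-sample values are
drawn lognormally around them (lognormal noise keeps expression and
abundance positive), deterministically for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gpr import parse_gpr
from .model import MetabolicModel, Reaction, Species, flag_exchanges
from .ras import ExpressionDataset
from .rps import MetabolomicsDataset

__all__ = [
    "PlantedScenario",
    "SyntheticData",
    "RecoverySummary",
    "generate_toy_model",
    "default_scenario",
    "zero_effect_scenario",
    "generate_planted_omics",
    "score_recovery",
]

PLANTABLE_CLASSES = ("metabolic_only", "transcriptional_only", "concerted")

#: group multipliers planted across the (three) groups; every pairwise
#: ratio is a factor 2, well clear of the 20% sign-call threshold
_BASE_MULTIPLIERS = (1.0, 2.0, 4.0)


def generate_toy_model(n_branches: int = 12, with_compartments: bool = True) -> MetabolicModel:
    """A small metabolic network with ``n_branches`` independent planted
    branches grafted onto a glucose/glutamine core.

    Each branch is an uptake -> transport -> conversion chain
    ``bs_i_e -> bs_i_c -> P_c`` whose conversion carries a single-gene
    GPR; by flux balance the three chain fluxes coincide, so the branch
    behaves as one independently bounded degree of freedom.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")

    species = [
        Species("glc_e", "glucose", "e"), Species("glc_c", "glucose", "c"),
        Species("pyr_c", "pyruvate", "c"),
        Species("lac_c", "lactate", "c"), Species("lac_e", "lactate", "e"),
        Species("gln_e", "glutamine", "e"), Species("gln_c", "glutamine", "c"),
        Species("glu_c", "glutamate", "c"), Species("glu_e", "glutamate", "e"),
        Species("P_c", "branch product", "c"), Species("P_e", "branch product", "e"),
        Species("prot_c", "protein", "c"), Species("prot_e", "protein", "e"),
    ]
    reactions = [
        Reaction("EX_glc_e", {"glc_e": -1}, -10, 0, is_exchange=True),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000),
        Reaction("GLYC", {"glc_c": -1, "pyr_c": 2}, 0, 1000,
                 gpr=parse_gpr("G_GLYC1 and G_GLYC2")),
        Reaction("LDH", {"pyr_c": -1, "lac_c": 1}, -1000, 1000,
                 gpr=parse_gpr("G_LDHA or G_LDHB")),
        Reaction("LACt", {"lac_c": -1, "lac_e": 1}, 0, 1000),
        Reaction("EX_lac_e", {"lac_e": -1}, 0, 1000, is_exchange=True),
        Reaction("EX_gln_e", {"gln_e": -1}, -10, 0, is_exchange=True),
        Reaction("GLNt", {"gln_e": -1, "gln_c": 1}, 0, 1000, gpr=parse_gpr("G_GLNT")),
        Reaction("GLS", {"gln_c": -1, "glu_c": 1}, 0, 1000, gpr=parse_gpr("G_GLS")),
        Reaction("GLUt", {"glu_c": -1, "glu_e": 1}, 0, 1000),
        Reaction("EX_glu_e", {"glu_e": -1}, 0, 1000, is_exchange=True),
        # catabolic drains: without them every glutamate/pyruvate molecule
        # would be forced out through the secretion exchanges and the
        # spent-medium ratio rows would pin all uptakes near zero
        Reaction("GDH", {"glu_c": -1, "P_c": 1}, 0, 1000, gpr=parse_gpr("G_GDH")),
        Reaction("PDH", {"pyr_c": -1, "P_c": 1}, 0, 1000, gpr=parse_gpr("G_PDH")),
        Reaction("BIOMASS", {"pyr_c": -0.4, "glu_c": -0.3, "P_c": -0.3, "prot_c": 1},
                 0, 1000),
        Reaction("PROTt", {"prot_c": -1, "prot_e": 1}, 0, 1000),
        Reaction("EX_prot_e", {"prot_e": -1}, 0, 1000, is_exchange=True),
        Reaction("Pt", {"P_c": -1, "P_e": 1}, 0, 1000),
        Reaction("EX_P_e", {"P_e": -1}, 0, 1000, is_exchange=True),
    ]
    if with_compartments:
        species += [Species("cit_c", "citrate", "c"), Species("cit_m", "citrate", "m")]
        reactions += [
            Reaction("CS", {"pyr_c": -1, "cit_c": 1}, 0, 1000, gpr=parse_gpr("G_CS")),
            Reaction("CITtcm", {"cit_c": -1, "cit_m": 1}, 0, 1000),
            Reaction("CITDHm", {"cit_m": -1, "glu_c": 1}, 0, 1000, gpr=parse_gpr("G_CITDH")),
        ]
    for i in range(1, n_branches + 1):
        species += [
            Species(f"bs{i}_e", f"branch substrate {i}", "e"),
            Species(f"bs{i}_c", f"branch substrate {i}", "c"),
        ]
        reactions += [
            Reaction(f"EX_bs{i}_e", {f"bs{i}_e": -1}, -10, 0, is_exchange=True),
            Reaction(f"BS{i}t", {f"bs{i}_e": -1, f"bs{i}_c": 1}, 0, 1000),
            Reaction(f"BR{i}", {f"bs{i}_c": -1, "P_c": 1}, 0, 1000,
                     gpr=parse_gpr(f"G_BR{i}")),
        ]
    model = MetabolicModel(species=species, reactions=reactions, id="toy")
    flag_exchanges(model)
    model.validate()
    return model


@dataclass
class PlantedScenario:
    """Ground truth for one synthetic experiment.

    ``classes`` maps branch-conversion reaction ids to their planted
    regulation class; ``multipliers`` maps the same ids to per-group
    multipliers applied to the regulated quantities (enzyme expression
    for transcriptional/concerted, substrate abundance and medium
    concentration for metabolic/concerted).
    """

    groups: tuple[str, ...] = ("A", "B", "C")
    classes: dict[str, str] = field(default_factory=dict)
    multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.1
    n_samples: int = 3
    seed: int = 0
    baseline_expression: float = 50.0
    baseline_abundance: float = 10.0
    base_medium_mM: float = 10.0

    def __post_init__(self):
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        for rid, cls in self.classes.items():
            if cls not in PLANTABLE_CLASSES:
                raise ValueError(f"unknown planted class {cls!r} for {rid!r}")
        for rid, mults in self.multipliers.items():
            if any(m <= 0 for m in mults.values()):
                raise ValueError(f"multipliers must be positive ({rid!r})")


def _branch_reactions(model: MetabolicModel) -> list[str]:
    return sorted(
        (r.id for r in model.reactions if r.id.startswith("BR")),
        key=lambda rid: int(rid[2:]),
    )


def default_scenario(
    model: MetabolicModel,
    groups: Sequence[str] = ("A", "B", "C"),
    noise_sd: float = 0.1,
    n_samples: int = 3,
    seed: int = 0,
) -> PlantedScenario:
    """Plant classes on the model's branches: roughly 5/12 metabolic,
    5/12 concerted, the rest transcriptional, with the group-multiplier
    profile rotated per branch so sign vectors differ across reactions."""
    branches = _branch_reactions(model)
    n = len(branches)
    n_met = max(1, round(5 * n / 12))
    n_con = max(1, round(5 * n / 12))
    classes, multipliers = {}, {}
    for j, rid in enumerate(branches):
        if j < n_met:
            cls = "metabolic_only"
        elif j < n_met + n_con:
            cls = "concerted"
        else:
            cls = "transcriptional_only"
        classes[rid] = cls
        perm = [_BASE_MULTIPLIERS[(j + k) % len(_BASE_MULTIPLIERS)]
                for k in range(len(groups))]
        multipliers[rid] = dict(zip(groups, perm))
    return PlantedScenario(
        groups=tuple(groups), classes=classes, multipliers=multipliers,
        noise_sd=noise_sd, n_samples=n_samples, seed=seed,
    )


def zero_effect_scenario(
    model: MetabolicModel,
    groups: Sequence[str] = ("A", "B", "C"),
    noise_sd: float = 0.05,
    n_samples: int = 3,
    seed: int = 0,
) -> PlantedScenario:
    """All multipliers equal to 1: no planted regulation anywhere; every
    between-group difference is measurement noise.

    The default noise keeps the coefficient of variation well below the
    20% fold-change guard of the sign calls (see the methods note), so
    the expected outcome is an all-zero sign matrix and an
    'inconclusive' label for every reaction.
    """
    branches = _branch_reactions(model)
    return PlantedScenario(
        groups=tuple(groups),
        classes={},
        multipliers={rid: {g: 1.0 for g in groups} for rid in branches},
        noise_sd=noise_sd, n_samples=n_samples, seed=seed,
    )


@dataclass
class SyntheticData:
    """All pipeline inputs for one synthetic experiment, plus ground truth."""

    expression: ExpressionDataset
    metabolomics: MetabolomicsDataset
    medium: "object"                       # MediumDefinition (import cycle)
    spent: pd.DataFrame
    exchange_map: dict[str, str]
    scenario: PlantedScenario
    biomass_id: str = "BIOMASS"
    glucose_exchange_id: str = "EX_glc_e"


def generate_planted_omics(model: MetabolicModel, scenario: PlantedScenario) -> SyntheticData:
    """Expression, metabolomics, medium and spent-medium tables realizing
    the planted scenario on the toy model (deterministic given the seed)."""
    from .constraints import MediumDefinition  # local import: avoid cycle

    known = set(model.reaction_ids)
    unknown = (set(scenario.classes) | set(scenario.multipliers)) - known
    if unknown:
        raise ValueError(f"scenario references unknown reactions {sorted(unknown)}")

    rng = np.random.default_rng(scenario.seed)
    groups = list(scenario.groups)
    cols = pd.MultiIndex.from_tuples(
        [(g, f"r{k + 1}") for g in groups for k in range(scenario.n_samples)],
        names=["group", "sample"],
    )

    def mult(rid: str, group: str, when: tuple[str, ...]) -> float:
        cls = scenario.classes.get(rid)
        if cls in when and rid in scenario.multipliers:
            return scenario.multipliers[rid][group]
        return 1.0

    def noisy(mean_per_group: Mapping[str, float]) -> np.ndarray:
        out = np.empty(len(cols))
        for j, (g, _) in enumerate(cols):
            out[j] = mean_per_group[g] * rng.lognormal(0.0, scenario.noise_sd)
        return out

    # --- expression: every model gene, branch genes scaled where planted
    gene_of_branch = {rid: f"G_{rid}" for rid in _branch_reactions(model)}
    expr_rows = {}
    for gene in model.genes:
        means = {g: scenario.baseline_expression for g in groups}
        for rid, gname in gene_of_branch.items():
            if gname == gene:
                means = {
                    g: scenario.baseline_expression
                    * mult(rid, g, ("transcriptional_only", "concerted"))
                    for g in groups
                }
        expr_rows[gene] = noisy(means)
    expression = ExpressionDataset(pd.DataFrame(expr_rows, index=cols).T)

    # --- metabolomics: one measured name per base metabolite
    name_map: dict[str, set[str]] = {}
    for sp in model.species:
        if sp.id.startswith("prot"):
            continue  # protein content is not an LC-MS metabolite
        name_map.setdefault(sp.name, set()).add(sp.id)
    abundance_rows = {}
    for name, sids in name_map.items():
        means = {g: scenario.baseline_abundance for g in groups}
        for rid in _branch_reactions(model):
            if any(sid in sids for sid in model.get_reaction(rid).substrates):
                means = {
                    g: scenario.baseline_abundance
                    * mult(rid, g, ("metabolic_only", "concerted"))
                    for g in groups
                }
        abundance_rows[name] = noisy(means)
    metabolomics = MetabolomicsDataset(
        pd.DataFrame(abundance_rows, index=cols).T, name_map=name_map
    )

    # --- medium: glc/gln shared; branch substrates scaled where planted
    medium = {}
    for g in groups:
        conc = {"glc_e": 17.5, "gln_e": 4.0}
        for rid in _branch_reactions(model):
            (sid,) = model.get_reaction(rid.replace("BR", "EX_bs") + "_e").stoichiometry
            conc[sid] = scenario.base_medium_mM * mult(
                rid, g, ("metabolic_only", "concerted")
            )
        medium[g] = conc

    # --- spent medium: consistent lactate/glucose 1.5, lactate/glutamine 5,
    #     glutamate/glutamine 0.8 ratios with small replicate scatter
    spent_rows = []
    deltas = {"glucose": -10.0, "lactate": 15.0, "glutamine": -3.0, "glutamate": 2.4}
    t0 = {"glucose": 17.5, "lactate": 0.0, "glutamine": 4.0, "glutamate": 0.0}
    for g in groups:
        for bio in (1, 2):
            for tech in (1, 2, 3):
                for met, delta in deltas.items():
                    scatter = rng.lognormal(0.0, 0.03)
                    spent_rows.append(
                        {
                            "group": g, "metabolite": met,
                            "bio_rep": bio, "tech_rep": tech,
                            "t0": t0[met], "t48": t0[met] + delta * scatter,
                        }
                    )
    spent = pd.DataFrame(spent_rows)

    exchange_map = {
        "glucose": "EX_glc_e", "lactate": "EX_lac_e",
        "glutamine": "EX_gln_e", "glutamate": "EX_glu_e",
    }
    return SyntheticData(
        expression=expression,
        metabolomics=metabolomics,
        medium=MediumDefinition(medium),
        spent=spent,
        exchange_map=exchange_map,
        scenario=scenario,
    )


@dataclass
class RecoverySummary:
    confusion: pd.DataFrame            # planted class x assigned label counts
    precision: dict[str, float]
    recall: dict[str, float]
    accuracy: float


def score_recovery(scenario: PlantedScenario, labels: pd.Series) -> RecoverySummary:
    """Confusion summary of assigned labels against the planted classes.

    ``labels`` maps reaction id -> assigned class (the concordance
    table's label column).  Precision for a class counts planted
    reactions only; recall is the fraction of that class's planted
    reactions recovered.
    """
    planted = pd.Series(scenario.classes, dtype=object)
    assigned = labels.reindex(planted.index).fillna("inconclusive")
    all_labels = sorted(set(planted) | set(assigned))
    confusion = pd.DataFrame(0, index=sorted(set(planted)), columns=all_labels)
    for rid in planted.index:
        confusion.loc[planted[rid], assigned[rid]] += 1

    precision, recall = {}, {}
    for cls in confusion.index:
        tp = confusion.loc[cls, cls] if cls in confusion.columns else 0
        n_assigned = int((assigned == cls).sum())
        n_planted = int((planted == cls).sum())
        precision[cls] = tp / n_assigned if n_assigned else np.nan
        recall[cls] = tp / n_planted if n_planted else np.nan
    accuracy = float((assigned == planted).mean()) if len(planted) else 1.0
    return RecoverySummary(confusion, precision, recall, accuracy)
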