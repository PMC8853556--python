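"""End-to-end orchestration: scores -> cell-relative models -> flux
sampling -> sign matrices -> concordance table.

The stages run in a fixed order (activity scores, propensity scores,
constraint layers, sampling, concordance); every intermediate is a
plain table that the corresponding module can re-load, and a manifest
records parameters and seeds so a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from .concordance import (
    ConcordanceResult,
    SignMatrix,
    concordance_table,
    kappa_series,
    pairwise_sign_matrix,
)
from .constraints import (
    CellModel,
    GrowthYieldConstraint,
    LayerConfig,
    MediumDefinition,
    build_cell_relative_models,
    derive_ratio_constraints,
)
from .model import MetabolicModel, read_sbml
from .ras import ExpressionDataset, RasTable, compute_ras_table
from .rps import (
    MetabolomicsDataset,
    RpsTable,
    compute_rps_table,
    eligible_reactions,
    map_metabolites,
)
from .sampling import FluxSampleSet, sample_fluxes

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "RunConfig", "PipelineResult", "run_pipeline", "run_from_config"]


@dataclass
class PipelineParams:
    """Numeric knobs of the pipeline, with the study defaults."""

    alpha: float = 0.05
    fold_up: float = 1.2
    fold_down: float = 0.8
    kappa_threshold: float = 0.2
    n_resamples: int = 1000
    n_samples_total: int = 5000
    n_batches: int = 10
    thinning: int = 10
    seed: int = 0
    base_uptake: float = 10.0
    max_test_n: int = 10000
    missing_policy: str = "skip"
    exclusion_list: tuple[str, ...] = ()
    exempt_list: tuple[str, ...] = ()
    type1: bool = True
    type2: bool = True
    type3: bool = True
    pooling: str = "pooled"
    batch_stability: bool = True

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (self.fold_down < 1 < self.fold_up):
            raise ValueError("fold thresholds must bracket 1")
        if not (0 <= self.kappa_threshold <= 1):
            raise ValueError("kappa threshold must be in [0, 1]")


@dataclass
class PipelineResult:
    ras_table: RasTable
    rps_table: RpsTable
    cell_models: dict[str, CellModel]
    samples: dict[str, FluxSampleSet]
    signs: dict[str, SignMatrix]
    concordance: ConcordanceResult
    batch_kappas: Optional[pd.DataFrame] = None

    @property
    def labels(self) -> pd.Series:
        return self.concordance.table["label"]


def _group_seed(seed: int, index: int) -> int:
    return (seed * 1_000_003 + 7919 * (index + 1)) % 2**31


def run_pipeline(
    model: MetabolicModel,
    expression: ExpressionDataset,
    metabolomics: MetabolomicsDataset,
    medium: Optional[MediumDefinition] = None,
    spent: Optional[pd.DataFrame] = None,
    exchange_map: Optional[Mapping[str, str]] = None,
    biomass_id: Optional[str] = None,
    glucose_exchange_id: Optional[str] = None,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Run every stage on in-memory inputs and return all intermediates.

    ``model`` is the generic (reversible) network; groups are taken from
    the expression dataset and must match the metabolomics and medium
    groups.  The growth-yield bracket is attached whenever both
    ``biomass_id`` and ``glucose_exchange_id`` are given and type 2 is
    enabled.
    """
    groups = expression.groups
    if metabolomics.groups != groups:
        raise ValueError("expression and metabolomics groups differ")

    # 1. activity scores on the generic model
    ras_table = compute_ras_table(model, expression, params.missing_policy)

    # 2. constraint layers
    ratios = None
    yield_constraint = None
    if params.type2:
        if spent is not None:
            if exchange_map is None:
                raise ValueError("spent-medium table given without an exchange map")
            ratios = derive_ratio_constraints(spent, exchange_map)
        if biomass_id and glucose_exchange_id:
            yield_constraint = GrowthYieldConstraint(biomass_id, glucose_exchange_id)
    layer_config = LayerConfig(
        type1=params.type1, type2=params.type2, type3=params.type3,
        base_uptake=params.base_uptake, exempt_list=tuple(params.exempt_list),
    )
    cell_models = build_cell_relative_models(
        model, groups, medium=medium, ratio_constraints=ratios,
        yield_constraint=yield_constraint, ras_table=ras_table, config=layer_config,
    )

    # 3. flux sampling per group
    samples = {
        g: sample_fluxes(
            cell_models[g].model,
            n_total=params.n_samples_total,
            n_batches=params.n_batches,
            thinning=params.thinning,
            seed=_group_seed(params.seed, i),
            group=g,
        )
        for i, g in enumerate(groups)
    }

    # 4. propensity scores on the irreversible network (substrates are
    #    direction-specific); structure is identical across groups
    irr = cell_models[groups[0]].model
    assignment = map_metabolites(irr, metabolomics)
    exclude = {biomass_id} if biomass_id else set()
    eligible = eligible_reactions(
        irr, assignment, params.exclusion_list, exclude_reactions=exclude
    )
    rps_table = compute_rps_table(irr, assignment, eligible)

    # 5. pairwise variation signs; activity signs are computed on the raw
    #    per-sample scores of GPR-bearing reactions, mapped onto the
    #    split reaction ids so all three matrices share an index space
    ras_split = _expand_to_split(ras_table, irr)
    signs = {
        "RAS": pairwise_sign_matrix(
            {g: ras_split[g] for g in groups}, "samples", tag="RAS",
            alpha=params.alpha, fold_up=params.fold_up, fold_down=params.fold_down,
        ),
        "RPS": pairwise_sign_matrix(
            {g: rps_table.group_samples(g) for g in groups}, "samples", tag="RPS",
            alpha=params.alpha, fold_up=params.fold_up, fold_down=params.fold_down,
        ),
        "FFD": pairwise_sign_matrix(
            {g: samples[g].fluxes for g in groups}, "distribution", tag="FFD",
            alpha=params.alpha, fold_up=params.fold_up, fold_down=params.fold_down,
            max_n=params.max_test_n,
        ),
    }

    # 6. per-batch flux-vs-propensity kappas (sampling robustness)
    batch_kappas = None
    if params.batch_stability and params.n_batches > 1:
        cols = {}
        for b in range(params.n_batches):
            ffd_b = pairwise_sign_matrix(
                {g: samples[g].batch(b) for g in groups}, "distribution",
                tag=f"FFD_batch{b}", alpha=params.alpha,
                fold_up=params.fold_up, fold_down=params.fold_down,
                max_n=params.max_test_n,
            )
            cols[b] = kappa_series(signs["RPS"], ffd_b)
        batch_kappas = pd.DataFrame(cols)

    # 7. concordance, significance, classification
    result = concordance_table(
        signs["RAS"], signs["RPS"], signs["FFD"],
        n_resamples=params.n_resamples, seed=params.seed,
        threshold=params.kappa_threshold, pooling=params.pooling,
        batch_kappas=batch_kappas,
    )
    return PipelineResult(
        ras_table=ras_table, rps_table=rps_table, cell_models=cell_models,
        samples=samples, signs=signs, concordance=result, batch_kappas=batch_kappas,
    )


def _expand_to_split(ras_table: RasTable, irr_model: MetabolicModel) -> dict[str, pd.DataFrame]:
    """Copy per-sample activity scores of GPR-bearing reactions onto the
    forward/reverse ids of the irreversible model; returns per-group frames."""
    back = irr_model.reverse_of
    rows, index = [], []
    per_sample = ras_table.per_sample
    for rxn in irr_model.reactions:
        orig = back.get(rxn.id, rxn.id)
        if orig in ras_table.gprless or orig not in per_sample.index:
            continue
        rows.append(per_sample.loc[orig])
        index.append(rxn.id)
    frame = pd.DataFrame(rows, index=index)
    return {g: frame[g] for g in ras_table.groups}


# ---------------------------------------------------------------------- #
# file-based runs
# ---------------------------------------------------------------------- #
@dataclass
class RunConfig:
    """Paths plus parameters for a file-based run (YAML-loadable)."""

    model: str
    expression: str
    metabolomics: str
    output_dir: str
    name_map: Optional[str] = None
    medium: Optional[str] = None
    spent_medium: Optional[str] = None
    exchange_map: dict[str, str] = field(default_factory=dict)
    biomass_id: Optional[str] = None
    glucose_exchange_id: Optional[str] = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        params = PipelineParams(**payload.pop("params", {}))
        return cls(params=params, **payload)


def run_from_config(config: RunConfig) -> PipelineResult:
    """Load all inputs from the configured paths, run the pipeline, and
    persist every intermediate plus a manifest under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = read_sbml(config.model)
    expression = ExpressionDataset.from_tsv(config.expression)
    metabolomics = MetabolomicsDataset.from_tsv(config.metabolomics, config.name_map)
    medium = MediumDefinition.from_tsv(config.medium) if config.medium else None
    spent = (
        pd.read_csv(config.spent_medium, sep="\t") if config.spent_medium else None
    )

    result = run_pipeline(
        model, expression, metabolomics, medium=medium, spent=spent,
        exchange_map=config.exchange_map or None,
        biomass_id=config.biomass_id,
        glucose_exchange_id=config.glucose_exchange_id,
        params=config.params,
    )

    result.ras_table.to_tsv(out / "ras.tsv")
    result.rps_table.to_tsv(out / "rps.tsv")
    for g, sset in result.samples.items():
        sset.to_tsv(out / f"ffd_{g}.tsv")
    for tag, matrix in result.signs.items():
        matrix.data.rename_axis("reaction").to_csv(out / f"signs_{tag.lower()}.tsv", sep="\t")
    result.concordance.to_tsv(out / "concordance.tsv")
    manifest = {
        "params": asdict(config.params),
        "inputs": {
            "model": str(config.model),
            "expression": str(config.expression),
            "metabolomics": str(config.metabolomics),
            "medium": config.medium,
            "spent_medium": config.spent_medium,
        },
        "groups": expression.groups,
        "n_reactions": len(model.reactions),
        "n_eligible": int(len(result.rps_table.eligible)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline outputs written to %s", out)
    return result
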