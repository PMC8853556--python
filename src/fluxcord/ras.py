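"""Reaction Activity Scores (RAS): expression data pushed through GPRs.

For every reaction with a GPR rule and every sample, the rule is
evaluated on the sample's gene expression values (AND -> minimum,
OR -> sum).  Per-group scores are the mean over that group's samples,
and the group means are then normalized reaction-wise by their maximum
across groups, yielding scores in [0, 1] that drive the
transcriptomics-derived flux bounds.  Reactions without a GPR (or whose
GPR cannot be evaluated on the given gene panel) carry the sentinel
score 1, which leaves their bounds untouched downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .gpr import evaluate_gpr
from .model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = ["ExpressionDataset", "RasTable", "compute_ras_table", "normalize_ras"]

#: sentinel per-sample score for reactions without an (evaluable) GPR
GPRLESS_SCORE = 1.0


def _read_grouped_tsv(path: str | Path, index_name: str) -> pd.DataFrame:
    """Read a TSV with first column = feature id and remaining columns
    named ``<group>__<sample>``; returns a frame with (group, sample)
    MultiIndex columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = []
    for c in df.columns:
        if "__" not in c:
            raise ValueError(
                f"column {c!r} is not of the form '<group>__<sample>'"
            )
        group, sample = c.split("__", 1)
        cols.append((group, sample))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["group", "sample"])
    df.index.name = index_name
    return df


def _write_grouped_tsv(df: pd.DataFrame, path: str | Path) -> None:
    flat = df.copy()
    flat.columns = [f"{g}__{s}" for g, s in df.columns]
    flat.to_csv(path, sep="\t")


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with a (group, sample) column
    MultiIndex.  Any non-negative unit (FPKM, counts) is accepted; no
    within-sample renormalization is applied."""

    data: pd.DataFrame

    def __post_init__(self):
        if (self.data.to_numpy(float) < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")
        self.data.index.name = "gene"
        for group in self.groups:
            if self.data[group].shape[1] < 1:
                raise ValueError(f"group {group!r} has no samples")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values("group")))

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionDataset":
        return cls(_read_grouped_tsv(path, "gene"))

    def to_tsv(self, path: str | Path) -> None:
        _write_grouped_tsv(self.data, path)


@dataclass
class RasTable:
    """Per-sample, per-group-mean and cross-group-normalized RAS."""

    per_sample: pd.DataFrame          # reactions x (group, sample)
    mean: pd.DataFrame                # reactions x group
    normalized: Optional[pd.DataFrame] = None   # reactions x group, in [0, 1]
    gprless: frozenset[str] = field(default_factory=frozenset)

    @property
    def groups(self) -> list[str]:
        return list(self.mean.columns)

    def group_samples(self, group: str) -> pd.DataFrame:
        return self.per_sample[group]

    def to_tsv(self, path: str | Path) -> None:
        out = self.per_sample.copy()
        out.columns = [f"{g}__{s}" for g, s in out.columns]
        for g in self.mean.columns:
            out[f"mean__{g}"] = self.mean[g]
        if self.normalized is not None:
            for g in self.normalized.columns:
                out[f"normalized__{g}"] = self.normalized[g]
        out.index.name = "reaction"
        out.to_csv(path, sep="\t")


def compute_ras_table(
    model: MetabolicModel,
    expression: ExpressionDataset,
    missing_policy: str = "skip",
) -> RasTable:
    """Evaluate every reaction's GPR on every sample and average per group.

    Reactions without a GPR -- or whose GPR is undefined on the gene
    panel under ``missing_policy`` -- receive the sentinel score 1 in
    every sample and are recorded in ``gprless``.
    """
    values = expression.data
    gene_arrays = {g: values.loc[g].to_numpy(float) for g in values.index}
    n_cols = values.shape[1]

    rows = np.empty((len(model.reactions), n_cols))
    gprless: set[str] = set()
    for i, rxn in enumerate(model.reactions):
        if rxn.gpr is None:
            rows[i] = GPRLESS_SCORE
            gprless.add(rxn.id)
            continue
        score = evaluate_gpr(rxn.gpr, gene_arrays, missing_policy=missing_policy)
        if score is None:
            logger.warning(
                "GPR of reaction %s is undefined on the supplied gene panel; "
                "falling back to the GPR-less sentinel score",
                rxn.id,
            )
            rows[i] = GPRLESS_SCORE
            gprless.add(rxn.id)
        else:
            rows[i] = np.broadcast_to(np.asarray(score, float), (n_cols,))

    per_sample = pd.DataFrame(rows, index=model.reaction_ids, columns=values.columns)
    mean = per_sample.T.groupby(level="group", sort=False).mean().T
    mean = mean[ExpressionDataset(values).groups]  # preserve input group order
    table = RasTable(per_sample=per_sample, mean=mean, gprless=frozenset(gprless))
    return normalize_ras(table)


def normalize_ras(table: RasTable) -> RasTable:
    """Divide group-mean RAS by the reaction-wise maximum over groups.

    Reactions whose RAS is zero in every group keep a normalized score of
    zero (rather than NaN).
    """
    mean = table.mean
    row_max = mean.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = mean.div(row_max, axis=0)
    normalized[row_max == 0] = 0.0
    table.normalized = normalized
    return table
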