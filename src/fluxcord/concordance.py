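"""Concordance analysis: pairwise variation signs, Cohen's kappa, the
resampling null, and regulatory classification.

For every ordered pair of groups and every reaction, each of the three
reaction-centric datasets (RAS, RPS, flux samples) votes up (+1), down
(-1) or no-change (0).  A vote requires both statistical significance
(Welch's t-test for the few-replicate RAS/RPS scores, Mann-Whitney U for
the large flux-sample distributions, p < alpha) and a relaxed 20%
fold-change of the central value (mean for scores, median for fluxes).
Agreement between two datasets' sign vectors is summarized per reaction
by Cohen's kappa -- the chance-corrected fraction of matching votes.
Significance of the flux-vs-propensity agreement is assessed against an
empirical null built by resampling sign vectors from the pooled
propensity votes, with Benjamini-Hochberg control of the false discovery
rate across reactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SignMatrix",
    "ConcordanceResult",
    "variation_sign",
    "pairwise_sign_matrix",
    "cohens_kappa",
    "empirical_null_pvalues",
    "bh_adjust",
    "classify_reactions",
    "concordance_table",
    "CLASS_LABELS",
]

CLASS_LABELS = (
    "concerted",
    "metabolic_only",
    "transcriptional_only",
    "other",
    "inconclusive",
)

_CATEGORIES = (-1, 0, 1)


def variation_sign(
    values_a: np.ndarray,
    values_b: np.ndarray,
    mode: str,
    alpha: float = 0.05,
    fold_up: float = 1.2,
    fold_down: float = 0.8,
    max_n: int = 10000,
) -> int:
    """Sign of the variation of group a relative to group b.

    ``mode="samples"`` (scores with few replicates): Welch's t-test and
    the ratio of means.  ``mode="distribution"`` (sampled fluxes):
    Mann-Whitney U test and the ratio of medians; each group is
    down-sampled to at most ``max_n`` evenly strided values, since at
    very large n the U test rejects for meaninglessly small shifts.

    Returns +1 when p < alpha and central_a / central_b >= fold_up, -1
    when p < alpha and the ratio is <= fold_down, else 0.  With fewer
    than two values in a group (samples mode) the test is undefined and
    0 is returned with a warning.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if mode == "samples":
        if len(a) < 2 or len(b) < 2:
            warnings.warn("a group has fewer than 2 values; sign set to 0")
            return 0
        central_a, central_b = a.mean(), b.mean()
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            return 0
        with np.errstate(all="ignore"):
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
    elif mode == "distribution":
        if len(a) > max_n:
            a = a[np.linspace(0, len(a) - 1, max_n).astype(int)]
        if len(b) > max_n:
            b = b[np.linspace(0, len(b) - 1, max_n).astype(int)]
        central_a, central_b = np.median(a), np.median(b)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            return 0
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    else:
        raise ValueError(f"mode must be 'samples' or 'distribution', got {mode!r}")

    if not (p < alpha):  # NaN-safe
        return 0
    if central_b == 0:
        ratio = np.inf if central_a > 0 else 1.0
    else:
        ratio = central_a / central_b
    if ratio >= fold_up:
        return 1
    if ratio <= fold_down:
        return -1
    return 0


@dataclass
class SignMatrix:
    """Reaction x group-pair sign calls for one dataset.

    Pair order is lexicographic on group labels and must be shared by
    every dataset entering a kappa comparison.
    """

    tag: str
    data: pd.DataFrame    # reactions x pair labels, values in {-1, 0, 1}
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        bad = ~self.data.isin([-1, 0, 1]).to_numpy()
        if bad.any():
            raise ValueError("sign matrix entries must be in {-1, 0, +1}")


def ordered_pairs(groups: Sequence[str]) -> tuple[tuple[str, str], ...]:
    return tuple(combinations(sorted(groups), 2))


def pairwise_sign_matrix(
    data: Mapping[str, pd.DataFrame],
    mode: str,
    tag: str = "",
    alpha: float = 0.05,
    fold_up: float = 1.2,
    fold_down: float = 0.8,
    max_n: int = 10000,
) -> SignMatrix:
    """Sign calls for every reaction and every (lexicographic) group pair.

    ``data`` maps group label -> reaction x sample frame; all groups must
    share the reaction index.
    """
    groups = list(data)
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    pairs = ordered_pairs(groups)
    index = data[groups[0]].index
    arrays = {g: df.loc[index].to_numpy(float) for g, df in data.items()}

    out = np.zeros((len(index), len(pairs)), dtype=int)
    for j, (ga, gb) in enumerate(pairs):
        A, B = arrays[ga], arrays[gb]
        for i in range(len(index)):
            out[i, j] = variation_sign(
                A[i], B[i], mode, alpha=alpha, fold_up=fold_up,
                fold_down=fold_down, max_n=max_n,
            )
    frame = pd.DataFrame(
        out, index=index, columns=[f"{a}|{b}" for a, b in pairs]
    )
    return SignMatrix(tag=tag, data=frame, pairs=pairs)


def cohens_kappa(signs_a: Sequence[int], signs_b: Sequence[int]) -> float:
    """Chance-corrected agreement between two categorical vectors.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement
    fraction and p_e the chance agreement implied by the two marginal
    category distributions.  Degenerate cases: two identical constant
    vectors give 1, two different constant vectors give -1 (fully
    concordant / fully opposite judgments); any other p_e = 1 situation
    cannot arise.
    """
    a = np.asarray(signs_a)
    b = np.asarray(signs_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("sign vectors must be non-empty and of equal length")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # both raters constant: full concordance or fully opposite judgments
        return 1.0 if a[0] == b[0] else -1.0
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for cat in np.union1d(a, b):
        p_e += float(np.mean(a == cat)) * float(np.mean(b == cat))
    return (p_o - p_e) / (1.0 - p_e)


def kappa_series(signs_a: SignMatrix, signs_b: SignMatrix) -> pd.Series:
    """Per-reaction kappa over the reactions common to both matrices."""
    if signs_a.pairs != signs_b.pairs:
        raise ValueError("sign matrices use different group-pair orderings")
    common = signs_a.data.index.intersection(signs_b.data.index)
    values = [
        cohens_kappa(signs_a.data.loc[r].to_numpy(), signs_b.data.loc[r].to_numpy())
        for r in common
    ]
    return pd.Series(values, index=common, dtype=float)


def empirical_null_pvalues(
    rps_signs: SignMatrix,
    ffd_signs: SignMatrix,
    observed: pd.Series,
    n_resamples: int = 1000,
    seed: int = 0,
    pooling: str = "pooled",
) -> pd.Series:
    """Empirical p-values for the flux-vs-propensity kappa scores.

    Null kappas are built by drawing pair-length sign vectors with
    replacement from the empirical distribution of propensity sign calls
    -- pooled across all eligible reactions and pairs by default, or
    per-reaction with ``pooling="per_reaction"`` -- and scoring them
    against each reaction's flux sign vector.  The add-one estimate
    p = (1 + #{null kappa >= observed}) / (1 + n_resamples) avoids
    exact zeros.
    """
    if rps_signs.data.empty:
        raise ValueError("empty propensity sign matrix")
    if pooling not in ("pooled", "per_reaction"):
        raise ValueError("pooling must be 'pooled' or 'per_reaction'")
    rng = np.random.default_rng(seed)
    n_pairs = rps_signs.data.shape[1]
    pool = rps_signs.data.to_numpy().ravel()
    draws = rng.choice(pool, size=(n_resamples, n_pairs))

    pvalues = {}
    for rid in observed.index:
        ffd_row = ffd_signs.data.loc[rid].to_numpy()
        if pooling == "per_reaction":
            row_pool = rps_signs.data.loc[rid].to_numpy()
            local = rng.choice(row_pool, size=(n_resamples, n_pairs))
        else:
            local = draws
        null = np.fromiter(
            (cohens_kappa(local[k], ffd_row) for k in range(n_resamples)),
            float,
            count=n_resamples,
        )
        pvalues[rid] = (1 + int((null >= observed.loc[rid]).sum())) / (1 + n_resamples)
    return pd.Series(pvalues, dtype=float).loc[observed.index]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _classify_one(
    k_rps_ffd: Optional[float],
    k_rps_ras: Optional[float],
    k_ras_ffd: Optional[float],
    threshold: float,
) -> str:
    def ok(x):
        return x is not None and np.isfinite(x)

    if ok(k_rps_ffd) and k_rps_ffd > threshold:
        if ok(k_rps_ras) and k_rps_ras > threshold:
            return "concerted"
        return "metabolic_only"   # also covers a missing RPS-vs-RAS score
    if ok(k_ras_ffd) and k_ras_ffd > threshold:
        return "transcriptional_only"
    magnitudes = [abs(x) for x in (k_rps_ffd, k_rps_ras, k_ras_ffd) if ok(x)]
    if magnitudes and max(magnitudes) > threshold:
        return "other"
    return "inconclusive"


def classify_reactions(
    kappas: pd.DataFrame,
    threshold: float = 0.2,
    no_signal: Optional[pd.Series] = None,
) -> pd.Series:
    """Quadrant classification of each reaction's regulation.

    ``kappas`` has columns ``kappa_rps_vs_ffd``, ``kappa_rps_vs_ras``,
    ``kappa_ras_vs_ffd`` (NaN = not computable).  A flux-vs-propensity
    score above the threshold means metabolic regulation -- concerted if
    the propensity-vs-activity score also clears it, metabolic-only
    otherwise (including a missing activity score).  Failing that, a high
    activity-vs-flux score indicates transcriptional control only.  Any
    remaining reaction whose strongest score still exceeds the threshold
    in magnitude is 'other'; the rest -- and reactions whose sign vectors
    carry no variation at all (``no_signal``) -- are inconclusive.
    """
    labels = {}
    for rid, row in kappas.iterrows():
        if no_signal is not None and bool(no_signal.get(rid, False)):
            labels[rid] = "inconclusive"
            continue
        labels[rid] = _classify_one(
            row.get("kappa_rps_vs_ffd"),
            row.get("kappa_rps_vs_ras"),
            row.get("kappa_ras_vs_ffd"),
            threshold,
        )
    return pd.Series(labels, dtype=object).loc[kappas.index]


@dataclass
class ConcordanceResult:
    """Per-reaction concordance table (the pipeline's final output)."""

    table: pd.DataFrame
    threshold: float = 0.2

    def to_tsv(self, path) -> None:
        self.table.rename_axis("reaction").to_csv(path, sep="\t")


def concordance_table(
    ras_signs: SignMatrix,
    rps_signs: SignMatrix,
    ffd_signs: SignMatrix,
    n_resamples: int = 1000,
    seed: int = 0,
    threshold: float = 0.2,
    pooling: str = "pooled",
    batch_kappas: Optional[pd.DataFrame] = None,
) -> ConcordanceResult:
    """Assemble kappas, empirical/adjusted p-values and class labels.

    Rows cover the propensity-eligible reactions.  The activity-vs-flux
    kappa is reported for context but never drives significance (the two
    datasets are not independent: the flux samples were constrained with
    the activity scores).  ``batch_kappas`` (reactions x batches) adds a
    per-reaction standard deviation of the flux-vs-propensity kappa
    across sampling batches.
    """
    eligible = rps_signs.data.index

    def _varies(matrix: SignMatrix) -> pd.Series:
        return (matrix.data != 0).any(axis=1)

    def _masked(k: pd.Series, a: SignMatrix, b: SignMatrix) -> pd.Series:
        # a kappa is only meaningful when both raters registered some
        # variation for the reaction; an all-zero sign vector carries no
        # agreement information (it would otherwise score a degenerate 1
        # against any other all-zero vector)
        applicable = _varies(a).reindex(k.index, fill_value=False) & _varies(
            b
        ).reindex(k.index, fill_value=False)
        return k.where(applicable)

    k_rps_ffd = _masked(kappa_series(rps_signs, ffd_signs), rps_signs, ffd_signs)
    k_rps_ras = _masked(kappa_series(rps_signs, ras_signs), rps_signs, ras_signs)
    k_ras_ffd = _masked(kappa_series(ras_signs, ffd_signs), ras_signs, ffd_signs)

    table = pd.DataFrame(index=eligible)
    table["kappa_rps_vs_ffd"] = k_rps_ffd
    table["kappa_rps_vs_ras"] = k_rps_ras
    table["kappa_ras_vs_ffd"] = k_ras_ffd
    if batch_kappas is not None:
        table["kappa_batch_sd"] = batch_kappas.std(axis=1, ddof=1)

    observed = table["kappa_rps_vs_ffd"].dropna()
    pvals = pd.Series(np.nan, index=eligible)
    if len(observed):
        pvals.loc[observed.index] = empirical_null_pvalues(
            rps_signs, ffd_signs, observed,
            n_resamples=n_resamples, seed=seed, pooling=pooling,
        )
    table["p_empirical"] = pvals
    adjusted = pd.Series(np.nan, index=eligible)
    if len(observed):
        adjusted.loc[observed.index] = bh_adjust(pvals.loc[observed.index].to_numpy())
    table["p_adjusted"] = adjusted

    def _has_signal(matrix: SignMatrix, rid) -> bool:
        return rid in matrix.data.index and bool(matrix.data.loc[rid].any())

    no_signal = pd.Series(
        [
            not any(_has_signal(m, rid) for m in (ras_signs, rps_signs, ffd_signs))
            for rid in eligible
        ],
        index=eligible,
    )
    table["label"] = classify_reactions(table, threshold, no_signal=no_signal)
    return ConcordanceResult(table=table, threshold=threshold)
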