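"""Near-uniform sampling of the constrained flux polytope.

The feasible region {v : S v = 0, lo <= A v <= hi, lb <= v <= ub} is an
intersection of a linear subspace with a box and a few half-spaces.  The
sampler parametrizes the subspace (stoichiometry plus any implicit
equality rows) by an orthonormal null-space basis and runs an
artificial-centering hit-and-run Markov chain in those coordinates:
each step picks a direction through a randomly chosen previous sample
relative to the running center, intersects the chord with every
inequality, and jumps to a uniform point on the chord.  States are
recorded every ``thinning`` accepted steps after a warm-up, and batches
run independent chains from per-batch sub-seeds so that the whole flux
sample set is reproducible from one master seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from ._lp import EQUALITY_TOL, InfeasibleModelError, build_system, interior_point
from .model import MetabolicModel, net_flux as _net_flux

logger = logging.getLogger(__name__)

__all__ = ["FluxSampleSet", "ValidityReport", "sample_fluxes", "verify_samples", "growth_yield"]


@dataclass
class FluxSampleSet:
    """Reaction x sample flux matrix for one group, with the sampling
    metadata needed to reproduce it."""

    group: str
    fluxes: pd.DataFrame                       # reactions x samples
    n_batches: int
    thinning: int
    seed: int
    tolerance: float = 1e-6
    batch_index: np.ndarray = field(default_factory=lambda: np.array([], int))
    split_map: Optional[dict[str, tuple[str, Optional[str]]]] = None

    @property
    def n_samples(self) -> int:
        return self.fluxes.shape[1]

    def batch(self, i: int) -> pd.DataFrame:
        """Columns belonging to sampling batch ``i``."""
        return self.fluxes.loc[:, self.batch_index == i]

    def net_flux(self, reaction_id: str) -> np.ndarray:
        """Per-sample forward-minus-reverse flux of an original reaction."""
        return _net_flux(self, reaction_id)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.fluxes.rename_axis("reaction").to_csv(path, sep="\t")
        meta = {
            "group": self.group,
            "n_batches": self.n_batches,
            "thinning": self.thinning,
            "seed": self.seed,
            "tolerance": self.tolerance,
            "batch_index": self.batch_index.tolist(),
            "split_map": {k: list(v) for k, v in (self.split_map or {}).items()},
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FluxSampleSet":
        path = Path(path)
        fluxes = pd.read_csv(path, sep="\t", index_col=0)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        split = {
            k: (v[0], v[1]) for k, v in (meta.get("split_map") or {}).items()
        } or None
        return cls(
            group=meta["group"],
            fluxes=fluxes,
            n_batches=meta["n_batches"],
            thinning=meta["thinning"],
            seed=meta["seed"],
            tolerance=meta.get("tolerance", 1e-6),
            batch_index=np.asarray(meta["batch_index"], int),
            split_map=split,
        )


class _Geometry:
    """Null-space parametrization of the polytope: v = v0 + N y with
    G y <= h collecting the box bounds and two-sided extra rows.

    Also computes a spanning set of warm-up vertices (the argmin/argmax
    flux-variability solutions of every free reaction), which seed the
    artificial-centering direction archive: flux polytopes are extremely
    anisotropic (a growth-yield bracket is orders of magnitude narrower
    than an uptake range), and chords between far-apart vertices are what
    lets the chain traverse the elongated directions."""

    def __init__(self, model: MetabolicModel):
        system = build_system(model)
        self.system = system
        v0, t = interior_point(system)
        self.v0 = v0
        self.slack = t

        eq_rows = [system.S]
        for i in range(system.A.shape[0]):
            if system.row_upper[i] - system.row_lower[i] <= EQUALITY_TOL:
                eq_rows.append(system.A[i][None, :])
        fixed = system.ub - system.lb <= EQUALITY_TOL
        if fixed.any():
            pins = np.zeros((int(fixed.sum()), system.n))
            pins[np.arange(int(fixed.sum())), np.where(fixed)[0]] = 1.0
            eq_rows.append(pins)
        E = np.vstack(eq_rows)
        self.N = null_space(E)

        G_rows, h = [], []
        for j in range(system.n):
            if fixed[j]:
                continue
            G_rows.append(self.N[j])
            h.append(system.ub[j] - v0[j])
            G_rows.append(-self.N[j])
            h.append(v0[j] - system.lb[j])
        for i in range(system.A.shape[0]):
            lo, hi = system.row_lower[i], system.row_upper[i]
            if hi - lo <= EQUALITY_TOL:
                continue
            row = system.A[i] @ self.N
            base = system.A[i] @ v0
            if np.isfinite(hi):
                G_rows.append(row)
                h.append(hi - base)
            if np.isfinite(lo):
                G_rows.append(-row)
                h.append(base - lo)
        self.G = np.asarray(G_rows) if G_rows else np.zeros((0, self.N.shape[1]))
        self.h = np.asarray(h, float)
        self.warmup_points = self._fva_vertices(fixed)

    def _fva_vertices(self, fixed: np.ndarray) -> np.ndarray:
        """Vertex solutions of min/max v_j per free reaction, mapped to
        null-space coordinates (columns of the returned array)."""
        from scipy.optimize import linprog

        system = self.system
        A_ub, b_ub, A_eq, b_eq, bounds = system.linprog_parts()
        points = []
        c = np.zeros(system.n)
        for j in np.where(~fixed)[0]:
            for sign in (1.0, -1.0):
                c[j] = sign
                res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                              bounds=bounds, method="highs")
                c[j] = 0.0
                if res.success:
                    points.append(res.x)
        if not points:
            return np.zeros((self.N.shape[1], 0))
        V = np.asarray(points).T                      # (n, k)
        return self.N.T @ (V - self.v0[:, None])      # exact: V - v0 in range(N)

    @property
    def dim(self) -> int:
        return self.N.shape[1]

    def to_flux(self, Y: np.ndarray) -> np.ndarray:
        """(dim, k) chain states -> (n, k) flux vectors."""
        return self.v0[:, None] + self.N @ Y


def _run_chain(
    geom: _Geometry,
    rng: np.random.Generator,
    n_record: int,
    thinning: int,
    warmup: int,
) -> np.ndarray:
    dim = geom.dim
    G, h = geom.G, geom.h
    W = geom.warmup_points                       # (dim, k) spanning vertices
    n_w = W.shape[1]
    if n_w:
        center = W.mean(axis=1)
        y = center.copy()
    else:
        center = np.zeros(dim)
        y = np.zeros(dim)                        # v0 itself
    # nudge the start strictly inside if the vertex mean sits on a face
    gy = G @ y if len(h) else np.zeros(0)
    recorded = np.empty((dim, n_record))
    archive: list[np.ndarray] = []
    n_seen = max(n_w, 1)

    total_steps = warmup + n_record * thinning
    n_rec = 0
    for step in range(total_steps):
        # artificial centering: direction through a random stored point
        # (warm-up vertex or recorded sample) and the running center
        k = rng.integers(n_w + len(archive)) if (n_w + len(archive)) else -1
        if k < 0:
            d = rng.standard_normal(dim)
        elif k < n_w:
            d = W[:, k] - center
        else:
            d = archive[k - n_w] - center
        norm = np.linalg.norm(d)
        if norm < 1e-14:
            d = rng.standard_normal(dim)
            norm = np.linalg.norm(d)
        d = d / norm
        u = G @ d
        alpha_max, alpha_min = np.inf, -np.inf
        pos = u > 1e-12
        neg = u < -1e-12
        if pos.any():
            alpha_max = np.min((h[pos] - gy[pos]) / u[pos])
        if neg.any():
            alpha_min = np.max((h[neg] - gy[neg]) / u[neg])
        if not np.isfinite(alpha_max) or not np.isfinite(alpha_min):
            raise InfeasibleModelError(
                "unbounded chord encountered; the polytope is not bounded"
            )
        alpha_min = min(alpha_min, 0.0)          # current point is feasible
        alpha_max = max(alpha_max, 0.0)
        alpha = rng.uniform(alpha_min, alpha_max)
        if alpha != 0.0:
            y = y + alpha * d
            gy = gy + alpha * u
        n_seen += 1
        center = center + (y - center) / n_seen
        if (step + 1) % 1000 == 0 and len(h):
            gy = G @ y                           # curb incremental drift
        if step >= warmup and (step - warmup + 1) % thinning == 0:
            recorded[:, n_rec] = y
            archive.append(y.copy())
            n_rec += 1
    return recorded


def sample_fluxes(
    model: MetabolicModel,
    n_total: int = 5000,
    n_batches: int = 10,
    thinning: int = 10,
    seed: int = 0,
    group: str = "",
    warmup: Optional[int] = None,
    tolerance: float = 1e-6,
) -> FluxSampleSet:
    """Sample ``n_total`` steady-state flux vectors near-uniformly.

    Samples are drawn in ``n_batches`` independent chains whose seeds
    derive from the master ``seed`` via a counter, each discarding
    ``thinning * 100`` warm-up steps by default and recording every
    ``thinning``-th state afterwards.  Deterministic given (model,
    parameters, seed).  A zero-volume polytope (single point) yields
    that vertex repeated, with a warning.
    """
    if n_total % n_batches:
        raise ValueError("n_total must be divisible by n_batches")
    geom = _Geometry(model)
    if warmup is None:
        warmup = thinning * 100

    per_batch = n_total // n_batches
    rids = geom.system.reaction_ids
    if geom.dim == 0:
        warnings.warn("polytope has zero dimension; returning the single vertex")
        V = np.tile(geom.v0[:, None], (1, n_total))
    elif geom.slack <= EQUALITY_TOL and len(geom.h) and np.all(geom.h < 1e-9):
        warnings.warn("polytope has empty interior; returning the vertex found")
        V = np.tile(geom.v0[:, None], (1, n_total))
    else:
        chunks = []
        for b in range(n_batches):
            rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
            Y = _run_chain(geom, rng, per_batch, thinning, warmup)
            chunks.append(geom.to_flux(Y))
        V = np.hstack(chunks)

    batch_index = np.repeat(np.arange(n_batches), per_batch)
    fluxes = pd.DataFrame(
        V, index=rids, columns=[f"s{i}" for i in range(n_total)]
    )
    logger.info(
        "sampled %d flux vectors (%d batches, thinning %d) for group %s",
        n_total, n_batches, thinning, group or model.id,
    )
    return FluxSampleSet(
        group=group or model.id,
        fluxes=fluxes,
        n_batches=n_batches,
        thinning=thinning,
        seed=seed,
        tolerance=tolerance,
        batch_index=batch_index,
        split_map=model.split_map,
    )


@dataclass
class ValidityReport:
    max_steady_state_residual: float
    max_bound_violation: float
    max_row_violation: float
    fraction_outside: float
    worst_sample: Optional[str]
    tolerance: float
    n_samples: int

    @property
    def passed(self) -> bool:
        if self.n_samples == 0:
            return True
        return (
            self.max_steady_state_residual <= self.tolerance
            and self.max_bound_violation <= self.tolerance
            and self.max_row_violation <= self.tolerance
        )


def verify_samples(
    model: MetabolicModel, samples: FluxSampleSet, tol: float = 1e-6
) -> ValidityReport:
    """Check every sample against S v = 0, the box bounds and the extra
    linear rows; reports the worst violations and the offending sample."""
    if samples.n_samples == 0:
        warnings.warn("empty sample set; validity check passes vacuously")
        return ValidityReport(0.0, 0.0, 0.0, 0.0, None, tol, 0)
    system = build_system(model)
    V = samples.fluxes.loc[system.reaction_ids].to_numpy(float)
    residual = np.abs(system.S @ V)
    bound_viol = np.maximum(system.lb[:, None] - V, V - system.ub[:, None])
    bound_viol = np.maximum(bound_viol, 0.0)
    if system.A.shape[0]:
        rows = system.A @ V
        row_viol = np.maximum(
            np.maximum(system.row_lower[:, None] - rows, rows - system.row_upper[:, None]),
            0.0,
        )
    else:
        row_viol = np.zeros((0, V.shape[1]))
    per_sample = np.concatenate([residual, bound_viol, row_viol]).max(axis=0)
    worst = int(per_sample.argmax())
    return ValidityReport(
        max_steady_state_residual=float(residual.max(initial=0.0)),
        max_bound_violation=float(bound_viol.max(initial=0.0)),
        max_row_violation=float(row_viol.max(initial=0.0)),
        fraction_outside=float((per_sample > tol).mean()),
        worst_sample=samples.fluxes.columns[worst],
        tolerance=tol,
        n_samples=V.shape[1],
    )


def growth_yield(samples: FluxSampleSet, yield_constraint, tol: float = 1e-9):
    """Per-sample growth yield on glucose and its median.

    The yield of a sample is protein output over glucose intake in gram
    units: ``protein_fraction * v_biomass / (uptake * mw_glc * 0.001)``
    with uptake the magnitude of the (net) glucose exchange flux.
    Samples with uptake below ``tol`` are excluded; their count is
    reported.  Raises if no sample takes up glucose.
    """
    v_bio = samples.net_flux(yield_constraint.biomass_id)
    uptake = -samples.net_flux(yield_constraint.glucose_exchange_id)
    keep = uptake > tol
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all samples have zero glucose uptake; yield undefined")
    yields = (
        yield_constraint.protein_fraction * v_bio[keep]
        / (uptake[keep] * yield_constraint.mw_glc * 0.001)
    )
    return yields, float(np.median(yields)), n_excluded
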