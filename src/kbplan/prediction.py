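"""Atlas-based per-voxel dose prediction.

The knowledge-based prediction pipeline has three stages:

1. **Atlas regression forests** — one random-forest regressor per atlas
   case, trained on that case's (voxel features → reference dose) pairs.
   Keeping forests per-case (rather than pooling) preserves the atlas
   structure and lets anatomically similar cases dominate the prediction.
2. **Similarity selection** — a compact geometry descriptor (PTV size,
   head-normalised PTV centroid, PTV–OAR distances) ranks atlas cases by
   closeness to the query; the top-k forests are evaluated.
3. **CRF refinement** — the per-voxel forest average is spatially smoothed
   by minimising a Gaussian (quadratic) conditional-random-field energy

   ``E(d) = sum_v w_v (d_v - u_v)^2 + lambda * sum_{(v,v')} a_{vv'} (d_v - d_{v'})^2``

   where ``u`` is the unary mean, ``w_v = 1/(spread_v^2 + eps)`` encodes
   forest agreement and ``a_{vv'} = exp(-(I_v - I_{v'})^2 / 2 sigma^2)``
   discourages smoothing across intensity edges.  With quadratic potentials
   the minimiser solves a sparse symmetric positive-definite linear system;
   conjugate gradients keep the energy non-increasing per iteration.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg
from sklearn.ensemble import RandomForestRegressor

from .evaluation import dose_metric  # noqa: F401  (re-export convenience)
from .features import FeatureMatrix, FeatureSpec, extract_features
from .grids import (
    AtlasLibrary,
    DoseGrid,
    GridMismatchError,
    ImageVolume,
    MissingStructureError,
    StructureSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ForestHyperparams",
    "ForestModel",
    "SimilarityRanking",
    "UnaryPrediction",
    "CRFParams",
    "CRFResult",
    "ConvergenceError",
    "train_atlas_forests",
    "geometry_descriptor",
    "select_atlases",
    "predict_unary",
    "crf_refine",
]


class ConvergenceError(RuntimeError):
    """Iterative solver failed to reach tolerance; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class ForestHyperparams:
    n_trees: int = 50
    max_depth: int = 12
    seed: int = 0

    def case_seed(self, case_id: str) -> int:
        """Per-case RNG seed, stable under atlas reordering."""
        return (self.seed ^ zlib.crc32(case_id.encode())) % (2**31)


@dataclass
class ForestModel:
    """A trained per-atlas-case regression forest."""

    case_id: str
    regressor: RandomForestRegressor
    columns: tuple[str, ...]
    hyper: ForestHyperparams

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        if features.columns != self.columns:
            raise ValueError(
                f"feature columns differ from training columns for {self.case_id!r}"
            )
        return self.regressor.predict(features.values)


def train_atlas_forests(
    library: AtlasLibrary,
    spec: FeatureSpec | None = None,
    hyper: ForestHyperparams | None = None,
) -> dict[str, ForestModel]:
    """Train one regression forest per atlas case (features → dose, cGy)."""
    if len(library) == 0:
        raise ValueError("atlas library is empty")
    if spec is None:
        spec = FeatureSpec()
    if hyper is None:
        hyper = ForestHyperparams()
    forests: dict[str, ForestModel] = {}
    for case in library:
        fm = extract_features(case.image, case.structures, spec)
        target = case.dose.dose[fm.mask]
        if target.shape[0] != fm.n_voxels:
            raise GridMismatchError(
                f"{case.case_id}: {target.shape[0]} dose voxels vs "
                f"{fm.n_voxels} feature rows"
            )
        reg = RandomForestRegressor(
            n_estimators=hyper.n_trees,
            max_depth=hyper.max_depth,
            random_state=hyper.case_seed(case.case_id),
            n_jobs=1,
        )
        reg.fit(fm.values, target)
        forests[case.case_id] = ForestModel(
            case_id=case.case_id, regressor=reg,
            columns=fm.columns, hyper=hyper,
        )
        logger.info("trained forest for %s on %d voxels", case.case_id, fm.n_voxels)
    return forests


# ---------------------------------------------------------------------------
# Atlas similarity
# ---------------------------------------------------------------------------

_DESCRIPTOR_OARS = ("Brainstem", "Chiasm")
_ABSENT_DESCRIPTOR = 10.0  # head radii; far beyond any real normalised distance


def geometry_descriptor(image: ImageVolume, structures: StructureSet) -> np.ndarray:
    """Compact anatomical-geometry descriptor of a case.

    Components (all in units of the head's equivalent-sphere radius, so
    cases on different grids are comparable): PTV equivalent radius, PTV
    centroid offset from the head centroid (3 components), and distances
    from the PTV centroid to brainstem and chiasm centroids.
    """
    external = structures.require("External")
    ptv = structures.require("PTVp_5400")
    if not ptv.any():
        raise MissingStructureError("query has an empty PTV")
    vol = image.voxel_volume_mm3
    head_radius = (3.0 * external.sum() * vol / (4.0 * np.pi)) ** (1 / 3)
    ptv_radius = (3.0 * ptv.sum() * vol / (4.0 * np.pi)) ** (1 / 3)
    head_c = image.voxel_coordinates(external).mean(axis=0)
    ptv_c = image.voxel_coordinates(ptv).mean(axis=0)
    parts = [ptv_radius / head_radius]
    parts += list((ptv_c - head_c) / head_radius)
    for name in _DESCRIPTOR_OARS:
        mask = structures.get(name)
        if mask is None or not mask.any():
            parts.append(_ABSENT_DESCRIPTOR)
        else:
            oar_c = image.voxel_coordinates(mask).mean(axis=0)
            parts.append(float(np.linalg.norm(ptv_c - oar_c)) / head_radius)
    return np.asarray(parts, dtype=float)


@dataclass(frozen=True)
class SimilarityRanking:
    """Atlas cases ordered by similarity to a query (scores nonincreasing)."""

    entries: tuple[tuple[str, float], ...]   # (case_id, similarity score)
    k_selected: int

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("similarity scores must be nonincreasing")
        if not (1 <= self.k_selected <= len(self.entries)):
            raise ValueError("k_selected out of range")

    @property
    def selected(self) -> tuple[tuple[str, float], ...]:
        return self.entries[: self.k_selected]

    @property
    def selected_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.selected)


def rank_by_descriptor(
    query_descriptor: np.ndarray,
    atlas_descriptors: Mapping[str, np.ndarray] | Sequence[tuple[str, np.ndarray]],
    k: int,
) -> SimilarityRanking:
    """Rank stored atlas descriptors against a query descriptor.

    Similarity is the negative Euclidean descriptor distance; ties are
    broken by the stored ordering.
    """
    items = list(atlas_descriptors.items()) if isinstance(atlas_descriptors, Mapping) \
        else list(atlas_descriptors)
    if not (1 <= k <= len(items)):
        raise ValueError(f"k must be in [1, {len(items)}], got {k}")
    q = np.asarray(query_descriptor, dtype=float)
    scored = [(cid, -float(np.linalg.norm(np.asarray(d, float) - q)))
              for cid, d in items]
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][1], i))
    entries = tuple(scored[i] for i in order)
    return SimilarityRanking(entries=entries, k_selected=k)


def select_atlases(
    query_image: ImageVolume,
    query_structures: StructureSet,
    library: AtlasLibrary,
    k: int = 3,
) -> SimilarityRanking:
    """Rank atlas cases by anatomical similarity to the query; select top-k."""
    q = geometry_descriptor(query_image, query_structures)
    descriptors = [(case.case_id, geometry_descriptor(case.image, case.structures))
                   for case in library]
    return rank_by_descriptor(q, descriptors, k)


# ---------------------------------------------------------------------------
# Unary prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnaryPrediction:
    """Similarity-weighted forest prediction: per-voxel mean and spread (cGy)."""

    mean: np.ndarray      # (n_voxels,)
    spread: np.ndarray    # (n_voxels,) weighted standard deviation
    mask: np.ndarray      # External mask defining the voxel rows
    n_clipped: int        # negative raw predictions clipped to 0

    def __post_init__(self) -> None:
        if self.mean.min() < 0 or self.spread.min() < 0:
            raise ValueError("mean and spread must be nonnegative")


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max()
    e = np.exp(z)
    return e / e.sum()


def predict_unary(
    query_features: FeatureMatrix,
    ranking: SimilarityRanking,
    forests: Mapping[str, ForestModel],
) -> UnaryPrediction:
    """Aggregate the selected atlas forests on the query's features.

    Weights are a unit-temperature softmax of the similarity scores; the
    per-voxel spread is the weighted standard deviation across forests.
    """
    selected = ranking.selected
    missing = [cid for cid, _ in selected if cid not in forests]
    if missing:
        raise KeyError(f"no trained forest for selected atlas case(s): {missing}")
    weights = _softmax(np.array([s for _, s in selected], dtype=float))
    preds = np.stack([forests[cid].predict(query_features)
                      for cid, _ in selected], axis=0)
    n_clipped = int((preds < 0).sum())
    if n_clipped:
        logger.info("clipped %d negative forest predictions to 0", n_clipped)
        preds = np.clip(preds, 0.0, None)
    mean = np.einsum("k,kv->v", weights, preds)
    var = np.einsum("k,kv->v", weights, (preds - mean[None, :]) ** 2)
    spread = np.sqrt(np.clip(var, 0.0, None))
    return UnaryPrediction(mean=mean, spread=spread,
                           mask=query_features.mask, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# Quadratic CRF refinement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRFParams:
    """Parameters of the Gaussian-potential CRF.

    ``pairwise_weight`` carries units 1/cGy^2 so the pairwise term is
    commensurate with the confidence weights 1/(spread^2 + eps); the default
    balances the two when forests disagree by a few hundred cGy.
    """

    pairwise_weight: float = 2e-6
    neighbourhood: int = 6           # 6 or 26
    appearance_scale: float = 50.0   # intensity-difference scale (HU-like)
    max_iterations: int = 1000
    tolerance: float = 1e-8
    epsilon_cGy2: float = 1.0

    def __post_init__(self) -> None:
        if self.pairwise_weight < 0:
            raise ValueError("pairwise_weight must be >= 0")
        if self.neighbourhood not in (6, 26):
            raise ValueError("neighbourhood must be 6 or 26")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.epsilon_cGy2 <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class CRFResult:
    """CRF refinement output: refined dose plus solver diagnostics."""

    dose: DoseGrid
    energies: np.ndarray     # energy after each CG iteration (incl. start)
    n_iterations: int
    final_residual: float


_OFFSETS_6 = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def _grid_edges(mask: np.ndarray, intensity: np.ndarray, neighbourhood: int,
                appearance_scale: float):
    """Neighbour-pair index arrays and appearance weights over masked voxels."""
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(int(mask.sum()))
    offsets = _OFFSETS_6 if neighbourhood == 6 else _OFFSETS_26
    rows_a, rows_b, weights = [], [], []
    for off in offsets:
        src = tuple(slice(None, -o) if o > 0 else slice(None) for o in off)
        dst = tuple(slice(o, None) if o > 0 else slice(None) for o in off)
        a = idx[src]
        b = idx[dst]
        valid = (a >= 0) & (b >= 0)
        a = a[valid]
        b = b[valid]
        di = intensity[src][valid] - intensity[dst][valid]
        w = np.exp(-(di**2) / (2.0 * appearance_scale**2))
        rows_a.append(a)
        rows_b.append(b)
        weights.append(w)
    return (np.concatenate(rows_a), np.concatenate(rows_b),
            np.concatenate(weights))


def crf_energy(d: np.ndarray, u: np.ndarray, w_unary: np.ndarray,
               lam: float, edges) -> float:
    a, b, w = edges
    unary = float(np.sum(w_unary * (d - u) ** 2))
    pairwise = float(np.sum(w * (d[a] - d[b]) ** 2))
    return unary + lam * pairwise


def crf_refine(unary: UnaryPrediction, image: ImageVolume,
               params: CRFParams | None = None) -> CRFResult:
    """Minimise the quadratic CRF energy around the unary prediction.

    Solves ``(W + lambda * L_a) d = W u`` (W = diagonal confidence weights,
    L_a = appearance-weighted graph Laplacian) by conjugate gradients
    started at ``u``; the CRF energy is recorded after every iteration and
    is non-increasing because CG minimises the quadratic over a growing
    Krylov subspace.  Raises :class:`ConvergenceError` if the tolerance is
    not met within ``max_iterations``.
    """
    if params is None:
        params = CRFParams()
    if unary.mask.shape != image.shape:
        raise GridMismatchError(
            f"unary grid {unary.mask.shape} != image grid {image.shape}"
        )
    u = unary.mean
    w_unary = 1.0 / (unary.spread**2 + params.epsilon_cGy2)
    lam = params.pairwise_weight

    def embed(values: np.ndarray) -> DoseGrid:
        grid = np.zeros(image.shape)
        grid[unary.mask] = np.clip(values, 0.0, None)
        return DoseGrid(dose=grid)

    edges = _grid_edges(unary.mask, image.values, params.neighbourhood,
                        params.appearance_scale)
    e0 = crf_energy(u, u, w_unary, lam, edges)
    if lam == 0.0:
        return CRFResult(dose=embed(u), energies=np.array([e0]),
                         n_iterations=0, final_residual=0.0)

    n = u.size
    a, b, w = edges
    rows = np.concatenate([a, b])
    cols = np.concatenate([b, a])
    vals = np.concatenate([-w, -w])
    deg = np.zeros(n)
    np.add.at(deg, a, w)
    np.add.at(deg, b, w)
    laplacian = sparse.coo_matrix(
        (np.concatenate([vals, deg]),
         (np.concatenate([rows, np.arange(n)]),
          np.concatenate([cols, np.arange(n)]))),
        shape=(n, n),
    ).tocsr()
    system = sparse.diags(w_unary) + lam * laplacian
    rhs = w_unary * u

    energies = [e0]

    def record(xk: np.ndarray) -> None:
        energies.append(crf_energy(xk, u, w_unary, lam, edges))

    # Jacobi preconditioner: the confidence weights span orders of magnitude
    # (agreeing forests get w ~ 1/eps), which otherwise stalls CG
    precond = sparse.diags(1.0 / system.diagonal())
    solution, info = cg(system, rhs, x0=u, rtol=params.tolerance,
                        maxiter=params.max_iterations, callback=record,
                        M=precond)
    residual = float(np.linalg.norm(system @ solution - rhs)
                     / max(np.linalg.norm(rhs), 1e-30))
    if info > 0:
        raise ConvergenceError(
            f"CRF solve did not converge in {params.max_iterations} iterations "
            f"(relative residual {residual:.3e})",
            residual,
        )
    if info < 0:
        raise ValueError("CRF linear system is ill-posed")
    return CRFResult(dose=embed(solution), energies=np.asarray(energies),
                     n_iterations=len(energies) - 1, final_residual=residual)
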