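"""Dose mimicking: convert a predicted dose into a deliverable plan.

A single-arc delivery is approximated by equispaced coplanar static beams,
each carved into a rectangular lattice of beamlets (parallel rays, no
divergence).  The influence matrix A maps nonnegative beamlet weights x to
voxel dose via deterministic ray tracing with exponential depth attenuation.
The plan is the minimiser of

    f(x) = sum_v c_v (A x - d_pred)_v^2 + gamma * ||L x||^2,   x >= 0,

where c_v up-weights target and serial-OAR voxels and L penalises
differences between neighbouring beamlets of the same beam ("technical
delivery constraints" reduce to weight nonnegativity plus fluence
smoothness).  A projected-gradient scheme with a Lipschitz step and
backtracking gives a monotone objective trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .evaluation import CriteriaReport, CriteriaTable, evaluate_criteria
from .grids import (
    DoseGrid,
    GridMismatchError,
    ImageVolume,
    SERIAL_OARS,
    StructureSet,
    check_same_grid,
)
from .phantom import beam_angles, ray_depths

__all__ = [
    "BeamGeometry",
    "InfluenceMatrix",
    "PlanObjective",
    "PlanResult",
    "DegenerateGeometryError",
    "build_influence_matrix",
    "optimize_plan",
    "deliverability_check",
    "default_voxel_weights",
]


class DegenerateGeometryError(ValueError):
    """Beam geometry cannot irradiate the target (e.g. isocentre outside body)."""


@dataclass(frozen=True)
class BeamGeometry:
    """Equispaced coplanar beam arrangement with a beamlet lattice per beam."""

    n_beams: int = 9
    beamlet_size_mm: float = 5.0
    mu_per_mm: float = 0.005
    lattice_margin_mm: float = 6.0   # lattice extent beyond the PTV projection

    def __post_init__(self) -> None:
        if self.n_beams < 3:
            raise ValueError("n_beams must be >= 3")
        if self.beamlet_size_mm <= 0:
            raise ValueError("beamlet size must be positive")
        if self.mu_per_mm < 0:
            raise ValueError("attenuation coefficient must be >= 0")


@dataclass(frozen=True)
class InfluenceMatrix:
    """Sparse beamlet-to-voxel dose map (cGy per unit weight).

    Rows index External voxels in C-order raster order; columns index
    beamlets described by the ``beamlets`` table (beam, row, col).
    """

    matrix: sparse.csr_matrix
    beamlets: pd.DataFrame          # columns: beam, row, col
    mask: np.ndarray                # External mask (defines row order)
    smoothness: sparse.csr_matrix   # finite-difference operator on beamlets

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]


def build_influence_matrix(image: ImageVolume, structures: StructureSet,
                           geom: BeamGeometry | None = None) -> InfluenceMatrix:
    """Deterministic parallel-ray influence matrix for a case.

    Each beamlet's column is nonzero only for voxels whose beam's-eye-view
    coordinates fall in that beamlet's lattice cell, with value
    ``exp(-mu * depth)`` (depth = path length through External upstream of
    the voxel).  Voxels outside External receive nothing.
    """
    if geom is None:
        geom = BeamGeometry()
    check_same_grid(image, structures)
    external = structures.require("External")
    ptv = structures.require("PTVp_5400")
    if not ptv.any():
        raise DegenerateGeometryError("PTV is empty")
    ptv_pts = image.voxel_coordinates(ptv)
    iso = ptv_pts.mean(axis=0)
    iso_idx = np.round((iso - np.asarray(image.origin))
                       / np.asarray(image.spacing)).astype(int)
    if (np.any(iso_idx < 0) or np.any(iso_idx >= np.array(image.shape))
            or not external[tuple(iso_idx)]):
        raise DegenerateGeometryError("isocentre lies outside External")

    ext_pts = image.voxel_coordinates(external)
    spacing = np.asarray(image.spacing)
    origin = np.asarray(image.origin)
    step_mm = float(min(image.spacing)) / 2.0
    size = geom.beamlet_size_mm

    rows, cols, vals = [], [], []
    beamlet_records: list[tuple[int, int, int]] = []
    beamlet_index: dict[tuple[int, int, int], int] = {}

    for b, theta in enumerate(beam_angles(geom.n_beams)):
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        e1 = np.array([-math.sin(theta), math.cos(theta), 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        ptv_uv = np.column_stack([ptv_pts @ e1, ptv_pts @ e2])
        lo = ptv_uv.min(axis=0) - geom.lattice_margin_mm
        hi = ptv_uv.max(axis=0) + geom.lattice_margin_mm
        n_cells = np.maximum(np.ceil((hi - lo) / size).astype(int), 1)

        ext_uv = np.column_stack([ext_pts @ e1, ext_pts @ e2])
        cell = np.floor((ext_uv - lo) / size).astype(int)
        in_lattice = np.all((cell >= 0) & (cell < n_cells), axis=1)
        vox = np.flatnonzero(in_lattice)
        if vox.size == 0:
            continue
        depth = ray_depths(external, spacing, origin, ext_pts[vox], u, step_mm)
        value = np.exp(-geom.mu_per_mm * depth)
        for voxel, (ci, cj), val in zip(vox, cell[vox], value):
            key = (b, int(ci), int(cj))
            col = beamlet_index.get(key)
            if col is None:
                col = len(beamlet_records)
                beamlet_index[key] = col
                beamlet_records.append(key)
            rows.append(voxel)
            cols.append(col)
            vals.append(val)

    if not beamlet_records:
        raise DegenerateGeometryError("no beamlet intersects the body")
    n_vox = len(ext_pts)
    n_blt = len(beamlet_records)
    matrix = sparse.coo_matrix((vals, (rows, cols)), shape=(n_vox, n_blt)).tocsr()
    beamlets = pd.DataFrame(beamlet_records, columns=["beam", "row", "col"])

    # fluence-smoothness operator: first differences between lattice
    # neighbours within each beam
    srows, scols, svals = [], [], []
    n_edges = 0
    for (b, ci, cj), col in beamlet_index.items():
        for nb in ((b, ci + 1, cj), (b, ci, cj + 1)):
            other = beamlet_index.get(nb)
            if other is not None:
                srows += [n_edges, n_edges]
                scols += [col, other]
                svals += [1.0, -1.0]
                n_edges += 1
    smoothness = sparse.coo_matrix(
        (svals, (srows, scols)), shape=(max(n_edges, 1), n_blt)
    ).tocsr()
    return InfluenceMatrix(matrix=matrix, beamlets=beamlets,
                           mask=external, smoothness=smoothness)


@dataclass(frozen=True)
class PlanObjective:
    """Objective weights for dose mimicking."""

    ptv_weight: float = 30.0
    serial_oar_weight: float = 5.0
    base_weight: float = 1.0
    smoothness_gamma: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.ptv_weight, self.serial_oar_weight, self.base_weight) <= 0:
            raise ValueError("voxel weights must be positive")
        if self.smoothness_gamma < 0:
            raise ValueError("gamma must be >= 0")


def default_voxel_weights(structures: StructureSet, mask: np.ndarray,
                          objective: PlanObjective) -> np.ndarray:
    """Per-voxel objective weights over the masked (External) voxels."""
    w = np.full(int(mask.sum()), objective.base_weight)
    for name in SERIAL_OARS:
        m = structures.get(name)
        if m is not None:
            w[m[mask]] = objective.serial_oar_weight
    ptv = structures.get("PTVp_5400")
    if ptv is not None:
        w[ptv[mask]] = objective.ptv_weight
    return w


@dataclass(frozen=True)
class PlanResult:
    """Optimised plan: beamlet weights, delivered dose and diagnostics."""

    weights: np.ndarray
    dose: DoseGrid
    objective_value: float
    mismatch_value: float
    smoothness_value: float
    trace: np.ndarray
    converged: bool
    n_iterations: int


def optimize_plan(
    predicted: DoseGrid,
    influence: InfluenceMatrix,
    objective: PlanObjective | None = None,
    structures: StructureSet | None = None,
    *,
    tol: float = 1e-6,
    max_iterations: int = 2000,
) -> PlanResult:
    """Fit nonnegative beamlet weights so the delivered dose mimics ``predicted``.

    Projected gradient descent with a power-iteration Lipschitz step and
    halving backtracking; terminates when the relative objective change
    drops below ``tol``.  The trace is monotonically non-increasing.
    """
    if objective is None:
        objective = PlanObjective()
    if predicted.shape != influence.mask.shape:
        raise GridMismatchError(
            f"predicted dose grid {predicted.shape} != influence grid "
            f"{influence.mask.shape}"
        )
    A = influence.matrix
    if A.nnz == 0:
        raise DegenerateGeometryError("influence matrix is empty")
    d = predicted.dose[influence.mask]
    if structures is not None:
        c = default_voxel_weights(structures, influence.mask, objective)
    else:
        c = np.full(A.shape[0], objective.base_weight)
    gamma = objective.smoothness_gamma
    L = influence.smoothness

    AtC = A.T.multiply(c).tocsr()          # A^T diag(c)
    LtL = (L.T @ L).tocsr()

    def f(x: np.ndarray) -> tuple[float, float, float]:
        r = A @ x - d
        mismatch = float(np.sum(c * r * r))
        smooth = float(x @ (LtL @ x))
        return mismatch + gamma * smooth, mismatch, smooth

    def grad(x: np.ndarray) -> np.ndarray:
        return 2.0 * (AtC @ (A @ x - d)) + 2.0 * gamma * (LtL @ x)

    # Lipschitz constant of the gradient via deterministic power iteration
    # (5% headroom: power iteration approaches the top eigenvalue from below)
    n = A.shape[1]
    v = np.ones(n) / math.sqrt(n)
    lip = 1.0
    for _ in range(60):
        w = 2.0 * (AtC @ (A @ v)) + 2.0 * gamma * (LtL @ v)
        norm = float(np.linalg.norm(w))
        if norm == 0.0:
            break
        lip = norm
        v = w / norm
    step0 = 1.0 / (1.05 * max(lip, 1e-12))

    # monotone FISTA: accelerated proximal gradient with a monotonicity
    # safeguard, so the recorded objective trace never increases
    x = np.zeros(n)
    fx, mis, smo = f(x)
    x_prev = x
    y = x
    t_k = 1.0
    trace = [fx]
    converged = False
    stall = 0
    for _ in range(max_iterations):
        z = np.clip(y - step0 * grad(y), 0.0, None)
        fz, mis_z, smo_z = f(z)
        if fz <= fx:
            x_new, fn, mis_n, smo_n = z, fz, mis_z, smo_z
        else:
            # fall back to a plain backtracked step from the best iterate
            g = grad(x)
            step = step0
            x_new, fn, mis_n, smo_n = x, fx, mis, smo
            for _ in range(30):
                cand = np.clip(x - step * g, 0.0, None)
                fc, mis_c, smo_c = f(cand)
                if fc <= fx:
                    x_new, fn, mis_n, smo_n = cand, fc, mis_c, smo_c
                    break
                step *= 0.5
        change = fx - fn
        t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_k * t_k))
        y = x_new + (t_k / t_next) * (z - x_new) \
            + ((t_k - 1.0) / t_next) * (x_new - x_prev)
        x_prev, x, fx, mis, smo = x, x_new, fn, mis_n, smo_n
        t_k = t_next
        trace.append(fx)
        stall = stall + 1 if change <= tol * max(abs(fx), 1e-12) else 0
        if stall >= 3:
            converged = True
            break

    dose_grid = np.zeros(predicted.shape)
    dose_grid[influence.mask] = A @ x
    delivered = DoseGrid(dose=np.clip(dose_grid, 0.0, None),
                         prescription_cGy=predicted.prescription_cGy,
                         n_fractions=predicted.n_fractions)
    return PlanResult(
        weights=x,
        dose=delivered,
        objective_value=fx,
        mismatch_value=mis,
        smoothness_value=smo,
        trace=np.asarray(trace),
        converged=converged,
        n_iterations=len(trace) - 1,
    )


def deliverability_check(result: PlanResult, structures: StructureSet,
                         criteria: CriteriaTable | None = None) -> CriteriaReport:
    """Evaluate the *delivered* dose (not the prediction) against the criteria."""
    if not result.converged:
        raise ValueError("plan did not converge; refusing to certify deliverability")
    return evaluate_criteria(result.dose, structures, criteria)
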