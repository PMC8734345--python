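"""Plan evaluation: DVHs, dose metrics, criterion tables, paired comparison.

Metric definitions
------------------
* ``Dmax`` — the point maximum dose: the single hottest voxel of a structure.
* ``Dmean`` — arithmetic mean dose over the structure's voxels.
* ``Dx`` — the dose received by at least x% of the structure's volume: the
  largest dose d such that >= x% of voxels receive >= d, computed by exact
  order statistics (no DVH-bin interpolation).

Criteria are strict inequalities: a brainstem Dmax of exactly 5400 cGy does
*not* meet ``Dmax < 5400 cGy``.

An empty / absent structure yields ``None`` from :func:`dose_metric` (the
"absent structure" signal) and a not-assessed row in criterion reports; the
paired comparison drops such cases from that row and records the reduced n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import DoseGrid, StructureSet, STRUCTURE_VOCABULARY

__all__ = [
    "DVHCurve",
    "MetricSpec",
    "Criterion",
    "CriteriaTable",
    "CriteriaReport",
    "ComparisonReport",
    "compute_dvh",
    "dose_metric",
    "evaluate_criteria",
    "paired_t_test",
    "compare_plans",
    "summarize_differences",
    "default_comparison_metrics",
    "format_gy",
]


def _dose_array(dose) -> np.ndarray:
    if isinstance(dose, DoseGrid):
        return dose.dose
    return np.asarray(dose, dtype=float)


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram for one structure."""

    structure: str
    bin_edges_cGy: np.ndarray      # ascending, starting at 0
    volume_fraction: np.ndarray    # fraction of voxels with dose >= edge
    voxel_count: int


@dataclass(frozen=True)
class MetricSpec:
    """A dose metric: kind in {'Dx', 'Dmax', 'Dmean'}; x = percent volume for Dx."""

    kind: str
    x: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("Dx", "Dmax", "Dmean"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind == "Dx":
            if self.x is None or not (0 < self.x <= 100):
                raise ValueError(f"Dx requires 0 < x <= 100, got {self.x}")
        elif self.x is not None:
            raise ValueError(f"{self.kind} takes no x")

    @property
    def label(self) -> str:
        if self.kind == "Dx":
            x = self.x
            return f"D{int(x)}" if float(x).is_integer() else f"D{x:g}"
        return self.kind


def compute_dvh(dose, mask: np.ndarray, bin_width_cGy: float = 10.0,
                structure: str = "") -> DVHCurve | None:
    """Cumulative DVH over ``mask`` voxels; ``None`` if the mask is empty.

    The curve starts at 1.0 (every voxel receives >= 0) and is appended a
    final edge above the maximum dose where it reaches exactly 0.
    """
    if bin_width_cGy <= 0:
        raise ValueError("bin_width_cGy must be positive")
    mask = np.asarray(mask, dtype=bool)
    values = _dose_array(dose)[mask]
    if values.size == 0:
        return None
    n_bins = int(math.floor(values.max() / bin_width_cGy)) + 2
    edges = bin_width_cGy * np.arange(n_bins + 1)
    frac = (values[None, :] >= edges[:, None]).mean(axis=1) if values.size * len(edges) < 5_000_000 else np.array(
        [(values >= e).mean() for e in edges]
    )
    return DVHCurve(structure=structure, bin_edges_cGy=edges,
                    volume_fraction=frac, voxel_count=int(values.size))


def dose_metric(dose, mask: np.ndarray, spec: MetricSpec) -> float | None:
    """Evaluate one dose metric over a structure mask (cGy).

    Returns ``None`` when the mask is empty — the absent-structure signal.
    """
    mask = np.asarray(mask, dtype=bool)
    values = _dose_array(dose)[mask]
    if values.size == 0:
        return None
    if spec.kind == "Dmax":
        return float(values.max())
    if spec.kind == "Dmean":
        return float(values.mean())
    # Dx: largest d such that >= x% of voxels receive >= d.  With voxels
    # sorted hottest first, the k hottest voxels (k = ceil(x/100 * n)) all
    # receive at least the k-th value, which is the answer.
    n = values.size
    k = int(math.ceil(spec.x / 100.0 * n))
    return float(np.sort(values)[n - k])


@dataclass(frozen=True)
class Criterion:
    structure: str
    metric: MetricSpec
    comparator: str  # '<' or '>'
    threshold_cGy: float

    def __post_init__(self) -> None:
        if self.comparator not in ("<", ">"):
            raise ValueError(f"comparator must be '<' or '>', got {self.comparator!r}")
        if self.threshold_cGy <= 0:
            raise ValueError("threshold must be positive")

    def is_met(self, value_cGy: float) -> bool:
        if self.comparator == "<":
            return value_cGy < self.threshold_cGy
        return value_cGy > self.threshold_cGy

    @property
    def label(self) -> str:
        return f"{self.metric.label} {self.comparator} {self.threshold_cGy:g} cGy"


@dataclass(frozen=True)
class CriteriaTable:
    """Plan-acceptance criteria: per-structure dose limits and coverage goals."""

    rows: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        for row in self.rows:
            if row.structure not in STRUCTURE_VOCABULARY:
                raise ValueError(f"unknown structure {row.structure!r} in criteria")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @classmethod
    def for_prescription(cls, prescription_cGy: float = 5400.0) -> "CriteriaTable":
        """Default criterion table for a homogeneous prescription.

        Target coverage thresholds are 95% of prescription; hotspot limits
        (PTV and whole-body Dmax) are 105%.  Serial-OAR point maxima are
        limited to the prescription itself; eyes and lenses carry absolute
        tolerances (4500 / 750 cGy).
        """
        rx = float(prescription_cGy)
        cover = 0.95 * rx
        hot = 1.05 * rx
        rows = [
            Criterion("GTVp", MetricSpec("Dx", 99), ">", cover),
            Criterion("CTVp_5400", MetricSpec("Dx", 98), ">", cover),
            Criterion("PTVp_5400", MetricSpec("Dx", 95), ">", cover),
            Criterion("PTVp_5400", MetricSpec("Dmax"), "<", hot),
            Criterion("Brainstem", MetricSpec("Dmax"), "<", rx),
            Criterion("Chiasm", MetricSpec("Dmax"), "<", rx),
            Criterion("External", MetricSpec("Dmax"), "<", hot),
            Criterion("Eye_L", MetricSpec("Dmax"), "<", 4500.0),
            Criterion("Eye_R", MetricSpec("Dmax"), "<", 4500.0),
            Criterion("Lens_L", MetricSpec("Dmax"), "<", 750.0),
            Criterion("Lens_R", MetricSpec("Dmax"), "<", 750.0),
            Criterion("OpticNrv_L", MetricSpec("Dmax"), "<", rx),
            Criterion("OpticNrv_R", MetricSpec("Dmax"), "<", rx),
            Criterion("SpinalCord", MetricSpec("Dmax"), "<", rx),
        ]
        return cls(rows=tuple(rows))

    @classmethod
    def default(cls) -> "CriteriaTable":
        return cls.for_prescription(5400.0)


@dataclass(frozen=True)
class CriteriaReport:
    """Row-per-criterion evaluation of one dose distribution."""

    table: pd.DataFrame  # structure, metric, comparator, threshold_cGy, value_cGy, assessed, met

    @property
    def n_assessed(self) -> int:
        return int(self.table["assessed"].sum())

    @property
    def n_met(self) -> int:
        return int(self.table.loc[self.table["assessed"], "met"].sum())

    @property
    def all_met(self) -> bool:
        assessed = self.table[self.table["assessed"]]
        return bool(assessed["met"].all()) if len(assessed) else False

    def failed_rows(self) -> pd.DataFrame:
        t = self.table
        return t[t["assessed"] & ~t["met"].astype(bool)]


def evaluate_criteria(dose, structures: StructureSet,
                      table: CriteriaTable | None = None) -> CriteriaReport:
    """Evaluate a dose distribution against a criterion table.

    Structures absent from the case are reported as not assessed (``met`` is
    NA), mirroring reduced-n reporting in clinical cohorts.
    """
    if table is None:
        table = CriteriaTable.default()
    records = []
    for row in table:
        mask = structures.get(row.structure)
        value = dose_metric(dose, mask, row.metric) if mask is not None else None
        assessed = value is not None
        records.append(
            {
                "structure": row.structure,
                "metric": row.metric.label,
                "comparator": row.comparator,
                "threshold_cGy": row.threshold_cGy,
                "value_cGy": value if assessed else np.nan,
                "assessed": assessed,
                "met": row.is_met(value) if assessed else pd.NA,
            }
        )
    return CriteriaReport(table=pd.DataFrame.from_records(records))


def paired_t_test(differences: Sequence[float]) -> tuple[float, float]:
    """One-sample two-sided t-test on paired differences.

    Returns ``(t, p)`` with p from the t distribution with n-1 degrees of
    freedom.  Degenerate cases are defined, not errors: identically-zero
    differences give ``(0, 1)``; identical nonzero differences (zero variance,
    nonzero mean) give ``(±inf, 0)``.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1:
        d = d.reshape(-1)
    n = d.size
    if n < 2:
        raise ValueError(f"paired t-test needs n >= 2, got n={n}")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p


def default_comparison_metrics() -> tuple[tuple[str, MetricSpec], ...]:
    """Structure/metric pairs of the standard OAR comparison report."""
    dmax = MetricSpec("Dmax")
    dmean = MetricSpec("Dmean")
    return (
        ("Brainstem", dmax),
        ("Chiasm", dmax),
        ("External", dmax),
        ("Eye_L", dmax),
        ("Eye_R", dmax),
        ("Lens_L", dmax),
        ("Lens_R", dmax),
        ("OpticNrv_L", dmax),
        ("OpticNrv_R", dmax),
        ("SpinalCord", dmax),
        ("Brain", dmean),
        ("Brain_Temporal_L", dmean),
        ("Brain_Temporal_R", dmean),
        ("Cochlea_L", dmean),
        ("Cochlea_R", dmean),
        ("Hippocampus_L", dmean),
        ("Hippocampus_R", dmean),
        ("Hypothalamus", dmean),
        ("Parotid_L", dmean),
        ("Parotid_R", dmean),
        ("Pituitary", dmean),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Paired automated-vs-manual dosimetric comparison (one row per metric)."""

    table: pd.DataFrame

    def significant_rows(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]


class UnpairedCasesError(ValueError):
    """Automated and manual cohorts do not contain the same case ids."""


def summarize_differences(ml_values: Sequence[float],
                          manual_values: Sequence[float]) -> dict:
    """Paired difference summary for one structure/metric row.

    Differences are automated-plan value minus manual-plan value, so a
    negative mean difference means lower dose (better OAR sparing) in the
    automated plan.
    """
    ml = np.asarray(ml_values, dtype=float)
    man = np.asarray(manual_values, dtype=float)
    if ml.shape != man.shape:
        raise ValueError("paired value arrays must have equal length")
    diffs = ml - man
    n = diffs.size
    if n >= 2:
        t, p = paired_t_test(diffs)
    else:
        t, p = math.nan, math.nan
    return {
        "n": int(n),
        "ml_mean_cGy": float(ml.mean()) if n else math.nan,
        "manual_mean_cGy": float(man.mean()) if n else math.nan,
        "mean_diff_cGy": float(diffs.mean()) if n else math.nan,
        "p_value": p,
        "t_statistic": t,
        "median_diff_cGy": float(np.median(diffs)) if n else math.nan,
        "max_diff_cGy": float(diffs.max()) if n else math.nan,
        "min_diff_cGy": float(diffs.min()) if n else math.nan,
        "significant": bool(p < 0.05) if not math.isnan(p) else pd.NA,
    }


def compare_plans(
    ml_doses: Mapping[str, DoseGrid],
    manual_doses: Mapping[str, DoseGrid],
    structures: Mapping[str, StructureSet],
    metric_table: Sequence[tuple[str, MetricSpec]] | None = None,
) -> ComparisonReport:
    """Paired per-structure comparison of two plan cohorts.

    For each (structure, metric) row the per-case difference is the
    automated value minus the manual value; cases where the structure is
    absent in either plan are excluded from that row with the reduced n
    recorded.  Two-sided paired t-tests, significance flagged at p < 0.05.
    """
    ml_ids = set(ml_doses)
    man_ids = set(manual_doses)
    if ml_ids != man_ids:
        offenders = sorted(ml_ids ^ man_ids)
        raise UnpairedCasesError(f"unpaired case ids: {offenders}")
    case_ids = sorted(ml_ids)
    missing_ss = [c for c in case_ids if c not in structures]
    if missing_ss:
        raise UnpairedCasesError(f"cases without structures: {missing_ss}")

    if metric_table is None:
        metric_table = default_comparison_metrics()

    records = []
    for structure, spec in metric_table:
        ml_vals, man_vals = [], []
        for cid in case_ids:
            mask = structures[cid].get(structure)
            if mask is None:
                continue
            v_ml = dose_metric(ml_doses[cid], mask, spec)
            v_man = dose_metric(manual_doses[cid], mask, spec)
            if v_ml is None or v_man is None:
                continue
            ml_vals.append(v_ml)
            man_vals.append(v_man)
        rec = {"structure": structure, "metric": spec.label}
        rec.update(summarize_differences(ml_vals, man_vals))
        records.append(rec)
    return ComparisonReport(table=pd.DataFrame.from_records(records))


def format_gy(value_cGy: float, decimals: int = 1) -> str:
    """Human-readable Gy with sign, e.g. ``-226 cGy -> '-2.3 Gy'``."""
    gy = value_cGy / 100.0
    return f"{gy:+.{decimals}f} Gy"
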