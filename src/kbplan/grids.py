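"""Core spatial containers shared across the planning pipeline.

All volumes live on a common axis-aligned voxel grid described by a voxel
spacing (mm per axis) and the physical coordinate of the first voxel centre
(``origin``, mm).  Coordinate convention: +x toward patient left, +y anterior,
+z superior; voxel index (i, j, k) maps to ``origin + index * spacing``.
Doses are stored in cGy throughout; Gy appears only in report formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

#: Controlled structure vocabulary (targets, organs at risk, body contour).
STRUCTURE_VOCABULARY: tuple[str, ...] = (
    "GTVp",
    "CTVp_5400",
    "PTVp_5400",
    "External",
    "Brain",
    "Brainstem",
    "Chiasm",
    "Eye_L",
    "Eye_R",
    "Lens_L",
    "Lens_R",
    "OpticNrv_L",
    "OpticNrv_R",
    "SpinalCord",
    "Brain_Temporal_L",
    "Brain_Temporal_R",
    "Cochlea_L",
    "Cochlea_R",
    "Hippocampus_L",
    "Hippocampus_R",
    "Hypothalamus",
    "Parotid_L",
    "Parotid_R",
    "Pituitary",
)

TARGET_STRUCTURES: tuple[str, ...] = ("GTVp", "CTVp_5400", "PTVp_5400")

#: Serial organs at risk: a single hot voxel matters, hence Dmax criteria and
#: extra weight in the dose-mimicking objective.
SERIAL_OARS: tuple[str, ...] = (
    "Brainstem",
    "Chiasm",
    "OpticNrv_L",
    "OpticNrv_R",
    "SpinalCord",
)


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


class MissingStructureError(KeyError):
    """A required structure is not present in a :class:`StructureSet`."""


def _as_tuple3(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar image (CT-like intensities, HU-like units)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"image must be 3-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _as_tuple3(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _as_tuple3(self.origin, "origin"))
        if min(self.spacing) <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    def voxel_coordinates(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(N, 3) physical coordinates of voxel centres (optionally masked)."""
        if mask is None:
            idx = np.stack(
                np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij"),
                axis=-1,
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(np.asarray(mask, dtype=bool))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class StructureSet:
    """Named binary masks sharing one voxel grid.

    ``absent`` records structures that anatomically do not exist for this
    case (e.g. a hippocampus consumed by the tumour): they carry no mask and
    downstream metrics report them as not assessed rather than zero.
    """

    masks: Mapping[str, np.ndarray]
    absent: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        shape = None
        for name, mask in self.masks.items():
            m = np.asarray(mask, dtype=bool)
            if m.ndim != 3:
                raise ValueError(f"mask {name!r} must be 3-D")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise GridMismatchError(
                    f"mask {name!r} shape {m.shape} != {shape}"
                )
            clean[name] = m
        object.__setattr__(self, "masks", clean)
        object.__setattr__(self, "absent", tuple(self.absent))
        overlap = set(self.absent) & set(clean)
        if overlap:
            raise ValueError(f"structures both present and absent: {sorted(overlap)}")

    @property
    def shape(self) -> tuple[int, int, int] | None:
        for m in self.masks.values():
            return m.shape
        return None

    def names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def get(self, name: str) -> np.ndarray | None:
        return self.masks.get(name)

    def require(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise MissingStructureError(
                f"structure {name!r} missing (present: {sorted(self.masks)}, "
                f"absent: {sorted(self.absent)})"
            ) from None

    def is_absent(self, name: str) -> bool:
        return name in self.absent


@dataclass(frozen=True)
class DoseGrid:
    """Nonnegative 3-D dose in cGy on the image grid."""

    dose: np.ndarray
    prescription_cGy: float = 5400.0
    n_fractions: int = 30

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        if d.ndim != 3:
            raise ValueError("dose must be 3-D")
        if not np.all(np.isfinite(d)):
            raise ValueError("dose contains non-finite values")
        if d.min() < 0:
            raise ValueError(f"dose must be nonnegative, min={d.min():g}")
        object.__setattr__(self, "dose", d)
        if self.prescription_cGy <= 0:
            raise ValueError("prescription must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dose.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class AtlasCase:
    """One training case: image, structures and its reference (clinical) dose."""

    case_id: str
    image: ImageVolume
    structures: StructureSet
    dose: DoseGrid

    def __post_init__(self) -> None:
        shapes = {self.image.shape, self.dose.shape}
        ss = self.structures.shape
        if ss is not None:
            shapes.add(ss)
        if len(shapes) != 1:
            raise GridMismatchError(f"case {self.case_id!r}: mixed grids {shapes}")


@dataclass(frozen=True)
class AtlasLibrary:
    """Ordered collection of atlas cases with unique ids."""

    cases: tuple[AtlasCase, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple(self.cases))
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate case ids: {ids}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.case_id for c in self.cases)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[AtlasCase]:
        return iter(self.cases)

    def get(self, case_id: str) -> AtlasCase:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)


def check_same_grid(*volumes) -> tuple[int, int, int]:
    """Assert all arguments (arrays or grid containers) share one shape."""
    shapes = set()
    for v in volumes:
        if v is None:
            continue
        if hasattr(v, "shape") and v.shape is not None:
            shapes.add(tuple(v.shape))
    if len(shapes) > 1:
        raise GridMismatchError(f"grids differ: {sorted(shapes)}")
    if not shapes:
        raise ValueError("no grids supplied")
    return shapes.pop()  # type: ignore[return-value]
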