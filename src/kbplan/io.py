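"""File I/O: NIfTI volumes, atlas directories, model bundles and reports.

Volumes are written as NIfTI with an axis-aligned affine (diagonal spacing,
origin in the translation column); masks are uint8, images and doses
float32.  An atlas directory holds one subdirectory per case::

    atlas/
      manifest.tsv            case_id, prescription_cGy, n_fractions, path
      case000_seed42/
        image.nii.gz
        dose.nii.gz
        meta.json             absent structures, prescription
        masks/<Structure>.nii.gz

Doses are stored in cGy.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import nibabel as nib
import numpy as np
import pandas as pd

from .features import FeatureSpec
from .grids import AtlasCase, AtlasLibrary, DoseGrid, ImageVolume, StructureSet
from .prediction import ForestHyperparams, ForestModel

__all__ = [
    "save_volume",
    "load_image",
    "load_dose",
    "save_structures",
    "load_structures",
    "write_atlas",
    "read_atlas",
    "save_model_bundle",
    "load_model_bundle",
]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(path, values: np.ndarray, spacing, origin,
                dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=dtype),
                          _affine(spacing, origin))
    nib.save(img, str(path))


def _load_nifti(path):
    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned volumes are supported")
    spacing = tuple(float(s) for s in np.diag(rot))
    if min(spacing) <= 0:
        raise ValueError(f"{path}: non-positive spacing in affine")
    origin = tuple(float(o) for o in aff[:3, 3])
    return np.asarray(img.dataobj), spacing, origin


def load_image(path) -> ImageVolume:
    values, spacing, origin = _load_nifti(path)
    return ImageVolume(values=values, spacing=spacing, origin=origin)


def load_dose(path, prescription_cGy: float = 5400.0,
              n_fractions: int = 30) -> DoseGrid:
    values, _, _ = _load_nifti(path)
    return DoseGrid(dose=values, prescription_cGy=prescription_cGy,
                    n_fractions=n_fractions)


def save_structures(directory, structures: StructureSet, spacing, origin) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in structures.masks.items():
        save_volume(directory / f"{name}.nii.gz", mask.astype(np.uint8),
                    spacing, origin, dtype=np.uint8)


def load_structures(directory, absent=()) -> StructureSet:
    directory = Path(directory)
    masks = {}
    for path in sorted(directory.glob("*.nii.gz")):
        name = path.name[: -len(".nii.gz")]
        values, _, _ = _load_nifti(path)
        masks[name] = values.astype(bool)
    return StructureSet(masks=masks, absent=tuple(absent))


def write_atlas(directory, library: AtlasLibrary) -> Path:
    """Write an atlas library as a directory tree with a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for case in library:
        case_dir = directory / case.case_id
        case_dir.mkdir(exist_ok=True)
        sp, og = case.image.spacing, case.image.origin
        save_volume(case_dir / "image.nii.gz", case.image.values, sp, og)
        save_volume(case_dir / "dose.nii.gz", case.dose.dose, sp, og)
        save_structures(case_dir / "masks", case.structures, sp, og)
        meta = {
            "case_id": case.case_id,
            "absent_structures": list(case.structures.absent),
            "prescription_cGy": case.dose.prescription_cGy,
            "n_fractions": case.dose.n_fractions,
        }
        (case_dir / "meta.json").write_text(json.dumps(meta, indent=2))
        records.append(
            {
                "case_id": case.case_id,
                "prescription_cGy": case.dose.prescription_cGy,
                "n_fractions": case.dose.n_fractions,
                "path": case.case_id,
            }
        )
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
    return directory


def read_atlas(directory) -> AtlasLibrary:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    cases = []
    for rec in manifest.itertuples():
        case_dir = directory / rec.path
        meta = json.loads((case_dir / "meta.json").read_text())
        image = load_image(case_dir / "image.nii.gz")
        dose = load_dose(case_dir / "dose.nii.gz",
                         prescription_cGy=float(rec.prescription_cGy),
                         n_fractions=int(rec.n_fractions))
        structures = load_structures(case_dir / "masks",
                                     absent=meta.get("absent_structures", ()))
        cases.append(AtlasCase(case_id=str(rec.case_id), image=image,
                               structures=structures, dose=dose))
    return AtlasLibrary(cases=tuple(cases))


def save_model_bundle(directory, forests: dict[str, ForestModel],
                      spec: FeatureSpec,
                      descriptors: dict[str, np.ndarray],
                      seed: int) -> Path:
    """Persist a trained model: forests, feature spec, atlas descriptors."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump({cid: fm.regressor for cid, fm in forests.items()},
                directory / "forests.joblib")
    any_model = next(iter(forests.values()))
    manifest = {
        "case_ids": list(forests),
        "columns": list(any_model.columns),
        "seed": seed,
        "hyper": {
            "n_trees": any_model.hyper.n_trees,
            "max_depth": any_model.hyper.max_depth,
            "seed": any_model.hyper.seed,
        },
        "feature_spec": {
            "smoothing_scales_mm": list(spec.smoothing_scales_mm),
            "texture_window_voxels": spec.texture_window_voxels,
            "distance_structures": list(spec.distance_structures),
            "include_coordinates": spec.include_coordinates,
        },
        "descriptors": {cid: list(map(float, d)) for cid, d in descriptors.items()},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_model_bundle(directory):
    """Load a persisted model bundle.

    Returns ``(forests, feature_spec, descriptors, seed)``.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    regressors = joblib.load(directory / "forests.joblib")
    fs = manifest["feature_spec"]
    spec = FeatureSpec(
        smoothing_scales_mm=tuple(fs["smoothing_scales_mm"]),
        texture_window_voxels=fs["texture_window_voxels"],
        distance_structures=tuple(fs["distance_structures"]),
        include_coordinates=fs["include_coordinates"],
    )
    hyper = ForestHyperparams(**manifest["hyper"])
    columns = tuple(manifest["columns"])
    forests = {
        cid: ForestModel(case_id=cid, regressor=regressors[cid],
                         columns=columns, hyper=hyper)
        for cid in manifest["case_ids"]
    }
    descriptors = {cid: np.asarray(d, dtype=float)
                   for cid, d in manifest["descriptors"].items()}
    return forests, spec, descriptors, int(manifest["seed"])
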