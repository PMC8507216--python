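"""File I/O: NIfTI image/mask pairs, cohort CSV, feature CSV, run manifests.

CSV is the interchange format for tables, JSON for models and reports, NIfTI
for volumes. Floats are serialized with 17 significant digits so that
round-tripped artifacts digest identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from ._utils import sha256_file, sha256_text
from .preprocessing import CTVolume, VOIMask
from .synthetic import ClinicalCovariates, SubjectRecord

FLOAT_FMT = "%.17g"

BOOL_COLUMNS = (
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "atrial_fibrillation",
    "smoking",
    "alcohol",
    "hvs",
    "ica_occlusion",
)

REQUIRED_COLUMNS = ("id", "age", "sex", "nihss", "aspects", "collateral_grade", "side") + BOOL_COLUMNS


def write_image_pair(volume: CTVolume, mask: VOIMask, image_path, mask_path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(mask_path))


def read_image_pair(image_path, mask_path) -> tuple[CTVolume, VOIMask]:
    """Load a NIfTI image/mask pair; mask binarized at > 0."""
    for p in (image_path, mask_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    vox = np.asarray(img.dataobj, dtype=float)
    mvox = np.asarray(msk.dataobj)
    if vox.shape != mvox.shape:
        raise ValueError(f"shape mismatch: image {vox.shape} vs mask {mvox.shape}")
    if not np.allclose(img.affine, msk.affine, atol=1e-6):
        raise ValueError("image and mask affines differ")
    if not np.all(np.isfinite(vox)):
        raise ValueError("image contains non-finite voxels")
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return CTVolume(vox, spacing), VOIMask(mvox > 0, spacing)


def cohort_to_dataframe(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.covariates
        row = {
            "id": r.id,
            "tfs_class": r.tfs_class,
            "split": r.split,
            "age": c.age,
            "sex": c.sex,
            "nihss": c.nihss,
            "aspects": c.aspects,
            "collateral_grade": c.collateral_grade,
            "side": c.side,
        }
        for b in BOOL_COLUMNS:
            row[b] = int(getattr(c, b))
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: list[SubjectRecord], path) -> None:
    cohort_to_dataframe(records).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort_csv(path) -> list[SubjectRecord]:
    """Parse a cohort table into typed records.

    The onset label comes from ``tfs_class`` ({early, late}) or from
    ``tfs_hours`` (<= 4.5 -> early). Range violations report the row index.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    if "tfs_class" not in df.columns and "tfs_hours" not in df.columns:
        raise ValueError("cohort CSV needs a tfs_class or tfs_hours column")
    records = []
    for idx, row in df.iterrows():
        if "tfs_class" in df.columns and not pd.isna(row.get("tfs_class", np.nan)):
            tfs = str(row["tfs_class"])
            if tfs not in ("early", "late"):
                raise ValueError(f"row {idx}: tfs_class must be early/late, got {tfs!r}")
        else:
            tfs = "early" if float(row["tfs_hours"]) <= 4.5 else "late"
        try:
            cov = ClinicalCovariates(
                age=float(row["age"]),
                sex=str(row["sex"]),
                nihss=int(row["nihss"]),
                aspects=int(row["aspects"]),
                collateral_grade=int(row["collateral_grade"]),
                side=str(row["side"]),
                **{b: bool(int(row[b])) for b in BOOL_COLUMNS},
            )
        except ValueError as err:
            raise ValueError(f"row {idx} (id={row['id']!r}): {err}") from err
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                tfs_class=tfs,
                covariates=cov,
                split=str(row["split"]) if "split" in df.columns else "unassigned",
            )
        )
    return records


def write_features_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="id", float_format=FLOAT_FMT)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split", double_precision=15))
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(obj), indent=1, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())


class RunManifest:
    """Digest record of a pipeline run: config hash, artifact hashes, seeds."""

    def __init__(self, config_text: str, seed: int):
        self.data = {
            "package_version": __version__,
            "config_sha256": sha256_text(config_text),
            "seed": seed,
            "artifacts": {},
            "timestamps": {},
        }

    def add(self, stage: str, path) -> None:
        self.data["artifacts"][f"{stage}:{Path(path).name}"] = sha256_file(path)
        self.data["timestamps"][stage] = time.time()

    @property
    def digests(self) -> dict:
        return dict(self.data["artifacts"])

    def save(self, path) -> None:
        write_json(self.data, path)
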