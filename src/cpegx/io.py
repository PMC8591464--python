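"""Readers and writers for the pipeline's on-disk interchange formats:
TSV expression matrices (rows = genes), CSV clinical tables, NIfTI volumes
and masks, and JSON model/truth files."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from cpegx.association import ExpressionMatrix

CLINICAL_COLUMNS = ["sample_id", "age", "size_mm", "grade", "axillary_load",
                    "ast", "time", "event"]


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_expression_tsv(path, kind: str = "continuous") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix.from_frame(df, kind=kind)


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    clinical.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"axillary_load": str, "ast": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def save_volume(array: np.ndarray, path, voxel_spacing=(1.35, 1.35, 1.35)) -> None:
    affine = np.diag(list(voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), spacing


def load_mask(path) -> np.ndarray:
    arr, _ = load_volume(path)
    return arr > 0.5
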