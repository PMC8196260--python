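"""File-format plumbing: NIfTI volumes, TSV tables, TAC files, truth records.

All on-disk formats are the field's plain ones -- NIfTI via nibabel, TSV
via pandas, JSON for structured records -- so outputs interoperate with
standard neuroimaging tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .kinetics import Tac

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_table",
    "load_table",
    "save_tac",
    "load_tac",
    "save_cohort",
]


def _affine(voxel_size=(1.5, 1.5, 1.5)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(path, data: np.ndarray, voxel_size=(1.5, 1.5, 1.5)) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size))
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def save_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_tac(path, tac: Tac) -> None:
    save_table(
        path,
        pd.DataFrame(
            {"frame_start": tac.frame_start, "frame_end": tac.frame_end, "activity": tac.activity}
        ),
    )


def load_tac(path) -> Tac:
    df = load_table(path)
    return Tac(df["frame_start"].to_numpy(), df["frame_end"].to_numpy(), df["activity"].to_numpy())


def save_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort to ``out_dir``: NIfTI series and masks, TSV
    cohort table, TSV TAC pairs, and the JSON truth record."""
    out = Path(out_dir)
    (out / "func").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "tacs").mkdir(exist_ok=True)

    for sub, series in zip(cohort.table["subject"], cohort.series):
        save_nifti(out / "func" / f"{sub}_bold.nii.gz", series.astype(np.float32))
    for label, mask in {**cohort.truth.seed_masks, **cohort.truth.network_masks}.items():
        save_nifti(out / "masks" / f"{label}.nii.gz", mask.astype(np.uint8))
    save_table(out / "cohort.tsv", cohort.table)
    for sub, pair in zip(cohort.table["subject"], cohort.tacs):
        if pair is None:
            continue
        save_tac(out / "tacs" / f"{sub}_target.tsv", pair[0])
        save_tac(out / "tacs" / f"{sub}_reference.tsv", pair[1])
    (out / "truth.json").write_text(cohort.truth.to_json())
    (out / "config.json").write_text(
        json.dumps(
            {
                "seed": cohort.seed,
                "n_subjects": cohort.config.n_subjects,
                "shape": list(cohort.config.shape),
                "n_timepoints": cohort.config.n_timepoints,
                "tr": cohort.config.tr,
            },
            indent=1,
        )
    )
    return out
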