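"""ROI time-series extraction from labelled 4D BOLD volumes.

Reads a 4D BOLD image, an integer label atlas of the 24 pain-connectome
regions (12 ROI types x 2 hemispheres), and a gray-matter tissue mask, and
produces the per-subject T x 24 matrix of gray-matter-restricted ROI mean
signals.  Voxel grids must match exactly; registration and resampling are
upstream concerns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .rois import COLUMN_ORDER, HEMISPHERES, ROI_TYPES

#: Gray-matter inclusion threshold for probabilistic masks. Voxels with
#: mask value strictly above this are treated as gray matter; binary masks
#: (0/1) pass through unchanged.
GM_THRESHOLD = 0.5


@dataclass(frozen=True)
class LabelAtlas:
    """Integer label volume plus the (roi_type, hemisphere) -> label map."""

    label_volume: np.ndarray
    label_table: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        labels = list(self.label_table.values())
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate label ids in label table")
        if any(l <= 0 for l in labels):
            raise ValueError("labels must be positive integers")
        vol = np.asarray(self.label_volume)
        if not np.issubdtype(vol.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {vol.dtype}")
        for (roi, hemi) in self.label_table:
            if roi not in ROI_TYPES:
                raise ValueError(f"unknown ROI type in label table: {roi!r}")
            if hemi not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere in label table: {hemi!r}")

    @property
    def roi_types(self) -> tuple[str, ...]:
        return tuple(r for r in ROI_TYPES if any(k[0] == r for k in self.label_table))


@dataclass
class RoiTimeSeriesMatrix:
    """Per-subject T x 24 matrix of ROI mean BOLD signals.

    ``matrix`` columns follow :data:`painconnectome.rois.COLUMN_ORDER`;
    ``voxel_counts`` records the gray-matter voxels averaged per column.
    """

    subject_id: str
    matrix: np.ndarray
    voxel_counts: dict[str, int]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(COLUMN_ORDER):
            raise ValueError(f"matrix must be T x {len(COLUMN_ORDER)}, got {m.shape}")
        if m.shape[0] < 50:
            raise ValueError(f"need at least 50 time points, got {m.shape[0]}")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix contains non-finite values")
        bad = [c for c, n in self.voxel_counts.items() if n < 1]
        if bad:
            raise ValueError(f"columns with zero voxels: {bad}")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(COLUMN_ORDER))

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            path.with_suffix(".json").write_text(
                json.dumps({"subject_id": self.subject_id, "voxel_counts": self.voxel_counts}, indent=1)
            )


def _load_volume(image: str | Path | nib.spatialimages.SpatialImage) -> np.ndarray:
    if isinstance(image, (str, Path)):
        image = nib.load(str(image))
    return np.asanyarray(image.dataobj)


def load_atlas(
    label_image: str | Path | nib.spatialimages.SpatialImage,
    label_table: str | Path | pd.DataFrame,
) -> LabelAtlas:
    """Load and validate a label atlas.

    ``label_table`` needs columns ``roi_type``, ``hemisphere``, ``label``.
    Labels listed in the table but absent from the volume trigger a
    warning; labels in the volume but not in the table are treated as
    background.
    """
    vol = _load_volume(label_image)
    if not np.issubdtype(vol.dtype, np.integer):
        if np.allclose(vol, np.round(vol)):
            vol = vol.astype(np.int32)
        else:
            raise ValueError("label volume contains non-integer values")

    if not isinstance(label_table, pd.DataFrame):
        label_table = pd.read_csv(label_table)
    required = {"roi_type", "hemisphere", "label"}
    if not required.issubset(label_table.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    if label_table["label"].duplicated().any():
        dupes = label_table.loc[label_table["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate label ids in table: {dupes}")

    table = {
        (row.roi_type, row.hemisphere): int(row.label)
        for row in label_table.itertuples()
    }
    atlas = LabelAtlas(label_volume=vol, label_table=table)

    present = set(np.unique(vol)) - {0}
    missing = [(roi, hemi) for (roi, hemi), lab in table.items() if lab not in present]
    if missing:
        warnings.warn(
            f"labels absent from volume for: {sorted(missing)}", stacklevel=2
        )
    return atlas


def extract_roi_timeseries(
    bold: str | Path | nib.spatialimages.SpatialImage,
    atlas: LabelAtlas,
    gm_mask: str | Path | nib.spatialimages.SpatialImage,
    min_voxels: int = 1,
    subject_id: str = "subject",
) -> RoiTimeSeriesMatrix:
    """Extract the T x 24 ROI mean time-series matrix.

    Each column is the unweighted mean over voxels whose atlas label
    matches and whose gray-matter mask value is positive (binary mask) or
    above :data:`GM_THRESHOLD` (probabilistic mask).  An ROI with fewer
    than ``min_voxels`` eligible voxels is an error naming the ROI.
    """
    if min_voxels < 1:
        raise ValueError(f"min_voxels must be >= 1, got {min_voxels}")
    bold_data = _load_volume(bold).astype(float)
    gm = _load_volume(gm_mask).astype(float)
    if bold_data.ndim != 4:
        raise ValueError(f"BOLD image must be 4D, got shape {bold_data.shape}")
    grid = bold_data.shape[:3]
    if atlas.label_volume.shape != grid or gm.shape != grid:
        raise ValueError(
            f"grid mismatch: bold {grid}, atlas {atlas.label_volume.shape}, "
            f"mask {gm.shape}"
        )

    # Binary masks keep all nonzero voxels; probabilistic masks are
    # thresholded at GM_THRESHOLD.
    if np.all(np.isin(gm, (0.0, 1.0))):
        gm_ok = gm > 0
    else:
        gm_ok = gm > GM_THRESHOLD

    n_time = bold_data.shape[3]
    matrix = np.full((n_time, len(COLUMN_ORDER)), np.nan)
    voxel_counts: dict[str, int] = {}
    for col_idx, col in enumerate(COLUMN_ORDER):
        roi, hemi = col.rsplit("_", 1)
        label = atlas.label_table.get((roi, hemi))
        if label is None:
            raise ValueError(f"label table has no entry for {roi} {hemi}")
        sel = (atlas.label_volume == label) & gm_ok
        n_vox = int(sel.sum())
        if n_vox < min_voxels:
            raise ValueError(
                f"ROI {roi} ({hemi}) has {n_vox} eligible gray-matter voxels "
                f"(min_voxels={min_voxels})"
            )
        matrix[:, col_idx] = bold_data[sel, :].mean(axis=0)
        voxel_counts[col] = n_vox

    return RoiTimeSeriesMatrix(subject_id=subject_id, matrix=matrix, voxel_counts=voxel_counts)
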