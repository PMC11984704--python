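"""Reading and writing FA volumes, label atlases and subject tables.

Fractional anisotropy (FA) is a scalar in [0, 1] derived from the diffusion
tensor; a white-matter tract is a labelled region of an integer atlas on the
same voxel grid.  This module is deliberately dumb about space: volumes must
already share a grid (registration happens upstream), affine metadata is
carried opaquely, and a shape mismatch is an error rather than an implicit
resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tolerance when validating that finite FA voxels lie in [0, 1].
FA_TOLERANCE = 1e-6

NW = "NW"
OB = "OB"
#: BMI threshold (kg/m^2) separating normal weight from overweight/obese.
GROUP_THRESHOLD = 25.0


class VolumeFormatError(ValueError):
    """Raised when a volume on disk violates the FA contract."""


class AtlasError(ValueError):
    """Raised for label/atlas inconsistencies."""


@dataclass(frozen=True)
class SubjectRecord:
    """One study participant: identifier, BMI (kg/m^2) and weight group."""

    subject_id: str
    bmi: float
    group: str

    def __post_init__(self) -> None:
        if self.group not in (NW, OB):
            raise ValueError(f"group must be {NW!r} or {OB!r}, got {self.group!r}")
        if self.bmi < 19:
            raise ValueError(f"BMI {self.bmi} below study inclusion minimum of 19")
        expected = NW if self.bmi < GROUP_THRESHOLD else OB
        if self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with BMI {self.bmi} "
                f"(threshold {GROUP_THRESHOLD})"
            )

    @classmethod
    def from_bmi(cls, subject_id: str, bmi: float) -> "SubjectRecord":
        return cls(subject_id, bmi, NW if bmi < GROUP_THRESHOLD else OB)


@dataclass
class FAVolume:
    """A 3D fractional-anisotropy map for one subject.

    Finite voxels lie in [0, 1]; non-finite voxels are tolerated on read and
    excluded from tract value lists downstream.
    """

    voxels: np.ndarray
    subject_id: str = ""
    affine: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.voxels.shape)


@dataclass
class AtlasVolume:
    """An integer label volume plus its label -> tract-name table.

    Label 0 is background and never appears in the table.
    """

    labels: np.ndarray
    label_table: dict[int, str]
    affine: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.labels.shape)

    @property
    def tract_names(self) -> list[str]:
        """Tract names in ascending label order (the canonical column order)."""
        return [self.label_table[k] for k in sorted(self.label_table)]

    def validate(self) -> None:
        if not self.label_table:
            raise AtlasError("label table is empty")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise AtlasError(f"labels present in volume but absent from table: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI via nibabel)
# ---------------------------------------------------------------------------

def read_fa_volume(path: str | Path, subject_id: str | None = None) -> FAVolume:
    """Read a 3D FA volume from a NIfTI file and validate its value range."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D FA data, got {data.ndim}D")
    finite = data[np.isfinite(data)]
    n_nonfinite = data.size - finite.size
    if n_nonfinite:
        logger.warning("%s: %d non-finite voxels (treated as background)", path, n_nonfinite)
    if finite.size and (finite.min() < -FA_TOLERANCE or finite.max() > 1 + FA_TOLERANCE):
        raise VolumeFormatError(
            f"{path}: FA values outside [0, 1] (range {finite.min():g}..{finite.max():g})"
        )
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return FAVolume(voxels=data, subject_id=sid, affine=np.asarray(img.affine))


def write_fa_volume(volume: FAVolume, path: str | Path) -> None:
    """Write an FA volume as float32 NIfTI (round-trips within float32 precision)."""
    affine = volume.affine if volume.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def read_label_table(path: str | Path) -> dict[int, str]:
    """Parse a two-column TSV ``label<TAB>tract_name`` (header row optional)."""
    table: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise AtlasError(f"{path}:{lineno}: expected 'label<TAB>name', got {line!r}")
            if lineno == 1 and not parts[0].strip().lstrip("-").isdigit():
                continue  # header
            try:
                label = int(parts[0])
            except ValueError as exc:
                raise AtlasError(f"{path}:{lineno}: non-integer label {parts[0]!r}") from exc
            if label <= 0:
                raise AtlasError(f"{path}:{lineno}: labels must be positive, got {label}")
            if label in table:
                raise AtlasError(f"{path}:{lineno}: duplicate label {label}")
            table[label] = parts[1].strip()
    if not table:
        raise AtlasError(f"{path}: label table has no entries")
    return table


def icbm_dti81_label_table() -> dict[int, str]:
    """The shipped 50-tract white-matter parcellation table (ICBM-DTI-81)."""
    with resources.as_file(
        resources.files("tractbmi").joinpath("data/icbm_dti81_labels.tsv")
    ) as p:
        return read_label_table(p)


def read_atlas(path: str | Path, label_table_path: str | Path) -> AtlasVolume:
    """Read an integer label volume and its label table; verify coverage."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise AtlasError(f"cannot read atlas {path}: {exc}") from exc
    data = np.squeeze(np.asarray(img.get_fdata()))
    if data.ndim != 3:
        raise AtlasError(f"{path}: expected 3D label data, got {data.ndim}D")
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise AtlasError(f"{path}: atlas voxels are not integer-valued")
    labels = rounded.astype(np.int64)
    if labels.min() < 0:
        raise AtlasError(f"{path}: negative labels present")
    atlas = AtlasVolume(labels=labels, label_table=read_label_table(label_table_path),
                        affine=np.asarray(img.affine))
    atlas.validate()
    return atlas


def write_atlas(atlas: AtlasVolume, path: str | Path, label_table_path: str | Path) -> None:
    affine = atlas.affine if atlas.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), affine), str(path))
    with open(label_table_path, "w") as fh:
        fh.write("label\ttract_name\n")
        for label in sorted(atlas.label_table):
            fh.write(f"{label}\t{atlas.label_table[label]}\n")


# ---------------------------------------------------------------------------
# Tract extraction
# ---------------------------------------------------------------------------

def extract_tract_voxels(fa: FAVolume, atlas: AtlasVolume, label: int) -> np.ndarray:
    """FA values at voxels carrying ``label``, non-finite values excluded.

    Order follows the C-order raster scan of the grid, so it is deterministic
    for fixed input.
    """
    if fa.shape != atlas.shape:
        raise AtlasError(f"shape mismatch: FA {fa.shape} vs atlas {atlas.shape}")
    if label != 0 and label not in atlas.label_table:
        raise AtlasError(f"unknown label {label}")
    values = fa.voxels[atlas.labels == label]
    return values[np.isfinite(values)]


# ---------------------------------------------------------------------------
# Subject tables
# ---------------------------------------------------------------------------

def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read a CSV with columns subject_id, bmi, group."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "bmi", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: subject table missing columns {sorted(missing)}")
    return [
        SubjectRecord(row.subject_id, float(row.bmi), str(row.group))
        for row in df.itertuples(index=False)
    ]


def write_subject_table(subjects: list[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "bmi": [s.bmi for s in subjects],
            "group": [s.group for s in subjects],
        }
    ).to_csv(path, index=False)
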