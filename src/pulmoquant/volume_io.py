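"""Reading, writing and validating paired-phase CT volumes and lung masks.

Conventions fixed here and relied on by every downstream stage:

* HU volumes and masks are NIfTI images (``.nii`` / ``.nii.gz``).
* Mask labels: 0 = background, 1 = right lung, 2 = left lung.  The whole
  lung is the union of labels 1 and 2; the lobes are disjoint by
  construction.
* Voxels are isotropic (default 0.05 mm, the usual reconstructed voxel
  size of retrospectively gated murine micro-CT).  The file header is the
  authority for voxel size; an explicit override is logged as a warning.
  Anisotropic headers are rejected unless ``allow_anisotropic=True``, in
  which case the voxel cell volume is the product of the three spacings.
* All computation happens in voxel-index space.  The NIfTI affine is
  carried through untouched and never used for any derived quantity (all
  quantities computed downstream are orientation-invariant).
* HU values outside the plausible [-1000, 3000] window are retained, not
  clamped — clamping would silently bias mean lung attenuation — but they
  are counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    EmptyRegionError,
    LabelSchemeError,
    MaskAlignmentError,
    PairingError,
    VolumeFormatError,
    VolumeValidationError,
)

logger = logging.getLogger(__name__)

#: Breathing phases of a retrospectively gated acquisition.
PHASE_INSPIRATION = "P01"
PHASE_EXPIRATION = "P02"
PHASES = (PHASE_INSPIRATION, PHASE_EXPIRATION)

#: Mask label scheme (fixed; foreign masks must be remapped before loading).
LABEL_BACKGROUND = 0
LABEL_RIGHT = 1
LABEL_LEFT = 2
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_RIGHT, LABEL_LEFT})

REGIONS = ("whole", "left", "right")

#: Default isotropic reconstructed voxel size, mm.
DEFAULT_VOXEL_SIZE_MM = 0.05

#: HU values outside this window are physically implausible; they are kept
#: but counted and logged on load.
HU_PLAUSIBLE = (-1000.0, 3000.0)

_ISOTROPY_RTOL = 1e-3


@dataclass
class CTVolume:
    """A 3D scalar field of Hounsfield units for one gated breathing phase."""

    data: np.ndarray
    voxel_size_mm: float
    phase: str
    subject_id: str
    day: int
    affine: np.ndarray | None = None
    #: voxel cell volume in mm^3; defaults to voxel_size_mm**3 (isotropic)
    voxel_volume_mm3: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"CT volume must be 3D, got {self.data.ndim}D shape {self.data.shape}"
            )
        if self.phase not in PHASES:
            raise VolumeValidationError(
                f"phase must be one of {PHASES}, got {self.phase!r}"
            )
        if not self.voxel_size_mm > 0:
            raise VolumeValidationError(
                f"voxel_size_mm must be positive, got {self.voxel_size_mm}"
            )
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise VolumeValidationError(
                f"volume contains {n_bad} non-finite voxel(s) (NaN/Inf)"
            )
        if self.voxel_volume_mm3 <= 0:
            self.voxel_volume_mm3 = float(self.voxel_size_mm) ** 3

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class LungMask:
    """Integer label field aligned to a :class:`CTVolume`.

    Labels: 0 background, 1 right lung, 2 left lung.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError(
                f"mask must be 3D, got {self.labels.ndim}D shape {self.labels.shape}"
            )
        present = set(np.unique(self.labels).tolist())
        bad = sorted(present - VALID_LABELS)
        if bad:
            raise LabelSchemeError(
                f"mask contains labels outside {{0,1,2}}: {bad}"
            )
        self.labels = self.labels.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass
class SubjectScanPair:
    """Paired end-inspiration (P01) and end-expiration (P02) reconstructions.

    The two phases are independent reconstructions and may differ in shape;
    each volume/mask pair is shape-matched, and both phases must share
    subject, study day and voxel size.
    """

    p01: tuple[CTVolume, LungMask]
    p02: tuple[CTVolume, LungMask]

    def __post_init__(self) -> None:
        v1, m1 = self.p01
        v2, m2 = self.p02
        if v1.shape != m1.shape or v2.shape != m2.shape:
            raise MaskAlignmentError("volume and mask shapes differ within a phase")
        if v1.phase != PHASE_INSPIRATION or v2.phase != PHASE_EXPIRATION:
            raise PairingError(
                f"expected phases ({PHASE_INSPIRATION}, {PHASE_EXPIRATION}), "
                f"got ({v1.phase}, {v2.phase})"
            )
        if (v1.subject_id, v1.day) != (v2.subject_id, v2.day):
            raise PairingError(
                f"phase pair mixes subjects/days: "
                f"({v1.subject_id}, day {v1.day}) vs ({v2.subject_id}, day {v2.day})"
            )
        if not np.isclose(v1.voxel_size_mm, v2.voxel_size_mm, rtol=1e-6):
            raise PairingError("phase pair has inconsistent voxel sizes")

    @property
    def subject_id(self) -> str:
        return self.p01[0].subject_id

    @property
    def day(self) -> int:
        return self.p01[0].day


def _load_3d(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, got shape {data.shape}"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, np.asarray(img.affine), zooms


def read_volume(
    path: str | Path,
    phase: str,
    subject_id: str = "",
    day: int = 0,
    voxel_size_mm: float | None = None,
    allow_anisotropic: bool = False,
) -> CTVolume:
    """Load a CT volume in HU from a NIfTI file.

    Voxel size is taken from the file header unless ``voxel_size_mm`` is
    given (override logged as a warning).  Anisotropic spacings raise
    unless ``allow_anisotropic`` is set, in which case the voxel volume is
    the product of the three spacings.
    """
    data, affine, zooms = _load_3d(path)
    data = np.asarray(data, dtype=np.float32)

    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise VolumeValidationError(
            f"{path}: volume contains {n_bad} non-finite voxel(s)"
        )

    if voxel_size_mm is not None:
        logger.warning(
            "%s: overriding header voxel size %s with %g mm", path, zooms, voxel_size_mm
        )
        vsize = float(voxel_size_mm)
        vvol = vsize**3
    else:
        iso = np.allclose(zooms, zooms[0], rtol=_ISOTROPY_RTOL)
        if not iso and not allow_anisotropic:
            raise VolumeFormatError(
                f"{path}: anisotropic voxel spacing {zooms}; pass "
                "allow_anisotropic=True to accept (cell volume = product of spacings)"
            )
        if not iso:
            logger.warning("%s: accepting anisotropic voxels %s", path, zooms)
        vsize = float(np.cbrt(np.prod(zooms))) if not iso else float(zooms[0])
        vvol = float(np.prod(zooms))

    lo, hi = HU_PLAUSIBLE
    n_out = int(((data < lo) | (data > hi)).sum())
    if n_out:
        logger.warning(
            "%s: %d voxel(s) outside plausible HU window [%g, %g]; retained unclamped",
            path, n_out, lo, hi,
        )

    return CTVolume(
        data=data,
        voxel_size_mm=vsize,
        phase=phase,
        subject_id=subject_id,
        day=int(day),
        affine=affine,
        voxel_volume_mm3=vvol,
    )


def read_mask(path: str | Path, volume: CTVolume) -> LungMask:
    """Load a lung mask aligned to ``volume``; labels must be within {0,1,2}."""
    data, _affine, _zooms = _load_3d(path)
    if data.shape != volume.shape:
        raise MaskAlignmentError(
            f"{path}: mask shape {data.shape} != volume shape {volume.shape}"
        )
    as_int = np.rint(data).astype(np.int64)
    if not np.allclose(data, as_int, atol=1e-6):
        raise LabelSchemeError(f"{path}: mask is not integer-valued")
    return LungMask(labels=as_int)


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a CT volume as float32 NIfTI (HU round-trip to float32 precision)."""
    path = Path(path)
    affine = volume.affine
    if affine is None:
        affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
    img.header.set_zooms((volume.voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return path


def write_mask(mask: LungMask, path: str | Path, voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM) -> Path:
    """Write a lung mask as uint8 NIfTI (bit-exact round-trip)."""
    path = Path(path)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), affine)
    img.header.set_zooms((voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return path


def region_select(mask: LungMask, region: str) -> np.ndarray:
    """Boolean voxel selection for a lung region.

    ``whole`` = labels {1, 2}; ``left`` = {2}; ``right`` = {1}.  Raises
    :class:`EmptyRegionError` on an empty selection, since mean lung
    attenuation is undefined on the empty set.
    """
    if region == "whole":
        sel = mask.labels > 0
    elif region == "left":
        sel = mask.labels == LABEL_LEFT
    elif region == "right":
        sel = mask.labels == LABEL_RIGHT
    else:
        raise ValueError(f"region must be one of {REGIONS}, got {region!r}")
    if not sel.any():
        raise EmptyRegionError(f"region {region!r} selects no voxels")
    return sel


# ---------------------------------------------------------------------------
# Study manifest

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "day",
    "path_p01_vol",
    "path_p01_mask",
    "path_p02_vol",
    "path_p02_mask",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a study manifest CSV and check its schema."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise VolumeFormatError(f"manifest {path} missing columns: {missing}")
    df["day"] = df["day"].astype(int)
    return df


def load_scan_pair(row: pd.Series, base_dir: str | Path = ".") -> SubjectScanPair:
    """Load both phases of one manifest row into a :class:`SubjectScanPair`."""
    base = Path(base_dir)
    sid, day = str(row["subject_id"]), int(row["day"])
    try:
        v1 = read_volume(base / row["path_p01_vol"], PHASE_INSPIRATION, sid, day)
        m1 = read_mask(base / row["path_p01_mask"], v1)
        v2 = read_volume(base / row["path_p02_vol"], PHASE_EXPIRATION, sid, day)
        m2 = read_mask(base / row["path_p02_mask"], v2)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"subject {sid} day {day}: {exc}") from exc
    return SubjectScanPair(p01=(v1, m1), p02=(v2, m2))
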