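"""Synthetic paired-phase murine thorax phantoms with exact ground truth.

The generator builds a digital mouse thorax: a soft-tissue body ellipsoid
near 0 HU containing two ellipsoidal lung lobes, the left lobe sized so
that it holds a configurable fraction (default one third) of the total
lung volume, as in the mouse.  Lung voxels are assigned to aeration
compartments (normo / hypo / non-aerated, plus a hyper-aerated remainder)
by ranking a spatial lesion-score field — a smooth random field plus
optional apical and left-lobe bias terms, emulating the apically and
left-dominant lesions of bleomycin-induced fibrosis — and taking the
top-scoring voxels as non-aerated, the next as hypo-aerated, and so on,
so the realized compartment counts match the requested fractions to
integer rounding.  HU values are drawn per compartment from Gaussians
truncated to that compartment's own HU window, which makes the
ground-truth compartment fractions exact by construction (untruncated
noise is available as a switch, for studying boundary leakage).

The end-inspiration volume (P01) is derived from the end-expiration
volume (P02) by dilating each lobe (newly recruited voxels get
normo-aerated HU) and lowering the HU of aerated voxels by a fixed air
gain.  This guarantees a coherent subject with positive tidal volume;
real gated acquisitions reconstruct the two phases independently, but a
coherent pair is what downstream tests need.

Cohorts place subjects in the three study arms (SAL saline control, BLM
bleomycin, BLM+NINT bleomycin + nintedanib) over study days 7/14/21 with
per-arm compartment trajectories and subject-level random effects.  Each
subject-day gets its own random stream derived by hashing the cohort seed
with the subject id and day, so regeneration is order-independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .errors import DesignError, PhantomSpecError
from .biomarkers import (
    AerationRanges,
    DEFAULT_RANGES,
    BiomarkerRecord,
    classify_aeration_field,
    HU_AIR,
)
from .volume_io import (
    CTVolume,
    LungMask,
    SubjectScanPair,
    LABEL_LEFT,
    LABEL_RIGHT,
    PHASE_INSPIRATION,
    PHASE_EXPIRATION,
    DEFAULT_VOXEL_SIZE_MM,
    MANIFEST_COLUMNS,
    write_mask,
    write_volume,
)

GROUPS = ("SAL", "BLM", "BLM+NINT")
DAYS = (7, 14, 21)
_GROUP_PREFIX = {"SAL": "SAL", "BLM": "BLM", "BLM+NINT": "NINT"}

#: margin kept from open interval endpoints when sampling, HU
_OPEN_EPS = 0.5
#: floor of the hyper-aerated sampling window, HU
_HU_FLOOR = -1000.0

# thorax geometry as fractions of the array extents; x = left-right,
# z = caudo-cranial (apex at high z)
_BODY_CENTER = (0.50, 0.50, 0.50)
_BODY_SEMI = (0.46, 0.46, 0.48)
_RIGHT_CENTER = (0.30, 0.50, 0.50)
_RIGHT_SEMI = (0.17, 0.28, 0.33)
_LEFT_CENTER = (0.72, 0.50, 0.50)

_SOFT_TISSUE_HU = 40.0
_SOFT_TISSUE_SD = 15.0


def derive_seed(*parts) -> int:
    """Deterministic sub-stream seed < 2**31 from hashed parts."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic subject scan pair."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM
    left_fraction: float = 1.0 / 3.0
    f_normo: float = 0.814
    f_hypo: float = 0.186
    f_non: float = 0.0
    hu_means: dict = field(
        default_factory=lambda: {
            "normo": -647.5, "hypo": -278.0, "non": 0.0, "other": -930.0,
        }
    )
    hu_sds: dict = field(
        default_factory=lambda: {"normo": 50.0, "hypo": 50.0, "non": 50.0, "other": 20.0}
    )
    #: multiplies total lung volume (applied as cube root on lobe semi-axes);
    #: models inflammation-driven volume change and inter-animal size spread
    lobe_volume_factor: float = 1.0
    lesion_apical_bias: float = 1.0
    lesion_left_bias: float = 0.0
    noise_weight: float = 1.0
    noise_sigma_voxels: float | None = None  # default: min(shape)/12
    inspiration_air_gain: float = 100.0
    inspiration_dilation: int = 1
    truncate_noise: bool = True
    ranges: AerationRanges = field(default_factory=AerationRanges)
    subject_id: str = "PHANTOM"
    day: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.f_normo, self.f_hypo, self.f_non)
        if any(not (0.0 <= f <= 1.0) for f in fr):
            raise PhantomSpecError(f"compartment fractions must lie in [0,1]: {fr}")
        if sum(fr) > 1.0 + 1e-9:
            raise PhantomSpecError(
                f"compartment fractions sum to {sum(fr):.4f} > 1"
            )
        if not (0.0 < self.left_fraction < 1.0):
            raise PhantomSpecError(
                f"left_fraction must lie in (0,1), got {self.left_fraction}"
            )
        if not self.lobe_volume_factor > 0:
            raise PhantomSpecError(
                f"lobe_volume_factor must be positive, got {self.lobe_volume_factor}"
            )
        for comp, (lo, hi) in self._sampling_windows().items():
            mu = self.hu_means[comp]
            if not (lo <= mu <= hi):
                raise PhantomSpecError(
                    f"HU mean for {comp!r} ({mu}) outside its window [{lo}, {hi}]"
                )

    def _sampling_windows(self) -> dict[str, tuple[float, float]]:
        r = self.ranges
        return {
            "normo": (r.normo[0], r.normo[1]),
            "hypo": (r.hypo[0] + _OPEN_EPS, r.hypo[1] - _OPEN_EPS),
            "non": (r.non[0], r.non[1]),
            "other": (_HU_FLOOR, r.normo[0] - _OPEN_EPS),
        }


@dataclass
class GroundTruth:
    """Exact per-voxel labels and analytic biomarker record of a phantom.

    Compartment labels for P02 are the labels the generator actually
    assigned; P01 labels are the classification of the generated P01 HU
    field (deterministic given the arrays).  ``records`` holds the
    biomarker record per region computed directly from the generated
    arrays by the defining formulas.
    """

    spec: PhantomSpec
    comp_labels_p01: np.ndarray  # int8 codes 0..3, -1 outside lung
    comp_labels_p02: np.ndarray
    fractions: dict  # region -> (pct_normo, pct_hypo, pct_non, pct_other), from P02 labels
    records: dict  # region -> BiomarkerRecord


def _ellipsoid(shape: tuple[int, int, int], center: tuple, semi: tuple) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, s, c, a in zip(grids, shape, center, semi):
        acc = acc + ((g - c * (s - 1)) / (a * s)) ** 2
    return acc <= 1.0


def _build_anatomy(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Body mask and lung label field (0/1/2) for the phantom thorax."""
    body = _ellipsoid(spec.shape, _BODY_CENTER, _BODY_SEMI)
    g = spec.lobe_volume_factor ** (1.0 / 3.0)
    right_semi = tuple(a * g for a in _RIGHT_SEMI)
    right = _ellipsoid(spec.shape, _RIGHT_CENTER, right_semi)
    # left/right lobe volume ratio lf/(1-lf) sets the left semi-axis scale
    s = (spec.left_fraction / (1.0 - spec.left_fraction)) ** (1.0 / 3.0)
    left_semi = tuple(a * s for a in right_semi)
    left = _ellipsoid(spec.shape, _LEFT_CENTER, left_semi)
    left &= ~right
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[right] = LABEL_RIGHT
    labels[left] = LABEL_LEFT
    if not right.any() or not left.any():
        raise PhantomSpecError(
            f"shape {spec.shape} too small to realize both lung lobes"
        )
    return body, labels


def _lesion_score(spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-voxel lesion propensity over the lung (higher = more diseased)."""
    nz = spec.shape[2]
    z_norm = np.broadcast_to(
        (np.arange(nz, dtype=np.float64) / max(nz - 1, 1))[None, None, :], spec.shape
    )
    sigma = spec.noise_sigma_voxels
    if sigma is None:
        sigma = min(spec.shape) / 12.0
    noise = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=sigma)
    lung = labels > 0
    mu, sd = noise[lung].mean(), noise[lung].std()
    if sd > 0:
        noise = (noise - mu) / sd
    score = (
        spec.lesion_apical_bias * z_norm
        + spec.lesion_left_bias * (labels == LABEL_LEFT)
        + spec.noise_weight * noise
    )
    return score


def _assign_compartments(
    spec: PhantomSpec, labels: np.ndarray, score: np.ndarray
) -> np.ndarray:
    """Rank lung voxels by lesion score into compartment codes 0..3.

    Codes follow biomarkers.COMPARTMENTS: 0 normo, 1 hypo, 2 non, 3 other
    (hyper-aerated remainder).  Counts are exact to integer rounding.
    """
    lung = labels > 0
    n = int(lung.sum())
    k_non = int(round(spec.f_non * n))
    k_hypo = int(round(spec.f_hypo * n))
    k_normo = int(round(spec.f_normo * n))
    overshoot = k_non + k_hypo + k_normo - n
    if overshoot > 0:
        k_normo -= overshoot
    order = np.argsort(-score[lung], kind="stable")
    codes_flat = np.full(n, 3, dtype=np.int8)
    codes_flat[order[:k_non]] = 2
    codes_flat[order[k_non:k_non + k_hypo]] = 1
    codes_flat[order[k_non + k_hypo:k_non + k_hypo + k_normo]] = 0
    comp = np.full(spec.shape, -1, dtype=np.int8)
    comp[lung] = codes_flat
    return comp


def _sample_hu(
    spec: PhantomSpec, comp: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-voxel HU from each compartment's (truncated) Gaussian."""
    out = np.zeros(spec.shape, dtype=np.float64)
    windows = spec._sampling_windows()
    for code, name in enumerate(("normo", "hypo", "non", "other")):
        sel = comp == code
        k = int(sel.sum())
        if k == 0:
            continue
        mu = float(spec.hu_means[name])
        sd = float(spec.hu_sds[name])
        if sd == 0:
            out[sel] = mu
        elif spec.truncate_noise:
            lo, hi = windows[name]
            a, b = (lo - mu) / sd, (hi - mu) / sd
            out[sel] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=k, random_state=rng)
        else:
            out[sel] = rng.normal(mu, sd, size=k)
    return out


def _record_from_arrays(
    spec: PhantomSpec,
    hu01: np.ndarray, lab01: np.ndarray,
    hu02: np.ndarray, lab02: np.ndarray,
    comp02: np.ndarray, region: str,
) -> BiomarkerRecord:
    """Biomarker record computed directly from arrays by the defining formulas."""
    sel01 = (lab01 > 0) if region == "whole" else (lab01 == (2 if region == "left" else 1))
    sel02 = (lab02 > 0) if region == "whole" else (lab02 == (2 if region == "left" else 1))
    n01, n02 = int(sel01.sum()), int(sel02.sum())
    vv = spec.voxel_size_mm**3
    v01, v02 = n01 * vv, n02 * vv
    mla01 = float(np.mean(hu01[sel01], dtype=np.float64))
    mla02 = float(np.mean(hu02[sel02], dtype=np.float64))
    air = v01 * mla01 / HU_AIR
    frc = v02 * mla02 / HU_AIR
    codes = comp02[sel02]
    counts = np.bincount(codes, minlength=4)
    fr = tuple(100.0 * counts[i] / n02 for i in range(4))
    return BiomarkerRecord(
        subject_id=spec.subject_id, day=spec.day, region=region,
        n_p01=n01, n_p02=n02, v_p01=v01, v_p02=v02,
        mla_p01=mla01, mla_p02=mla02, air=air, frc=frc,
        tissue=v02 - frc, tv=air - frc,
        pct_gas_p01=100.0 * air / v01, pct_gas_p02=100.0 * frc / v02,
        pct_normo=fr[0], pct_hypo=fr[1], pct_non=fr[2], pct_other=fr[3],
    )


def generate_subject(spec: PhantomSpec) -> tuple[SubjectScanPair, GroundTruth]:
    """Generate one paired-phase phantom scan and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    body, labels02 = _build_anatomy(spec)
    score = _lesion_score(spec, labels02, rng)
    comp02 = _assign_compartments(spec, labels02, score)

    # expiration (P02) HU field
    hu02 = np.full(spec.shape, _HU_FLOOR, dtype=np.float64)
    hu02[body] = _SOFT_TISSUE_HU + _SOFT_TISSUE_SD * rng.standard_normal(int(body.sum()))
    lung02 = labels02 > 0
    hu02[lung02] = _sample_hu(spec, comp02, rng)[lung02]

    # inspiration (P01): dilate lobes, recruit normo air, lower aerated HU
    struct = ndimage.generate_binary_structure(3, 1)
    right01 = ndimage.binary_dilation(
        labels02 == LABEL_RIGHT, structure=struct, iterations=spec.inspiration_dilation
    )
    left01 = ndimage.binary_dilation(
        labels02 == LABEL_LEFT, structure=struct, iterations=spec.inspiration_dilation
    ) & ~right01
    labels01 = np.zeros(spec.shape, dtype=np.uint8)
    labels01[right01] = LABEL_RIGHT
    labels01[left01] = LABEL_LEFT
    lung01 = labels01 > 0

    hu01 = hu02.copy()
    recruited = lung01 & ~lung02
    k = int(recruited.sum())
    if k:
        mu = float(spec.hu_means["normo"])
        sd = float(spec.hu_sds["normo"])
        if sd == 0:
            hu01[recruited] = mu
        else:
            lo, hi = spec._sampling_windows()["normo"]
            a, b = (lo - mu) / sd, (hi - mu) / sd
            hu01[recruited] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=k, random_state=rng)
    aerated = recruited | (np.isin(comp02, (0, 1, 3)) & lung02)
    hu01[aerated] = np.maximum(hu01[aerated] - spec.inspiration_air_gain, _HU_FLOOR)

    # float32 is the storage dtype; ground truth is computed on exactly the
    # arrays a reader will see
    hu01_f = hu01.astype(np.float32)
    hu02_f = hu02.astype(np.float32)

    comp01 = np.full(spec.shape, -1, dtype=np.int8)
    comp01[lung01] = classify_aeration_field(hu01_f[lung01], spec.ranges)

    vol01 = CTVolume(hu01_f, spec.voxel_size_mm, PHASE_INSPIRATION, spec.subject_id, spec.day)
    vol02 = CTVolume(hu02_f, spec.voxel_size_mm, PHASE_EXPIRATION, spec.subject_id, spec.day)
    pair = SubjectScanPair(p01=(vol01, LungMask(labels01)), p02=(vol02, LungMask(labels02)))

    fractions = {}
    records = {}
    for region in ("whole", "left", "right"):
        sel = lung02 if region == "whole" else (labels02 == (2 if region == "left" else 1))
        counts = np.bincount(comp02[sel], minlength=4)
        n = int(sel.sum())
        fractions[region] = tuple(100.0 * counts[i] / n for i in range(4))
        records[region] = _record_from_arrays(
            spec, hu01_f, labels01, hu02_f, labels02, comp02, region
        )

    truth = GroundTruth(
        spec=spec,
        comp_labels_p01=comp01,
        comp_labels_p02=comp02,
        fractions=fractions,
        records=records,
    )
    return pair, truth


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class CohortDesign:
    """Study arms, sizes, days and per-arm compartment trajectories."""

    group_sizes: dict = field(
        default_factory=lambda: {"SAL": 4, "BLM": 7, "BLM+NINT": 12}
    )
    days: tuple = DAYS
    #: group -> day -> (f_normo, f_hypo, f_non)
    trajectories: dict = field(default_factory=lambda: DEFAULT_TRAJECTORIES)
    #: group -> lesion_left_bias for that arm
    left_bias: dict = field(
        default_factory=lambda: {"SAL": 0.0, "BLM": 1.0, "BLM+NINT": 1.0}
    )
    #: group -> day -> total lung volume factor (inflammation-driven swelling)
    volume_trajectories: dict = field(default_factory=lambda: DEFAULT_VOLUME_TRAJECTORIES)
    #: log-sd of subject-level multiplicative effects on hypo/non fractions
    subject_sigma: float = 0.15
    #: log-sd of subject-level lung size variation
    size_sigma: float = 0.05
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise DesignError("cohort design has no groups")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise DesignError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 1:
                raise DesignError(f"group {g!r} is empty")
        for d in self.days:
            if d not in DAYS:
                raise DesignError(f"unknown study day {d}; expected one of {DAYS}")
        for g in self.group_sizes:
            for d in self.days:
                if d not in self.trajectories.get(g, {}):
                    raise DesignError(f"no trajectory for group {g!r} day {d}")


#: Per-arm compartment trajectories (f_normo, f_hypo, f_non).  Day-7 and
#: day-21 values follow the representative compartment percentages of the
#: bleomycin study arms (SAL 81.4/18.6/0; BLM 73.8/24.7/1.5 -> 22.7/38.4/38.9;
#: BLM+NINT 57.7/36.1/6.2 -> 48.7/39.1/12.2); day 14 is their midpoint.
DEFAULT_TRAJECTORIES = {
    "SAL": {7: (0.814, 0.186, 0.0), 14: (0.814, 0.186, 0.0), 21: (0.814, 0.186, 0.0)},
    "BLM": {
        7: (0.738, 0.247, 0.015),
        14: (0.4825, 0.3155, 0.202),
        21: (0.227, 0.384, 0.389),
    },
    "BLM+NINT": {
        7: (0.577, 0.361, 0.062),
        14: (0.532, 0.376, 0.092),
        21: (0.487, 0.391, 0.122),
    },
}

#: Total-lung-volume factors per arm and day: bleomycin arms swell early
#: (acute inflammation on day 7) and partially recede as fibrosis replaces
#: edema; the treated arm recedes slightly faster.
DEFAULT_VOLUME_TRAJECTORIES = {
    "SAL": {7: 1.0, 14: 1.0, 21: 1.0},
    "BLM": {7: 1.15, 14: 1.10, 21: 1.05},
    "BLM+NINT": {7: 1.15, 14: 1.08, 21: 1.02},
}


def _subject_targets(
    base: tuple[float, float, float], m_hypo: float, m_non: float
) -> tuple[float, float, float]:
    f_normo, f_hypo, f_non = base
    f_hypo = min(f_hypo * m_hypo, 0.95)
    f_non = min(f_non * m_non, 0.95)
    total = f_hypo + f_non
    if total > 0.98:
        f_hypo *= 0.98 / total
        f_non *= 0.98 / total
    return (max(1.0 - f_hypo - f_non, 0.0), f_hypo, f_non)


def generate_cohort(
    design: CohortDesign,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[SubjectScanPair], list[GroundTruth]]:
    """Generate a full cohort: one scan pair per subject per study day.

    Subject-level multiplicative random effects (log-normal, sd
    ``design.subject_sigma``) perturb each subject's hypo/non target
    fractions consistently across days.  If ``out_dir`` is given, NIfTI
    volumes/masks, per-subject ground-truth JSON and a manifest CSV are
    written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    rows = []
    pairs: list[SubjectScanPair] = []
    truths: list[GroundTruth] = []
    for group, n in design.group_sizes.items():
        prefix = _GROUP_PREFIX[group]
        for i in range(n):
            subject_id = f"{prefix}{i + 1:02d}"
            subj_rng = np.random.default_rng(derive_seed(seed, subject_id))
            m_hypo, m_non = np.exp(
                design.subject_sigma * subj_rng.standard_normal(2)
            )
            m_size = float(np.exp(design.size_sigma * subj_rng.standard_normal()))
            for day in design.days:
                f_normo, f_hypo, f_non = _subject_targets(
                    design.trajectories[group][day], m_hypo, m_non
                )
                vol_factor = design.volume_trajectories.get(group, {}).get(day, 1.0)
                spec = replace(
                    design.base_spec,
                    f_normo=f_normo,
                    f_hypo=f_hypo,
                    f_non=f_non,
                    lobe_volume_factor=m_size * vol_factor,
                    lesion_left_bias=design.left_bias.get(group, 0.0),
                    subject_id=subject_id,
                    day=day,
                    seed=derive_seed(seed, subject_id, day),
                )
                pair, truth = generate_subject(spec)
                pairs.append(pair)
                truths.append(truth)
                paths = {c: "" for c in MANIFEST_COLUMNS[3:]}
                if out is not None:
                    stem = f"{subject_id}_d{day:02d}"
                    paths = {
                        "path_p01_vol": f"{stem}_P01_vol.nii.gz",
                        "path_p01_mask": f"{stem}_P01_mask.nii.gz",
                        "path_p02_vol": f"{stem}_P02_vol.nii.gz",
                        "path_p02_mask": f"{stem}_P02_mask.nii.gz",
                    }
                    write_volume(pair.p01[0], out / paths["path_p01_vol"])
                    write_mask(pair.p01[1], out / paths["path_p01_mask"], spec.voxel_size_mm)
                    write_volume(pair.p02[0], out / paths["path_p02_vol"])
                    write_mask(pair.p02[1], out / paths["path_p02_mask"], spec.voxel_size_mm)
                    _write_truth_json(truth, out / f"{stem}_truth.json")
                rows.append(
                    {"subject_id": subject_id, "group": group, "day": day, **paths}
                )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest, pairs, truths


def _write_truth_json(truth: GroundTruth, path: Path) -> None:
    payload = {
        "subject_id": truth.spec.subject_id,
        "day": truth.spec.day,
        "fractions": {k: list(v) for k, v in truth.fractions.items()},
        "records": {k: _record_dict(r) for k, r in truth.records.items()},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _record_dict(r: BiomarkerRecord) -> dict:
    d = asdict(r)
    d.pop("flags", None)
    return d
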