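"""Densitometric parameters and biomarkers from paired-phase lung CT.

From a pair of gated reconstructions (end-inspiration P01, end-expiration
P02) and their lung masks, this module computes, per region (whole / left /
right lung):

* raw parameters — voxel count N, lung volume V = N · voxel volume, mean
  lung attenuation MLA = ΣHU / N, inspiratory air volume
  Air = V_P01 · MLA_P01 / (−1000 HU), and functional residual capacity
  FRC = V_P02 · MLA_P02 / (−1000 HU);
* derived biomarkers — Tissue = V_P02 − FRC (non-gas lung volume),
  tidal volume TV = Air − FRC, gas fractions %Gas_phase = 100·air/V
  (algebraically equal to −MLA/10), and aeration-compartment percentages.

Aeration compartments use the preclinical HU windows: normo-aerated
[−860, −435], hypo-aerated (−435, −121), non-aerated [−121, 121].  Bracket
notation is honored literally: −435 belongs to normo and −121 to non.
Voxels outside all three windows (hyper-aerated below −860, or dense above
121) fall into an explicit fourth class, ``other``, so the denominator of
every percentage is the full voxel count of the selected region and the
four percentages sum to 100.

Air and FRC may come out negative when MLA > 0 (a severely consolidated
region); such values are flagged, never clipped, so the conservation
identities Tissue + FRC = V_P02 and TV = Air − FRC stay exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyRegionError, PairingError
from .volume_io import CTVolume, SubjectScanPair, region_select, REGIONS

logger = logging.getLogger(__name__)

COMPARTMENTS = ("normo", "hypo", "non", "other")

#: Reference attenuation of pure air, HU.
HU_AIR = -1000.0


@dataclass(frozen=True)
class AerationRanges:
    """HU windows defining the aeration compartments.

    ``normo`` and ``non`` are closed intervals; ``hypo`` is the open
    interval between them.  Defaults are the preclinical murine windows.
    """

    normo: tuple[float, float] = (-860.0, -435.0)
    hypo: tuple[float, float] = (-435.0, -121.0)
    non: tuple[float, float] = (-121.0, 121.0)

    def __post_init__(self) -> None:
        if not (
            self.normo[0] < self.normo[1] <= self.hypo[0] < self.hypo[1]
            <= self.non[0] < self.non[1]
        ):
            raise ValueError(f"aeration windows must be ordered and disjoint: {self}")


DEFAULT_RANGES = AerationRanges()


@dataclass
class BiomarkerRecord:
    """All raw parameters and biomarkers for one (subject, day, region)."""

    subject_id: str
    day: int
    region: str
    n_p01: int
    n_p02: int
    v_p01: float
    v_p02: float
    mla_p01: float
    mla_p02: float
    air: float
    frc: float
    tissue: float
    tv: float
    pct_gas_p01: float
    pct_gas_p02: float
    pct_normo: float
    pct_hypo: float
    pct_non: float
    pct_other: float
    #: phase the compartment percentages were computed on ("P01" or "P02")
    compartment_phase: str = "P02"
    flags: list[str] = field(default_factory=list)


@dataclass
class HUHistogram:
    """HU frequency distribution of one region in one phase."""

    bin_edges: np.ndarray
    counts: np.ndarray
    region: str
    phase: str

    @property
    def n(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# Elementary operations

def lung_volume(volume: CTVolume, sel: np.ndarray) -> float:
    """Region volume in mm^3: voxel count times voxel cell volume."""
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise EmptyRegionError("lung_volume: empty voxel selection")
    return n * volume.voxel_volume_mm3


def mean_lung_attenuation(volume: CTVolume, sel: np.ndarray) -> float:
    """Arithmetic mean HU over the selected voxels (MLA)."""
    if not np.any(sel):
        raise EmptyRegionError("mean_lung_attenuation: empty voxel selection")
    return float(np.mean(volume.data[sel], dtype=np.float64))


def air_volume(v_mm3: float, mla_hu: float) -> float:
    """Air content of a region, mm^3: V · MLA / (−1000 HU).

    Negative when MLA > 0; callers flag, never clip.
    """
    if v_mm3 < 0:
        raise ValueError(f"volume must be non-negative, got {v_mm3}")
    return v_mm3 * mla_hu / HU_AIR


def classify_aeration(hu: float, ranges: AerationRanges = DEFAULT_RANGES) -> str:
    """Aeration class of a single HU value.

    Interval endpoints follow the bracket notation of the windows: the
    normo and non windows are closed, hypo is open, so ties at −435 go to
    normo and ties at −121 go to non.
    """
    if ranges.normo[0] <= hu <= ranges.normo[1]:
        return "normo"
    if ranges.non[0] <= hu <= ranges.non[1]:
        return "non"
    if ranges.hypo[0] < hu < ranges.hypo[1]:
        return "hypo"
    return "other"


def classify_aeration_field(
    hu: np.ndarray, ranges: AerationRanges = DEFAULT_RANGES
) -> np.ndarray:
    """Vectorized :func:`classify_aeration`: integer codes indexing COMPARTMENTS."""
    hu = np.asarray(hu)
    out = np.full(hu.shape, 3, dtype=np.int8)  # other
    out[(hu > ranges.hypo[0]) & (hu < ranges.hypo[1])] = 1
    out[(hu >= ranges.normo[0]) & (hu <= ranges.normo[1])] = 0
    out[(hu >= ranges.non[0]) & (hu <= ranges.non[1])] = 2
    return out


def compartment_fractions(
    volume: CTVolume, sel: np.ndarray, ranges: AerationRanges = DEFAULT_RANGES
) -> tuple[float, float, float, float]:
    """Percent of region voxels per aeration class (normo, hypo, non, other).

    The denominator is the full voxel count of the selected region, so the
    four values sum to 100.
    """
    if not np.any(sel):
        raise EmptyRegionError("compartment_fractions: empty voxel selection")
    codes = classify_aeration_field(volume.data[sel], ranges)
    n = codes.size
    counts = np.bincount(codes, minlength=4)
    return tuple(100.0 * counts[i] / n for i in range(4))  # type: ignore[return-value]


def hu_histogram(
    volume: CTVolume,
    sel: np.ndarray,
    bin_width: float = 10.0,
    region: str = "whole",
) -> HUHistogram:
    """HU frequency distribution over [min, max] in ``bin_width``-wide bins.

    Bins are half-open with the last bin closed, so counts always sum to
    the region voxel count.  Default width 10 HU.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if not np.any(sel):
        raise EmptyRegionError("hu_histogram: empty voxel selection")
    values = np.asarray(volume.data[sel], dtype=np.float64)
    lo = float(values.min())
    hi = float(values.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width))) if hi > lo else 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    return HUHistogram(bin_edges=edges, counts=counts, region=region, phase=volume.phase)


# ---------------------------------------------------------------------------
# Assembly

def functional_biomarkers(
    pair: SubjectScanPair,
    region: str,
    ranges: AerationRanges = DEFAULT_RANGES,
    compartment_phase: str = "P02",
) -> BiomarkerRecord:
    """Assemble the full biomarker record for one region of one scan pair.

    Air comes from P01, FRC from P02; TV = Air − FRC and
    Tissue = V_P02 − FRC.  Compartment percentages are computed on the
    expiratory phase by default (``compartment_phase="P01"`` switches).
    """
    v01, m01 = pair.p01
    v02, m02 = pair.p02
    sel01 = region_select(m01, region)
    sel02 = region_select(m02, region)

    n01 = int(np.count_nonzero(sel01))
    n02 = int(np.count_nonzero(sel02))
    vol01 = lung_volume(v01, sel01)
    vol02 = lung_volume(v02, sel02)
    mla01 = mean_lung_attenuation(v01, sel01)
    mla02 = mean_lung_attenuation(v02, sel02)
    air = air_volume(vol01, mla01)
    frc = air_volume(vol02, mla02)

    flags: list[str] = []
    if air < 0:
        flags.append("negative_air")
    if frc < 0:
        flags.append("negative_frc")
    if flags:
        logger.warning(
            "%s day %d %s: non-physical air volume flagged: %s",
            pair.subject_id, pair.day, region, flags,
        )

    if compartment_phase == "P02":
        fr = compartment_fractions(v02, sel02, ranges)
    elif compartment_phase == "P01":
        fr = compartment_fractions(v01, sel01, ranges)
    else:
        raise PairingError(f"compartment_phase must be P01 or P02, got {compartment_phase!r}")

    return BiomarkerRecord(
        subject_id=pair.subject_id,
        day=pair.day,
        region=region,
        n_p01=n01,
        n_p02=n02,
        v_p01=vol01,
        v_p02=vol02,
        mla_p01=mla01,
        mla_p02=mla02,
        air=air,
        frc=frc,
        tissue=vol02 - frc,
        tv=air - frc,
        pct_gas_p01=100.0 * air / vol01,
        pct_gas_p02=100.0 * frc / vol02,
        pct_normo=fr[0],
        pct_hypo=fr[1],
        pct_non=fr[2],
        pct_other=fr[3],
        compartment_phase=compartment_phase,
        flags=flags,
    )


def compute_all_regions(
    pair: SubjectScanPair,
    ranges: AerationRanges = DEFAULT_RANGES,
    compartment_phase: str = "P02",
) -> list[BiomarkerRecord]:
    """Biomarker records for whole, left and right lung of one scan pair."""
    return [
        functional_biomarkers(pair, region, ranges, compartment_phase)
        for region in REGIONS
    ]


def records_to_frame(records: list[BiomarkerRecord]) -> pd.DataFrame:
    """Tidy one-row-per-(subject, day, region) table of all biomarker fields."""
    rows = []
    for r in records:
        d = asdict(r)
        d["flags"] = ";".join(d["flags"])
        rows.append(d)
    return pd.DataFrame(rows)


def histograms_to_frame(hists: list[HUHistogram], subject_id: str = "", day: int = 0) -> pd.DataFrame:
    """Tidy histogram table: (region, phase, bin_left, bin_right, count)."""
    rows = []
    for h in hists:
        for left, right, c in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
            rows.append(
                {
                    "subject_id": subject_id,
                    "day": day,
                    "region": h.region,
                    "phase": h.phase,
                    "bin_left": float(left),
                    "bin_right": float(right),
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows)


def compute_study(
    manifest: pd.DataFrame,
    base_dir: str | Path = ".",
    ranges: AerationRanges = DEFAULT_RANGES,
    compartment_phase: str = "P02",
) -> pd.DataFrame:
    """Run the biomarker extraction over every manifest row.

    Returns the tidy biomarker table joined with the group column of the
    manifest.
    """
    from .volume_io import load_scan_pair

    all_records: list[BiomarkerRecord] = []
    groups: dict[tuple[str, int], str] = {}
    for _, row in manifest.iterrows():
        pair = load_scan_pair(row, base_dir=base_dir)
        all_records.extend(compute_all_regions(pair, ranges, compartment_phase))
        groups[(str(row["subject_id"]), int(row["day"]))] = str(row["group"])
    df = records_to_frame(all_records)
    df["group"] = [groups[(s, d)] for s, d in zip(df["subject_id"], df["day"])]
    return df
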