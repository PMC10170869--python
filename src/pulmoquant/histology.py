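"""Ashcroft fibrosis scoring: aggregation and correlation with CT biomarkers.

The Ashcroft score grades pulmonary fibrosis on an ordinal 0-8 scale per
microscopic field.  Fields are scored per lobe; severity classes are
no/mild (scores 0-3), moderate (exactly 4) and severe (>= 5).  Per
subject and region this module reports the mean field score and the
class frequency distribution (percent of fields per class, summing to
100), where the whole-lung summary pools the fields of both lobes — the
score is defined per field, so pooling, not averaging of lobe means, is
the natural aggregate.

For imaging-histology validation, Spearman rank correlations (average
ranks on ties, two-sided p) are computed between each CT biomarker at
study end and the mean Ashcroft score across subjects; a reporting mask
hides entries with p above the significance threshold while the raw
table keeps everything.

A synthetic score generator is included for phantom cohorts: it maps the
ground-truth non-aerated percentage through a saturating monotone curve
to an expected score and draws integer field scores around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyRegionError, InsufficientDataError, ScoreValidationError

SEVERITY_CLASSES = ("no_mild", "moderate", "severe")
LOBES = ("left", "right")

ASHCROFT_MIN, ASHCROFT_MAX = 0, 8


@dataclass
class AshcroftRecord:
    """Field scores of one lobe of one subject at sacrifice."""

    subject_id: str
    lobe: str
    field_scores: list[int]

    def __post_init__(self) -> None:
        if self.lobe not in LOBES:
            raise ScoreValidationError(f"lobe must be left/right, got {self.lobe!r}")
        if not self.field_scores:
            raise ScoreValidationError(
                f"{self.subject_id}/{self.lobe}: at least one field score required"
            )
        for s in self.field_scores:
            ashcroft_class(s)


@dataclass
class SeverityDistribution:
    """Percent of fields per fibrosis severity class; sums to 100."""

    pct_no_mild: float
    pct_moderate: float
    pct_severe: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pct_no_mild, self.pct_moderate, self.pct_severe)


def ashcroft_class(score: int) -> str:
    """Severity class of one field score: 0-3 no/mild, 4 moderate, >=5 severe."""
    if not float(score).is_integer() or not (ASHCROFT_MIN <= score <= ASHCROFT_MAX):
        raise ScoreValidationError(
            f"Ashcroft score must be an integer in [{ASHCROFT_MIN}, {ASHCROFT_MAX}], got {score!r}"
        )
    score = int(score)
    if score <= 3:
        return "no_mild"
    if score == 4:
        return "moderate"
    return "severe"


def ashcroft_summary(
    records: list[AshcroftRecord], region: str = "whole"
) -> tuple[float, SeverityDistribution]:
    """Mean field score and severity-class percentages for a region.

    ``whole`` pools the fields of both lobes; ``left``/``right`` restrict
    to one lobe.
    """
    if region == "whole":
        scores = [s for r in records for s in r.field_scores]
    elif region in LOBES:
        scores = [s for r in records if r.lobe == region for s in r.field_scores]
    else:
        raise ValueError(f"region must be whole/left/right, got {region!r}")
    if not scores:
        raise EmptyRegionError(f"no Ashcroft fields for region {region!r}")
    classes = [ashcroft_class(s) for s in scores]
    n = len(scores)
    dist = SeverityDistribution(
        pct_no_mild=100.0 * classes.count("no_mild") / n,
        pct_moderate=100.0 * classes.count("moderate") / n,
        pct_severe=100.0 * classes.count("severe") / n,
    )
    return float(np.mean(scores)), dist


def read_ashcroft_csv(path) -> list[AshcroftRecord]:
    """Load field scores from a CSV of (subject_id, lobe, field_index, score)."""
    df = pd.read_csv(path, comment="#")
    records = []
    for (sid, lobe), sub in df.groupby(["subject_id", "lobe"], sort=True):
        scores = sub.sort_values("field_index")["score"].astype(int).tolist()
        records.append(AshcroftRecord(str(sid), str(lobe), scores))
    return records


def summarize_cohort(records: list[AshcroftRecord]) -> pd.DataFrame:
    """Per-subject, per-region mean score and class percentages."""
    rows = []
    by_subject: dict[str, list[AshcroftRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    for sid in sorted(by_subject):
        for region in ("whole", "left", "right"):
            try:
                mean, dist = ashcroft_summary(by_subject[sid], region)
            except EmptyRegionError:
                continue
            rows.append(
                {
                    "subject_id": sid,
                    "region": region,
                    "mean_ashcroft": mean,
                    "pct_no_mild": dist.pct_no_mild,
                    "pct_moderate": dist.pct_moderate,
                    "pct_severe": dist.pct_severe,
                    "n_fields": sum(len(r.field_scores) for r in by_subject[sid]
                                    if region == "whole" or r.lobe == region),
                }
            )
    return pd.DataFrame(rows)


def spearman_matrix(
    study: pd.DataFrame,
    histology_summary: pd.DataFrame,
    region: str,
    day: int = 21,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman R between each CT biomarker and the mean Ashcroft score.

    ``study`` is the long study table, ``histology_summary`` the output of
    :func:`summarize_cohort`.  Matches subjects having both values at the
    given day/region; needs at least 3.  Returns one row per biomarker
    with R, two-sided p and a ``masked`` flag marking entries a
    significance-filtered report would hide (p >= alpha or undefined).
    """
    hist = histology_summary[histology_summary["region"] == region]
    hist = hist.set_index("subject_id")["mean_ashcroft"]
    sub = study[(study["day"] == day) & (study["region"] == region)]
    rows = []
    for biomarker, bsub in sub.groupby("biomarker", sort=True):
        merged = bsub.set_index("subject_id")["value"].to_frame().join(hist, how="inner").dropna()
        n = len(merged)
        if n < 3:
            raise InsufficientDataError(
                f"Spearman needs >=3 subjects with both values, got {n} for {biomarker}"
            )
        x = merged["value"].to_numpy()
        y = merged["mean_ashcroft"].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append(
                {"biomarker": biomarker, "region": region, "n": n,
                 "spearman_r": np.nan, "pvalue": np.nan,
                 "masked": True, "flag": "undefined_constant_input"}
            )
            continue
        r, p = stats.spearmanr(x, y)
        rows.append(
            {"biomarker": biomarker, "region": region, "n": n,
             "spearman_r": float(r), "pvalue": float(p),
             "masked": bool(p >= alpha), "flag": ""}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic scores for phantom cohorts

#: half-saturation constant of the %Non -> expected-score curve
_SCORE_K = 12.0
_SCORE_SD = 1.2


def expected_score_from_pct_non(pct_non: float, k: float = _SCORE_K) -> float:
    """Saturating monotone map from non-aerated percentage to expected score."""
    return ASHCROFT_MAX * pct_non / (pct_non + k)


def generate_synthetic_ashcroft(
    pct_non_by_subject_lobe: dict[tuple[str, str], float],
    seed: int,
    n_fields: int = 12,
    score_sd: float = _SCORE_SD,
) -> list[AshcroftRecord]:
    """Draw integer field scores around the expected score of each lobe.

    ``pct_non_by_subject_lobe`` maps (subject_id, lobe) to the ground-truth
    non-aerated percentage of that lobe (typically at sacrifice, day 21).
    Scores are normal draws around the expected score, rounded and clipped
    to the 0-8 scale.  Synthetic stand-in for slide scoring; labelled as
    such wherever it is written out.
    """
    rng = np.random.default_rng(seed)
    records = []
    for (sid, lobe) in sorted(pct_non_by_subject_lobe):
        expected = expected_score_from_pct_non(pct_non_by_subject_lobe[(sid, lobe)])
        raw = rng.normal(expected, score_sd, size=n_fields)
        scores = np.clip(np.rint(raw), ASHCROFT_MIN, ASHCROFT_MAX).astype(int)
        records.append(AshcroftRecord(sid, lobe, scores.tolist()))
    return records


def ashcroft_records_to_frame(records: list[AshcroftRecord]) -> pd.DataFrame:
    rows = [
        {"subject_id": r.subject_id, "lobe": r.lobe, "field_index": i, "score": s}
        for r in records
        for i, s in enumerate(r.field_scores)
    ]
    return pd.DataFrame(rows)
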