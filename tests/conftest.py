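import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pulmoquant import (  # noqa: E402
    CTVolume,
    LungMask,
    SubjectScanPair,
    PhantomSpec,
    generate_subject,
)
from pulmoquant.phantom import derive_seed  # noqa: E402


@pytest.fixture(scope="session")
def small_phantom():
    """One 32-cube phantom with a three-compartment mix and default noise."""
    spec = PhantomSpec(
        shape=(32, 32, 32), f_normo=0.6, f_hypo=0.3, f_non=0.1, seed=20240501
    )
    return generate_subject(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Phantom with zero HU noise: compartment values exactly at their means."""
    spec = PhantomSpec(
        shape=(32, 32, 32),
        f_normo=0.6,
        f_hypo=0.3,
        f_non=0.1,
        hu_sds={"normo": 0.0, "hypo": 0.0, "non": 0.0, "other": 0.0},
        seed=7,
    )
    return generate_subject(spec)


def make_pair(data01, data02, labels01=None, labels02=None, voxel=0.05,
              subject="S1", day=21):
    """Build a SubjectScanPair directly from arrays (shared test helper)."""
    data01 = np.asarray(data01, dtype=np.float32)
    data02 = np.asarray(data02, dtype=np.float32)
    if labels01 is None:
        labels01 = np.ones(data01.shape, dtype=np.uint8)
        labels01[data01.shape[0] // 2:] = 2
    if labels02 is None:
        labels02 = np.ones(data02.shape, dtype=np.uint8)
        labels02[data02.shape[0] // 2:] = 2
    v01 = CTVolume(data01, voxel, "P01", subject, day)
    v02 = CTVolume(data02, voxel, "P02", subject, day)
    return SubjectScanPair(p01=(v01, LungMask(labels01)), p02=(v02, LungMask(labels02)))


@pytest.fixture
def pair_factory():
    return make_pair


def lobe_study_table(pairs, group, biomarker="pct_non", day=21):
    """Long study table of one biomarker for left/right lobes of many pairs."""
    from pulmoquant.biomarkers import functional_biomarkers

    rows = []
    for p in pairs:
        for region in ("left", "right"):
            rec = functional_biomarkers(p, region)
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "group": group,
                    "day": day,
                    "region": region,
                    "biomarker": biomarker,
                    "value": getattr(rec, biomarker),
                }
            )
    return pd.DataFrame(rows)
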