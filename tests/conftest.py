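import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sfindex as sf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def doubling_curve() -> sf.StandardCurve:
    """Exact per-cycle doubling curve (efficiency 100%)."""
    slope = -1.0 / np.log10(2.0)
    return sf.StandardCurve(
        channel="AURKA",
        slope=slope,
        intercept=39.0,
        efficiency_pct=sf.efficiency_from_slope(slope),
        r_squared=1.0,
    )


@pytest.fixture
def small_training_data() -> sf.TrainingDataset:
    return sf.simulate_training(sf.TrainingSimConfig(n_per_class=53, seed=7))


@pytest.fixture
def cohort_333_spec() -> sf.CohortCountSpec:
    """The full-cohort contingency structure: 627 records, 4 WHO strata, 3 tiers."""
    return sf.CohortCountSpec(
        who={"normospermic": 342, "one_abnormal": 145, "two_abnormal": 85, "oat": 55},
        tiers={"normal": 257, "intermediate": 26, "low": 344},
    )


def brute_force_pr(scores, labels, thresholds):
    """Independent PR oracle: explicit confusion matrix per threshold."""
    out = []
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    for t in thresholds:
        tp = fp = fn = 0
        for s, y in zip(scores, labels):
            pred = s >= t
            if pred and y == 1:
                tp += 1
            elif pred and y == 0:
                fp += 1
            elif not pred and y == 1:
                fn += 1
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / (tp + fn)
        out.append((t, precision, recall))
    return out


def brute_force_best_f1(scores, labels, band=None):
    """Independent threshold-selection oracle over the full candidate grid."""
    thresholds = sorted(set(list(map(float, scores)) + [0.0, 1.0]))
    best_t, best_f1 = None, -1.0
    for t, p, r in brute_force_pr(scores, labels, thresholds):
        if band is not None and not (band[0] <= t <= band[1]):
            continue
        f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = t, f1
    return best_t
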