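"""Shared fixtures: small synthetic cohorts and feature-table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from paintrace import SimulationConfig, generate_cohort
from paintrace.features import FEATURE_NAMES, META_COLUMNS
from paintrace.session import STATES


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Two-subject, short-session cohort config for fast unit tests."""
    return SimulationConfig(
        n_subjects=2,
        sessions_per_subject_per_state=2,
        n_rois=20,
        duration_s=60.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_feature_table(
    rng: np.random.Generator,
    n_per_class: dict[str, int],
    pain_shift: float = 0.15,
    n_subjects: int = 8,
) -> pd.DataFrame:
    """Feature-level synthetic cohort: random ratio features in [0, 1] with a
    mild upward shift for pain sessions, and a correlation feature."""
    rows = []
    i = 0
    for state in STATES:
        for _ in range(n_per_class.get(state, 0)):
            base = rng.uniform(0.05, 0.45, size=12)
            if state == "pain":
                base = base + pain_shift
            corr = rng.uniform(0.0, 0.3) + (0.3 if state == "analgesic" else 0.0)
            values = np.clip(np.append(base, corr), 0.0, 1.0)
            meta = {
                "session_id": f"s{i:04d}",
                "subject_id": f"m{i % n_subjects:02d}",
                "class_label": state,
                "reference_id": f"ref{i % n_subjects:02d}",
            }
            rows.append({**meta, **dict(zip(FEATURE_NAMES, values))})
            i += 1
    table = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))
    return table.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
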