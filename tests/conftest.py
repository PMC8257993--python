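import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> pd.DataFrame:
    """Three-row well-formed participant table, one missing gestational age."""
    from dhatrial.trial_data import frame_from_records, ParticipantRecord

    return frame_from_records(
        [
            ParticipantRecord("P1", "A", "LOW_200", 0, 5.2, 230, 2100.0, 44.0, 31.0,
                              0, 0, 1, 1, 1, False),
            ParticipantRecord("P2", "B", "HIGH_1000", 1, 7.1, 275, 3400.0, 50.5, 34.2,
                              0, 0, 0, 0, 0, False),
            ParticipantRecord("P3", "C", "LOW_200", 2, 6.0, None, None, None, None,
                              None, None, None, None, None, True),
        ]
    )


def make_counts_table(e_low: int, n_low: int, e_high: int, n_high: int,
                      seed: int = 0) -> pd.DataFrame:
    """Participant table realising exact EPB counts per arm.

    Gestational ages are spread over a few distinct values so the mixture
    model is not degenerate; EPB births sit well below 238 days.
    """
    from dhatrial.trial_data import frame_from_records, ParticipantRecord

    rng = np.random.default_rng(seed)
    recs = []
    i = 0
    for arm, e, n in (("LOW_200", e_low, n_low), ("HIGH_1000", e_high, n_high)):
        for j in range(n):
            ga = int(rng.integers(210, 235)) if j < e else int(rng.integers(255, 290))
            recs.append(
                ParticipantRecord(
                    f"P{i:05d}", "ABC"[i % 3], arm, i % 100,
                    float(np.clip(np.round(rng.normal(6.38, 1.77), 2), 0.5, 24.5)), ga,
                )
            )
            i += 1
    return frame_from_records(recs)
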