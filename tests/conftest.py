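import numpy as np
import pandas as pd
import pytest


def make_cohort(
    followup_days,
    event,
    eolci=None,
    prob=None,
    age=None,
    **categoricals,
) -> pd.DataFrame:
    """Small hand-built cohort table in the canonical schema."""
    n = len(followup_days)
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "eolci_score": eolci if eolci is not None else np.linspace(0, 100, n).round(),
            "stanford_prob": prob if prob is not None else np.linspace(0.05, 0.95, n),
            "followup_days": followup_days,
            "event": event,
            "age": age if age is not None else np.linspace(40, 80, n).round(),
        }
    )
    for col, values in categoricals.items():
        df[col] = values
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort():
    """Six patients with interleaved deaths and censorings."""
    return make_cohort(
        followup_days=[30.0, 91.0, 91.0, 200.0, 365.0, 400.0],
        event=[True, False, True, False, True, False],
        sex=["Female", "Male", "Female", "Male", "Female", "Male"],
    )


def brute_force_auc(scores, labels) -> float:
    """Exhaustive case-control pair enumeration with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    cases = scores[labels]
    ctrls = scores[~labels]
    total = 0.0
    for c in cases:
        for d in ctrls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(ctrls))


def brute_force_cindex(scores, time, event):
    """Exhaustive comparable-pair enumeration of Harrell's C.

    Returns (c_index, n_comparable); pairs with tied event times and both
    events are not comparable, tied scores credit one half.
    """
    n = len(scores)
    conc = 0.0
    comp = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = event[i] and (
                time[i] < time[j] or (time[i] == time[j] and not event[j])
            )
            if not comparable:
                continue
            comp += 1
            if scores[i] > scores[j]:
                conc += 1.0
            elif scores[i] == scores[j]:
                conc += 0.5
    if comp == 0:
        return float("nan"), 0
    return conc / comp, comp
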