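import numpy as np
import pytest

import necsuff as ns


@pytest.fixture
def lung_table() -> ns.TwoByTwoTable:
    """Smoking x lung-cancer-death cohort counts."""
    return ns.lung_cancer_fixture()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_survival() -> ns.SurvivalSample:
    """Tiny two-group censored sample for hand-checkable estimates."""
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    events = np.array([1, 0, 1, 1, 0, 1, 1, 1])
    import pandas as pd

    group = pd.DataFrame({"group": [1, 1, 1, 0, 0, 0, 1, 0]})
    return ns.SurvivalSample(times=times, events=events, covariates=group)


def brute_force_binary(probs, p_bar):
    """Straight-loop arithmetic for DN1, DN2, DS1, DS2 and indirect EV.

    Term-by-term summation of the defining formulas, independent of any
    vectorised code path.
    """
    import math

    s1 = s2 = t1 = t2 = inacc = 0.0
    n_less = n_greater = 0
    for p in probs:
        inacc += p * (1 - p)
        if p < p_bar:
            k = (p_bar - p) / p_bar
            s1 += k * k
            s2 += k
            n_less += 1
        elif p > p_bar:
            k = (p - p_bar) / (1 - p_bar)
            t1 += k * k
            t2 += k
            n_greater += 1
    dn1 = math.sqrt(s1 / n_less) if n_less else 0.0
    dn2 = s2 / n_less if n_less else 0.0
    ds1 = math.sqrt(t1 / n_greater) if n_greater else 0.0
    ds2 = t2 / n_greater if n_greater else 0.0
    ev = 1 - (inacc / len(probs)) / (p_bar * (1 - p_bar))
    return dn1, dn2, ds1, ds2, ev, n_less, n_greater
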