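"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ricotem import CohortSpec, PhenotypeParams, RotemTrace, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged 27-patient synthetic cohort (7/9/6/2/2/1 + controls)."""
    return simulate_cohort(CohortSpec(seed=42))


@pytest.fixture()
def noise_free_params():
    return PhenotypeParams(noise_cv=0.0)


def random_monotone_trace(rng: np.random.Generator) -> RotemTrace:
    """A random non-decreasing trace with irregular sampling."""
    n = int(rng.integers(5, 60))
    t = np.cumsum(rng.uniform(0.5, 60.0, size=n))
    t -= t[0]
    a = np.cumsum(rng.uniform(0.0, 3.0, size=n))
    a -= a[0]
    return RotemTrace("extem", t, a)


def brute_force_crossing(trace: RotemTrace, threshold_mm: float, step_s: float = 1e-3):
    """Dense-grid scan oracle for the first threshold crossing.

    Resamples the piecewise-linear trace on a fine uniform grid and returns
    the first grid time at or past the threshold (accurate to ``step_s``),
    independently of the analytic interpolation in the implementation.
    """
    t = np.arange(trace.times_s[0], trace.times_s[-1] + step_s / 2, step_s)
    a = np.interp(t, trace.times_s, trace.amplitudes_mm)
    idx = np.flatnonzero(a >= threshold_mm)
    if idx.size == 0:
        return None
    return float(t[idx[0]])


def mann_whitney_enumeration(a, b):
    """Full-enumeration oracle for the exact two-sided Mann-Whitney p.

    Enumerates all C(n_a + n_b, n_a) group assignments of the combined
    (tie-free) values, computes the U statistic of the first group for each,
    and doubles the smaller tail probability (the null distribution of U is
    symmetric without ties). Also returns the observed U.
    """
    a, b = list(a), list(b)
    combined = a + b
    n_a, n_b = len(a), len(b)

    def u_stat(group_a, group_b):
        return sum(x > y for x in group_a for y in group_b)

    u_obs = u_stat(a, b)
    us = []
    idx = range(len(combined))
    for pick in itertools.combinations(idx, n_a):
        ga = [combined[i] for i in pick]
        gb = [combined[i] for i in idx if i not in pick]
        us.append(u_stat(ga, gb))
    us = np.asarray(us)
    total = len(us)
    p_low = np.sum(us <= u_obs) / total
    p_high = np.sum(us >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))
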