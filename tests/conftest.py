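"""Shared fixtures and simulation oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ivivsim.be import CrossoverDataset, NCAResult, SubjectOutcome
from ivivsim.trial import cv_to_sigma


def bateman_chain(t, dose, rates):
    """Amount in the last compartment of a first-order chain (all rates distinct).

    Independent closed-form oracle: for the chain dose -> ... -> out with
    rate constants ``rates = (k1, ..., kn)``, the amount in compartment n is
    ``dose * prod(k[:-1]) * sum_i exp(-k_i t) / prod_{j != i}(k_j - k_i)``.
    """
    t = np.asarray(t, dtype=float)
    k = np.asarray(rates, dtype=float)
    out = np.zeros_like(t)
    for i in range(k.size):
        denom = np.prod([k[j] - k[i] for j in range(k.size) if j != i])
        out += np.exp(-k[i] * t) / denom
    return dose * np.prod(k[:-1]) * out


def simulate_crossover(
    n: int,
    gmr: float,
    wsv_cv: float,
    bsv_cv: float,
    rng: np.random.Generator,
) -> CrossoverDataset:
    """Direct lognormal 2x2 crossover data generator (BE-layer oracle).

    Per subject i: ``ln T_i = s_i + ln(gmr) + e``, ``ln R_i = s_i + e'`` with
    subject effects ``s_i ~ N(0, sigma_b^2)`` and within-subject errors
    ``e ~ N(0, sigma_w^2)``, independently for AUC and Cmax.  Sequences are
    alternated for exact balance.
    """
    sw = cv_to_sigma(wsv_cv)
    sb = cv_to_sigma(bsv_cv)
    subjects = []
    for i in range(n):
        seq = "TR" if i % 2 == 0 else "RT"
        s_auc = rng.normal(0.0, sb)
        s_cmax = rng.normal(0.0, sb)
        vals = {
            "T": (
                math.exp(s_auc + math.log(gmr) + rng.normal(0.0, sw)),
                math.exp(s_cmax + math.log(gmr) + rng.normal(0.0, sw)),
            ),
            "R": (
                math.exp(s_auc + rng.normal(0.0, sw)),
                math.exp(s_cmax + rng.normal(0.0, sw)),
            ),
        }
        periods = tuple(
            NCAResult(auc_last=vals[prod][0], cmax=vals[prod][1], tmax=60.0)
            for prod in seq
        )
        subjects.append(SubjectOutcome(i + 1, seq, periods))
    return CrossoverDataset(tuple(subjects))


def round_sig(x: float, n: int) -> float:
    """Round to ``n`` significant figures (decimal half-up, as tables print)."""
    if x == 0:
        return 0.0
    from decimal import ROUND_HALF_UP, Decimal

    exp = math.floor(math.log10(abs(x)))
    quantum = Decimal(1).scaleb(exp - n + 1)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
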