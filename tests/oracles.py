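"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy/statsmodels: the Fisher oracle enumerates
the hypergeometric distribution in exact rational arithmetic, and the BH
oracle applies the step-up definition directly.
"""

from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by full enumeration.

    Fixes both margins, computes every table's exact hypergeometric
    probability as a Fraction, and sums those no more probable than the
    observed table (with the same 1e-7 relative gate the conventional
    implementation uses for ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in support}
    cutoff = pmf[a] * Fraction(10**7 + 1, 10**7)
    return float(sum(p for p in pmf.values() if p <= cutoff))


def bh_step_up_oracle(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values straight from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def bh_rejections_oracle(p_values: list[float], alpha: float) -> set[int]:
    """Classic step-up rejection set: largest k with p_(k) <= k*alpha/m."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p_values[i] <= rank * alpha / m:
            k_star = rank
    return set(order[:k_star])
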