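"""Independent brute-force oracles used to cross-check the implementation."""
from fractions import Fraction
from math import comb


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided conditional exact p-value of a 2x2 table by enumeration.

    Exact rational hypergeometric arithmetic: sums the probabilities of all
    tables with the same margins whose probability does not exceed the
    observed table's (with the conventional 1 + 1e-7 relative slack for
    floating-point table probabilities). Independent of scipy.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    threshold = pmf(a) * Fraction(10**7 + 1, 10**7)
    total = sum((p for x in range(lo, hi + 1)
                 if (p := pmf(x)) <= threshold), Fraction(0))
    return float(total)


def pearson_oracle(xs, ys) -> float:
    """Definition-level Pearson correlation (no numpy)."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / (sxx * syy) ** 0.5
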