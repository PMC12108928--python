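"""Independent reference implementations used only to check the package.

These are deliberately written with a different structure from the library
code: the rainflow oracle rescans the whole sequence from the left after
every extraction instead of using a stack, and the Glinka oracle is plain
interval bisection.  They trade speed for obviousness.
"""

from __future__ import annotations

import math


def brute_force_rainflow(values, tol: float = 1e-9) -> dict[tuple[float, float], float]:
    """Four-point rainflow by repeated left-to-right scanning.

    Any four consecutive turning points whose inner range does not exceed
    either neighbouring range yield one closed cycle; the scan restarts from
    the beginning after each extraction.  Remaining adjacent pairs are
    half-cycles (count 0.5).  Returns {(s_max, s_min): count}.
    """
    seq = [float(v) for v in values]
    counts: dict[tuple[float, float], float] = {}

    def add(x: float, y: float, c: float) -> None:
        hi, lo = max(x, y), min(x, y)
        if hi - lo <= tol:
            return
        for (h, l), _ in counts.items():
            if abs(h - hi) <= tol and abs(l - lo) <= tol:
                counts[(h, l)] += c
                return
        counts[(hi, lo)] = c

    extracted = True
    while extracted:
        extracted = False
        for i in range(len(seq) - 3):
            s1, s2, s3, s4 = seq[i : i + 4]
            inner = abs(s3 - s2)
            if inner <= abs(s2 - s1) and inner <= abs(s4 - s3):
                add(s2, s3, 1.0)
                del seq[i + 1 : i + 3]
                extracted = True
                break
    for x, y in zip(seq, seq[1:]):
        add(x, y, 0.5)
    return counts


def bisect_glinka(s: float, kt: float, e_mod: float, e_exp: float,
                  k_coeff: float, iters: int = 200) -> float:
    """Glinka root by plain bisection on (0, kt*|s|]; sign restored."""
    if s == 0.0:
        return 0.0
    mag = abs(s)
    rhs = (kt * mag) ** 2 / e_mod

    def f(sig: float) -> float:
        return (sig * sig / e_mod
                + (2.0 * sig / (e_exp + 1.0)) * (sig / k_coeff) ** (1.0 / e_exp)
                - rhs)

    lo, hi = 0.0, kt * mag
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return math.copysign(0.5 * (lo + hi), s)


def paris_closed_form(a0: float, delta_sigma: float, c: float, m: float,
                      n: float) -> float:
    """Closed-form crack length after n cycles for da/dN = C (ds*sqrt(pi a))^m.

    Valid for m != 2: a(n) = [a0^(1-m/2) + (1-m/2) C (ds*sqrt(pi))^m n]^(2/(2-m)).
    """
    p = 1.0 - m / 2.0
    base = a0**p + p * c * (delta_sigma * math.sqrt(math.pi)) ** m * n
    return base ** (1.0 / p)
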