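"""Independent brute-force oracle for the discrete information statistics.

Pure-python enumeration of the empirical joint distribution (dicts and
math.log2 only) — deliberately shares no code with the package's vectorized
implementation.
"""

import math
from collections import Counter


def _dist(seq):
    n = len(seq)
    return {k: v / n for k, v in Counter(seq).items()}


def entropy(labels):
    return sum(p * math.log2(1.0 / p) for p in _dist(labels).values() if p > 0)


def mutual_information(x, y):
    px = _dist(x)
    py = _dist(y)
    pxy = _dist(list(zip(x, y)))
    total = 0.0
    for (xi, yi), pj in pxy.items():
        total += pj * math.log2(pj / (px[xi] * py[yi]))
    return total


def specific_information(x_value, s, x):
    """I(X=x; S) = sum_s p(s|x) [log2 1/p(x) - log2 1/p(x|s)]."""
    px = _dist(x)[x_value]
    pairs = [(si, xi) for si, xi in zip(s, x)]
    ps = _dist(s)
    pxs = _dist(pairs)
    total = 0.0
    for si in ps:
        p_joint = pxs.get((si, x_value), 0.0)
        if p_joint == 0.0:
            continue
        p_s_given_x = p_joint / px
        p_x_given_s = p_joint / ps[si]
        total += p_s_given_x * (math.log2(1.0 / px) - math.log2(1.0 / p_x_given_s))
    return total


def minimum_information(x, s1, s2):
    return sum(
        p * min(specific_information(xv, s1, x), specific_information(xv, s2, x))
        for xv, p in _dist(x).items()
    )


def transmission(x, y_past, z_past, z_future):
    joint = list(zip(z_past, y_past))
    return minimum_information(x, z_future, joint) - minimum_information(
        x, z_future, z_past
    )
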