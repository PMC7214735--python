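"""Independent brute-force references used to check the package's numerics.

These deliberately re-derive the same quantities with plain Python loops and
no shared code with the package internals.
"""

import math


def dl_brute(d, var):
    """DerSimonian–Laird pooling written out longhand.

    Returns (d_pooled, se, tau2, Q).
    """
    k = len(d)
    w = [1.0 / v for v in var]
    d_fe = sum(w[i] * d[i] for i in range(k)) / sum(w)
    q = sum(w[i] * (d[i] - d_fe) ** 2 for i in range(k))
    if k == 1:
        tau2 = 0.0
    else:
        c = sum(w) - sum(x * x for x in w) / sum(w)
        tau2 = (q - (k - 1)) / c
        if tau2 < 0:
            tau2 = 0.0
    ws = [1.0 / (var[i] + tau2) for i in range(k)]
    d_re = sum(ws[i] * d[i] for i in range(k)) / sum(ws)
    se = math.sqrt(1.0 / sum(ws))
    return d_re, se, tau2, q


def fixed_effect(d, var):
    """Inverse-variance fixed-effect pooled mean and SE."""
    w = [1.0 / v for v in var]
    return (
        sum(wi * di for wi, di in zip(w, d)) / sum(w),
        math.sqrt(1.0 / sum(w)),
    )
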