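"""Naive, independent re-implementation of the four signal formulas.

Deliberately written from the printed closed forms, term by term, with
no reference to the package's implementation — used only to cross-check
``pvsignal.signal_stats`` on random tables.
"""

import math


def naive_all(a, b, c, d):
    n = a + b + c + d
    out = {}
    ror = (a / c) / (b / d)
    se_ror = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    out["ror"] = ror
    out["ror_low"] = math.exp(math.log(ror) - 1.96 * se_ror)
    out["ror_high"] = math.exp(math.log(ror) + 1.96 * se_ror)

    prr = (a / (a + b)) / (c / (c + d))
    se_prr = math.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
    out["prr"] = prr
    out["prr_low"] = math.exp(math.log(prr) - 1.96 * se_prr)
    out["prr_high"] = math.exp(math.log(prr) + 1.96 * se_prr)
    expected = [
        [(a + b) * (a + c) / n, (a + b) * (b + d) / n],
        [(c + d) * (a + c) / n, (c + d) * (b + d) / n],
    ]
    observed = [[a, b], [c, d]]
    out["chi2_pearson"] = sum(
        (observed[i][j] - expected[i][j]) ** 2 / expected[i][j]
        for i in range(2) for j in range(2)
    )
    out["chi2_yates"] = sum(
        max(abs(observed[i][j] - expected[i][j]) - 0.5, 0.0) ** 2
        / expected[i][j]
        for i in range(2) for j in range(2)
    )

    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    gam = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
    out["ic"] = math.log(a * n / ((a + b) * (a + c))) / math.log(2.0)
    e_ic = (
        math.log(a + g11) + math.log(n + al) + math.log(n + be)
        - math.log(n + gam) - math.log(a + b + a1) - math.log(a + c + b1)
    ) / math.log(2.0)
    v_ic = (
        (n - a + gam - g11) / ((a + g11) * (1 + n + gam))
        + (n - (a + b) + al - a1) / ((a + b + a1) * (1 + n + al))
        + (n - (a + c) + be - b1) / ((a + c + b1) * (1 + n + be))
    ) / math.log(2.0) ** 2
    out["e_ic"] = e_ic
    out["v_ic"] = v_ic
    out["ic_025"] = e_ic - 2.0 * math.sqrt(v_ic)

    ebgm = a * n / ((a + b) * (a + c))
    out["ebgm"] = ebgm
    out["ebgm05"] = math.exp(math.log(ebgm) - 1.64 * se_ror)
    return out
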