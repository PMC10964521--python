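"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit per-cell loops and textbook
formulas, deliberately sharing no code with the package, so agreement
between the two routes is meaningful.
"""

import math


def brute_indices(yp, ys, mean_yp, mean_ys):
    """All six tolerance indices for one genotype, evaluated term by term."""
    si = 1.0 - mean_ys / mean_yp
    return {
        "ssi": (1.0 - ys / yp) / si,
        "tol": yp - ys,
        "mp": (yp + ys) / 2.0,
        "gmp": math.sqrt(yp * ys),
        "sti": (yp * ys) / (mean_yp * mean_yp),
        "hm": (2.0 * yp * ys) / (yp + ys),
    }


def brute_slope(x, y):
    """Least-squares slope of y on x via the normal equations."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)


def brute_anova(cells):
    """Two-factor balanced ANOVA from a g x s x r nested list of values.

    Returns dict with df, ss, ms per source, computed with explicit loops
    over cell and marginal means.
    """
    g = len(cells)
    s = len(cells[0])
    r = len(cells[0][0])
    n = g * s * r
    grand = sum(v for gi in cells for si in gi for v in si) / n
    m_g = [sum(v for si in gi for v in si) / (s * r) for gi in cells]
    m_s = [
        sum(cells[i][j][k] for i in range(g) for k in range(r)) / (g * r)
        for j in range(s)
    ]
    m_gs = [[sum(cells[i][j]) / r for j in range(s)] for i in range(g)]

    ss_g = s * r * sum((m - grand) ** 2 for m in m_g)
    ss_s = g * r * sum((m - grand) ** 2 for m in m_s)
    ss_gs = r * sum(
        (m_gs[i][j] - m_g[i] - m_s[j] + grand) ** 2
        for i in range(g)
        for j in range(s)
    )
    ss_e = sum(
        (cells[i][j][k] - m_gs[i][j]) ** 2
        for i in range(g)
        for j in range(s)
        for k in range(r)
    )
    df = {"G": g - 1, "S": s - 1, "GxS": (g - 1) * (s - 1), "E": g * s * (r - 1)}
    ss = {"G": ss_g, "S": ss_s, "GxS": ss_gs, "E": ss_e}
    ms = {k: ss[k] / df[k] for k in ss}
    return {"df": df, "ss": ss, "ms": ms, "grand_mean": grand}


def brute_duncan_share(values, lsr):
    """Pairwise 'share a letter' matrix by exhaustive range checks.

    ``values`` are the means sorted descending; ``lsr`` maps span p to its
    least significant range.  Two means are *not* separated when any range
    containing both has extremes closer than that range's R_p (the
    protection rule), checked here literally over every containing pair.
    """
    k = len(values)
    share = [[False] * k for _ in range(k)]
    for i in range(k):
        for j in range(i, k):
            nonsig = False
            for a in range(0, i + 1):
                for b in range(j, k):
                    if a == b:
                        nonsig = True  # a single mean is never split
                        continue
                    span = b - a + 1
                    if values[a] - values[b] <= lsr[span]:
                        nonsig = True
            share[i][j] = share[j][i] = nonsig
    return share
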