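"""Brute-force reference implementations used only as test oracles.

Deliberately slow and structurally independent of the package: the
flood fill is a queue-based BFS over explicit pixel lists, hole filling
is a BFS over the border-connected complement, the log-linear fit uses
the normal equations written out by hand, and the ICC comes from
explicit loop-based two-way ANOVA sums of squares.
"""

import math

import numpy as np


def floodfill_roi(image, seed_rc, threshold):
    """8-connected component of {pixel >= threshold} containing the seed,
    then fill every background pocket not reachable from the border."""
    h, w = image.shape
    above = [[image[r][c] >= threshold for c in range(w)] for r in range(h)]
    comp = [[False] * w for _ in range(h)]
    queue = [tuple(seed_rc)]
    comp[seed_rc[0]][seed_rc[1]] = True
    nbrs8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    while queue:
        r, c = queue.pop()
        for dr, dc in nbrs8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and above[rr][cc] and not comp[rr][cc]:
                comp[rr][cc] = True
                queue.append((rr, cc))
    # border-connected complement (4-connectivity, the complement of
    # 8-connected foreground)
    outside = [[False] * w for _ in range(h)]
    queue = []
    for r in range(h):
        for c in (0, w - 1):
            if not comp[r][c]:
                outside[r][c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not comp[r][c]:
                outside[r][c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.pop()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not comp[rr][cc] and not outside[rr][cc]:
                outside[rr][cc] = True
                queue.append((rr, cc))
    filled = np.array(
        [[comp[r][c] or not outside[r][c] for c in range(w)] for r in range(h)]
    )
    return filled


def loglinear_adc(signals, b_values):
    """Slope of ln S on b by the normal equations; returns -slope, floored at 0."""
    xs = [b for b, s in zip(b_values, signals) if s > 0]
    ys = [math.log(s) for s in signals if s > 0]
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    return max(-slope, 0.0)


def icc_two_way(table):
    """All four two-way random-effects ICC point estimates from explicit
    loop-based ANOVA sums of squares."""
    n = len(table)
    k = len(table[0])
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msb = ss_rows / (n - 1)
    msj = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return {
        "agreement_single": (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n),
        "agreement_average": (msb - mse) / (msb + (msj - mse) / n),
        "consistency_single": (msb - mse) / (msb + (k - 1) * mse),
        "consistency_average": (msb - mse) / msb,
    }


def welch_from_summary(m1, s1, n1, m2, s2, n2):
    """Textbook Welch statistic, Satterthwaite df and two-sided p."""
    from scipy.stats import t as tdist

    a = s1 * s1 / n1
    b = s2 * s2 / n2
    t = (m1 - m2) / math.sqrt(a + b)
    df = (a + b) ** 2 / (a * a / (n1 - 1) + b * b / (n2 - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p
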