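"""Independent brute-force re-implementations used only as test oracles.

Everything here is written with plain Python loops against the *definitions*
(Gaussian kernel density, local maxima, ESACP decision rules, cross-product
odds ratios) so the fast vectorized package code can be checked against a
second route.
"""
import math


def naive_density(x, cells, bandwidth):
    return sum(math.exp(-0.5 * ((x - c) / bandwidth) ** 2) for c in cells)


def naive_classify(
    c_values,
    bandwidth=0.1,
    grid_step=0.01,
    min_fraction=0.05,
    min_cells=5,
    diploid=(1.8, 2.2),
    tetraploid=(3.6, 4.4),
    rare_cutoff=9.0,
    doubling_tol=0.10,
):
    """Classify a small specimen by enumerating all candidate KDE modes.

    Returns (classification, reasons, stemline positions).
    """
    cells = sorted(float(c) for c in c_values)
    n = len(cells)
    top = max(cells) + 4 * bandwidth + grid_step
    grid = []
    x = 0.0
    while x < top:
        grid.append(x)
        x += grid_step
    d = [naive_density(g, cells, bandwidth) for g in grid]

    # local maxima, plateau resolved to its middle grid point
    peak_indices = []
    i = 1
    while i < len(d) - 1:
        if d[i] > d[i - 1]:
            j = i
            while j + 1 < len(d) and d[j + 1] == d[i]:
                j += 1
            if j < len(d) - 1 and d[j + 1] < d[i]:
                peak_indices.append((i + j) // 2)
            i = j + 1
        else:
            i += 1

    # topographic prominence: height above the lowest saddle separating the
    # peak from higher ground on either side (signal ends count as ground)
    def prominence(p):
        bases = []
        for direction in (-1, 1):
            i, lowest = p, d[p]
            while 0 <= i < len(d) and d[i] <= d[p]:
                lowest = min(lowest, d[i])
                i += direction
            bases.append(lowest)
        return d[p] - max(bases)

    # prominence floor: 0.4x the height of a minimal admissible stemline
    # concentrated at one point (naive_density is unnormalized, where that
    # height is min_fraction * n)
    floor = 0.4 * min_fraction * n
    peaks = [grid[p] for p in peak_indices if prominence(p) >= floor]
    if not peaks:
        peaks = [grid[max(range(len(d)), key=lambda k: d[k])]]

    # a candidate's cells are those within 2.5 bandwidths of its position;
    # the stemline gate applies to the count in excess of the local
    # continuum estimated from equal-width flanking bands
    window = 2.5 * bandwidth
    stems = []
    for pos in peaks:
        ms = [c for c in cells if abs(c - pos) <= window]
        n_flank = sum(1 for c in cells if window < abs(c - pos) <= 2 * window)
        excess = len(ms) - n_flank
        if excess < min_cells or excess / n < min_fraction:
            continue
        # refine the mode over a fine local grid plus the member values
        candidates = list(ms)
        x = min(ms) - bandwidth
        while x < max(ms) + bandwidth:
            candidates.append(x)
            x += grid_step / 10
        best = max(candidates, key=lambda g: naive_density(g, ms, bandwidth))
        stems.append((best, len(ms)))

    stems.sort(key=lambda s: (-s[1], s[0]))

    def in_euploid(p):
        return diploid[0] <= p <= diploid[1] or tetraploid[0] <= p <= tetraploid[1]

    euploid = [False] * len(stems)
    doubling_of = [None] * len(stems)
    for i, (pos, _) in enumerate(stems):
        best_j, best_err = None, float("inf")
        for j in range(i):
            target = 2.0 * stems[j][0]
            err = abs(pos - target) / target
            if err <= doubling_tol and err < best_err:
                best_j, best_err = j, err
        doubling_of[i] = best_j

    trigger = False
    for i, (pos, _) in enumerate(stems):
        if in_euploid(pos):
            euploid[i] = True
        elif doubling_of[i] is not None and euploid[doubling_of[i]]:
            euploid[i] = True
        else:
            trigger = True

    reasons = []
    if trigger:
        reasons.append("stemline_aneuploidy")
    if any(c > rare_cutoff for c in cells):
        reasons.append("single_cell_aneuploidy")
    cls = "aneuploid" if reasons else "non_aneuploid"
    return cls, reasons, [s[0] for s in stems]


def naive_or_2x2(a, b, c, d):
    """Cross-product odds ratio of a 2x2 outcome-by-exposure table."""
    return (a * d) / (b * c)
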