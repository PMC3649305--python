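"""Independent brute-force oracles used by the test suite.

Every function here deliberately avoids the library code paths (and
scipy morphology/labeling) so that agreement between an oracle and the
implementation is meaningful.
"""

from __future__ import annotations

import numpy as np


def flood_fill_regions(slice_2d, connectivity=8):
    """Brute-force per-slice connected components via BFS flood fill.

    Returns a list of pixel frozensets {(x, y), ...}, one per region.
    """
    h, w = slice_2d.shape
    if connectivity == 8:
        offsets = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                   if (dx, dy) != (0, 0)]
    else:
        offsets = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    seen = set()
    regions = []
    for y in range(h):
        for x in range(w):
            if slice_2d[y, x] and (x, y) not in seen:
                stack = [(x, y)]
                comp = set()
                seen.add((x, y))
                while stack:
                    px, py = stack.pop()
                    comp.add((px, py))
                    for dx, dy in offsets:
                        nx, ny = px + dx, py + dy
                        if 0 <= nx < w and 0 <= ny < h \
                                and slice_2d[ny, nx] \
                                and (nx, ny) not in seen:
                            seen.add((nx, ny))
                            stack.append((nx, ny))
                regions.append(frozenset(comp))
    return regions


def moment_matching_cut(values, masses):
    """Exhaustive bilevel moment-discrepancy minimization.

    For every cut index k (below class = values[:k+1]) the below/above
    class means and mass fractions define a bilevel image; the cut
    minimizing the squared discrepancy of the 2nd and 3rd moments (the
    1st is preserved by construction) is returned along with the
    discrepancy at every cut.
    """
    values = np.asarray(values, dtype=float)
    masses = np.asarray(masses, dtype=float)
    masses = masses / masses.sum()
    m2 = float(np.sum(masses * values ** 2))
    m3 = float(np.sum(masses * values ** 3))
    scale2 = max(abs(m2), 1.0)
    scale3 = max(abs(m3), 1.0)
    discrepancies = []
    for k in range(len(values) - 1):
        p0 = masses[:k + 1].sum()
        p1 = 1.0 - p0
        z0 = np.sum(masses[:k + 1] * values[:k + 1]) / p0
        z1 = np.sum(masses[k + 1:] * values[k + 1:]) / p1
        d2 = (p0 * z0 ** 2 + p1 * z1 ** 2 - m2) / scale2
        d3 = (p0 * z0 ** 3 + p1 * z1 ** 3 - m3) / scale3
        discrepancies.append(d2 * d2 + d3 * d3)
    best = int(np.argmin(discrepancies))
    return best, discrepancies


def otsu_best_partitions(values):
    """All value-cuts maximizing between-class variance, by plain loops."""
    values = sorted(float(v) for v in values)
    distinct = sorted(set(values))
    best = []
    best_bcv = -1.0
    for cut in distinct[:-1]:
        lo = [v for v in values if v <= cut]
        hi = [v for v in values if v > cut]
        mu_lo = sum(lo) / len(lo)
        mu_hi = sum(hi) / len(hi)
        bcv = len(lo) * len(hi) * (mu_lo - mu_hi) ** 2
        if bcv > best_bcv + 1e-9:
            best_bcv = bcv
            best = [cut]
        elif abs(bcv - best_bcv) <= 1e-9:
            best.append(cut)
    return best, best_bcv


def synchronous_dilation_split(M, refs):
    """Pure-python synchronous seeded growth with dam detection.

    Mirrors the dam-splitting contract: each reference region grows one
    8-neighbourhood step per round inside M; pixels reached by several
    fronts in the same round become dams and block growth.  Returns
    (parts, dams) with parts the final per-label grown sets plus the
    8-connected components of any pixels left unreached behind dams.
    """
    M = set(M)
    labels = {}
    for k, ref in enumerate(refs):
        for p in ref:
            labels[p] = k
    dams = set()
    offsets = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               if (dx, dy) != (0, 0)]
    while True:
        claims = {}
        for (x, y), k in labels.items():
            for dx, dy in offsets:
                q = (x + dx, y + dy)
                if q in M and q not in labels and q not in dams:
                    claims.setdefault(q, set()).add(k)
        if not claims:
            break
        for q, ks in claims.items():
            if len(ks) == 1:
                labels[q] = next(iter(ks))
            else:
                dams.add(q)
    parts = []
    for k in range(len(refs)):
        part = frozenset(p for p, lab in labels.items() if lab == k)
        if part:
            parts.append(part)
    unreached = M - dams - set(labels)
    seen = set()
    for p in sorted(unreached):
        if p in seen:
            continue
        stack = [p]
        comp = set()
        seen.add(p)
        while stack:
            x, y = stack.pop()
            comp.add((x, y))
            for dx, dy in offsets:
                q = (x + dx, y + dy)
                if q in unreached and q not in seen:
                    seen.add(q)
                    stack.append(q)
        parts.append(frozenset(comp))
    return parts, frozenset(dams)


def erode(pixels, element_offsets):
    """Binary erosion of a pixel set by explicit element offsets."""
    pixels = set(pixels)
    return {p for p in pixels
            if all((p[0] + dx, p[1] + dy) in pixels
                   for dx, dy in element_offsets)}


def dilate(pixels, element_offsets):
    """Binary dilation of a pixel set by explicit element offsets."""
    out = set()
    for x, y in pixels:
        for dx, dy in element_offsets:
            out.add((x + dx, y + dy))
    return out


def square_offsets(size):
    r = size // 2
    return [(dx, dy) for dx in range(-r, r + 1) for dy in range(-r, r + 1)]


def cronbach_alpha_bruteforce(matrix):
    """Direct transcription of the alpha formula with explicit loops.

    Rows are raters, columns are items; sample variances.
    """
    matrix = [list(map(float, row)) for row in matrix]
    n_raters = len(matrix)
    k = len(matrix[0])

    def sample_var(xs):
        mean = sum(xs) / len(xs)
        return sum((x - mean) ** 2 for x in xs) / (len(xs) - 1)

    item_var_sum = 0.0
    for i in range(k):
        item_var_sum += sample_var([matrix[r][i] for r in range(n_raters)])
    totals = [sum(matrix[r]) for r in range(n_raters)]
    total_var = sample_var(totals)
    return k / (k - 1) * (1.0 - item_var_sum / total_var)


def flood_fill_3d_6conn(volume, seeds):
    """3D BFS region growing with 6-connectivity from seed coordinates."""
    volume = np.asarray(volume, dtype=bool)
    nz, ny, nx = volume.shape
    seen = set()
    stack = [s for s in seeds if volume[s]]
    seen.update(stack)
    while stack:
        z, y, x = stack.pop()
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            q = (z + dz, y + dy, x + dx)
            if 0 <= q[0] < nz and 0 <= q[1] < ny and 0 <= q[2] < nx \
                    and volume[q] and q not in seen:
                seen.add(q)
                stack.append(q)
    return seen
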