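"""Independent naive reference implementations used only by tests.

Deliberately slow and simple-minded — explicit loops, flood fill by
hand — so they share no code path with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_patches(values: np.ndarray, nodata: int, connectivity: int):
    """Label same-class connected components by BFS flood fill.

    Returns (labels array, {label: class code}, {label: cell count}).
    """
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    rows, cols = values.shape
    labels = np.zeros_like(values, dtype=int)
    patch_class: dict[int, int] = {}
    patch_cells: dict[int, int] = {}
    next_label = 0
    for r in range(rows):
        for c in range(cols):
            if values[r, c] == nodata or labels[r, c] != 0:
                continue
            next_label += 1
            code = values[r, c]
            patch_class[next_label] = int(code)
            count = 0
            queue = deque([(r, c)])
            labels[r, c] = next_label
            while queue:
                i, j = queue.popleft()
                count += 1
                for di, dj in nbrs:
                    ni, nj = i + di, j + dj
                    if (
                        0 <= ni < rows and 0 <= nj < cols
                        and labels[ni, nj] == 0 and values[ni, nj] == code
                    ):
                        labels[ni, nj] = next_label
                        queue.append((ni, nj))
            patch_cells[next_label] = count
    return labels, patch_class, patch_cells


def naive_class_metrics(values, nodata, cell_size_m, codes, connectivity=8):
    """Cell-by-cell recomputation of CA/NP/PD/PLAND/LPI/MPS per class code.

    Units match the package: CA/MPS in ha, PD per 100 ha, PLAND/LPI in %.
    """
    _, patch_class, patch_cells = flood_fill_patches(values, nodata, connectivity)
    cell_ha = cell_size_m * cell_size_m / 1e4
    total_cells = sum(
        1
        for r in range(values.shape[0])
        for c in range(values.shape[1])
        if values[r, c] != nodata
    )
    total_ha = total_cells * cell_ha
    out = {}
    for code in codes:
        cells = int((values == code).sum())
        sizes = [n for lab, n in patch_cells.items() if patch_class[lab] == code]
        ca = cells * cell_ha
        np_ = len(sizes)
        out[code] = {
            "CA": ca,
            "NP": np_,
            "PD": np_ / (total_ha / 100.0),
            "PLAND": 100.0 * ca / total_ha,
            "LPI": 100.0 * max(sizes) * cell_ha / total_ha if sizes else 0.0,
            "MPS": ca / np_ if np_ else float("nan"),
        }
    return out


def naive_transfer(a_values, b_values, nodata, cell_size_m, codes):
    """Loop-based area cross-tabulation in km² (rows = epoch-1 class)."""
    k = len(codes)
    pos = {c: i for i, c in enumerate(codes)}
    A = [[0.0] * k for _ in range(k)]
    cell_km2 = cell_size_m * cell_size_m / 1e6
    for r in range(a_values.shape[0]):
        for c in range(a_values.shape[1]):
            va, vb = a_values[r, c], b_values[r, c]
            if va == nodata or vb == nodata:
                continue
            A[pos[va]][pos[vb]] += cell_km2
    return np.array(A)


def naive_grey(reference, comparisons, rho):
    """Double-loop Deng grey relational coefficients and degrees.

    ``comparisons``: {name: list of values}.  Returns ({name: [xi...]},
    {name: R}).
    """
    deltas = {
        m: [abs(x0 - xm) for x0, xm in zip(reference, series)]
        for m, series in comparisons.items()
    }
    all_d = [d for ds in deltas.values() for d in ds]
    dmin, dmax = min(all_d), max(all_d)
    xi = {}
    for m, ds in deltas.items():
        if dmax == 0:
            xi[m] = [1.0] * len(ds)
        else:
            xi[m] = [(dmin + rho * dmax) / (d + rho * dmax) for d in ds]
    R = {m: sum(v) / len(v) for m, v in xi.items()}
    return xi, R


def naive_entropy_weights(matrix):
    """Textbook entropy weights for a non-negative observations × indicators
    list-of-lists."""
    n = len(matrix)
    m = len(matrix[0])
    d = []
    for j in range(m):
        col = [row[j] for row in matrix]
        s = sum(col)
        if s <= 0:
            d.append(0.0)
            continue
        e = 0.0
        for x in col:
            p = x / s
            if p > 0:
                e -= p * math.log(p)
        e /= math.log(n)
        d.append(1.0 - e)
    total = sum(d)
    if total <= 0:
        return [1.0 / m] * m
    return [x / total for x in d]


def naive_topsis(matrix, polarities=None):
    """Loop-based min-max + entropy + TOPSIS on a list-of-lists panel.

    Returns (closeness list, rank list) with competition ranking.
    """
    n, m = len(matrix), len(matrix[0])
    polarities = polarities or ["benefit"] * m
    norm = [[0.0] * m for _ in range(n)]
    for j in range(m):
        col = [row[j] for row in matrix]
        lo, hi = min(col), max(col)
        for i in range(n):
            if hi == lo:
                z = 0.0
            else:
                z = (matrix[i][j] - lo) / (hi - lo)
                if polarities[j] == "cost":
                    z = 1.0 - z
            norm[i][j] = z
    w = naive_entropy_weights(norm)
    weighted = [[w[j] * norm[i][j] for j in range(m)] for i in range(n)]
    qp = [max(weighted[i][j] for i in range(n)) for j in range(m)]
    qm = [min(weighted[i][j] for i in range(n)) for j in range(m)]
    closeness = []
    for i in range(n):
        dp = math.sqrt(sum((qp[j] - weighted[i][j]) ** 2 for j in range(m)))
        dm = math.sqrt(sum((qm[j] - weighted[i][j]) ** 2 for j in range(m)))
        closeness.append(0.5 if dp + dm == 0 else dm / (dp + dm))
    ranks = [1 + sum(1 for other in closeness if other > c) for c in closeness]
    return closeness, ranks
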