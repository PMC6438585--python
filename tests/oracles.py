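"""Independent brute-force oracles for the texture matrices and the
statistical tests.

Everything here is a literal nested-loop enumeration written directly from
the definitions, deliberately ignoring the vectorized implementations it
checks.  Only usable on tiny grids.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_brute(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Ordered-pair counts over the 26 unit offsets (13 directions, both
    signs): a double loop over every voxel and offset."""
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    offsets = OFFSETS_13 + [tuple(-d for d in o) for o in OFFSETS_13]
    for p in itertools.product(*(range(n) for n in levels.shape)):
        if not mask[p]:
            continue
        for off in offsets:
            q = tuple(a + b for a, b in zip(p, off))
            if _in(levels.shape, q) and mask[q]:
                counts[levels[p] - 1, levels[q] - 1] += 1
    return counts


def glrlm_brute(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                max_len: int) -> np.ndarray:
    """Run-length counts by walking every line in every direction."""
    counts = np.zeros((n_levels, max_len), dtype=np.int64)
    shape = levels.shape
    for off in OFFSETS_13:
        back = tuple(-d for d in off)
        for p in itertools.product(*(range(n) for n in shape)):
            if not mask[p]:
                continue
            prev = tuple(a + b for a, b in zip(p, back))
            # run start: predecessor absent or different level
            if _in(shape, prev) and mask[prev] and levels[prev] == levels[p]:
                continue
            length = 1
            cur = p
            while True:
                nxt = tuple(a + b for a, b in zip(cur, off))
                if _in(shape, nxt) and mask[nxt] and levels[nxt] == levels[cur]:
                    length += 1
                    cur = nxt
                else:
                    break
            counts[levels[p] - 1, length - 1] += 1
    return counts


def ngldm_brute(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Dependence matrix plus the per-level |level - neighborhood mean| sums."""
    q = np.zeros((n_levels, 27), dtype=np.int64)
    s = np.zeros(n_levels, dtype=np.float64)
    n_i = np.zeros(n_levels, dtype=np.int64)
    for p in itertools.product(*(range(n) for n in levels.shape)):
        if not mask[p]:
            continue
        neigh = []
        for off in NEIGHBORS_26:
            qp = tuple(a + b for a, b in zip(p, off))
            if _in(levels.shape, qp) and mask[qp]:
                neigh.append(levels[qp])
        dep = sum(1 for lv in neigh if lv == levels[p])
        q[levels[p] - 1, dep] += 1
        if neigh:
            s[levels[p] - 1] += abs(levels[p] - float(np.mean(neigh)))
            n_i[levels[p] - 1] += 1
    return q, s, n_i


def glzlm_brute(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts by explicit flood fill over 26-connectivity."""
    n_vox = int(mask.sum())
    counts = np.zeros((n_levels, n_vox), dtype=np.int64)
    seen = np.zeros(levels.shape, dtype=bool)
    for p in itertools.product(*(range(n) for n in levels.shape)):
        if not mask[p] or seen[p]:
            continue
        stack, zone = [p], []
        seen[p] = True
        while stack:
            cur = stack.pop()
            zone.append(cur)
            for off in NEIGHBORS_26:
                q = tuple(a + b for a, b in zip(cur, off))
                if (_in(levels.shape, q) and mask[q] and not seen[q]
                        and levels[q] == levels[cur]):
                    seen[q] = True
                    stack.append(q)
        counts[levels[p] - 1, len(zone) - 1] += 1
    return counts


def friedman_brute(values: np.ndarray):
    """Friedman chi-square from first principles (average ranks on ties)."""
    n, k = values.shape
    ranks = np.empty_like(values, dtype=float)
    for row in range(n):
        order = values[row]
        for col in range(k):
            less = np.sum(order < order[col])
            equal = np.sum(order == order[col])
            ranks[row, col] = less + (equal + 1) / 2.0
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)


def wilcoxon_exact_brute(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments
    (requires distinct non-zero |differences|, n <= 14)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = float(ranks[d > 0].sum())
    total = 0
    count_le = 0
    count_ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        total += 1
        count_le += w <= w_plus
        count_ge += w >= w_plus
    p = 2.0 * min(count_le, count_ge) / total
    return min(p, 1.0)


def icc21_brute(y1: np.ndarray, y2: np.ndarray) -> float:
    """ICC(2,1) through an explicit two-way ANOVA decomposition."""
    data = np.column_stack([y1, y2]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * sum((data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
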