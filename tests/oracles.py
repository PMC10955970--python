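"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (per-pixel loops, flood fill,
pairwise enumeration) kept free of any code from the package's own
feature/ROC paths.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12
_COARSENESS_CAP = 1e6


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """Direct per-pixel Amadasun-King NGTDM summation."""
    rows, cols = levels.shape
    n = np.zeros(n_levels + 1)
    s = np.zeros(n_levels + 1)
    N = 0
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            nbrs = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]:
                        nbrs.append(levels[rr, cc])
            if not nbrs:
                continue
            N += 1
            i = levels[r, c]
            n[i] += 1
            s[i] += abs(i - float(np.mean(nbrs)))
    if N == 0:
        return {k: np.nan for k in ("coarseness", "contrast", "busyness", "complexity", "strength")}
    p = n / N
    i_idx = [i for i in range(1, n_levels + 1) if p[i] > 0]
    Ngp = len(i_idx)

    coarseness = min(1.0 / (sum(p[i] * s[i] for i in range(1, n_levels + 1)) + _EPS),
                     _COARSENESS_CAP)
    if Ngp <= 1:
        contrast = 0.0
        busyness = 0.0
    else:
        pair = sum(p[i] * p[j] * (i - j) ** 2 for i in i_idx for j in i_idx)
        contrast = pair / (Ngp * (Ngp - 1)) * (sum(s[1:]) / N)
        denom = sum(abs(i * p[i] - j * p[j]) for i in i_idx for j in i_idx)
        busyness = sum(p[i] * s[i] for i in i_idx) / (denom + _EPS)
    complexity = sum(
        abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
        for i in i_idx for j in i_idx
    ) / N
    strength = sum((p[i] + p[j]) * (i - j) ** 2 for i in i_idx for j in i_idx) / (
        sum(s[1:]) + _EPS
    )
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness,
            "complexity": complexity, "strength": strength}


def _flood_zones(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[tuple[int, int]]:
    """(level, size) of every 8-connected same-level zone, by flood fill."""
    rows, cols = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or seen[r, c]:
                continue
            g = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (0 <= r2 < rows and 0 <= c2 < cols and mask[r2, c2]
                                and not seen[r2, c2] and levels[r2, c2] == g):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((int(g), size))
    return zones


def brute_glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """GLSZM scalars from independently flood-filled zones."""
    zones = _flood_zones(levels, mask, n_levels)
    Nz = len(zones)
    if Nz == 0:
        return {k: np.nan for k in ("sze", "lze", "zsn", "zse", "lzhge", "gln")}
    sze = sum(1.0 / s**2 for _, s in zones) / Nz
    lze = sum(float(s) ** 2 for _, s in zones) / Nz
    from collections import Counter

    by_size = Counter(s for _, s in zones)
    zsn = sum(v**2 for v in by_size.values()) / Nz
    by_cell = Counter(zones)
    zse = -sum((v / Nz) * np.log2(v / Nz) for v in by_cell.values())
    lzhge = sum(float(s) ** 2 * float(g) ** 2 for g, s in zones) / Nz
    by_level = Counter(g for g, _ in zones)
    gln = sum(v**2 for v in by_level.values()) / Nz
    return {"sze": sze, "lze": lze, "zsn": zsn, "zse": zse, "lzhge": lzhge, "gln": gln}


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the pairwise concordance statistic (ties count half)."""
    pos = np.asarray(scores)[np.asarray(labels, dtype=bool)]
    neg = np.asarray(scores)[~np.asarray(labels, dtype=bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass Pearson correlation, independent of pandas/numpy corr."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = float(np.sum((x - mx) * (y - my)))
    den = float(np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2)))
    return num / den
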