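"""Brute-force enumeration oracles for texture matrices and features.

Everything here is written as plain nested loops over voxels, pairs and
matrix entries, independent of the vectorised implementation it checks.
Intended for hand-checkable grids (a few hundred voxels at most).
"""

from __future__ import annotations

import math

import numpy as np

DIRS = [(dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)]
DIRS_26 = [(dx, dy, dz)
           for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
           if (dx, dy, dz) != (0, 0, 0)]


def glcm_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    out = np.zeros((ng + 1, ng + 1))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for dx, dy, dz in DIRS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz:
                        b = levels[u, v, w]
                        if b > 0:
                            out[a, b] += 1
    return out


def glrlm_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    nx, ny, nz = levels.shape
    max_len = int(math.ceil(math.sqrt(nx * nx + ny * ny + nz * nz))) + 1
    out = np.zeros((ng + 1, max_len + 1))
    for d in DIRS:
        dx, dy, dz = d
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    g = levels[x, y, z]
                    if g == 0:
                        continue
                    # only start a run when the predecessor breaks it
                    px, py, pz = x - dx, y - dy, z - dz
                    if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz \
                            and levels[px, py, pz] == g:
                        continue
                    length = 1
                    u, v, w = x + dx, y + dy, z + dz
                    while 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                            and levels[u, v, w] == g:
                        length += 1
                        u, v, w = u + dx, v + dy, w + dz
                    out[g, length] += 1
    return out


def glszm_brute(levels: np.ndarray, ng: int, n_voxels: int) -> np.ndarray:
    out = np.zeros((ng + 1, n_voxels + 1))
    seen = np.zeros(levels.shape, dtype=bool)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = levels[x, y, z]
                if g == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in DIRS_26:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                                and not seen[u, v, w] and levels[u, v, w] == g:
                            seen[u, v, w] = True
                            stack.append((u, v, w))
                out[g, size] += 1
    return out


def ngtdm_brute(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    s = np.zeros(ng + 1)
    n = np.zeros(ng + 1)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = levels[x, y, z]
                if g == 0:
                    continue
                neigh = []
                for dx, dy, dz in DIRS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                            and levels[u, v, w] > 0:
                        neigh.append(levels[u, v, w])
                if neigh:
                    s[g] += abs(g - sum(neigh) / len(neigh))
                    n[g] += 1
    return s, n


# --- features, as literal double sums over matrix entries -------------------

def glcm_features_brute(glcm: np.ndarray) -> dict:
    total = glcm.sum()
    p = glcm / total
    ng = glcm.shape[0] - 1
    mu = sum(i * p[i, j] for i in range(ng + 1) for j in range(ng + 1))
    var = sum((i - mu) ** 2 * p[i, j] for i in range(ng + 1) for j in range(ng + 1))
    out = {
        "energy": sum(p[i, j] ** 2 for i in range(ng + 1) for j in range(ng + 1)),
        "contrast": sum((i - j) ** 2 * p[i, j] for i in range(ng + 1) for j in range(ng + 1)),
        "entropy": -sum(p[i, j] * math.log2(p[i, j])
                        for i in range(ng + 1) for j in range(ng + 1) if p[i, j] > 0),
        "homogeneity": sum(p[i, j] / (1 + abs(i - j))
                           for i in range(ng + 1) for j in range(ng + 1)),
        "sum_average": sum((i + j) * p[i, j] for i in range(ng + 1) for j in range(ng + 1)),
        "variance": var,
        "dissimilarity": sum(abs(i - j) * p[i, j]
                             for i in range(ng + 1) for j in range(ng + 1)),
        "autocorrelation": sum(i * j * p[i, j]
                               for i in range(ng + 1) for j in range(ng + 1)),
    }
    if var > 0:
        out["correlation"] = sum((i - mu) * (j - mu) * p[i, j]
                                 for i in range(ng + 1) for j in range(ng + 1)) / var
    else:
        out["correlation"] = math.nan
    return out


def _rz_features_brute(mat: np.ndarray, n_voxels: int, kind: str) -> dict:
    total = mat.sum()
    ng = mat.shape[0] - 1
    lm = mat.shape[1] - 1
    entries = [(g, l, mat[g, l]) for g in range(1, ng + 1)
               for l in range(1, lm + 1) if mat[g, l] > 0]
    mu_g = sum(c * g for g, l, c in entries) / total
    mu_l = sum(c * l for g, l, c in entries) / total
    short, long_ = ("sre", "lre") if kind == "r" else ("sze", "lze")
    nunif = "rln" if kind == "r" else "zsn"
    pct = "rp" if kind == "r" else "zp"
    lg, hg = ("lgre", "hgre") if kind == "r" else ("lgze", "hgze")
    sl, sh = ("srlge", "srhge") if kind == "r" else ("szlge", "szhge")
    ll, lh = ("lrlge", "lrhge") if kind == "r" else ("lzlge", "lzhge")
    lv = "rlv" if kind == "r" else "zsv"
    return {
        short: sum(c / l ** 2 for g, l, c in entries) / total,
        long_: sum(c * l ** 2 for g, l, c in entries) / total,
        "gln": sum(mat[g, :].sum() ** 2 for g in range(1, ng + 1)) / total,
        nunif: sum(mat[:, l].sum() ** 2 for l in range(1, lm + 1)) / total,
        pct: total / n_voxels,
        lg: sum(c / g ** 2 for g, l, c in entries) / total,
        hg: sum(c * g ** 2 for g, l, c in entries) / total,
        sl: sum(c / (g ** 2 * l ** 2) for g, l, c in entries) / total,
        sh: sum(c * g ** 2 / l ** 2 for g, l, c in entries) / total,
        ll: sum(c * l ** 2 / g ** 2 for g, l, c in entries) / total,
        lh: sum(c * g ** 2 * l ** 2 for g, l, c in entries) / total,
        "glv": sum(c * (g - mu_g) ** 2 for g, l, c in entries) / total,
        lv: sum(c * (l - mu_l) ** 2 for g, l, c in entries) / total,
    }


def glrlm_features_brute(mat, n_voxels):
    return _rz_features_brute(mat, n_voxels, "r")


def glszm_features_brute(mat, n_voxels):
    return _rz_features_brute(mat, n_voxels, "z")


def ngtdm_features_brute(s: np.ndarray, n: np.ndarray, n_voxels: int) -> dict:
    total = n.sum()
    ng = len(n) - 1
    p = n / total
    levels = [i for i in range(ng + 1) if p[i] > 0]
    ngp = len(levels)
    out = {}
    denom = sum(p[i] * s[i] for i in levels)
    out["coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        out["contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in levels for j in levels)
            / (ngp * (ngp - 1)) * (sum(s[i] for i in levels) / total))
        bden = sum(abs(i * p[i] - j * p[j]) for i in levels for j in levels)
        out["busyness"] = denom / bden if bden > 0 else math.nan
        out["complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in levels for j in levels) / total
        stot = sum(s[i] for i in levels)
        out["strength"] = (sum((p[i] + p[j]) * (i - j) ** 2
                               for i in levels for j in levels) / stot
                           if stot > 0 else 0.0)
    else:
        out.update(contrast=math.nan, busyness=math.nan,
                   complexity=math.nan, strength=math.nan)
    return out
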