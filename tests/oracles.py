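"""Independent brute-force oracles for texture features.

Everything here is computed by explicit Python loops straight from the
matrix definitions (voxel-pair enumeration, line scanning, flood fill,
neighbourhood gathering) — deliberately slow and deliberately sharing no
code with the package implementation.
"""

import math
from collections import deque

import numpy as np

DIRS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1), (1, 0, 0),
    (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]
DIRS_26 = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
           for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]


def _inb(v, shape):
    return all(0 <= v[a] < shape[a] for a in range(3))


def log2(x):
    return math.log2(x) if x > 0 else 0.0


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def cooccurrence_matrix(levels, mask, d, ng):
    P = np.zeros((ng, ng))
    for v in np.ndindex(levels.shape):
        if not mask[v]:
            continue
        w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
        if _inb(w, levels.shape) and mask[w]:
            P[levels[v] - 1, levels[w] - 1] += 1
    P = P + P.T
    s = P.sum()
    return P / s if s > 0 else None


def glcm_oracle(levels, mask):
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())
    per_dir = []
    for d in DIRS_13:
        p = cooccurrence_matrix(levels, mask, d, ng)
        if p is None:
            continue
        per_dir.append(_glcm_feats(p, ng))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _glcm_feats(p, ng):
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    sigx2 = sum((i + 1 - ux) ** 2 * px[i] for i in range(ng))
    psum = [0.0] * (2 * ng - 1)
    pdiff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            psum[i + j] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]
    autoc = sum((i + 1) * (j + 1) * p[i][j]
                for i in range(ng) for j in range(ng))
    corr = (autoc - ux * ux) / sigx2 if sigx2 > 0 else 1.0
    da = sum(k * pdiff[k] for k in range(ng))
    hxy = -sum(p[i][j] * log2(p[i][j])
               for i in range(ng) for j in range(ng))
    hx = -sum(px[i] * log2(px[i]) for i in range(ng))
    hxy1 = -sum(p[i][j] * log2(px[i] * px[j])
                for i in range(ng) for j in range(ng))
    hxy2 = -sum(px[i] * px[j] * log2(px[i] * px[j])
                for i in range(ng) for j in range(ng))
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    occ = [i for i in range(ng) if px[i] > 0]
    if len(occ) > 1:
        q = np.zeros((len(occ), len(occ)))
        for a, i in enumerate(occ):
            for b, j in enumerate(occ):
                q[a, b] = sum(p[i][k] * p[j][k] / (px[i] * px[k])
                              for k in occ)
        eigs = sorted(abs(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, min(eigs[-2], 1.0)))
    else:
        mcc = 1.0
    return {
        "Autocorrelation": autoc,
        "ClusterProminence": sum((i + j + 2 - 2 * ux) ** 4 * p[i][j]
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum((i + j + 2 - 2 * ux) ** 3 * p[i][j]
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum((i + j + 2 - 2 * ux) ** 2 * p[i][j]
                               for i in range(ng) for j in range(ng)),
        "Contrast": sum((i - j) ** 2 * p[i][j]
                        for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(pdiff[k] * log2(pdiff[k])
                                  for k in range(ng)),
        "DifferenceVariance": sum((k - da) ** 2 * pdiff[k]
                                  for k in range(ng)),
        "Id": sum(p[i][j] / (1 + abs(i - j))
                  for i in range(ng) for j in range(ng)),
        "Idm": sum(p[i][j] / (1 + (i - j) ** 2)
                   for i in range(ng) for j in range(ng)),
        "Idmn": sum(p[i][j] / (1 + ((i - j) / ng) ** 2)
                    for i in range(ng) for j in range(ng)),
        "Idn": sum(p[i][j] / (1 + abs(i - j) / ng)
                   for i in range(ng) for j in range(ng)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(p[i][j] / (i - j) ** 2
                               for i in range(ng) for j in range(ng)
                               if i != j),
        "JointAverage": ux,
        "JointEnergy": sum(p[i][j] ** 2
                           for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "MaximumProbability": max(p[i][j]
                                  for i in range(ng) for j in range(ng)),
        "MCC": mcc,
        "SumAverage": sum((k + 2) * psum[k] for k in range(2 * ng - 1)),
        "SumEntropy": -sum(psum[k] * log2(psum[k])
                           for k in range(2 * ng - 1)),
        "SumSquares": sigx2,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def run_length_runs(levels, mask, d):
    """Enumerate (gray level, run length) by walking each line."""
    levels = np.where(mask, levels, 0)
    runs = []
    for v in np.ndindex(levels.shape):
        if levels[v] == 0:
            continue
        prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
        if _inb(prev, levels.shape) and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
        while _inb(w, levels.shape) and levels[w] == levels[v]:
            length += 1
            w = (w[0] + d[0], w[1] + d[1], w[2] + d[2])
        runs.append((int(levels[v]), length))
    return runs


def glrlm_oracle(levels, mask):
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())
    n_vox = int(mask.sum())
    per_dir = []
    for d in DIRS_13:
        runs = run_length_runs(levels, mask, d)
        per_dir.append(_rl_feats(runs, ng, n_vox))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _rl_feats(runs, ng, n_vox):
    nr = len(runs)
    nl = max(l for _, l in runs)
    P = np.zeros((ng, nl))
    for g, l in runs:
        P[g - 1, l - 1] += 1
    pg = [sum(P[g]) for g in range(ng)]
    pl = [sum(P[:, l]) for l in range(nl)]
    mu_g = sum((g + 1) * P[g][l] for g in range(ng) for l in range(nl)) / nr
    mu_l = sum((l + 1) * P[g][l] for g in range(ng) for l in range(nl)) / nr
    S = lambda f: sum(f(g + 1, l + 1) * P[g][l]
                      for g in range(ng) for l in range(nl)) / nr
    return {
        "GrayLevelNonUniformity": sum(x**2 for x in pg) / nr,
        "GrayLevelNonUniformityNormalized": sum(x**2 for x in pg) / nr**2,
        "GrayLevelVariance": S(lambda g, l: (g - mu_g) ** 2),
        "HighGrayLevelRunEmphasis": S(lambda g, l: g**2),
        "LongRunEmphasis": S(lambda g, l: l**2),
        "LongRunHighGrayLevelEmphasis": S(lambda g, l: g**2 * l**2),
        "LongRunLowGrayLevelEmphasis": S(lambda g, l: l**2 / g**2),
        "LowGrayLevelRunEmphasis": S(lambda g, l: 1.0 / g**2),
        "RunEntropy": -sum((P[g][l] / nr) * log2(P[g][l] / nr)
                           for g in range(ng) for l in range(nl)),
        "RunLengthNonUniformity": sum(x**2 for x in pl) / nr,
        "RunLengthNonUniformityNormalized": sum(x**2 for x in pl) / nr**2,
        "RunPercentage": nr / n_vox,
        "RunVariance": S(lambda g, l: (l - mu_l) ** 2),
        "ShortRunEmphasis": S(lambda g, l: 1.0 / l**2),
        "ShortRunHighGrayLevelEmphasis": S(lambda g, l: g**2 / l**2),
        "ShortRunLowGrayLevelEmphasis": S(lambda g, l: 1.0 / (g**2 * l**2)),
    }


# ---------------------------------------------------------------------------
# GLSZM (flood-fill zones)
# ---------------------------------------------------------------------------

def flood_fill_zones(levels, mask):
    """(gray level, zone size) by BFS over 26-connected same-level voxels."""
    levels = np.where(mask, levels, 0)
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []
    for v in np.ndindex(levels.shape):
        if levels[v] == 0 or seen[v]:
            continue
        g = levels[v]
        size = 0
        q = deque([v])
        seen[v] = True
        while q:
            u = q.popleft()
            size += 1
            for d in DIRS_26:
                w = (u[0] + d[0], u[1] + d[1], u[2] + d[2])
                if _inb(w, levels.shape) and not seen[w] and levels[w] == g:
                    seen[w] = True
                    q.append(w)
        zones.append((int(g), size))
    return zones


def glszm_oracle(levels, mask):
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())
    n_vox = int(mask.sum())
    zones = flood_fill_zones(levels, mask)
    nz = len(zones)
    ns = max(s for _, s in zones)
    P = np.zeros((ng, ns))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    pg = [sum(P[g]) for g in range(ng)]
    ps = [sum(P[:, s]) for s in range(ns)]
    mu_g = sum((g + 1) * P[g][s] for g in range(ng) for s in range(ns)) / nz
    mu_s = sum((s + 1) * P[g][s] for g in range(ng) for s in range(ns)) / nz
    S = lambda f: sum(f(g + 1, s + 1) * P[g][s]
                      for g in range(ng) for s in range(ns)) / nz
    return {
        "GrayLevelNonUniformity": sum(x**2 for x in pg) / nz,
        "GrayLevelNonUniformityNormalized": sum(x**2 for x in pg) / nz**2,
        "GrayLevelVariance": S(lambda g, s: (g - mu_g) ** 2),
        "HighGrayLevelZoneEmphasis": S(lambda g, s: g**2),
        "LargeAreaEmphasis": S(lambda g, s: s**2),
        "LargeAreaHighGrayLevelEmphasis": S(lambda g, s: g**2 * s**2),
        "LargeAreaLowGrayLevelEmphasis": S(lambda g, s: s**2 / g**2),
        "LowGrayLevelZoneEmphasis": S(lambda g, s: 1.0 / g**2),
        "SizeZoneNonUniformity": sum(x**2 for x in ps) / nz,
        "SizeZoneNonUniformityNormalized": sum(x**2 for x in ps) / nz**2,
        "SmallAreaEmphasis": S(lambda g, s: 1.0 / s**2),
        "SmallAreaHighGrayLevelEmphasis": S(lambda g, s: g**2 / s**2),
        "SmallAreaLowGrayLevelEmphasis": S(lambda g, s: 1.0 / (g**2 * s**2)),
        "ZoneEntropy": -sum((P[g][s] / nz) * log2(P[g][s] / nz)
                            for g in range(ng) for s in range(ns)),
        "ZonePercentage": nz / n_vox,
        "ZoneVariance": S(lambda g, s: (s - mu_s) ** 2),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_oracle(levels, mask):
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())
    n_i = [0.0] * ng
    s_i = [0.0] * ng
    nvp = 0
    for v in np.ndindex(levels.shape):
        if not mask[v]:
            continue
        nbrs = []
        for d in DIRS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inb(w, levels.shape) and mask[w]:
                nbrs.append(levels[w])
        if not nbrs:
            continue
        nvp += 1
        g = int(levels[v])
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - sum(nbrs) / len(nbrs))
    p_i = [n / nvp for n in n_i]
    occ = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(occ)
    sum_ps = sum(p_i[i] * s_i[i] for i in occ)
    coarseness = min(1.0 / sum_ps if sum_ps > 0 else 1e6, 1e6)
    if ngp > 1:
        contrast = (sum(p_i[i] * p_i[j] * (i - j) ** 2
                        for i in occ for j in occ) / (ngp * (ngp - 1))) \
            * (sum(s_i) / nvp)
        denom = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
                    for i in occ for j in occ)
        busyness = sum_ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    complexity = sum(abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                     / (p_i[i] + p_i[j]) for i in occ for j in occ) / nvp
    stot = sum(s_i)
    strength = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                    for i in occ for j in occ) / stot if stot > 0 else 0.0)
    return {"Busyness": busyness, "Coarseness": coarseness,
            "Complexity": complexity, "Contrast": contrast,
            "Strength": strength}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_dependences(levels, mask, alpha=0):
    """(gray level, dependence count) per masked voxel by neighbour loops."""
    levels = np.where(mask, levels, 0)
    out = []
    for v in np.ndindex(levels.shape):
        if not mask[v]:
            continue
        dep = 0
        for d in DIRS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (_inb(w, levels.shape) and mask[w]
                    and abs(int(levels[w]) - int(levels[v])) <= alpha):
                dep += 1
        out.append((int(levels[v]), dep))
    return out


def gldm_oracle(levels, mask, alpha=0):
    levels = np.where(mask, levels, 0)
    ng = int(levels.max())
    deps = gldm_dependences(levels, mask, alpha)
    nd = max(d for _, d in deps) + 1
    P = np.zeros((ng, nd))
    for g, d in deps:
        P[g - 1, d] += 1
    nz = P.sum()
    pg = [sum(P[g]) for g in range(ng)]
    pd_ = [sum(P[:, d]) for d in range(nd)]
    # emphasis index j = dependence + 1
    mu_g = sum((g + 1) * P[g][d] for g in range(ng) for d in range(nd)) / nz
    mu_j = sum((d + 1) * P[g][d] for g in range(ng) for d in range(nd)) / nz
    S = lambda f: sum(f(g + 1, d + 1) * P[g][d]
                      for g in range(ng) for d in range(nd)) / nz
    return {
        "DependenceEntropy": -sum((P[g][d] / nz) * log2(P[g][d] / nz)
                                  for g in range(ng) for d in range(nd)),
        "DependenceNonUniformity": sum(x**2 for x in pd_) / nz,
        "DependenceNonUniformityNormalized": sum(x**2 for x in pd_) / nz**2,
        "DependenceVariance": S(lambda g, j: (j - mu_j) ** 2),
        "GrayLevelNonUniformity": sum(x**2 for x in pg) / nz,
        "GrayLevelVariance": S(lambda g, j: (g - mu_g) ** 2),
        "HighGrayLevelEmphasis": S(lambda g, j: g**2),
        "LargeDependenceEmphasis": S(lambda g, j: j**2),
        "LargeDependenceHighGrayLevelEmphasis": S(lambda g, j: g**2 * j**2),
        "LargeDependenceLowGrayLevelEmphasis": S(lambda g, j: j**2 / g**2),
        "LowGrayLevelEmphasis": S(lambda g, j: 1.0 / g**2),
        "SmallDependenceEmphasis": S(lambda g, j: 1.0 / j**2),
        "SmallDependenceHighGrayLevelEmphasis": S(lambda g, j: g**2 / j**2),
        "SmallDependenceLowGrayLevelEmphasis":
            S(lambda g, j: 1.0 / (g**2 * j**2)),
    }


ORACLES = {
    "glcm": glcm_oracle,
    "glrlm": glrlm_oracle,
    "glszm": glszm_oracle,
    "ngtdm": ngtdm_oracle,
    "gldm": gldm_oracle,
}
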