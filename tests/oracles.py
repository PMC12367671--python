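"""Independent brute-force oracles for the texture features and statistics.

Everything here is written directly from the definitional sums with plain
Python loops over voxels, pairs, runs, zones and neighborhoods — no code is
shared with the package. Shared *conventions* (documented in the package):
base-2 entropies over positive terms, gray levels keep their bin values,
Ng = number of occupied levels, GLDM column j = dependence count + 1,
degenerate values (Correlation/MCC = 1, Imc = 0, NGTDM zeros, Coarseness
capped at 1e6) as stated.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

ALL_OFFSETS = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
HALF_DIRECTIONS = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
COARSENESS_CAP = 1e6


def _levels(values: np.ndarray, mask: np.ndarray, bin_width: float) -> dict:
    vmin = min(values[v] for v in zip(*np.nonzero(mask)))
    return {
        v: int(math.floor((values[v] - vmin) / bin_width)) + 1
        for v in zip(*np.nonzero(mask))
    }


def _in(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def _entropy(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


# ---------------------------------------------------------------------------
# first order


def brute_first_order(values, mask, spacing, bin_width=25.0) -> dict:
    x = sorted(values[v] for v in zip(*np.nonzero(mask)))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    lv = _levels(values, mask, bin_width)
    counts: dict[int, int] = {}
    for g in lv.values():
        counts[g] = counts.get(g, 0) + 1
    probs = [c / n for c in counts.values()]
    energy = sum(v * v for v in x)
    return {
        "firstorder_10Percentile": p10,
        "firstorder_90Percentile": p90,
        "firstorder_Energy": energy,
        "firstorder_Entropy": _entropy(probs),
        "firstorder_InterquartileRange": p75 - p25,
        "firstorder_Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "firstorder_Maximum": x[-1],
        "firstorder_Mean": mean,
        "firstorder_MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "firstorder_Median": float(np.median(x)),
        "firstorder_Minimum": x[0],
        "firstorder_Range": x[-1] - x[0],
        "firstorder_RobustMeanAbsoluteDeviation": (
            sum(abs(v - rmean) for v in robust) / len(robust) if robust else 0.0
        ),
        "firstorder_RootMeanSquared": math.sqrt(sum(v * v for v in x) / n),
        "firstorder_Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "firstorder_TotalEnergy": float(np.prod(spacing)) * energy,
        "firstorder_Uniformity": sum(p * p for p in probs),
        "firstorder_Variance": m2,
    }


# ---------------------------------------------------------------------------
# GLCM


def _glcm_features_from_pairs(p: dict, ng: int) -> dict:
    levels = sorted({i for i, _ in p} | {j for _, j in p})
    px = {i: sum(v for (a, _), v in p.items() if a == i) for i in levels}
    py = {j: sum(v for (_, b), v in p.items() if b == j) for j in levels}
    ux = sum(i * px[i] for i in levels)
    uy = sum(j * py[j] for j in levels)
    sigx = math.sqrt(sum(px[i] * (i - ux) ** 2 for i in levels))
    sigy = math.sqrt(sum(py[j] * (j - uy) ** 2 for j in levels))
    pd: dict[int, float] = {}
    psum: dict[int, float] = {}
    for (i, j), v in p.items():
        pd[abs(i - j)] = pd.get(abs(i - j), 0.0) + v
        psum[i + j] = psum.get(i + j, 0.0) + v
    da = sum(k * v for k, v in pd.items())
    hx, hy = _entropy(px.values()), _entropy(py.values())
    hxy = _entropy(p.values())
    hxy1 = -sum(v * math.log2(px[i] * py[j]) for (i, j), v in p.items() if v > 0)
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in levels
        for j in levels
        if px[i] * py[j] > 0
    )
    if sigx > 0 and sigy > 0:
        corr = (sum(i * j * v for (i, j), v in p.items()) - ux * uy) / (sigx * sigy)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    occ = [i for i in levels if px[i] > 0]
    if len(occ) > 1:
        q = np.zeros((len(occ), len(occ)))
        for a, i in enumerate(occ):
            for b, j in enumerate(occ):
                q[a, b] = sum(
                    p.get((i, k), 0.0) * p.get((j, k), 0.0) / (px[i] * py[k])
                    for k in occ
                    if py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0
    return {
        "glcm_Autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "glcm_ClusterProminence": sum(v * (i + j - ux - uy) ** 4 for (i, j), v in p.items()),
        "glcm_ClusterShade": sum(v * (i + j - ux - uy) ** 3 for (i, j), v in p.items()),
        "glcm_ClusterTendency": sum(v * (i + j - ux - uy) ** 2 for (i, j), v in p.items()),
        "glcm_Contrast": sum(v * (i - j) ** 2 for (i, j), v in p.items()),
        "glcm_Correlation": corr,
        "glcm_DifferenceAverage": da,
        "glcm_DifferenceEntropy": _entropy(pd.values()),
        "glcm_DifferenceVariance": sum(v * (k - da) ** 2 for k, v in pd.items()),
        "glcm_Id": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
        "glcm_Idm": sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items()),
        "glcm_Idmn": sum(v / (1 + (i - j) ** 2 / ng**2) for (i, j), v in p.items()),
        "glcm_Idn": sum(v / (1 + abs(i - j) / ng) for (i, j), v in p.items()),
        "glcm_Imc1": imc1,
        "glcm_Imc2": imc2,
        "glcm_InverseVariance": sum(
            v / (i - j) ** 2 for (i, j), v in p.items() if i != j
        ),
        "glcm_JointAverage": ux,
        "glcm_JointEnergy": sum(v * v for v in p.values()),
        "glcm_JointEntropy": hxy,
        "glcm_MCC": mcc,
        "glcm_MaximumProbability": max(p.values()),
        "glcm_SumEntropy": _entropy(psum.values()),
        "glcm_SumSquares": sum(v * (i - ux) ** 2 for (i, j), v in p.items()),
    }


def brute_glcm(values, mask, bin_width=25.0) -> dict:
    lv = _levels(values, mask, bin_width)
    ng = len(set(lv.values()))
    shape = mask.shape
    per_dir = []
    for d in HALF_DIRECTIONS:
        counts: dict[tuple[int, int], float] = {}
        for v in lv:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in(shape, w) and w in lv:
                for pair in ((lv[v], lv[w]), (lv[w], lv[v])):
                    counts[pair] = counts.get(pair, 0.0) + 1.0
        total = sum(counts.values())
        if total == 0:
            continue
        p = {k: c / total for k, c in counts.items()}
        per_dir.append(_glcm_features_from_pairs(p, ng))
    return {k: sum(d[k] for d in per_dir) / len(per_dir) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM


def _size_features(P: dict, n_voxels: int, prefix: str, small: str, large: str, col: str) -> dict:
    nr = sum(P.values())
    p = {k: v / nr for k, v in P.items()}
    pg: dict[int, float] = {}
    pj: dict[int, float] = {}
    for (i, j), v in p.items():
        pg[i] = pg.get(i, 0.0) + v
        pj[j] = pj.get(j, 0.0) + v
    mu_g = sum(i * v for i, v in pg.items())
    mu_j = sum(j * v for j, v in pj.items())
    ent_name = "RunEntropy" if prefix == "glrlm" else "ZoneEntropy"
    nun = "RunLengthNonUniformity" if prefix == "glrlm" else "SizeZoneNonUniformity"
    pct = "RunPercentage" if prefix == "glrlm" else "ZonePercentage"
    var = "RunVariance" if prefix == "glrlm" else "ZoneVariance"
    return {
        f"{prefix}_GrayLevelNonUniformity": sum((v * nr) ** 2 for v in pg.values()) / nr,
        f"{prefix}_GrayLevelNonUniformityNormalized": sum(v**2 for v in pg.values()),
        f"{prefix}_GrayLevelVariance": sum(v * (i - mu_g) ** 2 for i, v in pg.items()),
        f"{prefix}_HighGrayLevel{col}Emphasis": sum(v * i * i for (i, j), v in p.items()),
        f"{prefix}_{large}Emphasis": sum(v * j * j for (i, j), v in p.items()),
        f"{prefix}_{large}HighGrayLevelEmphasis": sum(v * i * i * j * j for (i, j), v in p.items()),
        f"{prefix}_{large}LowGrayLevelEmphasis": sum(v * j * j / (i * i) for (i, j), v in p.items()),
        f"{prefix}_LowGrayLevel{col}Emphasis": sum(v / (i * i) for (i, j), v in p.items()),
        f"{prefix}_{ent_name}": _entropy(p.values()),
        f"{prefix}_{nun}": sum((v * nr) ** 2 for v in pj.values()) / nr,
        f"{prefix}_{nun}Normalized": sum(v**2 for v in pj.values()),
        f"{prefix}_{pct}": nr / n_voxels,
        f"{prefix}_{var}": sum(v * (j - mu_j) ** 2 for j, v in pj.items()),
        f"{prefix}_{small}Emphasis": sum(v / (j * j) for (i, j), v in p.items()),
        f"{prefix}_{small}HighGrayLevelEmphasis": sum(v * i * i / (j * j) for (i, j), v in p.items()),
        f"{prefix}_{small}LowGrayLevelEmphasis": sum(v / (i * i * j * j) for (i, j), v in p.items()),
    }


def brute_glrlm(values, mask, bin_width=25.0) -> dict:
    lv = _levels(values, mask, bin_width)
    shape = mask.shape
    n_voxels = len(lv)
    per_dir = []
    for d in HALF_DIRECTIONS:
        P: dict[tuple[int, int], float] = {}
        for v in lv:
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if _in(shape, prev) and prev in lv and lv[prev] == lv[v]:
                continue  # not a run start
            length = 1
            cur = v
            while True:
                nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if _in(shape, nxt) and nxt in lv and lv[nxt] == lv[v]:
                    length += 1
                    cur = nxt
                else:
                    break
            key = (lv[v], length)
            P[key] = P.get(key, 0.0) + 1.0
        per_dir.append(_size_features(P, n_voxels, "glrlm", "ShortRun", "LongRun", "Run"))
    return {k: sum(d[k] for d in per_dir) / len(per_dir) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM


def brute_glszm(values, mask, bin_width=25.0) -> dict:
    lv = _levels(values, mask, bin_width)
    shape = mask.shape
    seen: set = set()
    P: dict[tuple[int, int], float] = {}
    for start in lv:
        if start in seen:
            continue
        g = lv[start]
        stack, zone = [start], {start}
        seen.add(start)
        while stack:  # flood fill, 26-connected
            cur = stack.pop()
            for d in ALL_OFFSETS:
                w = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if _in(shape, w) and w in lv and w not in seen and lv[w] == g:
                    seen.add(w)
                    zone.add(w)
                    stack.append(w)
        key = (g, len(zone))
        P[key] = P.get(key, 0.0) + 1.0
    return _size_features(P, len(lv), "glszm", "SmallArea", "LargeArea", "Zone")


# ---------------------------------------------------------------------------
# GLDM


def brute_gldm(values, mask, bin_width=25.0, alpha=0) -> dict:
    lv = _levels(values, mask, bin_width)
    shape = mask.shape
    P: dict[tuple[int, int], float] = {}
    for v in lv:
        dep = 0
        for d in ALL_OFFSETS:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in(shape, w) and w in lv and abs(lv[w] - lv[v]) <= alpha:
                dep += 1
        key = (lv[v], dep + 1)  # column index is dependence + 1
        P[key] = P.get(key, 0.0) + 1.0
    nz = sum(P.values())
    p = {k: v / nz for k, v in P.items()}
    pg: dict[int, float] = {}
    pj: dict[int, float] = {}
    for (i, j), v in p.items():
        pg[i] = pg.get(i, 0.0) + v
        pj[j] = pj.get(j, 0.0) + v
    mu_g = sum(i * v for i, v in pg.items())
    mu_j = sum(j * v for j, v in pj.items())
    return {
        "gldm_DependenceEntropy": _entropy(p.values()),
        "gldm_DependenceNonUniformity": sum((v * nz) ** 2 for v in pj.values()) / nz,
        "gldm_DependenceNonUniformityNormalized": sum(v**2 for v in pj.values()),
        "gldm_DependenceVariance": sum(v * (j - mu_j) ** 2 for j, v in pj.items()),
        "gldm_GrayLevelNonUniformity": sum((v * nz) ** 2 for v in pg.values()) / nz,
        "gldm_GrayLevelVariance": sum(v * (i - mu_g) ** 2 for i, v in pg.items()),
        "gldm_HighGrayLevelEmphasis": sum(v * i * i for (i, j), v in p.items()),
        "gldm_LargeDependenceEmphasis": sum(v * j * j for (i, j), v in p.items()),
        "gldm_LargeDependenceHighGrayLevelEmphasis": sum(
            v * i * i * j * j for (i, j), v in p.items()
        ),
        "gldm_LargeDependenceLowGrayLevelEmphasis": sum(
            v * j * j / (i * i) for (i, j), v in p.items()
        ),
        "gldm_LowGrayLevelEmphasis": sum(v / (i * i) for (i, j), v in p.items()),
        "gldm_SmallDependenceEmphasis": sum(v / (j * j) for (i, j), v in p.items()),
        "gldm_SmallDependenceHighGrayLevelEmphasis": sum(
            v * i * i / (j * j) for (i, j), v in p.items()
        ),
        "gldm_SmallDependenceLowGrayLevelEmphasis": sum(
            v / (i * i * j * j) for (i, j), v in p.items()
        ),
    }


# ---------------------------------------------------------------------------
# NGTDM


def brute_ngtdm(values, mask, bin_width=25.0) -> dict:
    lv = _levels(values, mask, bin_width)
    shape = mask.shape
    nv = len(lv)
    n: dict[int, int] = {}
    s: dict[int, float] = {}
    for v in lv:
        g = lv[v]
        n[g] = n.get(g, 0) + 1
        nbrs = []
        for d in ALL_OFFSETS:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in(shape, w) and w in lv:
                nbrs.append(lv[w])
        if nbrs:
            s[g] = s.get(g, 0.0) + abs(g - sum(nbrs) / len(nbrs))
        else:
            s.setdefault(g, 0.0)
    levels = sorted(n)
    p = {g: n[g] / nv for g in levels}
    ngp = len(levels)
    sum_ps = sum(p[g] * s[g] for g in levels)
    coarseness = min(1.0 / sum_ps if sum_ps > 0 else COARSENESS_CAP, COARSENESS_CAP)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in levels for j in levels)
            / (ngp * (ngp - 1))
            * sum(s.values())
            / nv
        )
        busy_den = sum(abs(i * p[i] - j * p[j]) for i in levels for j in levels)
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in levels
                for j in levels
            )
            / nv
        )
        s_total = sum(s.values())
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in levels for j in levels) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_Busyness": busyness,
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Contrast": contrast,
        "ngtdm_Strength": strength,
    }


def brute_all_features(values, mask, spacing=(1.0, 1.0, 1.0), bin_width=25.0) -> dict:
    out = {}
    out.update(brute_first_order(values, mask, spacing, bin_width))
    out.update(brute_glcm(values, mask, bin_width))
    out.update(brute_glrlm(values, mask, bin_width))
    out.update(brute_glszm(values, mask, bin_width))
    out.update(brute_gldm(values, mask, bin_width))
    out.update(brute_ngtdm(values, mask, bin_width))
    return out


# ---------------------------------------------------------------------------
# Statistics oracles


def exact_mwu_pvalue(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of all label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    u_obs = u_stat(x, y)
    n2 = len(y)
    mid = n1 * n2 / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
    return count / total


def auc_by_concordance(scores, labels, positive_class) -> float:
    """AUC as the fraction of concordant positive/negative pairs (ties half)."""
    pos = [s for s, l in zip(scores, labels) if l == positive_class]
    neg = [s for s, l in zip(scores, labels) if l != positive_class]
    c = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return c / (len(pos) * len(neg))


def dunn_z_transcription(groups: dict) -> dict:
    """Textbook Dunn z statistics (pooled ranks, tie correction), per pair."""
    names = list(groups)
    pooled = [v for k in names for v in groups[k]]
    n_total = len(pooled)
    order = sorted(range(n_total), key=lambda i: pooled[i])
    ranks = [0.0] * n_total
    i = 0
    while i < n_total:
        j = i
        while j + 1 < n_total and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    tie_counts: dict[float, int] = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in tie_counts.values()) / (12.0 * (n_total - 1))
    base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = {}
    start = 0
    for k in names:
        sz = len(groups[k])
        mean_ranks[k] = sum(ranks[start : start + sz]) / sz
        start += sz
    out = {}
    for a_i, a in enumerate(names):
        for b in names[a_i + 1 :]:
            var = base * (1.0 / len(groups[a]) + 1.0 / len(groups[b]))
            out[(a, b)] = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(var) if var > 0 else 0.0
    return out


def kruskal_h_transcription(groups) -> float:
    """Hand formula: H = (12 / (N(N+1))) sum n_i Rbar_i^2 - 3(N+1), tie-corrected."""
    pooled = [v for g in groups for v in g]
    n_total = len(pooled)
    order = sorted(range(n_total), key=lambda i: pooled[i])
    ranks = [0.0] * n_total
    i = 0
    while i < n_total:
        j = i
        while j + 1 < n_total and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        rsum = sum(ranks[start : start + len(g)])
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    tie_counts: dict[float, int] = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in tie_counts.values()) / (n_total**3 - n_total)
    return h / correction if correction > 0 else 0.0


def bh_step_up(pvals) -> list:
    """Hand transcription of the Benjamini-Hochberg adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
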