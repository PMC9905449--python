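"""Independent brute-force oracles for the windowed texture features.

Deliberately written from the feature definitions alone — exhaustive
enumeration of pixel pairs, runs and neighbourhoods with plain Python
loops — and kept free of any import from the production feature code, so
agreement is a meaningful check.
"""

import math

import numpy as np

EPS = 2.2e-16
DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


def first_order_oracle(window, levels, voxel_volume=1.0):
    flat = [int(v) for v in np.asarray(levels).ravel()]
    n = len(flat)
    probs = [flat.count(lv) / n for lv in sorted(set(flat))]
    entropy = -sum(p * math.log2(p + EPS) for p in probs)
    uniformity = sum(p * p for p in probs)
    total_energy = voxel_volume * float(sum(float(x) ** 2 for x in np.asarray(window).ravel()))
    return {"Entropy": entropy, "TotalEnergy": total_energy, "Uniformity": uniformity}


def glcm_oracle(levels):
    """Pair counts at distance 1 in four directions, symmetric, pooled."""
    lv = np.asarray(levels)
    rows, cols = lv.shape
    pairs = {}
    for dr, dc in DIRECTIONS:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    for a, b in ((int(lv[r, c]), int(lv[r2, c2])), (int(lv[r2, c2]), int(lv[r, c]))):
                        pairs[(a, b)] = pairs.get((a, b), 0) + 1
    total = sum(pairs.values())
    p = {k: v / total for k, v in pairs.items()}
    return p


def glcm_features_oracle(levels):
    p = glcm_oracle(levels)
    jid = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    idm = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    joint_energy = sum(v * v for v in p.values())
    max_prob = max(p.values())
    return {"Id": jid, "Idm": idm, "JointEnergy": joint_energy, "MaximumProbability": max_prob}


def gldm_oracle(levels, alpha=0):
    lv = np.asarray(levels)
    rows, cols = lv.shape
    entries = []  # (level, dependence size) per pixel
    for r in range(rows):
        for c in range(cols):
            dep = 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < rows and 0 <= c2 < cols:
                        if abs(int(lv[r2, c2]) - int(lv[r, c])) <= alpha:
                            dep += 1
            entries.append((int(lv[r, c]), dep))
    nz = len(entries)
    lde = sum(j * j for _, j in entries) / nz
    j_counts = {}
    for _, j in entries:
        j_counts[j] = j_counts.get(j, 0) + 1
    dnn = sum(v * v for v in j_counts.values()) / nz**2
    mu = sum(j for _, j in entries) / nz
    dv = sum((j - mu) ** 2 for _, j in entries) / nz
    return {
        "DependenceNonUniformityNormalized": dnn,
        "DependenceVariance": dv,
        "LargeDependenceEmphasis": lde,
    }


def _runs_in_line(seq):
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        runs.append((seq[i], j - i + 1))
        i = j + 1
    return runs


def _direction_lines(lv, dr, dc):
    rows, cols = lv.shape
    if (dr, dc) == (0, 1):
        starts = [(r, 0) for r in range(rows)]
    elif (dr, dc) == (1, 0):
        starts = [(0, c) for c in range(cols)]
    elif (dr, dc) == (1, 1):
        starts = [(r, 0) for r in range(rows)] + [(0, c) for c in range(1, cols)]
    elif (dr, dc) == (1, -1):
        starts = [(0, c) for c in range(cols)] + [(r, cols - 1) for r in range(1, rows)]
    lines = []
    for r0, c0 in starts:
        line = []
        r, c = r0, c0
        while 0 <= r < rows and 0 <= c < cols:
            line.append(int(lv[r, c]))
            r, c = r + dr, c + dc
        lines.append(line)
    return lines


def glrlm_oracle(levels, directions=DIRECTIONS):
    lv = np.asarray(levels)
    n_pix = lv.size
    feats = {"GrayLevelNonUniformityNormalized": 0.0, "RunLengthNonUniformityNormalized": 0.0,
             "RunPercentage": 0.0, "ShortRunEmphasis": 0.0}
    for dr, dc in directions:
        runs = []
        for line in _direction_lines(lv, dr, dc):
            runs.extend(_runs_in_line(line))
        nr = len(runs)
        sre = sum(1.0 / length**2 for _, length in runs) / nr
        level_counts, length_counts = {}, {}
        for level, length in runs:
            level_counts[level] = level_counts.get(level, 0) + 1
            length_counts[length] = length_counts.get(length, 0) + 1
        feats["ShortRunEmphasis"] += sre
        feats["RunPercentage"] += nr / n_pix
        feats["GrayLevelNonUniformityNormalized"] += sum(v * v for v in level_counts.values()) / nr**2
        feats["RunLengthNonUniformityNormalized"] += sum(v * v for v in length_counts.values()) / nr**2
    return {k: v / len(directions) for k, v in feats.items()}


def all_features_oracle(window, levels, voxel_volume=1.0):
    """All 14 features in the production vector order."""
    fo = first_order_oracle(window, levels, voxel_volume)
    gl = glcm_features_oracle(levels)
    gd = gldm_oracle(levels)
    gr = glrlm_oracle(levels)
    return [
        fo["Entropy"], fo["TotalEnergy"], fo["Uniformity"],
        gl["Id"], gl["Idm"], gl["JointEnergy"], gl["MaximumProbability"],
        gd["DependenceNonUniformityNormalized"], gd["DependenceVariance"],
        gd["LargeDependenceEmphasis"],
        gr["GrayLevelNonUniformityNormalized"], gr["RunLengthNonUniformityNormalized"],
        gr["RunPercentage"], gr["ShortRunEmphasis"],
    ]
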