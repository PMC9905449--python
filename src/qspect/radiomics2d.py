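"""Windowed 2D radiomic texture features.

Fourteen features per modality, chosen for reproducibility across
acquisition conditions: three first-order statistics, four gray-level
co-occurrence (GLCM) features, three gray-level dependence (GLDM) features
and four gray-level run-length (GLRLM) features. Each sample's feature
vector is the CT window's 14 features followed by the normalized-SPECT
window's 14 (28 values).

Gray levels are discretized on *fixed global bin edges per modality* (CT:
25 HU bins over [-1050, 400]; normalized SPECT: 0.05-wide bins over
[0, 1.5]) rather than per-window min-max: windows hold only 9-25 pixels, so
per-window ranges would be unstable and features incomparable across
samples. Values outside the global range are clamped into the end bins.

Texture-matrix conventions (fixed for determinism): GLCM at distance 1 in
the four 2D directions, symmetrized, pooled across directions and
normalized to sum 1; GLRLM counts maximal equal-level runs per direction,
features averaged over the four directions; GLDM dependence size of a pixel
is 1 + the number of its 8-neighbours inside the window whose level differs
by at most ``alpha`` (default 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .volume_io import Modality

logger = logging.getLogger(__name__)

__all__ = [
    "RadiomicsConfig",
    "DiscretizedWindow",
    "discretize",
    "glcm_matrix",
    "glcm_features",
    "first_order_features",
    "gldm_features",
    "glrlm_features",
    "extract_feature_vector",
    "FEATURE_NAMES",
    "FEATURE_COLUMNS",
    "feature_schema",
]

#: guard added inside the entropy logarithm (machine epsilon)
ENTROPY_EPS = 2.2e-16

# modalities already warned about out-of-range clamping (warn once, then debug)
_clamp_warned: set = set()

#: the 14 per-modality features, in fixed vector order
FEATURE_NAMES = [
    "firstorder_Entropy",
    "firstorder_TotalEnergy",
    "firstorder_Uniformity",
    "glcm_Id",
    "glcm_Idm",
    "glcm_JointEnergy",
    "glcm_MaximumProbability",
    "gldm_DependenceNonUniformityNormalized",
    "gldm_DependenceVariance",
    "gldm_LargeDependenceEmphasis",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_ShortRunEmphasis",
]

#: the 28 sample-table feature columns: CT block then SPECT block
FEATURE_COLUMNS = [f"ct_{n}" for n in FEATURE_NAMES] + [f"spect_{n}" for n in FEATURE_NAMES]

_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))  # 0, 45, 90, 135 degrees


@dataclass
class RadiomicsConfig:
    """Discretization and texture settings.

    ``voxel_volume`` (mm^3) scales TotalEnergy; set to 1.0 for unitless
    tests, or to dz*dy*dx of the CT grid in the pipeline.
    """

    ct_range: tuple[float, float] = (-1050.0, 400.0)
    ct_bin_width: float = 25.0
    spect_range: tuple[float, float] = (0.0, 1.5)
    spect_bin_width: float = 0.05
    gldm_alpha: int = 0
    voxel_volume: float = 1.0

    def bins_for(self, modality: Modality) -> tuple[float, float, int]:
        if Modality(modality) is Modality.CT:
            lo, hi = self.ct_range
            width = self.ct_bin_width
        else:
            lo, hi = self.spect_range
            width = self.spect_bin_width
        n_levels = int(round((hi - lo) / width))
        return lo, width, n_levels


@dataclass
class DiscretizedWindow:
    """Integer gray levels of a window plus the shared binning."""

    levels: np.ndarray  # 2D int, values in 1..n_levels
    n_levels: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.ndim != 2:
            raise ValueError("levels must be 2D")
        if self.levels.min() < 1 or self.levels.max() > self.n_levels:
            raise ValueError("levels outside [1, n_levels]")


def discretize(
    window: np.ndarray, modality: Modality | str, config: RadiomicsConfig | None = None
) -> DiscretizedWindow:
    """Map raw window values to integer gray levels on global bin edges."""
    config = config or RadiomicsConfig()
    window = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    lo, width, n_levels = config.bins_for(Modality(modality))
    raw = np.floor((window - lo) / width).astype(np.int64) + 1
    if raw.min() < 1 or raw.max() > n_levels:
        key = Modality(modality).value
        level = logging.WARNING if key not in _clamp_warned else logging.DEBUG
        _clamp_warned.add(key)
        logger.log(
            level,
            "window values outside the global %s discretization range; clamped to end bins",
            key,
        )
    levels = np.clip(raw, 1, n_levels)
    edges = lo + width * np.arange(n_levels + 1)
    return DiscretizedWindow(levels, n_levels, edges)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrix(dw: DiscretizedWindow) -> tuple[np.ndarray, np.ndarray]:
    """Normalized symmetric co-occurrence matrix pooled over four directions.

    Returns ``(P, level_values)``: ``P`` is indexed over the sorted distinct
    levels present in the window, ``level_values`` gives the actual gray
    level of each index (needed for |i - j| terms).
    """
    lv = dw.levels
    if lv.size < 2:
        raise ValueError("GLCM needs at least 2 pixels")
    present = np.unique(lv)
    index = {int(v): k for k, v in enumerate(present)}
    n = len(present)
    counts = np.zeros((n, n), dtype=float)
    rows, cols = lv.shape
    for dr, dc in _DIRECTIONS:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    a = index[int(lv[r, c])]
                    b = index[int(lv[r2, c2])]
                    counts[a, b] += 1
                    counts[b, a] += 1  # symmetrize
    total = counts.sum()
    return counts / total, present.astype(float)


def glcm_features(P: np.ndarray, level_values: np.ndarray) -> dict[str, float]:
    """Id, Idm, JointEnergy and MaximumProbability from a normalized GLCM."""
    P = np.asarray(P, dtype=float)
    lv = np.asarray(level_values, dtype=float)
    diff = np.abs(lv[:, None] - lv[None, :])
    return {
        "Id": float(np.sum(P / (1.0 + diff))),
        "Idm": float(np.sum(P / (1.0 + diff**2))),
        "JointEnergy": float(np.sum(P**2)),
        "MaximumProbability": float(P.max()),
    }


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------


def first_order_features(
    window: np.ndarray, dw: DiscretizedWindow, voxel_volume: float = 1.0
) -> dict[str, float]:
    """Entropy/TotalEnergy/Uniformity of one window.

    Entropy and Uniformity use the discretized-level histogram; TotalEnergy
    is ``voxel_volume * sum(x^2)`` over the raw values.
    """
    window = np.asarray(window, dtype=float)
    _, counts = np.unique(dw.levels, return_counts=True)
    p = counts / counts.sum()
    entropy = float(-np.sum(p * np.log2(p + ENTROPY_EPS)))
    return {
        "Entropy": entropy,
        "TotalEnergy": float(voxel_volume * np.sum(window**2)),
        "Uniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_features(dw: DiscretizedWindow, alpha: int = 0) -> dict[str, float]:
    """Dependence-matrix features (8-neighbourhood, |level diff| <= alpha).

    Dependence size of a pixel is 1 (itself) plus the number of its
    in-window 8-neighbours within ``alpha`` gray levels. Nz equals the pixel
    count (every pixel forms a dependence zone).
    """
    lv = dw.levels
    if lv.size < 2:
        raise ValueError("GLDM needs at least 2 pixels")
    rows, cols = lv.shape
    # P[(level, j)] -> count
    P: dict[tuple[int, int], float] = {}
    for r in range(rows):
        for c in range(cols):
            center = int(lv[r, c])
            dep = 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < rows and 0 <= c2 < cols:
                        if abs(int(lv[r2, c2]) - center) <= alpha:
                            dep += 1
            key = (center, dep)
            P[key] = P.get(key, 0.0) + 1.0
    nz = sum(P.values())
    j_marginal: dict[int, float] = {}
    for (_, j), cnt in P.items():
        j_marginal[j] = j_marginal.get(j, 0.0) + cnt
    lde = sum(j * j * cnt for (_, j), cnt in P.items()) / nz
    dnn = sum(cnt**2 for cnt in j_marginal.values()) / nz**2
    mu_j = sum(j * cnt for (_, j), cnt in P.items()) / nz
    dv = sum((j - mu_j) ** 2 * cnt for (_, j), cnt in P.items()) / nz
    return {
        "DependenceNonUniformityNormalized": float(dnn),
        "DependenceVariance": float(dv),
        "LargeDependenceEmphasis": float(lde),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _lines(lv: np.ndarray, direction: tuple[int, int]) -> list[list[int]]:
    rows, cols = lv.shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        return [list(lv[r, :]) for r in range(rows)]
    if (dr, dc) == (1, 0):
        return [list(lv[:, c]) for c in range(cols)]
    if (dr, dc) == (1, 1):
        flipped = lv[:, ::-1]
        return [
            list(np.diagonal(flipped, offset=k)) for k in range(-(rows - 1), cols)
        ]
    if (dr, dc) == (1, -1):
        return [list(np.diagonal(lv, offset=k)) for k in range(-(rows - 1), cols)]
    raise ValueError(f"unsupported direction {direction}")


def _runs(line: list[int]) -> list[tuple[int, int]]:
    """Maximal (level, length) runs of a 1D sequence."""
    runs = []
    i = 0
    while i < len(line):
        j = i
        while j + 1 < len(line) and line[j + 1] == line[i]:
            j += 1
        runs.append((int(line[i]), j - i + 1))
        i = j + 1
    return runs


def glrlm_features(
    dw: DiscretizedWindow, directions: tuple[tuple[int, int], ...] = _DIRECTIONS
) -> dict[str, float]:
    """Run-length features, computed per direction and averaged."""
    lv = dw.levels
    if lv.size < 2:
        raise ValueError("GLRLM needs at least 2 pixels")
    np_pixels = lv.size
    acc = {k: 0.0 for k in ("GLNN", "RLNN", "RP", "SRE")}
    for direction in directions:
        P: dict[tuple[int, int], float] = {}
        for line in _lines(lv, direction):
            for level, length in _runs(line):
                P[(level, length)] = P.get((level, length), 0.0) + 1.0
        nr = sum(P.values())
        level_marginal: dict[int, float] = {}
        length_marginal: dict[int, float] = {}
        for (i, j), cnt in P.items():
            level_marginal[i] = level_marginal.get(i, 0.0) + cnt
            length_marginal[j] = length_marginal.get(j, 0.0) + cnt
        acc["SRE"] += sum(cnt / j**2 for (_, j), cnt in P.items()) / nr
        acc["RP"] += nr / np_pixels
        acc["RLNN"] += sum(c**2 for c in length_marginal.values()) / nr**2
        acc["GLNN"] += sum(c**2 for c in level_marginal.values()) / nr**2
    n = len(directions)
    return {
        "GrayLevelNonUniformityNormalized": acc["GLNN"] / n,
        "RunLengthNonUniformityNormalized": acc["RLNN"] / n,
        "RunPercentage": acc["RP"] / n,
        "ShortRunEmphasis": acc["SRE"] / n,
    }


# ---------------------------------------------------------------------------
# assembled vector
# ---------------------------------------------------------------------------


def _modality_features(
    window: np.ndarray, modality: Modality, config: RadiomicsConfig
) -> list[float]:
    dw = discretize(window, modality, config)
    fo = first_order_features(window, dw, config.voxel_volume)
    P, lv = glcm_matrix(dw)
    glcm = glcm_features(P, lv)
    gldm = gldm_features(dw, config.gldm_alpha)
    glrlm = glrlm_features(dw)
    values = [
        fo["Entropy"], fo["TotalEnergy"], fo["Uniformity"],
        glcm["Id"], glcm["Idm"], glcm["JointEnergy"], glcm["MaximumProbability"],
        gldm["DependenceNonUniformityNormalized"], gldm["DependenceVariance"],
        gldm["LargeDependenceEmphasis"],
        glrlm["GrayLevelNonUniformityNormalized"],
        glrlm["RunLengthNonUniformityNormalized"],
        glrlm["RunPercentage"], glrlm["ShortRunEmphasis"],
    ]
    if not all(np.isfinite(values)):
        raise ValueError("non-finite feature value produced")
    return values


def extract_feature_vector(
    ct_window: np.ndarray,
    spect_window: np.ndarray,
    config: RadiomicsConfig | None = None,
) -> np.ndarray:
    """28-long feature vector: 14 CT features then 14 SPECT features.

    Both windows must be square with the same (odd) side; the SPECT window
    must already be normalized.
    """
    config = config or RadiomicsConfig()
    ct_window = np.asarray(ct_window, dtype=float)
    spect_window = np.asarray(spect_window, dtype=float)
    if ct_window.shape != spect_window.shape:
        raise ValueError(
            f"window shapes differ: {ct_window.shape} vs {spect_window.shape}"
        )
    values = _modality_features(ct_window, Modality.CT, config)
    values += _modality_features(spect_window, Modality.SPECT, config)
    return np.array(values, dtype=float)


def feature_schema() -> list[dict]:
    """The shipped machine-readable feature-column schema."""
    with resources.files("qspect").joinpath("feature_schema.json").open() as fh:
        return json.load(fh)
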