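"""Window-sample enumeration inside ROIs and count matching across window sizes.

A sample is an ROI pixel whose centred ``side x side`` square lies entirely
inside the ROI's pixel set; texture features are later computed on that
square in both modalities. Because containment shrinks with the window, a
5x5 analysis yields fewer samples than a 3x3 one on the same ROIs;
``match_sample_counts`` subsamples the denser table so comparative
statistics across window sizes use equal per-stratum sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import RoiAnnotation, TissueClass

__all__ = ["WindowSample", "enumerate_window_samples", "match_sample_counts"]


@dataclass
class WindowSample:
    """An ROI pixel with a fully contained centred square window."""

    patient_id: str
    roi_id: int
    slice_index: int
    center: tuple[int, int]  # (row, col)
    window_side: int
    label: TissueClass
    features: np.ndarray | None = None


def enumerate_window_samples(roi: RoiAnnotation, window_side: int) -> list[WindowSample]:
    """All ROI pixels whose full centred window lies inside the ROI.

    ``window_side`` must be odd and >= 3 (3 and 5 are the standard
    configurations). Samples are returned in deterministic raster (row-major)
    order of their centre pixel.
    """
    if window_side % 2 == 0 or window_side < 3:
        raise ValueError(f"window_side must be odd and >= 3, got {window_side}")
    half = window_side // 2
    pixels = roi.pixels
    samples = []
    for r, c in sorted(pixels):
        ok = all(
            (r + dr, c + dc) in pixels
            for dr in range(-half, half + 1)
            for dc in range(-half, half + 1)
        )
        if ok:
            samples.append(
                WindowSample(
                    patient_id=roi.patient_id,
                    roi_id=roi.roi_id,
                    slice_index=roi.slice_index,
                    center=(r, c),
                    window_side=window_side,
                    label=roi.label,
                )
            )
    return samples


def match_sample_counts(
    table_a: pd.DataFrame, table_b: pd.DataFrame, seed: int, stratify: bool = True
) -> pd.DataFrame:
    """Subsample ``table_a`` to ``table_b``'s per-stratum row counts.

    Strata are (patient_id, label) pairs; within each stratum a uniform
    subsample without replacement is drawn, reproducibly for a given seed.
    With ``stratify=False`` a single global subsample to ``len(table_b)``
    rows is drawn instead. Every stratum of ``table_b`` must exist in
    ``table_a`` with at least as many rows.
    """
    rng = np.random.default_rng(seed)
    if not stratify:
        if len(table_a) < len(table_b):
            raise ValueError("table_a has fewer rows than table_b")
        idx = rng.choice(len(table_a), size=len(table_b), replace=False)
        return table_a.iloc[np.sort(idx)].reset_index(drop=True)

    keys = ["patient_id", "label"]
    counts_b = table_b.groupby(keys, sort=True).size()
    groups_a = table_a.groupby(keys, sort=True)
    pieces = []
    for stratum, n_b in counts_b.items():
        try:
            grp = groups_a.get_group(stratum)
        except KeyError:
            raise ValueError(f"stratum {stratum} present in table_b but absent from table_a")
        if len(grp) < n_b:
            raise ValueError(
                f"stratum {stratum}: table_a has {len(grp)} rows < table_b's {n_b}"
            )
        idx = rng.choice(len(grp), size=n_b, replace=False)
        pieces.append(grp.iloc[np.sort(idx)])
    out = pd.concat(pieces, axis=0)
    return out.sort_index().reset_index(drop=True)
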