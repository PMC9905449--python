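"""Lesion-level diagnosis: majority vote over a region's sample predictions.

Each annotated region receives the most frequent predicted tissue pattern
among its window samples, and three one-vs-rest binary calls (PE / no PE,
pneumonia / no pneumonia, healthy / not healthy) derived from that modal
class. Ties are broken by clinical severity — PE first — so the most
dangerous pattern is never out-voted by an equally frequent benign one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import PredictionResult
from .volume_io import TissueClass

__all__ = ["RoiDiagnosis", "aggregate_roi", "TIE_BREAK_PRIORITY"]

#: tie-break order, most severe first
TIE_BREAK_PRIORITY = (
    TissueClass.PE,
    TissueClass.PNEUMONIA,
    TissueClass.ABNORMAL_CT_LOW_PERF,
    TissueClass.HEALTHY,
    TissueClass.BODY_TISSUE,
    TissueClass.BACKGROUND,
)


@dataclass
class RoiDiagnosis:
    roi_id: int
    modal_class: TissueClass
    class_counts: dict[TissueClass, int]
    binary_calls: dict[str, bool]

    @property
    def n_samples(self) -> int:
        return sum(self.class_counts.values())


def aggregate_roi(
    predictions: list[PredictionResult] | list[TissueClass] | np.ndarray,
    roi_id: int = 0,
) -> RoiDiagnosis:
    """Majority vote over one region's per-sample predicted labels.

    Accepts `PredictionResult` objects, tissue classes, or integer codes.
    The modal class decides the three binary calls; at most one of them is
    positive (none if an extra category wins the vote — extra-category votes
    are kept, an all-background region is simply called negative for all
    three clinical targets).
    """
    if len(predictions) == 0:
        raise ValueError("cannot aggregate an empty ROI")
    labels = [
        p.label if isinstance(p, PredictionResult) else TissueClass(int(p))
        for p in predictions
    ]
    counts = {c: 0 for c in TissueClass}
    for lab in labels:
        counts[lab] += 1
    best = max(counts.values())
    modal = next(c for c in TIE_BREAK_PRIORITY if counts[c] == best)
    calls = {
        "PE": modal is TissueClass.PE,
        "PNEUMONIA": modal is TissueClass.PNEUMONIA,
        "HEALTHY": modal is TissueClass.HEALTHY,
    }
    return RoiDiagnosis(
        roi_id=roi_id,
        modal_class=modal,
        class_counts={c: n for c, n in counts.items() if n > 0},
        binary_calls=calls,
    )
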