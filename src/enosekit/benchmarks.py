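"""Reference confusion matrices for the worked evaluation examples.

These are published 10-fold cross-validation results for butanone/ethanol
classification on a 16k-sensor conducting-polymer array, reproduced here as
plain count matrices (rows = estimated labels, columns = known labels).
They serve as fixed inputs for exercising the precision/recall arithmetic —
including the by-hand convention of truncating non-terminating ratios such
as 7/9 to 0.77 before macro-averaging.
"""

from __future__ import annotations

import numpy as np

from .evaluate import ConfusionMatrix

__all__ = ["mixture_series_confusion", "background_series_confusion"]


def mixture_series_confusion() -> ConfusionMatrix:
    """41-measurement varying-ratio mixture series (5 classes).

    Pure compounds were always recognized; five mixture measurements were
    assigned to the neighbouring composition (three B25E75 predicted as
    B50E50, two B50E50 predicted as B75E25).
    """
    return ConfusionMatrix(
        counts=np.array(
            [
                [8, 0, 0, 0, 0],
                [0, 8, 2, 0, 0],
                [0, 0, 7, 3, 0],
                [0, 0, 0, 5, 0],
                [0, 0, 0, 0, 8],
            ]
        ),
        class_order=["B100", "B75E25", "B50E50", "B25E75", "E100"],
    )


def background_series_confusion() -> ConfusionMatrix:
    """20-measurement butanone steps over a constant ethanol background.

    All measurements were classified correctly (diagonal matrix).
    """
    return ConfusionMatrix(
        counts=np.diag([3, 3, 3, 3, 8]),
        class_order=["B10E40", "B20E40", "B30E40", "B40E40", "E40"],
    )
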