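"""Small bundled example datasets.

The validation confusion matrix comes from a zoo study that compared
automated pose-based classification against manual coding of two pygmy
hippopotamuses (an adult female and her calf) over 1200 co-observed
seconds of video.  Rows are the automated prediction, columns the
manual annotation; the manual "Out of View" and automated "Not
Labeled" seconds form one joint category.
"""

from __future__ import annotations

import numpy as np

from .evaluation import EVAL_CATEGORIES, ConfusionMatrix

_HIPPO_COUNTS = np.array(
    [
        #  Stand  Lying  Forag  Locom  OoV/NL   (manual)
        [100, 2, 158, 27, 0],  # predicted Standing
        [9, 225, 3, 0, 0],  # predicted Lying Down
        [1, 0, 221, 2, 0],  # predicted Foraging/Feeding
        [0, 0, 0, 26, 0],  # predicted Locomotion
        [85, 41, 11, 3, 286],  # predicted Not Labeled
    ],
    dtype=np.int64,
)

#: Kendall's W between manual and automated time budgets (five
#: categories) reported for each individual in the same study.
HIPPO_CONCORDANCE_W = {"female": 0.95, "calf": 0.50}


def hippo_confusion() -> ConfusionMatrix:
    """The 5x5 validation confusion matrix (1200 co-observed seconds)."""
    return ConfusionMatrix(categories=EVAL_CATEGORIES, counts=_HIPPO_COUNTS.copy())
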