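"""Per-candidate ground-truth labels with missing/"unsure" codes.

Statuses are coded 0 / 1 / MISSING (-1) / UNSURE (-2).  A status that is
missing or unsure zeroes the corresponding loss weight, so the network is
never penalized where the ground truth is unknown.  Label dependency is
enforced: an observed PRL- or CVS-positive candidate must be lesion-positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import MISSING, UNSURE

__all__ = ["LabelRecord", "MISSING", "UNSURE"]

_VALID = {0, 1, MISSING, UNSURE}


@dataclass(frozen=True)
class LabelRecord:
    candidate_id: int
    lesion: int = MISSING
    prl: int = MISSING
    cvs: int = MISSING

    def __post_init__(self):
        for status in (self.lesion, self.prl, self.cvs):
            if status not in _VALID:
                raise ValueError(f"invalid status code {status}")
        if self.lesion == 0 and (self.prl == 1 or self.cvs == 1):
            raise ValueError(
                "label dependency violated: PRL/CVS positive requires lesion positive")

    @property
    def statuses(self) -> tuple[int, int, int]:
        return (self.lesion, self.prl, self.cvs)

    @property
    def loss_weights(self) -> np.ndarray:
        """(w_lesion, w_prl, w_cvs): 1 where observed, 0 where missing/unsure."""
        return np.array([1.0 if s in (0, 1) else 0.0 for s in self.statuses])

    @property
    def targets(self) -> np.ndarray:
        """Binary targets; arbitrary (0) where the weight is zero."""
        return np.array([1.0 if s == 1 else 0.0 for s in self.statuses])

    @property
    def n_positive(self) -> int:
        return sum(1 for s in self.statuses if s == 1)

    @property
    def any_observed(self) -> bool:
        return any(s in (0, 1) for s in self.statuses)
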