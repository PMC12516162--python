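"""Subject-level biomarker scores, coordinate matching, and ROC utilities.

Subject scores are threshold-invariant: the lesion score is the sum of
candidate lesion probabilities; the PRL percentage is the lesion-probability-
weighted mean of PRL probabilities times 100 (CVS identically), avoiding the
variance and bias of hard post-threshold counts.

Candidate-level evaluation matches gold-standard lesion coordinates into the
candidate partition: a candidate containing a PRL coordinate is PRL-positive,
a candidate containing no gold coordinate is a false-positive candidate (or
label-missing when the subject's lesion coordinates are incomplete).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .labels import MISSING, UNSURE, LabelRecord
from .split import CandidateMap

__all__ = [
    "SubjectScores",
    "subject_scores",
    "match_coordinates",
    "assemble_candidate_labels",
    "RocResult",
    "roc_and_youden",
]


@dataclass(frozen=True)
class SubjectScores:
    """lesion_score = sum of p_lesion; prl_pct / cvs_pct = lesion-weighted mean
    of p_prl / p_cvs x 100 (None when undefined: no candidates or zero total
    lesion probability)."""

    lesion_score: float
    prl_pct: float | None
    cvs_pct: float | None


def subject_scores(predictions) -> SubjectScores:
    """Aggregate candidate predictions for one subject.

    ``predictions`` is a DataFrame with p_lesion/p_prl/p_cvs columns or a
    sequence of :class:`CandidatePrediction`.
    """
    if isinstance(predictions, pd.DataFrame):
        p_les = predictions["p_lesion"].to_numpy(float)
        p_prl = predictions["p_prl"].to_numpy(float)
        p_cvs = predictions["p_cvs"].to_numpy(float)
    else:
        p_les = np.array([p.p_lesion for p in predictions], float)
        p_prl = np.array([p.p_prl for p in predictions], float)
        p_cvs = np.array([p.p_cvs for p in predictions], float)
    total = p_les.sum()
    if len(p_les) == 0 or total <= 0:
        return SubjectScores(lesion_score=float(total) if len(p_les) else 0.0,
                             prl_pct=None, cvs_pct=None)
    return SubjectScores(
        lesion_score=float(total),
        prl_pct=float(100.0 * (p_les * p_prl).sum() / total),
        cvs_pct=float(100.0 * (p_les * p_cvs).sum() / total))


# ---------------------------------------------------------------------------
# coordinate matching

_STR_TO_CODE = {"0": 0, "1": 1, "NA": MISSING, "unsure": UNSURE,
                0: 0, 1: 1, 0.0: 0, 1.0: 1}


def _code(value) -> int:
    if isinstance(value, float) and np.isnan(value):
        return MISSING
    try:
        return _STR_TO_CODE[value]
    except KeyError:
        raise ValueError(f"unrecognized status value {value!r}") from None


def match_coordinates(candidate_map: CandidateMap,
                      gold: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Map each gold coordinate to the candidate containing it.

    Returns the gold table with a ``candidate_id`` column (0 = unmatched) and
    a coverage dict: the fraction of positive lesion / PRL / CVS coordinates
    that fall inside some candidate.
    """
    shape = candidate_map.labels.shape
    out = gold.copy()
    ids = []
    for _, row in gold.iterrows():
        x, y, z = int(row.x), int(row.y), int(row.z)
        if not (0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]):
            raise ValueError(f"gold coordinate ({x}, {y}, {z}) outside volume {shape}")
        ids.append(int(candidate_map.labels[x, y, z]))
    out["candidate_id"] = ids
    matched = out["candidate_id"] > 0
    coverage = {}
    for column in ("lesion", "prl", "cvs"):
        codes = out[column].map(_code)
        pos = codes == 1
        coverage[column] = float(matched[pos].mean()) if pos.any() else np.nan
    return out, coverage


def assemble_candidate_labels(candidate_map: CandidateMap,
                              gold: pd.DataFrame) -> list[LabelRecord]:
    """Candidate-level labels from the matched gold coordinates.

    A candidate's status is the OR of its contained coordinates' statuses; a
    coordinate with "unsure" CVS confers lesion-positive but CVS-missing
    status.  When the subject's lesion (or CVS) labels are incomplete — any
    "NA" in the corresponding column — candidates without positive evidence
    get a missing status for that component instead of 0, so training never
    penalizes the unknown.
    """
    matched, _ = match_coordinates(candidate_map, gold)
    lesion_codes = matched["lesion"].map(_code)
    cvs_codes = matched["cvs"].map(_code)
    prl_codes = matched["prl"].map(_code)
    subject_lesions_missing = bool((lesion_codes == MISSING).any())
    subject_cvs_missing = bool((cvs_codes == MISSING).any())
    records = []
    for cid in candidate_map.candidate_ids:
        rows = matched["candidate_id"] == cid
        les = lesion_codes[rows]
        prl = prl_codes[rows]
        cvs = cvs_codes[rows]
        prl_status = 1 if (prl == 1).any() else 0
        if (cvs == 1).any():
            cvs_status = 1
        elif (cvs == UNSURE).any():
            cvs_status = UNSURE
        elif (cvs == MISSING).any() or (not rows.any() and subject_cvs_missing):
            cvs_status = MISSING
        elif rows.any():
            cvs_status = 0
        else:
            cvs_status = 0
        if (les == 1).any() or prl_status == 1 or cvs_status == 1 \
                or (cvs == UNSURE).any():
            lesion_status = 1
        elif (les == MISSING).any() or (not rows.any() and subject_lesions_missing):
            lesion_status = MISSING
        else:
            lesion_status = 0
        records.append(LabelRecord(candidate_id=int(cid), lesion=lesion_status,
                                   prl=prl_status, cvs=cvs_status))
    return records


# ---------------------------------------------------------------------------
# ROC / Youden

@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float
    youden_threshold: float
    youden_j: float


def roc_and_youden(scores, labels) -> RocResult:
    """Empirical ROC (score >= threshold is positive), trapezoidal AUROC, and
    the Youden-J-maximizing threshold (ties broken to the lower threshold).

    Labels coded missing/unsure are excluded before the curve is built.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    observed = (y == 0) | (y == 1)
    s, y = s[observed], y[observed].astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires at least one positive and one negative label")
    fpr, tpr, thr = roc_curve(y, s)
    auroc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = j.max()
    tied = np.flatnonzero(j >= best - 1e-12)
    youden_threshold = float(thr[tied].min())
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auroc=auroc,
                     youden_threshold=youden_threshold, youden_j=float(best))
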