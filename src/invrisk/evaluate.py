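"""Model evaluation: presence-background AUC, the two classification
thresholds, and three-class habitat maps.

With presence-only data there are no true absences, so the ROC is
computed against the background sample: AUC is the probability that a
random presence scores above a random background cell (Mann-Whitney
statistic with midrank tie handling).

Two thresholds convert continuous suitability into habitat classes:

* the *least training presence* (LTP) threshold -- the minimum score of
  any training presence, i.e. the most permissive cutoff that still
  classifies every training presence as suitable; and
* the *maximum sensitivity + specificity* (maxSSS) threshold -- the
  score maximising sensitivity (presences >= t) plus specificity
  (background < t), ties resolved to the smallest candidate score.

Cells at or above the maxSSS threshold are *suitable high-risk habitat*
(class 2); cells between LTP and maxSSS are *suitable low-risk habitat*
(class 1); the rest are unsuitable (class 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .grids import Layer


class EvaluationError(ValueError):
    pass


def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    Equals pair counting: (#{pres > bg} + 0.5 #{pres = bg}) / (n_p n_b).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise EvaluationError("AUC needs non-empty presence and background scores")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    return float((r_p - p.size * (p.size + 1) / 2.0) / (p.size * b.size))


def auc_band(value: float) -> str:
    """Discrimination label; each band requires the value to exceed its bound
    (0.5 itself is chance-level)."""
    if value > 0.9:
        return "excellent"
    if value > 0.8:
        return "very good"
    if value > 0.7:
        return "good"
    if value > 0.5:
        return "poor"
    return "random-ish"


def ltp_threshold(training_presence_scores) -> float:
    """Least training presence: the minimum training-presence score."""
    p = np.asarray(training_presence_scores, dtype=float)
    if p.size == 0:
        raise EvaluationError("LTP threshold needs at least one presence score")
    return float(p.min())


def max_sss_threshold(presence_scores, background_scores) -> float:
    """Threshold maximising sensitivity + specificity over the candidate set
    of sorted unique observed scores; ties go to the smallest threshold."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise EvaluationError("maxSSS needs non-empty presence and background scores")
    candidates = np.unique(np.concatenate([p, b]))
    best_t, best_val = candidates[0], -np.inf
    for t in candidates:
        sens = float((p >= t).mean())
        spec = float((b < t).mean())
        if sens + spec > best_val + 1e-12:
            best_val = sens + spec
            best_t = t
    return float(best_t)


@dataclass
class ThresholdPair:
    """LTP (low) and maxSSS (high) thresholds for one fitted model.

    With very few presences the LTP minimum can exceed the maxSSS
    optimum; in that case t_high is raised to t_low and the pair is
    flagged rather than failing.
    """

    t_low: float
    t_high: float
    flagged: bool = False

    def __post_init__(self) -> None:
        for t in (self.t_low, self.t_high):
            if not 0.0 <= t <= 1.0:
                raise EvaluationError(f"threshold {t} outside [0, 1]")
        if self.t_low > self.t_high:
            self.t_high = self.t_low
            self.flagged = True


def thresholds_from_training(
    training_presence_scores, background_scores
) -> ThresholdPair:
    """Compute both thresholds from training presences and background."""
    return ThresholdPair(
        t_low=ltp_threshold(training_presence_scores),
        t_high=max_sss_threshold(training_presence_scores, background_scores),
    )


def classify_map(suitability: Layer, thresholds: ThresholdPair) -> Layer:
    """Three-class habitat map: 0 unsuitable, 1 suitable low-risk,
    2 suitable high-risk.  Both comparisons are inclusive (>=); nodata
    propagates."""
    vals = suitability.values
    classes = np.full(vals.shape, np.nan)
    finite = np.isfinite(vals)
    classes[finite] = 0.0
    classes[finite & (vals >= thresholds.t_low)] = 1.0
    classes[finite & (vals >= thresholds.t_high)] = 2.0
    return Layer(spec=suitability.spec, name="habitat_class", values=classes)
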