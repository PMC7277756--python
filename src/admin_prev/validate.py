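"""Agreement of the case-finding algorithm with a clinical registry.

The algorithm is a binary classifier over an explicit evaluation frame, so
its operating point is a single 2x2 table.  Point estimates come with exact
(Clopper-Pearson) binomial confidence intervals; the ROC area of a binary
rule is the two-segment trapezoid (sensitivity + specificity) / 2, and
chance-corrected agreement is Cohen's kappa.

The frame is always an explicit argument: with a single-centre registry as
reference, specificity and predictive values measure agreement with that
registry, not with true disease status in the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.stats import beta as beta_dist


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total == 0:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def cross_classify(algorithm_ids: Iterable, reference_ids: Iterable,
                   frame_ids: Iterable) -> ConfusionTable:
    """2x2 cross-classification of algorithm vs reference over a frame.

    The algorithm set is intersected with the frame; the reference must be
    contained in it.
    """
    frame = set(frame_ids)
    if not frame:
        raise ValueError("evaluation frame is empty")
    ref = set(reference_ids)
    if not ref <= frame:
        raise ValueError("reference ids must be a subset of the frame")
    alg = set(algorithm_ids) & frame
    tp = len(alg & ref)
    fp = len(alg - ref)
    fn = len(ref - alg)
    tn = len(frame) - tp - fp - fn
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(x: int, n: int, level: float = 0.95
                    ) -> tuple[float, float]:
    """Exact two-sided binomial CI via beta quantiles."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n with n > 0")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def _proportion(x: int, n: int, level: float, margin: str
                ) -> tuple[float, tuple[float, float]]:
    if n == 0:
        raise ValueError(f"zero denominator for {margin}")
    return x / n, clopper_pearson(x, n, level)


def sensitivity(t: ConfusionTable, level: float = 0.95):
    """tp / (tp + fn) with exact CI."""
    return _proportion(t.tp, t.tp + t.fn, level, "sensitivity (tp+fn)")


def specificity(t: ConfusionTable, level: float = 0.95):
    """tn / (tn + fp) with exact CI."""
    return _proportion(t.tn, t.tn + t.fp, level, "specificity (tn+fp)")


def ppv(t: ConfusionTable, level: float = 0.95):
    """tp / (tp + fp) with exact CI."""
    return _proportion(t.tp, t.tp + t.fp, level, "PPV (tp+fp)")


def npv(t: ConfusionTable, level: float = 0.95):
    """tn / (tn + fn) with exact CI."""
    return _proportion(t.tn, t.tn + t.fn, level, "NPV (tn+fn)")


def auc_binary(sens: float, spec: float) -> float:
    """ROC area of a single binary rule: (sensitivity + specificity) / 2."""
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return 0.5 * (sens + spec)


def cohen_kappa(t: ConfusionTable) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    n = t.total
    p_o = (t.tp + t.tn) / n
    p_e = (
        (t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)
    ) / (n * n)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("degenerate margins: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def validation_report(algorithm_ids: Iterable, reference_ids: Iterable,
                      frame_ids: Iterable, level: float = 0.95) -> dict:
    """All agreement statistics for one algorithm over one frame."""
    t = cross_classify(algorithm_ids, reference_ids, frame_ids)
    se, se_ci = sensitivity(t, level)
    sp, sp_ci = specificity(t, level)
    pp, pp_ci = ppv(t, level)
    np_, np_ci = npv(t, level)
    return {
        "table": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn},
        "sensitivity": se, "sensitivity_ci": list(se_ci),
        "specificity": sp, "specificity_ci": list(sp_ci),
        "ppv": pp, "ppv_ci": list(pp_ci),
        "npv": np_, "npv_ci": list(np_ci),
        "auc": auc_binary(se, sp),
        "kappa": cohen_kappa(t),
        "level": level,
    }
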