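"""Evaluation suite for beat-to-beat SBP sequence estimation.

Sequence metrics
    MAE   mean absolute error over all m·n beats (mmHg),
    Rseq  mean over sequences of the within-sequence Pearson correlation
          between ground-truth and estimated trajectories,
    VE    variability error: the mean absolute difference between the
          first-order difference sequences (the ARV-based trend error), with
          1/(n-1) per-sequence normalisation (mmHg).

Value metrics
    ME/SD of the signed error (convention: pred − gt, population SD),
    10-beat-averaged variants, Bland–Altman agreement (mean difference,
    ±1.96·SD limits, % within limits).

State detection
    A sequence is "unsteady" when its SBP span (max − min) strictly exceeds
    10 mmHg; unsteady is the positive class in the ACC/Pre/Rec/F1 report.

Device-validation operations
    AAMI: pass iff |ME| ≤ 5 mmHg, SD ≤ 8 mmHg and ≥ 85 subjects.
    BHS:  grade A/B/C from the cumulative percentage of absolute errors
          within 5/10/15 mmHg (all three thresholds, boundaries inclusive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger("beatbp.metrics")

__all__ = [
    "SequencePair", "EvaluationReport", "mae_seq", "rseq", "diff_seq", "ve",
    "classify_state", "classification_report", "beat_averaged", "me_sd",
    "aami_check", "bhs_grade", "bland_altman", "evaluate_pairs",
    "STEADY_THRESH_MMHG",
]

STEADY_THRESH_MMHG = 10.0
BHS_LIMITS = {"A": (60.0, 85.0, 95.0), "B": (50.0, 75.0, 90.0),
              "C": (40.0, 65.0, 85.0)}


@dataclass
class SequencePair:
    """One ground-truth / estimated SBP sequence pair (equal length >= 2)."""

    gt: np.ndarray
    pred: np.ndarray

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=float)
        self.pred = np.asarray(self.pred, dtype=float)
        if self.gt.shape != self.pred.shape:
            raise ValueError("gt and pred must have equal length")
        if self.gt.ndim != 1 or len(self.gt) < 2:
            raise ValueError("sequences must be 1-D with length >= 2")


def _as_pairs(pairs) -> list:
    return [p if isinstance(p, SequencePair) else SequencePair(*p) for p in pairs]


# ------------------------------------------------------------------ sequence

def mae_seq(pairs) -> float:
    """Mean absolute error over all beats of all sequences (mmHg)."""
    pairs = _as_pairs(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    return float(np.mean(np.concatenate(
        [np.abs(p.gt - p.pred) for p in pairs])))


def rseq(pairs) -> float:
    """Mean within-sequence Pearson correlation.

    Pairs where either sequence has zero variance have an undefined
    correlation and are excluded (with a logged count).
    """
    pairs = _as_pairs(pairs)
    rs = []
    skipped = 0
    for p in pairs:
        if np.std(p.gt) == 0 or np.std(p.pred) == 0:
            skipped += 1
            continue
        rs.append(float(np.corrcoef(p.gt, p.pred)[0, 1]))
    if skipped:
        logger.warning("rseq: excluded %d zero-variance pair(s)", skipped)
    if not rs:
        raise ValueError("no pair with defined correlation")
    return float(np.mean(rs))


def diff_seq(seq: np.ndarray) -> np.ndarray:
    """First-order difference sequence (x_2 - x_1, ..., x_n - x_{n-1})."""
    return np.diff(np.asarray(seq, dtype=float))


def ve(pairs) -> float:
    """Variability error: mean |Δgt − Δpred| with 1/(n−1) normalisation."""
    pairs = _as_pairs(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    return float(np.mean([
        np.mean(np.abs(diff_seq(p.gt) - diff_seq(p.pred))) for p in pairs]))


# --------------------------------------------------------------------- states

def classify_state(seq: np.ndarray, thresh: float = STEADY_THRESH_MMHG) -> str:
    """'unsteady' iff the sequence span strictly exceeds ``thresh`` mmHg."""
    seq = np.asarray(seq, dtype=float)
    return "unsteady" if (seq.max() - seq.min()) > thresh else "steady"


def classification_report(gt_labels, pred_labels) -> dict:
    """ACC/Pre/Rec/F1 with 'unsteady' as the positive class."""
    gt = np.asarray(gt_labels)
    pr = np.asarray(pred_labels)
    if gt.shape != pr.shape:
        raise ValueError("label arrays must have equal length")
    pos = "unsteady"
    tp = int(np.sum((gt == pos) & (pr == pos)))
    fp = int(np.sum((gt != pos) & (pr == pos)))
    fn = int(np.sum((gt == pos) & (pr != pos)))
    tn = int(np.sum((gt != pos) & (pr != pos)))
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn, "acc": acc,
            "precision": precision, "recall": recall, "f1": f1}


# ---------------------------------------------------------------- aggregation

def beat_averaged(pairs, window: int = 10) -> list:
    """Non-overlapping ``window``-beat means of gt and pred (60 -> 6 values);
    trailing beats that do not fill a window are discarded."""
    out = []
    for p in _as_pairs(pairs):
        k = len(p.gt) // window
        if k < 2:
            raise ValueError("need at least two full windows per sequence")
        gt = p.gt[: k * window].reshape(k, window).mean(axis=1)
        pr = p.pred[: k * window].reshape(k, window).mean(axis=1)
        out.append(SequencePair(gt, pr))
    return out


def me_sd(pairs) -> tuple[float, float]:
    """Mean error and population SD of the signed error pred − gt (mmHg)."""
    pairs = _as_pairs(pairs)
    e = np.concatenate([p.pred - p.gt for p in pairs])
    return float(np.mean(e)), float(np.std(e))


# ----------------------------------------------------------------- standards

def aami_check(me: float, sd: float, n_subjects: int) -> dict:
    """AAMI verdict: |ME| ≤ 5 mmHg, SD ≤ 8 mmHg, ≥ 85 subjects."""
    ok = abs(me) <= 5.0 and sd <= 8.0 and n_subjects >= 85
    return {"pass": bool(ok), "me": float(me), "sd": float(sd),
            "n_subjects": int(n_subjects)}


def bhs_grade(abs_errors) -> dict:
    """Cumulative percentages of |error| ≤ 5/10/15 mmHg and the BHS grade.

    A grade requires all three thresholds; boundaries are inclusive. Errors
    meeting no grade are reported as 'D'.
    """
    e = np.abs(np.asarray(abs_errors, dtype=float))
    if e.size == 0:
        raise ValueError("need at least one error")
    pcts = tuple(float(100.0 * np.mean(e <= t)) for t in (5.0, 10.0, 15.0))
    grade = "D"
    for g in ("C", "B", "A"):
        if all(p >= lim for p, lim in zip(pcts, BHS_LIMITS[g])):
            grade = g
    return {"pct5": pcts[0], "pct10": pcts[1], "pct15": pcts[2],
            "grade": grade}


def bland_altman(pairs) -> dict:
    """Mean difference, ±1.96·SD limits of agreement, % of points within."""
    pairs = _as_pairs(pairs)
    d = np.concatenate([p.pred - p.gt for p in pairs])
    mean_diff = float(np.mean(d))
    sd = float(np.std(d))
    lo, hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    within = float(100.0 * np.mean((d >= lo) & (d <= hi)))
    return {"mean_diff": mean_diff, "loa_low": float(lo), "loa_high": float(hi),
            "pct_within": within}


# --------------------------------------------------------------------- report

@dataclass
class EvaluationReport:
    mae: float
    rseq: float
    ve: float
    me: float
    sd: float
    beat_avg: dict
    class_table: dict
    bhs: dict
    aami: dict
    bland_altman: dict
    n_sequences: int
    n_subjects: int

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    def summary(self) -> str:
        c = self.class_table
        return "\n".join([
            f"sequences: {self.n_sequences}  subjects: {self.n_subjects}",
            f"MAE  {self.mae:7.3f} mmHg   Rseq {self.rseq:6.3f}   "
            f"VE {self.ve:6.3f} mmHg",
            f"ME   {self.me:7.3f} mmHg   SD   {self.sd:6.3f} mmHg",
            f"beat-avg MAE {self.beat_avg['mae']:.3f}  ME "
            f"{self.beat_avg['me']:.3f}  SD {self.beat_avg['sd']:.3f} mmHg",
            f"state detection: ACC {c['acc']:.4f}  Pre {c['precision']:.4f}  "
            f"Rec {c['recall']:.4f}  F1 {c['f1']:.4f}  "
            f"(TP {c['tp']} FP {c['fp']} FN {c['fn']} TN {c['tn']})",
            f"BHS: {self.bhs['pct5']:.2f}% / {self.bhs['pct10']:.2f}% / "
            f"{self.bhs['pct15']:.2f}%  grade {self.bhs['grade']}",
            f"AAMI: {'pass' if self.aami['pass'] else 'fail'} "
            f"(ME {self.aami['me']:.3f}, SD {self.aami['sd']:.3f}, "
            f"n={self.aami['n_subjects']})",
            f"Bland-Altman: {self.bland_altman['mean_diff']:.3f} "
            f"[{self.bland_altman['loa_low']:.3f}, "
            f"{self.bland_altman['loa_high']:.3f}] mmHg, "
            f"{self.bland_altman['pct_within']:.1f}% within",
        ])


def evaluate_pairs(pairs, n_subjects: int = 1,
                   thresh: float = STEADY_THRESH_MMHG,
                   beat_window: int = 10) -> EvaluationReport:
    """Full evaluation of ground-truth/estimated sequence pairs."""
    pairs = _as_pairs(pairs)
    abs_err = np.concatenate([np.abs(p.pred - p.gt) for p in pairs])
    m, s = me_sd(pairs)
    ba_pairs = beat_averaged(pairs, window=beat_window)
    ba_me, ba_sd = me_sd(ba_pairs)
    gt_lab = [classify_state(p.gt, thresh) for p in pairs]
    pr_lab = [classify_state(p.pred, thresh) for p in pairs]
    return EvaluationReport(
        mae=mae_seq(pairs),
        rseq=rseq(pairs),
        ve=ve(pairs),
        me=m,
        sd=s,
        beat_avg={"mae": mae_seq(ba_pairs), "me": ba_me, "sd": ba_sd},
        class_table=classification_report(gt_lab, pr_lab),
        bhs=bhs_grade(abs_err),
        aami=aami_check(m, s, n_subjects),
        bland_altman=bland_altman(pairs),
        n_sequences=len(pairs),
        n_subjects=n_subjects,
    )
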