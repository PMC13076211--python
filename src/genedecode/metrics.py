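"""Base-wise F1 metrics and feature-level exact-match evaluation.

Base-wise scores are computed from confusion counts over unmasked,
non-padded bases only.  The aggregate scores are support-weighted averages of
per-class F1: genic F1 over {UTR, CDS, intron}, subgenic F1 over {CDS,
intron} and phase F1 over {phase 0, 1, 2}.  Feature-level evaluation reduces
both annotations to the primary (longest-protein) transcript with UTRs
removed and counts exact coordinate matches at the exon, intron, intron
chain and transcript levels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .encoding import CLASS_NAMES, LabeledTracks, SubsequenceBatch
from .models import GeneModel

FEATURE_LEVELS = ("exon", "intron", "intron_chain", "transcript")


def confusion(
    pred_classes: np.ndarray, truth_classes: np.ndarray, mask: np.ndarray, k: int = 4
) -> np.ndarray:
    """K x K confusion counts (true x predicted) over unmasked bases."""
    if pred_classes.shape != truth_classes.shape:
        raise ValueError("prediction/truth length mismatch")
    keep = ~mask
    t = truth_classes[keep]
    p = pred_classes[keep]
    return np.bincount(k * t + p, minlength=k * k).reshape(k, k)


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


@dataclass
class F1Report:
    """Per-class precision/recall/F1 plus the weighted aggregates."""

    class_names: tuple
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray  # true-class base counts (the aggregation weights)
    genic_f1: float = 0.0
    subgenic_f1: float = 0.0
    phase_f1: float = 0.0
    empty_classes: tuple = ()  # classes with zero support (F1 reported as 0)
    n_evaluated: int = 0


def _weighted(f1: np.ndarray, support: np.ndarray, idx) -> float:
    idx = list(idx)
    tot = support[idx].sum()
    if tot == 0:
        return 0.0
    return float((f1[idx] * support[idx]).sum() / tot)


def f1_scores(
    class_cm: np.ndarray, phase_cm: np.ndarray | None = None
) -> F1Report:
    """Precision, recall and F1 per genic class plus weighted aggregates.

    ``phase_f1`` is the support-weighted F1 over the three coding phases of
    the phase confusion matrix (channels {none, 0, 1, 2}); classes with no
    true support are flagged and score 0.
    """
    k = class_cm.shape[0]
    tp = np.diag(class_cm).astype(float)
    fp = class_cm.sum(axis=0) - tp
    fn = class_cm.sum(axis=1) - tp
    prec = np.zeros(k)
    rec = np.zeros(k)
    f1 = np.zeros(k)
    for i in range(k):
        prec[i], rec[i], f1[i] = _prf(tp[i], fp[i], fn[i])
    support = class_cm.sum(axis=1)
    report = F1Report(
        class_names=CLASS_NAMES,
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        genic_f1=_weighted(f1, support, [1, 2, 3]),
        subgenic_f1=_weighted(f1, support, [2, 3]),
        empty_classes=tuple(
            CLASS_NAMES[i] for i in range(min(k, 4)) if support[i] == 0
        ),
        n_evaluated=int(class_cm.sum()),
    )
    if phase_cm is not None:
        ptp = np.diag(phase_cm).astype(float)
        pfp = phase_cm.sum(axis=0) - ptp
        pfn = phase_cm.sum(axis=1) - ptp
        pf1 = np.zeros(phase_cm.shape[0])
        for i in range(phase_cm.shape[0]):
            _, _, pf1[i] = _prf(ptp[i], pfp[i], pfn[i])
        psup = phase_cm.sum(axis=1)
        report.phase_f1 = _weighted(pf1, psup, [1, 2, 3])
    return report


def evaluate_tracks(pred, truth: LabeledTracks, mask: np.ndarray | None = None) -> F1Report:
    """Argmax the prediction tracks and score them against reference labels."""
    mask = truth.mask if mask is None else mask
    cm = confusion(pred.class_probs.argmax(axis=1), truth.class_ids, mask)
    pm = confusion(pred.phase_probs.argmax(axis=1), truth.phase_ids, mask)
    return f1_scores(cm, pm)


def sample_subsequences(
    batch: SubsequenceBatch, n: int = 800, seed: int | None = None
) -> np.ndarray:
    """Indices of a seeded random sample of ``n`` windows, without
    replacement (all windows when fewer are available)."""
    total = batch.n_windows
    if total < 1:
        raise ValueError("empty batch")
    if total <= n:
        return np.arange(total)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(total, size=n, replace=False))


def transition_adjacent_f1(pred, truth: LabeledTracks, radius: int = 3) -> F1Report:
    """F1 restricted to unmasked bases within ``radius`` of a true class
    transition (the bases immediately before/after a boundary).

    With no transitions in the truth the report is empty (zero bases
    evaluated) and all classes are flagged.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    cls = truth.class_ids
    change = np.flatnonzero(cls[1:] != cls[:-1]) + 1  # first base of new class
    near = np.zeros(len(truth), dtype=bool)
    for p in change:
        near[max(0, p - radius) : p + radius] = True
    mask = truth.mask | ~near
    return evaluate_tracks(pred, truth, mask=mask)


# ---------------------------------------------------------------------------
# feature-level exact matches
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatchReport:
    level: str
    tp: int
    fp: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self):
        self.precision, self.recall, self.f1 = _prf(self.tp, self.fp, self.fn)


def _features(models: list[GeneModel], level: str) -> Counter:
    out: Counter = Counter()
    for m in models:
        if not m.cds:
            continue
        segs = list(m.cds)  # UTRs removed: CDS-bounded exons
        key = (m.contig_id, m.strand)
        introns = tuple(
            (segs[i][1], segs[i + 1][0]) for i in range(len(segs) - 1)
        )
        if level == "exon":
            for iv in segs:
                out[key + iv] += 1
        elif level == "intron":
            for iv in introns:
                out[key + iv] += 1
        elif level == "intron_chain":
            if introns:
                out[key + (introns,)] += 1
        elif level == "transcript":
            out[key + (introns, segs[0][0], segs[-1][1])] += 1
        else:
            raise ValueError(f"unknown level {level!r}")
    return out


def feature_match(
    pred: list[GeneModel], ref: list[GeneModel], level: str = "all"
):
    """Exact-coordinate feature matches between two annotations.

    Both annotations are reduced to CDS features of the primary transcript;
    a feature counts as TP only on an exact interval (and, for chains, exact
    ordered-list) match on the same contig and strand.  ``level='all'``
    returns a dict over all four levels.
    """
    if level == "all":
        return {lv: feature_match(pred, ref, lv) for lv in FEATURE_LEVELS}
    p = _features(pred, level)
    r = _features(ref, level)
    tp = sum(min(p[k], r[k]) for k in p.keys() & r.keys())
    return FeatureMatchReport(
        level=level, tp=tp, fp=sum(p.values()) - tp, fn=sum(r.values()) - tp
    )


def report_frame(reports: dict) -> "pandas.DataFrame":
    """Feature-match reports as a tidy DataFrame (one row per level)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "level": r.level,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
            }
            for r in reports.values()
        ]
    )
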