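"""Class- and transition-weighted dual-head cross-entropy loss.

The labeler has two output heads: genic class and coding phase.  The overall
loss is ``0.8 * weighted_CE(class) + 0.2 * CE(phase)``.  The class head uses
per-class weights (the intergenic class is by far the most common and the one
we care least about, so it is down-weighted) that are further multiplied
within a small radius of the four class transition sites -- start codon, stop
codon, donor splice site, acceptor splice site -- to push predictions to be
sharp exactly where gene structure is decided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import CDS, IG, INTRON, UTR, LabeledTracks

SITE_CATEGORIES = ("start_codon", "stop_codon", "donor", "acceptor")


@dataclass(frozen=True)
class LossConfig:
    #: per-class weights in (intergenic, UTR, CDS, intron) order
    class_weights: tuple[float, float, float, float] = (0.7, 1.6, 1.2, 1.2)
    transition_multiplier: float = 10.0
    transition_radius: int = 3
    genic_head_weight: float = 0.8
    phase_head_weight: float = 0.2

    def __post_init__(self):
        if abs(self.genic_head_weight + self.phase_head_weight - 1.0) > 1e-9:
            raise ValueError("head weights must sum to 1")
        if self.transition_multiplier < 1:
            raise ValueError("transition multiplier must be >= 1")
        if self.transition_radius < 0:
            raise ValueError("transition radius must be >= 0")


def transition_sites(truth: LabeledTracks) -> dict[str, np.ndarray]:
    """Flag the four transition-site categories from the reference class track.

    Exactly four categories exist; a site is flagged at the first base of the
    new class (e.g. the A of ATG for a start codon).  Transcription start/end
    (intergenic <-> UTR) is deliberately not a category.
    """
    cls = truth.class_ids
    prev, nxt = cls[:-1], cls[1:]
    exonic_prev = (prev == UTR) | (prev == CDS)
    exonic_next = (nxt == UTR) | (nxt == CDS)
    flags = {
        "start_codon": ((prev == IG) | (prev == UTR)) & (nxt == CDS),
        "stop_codon": (prev == CDS) & ((nxt == IG) | (nxt == UTR)),
        "donor": exonic_prev & (nxt == INTRON),
        "acceptor": (prev == INTRON) & exonic_next,
    }
    out = {}
    for name in SITE_CATEGORIES:
        arr = np.zeros(len(truth), dtype=bool)
        arr[1:] = flags[name]
        out[name] = arr
    return out


def transition_weight_map(truth: LabeledTracks, cfg: LossConfig) -> np.ndarray:
    """Per-base loss weights: class weight, boosted near transition sites,
    zero at masked bases."""
    w = np.asarray(cfg.class_weights, dtype=np.float64)[truth.class_ids]
    boost = np.zeros(len(truth), dtype=bool)
    r = cfg.transition_radius
    if r > 0:
        sites = np.zeros(len(truth), dtype=bool)
        for arr in transition_sites(truth).values():
            sites |= arr
        for p in np.flatnonzero(sites):
            boost[max(0, p - r) : p + r] = True
    w[boost] *= cfg.transition_multiplier
    w[truth.mask] = 0.0
    return w


def _check_rows(p: np.ndarray, what: str) -> None:
    if p.min() < -1e-9 or np.abs(p.sum(axis=1) - 1).max() > 1e-4:
        raise ValueError(f"{what} rows are not probability distributions")


def composite_loss(pred, truth: LabeledTracks, cfg: LossConfig = LossConfig()) -> float:
    """Weighted sum of the two heads, averaged over unmasked bases.

    Class head: categorical cross-entropy with :func:`transition_weight_map`
    weights, normalized by the total weight.  Phase head: plain categorical
    cross-entropy.  With ``transition_multiplier = 1`` this reduces to the
    plain class-weighted loss; predictions at masked bases never contribute.
    """
    class_probs, phase_probs = pred.class_probs, pred.phase_probs
    if class_probs.shape != truth.genic_class.shape:
        raise ValueError("prediction/truth shape mismatch")
    _check_rows(class_probs, "class head")
    _check_rows(phase_probs, "phase head")
    keep = ~truth.mask
    if not keep.any():
        raise ValueError("no unmasked bases to evaluate")
    tiny = np.finfo(np.float64).tiny
    ce_class = -np.log(
        np.maximum((class_probs * truth.genic_class).sum(axis=1), tiny)
    )
    ce_phase = -np.log(np.maximum((phase_probs * truth.phase).sum(axis=1), tiny))
    w = transition_weight_map(truth, cfg)
    class_term = float((w * ce_class).sum() / w.sum())
    phase_term = float(ce_phase[keep].mean())
    return cfg.genic_head_weight * class_term + cfg.phase_head_weight * phase_term
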