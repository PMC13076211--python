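"""Probability tracks, the noise oracle, and sliding-window mean-ensemble
inference."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import LabeledTracks


@dataclass
class PredictionTracks:
    """Per-base class and phase probability vectors (each row a distribution),
    in the same strand-local orientation as the label tracks."""

    class_probs: np.ndarray  # (L, 4)
    phase_probs: np.ndarray  # (L, 4)
    contig_id: str = ""
    strand: str = "+"

    def __len__(self) -> int:
        return self.class_probs.shape[0]

    def validate(self) -> None:
        for name, p in (("class", self.class_probs), ("phase", self.phase_probs)):
            if p.min() < -1e-9 or np.abs(p.sum(axis=1) - 1).max() > 1e-4:
                raise ValueError(f"{name} rows are not probability distributions")


def oracle_predictor(
    truth: LabeledTracks,
    noise: float,
    seed: int | None = None,
    jitter: bool = False,
) -> PredictionTracks:
    """Corrupt reference labels into probability tracks (weight-free stand-in).

    Each row is ``(1 - noise) * one_hot + noise * u`` where ``u`` is the
    uniform distribution, or -- with ``jitter`` -- a seeded symmetric
    Dirichlet(1,1,1,1) draw (uniform in expectation), so that larger noise can
    actually flip argmax calls.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError(f"noise must be in [0, 1], got {noise}")
    L = len(truth)
    if jitter:
        rng = np.random.default_rng(seed)
        u_class = rng.dirichlet(np.ones(4), size=L)
        u_phase = rng.dirichlet(np.ones(4), size=L)
    else:
        u_class = u_phase = np.full((L, 4), 0.25)
    out = PredictionTracks(
        class_probs=(1 - noise) * truth.genic_class + noise * u_class,
        phase_probs=(1 - noise) * truth.phase + noise * u_phase,
        contig_id=truth.contig_id,
        strand=truth.strand,
    )
    out.validate()
    return out


def predict_sliding(
    predict_fn,
    encoding: np.ndarray,
    window: int,
    stride: int | None = None,
) -> PredictionTracks:
    """Mean-ensemble inference over overlapping windows.

    ``predict_fn`` maps a ``(window, 4)`` base-encoding slice to a pair of
    ``(window, 4)`` probability matrices.  Short trailing windows are padded
    with uniform rows, predicted, and trimmed; each base's output is the
    arithmetic mean over all windows covering it (a distribution by
    convexity, renormalized only to absorb float error).
    """
    L = encoding.shape[0]
    stride = window if stride is None else stride
    if stride <= 0 or stride > window:
        raise ValueError("stride must be in (0, window]")
    starts = list(range(0, max(L - window, 0) + 1, stride))
    if starts[-1] + window < L:
        starts.append(L - window if L >= window else 0)
    sum_class = np.zeros((L, 4))
    sum_phase = np.zeros((L, 4))
    cover = np.zeros(L)
    for s in starts:
        sl = encoding[s : s + window]
        if sl.shape[0] < window:
            sl = np.vstack([sl, np.full((window - sl.shape[0], 4), 0.25)])
        c, p = predict_fn(sl)
        n = min(window, L - s)
        sum_class[s : s + n] += c[:n]
        sum_phase[s : s + n] += p[:n]
        cover[s : s + n] += 1
    cls = sum_class / cover[:, None]
    ph = sum_phase / cover[:, None]
    cls /= cls.sum(axis=1, keepdims=True)
    ph /= ph.sum(axis=1, keepdims=True)
    return PredictionTracks(cls, ph)
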