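"""A small trainable base-wise labeler with two output heads.

This is a generative sequence labeler in the gene-finder tradition: a hidden
state chain over intergenic, UTR, motif-anchored start/stop and splice-site
states, phase-tracked coding states with 3-periodic Markov-chain emissions,
and phase-carrying intron states.  All parameters -- emission tables up to
second order, self-loop/branch probabilities -- are estimated by supervised
counting from labeled windows, and prediction runs the forward-backward
algorithm, whose posterior state marginals are reduced to the genic-class
and coding-phase probability tracks the rest of the pipeline consumes.

Training tries a small grid of emission context orders ("checkpoints") and
returns the one with maximal genic F1 on the validation batch; with order 0
the coding emissions lose their periodic context, which serves as the
ablation switch.  Everything is deterministic given the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import CDS, IG, INTRON, UTR, SubsequenceBatch
from .metrics import confusion, f1_scores

N_STATES = 27
S_IG, S_U5, S_U3 = 0, 1, 2
S_M = (3, 4, 5)  # start codon A, T, G
S_C = (6, 7, 8)  # regular codon positions
S_S = (9, 10, 11)  # stop codon positions


def _intron(r: int, j: int) -> int:
    """Intron state for resume codon position r: j in (D0, D1, body, A0, A1)."""
    return 12 + 5 * r + j


#: genic-class channel per state
STATE_CLASS = np.array([IG, UTR, UTR] + [CDS] * 9 + [INTRON] * 15)
#: phase-track channel per state (codon position p -> channel (1, 3, 2)[p])
STATE_PHASE = np.zeros(N_STATES, dtype=np.int64)
for _p, _ch in enumerate((1, 3, 2)):
    STATE_PHASE[S_M[_p]] = _ch
    STATE_PHASE[S_C[_p]] = _ch
    STATE_PHASE[S_S[_p]] = _ch

_ALLOWED: list[tuple[int, int]] = [
    (S_IG, S_IG), (S_IG, S_U5), (S_IG, S_M[0]),
    (S_U5, S_U5), (S_U5, S_M[0]),
    (S_U3, S_U3), (S_U3, S_IG),
    (S_M[0], S_M[1]), (S_M[1], S_M[2]),
    (S_M[2], S_C[0]), (S_M[2], S_S[0]),
    (S_C[0], S_C[1]), (S_C[1], S_C[2]),
    (S_C[2], S_C[0]), (S_C[2], S_S[0]),
    (S_S[0], S_S[1]), (S_S[1], S_S[2]),
    (S_S[2], S_U3), (S_S[2], S_IG),
]
for _r in range(3):
    _donor_from = {0: [S_M[2], S_C[2], S_S[2]], 1: [S_M[0], S_C[0], S_S[0]],
                   2: [S_M[1], S_C[1], S_S[1]]}[_r]
    for _f in _donor_from:
        if _f != S_S[2]:  # no intron after the final stop base
            _ALLOWED.append((_f, _intron(_r, 0)))
    _ALLOWED += [
        (_intron(_r, 0), _intron(_r, 1)),
        (_intron(_r, 1), _intron(_r, 2)), (_intron(_r, 1), _intron(_r, 3)),
        (_intron(_r, 2), _intron(_r, 2)), (_intron(_r, 2), _intron(_r, 3)),
        (_intron(_r, 3), _intron(_r, 4)),
        (_intron(_r, 4), S_C[_r]), (_intron(_r, 4), S_S[_r]),
    ]
ALLOWED = np.zeros((N_STATES, N_STATES), dtype=bool)
for _f, _t in _ALLOWED:
    ALLOWED[_f, _t] = True

_PHASE_TO_POS = {1: 0, 3: 1, 2: 2}  # phase channel -> codon position

#: emission tying groups: the two UTR states share one table, and each intron
#: role (donor bases, body, acceptor bases) shares its table across the three
#: resume-phase copies -- their composition is identical, only the structural
#: bookkeeping differs, and tying triples the effective counts.
TIE_GROUPS: list[tuple[int, ...]] = (
    [(S_IG,), (S_U5, S_U3)]
    + [(s,) for s in range(3, 12)]
    + [tuple(_intron(r, j) for r in range(3)) for j in range(5)]
)


@dataclass(frozen=True)
class ToyModelConfig:
    emission_orders: tuple[int, ...] = (0, 1, 2)
    emission_pseudocount: float = 0.1
    transition_pseudocount: float = 0.1


def assign_states(
    y_class: np.ndarray, y_phase: np.ndarray, pad: np.ndarray
) -> np.ndarray:
    """Map reference labels of one window to labeler states (-1 = skip).

    Start/stop codons, splice-site bases and UTR sidedness are recovered from
    run boundaries; runs truncated by the window edge stay unassigned.
    """
    W = y_class.shape[0]
    cls = y_class.argmax(axis=1)
    cls[pad] = -2
    ph = y_phase.argmax(axis=1)
    st = np.full(W, -1, dtype=np.int64)
    st[cls == IG] = S_IG
    is_cds = cls == CDS
    pos = np.array([_PHASE_TO_POS.get(c, 0) for c in ph])
    st[is_cds] = np.array(S_C)[pos[is_cds]]
    # run boundaries
    change = np.flatnonzero(cls[1:] != cls[:-1]) + 1
    bounds = np.concatenate([[0], change, [W]])
    runs = [(int(bounds[i]), int(bounds[i + 1]), int(cls[bounds[i]]))
            for i in range(len(bounds) - 1)]
    for i, (a, b, c) in enumerate(runs):
        left = runs[i - 1][2] if i > 0 else None
        right = runs[i + 1][2] if i + 1 < len(runs) else None
        if c == CDS:
            if left in (IG, UTR) and b - a >= 3:
                st[a : a + 3] = S_M
            if right in (IG, UTR) and b - a >= 3:
                st[b - 3 : b] = S_S
        elif c == UTR:
            if right == CDS:
                st[a:b] = S_U5
            elif left == CDS:
                st[a:b] = S_U3
            else:
                st[a:b] = -1
        elif c == INTRON:
            if right == CDS and b - a >= 4:
                r = int(pos[b]) if b < W else 0
                st[a:b] = _intron(r, 2)
                st[a] = _intron(r, 0)
                st[a + 1] = _intron(r, 1)
                st[b - 2] = _intron(r, 3)
                st[b - 1] = _intron(r, 4)
            else:
                st[a:b] = -1
    st[pad] = -1
    return st


class GenerativeLabeler:
    """Fitted labeler: emission tables at a given context order + transition
    matrix.  ``predict_window`` maps a one-hot/ambiguity-encoded window to
    (class_probs, phase_probs)."""

    def __init__(self, emissions: np.ndarray, order0: np.ndarray,
                 transitions: np.ndarray, order: int):
        self.emissions = emissions  # (S, 4**order, 4)
        self.order0 = order0  # (S, 4) context-free fallback
        self.transitions = transitions  # (S, S) row-stochastic
        self.order = order

    def _emission_probs(self, base_idx: np.ndarray) -> np.ndarray:
        W = base_idx.shape[0]
        o = self.order
        e = self.order0[:, base_idx].T.copy()
        if o >= 1:
            ctx = np.zeros(W, dtype=np.int64)
            for k in range(o, 0, -1):  # oldest base most significant
                ctx[o:] = ctx[o:] * 4 + base_idx[o - k : W - k]
            e[o:] = self.emissions[:, ctx[o:], base_idx[o:]].T
        return e

    def predict_window(self, x: np.ndarray):
        base_idx = x.argmax(axis=1)
        e = self._emission_probs(base_idx)
        W = e.shape[0]
        T = self.transitions
        alpha = np.empty((W, N_STATES))
        a = np.full(N_STATES, 1.0 / N_STATES) * e[0]
        alpha[0] = a / a.sum()
        for t in range(1, W):
            a = (T.T @ alpha[t - 1]) * e[t]
            s = a.sum()
            alpha[t] = a / s if s > 0 else 1.0 / N_STATES
        beta = np.empty((W, N_STATES))
        b = np.ones(N_STATES)
        beta[W - 1] = b
        for t in range(W - 2, -1, -1):
            b = T @ (beta[t + 1] * e[t + 1])
            s = b.sum()
            beta[t] = b / s if s > 0 else 1.0 / N_STATES
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        class_probs = np.zeros((W, 4))
        phase_probs = np.zeros((W, 4))
        for s in range(N_STATES):
            class_probs[:, STATE_CLASS[s]] += gamma[:, s]
            phase_probs[:, STATE_PHASE[s]] += gamma[:, s]
        return class_probs, phase_probs


@dataclass
class TrainResult:
    predictor: GenerativeLabeler
    history: list = field(default_factory=list)  # (order, validation genic F1)
    best_order: int = 0


def _count(batch: SubsequenceBatch, max_order: int = 2):
    """Emission counts at max order (marginalized later) and transition
    counts, over unmasked non-padding bases."""
    n_ctx = 4**max_order
    E = np.zeros((N_STATES, n_ctx, 4))
    T = np.zeros((N_STATES, N_STATES))
    any_unmasked = False
    for w in range(batch.n_windows):
        st = assign_states(batch.y_class[w], batch.y_phase[w], batch.pad_mask[w])
        base_idx = batch.x[w].argmax(axis=1)
        usable = (st >= 0) & ~batch.mask[w]
        any_unmasked |= bool((~batch.mask[w]).any())
        W = st.shape[0]
        ctx = np.zeros(W, dtype=np.int64)
        for k in range(max_order, 0, -1):
            ctx[max_order:] = ctx[max_order:] * 4 + base_idx[max_order - k : W - k]
        sel = np.flatnonzero(usable)
        sel = sel[sel >= max_order]
        np.add.at(E, (st[sel], ctx[sel], base_idx[sel]), 1)
        both = usable[1:] & usable[:-1]
        np.add.at(T, (st[:-1][both], st[1:][both]), 1)
    if not any_unmasked:
        raise ValueError("no unmasked bases in the training batch")
    for group in TIE_GROUPS:
        if len(group) > 1:
            E[list(group)] = E[list(group)].sum(axis=0)
    return E, T


def _normalize(counts: np.ndarray, pseudo: float) -> np.ndarray:
    c = counts + pseudo
    return c / c.sum(axis=-1, keepdims=True)


def train_toy(
    train_batch: SubsequenceBatch,
    val_batch: SubsequenceBatch,
    cfg: ToyModelConfig = ToyModelConfig(),
    seed: int = 0,
) -> TrainResult:
    """Fit by counting, then select the emission order ("checkpoint") with
    maximal validation genic F1.

    Training and validation batches are expected to be disjoint by contig;
    nothing here is stochastic, so results are identical across runs with the
    same inputs (the seed is accepted for interface symmetry).
    """
    del seed  # counting + argmax: deterministic by construction
    E2, Tc = _count(train_batch, max_order=2)
    Tmat = np.where(ALLOWED, Tc + cfg.transition_pseudocount, 0.0)
    Tmat /= Tmat.sum(axis=1, keepdims=True)
    E_by_order = {
        2: E2,
        1: E2.reshape(N_STATES, 4, 4, 4).sum(axis=1),
        0: E2.sum(axis=1),
    }
    order0 = _normalize(E_by_order[0], cfg.emission_pseudocount)
    history = []
    best = None
    for order in cfg.emission_orders:
        em = _normalize(E_by_order[order], cfg.emission_pseudocount)
        if order == 0:
            em = em.reshape(N_STATES, 1, 4)
        model = GenerativeLabeler(em, order0, Tmat, order)
        cm = np.zeros((4, 4), dtype=np.int64)
        for w in range(val_batch.n_windows):
            cls, _ = model.predict_window(val_batch.x[w])
            cm += confusion(
                cls.argmax(axis=1),
                val_batch.y_class[w].argmax(axis=1),
                val_batch.mask[w],
            )
        f1 = f1_scores(cm).genic_f1
        history.append((order, f1))
        if best is None or f1 > best[1]:
            best = (model, f1, order)
    return TrainResult(predictor=best[0], history=history, best_order=best[2])


def save_model(path, model: GenerativeLabeler) -> None:
    np.savez_compressed(
        path,
        emissions=model.emissions,
        order0=model.order0,
        transitions=model.transitions,
        order=np.array([model.order]),
    )


def load_model(path) -> GenerativeLabeler:
    with np.load(path) as z:
        return GenerativeLabeler(
            z["emissions"], z["order0"], z["transitions"], int(z["order"][0])
        )
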