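"""Independent oracles used by the test suite.

These deliberately avoid the library's dynamic-programming and vectorized
code paths: the path oracle enumerates every legal state path by depth-first
search (with the admissible bound acc <= best, which cannot change the
minimum since all penalties are non-negative), and the F1 oracle recomputes
precision/recall/F1 from raw labels by explicit counting.
"""

from collections import defaultdict
from math import inf

import numpy as np

from genedecode.decoder import emission_penalty, transition_penalty
from genedecode.predict import PredictionTracks
from genedecode.states import HmmStateSpace


def brute_force_min_penalty(
    space: HmmStateSpace, tracks: PredictionTracks, seq, params
) -> float:
    """Minimum total penalty over all legal state paths that start from and
    end in the intergenic state (inf when no finite path exists)."""
    residues = seq.residues
    L = len(residues)
    ig = space.by_name["IG"].index
    succ = defaultdict(list)
    for tr in space.transitions:
        succ[tr.frm].append(tr)
    best = [inf]

    def dfs(state: int, t: int, acc: float) -> None:
        if acc > best[0]:
            return
        if t == L:
            if state == ig:
                best[0] = min(best[0], acc)
            return
        for tr in succ[state]:
            pen = transition_penalty(tr, space, residues, t, params)
            if pen == inf:
                continue
            e = emission_penalty(
                space.states[tr.to],
                tracks.class_probs[t],
                tracks.phase_probs[t],
                params,
            )
            dfs(tr.to, t + 1, acc + pen + e)

    dfs(ig, 0, 0.0)
    return best[0]


def brute_force_f1(truth: np.ndarray, pred: np.ndarray, classes) -> dict:
    """Per-class precision/recall/F1 by direct counting over raw labels."""
    out = {}
    for c in classes:
        tp = int(np.sum((truth == c) & (pred == c)))
        fp = int(np.sum((truth != c) & (pred == c)))
        fn = int(np.sum((truth == c) & (pred != c)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = {"precision": prec, "recall": rec, "f1": f1,
                  "support": int(np.sum(truth == c))}
    return out


def brute_force_weighted_f1(truth, pred, classes) -> float:
    per = brute_force_f1(truth, pred, classes)
    tot = sum(per[c]["support"] for c in classes)
    if tot == 0:
        return 0.0
    return sum(per[c]["f1"] * per[c]["support"] for c in classes) / tot


def random_instance(seed: int, min_len: int = 18, max_len: int = 30):
    """A seeded random decode instance: sequence + Dirichlet probability
    tracks, occasionally with a planted short gene so coding paths exist."""
    from genedecode.dna import ContigSequence

    rng = np.random.default_rng(seed)
    L = int(rng.integers(min_len, max_len + 1))
    bases = rng.choice(list("ACGT"), size=L)
    if rng.random() < 0.6 and L >= 14:
        # plant ATG ... stop so finite coding paths are likely
        start = int(rng.integers(0, L - 12))
        bases[start : start + 3] = list("ATG")
        bases[start + 9 : start + 12] = list("TAA")
    seq = ContigSequence("t", "".join(bases))
    cls = rng.dirichlet(np.full(4, 0.8), size=L)
    ph = rng.dirichlet(np.full(4, 0.8), size=L)
    return seq, PredictionTracks(cls, ph, "t", "+")
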