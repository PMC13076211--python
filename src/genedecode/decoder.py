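"""Min-penalty decoding of probability tracks into gene models.

The decoder first finds candidate genic regions -- maximal intervals where a
sliding-window average of the intergenic probability stays below a threshold
-- then, within each region (plus an intergenic margin), runs a Viterbi-style
dynamic program over the gene-grammar state space.  The path penalty is the
sum of per-base emission penalties (negative log of the probability the
tracks assign to the state's genic class, plus the phase term for CDS
states) and per-transition motif penalties (zero at the required motif,
configurable or infinite otherwise).  No likelihood is trained: the grammar
encodes established biology and the probability tracks carry all the
evidence.

Penalties are additive, so ties are possible; they are broken by fixed state
order (intergenic first), which prefers paths that enter genic states later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dna import ContigSequence, base_indices
from .encoding import CDS, IG, to_local
from .models import GeneModel
from .predict import PredictionTracks
from .states import HmmStateSpace, State, StateSpaceConfig, Transition, build_state_space

INF = math.inf


@dataclass(frozen=True)
class PenaltyParams:
    """Tunable penalties and thresholds of the decoder (all config, none
    fitted)."""

    intergenic_window: int = 100
    intergenic_threshold: float = 0.5
    emission_floor: float = 1e-8
    min_cds_length: int = 60
    #: per-motif-class transition penalties; canonical GT-AG is free and the
    #: non-canonical classes default to infinity (canonical-only decoding).
    motif_penalties: dict = field(
        default_factory=lambda: {"gt_ag": 0.0, "gc_ag": INF, "other": INF}
    )

    def __post_init__(self):
        if not 0 < self.emission_floor <= 1:
            raise ValueError("emission floor must be in (0, 1]")
        if not 0 < self.intergenic_threshold < 1:
            raise ValueError("intergenic threshold must be in (0, 1)")
        if self.motif_penalties.get("gt_ag", 0.0) != 0.0:
            raise ValueError("canonical GT-AG motifs must have penalty 0")


@dataclass(frozen=True)
class CandidateRegion:
    contig_id: str
    start: int  # 0-based half-open, strand-local
    end: int
    strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty candidate region")


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with partial windows at the edges."""
    L = x.shape[0]
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(L) - half, 0)
    hi = np.minimum(np.arange(L) + (window - half), L)
    return (csum[hi] - csum[lo]) / (hi - lo)


def find_candidate_regions(
    tracks: PredictionTracks, params: PenaltyParams = PenaltyParams()
) -> list[CandidateRegion]:
    """Maximal intervals of consistently low intergenic probability.

    The windowed moving average of the intergenic probability is compared
    against the threshold position by position; runs below threshold become
    regions, and regions separated by less than one window are merged.
    """
    avg = moving_average(tracks.class_probs[:, IG], params.intergenic_window)
    below = avg < params.intergenic_threshold
    runs: list[list[int]] = []
    idx = np.flatnonzero(below)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        run_ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
        for s, e in zip(run_starts, run_ends):
            if runs and s - runs[-1][1] < params.intergenic_window:
                runs[-1][1] = int(e)
            else:
                runs.append([int(s), int(e)])
    return [
        CandidateRegion(tracks.contig_id, s, e, tracks.strand) for s, e in runs
    ]


# ---------------------------------------------------------------------------
# penalties
# ---------------------------------------------------------------------------

def emission_penalty(
    state: State,
    class_row: np.ndarray,
    phase_row: np.ndarray,
    params: PenaltyParams = PenaltyParams(),
) -> float:
    """Per-base discrepancy between a state and the predicted distributions:
    ``-log P(class)``, plus ``-log P(phase)`` for CDS states, floored at the
    emission floor."""
    eps = params.emission_floor
    pen = -math.log(max(eps, float(class_row[state.super_class])))
    if state.super_class == CDS:
        pen += -math.log(max(eps, float(phase_row[1 + state.phase])))
    return pen


def transition_penalty(
    trans: Transition,
    space: HmmStateSpace,
    seq: str,
    t: int,
    params: PenaltyParams = PenaltyParams(),
) -> float:
    """Penalty of taking ``trans`` so that the entered state emits base ``t``.

    Zero when every required motif base matches (canonical case); the
    configured motif-class penalty otherwise, and infinity for a mismatched
    hard requirement.  Positions outside the sequence fail their checks.
    """
    to_state = space.states[trans.to]
    checks = list(trans.checks)
    if to_state.base_allowed is not None:
        checks.append((0, to_state.base_allowed))
    for off, allowed in checks:
        p = t + off
        if not (0 <= p < len(seq)) or seq[p] not in allowed:
            return INF
    return params.motif_penalties.get(trans.penalty_key, INF) if trans.penalty_key else 0.0


# ---------------------------------------------------------------------------
# dynamic programming
# ---------------------------------------------------------------------------

def _emission_matrix(
    space: HmmStateSpace, tracks: PredictionTracks, seq_idx: np.ndarray,
    start: int, end: int, params: PenaltyParams,
) -> np.ndarray:
    """(L, S) emission penalties for the slice, including hard per-state base
    requirements."""
    eps = params.emission_floor
    cls = -np.log(np.maximum(eps, tracks.class_probs[start:end]))
    ph = -np.log(np.maximum(eps, tracks.phase_probs[start:end]))
    L = end - start
    E = np.empty((L, space.n_states))
    from .dna import CHANNELS

    for s in space.states:
        col = cls[:, s.super_class].copy()
        if s.super_class == CDS:
            col += ph[:, 1 + s.phase]
        if s.base_allowed is not None:
            allowed = np.isin(seq_idx[start:end], [CHANNELS.index(b) for b in s.base_allowed])
            col = np.where(allowed, col, INF)
        E[:, s.index] = col
    return E


def _viterbi(
    space: HmmStateSpace,
    E: np.ndarray,
    seq: str,
    seq_idx: np.ndarray,
    start: int,
    params: PenaltyParams,
) -> tuple[list[int], float] | None:
    """Min-sum DP over the slice; path must start and end in intergenic.

    Returns ``(state path, total penalty)`` or None when no finite-penalty
    path exists.  Ties break toward the lowest predecessor index (intergenic
    is state 0), preferring paths that enter genic states later.
    """
    from .dna import CHANNELS

    L, S = E.shape
    ig = space.by_name["IG"].index

    # static penalty matrix; checked transitions start as INF and are patched
    # per position from precomputed validity masks
    M = np.full((S, S), INF)
    checked: list[tuple[Transition, float]] = []
    for tr in space.transitions:
        base_pen = params.motif_penalties.get(tr.penalty_key, INF) if tr.penalty_key else 0.0
        to_state = space.states[tr.to]
        checks = list(tr.checks)
        if to_state.base_allowed is not None:
            checks.append((0, to_state.base_allowed))
        if not checks:
            M[tr.frm, tr.to] = base_pen
        else:
            checked.append((tr, base_pen))
    # per-position validity of each checked transition (vectorized over t)
    n_chk = len(checked)
    ok = np.ones((n_chk, L), dtype=bool)
    pens = np.empty(n_chk)
    frm_idx = np.empty(n_chk, dtype=np.int64)
    to_idx = np.empty(n_chk, dtype=np.int64)
    for k, (tr, base_pen) in enumerate(checked):
        pens[k] = base_pen
        frm_idx[k], to_idx[k] = tr.frm, tr.to
        to_state = space.states[tr.to]
        checks = list(tr.checks)
        if to_state.base_allowed is not None:
            checks.append((0, to_state.base_allowed))
        for off, allowed in checks:
            pos = np.arange(start, start + L) + off
            valid = (pos >= 0) & (pos < len(seq))
            match = np.zeros(L, dtype=bool)
            codes = [CHANNELS.index(b) for b in allowed]
            match[valid] = np.isin(seq_idx[pos[valid]], codes)
            # ambiguity-containing positions: fall back to string membership
            ok[k] &= match

    cost = np.full(S, INF)
    # virtual intergenic state before the slice
    first = np.where(M[ig] < INF, M[ig], INF).copy()
    k0 = np.flatnonzero((frm_idx == ig) & ok[:, 0])
    first[to_idx[k0]] = np.minimum(first[to_idx[k0]], pens[k0])
    cost = first + E[0]
    back = np.zeros((L, S), dtype=np.int16)
    back[0] = -1
    for t in range(1, L):
        C = cost[:, None] + M
        kk = np.flatnonzero(ok[:, t])
        if kk.size:
            cand = cost[frm_idx[kk]] + pens[kk]
            cur = C[frm_idx[kk], to_idx[kk]]
            C[frm_idx[kk], to_idx[kk]] = np.minimum(cur, cand)
        back[t] = C.argmin(axis=0)
        cost = C[back[t], np.arange(S)] + E[t]
    if not np.isfinite(cost[ig]):
        return None
    path = [ig]
    for t in range(L - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, float(cost[ig])


def _parse_path(
    path: list[int], space: HmmStateSpace, offset: int
) -> list[tuple[list, list]]:
    """Split a state path into genes: (exon intervals, CDS intervals) pairs in
    strand-local coordinates.

    A gene closes at the last base of its stop codon; trailing UTR up to the
    next coding start (or intergenic) is its 3' UTR.
    """
    states = [space.states[i] for i in path]
    genes: list[tuple[list, list]] = []
    cur_exon: list = []
    cur_cds: list = []
    in_gene = False
    seen_stop = False

    def push(intervals, t):
        p = offset + t
        if intervals and intervals[-1][1] == p:
            intervals[-1][1] = p + 1
        else:
            intervals.append([p, p + 1])

    def close():
        nonlocal cur_exon, cur_cds, in_gene, seen_stop
        if cur_cds:
            genes.append((cur_exon, cur_cds))
        cur_exon, cur_cds = [], []
        in_gene, seen_stop = False, False

    for t, st in enumerate(states):
        if st.super_class == IG:
            if in_gene:
                close()
            continue
        if st.name == "start0" and seen_stop:
            close()  # UTR-bridged second gene: previous UTR stays 3' UTR
        in_gene = True
        if st.super_class == CDS:
            push(cur_exon, t)
            push(cur_cds, t)
            if st.name == "stopX":
                seen_stop = True
        elif st.intron_entry is None:  # UTR; introns split exons by
            push(cur_exon, t)          # simply not extending them
    if in_gene:
        close()
    return genes


def decode_region(
    region: CandidateRegion,
    tracks: PredictionTracks,
    seq: ContigSequence,
    params: PenaltyParams = PenaltyParams(),
    space: HmmStateSpace | None = None,
    seq_idx: np.ndarray | None = None,
    margin: int | None = None,
) -> list[GeneModel]:
    """Decode one candidate region into zero or more gene models.

    The region is extended by an intergenic margin on both sides so the path
    can anchor in the intergenic state; results are reported in strand-local
    coordinates on ``region.strand`` (genomic mapping is
    :func:`decode_genome`'s job).  Genes shorter than ``min_cds_length`` of
    CDS are dropped.
    """
    if space is None:
        space = build_state_space()
    residues = seq.residues
    if seq_idx is None:
        seq_idx = base_indices(residues)
    margin = params.intergenic_window if margin is None else margin
    s = max(0, region.start - margin)
    e = min(len(residues), region.end + margin)
    E = _emission_matrix(space, tracks, seq_idx, s, e, params)
    result = _viterbi(space, E, residues, seq_idx, s, params)
    if result is None:
        return []
    path, _ = result
    out = []
    for exons, cds in _parse_path(path, space, s):
        if sum(ce - cs for cs, ce in cds) < params.min_cds_length:
            continue
        out.append(
            GeneModel(
                gene_id="",
                contig_id=region.contig_id,
                strand=region.strand,
                exons=tuple((a, b) for a, b in exons),
                cds=tuple((a, b) for a, b in cds),
            )
        )
    return out


def decode_path(
    tracks: PredictionTracks,
    seq: ContigSequence,
    params: PenaltyParams = PenaltyParams(),
    space: HmmStateSpace | None = None,
    start: int = 0,
    end: int | None = None,
):
    """Raw DP result over a slice: ``(state name list, total penalty)`` or
    ``None`` when no finite path exists.  Exposed for inspection and for
    cross-checks against path enumeration."""
    if space is None:
        space = build_state_space()
    end = len(seq) if end is None else end
    seq_idx = base_indices(seq.residues)
    E = _emission_matrix(space, tracks, seq_idx, start, end, params)
    result = _viterbi(space, E, seq.residues, seq_idx, start, params)
    if result is None:
        return None
    path, total = result
    return [space.states[i].name for i in path], total


def decode_genome(
    tracks_by_strand: dict[tuple[str, str], PredictionTracks],
    seqs: dict[str, ContigSequence],
    params: PenaltyParams = PenaltyParams(),
    space: HmmStateSpace | None = None,
) -> list[GeneModel]:
    """Decode both strands of every contig and assign stable gene ids.

    Minus-strand tracks run along the reverse complement; decoded intervals
    are mapped back to forward genomic coordinates.  Raises on a contig
    mismatch between tracks and sequences.
    """
    if space is None:
        space = build_state_space()
    for (cid, _), tr in tracks_by_strand.items():
        if cid not in seqs:
            raise ValueError(f"tracks refer to unknown contig {cid!r}")
        if len(tr) != len(seqs[cid]):
            raise ValueError(f"track/sequence length mismatch on contig {cid!r}")
    models: list[GeneModel] = []
    for (cid, strand), tr in sorted(tracks_by_strand.items()):
        seq = seqs[cid]
        local_seq = seq if strand == "+" else seq.reverse_complement()
        seq_idx = base_indices(local_seq.residues)
        L = len(seq)
        for region in find_candidate_regions(tr, params):
            for m in decode_region(
                region, tr, local_seq, params, space, seq_idx=seq_idx
            ):
                exons = sorted(to_local(tuple(iv), L, strand) for iv in m.exons)
                cds = sorted(to_local(tuple(iv), L, strand) for iv in m.cds)
                models.append(
                    GeneModel("", cid, strand, tuple(exons), tuple(cds))
                )
    models.sort(key=lambda m: (m.contig_id, m.span, m.strand))
    return [
        GeneModel(f"gene_{i + 1:06d}", m.contig_id, m.strand, m.exons, m.cds)
        for i, m in enumerate(models)
    ]
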