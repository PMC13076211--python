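"""Per-base label tracks and fixed-length subsequence windows.

The genic-class track is one-hot over {intergenic, UTR, CDS, intron} and the
phase track one-hot over {none, 0, 1, 2}; the per-base phase is the number of
bases until the start of the next codon, so a codon reads (0, 2, 1).  A boolean
mask marks bases excluded from loss and metrics (annotation errors, padding).

Both strands are labeled; a minus-strand track runs along the reverse
complement ("strand-local" orientation) and coordinates are mapped back on
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dna import ContigSequence
from .models import GeneModel, Interval

CLASS_NAMES = ("intergenic", "utr", "cds", "intron")
PHASE_NAMES = ("none", "phase0", "phase1", "phase2")
IG, UTR, CDS, INTRON = range(4)

#: phase-track channel for a base at codon position p (0-based): the number of
#: bases until the next codon start is (3 - p) % 3, living in channel 1 + that.
PHASE_CHANNEL_BY_CODON_POS = (1, 3, 2)


def to_local(iv: Interval, length: int, strand: str) -> Interval:
    """Map a genomic interval to strand-local coordinates (identity on '+')."""
    if strand == "+":
        return iv
    s, e = iv
    return (length - e, length - s)


@dataclass
class LabeledTracks:
    """Reference label tracks for one contig strand (strand-local order)."""

    genic_class: np.ndarray  # (L, 4) one-hot
    phase: np.ndarray  # (L, 4) one-hot
    mask: np.ndarray  # (L,) bool, True = excluded from loss & metrics
    contig_id: str = ""
    strand: str = "+"

    def __len__(self) -> int:
        return self.genic_class.shape[0]

    @property
    def class_ids(self) -> np.ndarray:
        return self.genic_class.argmax(axis=1)

    @property
    def phase_ids(self) -> np.ndarray:
        return self.phase.argmax(axis=1)


def label_bases(
    models: list[GeneModel], seq: ContigSequence, strand: str = "+"
) -> LabeledTracks:
    """Label every base of one strand of a contig.

    Bases covered by no transcript are intergenic; exonic non-CDS bases are
    UTR; intron = within the transcript span but not exonic; phase is set only
    on CDS bases.  Overlapping same-strand models are labeled in input order
    (later models win) -- resolving them is :func:`flag_errors`' job.
    """
    L = len(seq)
    cls = np.zeros(L, dtype=np.int64)
    phase_ch = np.zeros(L, dtype=np.int64)
    for m in models:
        if m.strand != strand:
            continue
        if m.span[0] < 0 or m.span[1] > L:
            raise ValueError(f"model {m.gene_id} outside contig bounds")
        s, e = to_local(m.span, L, strand)
        cls[s:e] = INTRON
        phase_ch[s:e] = 0
        for iv in m.exons:
            ls, le = to_local(iv, L, strand)
            cls[ls:le] = UTR
        # CDS intervals in translation order are ascending strand-local
        acc = 0
        local_cds = sorted(to_local(iv, L, strand) for iv in m.cds)
        for ls, le in local_cds:
            cls[ls:le] = CDS
            idx = acc + np.arange(le - ls)
            phase_ch[ls:le] = np.asarray(PHASE_CHANNEL_BY_CODON_POS)[idx % 3]
            acc += le - ls
    genic = np.zeros((L, 4), dtype=np.float32)
    genic[np.arange(L), cls] = 1.0
    ph = np.zeros((L, 4), dtype=np.float32)
    ph[np.arange(L), phase_ch] = 1.0
    return LabeledTracks(genic, ph, np.zeros(L, dtype=bool), seq.contig_id, strand)


def flag_errors(
    models: list[GeneModel],
    seq: ContigSequence,
    tracks: LabeledTracks,
) -> LabeledTracks:
    """Mask bases of erroneous annotation; returns updated tracks.

    Masked: every base of a partial or broken model (CDS missing a start
    and/or stop, CDS length not divisible by 3, non-canonical introns, or the
    model touching a contig edge, i.e. possibly truncated) and the overlap
    region of same-strand overlapping models.
    """
    L = len(seq)
    strand = tracks.strand
    mask = tracks.mask.copy()
    mine = [m for m in models if m.strand == strand]
    for m in mine:
        s, e = m.span
        if s <= 0 or e >= L or m.validate(seq):
            ls, le = to_local((max(s, 0), min(e, L)), L, strand)
            mask[ls:le] = True
    for i, a in enumerate(mine):
        for b in mine[i + 1 :]:
            s = max(a.span[0], b.span[0])
            e = min(a.span[1], b.span[1])
            if s < e:
                ls, le = to_local((s, e), L, strand)
                mask[ls:le] = True
    return replace(tracks, mask=mask)


def label_contig(
    models: list[GeneModel], seq: ContigSequence
) -> dict[str, LabeledTracks]:
    """Labeled + error-masked tracks for both strands of a contig."""
    return {
        strand: flag_errors(models, seq, label_bases(models, seq, strand))
        for strand in "+-"
    }


# ---------------------------------------------------------------------------
# chunking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChunkConfig:
    train_length: int = 21_384
    inference_length_plant: int = 106_920
    inference_length_animal: int = 213_840

    def __post_init__(self):
        for n in (self.inference_length_plant, self.inference_length_animal):
            if n % self.train_length:
                raise ValueError(
                    f"inference length {n} is not a multiple of {self.train_length}"
                )

    def length_for(self, mode: str) -> int:
        return {
            "train": self.train_length,
            "inference_plant": self.inference_length_plant,
            "inference_animal": self.inference_length_animal,
        }[mode]


@dataclass
class SubsequenceBatch:
    """Fixed-length windows over encodings and label tracks.

    ``mask`` is the loss/metric exclusion mask (annotation errors *or*
    padding); ``pad_mask`` flags padding positions only.  ``origins`` records
    (contig_id, start, strand) per window so windows can be stitched back.
    """

    x: np.ndarray | None  # (N, W, 4) base encoding
    y_class: np.ndarray | None  # (N, W, 4)
    y_phase: np.ndarray | None  # (N, W, 4)
    mask: np.ndarray  # (N, W) bool
    pad_mask: np.ndarray  # (N, W) bool
    origins: list[tuple[str, int, str]] = field(default_factory=list)
    window_length: int = 21_384

    @property
    def n_windows(self) -> int:
        return self.mask.shape[0]


def chunk(
    encoding: np.ndarray | None,
    tracks: LabeledTracks | None,
    cfg: ChunkConfig = ChunkConfig(),
    mode: str = "train",
) -> SubsequenceBatch:
    """Tile a contig strand into fixed-length windows, padding the last one.

    Padded positions carry all-zero rows and are masked.  An empty contig
    yields an empty batch.
    """
    W = cfg.length_for(mode)
    ref = encoding if encoding is not None else tracks.genic_class
    L = ref.shape[0]
    n = max(0, -(-L // W))  # ceil
    contig_id = tracks.contig_id if tracks is not None else ""
    strand = tracks.strand if tracks is not None else "+"

    def pad(a):
        if a is None:
            return None
        out = np.zeros((n, W) + a.shape[1:], dtype=a.dtype)
        flat = out.reshape(n * W, *a.shape[1:])
        flat[:L] = a
        return out

    pad_mask = np.ones((n, W), dtype=bool)
    pad_mask.reshape(-1)[:L] = False
    base_mask = (
        tracks.mask if tracks is not None else np.zeros(L, dtype=bool)
    )
    mask = pad_mask.copy()
    mask.reshape(-1)[:L] |= base_mask
    return SubsequenceBatch(
        x=pad(encoding),
        y_class=pad(tracks.genic_class) if tracks is not None else None,
        y_phase=pad(tracks.phase) if tracks is not None else None,
        mask=mask,
        pad_mask=pad_mask,
        origins=[(contig_id, i * W, strand) for i in range(n)],
        window_length=W,
    )


def dechunk(batch: SubsequenceBatch, length: int):
    """Drop padding and concatenate windows back into contig-length arrays."""
    def unpad(a):
        if a is None:
            return None
        return a.reshape(-1, *a.shape[2:])[:length]

    return {
        "x": unpad(batch.x),
        "y_class": unpad(batch.y_class),
        "y_phase": unpad(batch.y_phase),
        "mask": batch.mask.reshape(-1)[:length],
    }
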