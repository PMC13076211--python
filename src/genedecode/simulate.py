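"""Seeded synthetic genomes with canonical gene models, for end-to-end tests.

The generator emulates the structure the decoder reasons about: random
intergenic background at a configurable GC fraction, multi-exon
protein-coding genes with an ATG start, TAA/TAG/TGA stop, GT..AG introns, no
in-frame stop codons, and UTRs on both ends.  CDS interiors are drawn
codon-wise from the 61 sense codons under a position-specific codon-usage
bias (uniform codon usage exists in no real genome, and the 3-periodic
compositional contrast bias creates is the signal content-based gene
finders rely on); introns are inserted afterwards at arbitrary CDS offsets
so all three interrupted phases occur.  Further compositional realism is
first-order only: UTRs are generated slightly GC-richer and introns
slightly AT-richer than bulk intergenic sequence, as in most plant and
vertebrate genomes.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .dna import ContigSequence, encode_sequence, revcomp, write_fasta
from .encoding import LabeledTracks, label_contig
from .models import STOP_CODONS, GeneModel, write_gff3
from .predict import PredictionTracks, oracle_predictor

SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
]

#: position-specific base preferences of coding sequence (C, A, T, G order),
#: typical of moderately biased codon usage: purine-rich first positions and
#: GC-rich third positions.  Codon probabilities are the normalized product
#: over positions, restricted to sense codons.
CODON_POSITION_WEIGHTS = (
    {"C": 0.20, "A": 0.30, "T": 0.15, "G": 0.35},
    {"C": 0.22, "A": 0.32, "T": 0.27, "G": 0.19},
    {"C": 0.30, "A": 0.20, "T": 0.20, "G": 0.30},
)


def _codon_probs() -> np.ndarray:
    w = np.array(
        [
            np.prod([CODON_POSITION_WEIGHTS[i][b] for i, b in enumerate(codon)])
            for codon in SENSE_CODONS
        ]
    )
    return w / w.sum()


SENSE_CODON_PROBS = _codon_probs()


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Study conditions for a toy genome; defaults are sized so the full
    pipeline runs in seconds."""

    n_contigs: int = 1
    contig_length: int = 100_000
    n_genes: int = 20
    exon_count: tuple[int, int] = (1, 4)  # inclusive range
    cds_codons: tuple[int, int] = (60, 400)
    intron_length: tuple[int, int] = (60, 300)
    utr_length: tuple[int, int] = (50, 300)
    gc: float = 0.42
    utr_gc: float = 0.50
    intron_gc: float = 0.36
    strand_prob: float = 0.5  # probability of the minus strand
    min_gap: int = 200  # minimum intergenic run between genes and at edges
    min_exon: int = 30
    seed: int = 0


def _bg(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([gc / 2, (1 - gc) / 2, (1 - gc) / 2, gc / 2])  # C A T G
    return "".join(np.array(list("CATG"))[rng.choice(4, size=n, p=p)])


def _build_gene(rng: np.random.Generator, spec: SyntheticGenomeSpec):
    """One gene in gene-local 5'->3' coordinates: (sequence, exons, cds)."""
    l5, l3 = rng.integers(spec.utr_length[0], spec.utr_length[1] + 1, size=2)
    n_codons = int(rng.integers(spec.cds_codons[0], spec.cds_codons[1] + 1))
    codons = rng.choice(len(SENSE_CODONS), size=n_codons - 2, p=SENSE_CODON_PROBS)
    cds = (
        "ATG"
        + "".join(SENSE_CODONS[i] for i in codons)
        + STOP_CODONS[rng.integers(0, 3)]
    )
    n_introns = int(rng.integers(spec.exon_count[0], spec.exon_count[1] + 1)) - 1
    # intron insertion offsets inside the CDS, keeping min_exon between them
    # and clear of the start/stop codons
    lo, hi = 3, len(cds) - 3
    offsets: list[int] = []
    for _ in range(n_introns):
        cand = [
            o
            for o in range(lo, hi)
            if all(abs(o - x) >= spec.min_exon for x in offsets)
        ]
        if not cand:
            break
        offsets.append(int(rng.choice(cand)))
    offsets.sort()
    seq_parts = [_bg(rng, int(l5), spec.utr_gc)]
    cds_ivs: list[tuple[int, int]] = []
    intron_ivs: list[tuple[int, int]] = []
    pos = int(l5)
    cursor = 0
    for off in offsets + [len(cds)]:
        seg = cds[cursor:off]
        cds_ivs.append((pos, pos + len(seg)))
        seq_parts.append(seg)
        pos += len(seg)
        if off < len(cds):
            ilen = int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
            seq_parts.append("GT" + _bg(rng, ilen - 4, spec.intron_gc) + "AG")
            intron_ivs.append((pos, pos + ilen))
            pos += ilen
        cursor = off
    seq_parts.append(_bg(rng, int(l3), spec.utr_gc))
    pos += int(l3)
    # exons = the gene span minus its introns
    exons: list[tuple[int, int]] = []
    start = 0
    for s, e in intron_ivs:
        exons.append((start, s))
        start = e
    exons.append((start, pos))
    return "".join(seq_parts), exons, cds_ivs


def simulate_genome(spec: SyntheticGenomeSpec):
    """Generate ``(contigs, gene models)`` satisfying the canonical grammar.

    Genes are placed left to right with at least ``min_gap`` intergenic bases
    between them and at contig edges; an infeasible spec (genes do not fit)
    raises with an explanation.  Minus-strand genes are built 5'->3' and
    written in reverse complement.
    """
    rng = np.random.default_rng(spec.seed)
    per_contig = np.full(spec.n_contigs, spec.n_genes // spec.n_contigs)
    per_contig[: spec.n_genes % spec.n_contigs] += 1
    contigs: list[ContigSequence] = []
    models: list[GeneModel] = []
    gene_no = 0
    for ci in range(spec.n_contigs):
        cid = f"contig_{ci + 1}"
        built = []
        for _ in range(int(per_contig[ci])):
            built.append(_build_gene(rng, spec))
        total = sum(len(g[0]) for g in built)
        slack = spec.contig_length - total - (len(built) + 1) * spec.min_gap
        if slack < 0:
            raise ValueError(
                f"spec infeasible: {len(built)} genes need "
                f"{total + (len(built) + 1) * spec.min_gap} bases, contig has "
                f"{spec.contig_length}"
            )
        extra = rng.multinomial(slack, np.ones(len(built) + 1) / (len(built) + 1)) \
            if built else np.array([slack])
        parts: list[str] = []
        cursor = 0
        for gi, (gseq, exons, cds_ivs) in enumerate(built):
            gap = spec.min_gap + int(extra[gi])
            parts.append(_bg(rng, gap, spec.gc))
            cursor += gap
            strand = "-" if rng.random() < spec.strand_prob else "+"
            glen = len(gseq)
            if strand == "+":
                g_exons = [(cursor + s, cursor + e) for s, e in exons]
                g_cds = [(cursor + s, cursor + e) for s, e in cds_ivs]
                parts.append(gseq)
            else:
                g_exons = sorted((cursor + glen - e, cursor + glen - s) for s, e in exons)
                g_cds = sorted((cursor + glen - e, cursor + glen - s) for s, e in cds_ivs)
                parts.append(revcomp(gseq))
            gene_no += 1
            models.append(
                GeneModel(
                    gene_id=f"sim_{gene_no:04d}",
                    contig_id=cid,
                    strand=strand,
                    exons=tuple(g_exons),
                    cds=tuple(g_cds),
                )
            )
            cursor += glen
        tail = spec.contig_length - cursor
        parts.append(_bg(rng, tail, spec.gc))
        contigs.append(ContigSequence(cid, "".join(parts)))
    for m in models:
        seq = next(c for c in contigs if c.contig_id == m.contig_id)
        problems = m.validate(seq)
        if problems:  # pragma: no cover - generator guarantee
            raise AssertionError(f"generated invalid model {m.gene_id}: {problems}")
    return contigs, models


@dataclass
class Fixture:
    """A complete synthetic test bundle."""

    spec: SyntheticGenomeSpec
    contigs: dict[str, ContigSequence]
    models: list[GeneModel]
    encodings: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    labels: dict[tuple[str, str], LabeledTracks] = field(default_factory=dict)
    preds: dict[tuple[str, str], PredictionTracks] = field(default_factory=dict)


def make_fixture(
    spec: SyntheticGenomeSpec = SyntheticGenomeSpec(),
    noise: float = 0.0,
    seed: int | None = None,
    out_dir=None,
) -> Fixture:
    """Simulate a genome, label it, and derive (optionally corrupted)
    probability tracks; with ``out_dir``, also write FASTA, GFF3 and the
    track container to disk."""
    contigs, models = simulate_genome(spec)
    fx = Fixture(spec, {c.contig_id: c for c in contigs}, models)
    for ci, c in enumerate(contigs):
        strands = label_contig(models, c)
        for si, (strand, tr) in enumerate(sorted(strands.items())):
            key = (c.contig_id, strand)
            fx.labels[key] = tr
            local = c if strand == "+" else c.reverse_complement()
            fx.encodings[key] = encode_sequence(local)
            fx.preds[key] = oracle_predictor(
                tr, noise,
                seed=None if seed is None else seed * 1000 + ci * 2 + si,
                jitter=noise > 0,
            )
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_fasta(contigs, os.path.join(out_dir, "genome.fa"))
        write_gff3(
            models,
            {c.contig_id: len(c) for c in contigs},
            os.path.join(out_dir, "annotation.gff3"),
        )
        from .tracksio import save_prediction_tracks

        save_prediction_tracks(os.path.join(out_dir, "tracks.npz"), fx.preds)
    return fx
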