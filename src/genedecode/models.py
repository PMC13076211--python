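"""Gene models (gene -> primary transcript -> exon/CDS/UTR) and GFF3 I/O.

Coordinates are 0-based half-open internally; GFF3 I/O converts to/from the
1-based inclusive convention.  Each :class:`GeneModel` holds a single primary
transcript; alternative isoforms are reduced to the longest-protein transcript
on input.  CDS intervals include the stop codon, as in standard GFF3 practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dna import ContigSequence, revcomp

Interval = tuple[int, int]

STOP_CODONS = ("TAA", "TAG", "TGA")


def _merge_adjacent(intervals: list[Interval]) -> tuple[Interval, ...]:
    """Merge touching/overlapping sorted intervals."""
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(e, out[-1][1]))
        else:
            out.append((s, e))
    return tuple(out)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with one primary transcript.

    ``exons`` and ``cds`` are sorted, disjoint genomic intervals (0-based
    half-open); ``cds`` includes the stop codon.  UTR intervals and introns are
    derived, not stored.
    """

    gene_id: str
    contig_id: str
    strand: str  # '+' or '-'
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = field(default=())

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        object.__setattr__(self, "exons", _merge_adjacent(list(self.exons)))
        object.__setattr__(self, "cds", tuple(sorted(self.cds)))

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    @property
    def cds_span(self) -> Interval:
        return (self.cds[0][0], self.cds[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def utr_intervals(self) -> tuple[Interval, ...]:
        """Exonic bases outside the CDS."""
        if not self.cds:
            return self.exons
        out: list[Interval] = []
        cs, ce = self.cds_span
        for s, e in self.exons:
            if s < cs:
                out.append((s, min(e, cs)))
            if e > ce:
                out.append((max(s, ce), e))
        return tuple(out)

    def utr5_intervals(self) -> tuple[Interval, ...]:
        cs, ce = self.cds_span
        if self.strand == "+":
            return tuple(iv for iv in self.utr_intervals if iv[1] <= cs)
        return tuple(iv for iv in self.utr_intervals if iv[0] >= ce)

    def utr3_intervals(self) -> tuple[Interval, ...]:
        cs, ce = self.cds_span
        if self.strand == "+":
            return tuple(iv for iv in self.utr_intervals if iv[0] >= ce)
        return tuple(iv for iv in self.utr_intervals if iv[1] <= cs)

    def coding_sequence(self, seq: ContigSequence) -> str:
        """Spliced CDS in translation (5'->3') orientation."""
        joined = "".join(seq.residues[s:e] for s, e in self.cds)
        return revcomp(joined) if self.strand == "-" else joined

    def validate(self, seq: ContigSequence | None = None) -> list[str]:
        """Return a list of structural problems (empty = valid).

        Checked: exon/CDS interval sanity, CDS within exons, CDS length a
        multiple of three, and -- when the sequence is given -- the canonical
        grammar: ATG start, TAA/TAG/TGA stop, no in-frame internal stop, and
        GT..AG bounds for every intron.
        """
        problems: list[str] = []
        if not self.exons:
            problems.append("no exons")
            return problems
        for i in range(len(self.exons) - 1):
            if self.exons[i][1] >= self.exons[i + 1][0]:
                problems.append("exons overlap or touch")
        for s, e in list(self.exons) + list(self.cds):
            if e <= s:
                problems.append(f"empty interval ({s},{e})")
        if not self.cds:
            problems.append("no CDS")
            return problems
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                problems.append(f"CDS interval ({s},{e}) not inside an exon")
        if self.cds_length % 3 != 0:
            problems.append(f"CDS length {self.cds_length} not divisible by 3")
        if seq is not None:
            if self.span[0] < 0 or self.span[1] > len(seq):
                problems.append("model outside contig bounds")
                return problems
            coding = self.coding_sequence(seq)
            if not coding.startswith("ATG"):
                problems.append(f"CDS does not start with ATG ({coding[:3]})")
            if coding[-3:] not in STOP_CODONS:
                problems.append(f"CDS does not end with a stop codon ({coding[-3:]})")
            for i in range(0, len(coding) - 3, 3):
                if coding[i : i + 3] in STOP_CODONS:
                    problems.append(f"in-frame stop codon at CDS offset {i}")
                    break
            for s, e in self.introns:
                intron = seq.residues[s:e]
                if self.strand == "-":
                    intron = revcomp(intron)
                if len(intron) < 4:
                    problems.append(f"intron ({s},{e}) shorter than 4 bases")
                elif not (intron.startswith("GT") and intron.endswith("AG")):
                    problems.append(
                        f"non-canonical intron ({s},{e}): {intron[:2]}..{intron[-2:]}"
                    )
        return problems

    def is_valid(self, seq: ContigSequence | None = None) -> bool:
        return not self.validate(seq)


def cds_phases(model: GeneModel) -> list[int]:
    """GFF3 phase column for each CDS interval (in genomic order).

    The phase is the number of bases to remove from the 5' end of the segment
    to reach the start of the next codon; segments are accumulated in
    translation order (ascending for '+', descending for '-')."""
    segs = list(model.cds) if model.strand == "+" else list(model.cds)[::-1]
    phases, acc = [], 0
    for s, e in segs:
        phases.append((3 - acc % 3) % 3)
        acc += e - s
    return phases if model.strand == "+" else phases[::-1]


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def write_gff3(models, contig_lengths: dict[str, int], path) -> None:
    """Serialize gene models to GFF3 (deterministic ordering).

    Emits gene, mRNA, exon, CDS, five_prime_UTR and three_prime_UTR rows,
    1-based inclusive, with the CDS phase column derived from the internal
    phase bookkeeping.  Models failing :meth:`GeneModel.validate` (structural
    checks only) are refused.
    """
    lines = ["##gff-version 3"]
    for cid in sorted(contig_lengths):
        lines.append(f"##sequence-region {cid} 1 {contig_lengths[cid]}")
    order = sorted(models, key=lambda m: (m.contig_id, m.span, m.strand, m.gene_id))
    for m in order:
        structural = [p for p in m.validate() if "stop" not in p and "ATG" not in p]
        if structural:
            raise ValueError(f"refusing to write invalid model {m.gene_id}: {structural}")
        gs, ge = m.span
        tid = f"{m.gene_id}.1"
        src = "genedecode"

        def row(ftype, s, e, phase=".", ident=None, parent=None):
            attrs = []
            if ident:
                attrs.append(f"ID={ident}")
            if parent:
                attrs.append(f"Parent={parent}")
            return (
                f"{m.contig_id}\t{src}\t{ftype}\t{s + 1}\t{e}\t.\t{m.strand}\t"
                f"{phase}\t{';'.join(attrs)}"
            )

        lines.append(row("gene", gs, ge, ident=m.gene_id))
        lines.append(row("mRNA", gs, ge, ident=tid, parent=m.gene_id))
        for s, e in m.utr5_intervals():
            lines.append(row("five_prime_UTR", s, e, parent=tid))
        for s, e in m.exons:
            lines.append(row("exon", s, e, parent=tid))
        for (s, e), ph in zip(m.cds, cds_phases(m)):
            lines.append(row("CDS", s, e, phase=str(ph), parent=tid))
        for s, e in m.utr3_intervals():
            lines.append(row("three_prime_UTR", s, e, parent=tid))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Read GFF3 into gene models, one primary transcript per gene.

    Tolerates gene -> mRNA -> exon/CDS/UTR hierarchies; when a gene carries
    several transcripts the one with the longest CDS (tie: lexicographic id)
    defines the model.  Transcripts without exon rows fall back to CDS+UTR
    rows as exons.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        best = None
        for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")
            )
            if not exons:
                utr = [
                    (f.start - 1, f.end)
                    for f in db.children(
                        mrna, featuretype=("five_prime_UTR", "three_prime_UTR")
                    )
                ]
                exons = list(cds) + utr
            if not exons:
                continue
            cds_len = sum(e - s for s, e in cds)
            key = (-cds_len, mrna.id)
            if best is None or key < best[0]:
                best = (key, exons, cds)
        if best is None:
            continue
        _, exons, cds = best
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig_id=gene.seqid,
                strand=gene.strand,
                exons=tuple(sorted(exons)),
                cds=tuple(cds),
            )
        )
    models.sort(key=lambda m: (m.contig_id, m.span, m.strand, m.gene_id))
    return models
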