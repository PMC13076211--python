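"""Nucleotide sequences and their numeric encoding.

Sequences are handled as upper-case IUPAC strings; the numeric encoding is a
``length x 4`` matrix with channel order **C, A, T, G**.  Unambiguous bases are
one-hot; ambiguity codes are spread uniformly over their compatible bases so
that every row still sums to one (``N`` encodes as four times 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: channel order of the base encoding
CHANNELS = "CATG"

#: IUPAC code -> compatible unambiguous bases
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN" + "tgcayrswmkvhdbn",
)

# 256-row lookup table: byte value of the (upper- or lower-case) character ->
# encoding row; invalid characters map to an all-zero row, detected afterwards.
_LUT = np.zeros((256, 4), dtype=np.float64)
for _code, _bases in IUPAC_CODES.items():
    _row = np.zeros(4)
    for _b in _bases:
        _row[CHANNELS.index(_b)] = 1.0 / len(_bases)
    _LUT[ord(_code)] = _row
    _LUT[ord(_code.lower())] = _row


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes and case."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContigSequence:
    """A named contig; residues are validated IUPAC characters."""

    contig_id: str
    residues: str

    def __post_init__(self) -> None:
        arr = np.frombuffer(self.residues.encode("ascii", "replace"), dtype=np.uint8)
        bad = np.flatnonzero(_LUT[arr].sum(axis=1) == 0)
        if bad.size:
            pos = int(bad[0])
            raise ValueError(
                f"contig {self.contig_id!r}: non-IUPAC character "
                f"{self.residues[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "ContigSequence":
        return ContigSequence(self.contig_id, revcomp(self.residues))


def encode_sequence(seq: "ContigSequence | str") -> np.ndarray:
    """Encode a sequence as a ``length x 4`` matrix (channels C, A, T, G).

    Every row sums to 1; ambiguity codes are distributed uniformly over their
    compatible channels.  Raises :class:`ValueError` naming the position of the
    first non-IUPAC character.
    """
    if isinstance(seq, ContigSequence):
        residues = seq.residues
        name = seq.contig_id
    else:
        residues = seq
        name = "<string>"
    if not residues:
        raise ValueError(f"contig {name!r}: empty sequence")
    arr = np.frombuffer(residues.encode("ascii", "replace"), dtype=np.uint8)
    enc = _LUT[arr]
    bad = np.flatnonzero(enc.sum(axis=1) == 0)
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"contig {name!r}: non-IUPAC character {residues[pos]!r} at position {pos}"
        )
    return enc


def base_indices(seq: str) -> np.ndarray:
    """Map residues to indices into :data:`CHANNELS` (ambiguity -> argmax, i.e.
    first compatible channel in C,A,T,G order)."""
    arr = np.frombuffer(seq.upper().encode("ascii", "replace"), dtype=np.uint8)
    return _LUT[arr].argmax(axis=1)


def read_fasta(path) -> dict[str, ContigSequence]:
    """Read a (possibly multi-contig, wrapped) FASTA file."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    out = {name: ContigSequence(name, str(fa[name][:]).upper()) for name in fa.keys()}
    fa.close()
    return out


def write_fasta(seqs, path, width: int = 70) -> None:
    seq_list = seqs.values() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for seq in seq_list:
            fh.write(f">{seq.contig_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq.residues[i : i + width] + "\n")
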