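"""Cassette reference: the V, D, J segments and constant flanks of the barcoding locus.

The barcoding cassette is an artificial VDJ locus: a single V, D and J
segment separated by recombination signal sequences.  Cre-triggered
RAG-mediated recombination joins the segments, deleting nucleotides at each
junction and adding untemplated (TdT) nucleotides, and may incorporate the D
segment in reverse-complement orientation.  The recombined region, read
between two constant anchors, is the heritable barcode.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}

_FASTA_IDS = ("V", "D", "J", "LCONST", "RCONST")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT)."""
    return str(Seq(sequence).reverse_complement())


def _check_nt(name: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"{name} must be a nonempty nucleotide string")
    bad = set(seq) - set(NT_ALPHABET)
    if bad:
        raise ValueError(f"{name} contains invalid characters {sorted(bad)}; expected uppercase ACGT")


@dataclass(frozen=True)
class CassetteReference:
    """The germline segments of the barcoding cassette.

    Parameters
    ----------
    v_seq, d_seq, j_seq
        Germline V, D and J segment sequences, 5'->3' on the top strand.
    left_const, right_const
        Constant sequences flanking the recombined region; the left constant
        doubles as the read anchor downstream of the UMI.
    """

    v_seq: str
    d_seq: str
    j_seq: str
    left_const: str
    right_const: str

    def __post_init__(self) -> None:
        for name in ("v_seq", "d_seq", "j_seq", "left_const", "right_const"):
            _check_nt(name, getattr(self, name))

    @property
    def d_revcomp(self) -> str:
        return reverse_complement(self.d_seq)

    def germline_barcode(self) -> str:
        """The zero-edit recombination product V+D+J (no trims, no insertions)."""
        return self.v_seq + self.d_seq + self.j_seq

    @classmethod
    def from_fasta(cls, path) -> "CassetteReference":
        """Read a reference from FASTA with records V, D, J, LCONST, RCONST."""
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        missing = [i for i in _FASTA_IDS if i not in records]
        if missing:
            raise ValueError(f"reference FASTA missing records: {missing}")
        return cls(
            v_seq=records["V"],
            d_seq=records["D"],
            j_seq=records["J"],
            left_const=records["LCONST"],
            right_const=records["RCONST"],
        )

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(self.v_seq), id="V", description="cassette V segment"),
            SeqRecord(Seq(self.d_seq), id="D", description="cassette D segment"),
            SeqRecord(Seq(self.j_seq), id="J", description="cassette J segment"),
            SeqRecord(Seq(self.left_const), id="LCONST", description="upstream constant anchor"),
            SeqRecord(Seq(self.right_const), id="RCONST", description="downstream constant"),
        ]
        SeqIO.write(records, str(path), "fasta")


# Synthetic default cassette.  Segment lengths mirror the real construct
# (V ~60 nt, D a short DSP2.4-like segment, J ~40 nt); the sequences
# themselves are synthetic stand-ins, not the deposited construct.
DEFAULT_V = "TTACGTAACCTCGCTCATATGAGCCAAGTTTGAACACTTCTCTGTCTCGGCTTACGTTTG"
DEFAULT_D = "TCTACTATCGGTACGAC"
DEFAULT_J = "TGTAAGATGAGTAAATAGTTAGGTGCAACGGGCTGATGGC"
DEFAULT_LCONST = "GAGGGTATCTTA"
DEFAULT_RCONST = "AACTATCGCGAT"


def default_reference() -> CassetteReference:
    """Built-in synthetic cassette with realistic segment lengths."""
    return CassetteReference(
        v_seq=DEFAULT_V,
        d_seq=DEFAULT_D,
        j_seq=DEFAULT_J,
        left_const=DEFAULT_LCONST,
        right_const=DEFAULT_RCONST,
    )
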