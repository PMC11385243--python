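"""The circular human mitochondrial reference genome.

The human mtDNA reference (rCRS, GenBank NC_012920.1) is a 16,569 bp circular
molecule.  Coordinates throughout this package are 1-based inclusive, matching
the "m.N" convention of the mitochondrial literature, and position arithmetic
is modular: position 16,569 + 1 wraps to position 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

MT_LENGTH = 16569
"""Length of the rCRS mitochondrial genome in base pairs."""

_ALPHABET = frozenset("ACGTN")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def wrap_position(position: int) -> int:
    """Map any integer onto the circular 1..16,569 coordinate system."""
    return (int(position) - 1) % MT_LENGTH + 1


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class MtReference:
    """A mitochondrial reference sequence with circular coordinates.

    Parameters
    ----------
    sequence
        Upper-case sequence of exactly 16,569 bases over ``{A, C, G, T, N}``.
    name
        Sequence identifier; defaults to the rCRS accession.
    """

    sequence: str
    name: str = "NC_012920.1"

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_LENGTH:
            raise ValueError(
                f"mitochondrial reference must be {MT_LENGTH} bp, "
                f"got {len(self.sequence)}"
            )
        if not _ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise ValueError(f"invalid bases in reference: {bad}")

    def __len__(self) -> int:
        return MT_LENGTH

    def base(self, position: int) -> str:
        """Reference base at a 1-based position (wraps the origin)."""
        return self.sequence[wrap_position(position) - 1]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based slice; wraps the origin when ``end < start``."""
        start = wrap_position(start)
        end = wrap_position(end)
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def base_array(self) -> np.ndarray:
        """Sequence as an array of single characters, index 0 = position 1."""
        return np.frombuffer(self.sequence.encode(), dtype="S1").astype("U1")

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "MtReference":
        """Read a single-record FASTA and validate its length."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"expected a single FASTA record, found {len(records)} in {path}"
            )
        rec = records[0]
        return cls(sequence=str(rec.seq).upper(), name=name or rec.id)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, MT_LENGTH, 70):
                fh.write(self.sequence[i : i + 70] + "\n")

    @classmethod
    def synthetic(cls, seed: int = 20240909) -> "MtReference":
        """A deterministic synthetic stand-in for the rCRS sequence.

        The real NC_012920.1 sequence is an external input; this generator
        produces a random 16,569 bp sequence (uniform base composition) so
        that the whole pipeline, including strand-aware codon arithmetic, can
        run self-contained.  It shares coordinates and annotation with the
        rCRS but not its bases: results on it are synthetic.
        """
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=MT_LENGTH))
        return cls(sequence=seq, name=f"synthetic-mt-{seed}")
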