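"""Locus annotation, low-complexity masks and codon context on the circular genome.

The packaged locus map follows the standard rCRS feature annotation: the
non-coding control region (D-loop, m.16024-576, spanning the origin), 2 rRNA
genes, 22 tRNA genes and 13 protein-coding genes, each on the heavy or light
strand.  Burden normalisation uses fixed per-class lengths (D-loop 1124,
rRNA 2511, tRNA 1486, protein-coding 11,382 bp); these constants are applied
as given and are not recomputed from the interval table, whose arithmetic
totals differ slightly (see ``LocusMap.computed_class_lengths``).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .reference import COMPLEMENT, MT_LENGTH, MtReference, wrap_position

LOCUS_CLASSES = ("D-loop", "rRNA", "tRNA", "protein-coding")

#: Per-class normalisation lengths in bp, used verbatim for burden rates.
NORMALIZATION_BP = {
    "D-loop": 1124,
    "rRNA": 2511,
    "tRNA": 1486,
    "protein-coding": 11382,
}

#: rCRS placeholder positions, masked unconditionally.
PLACEHOLDER_REGION = (3106, 3107)


class CoordinateError(ValueError):
    """A position outside the 1..16,569 coordinate range."""


def _check_position(position: int) -> int:
    position = int(position)
    if not 1 <= position <= MT_LENGTH:
        raise CoordinateError(f"position {position} outside 1..{MT_LENGTH}")
    return position


@dataclass(frozen=True)
class LocusInterval:
    """One annotated feature, 1-based inclusive; wraps the origin iff end < start."""

    name: str
    start: int
    end: int
    strand: str  # "heavy" | "light"
    locus_class: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= MT_LENGTH and 1 <= self.end <= MT_LENGTH):
            raise CoordinateError(f"{self.name}: interval outside genome")
        if self.strand not in ("heavy", "light"):
            raise ValueError(f"{self.name}: bad strand {self.strand!r}")
        if self.locus_class not in LOCUS_CLASSES:
            raise ValueError(f"{self.name}: bad locus class {self.locus_class!r}")
        if self.wraps and self.locus_class != "D-loop":
            raise ValueError(f"{self.name}: only the D-loop may wrap the origin")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    @property
    def length(self) -> int:
        if self.wraps:
            return (MT_LENGTH - self.start + 1) + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        position = _check_position(position)
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def positions(self) -> np.ndarray:
        """All 1-based positions of the interval, in genomic order."""
        if self.wraps:
            return np.concatenate(
                [np.arange(self.start, MT_LENGTH + 1), np.arange(1, self.end + 1)]
            )
        return np.arange(self.start, self.end + 1)


class LocusMap:
    """Ordered collection of loci with a deterministic position → class mapping.

    Overlapping features are resolved for burden assignment by a first-wins
    precedence in genome (file) order; consequence annotation instead asks for
    *all* genes at a position via :meth:`genes_at`.
    """

    def __init__(self, intervals: list[LocusInterval]):
        self.intervals = list(intervals)
        # first-wins assignment over the whole genome
        self._class = np.full(MT_LENGTH + 1, "", dtype=object)
        self._name = np.full(MT_LENGTH + 1, "", dtype=object)
        for iv in self.intervals:
            pos = iv.positions()
            free = self._class[pos] == ""
            self._class[pos[free]] = iv.locus_class
            self._name[pos[free]] = iv.name

    def locus_of(self, position: int) -> tuple[str, str | None]:
        """Locus class and feature name at a position.

        Returns ``("intergenic", None)`` for the few unannotated positions.
        Positions on either side of the origin inside m.16024-576 resolve to
        the D-loop.
        """
        position = _check_position(position)
        cls = self._class[position]
        if cls == "":
            return "intergenic", None
        return str(cls), str(self._name[position])

    def loci_at(self, position: int) -> list[LocusInterval]:
        position = _check_position(position)
        return [iv for iv in self.intervals if iv.contains(position)]

    def genes_at(self, position: int) -> list[LocusInterval]:
        """All protein-coding genes overlapping a position (may be several)."""
        return [
            iv for iv in self.loci_at(position) if iv.locus_class == "protein-coding"
        ]

    @property
    def genes(self) -> list[LocusInterval]:
        return [iv for iv in self.intervals if iv.locus_class == "protein-coding"]

    def gene(self, name: str) -> LocusInterval:
        for iv in self.intervals:
            if iv.name == name:
                return iv
        raise KeyError(name)

    def computed_class_lengths(self) -> dict[str, int]:
        """bp per class under the first-wins assignment (positions counted once).

        These arithmetic totals differ from the fixed ``NORMALIZATION_BP``
        constants by a few to a few dozen bp; normalisation deliberately uses
        the constants, and the discrepancy is documented by a test.
        """
        out = {}
        for cls in LOCUS_CLASSES:
            out[cls] = int(np.sum(self._class[1:] == cls))
        return out

    @classmethod
    def from_tsv(cls, path) -> "LocusMap":
        df = pd.read_csv(path, sep="\t", dtype={"name": str})
        ivs = [
            LocusInterval(
                name=r["name"],
                start=int(r["start"]),
                end=int(r["end"]),
                strand=r["strand"],
                locus_class=r["locus_class"],
            )
            for r in df.to_dict("records")
        ]
        return cls(ivs)

    @classmethod
    def default(cls) -> "LocusMap":
        with resources.as_file(
            resources.files("mthet.data").joinpath("loci.tsv")
        ) as p:
            return cls.from_tsv(p)


class MaskSet:
    """Low-complexity regions excluded from comparative analysis.

    Membership is an O(1) lookup against a precomputed boolean genome array.
    The rCRS placeholder positions 3,106-3,107 are masked regardless of the
    configured region list.
    """

    def __init__(self, regions, mask_placeholder: bool = True):
        self.regions = [(int(s), int(e)) for s, e in regions]
        for s, e in self.regions:
            if not (1 <= s <= MT_LENGTH and 1 <= e <= MT_LENGTH and s <= e):
                raise CoordinateError(f"mask region ({s}, {e}) outside genome")
        self._mask = np.zeros(MT_LENGTH + 1, dtype=bool)
        for s, e in self.regions:
            self._mask[s : e + 1] = True
        if mask_placeholder:
            s, e = PLACEHOLDER_REGION
            self._mask[s : e + 1] = True

    def __contains__(self, position: int) -> bool:
        return bool(self._mask[_check_position(position)])

    def contains(self, positions) -> np.ndarray:
        """Vectorised membership for an array of 1-based positions."""
        pos = np.asarray(positions, dtype=int)
        if pos.size and (pos.min() < 1 or pos.max() > MT_LENGTH):
            raise CoordinateError("positions outside 1..16,569")
        return self._mask[pos]

    @property
    def masked_positions(self) -> np.ndarray:
        return np.flatnonzero(self._mask)

    @classmethod
    def from_tsv(cls, path, mask_placeholder: bool = True) -> "MaskSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            list(zip(df["start"], df["end"])), mask_placeholder=mask_placeholder
        )

    @classmethod
    def default(cls) -> "MaskSet":
        with resources.as_file(
            resources.files("mthet.data").joinpath("masks.tsv")
        ) as p:
            return cls.from_tsv(p)


def in_mask(position: int, masks: MaskSet) -> bool:
    """True iff the position lies in any mask interval (inclusive ends)."""
    return position in masks


def locus_of(position: int, locus_map: LocusMap) -> tuple[str, str | None]:
    """Locus class and name at a 1-based position (see :meth:`LocusMap.locus_of`)."""
    return locus_map.locus_of(position)


@dataclass(frozen=True)
class CodonContext:
    """Reading-frame context of one position within a protein-coding gene.

    ``codon`` is read 5'→3' on the coding strand: for light-strand genes
    (MT-ND6) it is the reverse complement of the genomic triplet.  ``offset``
    is the 0-based position of the query base within that codon.  Codons cut
    short by the gene boundary (stop codons completed by polyadenylation) are
    padded with ``A`` and flagged ``incomplete_stop``.
    """

    codon_number: int
    offset: int
    codon: str
    incomplete_stop: bool = False


def codon_context(
    position: int, gene: LocusInterval, reference: MtReference
) -> CodonContext:
    """Codon index, within-codon offset and coding-strand codon at a position."""
    position = _check_position(position)
    if gene.locus_class != "protein-coding":
        raise ValueError(f"{gene.name} is not protein-coding")
    if not gene.contains(position):
        raise ValueError(f"position {position} outside {gene.name}")
    seq = reference.sequence
    if gene.strand == "heavy":
        i = position - gene.start
        ci, off = divmod(i, 3)
        codon_start = gene.start + 3 * ci
        raw = seq[codon_start - 1 : min(codon_start + 2, gene.end)]
    else:
        # light-strand genes are read from gene.end downwards; the coding
        # codon is the complement of the genomic triplet in reversed order
        i = gene.end - position
        ci, off = divmod(i, 3)
        top = gene.end - 3 * ci
        lo = max(top - 2, gene.start)
        raw = "".join(COMPLEMENT[b] for b in reversed(seq[lo - 1 : top]))
    incomplete = len(raw) < 3
    codon = raw + "A" * (3 - len(raw))
    return CodonContext(
        codon_number=ci + 1, offset=off, codon=codon, incomplete_stop=incomplete
    )
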