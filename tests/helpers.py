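"""Independent brute-force oracles used by the test suite."""

from Bio.Seq import Seq

from mthet.reference import MtReference


def translate_gene(sequence: str, gene) -> str:
    """Whole-protein translation of a gene from a full genome string.

    Light-strand genes are reverse complemented; sequences whose length is
    not a multiple of 3 (polyadenylation-completed stops) are A-padded.
    Uses the vertebrate mitochondrial code.
    """
    sub = sequence[gene.start - 1 : gene.end]
    if gene.strand == "light":
        sub = str(Seq(sub).reverse_complement())
    sub = sub + "A" * ((3 - len(sub) % 3) % 3)
    return str(Seq(sub).translate(table=2))


def oracle_consequence(reference: MtReference, gene, position: int, alt: str) -> str:
    """Synonymy of a substitution by rebuilding and translating the whole CDS."""
    seq = reference.sequence
    mutated = seq[: position - 1] + alt + seq[position:]
    before = translate_gene(seq, gene)
    after = translate_gene(mutated, gene)
    return "synonymous" if before == after else "non-synonymous"


def splice(reference: MtReference, start: int, bases: str) -> MtReference:
    """A copy of the reference with ``bases`` written at 1-based ``start``."""
    seq = reference.sequence
    out = seq[: start - 1] + bases + seq[start - 1 + len(bases) :]
    return MtReference(sequence=out, name=f"{reference.name}-spliced")
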