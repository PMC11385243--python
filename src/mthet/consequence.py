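"""Protein-level consequence and pathogenicity classification.

Substitutions in the 13 mitochondrial protein-coding genes are classified as
synonymous or non-synonymous by translating the reference and mutated codon
with the vertebrate mitochondrial genetic code (translation table 2: AGA/AGG
are stops, ATA codes Met, TGA codes Trp).  Light-strand genes (MT-ND6) are
evaluated on the reverse-complement codon.  Variants elsewhere are
non-coding.  Pathogenicity is not predicted here: per-variant MutPred and
APOGEE 2 scores are consumed as lookup tables and thresholded
(score > 0.50 and > 0.38 respectively, strict).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from Bio.Data import CodonTable

from .annotation import LocusInterval, LocusMap, codon_context
from .calling import VariantCall
from .reference import COMPLEMENT, MtReference

MUTPRED_THRESHOLD = 0.50
APOGEE2_THRESHOLD = 0.38

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]
#: codon → amino acid under the vertebrate mitochondrial code ('*' = stop)
MITO_CODON_TABLE = dict(_TABLE2.forward_table)
MITO_CODON_TABLE.update({c: "*" for c in _TABLE2.stop_codons})

_SEVERITY = {"synonymous": 0, "missense": 1, "stop_loss": 2, "stop_gain": 3}


class ReferenceMismatchError(ValueError):
    """Variant ref base disagrees with the reference sequence."""


def translate_codon(codon: str) -> str:
    """Amino acid (or ``*``) for a codon under the vertebrate mitochondrial code."""
    return MITO_CODON_TABLE[codon.upper()]


@dataclass(frozen=True)
class AnnotatedVariant:
    """A somatic variant call with locus, consequence and pathogenicity fields."""

    position: int
    ref: str
    alt: str
    hf: float
    depth: int
    zygosity: str
    locus_class: str
    gene: str | None
    consequence: str  # synonymous | non-synonymous | non-coding
    effect: str | None = None  # missense | stop_gain | stop_loss
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    incomplete_stop_caveat: bool = False
    mutpred_score: float | None = None
    apogee2_score: float | None = None
    pathogenic_mutpred: bool | None = None
    pathogenic_apogee2: bool | None = None

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"


def _classify_codon_change(aa_ref: str, aa_alt: str) -> str:
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gain"
    if aa_ref == "*":
        return "stop_loss"
    return "missense"


def annotate_consequence(
    variant: VariantCall,
    locus_map: LocusMap,
    reference: MtReference,
) -> AnnotatedVariant:
    """Attach locus class and synonymous/non-synonymous consequence to a call.

    The burden locus class follows the map's first-wins precedence; when the
    class is protein-coding, every overlapping gene is evaluated and the most
    severe effect (stop_gain > stop_loss > missense > synonymous) is reported
    with its gene.  Codons truncated by a polyadenylation-completed stop are
    evaluated on the A-padded codon and flagged with a caveat.
    """
    ref_base = reference.base(variant.position)
    if ref_base != variant.ref:
        raise ReferenceMismatchError(
            f"position {variant.position}: call ref {variant.ref!r} != "
            f"reference {ref_base!r}"
        )
    locus_class, name = locus_map.locus_of(variant.position)
    base = dict(
        position=variant.position,
        ref=variant.ref,
        alt=variant.alt,
        hf=variant.hf,
        depth=variant.depth,
        zygosity=variant.zygosity,
        locus_class=locus_class,
    )
    if locus_class != "protein-coding":
        return AnnotatedVariant(gene=name, consequence="non-coding", **base)

    best = None
    for gene in locus_map.genes_at(variant.position):
        ctx = codon_context(variant.position, gene, reference)
        placed = variant.alt if gene.strand == "heavy" else COMPLEMENT[variant.alt]
        codon_alt = ctx.codon[: ctx.offset] + placed + ctx.codon[ctx.offset + 1 :]
        aa_ref = translate_codon(ctx.codon)
        aa_alt = translate_codon(codon_alt)
        effect = _classify_codon_change(aa_ref, aa_alt)
        cand = (
            _SEVERITY[effect],
            gene,
            ctx,
            codon_alt,
            aa_ref,
            aa_alt,
            effect,
        )
        if best is None or cand[0] > best[0]:
            best = cand
    assert best is not None  # locus_class == protein-coding guarantees a gene
    _, gene, ctx, codon_alt, aa_ref, aa_alt, effect = best
    return AnnotatedVariant(
        gene=gene.name,
        consequence="synonymous" if effect == "synonymous" else "non-synonymous",
        effect=None if effect == "synonymous" else effect,
        codon_ref=ctx.codon,
        codon_alt=codon_alt,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        incomplete_stop_caveat=ctx.incomplete_stop,
        **base,
    )


class ScoreTable:
    """Per-variant pathogenicity scores keyed by (position, ref, alt).

    Lookups outside the table return ``None`` ("unscored"), never a default
    score; scores must lie in [0, 1].
    """

    def __init__(self, scores: dict, tool: str):
        self.tool = tool
        self.scores = {}
        for (pos, ref, alt), s in scores.items():
            s = float(s)
            if not 0.0 <= s <= 1.0:
                raise ValueError(
                    f"{tool} score {s} at {pos}{ref}>{alt} outside [0, 1]"
                )
            self.scores[(int(pos), ref, alt)] = s

    def get(self, position: int, ref: str, alt: str) -> float | None:
        return self.scores.get((position, ref, alt))

    def __len__(self) -> int:
        return len(self.scores)

    def to_tsv(self, path) -> None:
        rows = [
            {"pos": p, "ref": r, "alt": a, "score": s, "tool": self.tool}
            for (p, r, a), s in sorted(self.scores.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tool: str | None = None) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t")
        label = tool or (str(df["tool"].iloc[0]) if "tool" in df and len(df) else "?")
        return cls(
            {
                (int(r.pos), r.ref, r.alt): float(r.score)
                for r in df.itertuples()
            },
            tool=label,
        )


def classify_pathogenicity(
    variant: AnnotatedVariant,
    mutpred: ScoreTable | None = None,
    apogee2: ScoreTable | None = None,
) -> AnnotatedVariant:
    """Threshold MutPred (> 0.50) and APOGEE 2 (> 0.38) scores, strictly.

    Non-coding variants never acquire pathogenicity flags; unscored variants
    keep ``None`` flags and are excluded from pathogenic-fraction denominators
    downstream.
    """
    if variant.locus_class != "protein-coding":
        return variant
    updates = {}
    if mutpred is not None:
        s = mutpred.get(variant.position, variant.ref, variant.alt)
        updates["mutpred_score"] = s
        updates["pathogenic_mutpred"] = None if s is None else s > MUTPRED_THRESHOLD
    if apogee2 is not None:
        s = apogee2.get(variant.position, variant.ref, variant.alt)
        updates["apogee2_score"] = s
        updates["pathogenic_apogee2"] = None if s is None else s > APOGEE2_THRESHOLD
    return replace(variant, **updates)


_FRAME_COLUMNS = [
    "pos", "ref", "alt", "hf", "depth", "zygosity", "locus_class", "gene",
    "consequence", "effect", "aa_ref", "aa_alt", "incomplete_stop_caveat",
    "mutpred_score", "apogee2_score", "pathogenic_mutpred", "pathogenic_apogee2",
]


def annotated_to_frame(variants, sample: str | None = None, cell: str | None = None):
    rows = []
    for v in variants:
        row = {
            **({"sample": sample} if sample is not None else {}),
            **({"cell": cell} if cell is not None else {}),
            "pos": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "hf": v.hf,
            "depth": v.depth,
            "zygosity": v.zygosity,
            "locus_class": v.locus_class,
            "gene": v.gene,
            "consequence": v.consequence,
            "effect": v.effect,
            "aa_ref": v.aa_ref,
            "aa_alt": v.aa_alt,
            "incomplete_stop_caveat": v.incomplete_stop_caveat,
            "mutpred_score": v.mutpred_score,
            "apogee2_score": v.apogee2_score,
            "pathogenic_mutpred": v.pathogenic_mutpred,
            "pathogenic_apogee2": v.pathogenic_apogee2,
        }
        rows.append(row)
    cols = (
        (["sample"] if sample is not None else [])
        + (["cell"] if cell is not None else [])
        + _FRAME_COLUMNS
    )
    return pd.DataFrame(rows, columns=cols)
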