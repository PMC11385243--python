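"""Reduction of per-cell calls to somatic variant sets.

A variant is *somatic* in the sense used here when it is heteroplasmic
(HF > 0.02 and < 0.98) in exactly one cell of a sample, and absent — below
the detection floor, since zero alt reads is unattainable under sequencing
error — from the sample's bulk consensus and from every other cell of the
same sample.  Before that reduction, calls in low-complexity mask regions are
removed and each cell is checked for homology with its consensus via
homoplasmic-variant sharing (a contamination proxy: cells sharing ≤ 99% of
the consensus homoplasmies are excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .annotation import MaskSet
from .calling import VariantCall

HOMOLOGY_THRESHOLD = 0.99


def apply_masks(calls, masks: MaskSet) -> list[VariantCall]:
    """Remove calls at masked positions; order is preserved."""
    return [c for c in calls if c.position not in masks]


@dataclass(frozen=True)
class SimilarityReport:
    """Homoplasmy-sharing similarity of one cell against its consensus."""

    cell: str
    fraction: float
    n_shared: int
    n_consensus: int
    passed: bool | None  # None when the consensus has no homoplasmies

    @property
    def assessable(self) -> bool:
        return self.passed is not None


def homology_check(
    cell_calls,
    consensus_calls,
    cell: str = "cell",
    threshold: float = HOMOLOGY_THRESHOLD,
) -> SimilarityReport:
    """Fraction of consensus homoplasmies shared by the cell; pass iff > threshold.

    A consensus homoplasmy counts as shared when the cell carries the same
    allele as its *major* allele (HF > 0.5): ancestry markers remain shared
    even when intracellular drift leaves them fractionally below the 0.98
    homoplasmy ceiling in a single cell.
    """
    cons = {c.key for c in consensus_calls if c.zygosity == "homoplasmic"}
    if not cons:
        warnings.warn(
            f"{cell}: consensus has no homoplasmies; homology cannot be assessed",
            stacklevel=2,
        )
        return SimilarityReport(cell, float("nan"), 0, 0, None)
    mine = {c.key for c in cell_calls if c.hf > 0.5}
    shared = cons & mine
    frac = len(shared) / len(cons)
    return SimilarityReport(cell, frac, len(shared), len(cons), frac > threshold)


@dataclass
class SomaticVariantSet:
    """Per-cell variants surviving the somatic filter, with provenance flags.

    ``variants`` holds the somatic survivors (heteroplasmic above the analysis
    floor); ``candidates`` additionally keeps consensus-absent private calls
    at any HF > 0 below the homoplasmy ceiling — the raw material of the
    full HF histogram.
    """

    sample: str
    cell: str
    variants: list[VariantCall]
    candidates: list[VariantCall] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.variants)

    def hfs(self) -> list[float]:
        return [v.hf for v in self.variants]


def identify_somatic(
    per_cell_calls,
    consensus_calls,
    analysis_floor: float = 0.02,
    absent_floor: float = 0.02,
    homo_ceiling: float = 0.98,
    sample: str = "sample",
) -> dict[str, SomaticVariantSet]:
    """Reduce per-cell call lists to somatic variant sets.

    ``per_cell_calls`` maps cell id → calls from cells that already passed
    coverage QC and the homology check, with masks applied.  A (position,
    alt) pair is somatic in cell c iff it is heteroplasmic there
    (``analysis_floor`` < HF < ``homo_ceiling``), not present at or above
    ``absent_floor`` in the consensus, and not present at or above
    ``absent_floor`` in any other cell.  With a single cell the privacy
    criterion is vacuous and a warning is emitted.
    """
    cells = list(per_cell_calls)
    if len(cells) < 2:
        warnings.warn(
            f"{sample}: fewer than 2 cells; privacy criterion cannot apply",
            stacklevel=2,
        )
    consensus_present = {
        c.key for c in consensus_calls if c.hf >= absent_floor
    }
    present_in: dict[tuple[int, str], set[str]] = {}
    for cell, calls in per_cell_calls.items():
        for c in calls:
            if c.hf >= absent_floor:
                present_in.setdefault(c.key, set()).add(cell)

    out: dict[str, SomaticVariantSet] = {}
    for cell, calls in per_cell_calls.items():
        variants, candidates, prov = [], [], {}
        for c in calls:
            if c.low_confidence or not 0.0 < c.hf < homo_ceiling:
                continue
            consensus_absent = c.key not in consensus_present
            privacy = not (present_in.get(c.key, set()) - {cell})
            if consensus_absent and privacy:
                candidates.append(c)
                if c.hf > analysis_floor:
                    variants.append(c)
                    prov[c.key] = {
                        "mask_passed": True,
                        "privacy_passed": True,
                        "consensus_absent": True,
                    }
        out[cell] = SomaticVariantSet(
            sample=sample,
            cell=cell,
            variants=variants,
            candidates=candidates,
            provenance=prov,
        )
    return out
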