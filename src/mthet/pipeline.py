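"""End-to-end per-sample driver: QC → calling → masks → homology → somatic → annotation."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import LocusMap, MaskSet
from .calling import (
    AlleleCountTable,
    QcReport,
    VariantCall,
    call_variants,
    coverage_qc,
)
from .consequence import (
    AnnotatedVariant,
    ScoreTable,
    annotate_consequence,
    annotated_to_frame,
    classify_pathogenicity,
)
from .reference import MtReference
from .somatic import (
    SimilarityReport,
    SomaticVariantSet,
    apply_masks,
    homology_check,
    identify_somatic,
)


@dataclass
class PipelineParams:
    """Tunable thresholds of the somatic pipeline (defaults = study settings)."""

    min_level: float = 0.02  # analysis/detection floor on HF
    absent_floor: float = 0.02  # "absent" means HF below this in comparators
    homo_ceiling: float = 0.98
    report_floor: float = 0.002  # emission floor for sub-threshold calls
    min_alt_depth: int = 4  # minimum supporting reads per emitted alt
    min_site_depth: int = 500
    error_rate: float = 0.001
    qc_min_fraction: float = 0.99
    qc_min_depth: int = 1500
    homology_threshold: float = 0.99
    denominator: str = "ref_alt"


@dataclass
class SampleResult:
    """Everything the pipeline derives from one sample's count tables."""

    sample: str
    qc: dict[str, QcReport]
    qc_failed: list[str]
    homology: dict[str, SimilarityReport]
    homology_failed: list[str]
    cell_calls: dict[str, list[VariantCall]]
    consensus_calls: list[VariantCall]
    somatic: dict[str, SomaticVariantSet]
    annotated: pd.DataFrame
    annotated_objects: list[AnnotatedVariant] = field(default_factory=list)

    @property
    def cells_passed(self) -> list[str]:
        return list(self.somatic)

    def somatic_variants(self) -> list[AnnotatedVariant]:
        return list(self.annotated_objects)

    def all_somatic_hfs(self, pre_floor: bool = False) -> list[float]:
        """Pooled HFs of somatic variants (or of all pre-floor candidates)."""
        out = []
        for s in self.somatic.values():
            out.extend(v.hf for v in (s.candidates if pre_floor else s.variants))
        return out


def run_sample(
    cells: dict[str, AlleleCountTable],
    consensus: AlleleCountTable,
    reference: MtReference,
    locus_map: LocusMap | None = None,
    masks: MaskSet | None = None,
    params: PipelineParams | None = None,
    mutpred: ScoreTable | None = None,
    apogee2: ScoreTable | None = None,
    sample: str | None = None,
) -> SampleResult:
    """Run the full somatic pipeline on one sample's cells plus consensus."""
    locus_map = locus_map or LocusMap.default()
    masks = masks or MaskSet.default()
    p = params or PipelineParams()
    sample = sample or consensus.sample.replace("_consensus", "")

    qc = {name: coverage_qc(t, p.qc_min_fraction, p.qc_min_depth) for name, t in cells.items()}
    qc_failed = [name for name, r in qc.items() if not r.passed]
    passed = {name: t for name, t in cells.items() if qc[name].passed}

    def _call(table: AlleleCountTable) -> list[VariantCall]:
        return apply_masks(
            call_variants(
                table,
                reference,
                min_level=p.min_level,
                min_site_depth=p.min_site_depth,
                error_rate=p.error_rate,
                report_floor=p.report_floor,
                min_alt_depth=p.min_alt_depth,
                denominator=p.denominator,
            ),
            masks,
        )

    consensus_calls = _call(consensus)
    cell_calls = {name: _call(t) for name, t in passed.items()}

    homology = {
        name: homology_check(calls, consensus_calls, cell=name, threshold=p.homology_threshold)
        for name, calls in cell_calls.items()
    }
    homology_failed = [n for n, r in homology.items() if r.passed is False]
    analysed = {n: c for n, c in cell_calls.items() if n not in homology_failed}

    somatic = identify_somatic(
        analysed,
        consensus_calls,
        analysis_floor=p.min_level,
        absent_floor=p.absent_floor,
        homo_ceiling=p.homo_ceiling,
        sample=sample,
    )

    annotated_objs: list[AnnotatedVariant] = []
    frames = []
    for cell, sset in somatic.items():
        avs = [annotate_consequence(v, locus_map, reference) for v in sset.variants]
        if mutpred is not None or apogee2 is not None:
            avs = [classify_pathogenicity(a, mutpred, apogee2) for a in avs]
        annotated_objs.extend(avs)
        frames.append(annotated_to_frame(avs, sample=sample, cell=cell))
    annotated = (
        pd.concat(frames, ignore_index=True)
        if frames
        else annotated_to_frame([], sample=sample, cell="")
    )

    return SampleResult(
        sample=sample,
        qc=qc,
        qc_failed=qc_failed,
        homology=homology,
        homology_failed=homology_failed,
        cell_calls=cell_calls,
        consensus_calls=consensus_calls,
        somatic=somatic,
        annotated=annotated,
        annotated_objects=annotated_objs,
    )
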