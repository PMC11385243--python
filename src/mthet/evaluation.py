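"""Parameter-recovery metrics of the somatic pipeline against simulator truth.

A simulated private somatic variant is *recoverable* when the pipeline's own
somatic definition can admit it: heteroplasmic in its cell (true HF below the
homoplasmy ceiling), in a cell that passed QC and homology, and diluted in
the consensus pool below the detection floor (a variant at HF h in one of n
cells sits at h/n in the consensus; at h/n ≥ floor it is genuinely present
there and is correctly rejected).  Recall is reported over recoverable truths
above a minimum true HF; precision over all somatic calls vs the full truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import MaskSet
from .pipeline import SampleResult
from .simulate import SimResult


@dataclass(frozen=True)
class RecoveryReport:
    n_true: int  # recoverable truths with true HF >= min_hf
    n_called: int
    n_true_called: int  # recall numerator
    n_called_true: int  # precision numerator
    n_masked_calls: int
    recall: float
    precision: float


def recovery_metrics(
    sims: list[SimResult],
    results: list[SampleResult],
    min_hf: float = 0.05,
    floor: float = 0.02,
    homo_ceiling: float = 0.98,
    masks: MaskSet | None = None,
) -> RecoveryReport:
    """Pool recall/precision of somatic identification over simulated samples."""
    masks = masks or MaskSet.default()
    n_true = n_called = tp_recall = tp_prec = n_masked = 0
    for sim, res in zip(sims, results):
        cells_ok = set(res.somatic)
        truth = sim.truth.somatic_truth()
        n_cells = sim.config.n_cells
        truth_keys = {
            (r.cell, r.pos, r.alt): r.hf
            for r in truth.itertuples()
            if r.cell in cells_ok
        }
        recoverable = {
            k
            for k, h in truth_keys.items()
            if h >= min_hf and h < homo_ceiling and h / n_cells < floor
        }
        called = {
            (cell, v.position, v.alt)
            for cell, s in res.somatic.items()
            for v in s.variants
        }
        n_true += len(recoverable)
        n_called += len(called)
        tp_recall += sum(1 for k in recoverable if k in called)
        tp_prec += sum(1 for k in called if k in truth_keys)
        n_masked += sum(1 for _, pos, _ in called if pos in masks)
    return RecoveryReport(
        n_true=n_true,
        n_called=n_called,
        n_true_called=tp_recall,
        n_called_true=tp_prec,
        n_masked_calls=n_masked,
        recall=tp_recall / n_true if n_true else float("nan"),
        precision=tp_prec / n_called if n_called else float("nan"),
    )
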