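"""Synthetic single-cell mtDNA study generator with ground truth.

Emulates the data structure of a single-cell mtDNA resequencing study of
bone-marrow mesenchymal stem cells: 13 patient samples of a handful of cells
each, every cell sharing its sample's homoplasmic germline haplotype, a few
sample-level heteroplasmies (HF ~0.02-0.94) whose per-cell fractions spread
by intracellular genetic drift, and per-cell private somatic variants, mostly
at low HF with a rare clonal-expansion tail.  Reads are not simulated;
per-position allele counts are drawn with a negative-binomial depth model and
a symmetric per-base miscall error, so counts always sum to depth.

Drift uses discrete Wright-Fisher resampling of the ~800 mtDNA copies per
cell: each generation the variant copy count is redrawn as
Binomial(copy_number, current fraction), absorbing at 0 and 1, with closed
form variance hf0(1-hf0)(1-(1-1/N)^t) after t generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .annotation import LocusMap, MaskSet
from .calling import BASES, AlleleCountTable, _BASE_INDEX
from .consequence import ScoreTable
from .reference import MT_LENGTH, MtReference

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimSampleConfig:
    """Parameters of one simulated patient sample.

    Defaults reflect the study conditions being emulated: ~800 mtDNA copies
    per MSC, 1-7 sample-level heteroplasmies at HF 0.02-0.94, deep coverage
    (~2000x) and per-cell private somatic variation dominated by low
    fractions (most below the 0.02 detection floor) with a rare (~1%)
    clonal-expansion component reaching HF > 0.25.
    """

    seed: int
    sample: str = "patient01"
    n_cells: int = 8
    copy_number: int = 800
    n_germline: int = 30
    n_shared_het: int | None = None  # None -> Uniform{1..7}
    shared_het_hf_range: tuple[float, float] = (0.02, 0.94)
    somatic_rate: float = 80.0  # Poisson mean private variants per cell
    somatic_hf_mean: float = 0.015  # exponential mean of initial somatic HF
    somatic_high_hf_prob: float = 0.01
    somatic_high_hf_range: tuple[float, float] = (0.25, 0.90)
    drift_generations: int = 20
    depth_mean: float = 2000.0
    depth_dispersion: float = 200.0
    consensus_depth_mean: float | None = None
    error_rate: float = 0.001
    transition_prob: float = 0.9  # alt-base draw bias toward transitions
    dloop_enrichment: float = 1.0  # placement weight multiplier in the D-loop
    n_qc_fail_cells: int = 0
    qc_fail_window_fraction: float = 0.05
    qc_fail_window_depth: float = 100.0
    contaminant_cells: int = 0  # cells carrying a foreign germline haplotype

    def __post_init__(self) -> None:
        if self.copy_number < 2:
            raise ValueError("copy_number must be >= 2")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for r in (self.somatic_rate, self.error_rate, self.somatic_hf_mean):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        lo, hi = self.shared_het_hf_range
        if not 0 < lo <= hi < 1:
            raise ValueError("shared_het_hf_range must lie inside (0, 1)")


@dataclass(frozen=True)
class TrueVariant:
    position: int
    ref: str
    alt: str
    hf: float
    kind: str  # germline | shared | somatic

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt)


@dataclass
class SimTruth:
    """Ground truth of one simulated sample, for parameter-recovery tests."""

    sample: str
    per_cell: dict[str, list[TrueVariant]]
    consensus: list[TrueVariant]

    def somatic_truth(self) -> pd.DataFrame:
        """One row per private somatic variant with its cell and true HF."""
        rows = [
            {"cell": cell, "pos": v.position, "ref": v.ref, "alt": v.alt, "hf": v.hf}
            for cell, vs in self.per_cell.items()
            for v in vs
            if v.kind == "somatic"
        ]
        return pd.DataFrame(rows, columns=["cell", "pos", "ref", "alt", "hf"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell, vs in self.per_cell.items():
            for v in vs:
                rows.append(
                    {
                        "unit": cell,
                        "pos": v.position,
                        "ref": v.ref,
                        "alt": v.alt,
                        "hf": v.hf,
                        "kind": v.kind,
                    }
                )
        for v in self.consensus:
            rows.append(
                {
                    "unit": "consensus",
                    "pos": v.position,
                    "ref": v.ref,
                    "alt": v.alt,
                    "hf": v.hf,
                    "kind": v.kind,
                }
            )
        return pd.DataFrame(
            rows, columns=["unit", "pos", "ref", "alt", "hf", "kind"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, sample: str = "sample") -> "SimTruth":
        df = pd.read_csv(path, sep="\t")
        per_cell: dict[str, list[TrueVariant]] = {}
        consensus: list[TrueVariant] = []
        for r in df.itertuples():
            v = TrueVariant(int(r.pos), r.ref, r.alt, float(r.hf), r.kind)
            if r.unit == "consensus":
                consensus.append(v)
            else:
                per_cell.setdefault(r.unit, []).append(v)
        return cls(sample=sample, per_cell=per_cell, consensus=consensus)


@dataclass
class SimResult:
    config: SimSampleConfig
    cells: dict[str, AlleleCountTable]
    consensus: AlleleCountTable
    truth: SimTruth
    qc_fail_expected: list[str] = field(default_factory=list)
    contaminant_expected: list[str] = field(default_factory=list)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def drift_hf(hf0, copy_number: int, generations: int, seed, size=None):
    """Wright-Fisher drift of a heteroplasmic fraction.

    Each generation resamples the variant copy count as
    Binomial(``copy_number``, current fraction); 0 and 1 are absorbing.
    With ``size`` set, returns an array of independent replicates.
    """
    rng = _as_rng(seed)
    scalar = size is None and np.isscalar(hf0)
    f = np.full(size or np.shape(hf0) or 1, hf0, dtype=float) if size else np.atleast_1d(
        np.asarray(hf0, dtype=float)
    ).copy()
    if np.any((f < 0) | (f > 1)):
        raise ValueError("hf0 must lie in [0, 1]")
    for _ in range(int(generations)):
        f = rng.binomial(copy_number, f) / copy_number
    return float(f[0]) if scalar else f


def _draw_alt(ref_base: str, rng: np.random.Generator, transition_prob: float) -> str:
    if rng.random() < transition_prob:
        return _TRANSITION[ref_base]
    tv = [b for b in BASES if b != ref_base and b != _TRANSITION[ref_base]]
    return tv[rng.integers(len(tv))]


def generate_counts(
    true_variants,
    depth_model,
    error_rate: float,
    reference: MtReference,
    seed,
    sample: str = "cell",
    is_consensus: bool = False,
    low_coverage_window: tuple[int, int, float] | None = None,
) -> AlleleCountTable:
    """Draw an allele-count table from a list of true variants.

    ``depth_model`` is either an int/float (constant depth) or a tuple
    ``(mean, dispersion)`` for a negative-binomial depth per position.  Each
    template molecule is misread to one of the three other bases with total
    probability ``error_rate`` (symmetric, e/3 each); counts at every
    position sum to the drawn depth.  ``low_coverage_window`` =
    ``(start, end, depth_mean)`` overrides the depth model inside one region,
    exercising the coverage-QC failure path.
    """
    rng = _as_rng(seed)
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must lie in [0, 0.25)")
    ref_arr = reference.base_array()
    frac = np.zeros((MT_LENGTH, 4))
    ref_idx = np.array([_BASE_INDEX.get(b, 0) for b in ref_arr])
    frac[np.arange(MT_LENGTH), ref_idx] = 1.0
    for v in true_variants:
        if v.alt == v.ref:
            raise ValueError(f"variant alt equals ref at position {v.position}")
        i = v.position - 1
        frac[i, _BASE_INDEX[v.ref]] -= v.hf
        frac[i, _BASE_INDEX[v.alt]] += v.hf
    if frac.min() < -1e-9:
        raise ValueError("variant fractions at a position exceed 1")
    frac = np.clip(frac, 0.0, 1.0)

    if np.isscalar(depth_model):
        depth = np.full(MT_LENGTH, int(depth_model))
    else:
        mean, disp = depth_model
        p = disp / (disp + mean)
        depth = rng.negative_binomial(disp, p, size=MT_LENGTH)
    if low_coverage_window is not None:
        s, e, m = low_coverage_window
        depth[s - 1 : e] = rng.poisson(m, size=e - s + 1)

    # miscall mixing: P(obs=b) = f_b (1 - 4e/3) + e/3
    probs = frac * (1.0 - 4.0 * error_rate / 3.0) + error_rate / 3.0
    probs /= probs.sum(axis=1, keepdims=True)
    counts = rng.multinomial(depth, probs)
    return AlleleCountTable.from_arrays(counts, sample=sample, is_consensus=is_consensus)


def _position_weights(masks: MaskSet, locus_map: LocusMap, enrichment: float):
    w = np.ones(MT_LENGTH)
    w[masks.masked_positions - 1] = 0.0
    if enrichment != 1.0:
        dloop = np.array(
            [locus_map.locus_of(p)[0] == "D-loop" for p in range(1, MT_LENGTH + 1)]
        )
        w[dloop] *= enrichment
    return w / w.sum()


def simulate_sample(
    config: SimSampleConfig,
    reference: MtReference | None = None,
    locus_map: LocusMap | None = None,
    masks: MaskSet | None = None,
) -> SimResult:
    """Simulate one patient sample: per-cell tables, a consensus table and truth.

    The consensus models the bulk aliquot as the cell-weighted pool of the
    sampled cells' true fractions: germline variants at HF 1, shared
    heteroplasmies at the mean of the per-cell drifted fractions, and each
    private somatic variant diluted to hf/n_cells.
    """
    reference = reference or MtReference.synthetic()
    locus_map = locus_map or LocusMap.default()
    masks = masks or MaskSet.default()
    rng = _as_rng(config.seed)
    weights = _position_weights(masks, locus_map, config.dloop_enrichment)
    ref_arr = reference.base_array()

    n_backbone = config.n_germline + 7  # germline + worst-case shared hets
    backbone_pos = rng.choice(
        MT_LENGTH, size=n_backbone, replace=False, p=weights
    ) + 1
    used_positions = set(int(p) for p in backbone_pos)

    germline = []
    for p in backbone_pos[: config.n_germline]:
        ref = str(ref_arr[p - 1])
        germline.append(
            TrueVariant(int(p), ref, _draw_alt(ref, rng, config.transition_prob), 1.0, "germline")
        )

    n_shared = (
        config.n_shared_het
        if config.n_shared_het is not None
        else int(rng.integers(1, 8))
    )
    lo, hi = config.shared_het_hf_range
    shared = []
    for p in backbone_pos[config.n_germline : config.n_germline + n_shared]:
        ref = str(ref_arr[p - 1])
        shared.append(
            TrueVariant(
                int(p),
                ref,
                _draw_alt(ref, rng, config.transition_prob),
                float(rng.uniform(lo, hi)),
                "shared",
            )
        )

    cell_names = [f"cell{i + 1:02d}" for i in range(config.n_cells)]
    qc_fail = [f"cell{config.n_cells + i + 1:02d}_lowcov" for i in range(config.n_qc_fail_cells)]
    contaminants = [f"cell{config.n_cells + config.n_qc_fail_cells + i + 1:02d}_foreign"
                    for i in range(config.contaminant_cells)]

    # per-cell drifted fractions of shared heteroplasmies
    per_cell: dict[str, list[TrueVariant]] = {}
    shared_cell_hf = {
        v.key: drift_hf(
            np.full(len(cell_names) + len(qc_fail), v.hf),
            config.copy_number,
            config.drift_generations,
            rng,
        )
        for v in shared
    }

    used_keys: set[tuple[int, str]] = set()
    N = config.copy_number

    def _somatic_for_cell() -> list[TrueVariant]:
        out = []
        n_som = rng.poisson(config.somatic_rate)
        for _ in range(n_som):
            # rejection-sample a fresh position (privacy: one cell per key)
            for _try in range(100):
                p = int(rng.choice(MT_LENGTH, p=weights)) + 1
                if p not in used_positions:
                    break
            else:  # pragma: no cover
                continue
            used_positions.add(p)
            ref = str(ref_arr[p - 1])
            alt = _draw_alt(ref, rng, config.transition_prob)
            if rng.random() < config.somatic_high_hf_prob:
                h0 = float(rng.uniform(*config.somatic_high_hf_range))
            else:
                h0 = min(float(rng.exponential(config.somatic_hf_mean)), 0.5)
                h0 = max(h0, 1.0 / N)
            h = drift_hf(h0, N, config.drift_generations, rng)
            if h <= 0.0:
                continue  # drifted out of the cell
            used_keys.add((p, alt))
            out.append(TrueVariant(p, ref, alt, float(min(h, 1.0)), "somatic"))
        return out

    for j, cell in enumerate(cell_names + qc_fail):
        vs = list(germline)
        for v in shared:
            h = float(shared_cell_hf[v.key][j])
            if h > 0:
                vs.append(replace(v, hf=h))
        vs.extend(_somatic_for_cell())
        per_cell[cell] = vs

    # contaminant cells: a different germline haplotype, no shared hets
    for cell in contaminants:
        n_pos = config.n_germline
        pos = rng.choice(MT_LENGTH, size=n_pos, replace=False, p=weights) + 1
        vs = []
        for p in pos:
            ref = str(ref_arr[p - 1])
            vs.append(TrueVariant(int(p), ref, _draw_alt(ref, rng, config.transition_prob), 1.0, "germline"))
        per_cell[cell] = vs

    # consensus: cell-weighted mean of true fractions over the main cells
    n_main = len(cell_names)
    consensus: list[TrueVariant] = list(germline)
    for v in shared:
        mean_hf = float(np.mean(shared_cell_hf[v.key][:n_main]))
        if mean_hf > 0:
            consensus.append(replace(v, hf=mean_hf))
    for cell in cell_names:
        for v in per_cell[cell]:
            if v.kind == "somatic":
                consensus.append(replace(v, hf=v.hf / n_main))

    depth_model = (config.depth_mean, config.depth_dispersion)
    cells_out: dict[str, AlleleCountTable] = {}
    for cell in cell_names + contaminants:
        cells_out[cell] = generate_counts(
            per_cell[cell], depth_model, config.error_rate, reference, rng, sample=cell
        )
    win_len = int(config.qc_fail_window_fraction * MT_LENGTH)
    for cell in qc_fail:
        start = int(rng.integers(1, MT_LENGTH - win_len))
        cells_out[cell] = generate_counts(
            per_cell[cell],
            depth_model,
            config.error_rate,
            reference,
            rng,
            sample=cell,
            low_coverage_window=(start, start + win_len - 1, config.qc_fail_window_depth),
        )
    consensus_table = generate_counts(
        consensus,
        (config.consensus_depth_mean or config.depth_mean, config.depth_dispersion),
        config.error_rate,
        reference,
        rng,
        sample=f"{config.sample}_consensus",
        is_consensus=True,
    )
    truth = SimTruth(sample=config.sample, per_cell=per_cell, consensus=consensus)
    return SimResult(
        config=config,
        cells=cells_out,
        consensus=consensus_table,
        truth=truth,
        qc_fail_expected=qc_fail,
        contaminant_expected=contaminants,
    )


def simulate_study(
    n_samples: int = 13,
    seed: int = 0,
    reference: MtReference | None = None,
    locus_map: LocusMap | None = None,
    masks: MaskSet | None = None,
    **config_overrides,
) -> list[SimResult]:
    """Simulate a cohort of patient samples with independent child seeds."""
    reference = reference or MtReference.synthetic()
    children = np.random.SeedSequence(seed).spawn(n_samples)
    results = []
    for i, child in enumerate(children):
        cfg = SimSampleConfig(
            seed=int(child.generate_state(1)[0] % (2**31)),
            sample=f"patient{i + 1:02d}",
            **config_overrides,
        )
        results.append(
            simulate_sample(cfg, reference=reference, locus_map=locus_map, masks=masks)
        )
    return results


def fabricate_score_tables(
    variant_keys, seed, coverage: float = 0.95
) -> tuple[ScoreTable, ScoreTable]:
    """Synthetic MutPred / APOGEE 2 score tables for a set of (pos, ref, alt).

    Real predictor outputs are external inputs; these stand-ins draw MutPred
    scores from Beta(5, 2) (right-skewed, most mass above 0.5) and APOGEE 2
    from Beta(1.3, 1.5) (flatter, roughly half above 0.38), emulating the
    qualitative pathogenicity skew of such tools.  A fraction of variants is
    left unscored to exercise the unscored code path.
    """
    rng = _as_rng(seed)
    mut, apo = {}, {}
    for key in variant_keys:
        if rng.random() < coverage:
            mut[tuple(key)] = float(rng.beta(5.0, 2.0))
        if rng.random() < coverage:
            apo[tuple(key)] = float(rng.beta(1.3, 1.5))
    return ScoreTable(mut, tool="MutPred"), ScoreTable(apo, tool="APOGEE2")


def write_sample(result: SimResult, outdir, reference: MtReference | None = None) -> None:
    """Serialise one simulated sample: cells/, consensus.tsv and truth.tsv."""
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    for name, table in result.cells.items():
        table.to_tsv(outdir / "cells" / f"{name}.tsv", reference=reference)
    result.consensus.to_tsv(outdir / "consensus.tsv", reference=reference)
    result.truth.to_tsv(outdir / "truth.tsv")
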