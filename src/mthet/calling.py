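"""Count-based substitution calling, heteroplasmic fraction and coverage QC.

The pipeline's entry point is a per-position allele-count table (one cell or
one bulk "consensus" sample).  At every position each non-reference base with
enough support is emitted as a call carrying its heteroplasmic fraction

    HF = alt_depth / (alt_depth + ref_depth)

(the variant allele depth relative to the reference allele depth; an
``alt/total`` denominator is available via ``denominator="total"``).  Calls
are classified as homoplasmic (HF > 0.98), heteroplasmic (0.02 < HF ≤ 0.98)
or sub-threshold; sub-threshold calls are kept — the low-HF noise spectrum is
itself an object of study — and flagged rather than dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import MT_LENGTH, MtReference

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: detection / analysis floor and homoplasmy ceiling on HF
DEFAULT_MIN_LEVEL = 0.02
HOMOPLASMY_CEILING = 0.98


class UndefinedHFError(ZeroDivisionError):
    """HF requested at a site with zero informative depth."""


def compute_hf(alt_depth: int, ref_depth: int) -> float:
    """Heteroplasmic fraction alt/(alt+ref); raises on zero total."""
    total = alt_depth + ref_depth
    if total <= 0:
        raise UndefinedHFError("alt_depth + ref_depth must be positive")
    return alt_depth / total


def classify_zygosity(
    hf: float,
    het_floor: float = DEFAULT_MIN_LEVEL,
    homo_ceiling: float = HOMOPLASMY_CEILING,
) -> str:
    """Zygosity class of an HF value.

    Strict inequalities as printed: HF > 0.98 is homoplasmic, 0.02 < HF ≤ 0.98
    heteroplasmic, anything else (including HF = 0.02 exactly) sub-threshold.
    """
    hf = float(hf)
    if not 0.0 <= hf <= 1.0:
        raise ValueError(f"HF {hf} outside [0, 1]")
    if hf > homo_ceiling:
        return "homoplasmic"
    if hf > het_floor:
        return "heteroplasmic"
    return "sub-threshold"


@dataclass(frozen=True)
class VariantCall:
    """One substitution call at a single position."""

    position: int
    ref: str
    alt: str
    alt_depth: int
    ref_depth: int
    depth: int
    hf: float
    zygosity: str
    p_error: float = float("nan")
    low_confidence: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt)

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"


class AlleleCountTable:
    """Per-position A/C/G/T counts plus depth for one cell or consensus sample.

    The underlying frame is indexed by 1-based position 1..16,569 (zero-filled
    where uncovered) with integer columns ``A, C, G, T, depth``; base counts
    must sum to depth at every position.
    """

    def __init__(self, df: pd.DataFrame, sample: str, is_consensus: bool = False):
        df = df.copy()
        expected = list(BASES) + ["depth"]
        missing = [c for c in expected if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        df = df[expected].astype(np.int64)
        if not df.index.equals(pd.RangeIndex(1, MT_LENGTH + 1)):
            df = df.reindex(pd.RangeIndex(1, MT_LENGTH + 1), fill_value=0)
        if (df.values < 0).any():
            raise ValueError("negative counts")
        if not (df[list(BASES)].sum(axis=1) == df["depth"]).all():
            raise ValueError("base counts do not sum to depth at every position")
        df.index.name = "pos"
        self.df = df
        self.sample = sample
        self.is_consensus = is_consensus

    @property
    def depth(self) -> np.ndarray:
        return self.df["depth"].to_numpy()

    def counts_matrix(self) -> np.ndarray:
        """(16569, 4) matrix of base counts, row 0 = position 1."""
        return self.df[list(BASES)].to_numpy()

    @classmethod
    def from_arrays(
        cls, counts: np.ndarray, sample: str, is_consensus: bool = False
    ) -> "AlleleCountTable":
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (MT_LENGTH, 4):
            raise ValueError(f"expected shape ({MT_LENGTH}, 4)")
        df = pd.DataFrame(
            counts, columns=list(BASES), index=pd.RangeIndex(1, MT_LENGTH + 1)
        )
        df["depth"] = counts.sum(axis=1)
        return cls(df, sample=sample, is_consensus=is_consensus)

    def to_tsv(self, path, reference: MtReference | None = None) -> None:
        out = self.df.copy()
        if reference is not None:
            out.insert(0, "ref", list(reference.sequence))
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path, sample: str | None = None, is_consensus: bool = False
    ) -> "AlleleCountTable":
        df = pd.read_csv(path, sep="\t", index_col="pos")
        from pathlib import Path

        name = sample if sample is not None else Path(path).stem
        return cls(df, sample=name, is_consensus=is_consensus)


@dataclass(frozen=True)
class QcReport:
    """Coverage quality control for one sample."""

    sample: str
    covered_fraction: float
    n_covered: int
    min_depth: int
    min_fraction: float
    passed: bool
    mean_depth: float = float("nan")


def coverage_qc(
    counts: AlleleCountTable,
    min_fraction: float = 0.99,
    min_depth: int = 1500,
) -> QcReport:
    """Pass iff ≥ ``min_fraction`` of the genome is covered at ≥ ``min_depth``."""
    depth = counts.depth
    n_cov = int((depth >= min_depth).sum())
    frac = n_cov / MT_LENGTH
    return QcReport(
        sample=counts.sample,
        covered_fraction=frac,
        n_covered=n_cov,
        min_depth=min_depth,
        min_fraction=min_fraction,
        passed=frac >= min_fraction,
        mean_depth=float(depth.mean()),
    )


def call_variants(
    counts: AlleleCountTable,
    reference: MtReference,
    min_level: float = DEFAULT_MIN_LEVEL,
    min_site_depth: int = 500,
    error_rate: float = 0.001,
    report_floor: float = 0.002,
    min_alt_depth: int = 4,
    min_informative_fraction: float = 0.5,
    denominator: str = "ref_alt",
) -> list[VariantCall]:
    """Emit substitution calls from an allele-count table.

    Every non-reference base whose HF reaches ``report_floor`` and is backed
    by at least ``min_alt_depth`` reads is emitted (multi-allelic sites give
    one call per alt base); calls with HF at or below ``min_level`` are
    flagged sub-threshold by their zygosity rather than dropped.  Each call
    carries a binomial p-value of its alt count against a Binomial(depth,
    ``error_rate``) noise model, and calls at sites below ``min_site_depth``
    are flagged low-confidence (excluded from downstream somatic sets).

    The ``min_alt_depth`` and ``min_informative_fraction`` floors matter at
    sites whose true allele differs from the reference (germline variants):
    there the rCRS base has near-zero depth, so a handful of stray miscalls
    of a third base would otherwise surface as a spurious homoplasmic call
    with HF = alt/(alt+0).  A call is only emitted when the ref+alt pair
    carries at least ``min_informative_fraction`` of the site's depth — the
    regime in which the alt/(alt+ref) heteroplasmic fraction is meaningful.
    """
    if not 0 < min_level < 0.5:
        raise ValueError("min_level must lie in (0, 0.5)")
    if denominator not in ("ref_alt", "total"):
        raise ValueError("denominator must be 'ref_alt' or 'total'")
    mat = counts.counts_matrix()
    depth = counts.depth
    ref_arr = reference.base_array()
    ref_idx = np.full(MT_LENGTH, -1, dtype=int)
    for b, i in _BASE_INDEX.items():
        ref_idx[ref_arr == b] = i
    valid = ref_idx >= 0  # N reference positions yield no calls
    rows = np.arange(MT_LENGTH)
    ref_depth = np.zeros(MT_LENGTH, dtype=np.int64)
    ref_depth[valid] = mat[rows[valid], ref_idx[valid]]

    calls: list[VariantCall] = []
    for alt_i, alt in enumerate(BASES):
        is_alt = valid & (ref_idx != alt_i)
        alt_depth = mat[:, alt_i]
        denom = (
            alt_depth + ref_depth if denominator == "ref_alt" else depth
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            hf = np.where(denom > 0, alt_depth / np.maximum(denom, 1), 0.0)
        emit = (
            is_alt
            & (alt_depth >= max(min_alt_depth, 1))
            & (denom > 0)
            & (hf >= report_floor)
            & (alt_depth + ref_depth >= min_informative_fraction * depth)
        )
        pos_sel = np.flatnonzero(emit)
        if pos_sel.size == 0:
            continue
        p_err = sps.binom.sf(alt_depth[pos_sel] - 1, depth[pos_sel], error_rate)
        for j, p in enumerate(pos_sel):
            calls.append(
                VariantCall(
                    position=int(p) + 1,
                    ref=str(ref_arr[p]),
                    alt=alt,
                    alt_depth=int(alt_depth[p]),
                    ref_depth=int(ref_depth[p]),
                    depth=int(depth[p]),
                    hf=float(hf[p]),
                    zygosity=classify_zygosity(float(hf[p]), het_floor=min_level),
                    p_error=float(p_err[j]),
                    low_confidence=bool(depth[p] < min_site_depth),
                )
            )
    calls.sort(key=lambda c: (c.position, c.alt))
    return calls


def calls_to_frame(calls) -> pd.DataFrame:
    """Tidy frame of calls (one row per (position, alt))."""
    return pd.DataFrame(
        [
            {
                "pos": c.position,
                "ref": c.ref,
                "alt": c.alt,
                "alt_depth": c.alt_depth,
                "ref_depth": c.ref_depth,
                "depth": c.depth,
                "hf": c.hf,
                "zygosity": c.zygosity,
                "p_error": c.p_error,
                "low_confidence": c.low_confidence,
            }
            for c in calls
        ],
        columns=[
            "pos",
            "ref",
            "alt",
            "alt_depth",
            "ref_depth",
            "depth",
            "hf",
            "zygosity",
            "p_error",
            "low_confidence",
        ],
    )


def frame_to_calls(df: pd.DataFrame) -> list[VariantCall]:
    return [
        VariantCall(
            position=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            alt_depth=int(r.alt_depth),
            ref_depth=int(r.ref_depth),
            depth=int(r.depth),
            hf=float(r.hf),
            zygosity=r.zygosity,
            p_error=float(r.p_error),
            low_confidence=bool(r.low_confidence),
        )
        for r in df.itertuples()
    ]


def write_calls_tsv(calls, path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[VariantCall]:
    return frame_to_calls(pd.read_csv(path, sep="\t"))


def write_calls_vcf(calls, reference: MtReference, sample: str, path) -> None:
    """Write calls as an uncompressed single-sample VCF with AD/DP/HF fields."""
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add("chrM", length=MT_LENGTH)
    header.formats.add("GT", 1, "String", "Genotype (placeholder)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alt)")
    header.formats.add("HF", 1, "Float", "Heteroplasmic fraction alt/(alt+ref)")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.position, c.alt)):
            rec = vcf.new_record(
                contig="chrM",
                start=c.position - 1,
                stop=c.position,
                alleles=(c.ref, c.alt),
            )
            rec.samples[sample]["GT"] = (0, 1)
            rec.samples[sample]["DP"] = c.depth
            rec.samples[sample]["AD"] = (c.ref_depth, c.alt_depth)
            rec.samples[sample]["HF"] = c.hf
            vcf.write(rec)


def read_calls_vcf(
    path,
    min_level: float = DEFAULT_MIN_LEVEL,
    min_site_depth: int = 500,
) -> list[VariantCall]:
    """Read a single-sample VCF with allele depths, recomputing HF from AD."""
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"expected a single-sample VCF, got {samples}")
        s = samples[0]
        for rec in vcf:
            ad = rec.samples[s].get("AD")
            if ad is None:
                raise ValueError(f"record at {rec.pos} lacks AD")
            ref_d, alt_d = int(ad[0]), int(ad[1])
            depth = rec.samples[s].get("DP") or (ref_d + alt_d)
            hf = compute_hf(alt_d, ref_d)
            calls.append(
                VariantCall(
                    position=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    alt_depth=alt_d,
                    ref_depth=ref_d,
                    depth=int(depth),
                    hf=hf,
                    zygosity=classify_zygosity(hf, het_floor=min_level),
                    low_confidence=int(depth) < min_site_depth,
                )
            )
    return calls
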