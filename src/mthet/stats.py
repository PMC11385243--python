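"""Summary and comparative statistics over somatic variant sets.

Implements the study's analyses: per-cell burdens normalised by locus length,
the 12-class substitution spectrum on the reference strand, many-to-one
comparisons of burdens and HF distributions (one-way ANOVA plus Dunnett's
test against an explicit reference group), the non-synonymous vs synonymous
Mann-Whitney contrasts, and distribution-shape statistics (kurtosis and
Shapiro-Wilk normality) of pathogenicity scores.  All tests are two-sided
and p-values are reported unadjusted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import LOCUS_CLASSES, NORMALIZATION_BP, LocusMap

#: the 12 possible single-base substitutions on the reference strand
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r, a in itertools.permutations("ACGT", 2)
)


@dataclass(frozen=True)
class TestResult:
    """One statistical test outcome."""

    name: str
    statistic: float
    pvalue: float
    reference: str | None = None
    groups: tuple = ()
    note: str | None = None


def hf_threshold_summary(hfs, floor: float = 0.02) -> dict:
    """Partition an HF list at the detection floor.

    Returns counts and percentages of variants below the floor (discarded as
    noise-dominated) and at or above it (retained for analysis).
    """
    hfs = np.asarray(list(hfs), dtype=float)
    n = hfs.size
    n_below = int((hfs < floor).sum())
    n_ret = n - n_below
    return {
        "n_total": n,
        "n_below": n_below,
        "n_retained": n_ret,
        "pct_below": 100.0 * n_below / n if n else float("nan"),
        "pct_retained": 100.0 * n_ret / n if n else float("nan"),
    }


def _iter_sets(somatic_sets):
    """Accept a mapping cell→set, an iterable of sets, or of (sample, set)."""
    if hasattr(somatic_sets, "values"):
        return list(somatic_sets.values())
    return list(somatic_sets)


def burden_by_locus(somatic_sets, locus_map: LocusMap | None = None) -> pd.DataFrame:
    """Per-cell, per-locus-class somatic counts, raw and length-normalised.

    Every cell contributes a row for each of the four locus classes (zero
    counts included); ``normalized`` is count divided by the fixed per-class
    length in bp.  Variants at the few intergenic positions carry no class
    and are excluded.
    """
    locus_map = locus_map or LocusMap.default()
    rows = []
    for sset in _iter_sets(somatic_sets):
        counts = dict.fromkeys(LOCUS_CLASSES, 0)
        for v in sset.variants:
            cls, _ = locus_map.locus_of(v.position)
            if cls in counts:
                counts[cls] += 1
        for cls in LOCUS_CLASSES:
            rows.append(
                {
                    "sample": sset.sample,
                    "cell": sset.cell,
                    "locus_class": cls,
                    "count": counts[cls],
                    "normalized": counts[cls] / NORMALIZATION_BP[cls],
                }
            )
    return pd.DataFrame(
        rows, columns=["sample", "cell", "locus_class", "count", "normalized"]
    )


def per_cell_totals(burden: pd.DataFrame) -> pd.DataFrame:
    """Total somatic count per cell (sum over locus classes)."""
    return (
        burden.groupby(["sample", "cell"], as_index=False)["count"].sum()
    )


def substitution_spectrum(variants) -> pd.DataFrame:
    """Counts and percentages of the 12 reference-strand substitution classes.

    ``variants`` is any iterable of objects with ``ref`` and ``alt``
    attributes (or a mapping / iterable of somatic sets, which are pooled).
    Complementary classes (e.g. T>C and A>G) are reported separately.
    """
    items = list(variants)
    if items and not hasattr(items[0], "ref"):
        items = [v for sset in _iter_sets(variants) for v in sset.variants]
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    for v in items:
        counts[f"{v.ref}>{v.alt}"] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "substitution": list(counts),
            "count": list(counts.values()),
            "percent": [
                100.0 * c / total if total else 0.0 for c in counts.values()
            ],
        }
    )


def compare_groups(
    values_by_group: dict, reference: str, test_name: str = "value"
) -> list[TestResult]:
    """One-way ANOVA across groups plus Dunnett's many-to-one test.

    Groups with fewer than 2 observations are excluded with a warning.  The
    reference group is mandatory and is the control of every Dunnett
    contrast.
    """
    groups = {}
    for name, vals in values_by_group.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size < 2:
            warnings.warn(f"group {name!r} has < 2 observations; excluded", stacklevel=2)
            continue
        groups[name] = vals
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing or too small")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = [reference] + [g for g in groups if g != reference]
    arrays = [groups[g] for g in names]
    f, p = sps.f_oneway(*arrays)
    out = [
        TestResult(
            name=f"ANOVA[{test_name}]",
            statistic=float(f),
            pvalue=float(p),
            groups=tuple(names),
        )
    ]
    dun = sps.dunnett(*arrays[1:], control=arrays[0])
    for i, g in enumerate(names[1:]):
        out.append(
            TestResult(
                name=f"Dunnett[{test_name}]",
                statistic=float(dun.statistic[i]),
                pvalue=float(dun.pvalue[i]),
                reference=reference,
                groups=(reference, g),
            )
        )
    return out


def compare_burdens(
    burden: pd.DataFrame,
    grouping: str,
    reference: str,
    value: str = "normalized",
) -> list[TestResult]:
    """ANOVA + Dunnett on per-cell burdens grouped by sample or locus class."""
    if grouping not in ("sample", "locus_class"):
        raise ValueError("grouping must be 'sample' or 'locus_class'")
    if grouping == "sample":
        df = per_cell_totals(burden) if value == "count" else burden
        vals = {
            g: sub.groupby("cell")[value].sum().to_numpy()
            for g, sub in df.groupby("sample")
        }
    else:
        vals = {
            g: sub[value].to_numpy() for g, sub in burden.groupby("locus_class")
        }
    return compare_groups(vals, reference, test_name=f"burden:{value}")


def compare_hf_distributions(
    somatic_sets,
    grouping: str,
    reference: str,
    locus_map: LocusMap | None = None,
) -> list[TestResult]:
    """ANOVA + Dunnett on pooled variant HFs grouped by sample or locus class.

    Each somatic variant contributes one HF observation to its group; cells
    without variants contribute nothing (an HF requires a variant).
    """
    if grouping not in ("sample", "locus_class"):
        raise ValueError("grouping must be 'sample' or 'locus_class'")
    vals: dict[str, list[float]] = {}
    if grouping == "sample":
        for sset in _iter_sets(somatic_sets):
            vals.setdefault(sset.sample, []).extend(v.hf for v in sset.variants)
    else:
        locus_map = locus_map or LocusMap.default()
        for sset in _iter_sets(somatic_sets):
            for v in sset.variants:
                cls, _ = locus_map.locus_of(v.position)
                vals.setdefault(cls, []).append(v.hf)
    return compare_groups(vals, reference, test_name="hf")


def mann_whitney(x, y, names: tuple[str, str] = ("x", "y")) -> TestResult:
    """Two-sided Mann-Whitney U test between two groups."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        name="MannWhitneyU", statistic=float(u), pvalue=float(p), groups=names
    )


@dataclass(frozen=True)
class ScoreShape:
    """Distribution-shape summary of a pathogenicity score sample.

    Both kurtosis conventions are reported explicitly: ``kurtosis_excess``
    (Fisher; normal = 0) and ``kurtosis_pearson`` (normal = 3).  Shape
    statistics are ``None`` for degenerate input (fewer than ``min_n``
    scores, or zero variance).
    """

    n: int
    kurtosis_excess: float | None
    kurtosis_pearson: float | None
    shapiro_statistic: float | None
    shapiro_pvalue: float | None
    n_pathogenic: int
    pathogenic_fraction: float
    threshold: float


def score_shape(scores, threshold: float, min_n: int = 8) -> ScoreShape:
    """Kurtosis, Shapiro-Wilk normality, and strict-threshold pathogenic counts."""
    s = np.asarray(list(scores), dtype=float)
    n = s.size
    n_path = int((s > threshold).sum())
    frac = n_path / n if n else float("nan")
    if n < min_n or np.ptp(s) == 0.0:
        return ScoreShape(n, None, None, None, None, n_path, frac, threshold)
    k_excess = float(sps.kurtosis(s, fisher=True, bias=True))
    w, p = sps.shapiro(s)
    return ScoreShape(
        n=n,
        kurtosis_excess=k_excess,
        kurtosis_pearson=k_excess + 3.0,
        shapiro_statistic=float(w),
        shapiro_pvalue=float(p),
        n_pathogenic=n_path,
        pathogenic_fraction=frac,
        threshold=threshold,
    )


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "test": r.name,
                "statistic": r.statistic,
                "pvalue": r.pvalue,
                "reference": r.reference,
                "groups": "|".join(map(str, r.groups)),
                "note": r.note,
            }
            for r in results
        ]
    )
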