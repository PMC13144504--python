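"""Clonal diversity and biopsy-representativeness statistics.

All metrics operate on :class:`~clonosim.profiles.CloneProfile` objects and
treat "detected" as present with nonzero frequency after upstream QC.
Frequencies p_i refer to a profile's relative read (or cell) masses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .profiles import CloneProfile

__all__ = [
    "StatsConfig",
    "RepresentativenessResult",
    "GroupComparisonResult",
    "shannon_index",
    "pct_barcodes_detected",
    "biomass_captured",
    "dominant_clones",
    "partition_center_periphery",
    "sample_tumor_correlation",
    "representativeness",
    "group_comparison",
]


@dataclass(frozen=True)
class StatsConfig:
    """Thresholds and method switches for the statistics layer.

    ``dominance_threshold`` is the strict frequency cutoff for a dominant
    clone (a clone is dominant iff p > threshold); ``shannon_base`` selects
    the logarithm base of the diversity index (None = natural log, nats);
    ``correlation_mode`` chooses whether profile correlations run over the
    union of barcode sets (absent = 0) or their intersection.
    """

    dominance_threshold: float = 0.01
    shannon_base: float | None = None
    correlation_mode: str = "union"

    def __post_init__(self):
        if not 0 < self.dominance_threshold < 1:
            raise ValueError("dominance_threshold must be in (0, 1)")
        if self.correlation_mode not in ("union", "intersection"):
            raise ValueError("correlation_mode must be 'union' or 'intersection'")


def shannon_index(p: CloneProfile, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over present barcodes.

    Reflects both richness and evenness: H = log(n) for a uniform profile
    of n clones, 0 for a single clone.  Natural log (nats) by default;
    empty profiles return 0 by convention.
    """
    freqs = np.array(list(p.frequencies.values()))
    if len(freqs) == 0:
        return 0.0
    h = float(-(freqs * np.log(freqs)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def pct_barcodes_detected(sample: CloneProfile, tumor: CloneProfile) -> float:
    """Percentage of the tumor's barcodes detected in the sample."""
    if not tumor:
        raise ValueError("tumor profile is empty")
    return 100.0 * len(sample.barcodes & tumor.barcodes) / len(tumor.barcodes)


def biomass_captured(
    samples: CloneProfile | list[CloneProfile], tumor: CloneProfile
) -> float:
    """Percentage of tumor read mass covered by barcodes detected in the
    union of the given biopsies.

    A single biopsy may be passed directly; a list models biopsy
    combinations (e.g. a deep needle plus a terminal plasma draw), whose
    captured biomass is monotone non-decreasing under union.
    """
    if not tumor:
        raise ValueError("tumor profile is empty")
    if isinstance(samples, CloneProfile):
        samples = [samples]
    detected: set[int] = set()
    for s in samples:
        detected |= s.barcodes
    freqs = tumor.frequencies
    return 100.0 * sum(freqs[b] for b in detected & tumor.barcodes)


def dominant_clones(
    tumor: CloneProfile, cfg: StatsConfig | None = None
) -> frozenset[int]:
    """Barcodes with frequency strictly greater than the dominance cutoff."""
    cfg = cfg or StatsConfig()
    return frozenset(
        b for b, f in tumor.frequencies.items() if f > cfg.dominance_threshold
    )


def partition_center_periphery(
    center: CloneProfile, periphery: list[CloneProfile]
) -> tuple[float, float, float]:
    """Classify every barcode as periphery-only, center-only, or shared.

    Returns percentages of the union (periphery_only, center_only, both),
    summing to 100.
    """
    if not periphery:
        raise ValueError("at least one periphery piece is required")
    peri: set[int] = set()
    for p in periphery:
        peri |= p.barcodes
    cent = set(center.barcodes)
    union = peri | cent
    if not union:
        raise ValueError("no barcodes in center or periphery")
    n = len(union)
    both = len(peri & cent)
    return (
        100.0 * (len(peri) - both) / n,
        100.0 * (len(cent) - both) / n,
        100.0 * both / n,
    )


def sample_tumor_correlation(
    sample: CloneProfile,
    tumor: CloneProfile,
    cfg: StatsConfig | None = None,
) -> float:
    """Pearson r between sample and tumor barcode frequencies.

    Computed over the union of barcode sets by default (a barcode absent
    from one profile contributes frequency 0 there); intersection mode is
    available via :class:`StatsConfig`.  Degenerate inputs (fewer than two
    barcodes, or zero variance) yield NaN with a warning rather than a
    silent 0.
    """
    cfg = cfg or StatsConfig()
    if cfg.correlation_mode == "union":
        barcodes = sorted(sample.barcodes | tumor.barcodes)
    else:
        barcodes = sorted(sample.barcodes & tumor.barcodes)
    if len(barcodes) < 2:
        warnings.warn("fewer than 2 barcodes in scope; correlation undefined")
        return float("nan")
    x = np.array([sample.frequency(b) for b in barcodes])
    y = np.array([tumor.frequency(b) for b in barcodes])
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in frequencies; correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class RepresentativenessResult:
    """How well one biopsy (or combination) reflects the whole tumor."""

    pct_barcodes_detected: float
    pct_biomass_captured: float
    detected: frozenset[int]
    missed_dominant: frozenset[int]
    pearson_r: float


def representativeness(
    samples: CloneProfile | list[CloneProfile],
    tumor: CloneProfile,
    cfg: StatsConfig | None = None,
) -> RepresentativenessResult:
    """Bundle the representativeness metrics for one biopsy/combination."""
    cfg = cfg or StatsConfig()
    if isinstance(samples, CloneProfile):
        sample_list = [samples]
    else:
        sample_list = list(samples)
    detected: set[int] = set()
    for s in sample_list:
        detected |= s.barcodes
    detected &= tumor.barcodes
    dom = dominant_clones(tumor, cfg)
    merged = CloneProfile(
        "+".join(s.label for s in sample_list),
        {
            b: sum(s.counts.get(b, 0.0) for s in sample_list)
            for b in set().union(*(s.barcodes for s in sample_list))
        }
        if sample_list and any(sample_list)
        else {},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = sample_tumor_correlation(merged, tumor, cfg)
    return RepresentativenessResult(
        pct_barcodes_detected=100.0 * len(detected) / len(tumor.barcodes),
        pct_biomass_captured=biomass_captured(sample_list, tumor),
        detected=frozenset(detected),
        missed_dominant=frozenset(dom - detected),
        pearson_r=r,
    )


@dataclass
class GroupComparisonResult:
    """Two-group t test or one-way ANOVA with Tukey-adjusted pairs.

    ``determined`` is False when any group has fewer than 3 observations,
    in which case p-values are reported as NaN (not determined).
    """

    method: str
    p_value: float
    statistic: float
    pairwise: pd.DataFrame | None = None
    determined: bool = True
    group_sizes: dict[str, int] = field(default_factory=dict)


def group_comparison(
    values, labels, cfg: StatsConfig | None = None
) -> GroupComparisonResult:
    """Compare a numeric outcome across groups.

    Two groups: unpaired two-sided Student's t test.  More than two:
    one-way ANOVA followed by Tukey's multiple-comparisons test.  Any
    group with n < 3 renders the result not determined (p-values NaN),
    matching the reporting convention for underpowered comparisons.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must align")
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("at least two groups are required")
    groups = {g: values[labels == g] for g in names}
    sizes = {str(g): int(len(v)) for g, v in groups.items()}
    if min(sizes.values()) < 2:
        raise ValueError("every group needs at least two observations")
    determined = min(sizes.values()) >= 3

    if len(names) == 2:
        t, p = sps.ttest_ind(groups[names[0]], groups[names[1]])
        return GroupComparisonResult(
            method="unpaired_t",
            p_value=float(p) if determined else float("nan"),
            statistic=float(t),
            determined=determined,
            group_sizes=sizes,
        )

    f, p = sps.f_oneway(*groups.values())
    tukey = pairwise_tukeyhsd(values, labels)
    pairs = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    if not determined:
        pairs["p-adj"] = float("nan")
    return GroupComparisonResult(
        method="anova_tukey",
        p_value=float(p) if determined else float("nan"),
        statistic=float(f),
        pairwise=pairs,
        determined=determined,
        group_sizes=sizes,
    )
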