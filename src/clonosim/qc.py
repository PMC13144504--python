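"""Quality-control filter chain for barcode count matrices.

The chain runs in a fixed order, mirroring how replicate PCR barcode data
are cleaned before any frequency analysis:

1. :func:`zero_low_counts` — per-sample counts at or below a floor
   (default 10 reads) are set to zero;
2. :func:`drop_low_depth_samples` — samples with fewer than 10,000 total
   reads are excluded;
3. :func:`drop_discordant_replicates` — replicates whose Pearson
   correlation with the rest of their replicate group falls below 0.6 are
   removed (cfDNA groups exempt: low-input plasma replicates are expected
   to disagree);
4. :func:`drop_sporadic_barcodes` — within each replicate group, barcodes
   seen in fewer than two replicates are discarded;
5. :func:`pool_and_normalize` — replicates are pooled by summation and
   converted to frequencies.

Whole-tumor profiles are then rebuilt from dissection pieces
(:func:`reconstruct_whole_tumor`) and all other specimens restricted to
the tumor's barcode set (:func:`restrict_to_tumor_barcodes`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon import CountMatrix
from .profiles import CloneProfile

__all__ = [
    "FilterConfig",
    "FilterReport",
    "zero_low_counts",
    "drop_low_depth_samples",
    "drop_discordant_replicates",
    "drop_sporadic_barcodes",
    "pool_and_normalize",
    "reconstruct_whole_tumor",
    "restrict_to_tumor_barcodes",
    "run_filter_chain",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the QC chain.

    ``low_count_zero_threshold`` zeroes counts <= its value;
    ``min_sample_reads`` drops samples strictly below it;
    ``min_replicate_pearson`` removes replicates strictly below it (classes
    in ``corr_exempt_classes`` are exempt); ``min_replicates_detected`` is
    the minimum number of replicates a barcode must appear in.
    ``correlation_scale`` selects the scale on which replicate concordance
    is computed ("raw" counts or "log1p").
    """

    low_count_zero_threshold: int = 10
    min_sample_reads: int = 10_000
    min_replicate_pearson: float = 0.6
    corr_exempt_classes: frozenset[str] = frozenset({"cfDNA"})
    min_replicates_detected: int = 2
    correlation_scale: str = "raw"

    def __post_init__(self):
        if self.low_count_zero_threshold < 0 or self.min_sample_reads < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 <= self.min_replicate_pearson <= 1:
            raise ValueError("min_replicate_pearson must be in [0, 1]")
        if self.min_replicates_detected < 0:
            raise ValueError("min_replicates_detected must be >= 0")
        if self.correlation_scale not in ("raw", "log1p"):
            raise ValueError("correlation_scale must be 'raw' or 'log1p'")


@dataclass
class FilterReport:
    """Ordered log of filter steps with read-mass accounting."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, **tallies) -> None:
        self.steps.append({"step": step, **tallies})

    def extend(self, other: "FilterReport") -> None:
        self.steps.extend(other.steps)

    @property
    def total_mass_removed(self) -> float:
        return float(sum(s.get("reads_removed", 0) for s in self.steps))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.steps, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def zero_low_counts(m: CountMatrix, cfg: FilterConfig | None = None) -> CountMatrix:
    """Set counts <= the low-count floor to zero (idempotent)."""
    cfg = cfg or FilterConfig()
    counts = m.counts.where(m.counts > cfg.low_count_zero_threshold, 0)
    return m.with_counts(counts)


def drop_low_depth_samples(
    m: CountMatrix, cfg: FilterConfig | None = None
) -> tuple[CountMatrix, FilterReport]:
    """Exclude samples whose total reads fall strictly below the minimum."""
    cfg = cfg or FilterConfig()
    report = FilterReport()
    totals = m.counts.sum(axis=0)
    dropped = totals[totals < cfg.min_sample_reads]
    for sample, total in dropped.items():
        report.add(
            "drop_low_depth_sample",
            sample=sample,
            total_reads=int(total),
            reads_removed=int(total),
            reason=f"total reads {int(total)} < {cfg.min_sample_reads}",
        )
    kept = [s for s in m.counts.columns if s not in set(dropped.index)]
    return m.with_counts(m.counts[kept]), report


def _replicate_correlations(
    counts: pd.DataFrame, members: list[str], scale: str
) -> dict[str, float]:
    """Mean pairwise Pearson r per replicate, on the union of barcodes
    nonzero in at least one member of each pair."""
    r_sums = {s: [] for s in members}
    for i, a in enumerate(members):
        for b_ in members[i + 1 :]:
            pair = counts[[a, b_]]
            pair = pair[(pair > 0).any(axis=1)]
            if scale == "log1p":
                pair = np.log1p(pair)
            if len(pair) < 2:
                r = np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # constant columns -> nan
                    r = float(np.corrcoef(pair[a], pair[b_])[0, 1])
            r_sums[a].append(r)
            r_sums[b_].append(r)
    return {s: float(np.mean(v)) if v else np.nan for s, v in r_sums.items()}


def drop_discordant_replicates(
    m: CountMatrix, cfg: FilterConfig | None = None
) -> tuple[CountMatrix, FilterReport]:
    """Remove replicates with Pearson r strictly below the threshold.

    cfDNA-class groups are exempt (kept, flagged in the report).  A
    replicate with undefined correlation (constant vectors, <2 shared
    barcodes) is treated as discordant.  Non-exempt groups of size 1
    cannot be checked: warned about and kept.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    to_drop: list[str] = []
    for group, members in m.replicate_groups().items():
        sample_class = m.samples.sample_class(members[0])
        if sample_class in cfg.corr_exempt_classes:
            rs = (
                _replicate_correlations(m.counts, members, cfg.correlation_scale)
                if len(members) > 1
                else {}
            )
            report.add(
                "replicate_concordance_exempt",
                replicate_group=group,
                sample_class=sample_class,
                correlations={s: r for s, r in rs.items()},
            )
            continue
        if len(members) == 1:
            warnings.warn(
                f"replicate group {group!r} has a single replicate; "
                "concordance not assessable, kept"
            )
            report.add("replicate_singleton_kept", replicate_group=group)
            continue
        rs = _replicate_correlations(m.counts, members, cfg.correlation_scale)
        for s, r in rs.items():
            if np.isnan(r) or r < cfg.min_replicate_pearson:
                to_drop.append(s)
                report.add(
                    "drop_discordant_replicate",
                    replicate_group=group,
                    sample=s,
                    pearson_r=None if np.isnan(r) else r,
                    reads_removed=int(m.counts[s].sum()),
                )
    kept = [s for s in m.counts.columns if s not in set(to_drop)]
    return m.with_counts(m.counts[kept]), report


def drop_sporadic_barcodes(
    m: CountMatrix, cfg: FilterConfig | None = None
) -> tuple[CountMatrix, FilterReport]:
    """Zero barcodes present in fewer replicates than required, per group.

    "Present" means count > 0 (after the earlier zeroing step).  Groups
    smaller than the requirement are judged on the replicates they have:
    with the default requirement of 2, a barcode seen in the single
    replicate of a singleton group is discarded, as written.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    counts = m.counts.copy()
    for group, members in m.replicate_groups().items():
        sub = counts[members]
        present_in = (sub > 0).sum(axis=1)
        sporadic = (present_in > 0) & (present_in < cfg.min_replicates_detected)
        if sporadic.any():
            removed_mass = int(sub.loc[sporadic].values.sum())
            counts.loc[sporadic, members] = 0
            report.add(
                "drop_sporadic_barcodes",
                replicate_group=group,
                barcodes_discarded=int(sporadic.sum()),
                reads_removed=removed_mass,
            )
    return m.with_counts(counts), report


def pool_and_normalize(m: CountMatrix) -> list[CloneProfile]:
    """Pool replicates by summation and normalize to frequencies.

    One profile per replicate group, labeled with the group name and
    carrying pooled counts; groups whose pooled total is zero yield an
    empty profile.
    """
    profiles = []
    for group, members in m.replicate_groups().items():
        pooled = m.counts[members].sum(axis=1)
        pooled = pooled[pooled > 0]
        meta = dict(m.samples.frame.loc[members[0]])
        meta.pop("sample_id", None)
        meta.pop("index", None)
        meta["n_replicates_pooled"] = len(members)
        profiles.append(CloneProfile(group, pooled.to_dict(), meta=meta))
    return profiles


def reconstruct_whole_tumor(
    pieces: list[CloneProfile], label: str = "tumor"
) -> CloneProfile:
    """Sum pooled piece counts per barcode and renormalize.

    Rebuilds the whole-tumor clone profile from its dissection pieces.
    """
    if not pieces:
        raise ValueError("at least one piece profile is required")
    counts: dict[int, float] = {}
    for piece in pieces:
        for b, c in piece.counts.items():
            counts[b] = counts.get(b, 0.0) + c
    return CloneProfile(label, counts, meta={"n_pieces": len(pieces)})


def restrict_to_tumor_barcodes(
    samples: list[CloneProfile], tumor: CloneProfile
) -> list[CloneProfile]:
    """Keep only tumor barcodes in each sample profile; log removed mass.

    Renormalization is implicit: frequencies are always computed over the
    retained counts.
    """
    if not tumor:
        warnings.warn("tumor profile is empty; all sample profiles emptied")
    out = []
    for s in samples:
        kept = s.restricted_to(tumor.barcodes)
        removed = s.total - kept.total
        kept.meta["mass_outside_tumor"] = removed
        out.append(kept)
    return out


def run_filter_chain(
    m: CountMatrix, cfg: FilterConfig | None = None
) -> tuple[CountMatrix, FilterReport]:
    """Apply the full chain in its fixed order with mass accounting."""
    cfg = cfg or FilterConfig()
    report = FilterReport()
    input_mass = m.total_reads

    zeroed = zero_low_counts(m, cfg)
    report.add(
        "zero_low_counts",
        threshold=cfg.low_count_zero_threshold,
        cells_zeroed=int(((m.counts > 0) & (zeroed.counts == 0)).values.sum()),
        reads_removed=int(input_mass - zeroed.total_reads),
    )
    deep, rep = drop_low_depth_samples(zeroed, cfg)
    report.extend(rep)
    concordant, rep = drop_discordant_replicates(deep, cfg)
    report.extend(rep)
    final, rep = drop_sporadic_barcodes(concordant, cfg)
    report.extend(rep)
    report.add(
        "mass_accounting",
        input_reads=int(input_mass),
        output_reads=int(final.total_reads),
        reads_removed_total=report.total_mass_removed,
    )
    return final, report
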