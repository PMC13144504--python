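"""Virtual biopsy sampling of a simulated tumor.

Three samplers, each yielding a :class:`~clonosim.profiles.CloneProfile`:

* :func:`dissect` — cut the tumor into axis-aligned pieces (five-piece
  in-silico plan: four peripheral slabs plus a central box; seven-piece
  plan adds the superior/inferior slabs, leaving a central cube);
* :func:`needle_biopsy` — a cylindrical core from the surface toward the
  centroid, at a configurable fraction of the tumor diameter (deep cores
  reach the center at depth 0.5, shallow cores cover a quarter diameter);
* :func:`sample_cfdna` — a sparse weighted draw of DNA fragments from the
  clone census, modeling plasma cell-free DNA whose detection improves
  with tumor burden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PartitionError
from .profiles import CloneProfile
from .simulate import CloneCensus, TumorState

__all__ = [
    "DissectionPlan",
    "NeedleSpec",
    "ShedModel",
    "dissect",
    "needle_biopsy",
    "canonical_needles",
    "sample_cfdna",
    "shed_weights_from_geometry",
]


# ---------------------------------------------------------------------------
# dissection


@dataclass(frozen=True)
class DissectionPlan:
    """Axis-aligned dissection into peripheral slabs plus a central piece.

    ``cut_fraction`` is the thickness of each peripheral slab as a fraction
    of the whole-tumor bounding box along its axis.  The five-piece plan
    cuts two slabs on x and two on y (labels A-D) leaving the central box E;
    the seven-piece plan additionally cuts the two z slabs, leaving the
    central cube as piece 7 — mirroring a dissection that removes
    transversal, lateral, then superior/inferior edges to expose the
    center.
    """

    style: str = "five"  # "five" or "seven"
    cut_fraction: float = 0.25

    def __post_init__(self):
        if self.style not in ("five", "seven"):
            raise ValueError(f"unknown dissection style {self.style!r}")
        if not 0 < self.cut_fraction < 0.5:
            raise ValueError("cut_fraction must be in (0, 0.5)")

    @property
    def labels(self) -> list[str]:
        if self.style == "five":
            return ["A", "B", "C", "D", "E"]
        return ["1", "2", "3", "4", "5", "6", "7"]

    @property
    def center_label(self) -> str:
        return self.labels[-1]


def dissect(state: TumorState, plan: DissectionPlan | None = None) -> list[CloneProfile]:
    """Partition all tumor cells into dissection pieces.

    Every occupied site is assigned to exactly one piece (slabs claim cells
    in cut order; the central piece takes the remainder), so concatenating
    the piece tallies reproduces the whole-tumor census exactly.
    """
    if plan is None:
        plan = DissectionPlan()
    if state.population_size == 0:
        raise PartitionError("cannot dissect an empty tumor")
    xyz = state.coords()
    barcodes = state.barcodes()
    n = len(barcodes)

    lo = xyz.min(axis=0).astype(float)
    hi = xyz.max(axis=0).astype(float)
    span = hi - lo + 1.0
    f = plan.cut_fraction
    axes = (0, 1) if plan.style == "five" else (0, 1, 2)

    assignment = np.full(n, -1, dtype=np.int64)
    piece = 0
    for ax in axes:
        low_cut = lo[ax] + f * span[ax]
        high_cut = hi[ax] + 1.0 - f * span[ax]
        free = assignment < 0
        assignment[free & (xyz[:, ax] < low_cut)] = piece
        piece += 1
        free = assignment < 0
        assignment[free & (xyz[:, ax] >= high_cut)] = piece
        piece += 1
    assignment[assignment < 0] = piece  # central piece

    labels = plan.labels
    if piece != len(labels) - 1:  # pragma: no cover - internal consistency
        raise PartitionError("piece count mismatch")
    profiles = []
    for p, label in enumerate(labels):
        mask = assignment == p
        tally = np.bincount(barcodes[mask]) if mask.any() else np.array([0])
        counts = {int(b): int(c) for b, c in enumerate(tally) if c > 0}
        profiles.append(
            CloneProfile(
                label,
                counts,
                meta={
                    "piece": label,
                    "center": label == plan.center_label,
                    "n_cells": int(mask.sum()),
                },
            )
        )
    if sum(p.meta["n_cells"] for p in profiles) != n:  # pragma: no cover
        raise PartitionError("dissection did not cover all cells")
    return profiles


# ---------------------------------------------------------------------------
# needle biopsies


@dataclass(frozen=True)
class NeedleSpec:
    """Geometry of one cylindrical core biopsy.

    ``direction`` points into the tumor; the entry point defaults to the
    tumor surface along that axis through the centroid.  ``depth_fraction``
    is the penetration depth as a fraction of the tumor diameter measured
    along the needle direction: 0.5 reaches the center (deep, "needle-a"),
    0.25 covers a quarter of the diameter (shallow, "needle-b").
    """

    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    depth_fraction: float = 0.5
    radius: float = 2.0
    entry: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not 0 < self.depth_fraction <= 1:
            raise ValueError("depth_fraction must be in (0, 1]")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if all(abs(c) < 1e-12 for c in self.direction):
            raise ValueError("direction must be a nonzero vector")


def canonical_needles(
    depth_fraction: float = 0.5, radius: float = 2.0
) -> list[NeedleSpec]:
    """The four planar needles (+x, -x, +y, -y) aimed at the tumor center."""
    dirs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)]
    return [
        NeedleSpec(direction=d, depth_fraction=depth_fraction, radius=radius)
        for d in dirs
    ]


def needle_biopsy(state: TumorState, spec: NeedleSpec) -> CloneProfile:
    """Cells inside the needle cylinder; an empty core is a valid result."""
    label = f"needle_{'a' if spec.depth_fraction >= 0.5 else 'b'}"
    if state.population_size == 0:
        return CloneProfile(label, {}, meta={"n_cells": 0})
    xyz = state.coords().astype(float)
    barcodes = state.barcodes()
    u = np.asarray(spec.direction, dtype=float)
    u = u / np.linalg.norm(u)
    centroid = xyz.mean(axis=0)

    proj = (xyz - centroid) @ u  # signed chord coordinate through centroid
    diameter = proj.max() - proj.min() + 1.0
    if spec.entry is not None:
        entry = np.asarray(spec.entry, dtype=float)
    else:
        entry = centroid + proj.min() * u
    t = (xyz - entry) @ u
    depth = spec.depth_fraction * diameter
    perp = xyz - entry - np.outer(t, u)
    dist = np.linalg.norm(perp, axis=1)
    mask = (t >= 0) & (t <= depth) & (dist <= spec.radius)

    tally = np.bincount(barcodes[mask]) if mask.any() else np.array([0])
    counts = {int(b): int(c) for b, c in enumerate(tally) if c > 0}
    return CloneProfile(
        label,
        counts,
        meta={
            "n_cells": int(mask.sum()),
            "depth_fraction": spec.depth_fraction,
            "direction": tuple(float(c) for c in spec.direction),
        },
    )


# ---------------------------------------------------------------------------
# plasma (cfDNA) draws


@dataclass(frozen=True)
class ShedModel:
    """Weighted-fragment model of DNA shedding into plasma.

    Each clone sheds fragments proportionally to its cell count times a
    per-clone shed weight (uniform by default; see
    :func:`shed_weights_from_geometry` for a necrotic-core boost).
    ``fragments`` is the total draw size F; sparse draws model low-input
    plasma, and detection then follows the quintuplicate PCR rule: the F
    fragments are split into 5 pseudo-replicates, per-replicate counts at
    or below ``low_count_zero_threshold`` are zeroed, and a clone is
    detected only if it remains nonzero in at least
    ``min_replicates_detected`` pseudo-replicates.
    """

    fragments: int = 1000
    base_weight: float = 1.0
    clone_weights: dict[int, float] | None = None
    n_pseudo_replicates: int = 5
    low_count_zero_threshold: int = 10
    min_replicates_detected: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if self.fragments < 0:
            raise ValueError("fragments must be >= 0")
        if self.base_weight < 0:
            raise ValueError("weights must be >= 0")

    @staticmethod
    def burden_scaled(
        population_size: int, k: float = 1e-4, **kwargs
    ) -> "ShedModel":
        """Draw size proportional to tumor burden: F = round(k * N)."""
        return ShedModel(fragments=int(round(k * population_size)), **kwargs)


def shed_weights_from_geometry(
    state: TumorState, core_fraction: float = 0.5, boost: float = 5.0
) -> dict[int, float]:
    """Per-clone shed weights with a necrotic-core boost.

    Cells within ``core_fraction`` of the tumor radius from the centroid
    shed ``boost`` times more; a clone's weight is the cell-weighted
    average, modeling necrotic centers that leak more DNA.
    """
    xyz = state.coords().astype(float)
    barcodes = state.barcodes()
    centroid = xyz.mean(axis=0)
    r = np.linalg.norm(xyz - centroid, axis=1)
    R = r.max() if len(r) else 0.0
    in_core = r < core_fraction * R
    weights: dict[int, float] = {}
    for b in np.unique(barcodes):
        mask = barcodes == b
        frac = in_core[mask].mean()
        weights[int(b)] = (1.0 - frac) + boost * frac
    return weights


def sample_cfdna(
    census: CloneCensus, model: ShedModel
) -> CloneProfile:
    """Draw F fragments from the census and apply the detection rule.

    Returns a profile over the *detected* clones only (pooled fragment
    counts); an unsuccessful recovery yields an empty profile.  With
    uniform shed weights the fragment draw is an unbiased multinomial
    sample of the census.
    """
    label = "cfDNA"
    ids = sorted(census.counts)
    if not ids or model.fragments == 0:
        return CloneProfile(label, {}, meta={"fragments": int(model.fragments)})
    rng = np.random.default_rng(model.rng_seed)
    w = np.array(
        [
            census.counts[b]
            * model.base_weight
            * (model.clone_weights.get(b, 1.0) if model.clone_weights else 1.0)
            for b in ids
        ],
        dtype=float,
    )
    if w.sum() == 0:
        return CloneProfile(label, {}, meta={"fragments": int(model.fragments)})
    p = w / w.sum()
    frags = rng.multinomial(model.fragments, p)
    # split each clone's fragments uniformly into pseudo-replicates
    k = model.n_pseudo_replicates
    reps = np.vstack(
        [rng.multinomial(c, np.full(k, 1.0 / k)) for c in frags]
    )  # (n_clones, k)
    reps[reps <= model.low_count_zero_threshold] = 0
    detected = (reps > 0).sum(axis=1) >= model.min_replicates_detected
    pooled = reps.sum(axis=1)
    counts = {
        b: int(pooled[i]) for i, b in enumerate(ids) if detected[i] and pooled[i] > 0
    }
    return CloneProfile(
        label,
        counts,
        meta={
            "fragments": int(model.fragments),
            "raw_fragments": {b: int(c) for b, c in zip(ids, frags) if c > 0},
            "detected": bool(counts),
        },
    )
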