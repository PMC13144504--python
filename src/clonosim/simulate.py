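"""Stochastic 3D lattice simulation of barcoded tumor growth.

The model is an agent-based kinetic Monte Carlo simulation on a cubic
lattice.  Every cell carries a heritable integer barcode identifying its
founder; daughters inherit the parent's barcode, so the set of barcodes in
a grown tumor is a subset of the founders'.  Three per-cell rates drive the
dynamics:

* birth rate ``b`` — the cell divides, placing a daughter in a uniformly
  chosen empty neighbor site (no empty neighbor: the division attempt is
  suppressed, making growth surface-limited);
* death rate ``d`` — the cell is removed and its site becomes reusable;
* mobility ``M`` — the cell hops to a uniformly chosen empty neighbor.

Because all cells share the same total rate ``b + d + M``, the standard
rate-weighted cell selection of kinetic Monte Carlo reduces to a uniform
draw over living cells followed by an event-type draw proportional to
``b : d : M``.  The inner loop is compiled with numba; identical
``(params, seed)`` pairs reproduce identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .errors import CapacityError, NoGrowthError
from .profiles import CloneProfile

__all__ = [
    "SimParams",
    "TumorState",
    "CloneCensus",
    "initialize_tumor",
    "grow_to",
    "clone_census",
]


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    Rates are events per cell per unit time (arbitrary units; only the
    ratios b:d:M matter for the embedded jump chain).  The default rates are
    placeholders in the spirit of lattice tumor-growth models of this
    family and are not calibrated to any particular tissue; override them
    freely.  ``lattice_extent=None`` auto-sizes the lattice to comfortably
    hold ``target_size`` cells.
    """

    birth_rate: float = 0.69
    death_rate: float = 0.1
    mobility: float = 0.05
    lattice_extent: int | None = None
    neighborhood: str = "moore"  # "moore" (26) or "von_neumann" (6)
    target_size: int = 200_000
    rng_seed: int = 0

    def __post_init__(self):
        if self.birth_rate < 0 or self.death_rate < 0 or self.mobility < 0:
            raise ValueError("rates must be nonnegative")
        if self.birth_rate + self.death_rate + self.mobility <= 0:
            raise ValueError("total event rate must be positive")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")

    def resolved_extent(self) -> int:
        """Lattice side length, derived from target_size when unset."""
        if self.lattice_extent is not None:
            if self.lattice_extent ** 3 <= self.target_size:
                raise CapacityError(
                    f"lattice_extent {self.lattice_extent} holds at most "
                    f"{self.lattice_extent ** 3} cells < target {self.target_size}"
                )
            return int(self.lattice_extent)
        # ball radius for target_size cells, with generous margin for
        # surface roughness and drift
        r = (3.0 * self.target_size / (4.0 * math.pi)) ** (1.0 / 3.0)
        return int(math.ceil(2.0 * r * 1.6)) + 8

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimParams":
        """Build from a config mapping (YAML-friendly key names)."""
        keys = {
            "birth_rate": "birth_rate",
            "death_rate": "death_rate",
            "mobility": "mobility",
            "neighborhood": "neighborhood",
            "lattice_extent": "lattice_extent",
            "target_size": "target_size",
            "seed": "rng_seed",
            "rng_seed": "rng_seed",
        }
        kwargs = {keys[k]: v for k, v in cfg.items() if k in keys}
        return cls(**kwargs)


def _neighbor_offsets(neighborhood: str) -> np.ndarray:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                if neighborhood == "von_neumann" and abs(dx) + abs(dy) + abs(dz) != 1:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs, dtype=np.int64)


@dataclass
class TumorState:
    """Lattice state of a growing tumor.

    ``occupancy`` is a flat int32 array of length ``extent**3`` holding 0
    for empty sites and the founder barcode ID (>=1) for occupied ones.
    ``cells`` lists the flat indices of the first ``population_size``
    occupied sites; ``site_slot`` maps a flat site index back to its
    position in ``cells`` (enables O(1) removal).
    """

    extent: int
    occupancy: np.ndarray
    cells: np.ndarray
    site_slot: np.ndarray
    population_size: int
    n_founders: int
    elapsed_events: int = 0

    @property
    def is_extinct(self) -> bool:
        return self.population_size == 0

    def coords(self) -> np.ndarray:
        """(n, 3) integer coordinates of living cells."""
        s = self.cells[: self.population_size]
        L = self.extent
        x = s // (L * L)
        rem = s % (L * L)
        return np.stack([x, rem // L, rem % L], axis=1)

    def barcodes(self) -> np.ndarray:
        """Barcode ID per living cell, aligned with :meth:`coords`."""
        return self.occupancy[self.cells[: self.population_size]].astype(np.int64)

    def copy(self) -> "TumorState":
        return TumorState(
            self.extent,
            self.occupancy.copy(),
            self.cells.copy(),
            self.site_slot.copy(),
            self.population_size,
            self.n_founders,
            self.elapsed_events,
        )

    def validate(self) -> None:
        """Cross-check list bookkeeping against a full lattice scan."""
        assert int((self.occupancy > 0).sum()) == self.population_size
        b = self.barcodes()
        assert b.min(initial=1) >= 1 and b.max(initial=1) <= self.n_founders
        assert len(np.unique(self.cells[: self.population_size])) == self.population_size

    def to_cell_table(self) -> pd.DataFrame:
        """Per-cell (x, y, z, barcode_id) table for external 3D rendering."""
        xyz = self.coords()
        return pd.DataFrame(
            {
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
                "barcode_id": self.barcodes(),
            }
        )

    def write_cells_tsv(self, path: str | Path) -> None:
        self.to_cell_table().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CloneCensus:
    """Exact tally of living cells per founder barcode."""

    counts: dict[int, int]

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n_clones(self) -> int:
        return len(self.counts)

    def to_profile(self, label: str = "tumor") -> CloneProfile:
        return CloneProfile(label, self.counts)

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.counts.items()), columns=["barcode_id", "cell_count"]
        )
        df.to_csv(path, sep="\t", index=False)


def initialize_tumor(n_founders: int, params: SimParams) -> TumorState:
    """Seed ``n_founders`` barcoded cells as a compact centered ball.

    Founders occupy the ``n_founders`` lattice sites closest to the lattice
    midpoint (ties broken lexicographically), with barcode IDs 1..n
    assigned in placement order.  Deterministic: no randomness is involved.
    """
    if n_founders < 1:
        raise ValueError(f"n_founders must be >= 1, got {n_founders}")
    if params.target_size < n_founders:
        raise ValueError("target_size must be >= n_founders")
    L = params.resolved_extent()
    c = L // 2
    # candidate cube comfortably larger than the founder ball
    r = int(math.ceil((3.0 * n_founders / (4.0 * math.pi)) ** (1.0 / 3.0))) + 2
    if c - r < 0 or c + r >= L:
        raise CapacityError(
            f"lattice extent {L} too small to seed {n_founders} founders centrally"
        )
    ax = np.arange(c - r, c + r + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    X, Y, Z = X.ravel(), Y.ravel(), Z.ravel()
    d2 = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2
    order = np.lexsort((Z, Y, X, d2))
    if n_founders > len(order):
        raise CapacityError("founder ball exceeds candidate cube")  # pragma: no cover
    chosen = order[:n_founders]

    occupancy = np.zeros(L * L * L, dtype=np.int32)
    cells = np.full(max(params.target_size, n_founders), -1, dtype=np.int64)
    site_slot = np.full(L * L * L, -1, dtype=np.int64)
    for i, j in enumerate(chosen):
        s = (X[j] * L + Y[j]) * L + Z[j]
        occupancy[s] = i + 1
        cells[i] = s
        site_slot[s] = i
    return TumorState(L, occupancy, cells, site_slot, n_founders, n_founders)


@njit(cache=True)
def _kmc(occupancy, cells, site_slot, n0, L, b, d, M, n_target, neigh, seed, max_events):
    """Kinetic Monte Carlo inner loop; returns (population, events)."""
    np.random.seed(seed)
    n = n0
    events = 0
    total = b + d + M
    nn = neigh.shape[0]
    cand = np.empty(nn, dtype=np.int64)
    L2 = L * L
    while 0 < n < n_target and events < max_events:
        events += 1
        i = np.random.randint(0, n)
        s = cells[i]
        x = s // L2
        rem = s % L2
        y = rem // L
        z = rem % L
        u = np.random.random() * total
        if u < b or u >= b + d:
            # birth or move: both need an empty neighbor site
            k = 0
            for j in range(nn):
                nx = x + neigh[j, 0]
                ny = y + neigh[j, 1]
                nz = z + neigh[j, 2]
                if 0 <= nx < L and 0 <= ny < L and 0 <= nz < L:
                    t = (nx * L + ny) * L + nz
                    if occupancy[t] == 0:
                        cand[k] = t
                        k += 1
            if k == 0:
                continue  # suppressed (surface-limited growth / blocked hop)
            t = cand[np.random.randint(0, k)]
            if u < b:
                occupancy[t] = occupancy[s]
                cells[n] = t
                site_slot[t] = n
                n += 1
            else:
                occupancy[t] = occupancy[s]
                occupancy[s] = 0
                site_slot[s] = -1
                cells[i] = t
                site_slot[t] = i
        else:
            # death: reusable empty site; swap-remove from the cell list
            occupancy[s] = 0
            site_slot[s] = -1
            last = n - 1
            ls = cells[last]
            cells[i] = ls
            site_slot[ls] = i
            cells[last] = -1
            n = last
    return n, events


def grow_to(state: TumorState, params: SimParams) -> TumorState:
    """Run the simulation until ``params.target_size`` cells (in place).

    Returns the same state object, updated.  Extinction before the target
    is a valid outcome signalled by ``state.is_extinct`` — not an
    exception.  Raises :class:`NoGrowthError` when growth is impossible
    (``b == 0 == d`` with a larger target) and :class:`CapacityError` when
    the target exceeds the lattice capacity.
    """
    n_target = params.target_size
    L = state.extent
    if n_target > L ** 3:
        raise CapacityError(f"target {n_target} exceeds lattice capacity {L ** 3}")
    if n_target <= state.population_size:
        return state
    if params.birth_rate == 0 and params.death_rate == 0:
        raise NoGrowthError("birth and death rates are both zero; target unreachable")
    if len(state.cells) < n_target:
        grown = np.full(n_target, -1, dtype=np.int64)
        grown[: state.population_size] = state.cells[: state.population_size]
        state.cells = grown
    seed = int(params.rng_seed) & 0x7FFFFFFF
    # generous event budget; the loop needs O(tens) of events per net cell
    max_events = max(10_000, 600 * n_target)
    n, events = _kmc(
        state.occupancy,
        state.cells,
        state.site_slot,
        state.population_size,
        L,
        float(params.birth_rate),
        float(params.death_rate),
        float(params.mobility),
        n_target,
        _neighbor_offsets(params.neighborhood),
        seed,
        max_events,
    )
    state.population_size = int(n)
    state.elapsed_events += int(events)
    if 0 < n < n_target:
        raise CapacityError(
            f"no progress after {events} events at population {n}; "
            "lattice likely saturated"
        )
    return state


def clone_census(state: TumorState) -> CloneCensus:
    """Tally living cells per founder barcode."""
    b = state.barcodes()
    if len(b) == 0:
        return CloneCensus({})
    binc = np.bincount(b, minlength=state.n_founders + 1)
    return CloneCensus({int(i): int(c) for i, c in enumerate(binc) if i >= 1 and c > 0})
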