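"""Clone frequency profiles.

A :class:`CloneProfile` is the common currency of the package: one specimen
(a tumor, a dissection piece, a needle core, a plasma draw, or a pooled
replicate group) represented as a mapping from integer barcode ID to a
nonnegative read/cell mass, with derived relative frequencies.  Zero-mass
barcodes are dropped on construction, so ``barcodes`` always lists clones
actually present in the specimen.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["CloneProfile"]

_FREQ_TOL = 1e-9


class CloneProfile:
    """Normalized barcode frequency vector for one specimen.

    Parameters
    ----------
    label
        Specimen name (e.g. ``"piece_E"``, ``"needle_a"``, ``"cfDNA3"``).
    counts
        Mapping of barcode ID to raw mass (cell count, read count, or
        fragment count).  Non-positive entries are discarded.
    meta
        Optional free-form annotations (piece flags, sample class, ...).
    """

    __slots__ = ("label", "counts", "meta")

    def __init__(
        self,
        label: str,
        counts: Mapping[int, float],
        meta: dict | None = None,
    ):
        cleaned: dict[int, float] = {}
        for b, c in counts.items():
            c = float(c)
            if c < 0:
                raise ValueError(f"negative count {c} for barcode {b}")
            if c > 0:
                cleaned[int(b)] = c
        self.label = str(label)
        self.counts = cleaned
        self.meta = dict(meta) if meta else {}

    # -- basic accessors ---------------------------------------------------

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def frequencies(self) -> dict[int, float]:
        """Relative frequencies p_i; sums to 1 for non-empty profiles."""
        t = self.total
        if t == 0:
            return {}
        return {b: c / t for b, c in self.counts.items()}

    def frequency(self, barcode: int) -> float:
        t = self.total
        if t == 0:
            return 0.0
        return self.counts.get(int(barcode), 0.0) / t

    @property
    def barcodes(self) -> frozenset[int]:
        return frozenset(self.counts)

    @property
    def richness(self) -> int:
        """Number of distinct barcodes present."""
        return len(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CloneProfile({self.label!r}, {self.richness} barcodes)"

    def validate(self) -> None:
        """Check the frequency-sum invariant (within 1e-9)."""
        if self.counts:
            s = sum(self.frequencies.values())
            if abs(s - 1.0) > _FREQ_TOL:
                raise AssertionError(f"frequencies sum to {s}, not 1")

    # -- derived profiles --------------------------------------------------

    def restricted_to(self, barcodes: Iterable[int], label: str | None = None) -> "CloneProfile":
        """Profile intersected with ``barcodes`` (mass renormalizes lazily)."""
        keep = set(int(b) for b in barcodes)
        return CloneProfile(
            label if label is not None else self.label,
            {b: c for b, c in self.counts.items() if b in keep},
            meta=self.meta,
        )

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        freqs = self.frequencies
        rows = sorted(self.counts)
        return pd.DataFrame(
            {
                "specimen": self.label,
                "barcode_id": rows,
                "count": [self.counts[b] for b in rows],
                "frequency": [freqs[b] for b in rows],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CloneProfile":
        df = pd.read_csv(path, sep="\t")
        label = str(df["specimen"].iloc[0]) if len(df) else Path(path).stem
        return cls(label, dict(zip(df["barcode_id"].astype(int), df["count"])))
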