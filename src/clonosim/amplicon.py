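"""Barcode amplicon demultiplexing and counting.

Reads are single-end amplicons with the fixed layout
``[sample index][anchor][barcode][filler]``: the sample index identifies the
specimen (added during the second, indexing PCR), the anchor is the
constant context immediately 5' of the barcode, and the barcode matches
one entry of a known library of short DNA tags.  Quality scores are
ignored.  Matching tolerates a configurable number of mismatches on the
index and on the barcode; ties between equally distant candidates are
conservatively left unassigned rather than split or arbitrarily resolved.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigError, FastqParseError

__all__ = [
    "ReadLayout",
    "BarcodeLibrary",
    "SampleSheet",
    "CountMatrix",
    "demultiplex_and_count",
]

_DNA = frozenset("ACGT")

SAMPLE_CLASSES = ("tumor_piece", "needle", "cfDNA", "lung", "CTC")
TISSUE_LOCATIONS = ("center", "periphery", "NA")


@dataclass(frozen=True)
class ReadLayout:
    """Positional read architecture for inline-indexed amplicons."""

    index_length: int = 8
    anchor: str = "ACGGTACCGT"
    read_length: int = 75

    def __post_init__(self):
        if self.index_length < 1:
            raise ConfigError("index_length must be >= 1")
        if not set(self.anchor) <= _DNA:
            raise ConfigError("anchor must be an A/C/G/T string")

    @property
    def barcode_start(self) -> int:
        return self.index_length + len(self.anchor)


class BarcodeLibrary:
    """Known barcode tags: integer ID -> DNA sequence.

    All sequences must be distinct, of one common length < 100 nt, over the
    A/C/G/T alphabet.
    """

    def __init__(self, sequences: dict[int, str]):
        if not sequences:
            raise ConfigError("barcode library is empty")
        seqs = {int(i): str(s).upper() for i, s in sequences.items()}
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ConfigError(f"barcode lengths differ: {sorted(lengths)}")
        (L,) = lengths
        if not 0 < L < 100:
            raise ConfigError(f"barcode length {L} out of range (0, 100)")
        for i, s in seqs.items():
            if not set(s) <= _DNA:
                raise ConfigError(f"barcode {i} has non-ACGT characters")
        if len(set(seqs.values())) != len(seqs):
            raise ConfigError("barcode sequences are not unique")
        self.sequences = seqs
        self.length = L
        self._by_seq = {s: i for i, s in seqs.items()}
        self._ids = np.array(sorted(seqs), dtype=np.int64)
        self._encoded = _encode([seqs[i] for i in self._ids])

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, barcode_id: int) -> str:
        return self.sequences[int(barcode_id)]

    def exact(self, seq: str) -> int | None:
        return self._by_seq.get(seq)

    def nearest(self, seq: str, max_mismatch: int) -> int | None:
        """Unique nearest library entry within the mismatch budget.

        Returns None on no hit or on a tie at the minimal distance.
        """
        if max_mismatch == 0 or len(seq) != self.length:
            return self.exact(seq) if len(seq) == self.length else None
        hit = self.exact(seq)
        if hit is not None:
            return hit
        q = _encode([seq])[0]
        dists = (self._encoded != q).sum(axis=1)
        best = int(dists.min())
        if best > max_mismatch:
            return None
        idx = np.flatnonzero(dists == best)
        if len(idx) != 1:
            return None  # ambiguous tie
        return int(self._ids[idx[0]])

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.sequences.items()), columns=["barcode_id", "sequence"]
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BarcodeLibrary":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["barcode_id"].astype(int), df["sequence"])))


def _encode(seqs: list[str]) -> np.ndarray:
    """DNA strings to a (n, L) uint8 matrix for vectorized Hamming."""
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )


class SampleSheet:
    """Sample metadata: ID, inline index, replicate group, class, location."""

    COLUMNS = ["sample_id", "index", "replicate_group", "sample_class", "tissue_location"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigError(f"sample sheet missing columns: {missing}")
        frame = frame[self.COLUMNS].copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["index"] = frame["index"].astype(str).str.upper()
        if frame["sample_id"].duplicated().any():
            raise ConfigError("duplicate sample_id in sample sheet")
        if frame["index"].duplicated().any():
            dup = frame.loc[frame["index"].duplicated(), "index"].tolist()
            raise ConfigError(f"duplicate index sequences in sample sheet: {dup}")
        bad = set(frame["sample_class"]) - set(SAMPLE_CLASSES)
        if bad:
            raise ConfigError(f"unknown sample_class values: {sorted(bad)}")
        # every sample of a replicate group must share one sample class
        per_group = frame.groupby("replicate_group")["sample_class"].nunique()
        mixed = per_group[per_group > 1].index.tolist()
        if mixed:
            raise ConfigError(f"replicate groups with mixed sample_class: {mixed}")
        lengths = frame["index"].str.len().unique()
        if len(lengths) != 1:
            raise ConfigError("all index sequences must share one length")
        self.frame = frame.set_index("sample_id", drop=False)
        self.index_length = int(lengths[0])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def index_of(self) -> dict[str, str]:
        return dict(zip(self.frame["index"], self.frame["sample_id"]))

    def replicate_groups(self) -> dict[str, list[str]]:
        return {
            g: list(sub["sample_id"])
            for g, sub in self.frame.groupby("replicate_group", sort=False)
        }

    def sample_class(self, sample_id: str) -> str:
        return str(self.frame.loc[sample_id, "sample_class"])

    def write_csv(self, path: str | Path) -> None:
        self.frame.reset_index(drop=True).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SampleSheet":
        # keep_default_na: "NA" is a legitimate tissue_location value
        return cls(pd.read_csv(path, keep_default_na=False))


class CountMatrix:
    """Barcode x sample read counts with sample metadata.

    ``counts`` rows are barcode IDs, columns sample IDs; ``unassigned``
    tallies reads that failed index or barcode assignment.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: SampleSheet,
        unassigned: int = 0,
    ):
        counts = counts.copy()
        if (counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = [s for s in counts.columns if s not in samples.frame.index]
        if missing:
            raise ConfigError(f"samples without metadata: {missing}")
        counts.index = counts.index.astype(int)
        counts.index.name = "barcode_id"
        self.counts = counts
        self.samples = samples
        self.unassigned = int(unassigned)

    @property
    def total_reads(self) -> int:
        return int(self.counts.values.sum())

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.samples, self.unassigned)

    def with_counts(self, counts: pd.DataFrame) -> "CountMatrix":
        return CountMatrix(counts, self.samples, self.unassigned)

    def metadata(self) -> pd.DataFrame:
        return self.samples.frame.loc[list(self.counts.columns)]

    def replicate_groups(self) -> dict[str, list[str]]:
        """Replicate groups restricted to samples still in the matrix."""
        present = set(self.counts.columns)
        groups = {}
        for g, ids in self.samples.replicate_groups().items():
            kept = [s for s in ids if s in present]
            if kept:
                groups[g] = kept
        return groups

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(
        cls, path: str | Path, samples: SampleSheet, unassigned: int = 0
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, samples, unassigned)

    @staticmethod
    def concat(matrices: list["CountMatrix"], samples: SampleSheet) -> "CountMatrix":
        counts = pd.concat([m.counts for m in matrices], axis=1).fillna(0).astype(int)
        return CountMatrix(counts, samples, sum(m.unassigned for m in matrices))


def _iter_fastq(reads) -> Iterator[tuple[str, str]]:
    """Yield (title, sequence) from a path, file-like, or pair iterable."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            yield from FastqGeneralIterator(fh)
    elif hasattr(reads, "read"):
        yield from FastqGeneralIterator(reads)
    else:  # already an iterable of (title, seq[, qual]) tuples
        for rec in reads:
            yield rec[0], rec[1]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_and_count(
    reads,
    lib: BarcodeLibrary,
    sheet: SampleSheet,
    max_mismatch_index: int = 0,
    max_mismatch_barcode: int = 0,
    layout: ReadLayout | None = None,
) -> CountMatrix:
    """Assign each read to a (sample, barcode) pair and count.

    A read is assigned iff its index region matches exactly one sample
    within ``max_mismatch_index`` and its barcode region matches exactly
    one library entry within ``max_mismatch_barcode``; everything else
    (no hit, equal-distance tie, short read) increments the unassigned
    tally, so assigned + unassigned always equals the input read count.
    """
    if max_mismatch_index < 0 or max_mismatch_barcode < 0:
        raise ValueError("mismatch budgets must be >= 0")
    if layout is None:
        layout = ReadLayout(index_length=sheet.index_length)
    if layout.index_length != sheet.index_length:
        raise ConfigError(
            f"layout index_length {layout.index_length} != sheet "
            f"index length {sheet.index_length}"
        )
    index_map = sheet.index_of()
    indexes = list(index_map)
    bc_start = layout.barcode_start
    bc_end = bc_start + lib.length

    counts: dict[tuple[str, int], int] = {}
    unassigned = 0
    n_records = 0
    stream = _iter_fastq(reads)
    while True:
        try:
            rec = next(stream, None)
        except ValueError as e:
            raise FastqParseError(n_records + 1, str(e)) from e
        if rec is None:
            break
        n_records += 1
        seq = rec[1].upper()
        if len(seq) < bc_end:
            unassigned += 1
            continue
        idx = seq[: layout.index_length]
        sample = index_map.get(idx)
        if sample is None and max_mismatch_index > 0:
            dists = [(_hamming(idx, cand), cand) for cand in indexes]
            best = min(d for d, _ in dists)
            if best <= max_mismatch_index:
                hits = [c for d, c in dists if d == best]
                if len(hits) == 1:
                    sample = index_map[hits[0]]
        if sample is None:
            unassigned += 1
            continue
        barcode = lib.nearest(seq[bc_start:bc_end], max_mismatch_barcode)
        if barcode is None:
            unassigned += 1
            continue
        counts[(sample, barcode)] = counts.get((sample, barcode), 0) + 1

    frame = pd.DataFrame(
        0, index=sorted(lib.sequences), columns=sheet.sample_ids, dtype=int
    )
    for (sample, barcode), c in counts.items():
        frame.loc[barcode, sample] = c
    return CountMatrix(frame, sheet, unassigned)
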