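"""Synthetic data with the statistical structure of barcode-sequencing
experiments.

Four generators, all seed-deterministic:

* :func:`synth_library` — a pool of distinct random DNA tags (pairwise
  Hamming distance >= 2);
* :func:`synth_tumor_profiles` — a log-normal clone abundance law split
  across tumor pieces by per-clone Dirichlet draws, so a small
  concentration produces spatially patchy clones (each clone's mass
  concentrated in few pieces) while a large one produces well-mixed
  tissue;
* :func:`simulate_counts` — Dirichlet-multinomial replicate read counts
  over a profile (overdispersion 0 reduces to a plain multinomial),
  emulating PCR duplicates for tissue and quintuplicates for
  plasma/lung;
* :func:`write_fastq` — the inverse of the amplicon counter: emits one
  read per counted molecule, with an optional uniform per-base
  substitution error, for round-trip tests.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon import BarcodeLibrary, CountMatrix, ReadLayout, SampleSheet
from .errors import CapacityError
from .profiles import CloneProfile

__all__ = [
    "SynthConfig",
    "synth_library",
    "synth_tumor_profiles",
    "simulate_counts",
    "write_fastq",
    "make_indexes",
    "make_sample_sheet",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic experiment.

    ``n_barcodes`` sizes the tag library (~2600 tags is typical of
    lentiviral pools); ``n_clones`` of them seed the synthetic tumor with
    abundances drawn log-normally (``abundance_sigma`` controls dominance
    structure: 1.5 yields a few >1% clones over many minor ones) unless an
    explicit ``abundance`` vector is given.  ``patchiness`` is the
    per-piece Dirichlet concentration governing how unevenly each clone
    spreads across ``n_pieces`` (small = patchy).  Replicate plans follow
    the PCR design: duplicates for tissue, quintuplicates for cfDNA/lung.
    """

    n_barcodes: int = 2600
    barcode_length: int = 20
    n_clones: int | None = None  # default: min(200, n_barcodes)
    abundance_sigma: float = 1.5
    abundance: tuple[float, ...] | None = None
    n_pieces: int = 5
    patchiness: float = 0.3
    tissue_replicates: int = 2
    cfdna_replicates: int = 5
    depth: int = 100_000
    overdispersion: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_clones is None:
            object.__setattr__(self, "n_clones", min(200, self.n_barcodes))
        if self.n_barcodes < 1 or self.n_clones < 1:
            raise ValueError("n_barcodes and n_clones must be >= 1")
        if self.n_clones > self.n_barcodes:
            raise ValueError("n_clones cannot exceed n_barcodes")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.patchiness <= 0:
            raise ValueError("patchiness (Dirichlet concentration) must be > 0")


def synth_library(cfg: SynthConfig) -> BarcodeLibrary:
    """Distinct random tags with pairwise Hamming distance >= 2.

    Tags are accepted by rejection against all previously accepted tags;
    IDs run 1..n.  Raises :class:`CapacityError` when the requested count
    cannot fit the sequence space.
    """
    L = cfg.barcode_length
    if cfg.n_barcodes > 4 ** L // max(1, 3 * L):  # Hamming-ball packing bound
        raise CapacityError(
            f"{cfg.n_barcodes} tags at distance >= 2 infeasible for length {L}"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    accepted = np.empty((cfg.n_barcodes, L), dtype=np.uint8)
    n = 0
    attempts = 0
    while n < cfg.n_barcodes:
        attempts += 1
        if attempts > 1000 * cfg.n_barcodes:  # pragma: no cover - safety
            raise CapacityError("rejection sampling failed to fill the library")
        cand = _BASES[rng.integers(0, 4, size=L)]
        if n and (accepted[:n] != cand).sum(axis=1).min() < 2:
            continue
        accepted[n] = cand
        n += 1
    seqs = {
        i + 1: accepted[i].tobytes().decode() for i in range(cfg.n_barcodes)
    }
    return BarcodeLibrary(seqs)


def synth_tumor_profiles(
    cfg: SynthConfig,
) -> tuple[CloneProfile, list[CloneProfile]]:
    """A whole-tumor profile and its per-piece split.

    Global clone frequencies come from the abundance law; each clone's
    mass is then divided across pieces by an independent Dirichlet draw
    with concentration ``patchiness``.  Piece masses sum exactly to the
    tumor profile, so the tumor equals the normalized sum of its pieces.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    ids = np.arange(1, cfg.n_clones + 1)
    if cfg.abundance is not None:
        ab = np.asarray(cfg.abundance, dtype=float)
        if len(ab) != cfg.n_clones or (ab < 0).any() or ab.sum() <= 0:
            raise ValueError("abundance vector must be nonnegative, length n_clones")
    else:
        ab = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=cfg.n_clones)
    freqs = ab / ab.sum()

    splits = rng.dirichlet(
        np.full(cfg.n_pieces, cfg.patchiness), size=cfg.n_clones
    )  # (n_clones, n_pieces)
    piece_mass = freqs[:, None] * splits

    labels = [chr(ord("A") + i) for i in range(cfg.n_pieces)]
    pieces = [
        CloneProfile(
            labels[j],
            {int(b): float(m) for b, m in zip(ids, piece_mass[:, j]) if m > 0},
            meta={"piece": labels[j], "center": j == cfg.n_pieces - 1},
        )
        for j in range(cfg.n_pieces)
    ]
    tumor = CloneProfile(
        "tumor", {int(b): float(f) for b, f in zip(ids, freqs) if f > 0}
    )
    return tumor, pieces


def simulate_counts(
    profile: CloneProfile,
    n_replicates: int,
    depth: int,
    overdispersion: float = 0.0,
    seed: int = 0,
    group: str | None = None,
    sample_class: str = "tumor_piece",
    tissue_location: str = "NA",
    sheet: SampleSheet | None = None,
) -> CountMatrix:
    """Replicate read counts for one specimen.

    Each replicate draws ``depth`` reads.  With ``overdispersion`` e > 0
    the replicate's sampling probabilities are first perturbed by a
    Dirichlet draw with concentration p_i / e, giving PCR-like
    between-replicate variance; e = 0 is a plain multinomial.  Replicates
    share a replicate group named after the profile (or ``group``).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    rng = np.random.default_rng(seed)
    group = group or profile.label
    ids = sorted(profile.counts)
    p = np.array([profile.frequencies[b] for b in ids])
    cols = {}
    sample_ids = [f"{group}_r{i + 1}" for i in range(n_replicates)]
    for sid in sample_ids:
        if overdispersion > 0:
            alpha = np.maximum(p / overdispersion, 1e-12)
            q = rng.dirichlet(alpha)
        else:
            q = p
        cols[sid] = rng.multinomial(depth, q)
    counts = pd.DataFrame(cols, index=ids, dtype=int)
    if sheet is None:
        sheet = make_sample_sheet(
            sample_ids,
            replicate_group=group,
            sample_class=sample_class,
            tissue_location=tissue_location,
        )
    return CountMatrix(counts, sheet)


def make_indexes(n: int, length: int = 8, offset: int = 0) -> list[str]:
    """Deterministic distinct index sequences (enumerated, not random)."""
    if n + offset > 4 ** length:
        raise CapacityError(f"cannot enumerate {n} indexes of length {length}")
    out = []
    for i, combo in enumerate(itertools.product("ACGT", repeat=length)):
        if i < offset:
            continue
        out.append("".join(combo))
        if len(out) == n:
            break
    return out


def make_sample_sheet(
    sample_ids: list[str],
    replicate_group: str | list[str],
    sample_class: str | list[str] = "tumor_piece",
    tissue_location: str | list[str] = "NA",
    index_length: int = 8,
    index_offset: int = 0,
) -> SampleSheet:
    """Assemble a sample sheet with enumerated unique indexes."""
    n = len(sample_ids)

    def _expand(v):
        return [v] * n if isinstance(v, str) else list(v)

    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "index": make_indexes(n, index_length, index_offset),
                "replicate_group": _expand(replicate_group),
                "sample_class": _expand(sample_class),
                "tissue_location": _expand(tissue_location),
            }
        )
    )


def write_fastq(
    m: CountMatrix,
    lib: BarcodeLibrary,
    sheet: SampleSheet | None = None,
    layout: ReadLayout | None = None,
    seed: int = 0,
    path: str | Path | None = None,
    error_rate: float = 0.0,
):
    """Emit one FASTQ record per counted read (inverse of the counter).

    Reads are ``[index][anchor][barcode][filler]`` padded to the layout
    read length with deterministic random bases, shuffled by ``seed``.
    ``error_rate`` applies uniform per-base substitution to whole reads.
    Returns the path if one was given, else the list of FASTQ text
    records.
    """
    sheet = sheet or m.samples
    if layout is None:
        layout = ReadLayout(index_length=sheet.index_length)
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    index_by_sample = dict(zip(sheet.frame["sample_id"], sheet.frame["index"]))

    pairs: list[tuple[str, int]] = []
    for sample in m.counts.columns:
        if sample not in index_by_sample:
            raise ValueError(f"sample {sample!r} not in the sample sheet")
        col = m.counts[sample]
        for barcode, c in col[col > 0].items():
            if int(barcode) not in lib.sequences:
                raise ValueError(f"barcode {barcode} not in the library")
            pairs.extend([(sample, int(barcode))] * int(c))
    order = rng.permutation(len(pairs))
    n_reads = len(pairs)

    core_len = sheet.index_length + len(layout.anchor) + lib.length
    read_len = max(layout.read_length, core_len)
    cores: dict[tuple[str, int], np.ndarray] = {}
    arr = np.empty((n_reads, read_len), dtype=np.uint8)
    names = []
    for k, j in enumerate(order):
        sample, barcode = pairs[j]
        key = (sample, barcode)
        core = cores.get(key)
        if core is None:
            core = np.frombuffer(
                (index_by_sample[sample] + layout.anchor + lib[barcode]).encode(),
                dtype=np.uint8,
            )
            cores[key] = core
        arr[k, :core_len] = core
        names.append(sample)
    if read_len > core_len:
        arr[:, core_len:] = _BASES[
            rng.integers(0, 4, size=(n_reads, read_len - core_len))
        ]
    if error_rate > 0 and n_reads:
        # uniform per-base substitution to one of the three other bases
        lut = np.zeros(256, dtype=np.uint8)
        lut[_BASES] = np.arange(4)
        hit = rng.random(arr.shape) < error_rate
        shift = rng.integers(1, 4, size=arr.shape)
        arr[hit] = _BASES[(lut[arr[hit]] + shift[hit]) % 4]

    qual = "I" * read_len
    records = [
        f"@read{k + 1} {names[k]}\n{arr[k].tobytes().decode()}\n+\n{qual}\n"
        for k in range(n_reads)
    ]

    if path is None:
        return records
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.writelines(records)
    return path
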