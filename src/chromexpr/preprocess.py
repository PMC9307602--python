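"""Turn raw tracks and sequence into fixed-length, scaled, model-ready gene inputs.

The pipeline mirrors standard practice for signal-over-promoter models:

1. each track is broadcast to per-base resolution over fixed 20-bp genomic
   regions (coverage-weighted mean where source intervals straddle a region;
   uncovered bases take the track kind's null value: p = 1, methylation = 0);
2. p-value tracks are transformed by ``-log10`` and min-max scaled to [0, 1]
   per track over all assembled gene regions; methylation is divided by 100;
3. the DNA sequence is one-hot encoded (rows A, C, G, T; ambiguous bases are
   all-zero rows);
4. a window around the TSS and a window around the TTS are concatenated into
   one L x m epigenetic matrix and one L x 4 sequence matrix per gene.  Minus
   strand genes are mirrored (sequence reverse-complemented, signal reversed)
   so that row 0 is always the most-upstream base.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import GeneAnnotation, RawTrack, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSpec",
    "TrackSet",
    "GeneInput",
    "SplitDataset",
    "regionize_track",
    "scale_pvalue",
    "scale_methylation",
    "one_hot",
    "build_trackset",
    "assemble_gene_input",
    "assemble_dataset",
    "split_dataset",
    "as_arrays",
    "save_dataset",
    "load_dataset",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class RegionSpec:
    """Extents (bp) of the two input windows and the signal bin size.

    Defaults are the optimum found by scanning window combinations:
    [-1000, +500] around the TSS plus [-500, +500] around the TTS, with
    signal binned over 20-bp regions.
    """

    tss_up: int = 1000
    tss_down: int = 500
    tts_up: int = 500
    tts_down: int = 500
    bin: int = 20

    def __post_init__(self) -> None:
        for name in ("tss_up", "tss_down", "tts_up", "tts_down", "bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RegionSpec.{name} must be positive")
        if self.length % self.bin != 0:
            raise ValueError(
                f"total window length {self.length} is not a multiple of bin={self.bin}"
            )

    @property
    def length(self) -> int:
        """Total model input length L."""
        return self.tss_up + self.tss_down + self.tts_up + self.tts_down

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrackSet:
    """m named tracks as per-base arrays scaled to [0, 1], constant over 20-bp regions."""

    names: list[str]
    kinds: list[str]
    data: dict[str, dict[str, np.ndarray]]  # track name -> chrom -> per-base values
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.names)

    def values(self, name: str, chrom: str, start: int, end: int) -> np.ndarray:
        return self.data[name][chrom][start:end]


def regionize_track(raw: RawTrack, chrom_lengths: dict[str, int], bin: int = 20) -> dict[str, np.ndarray]:
    """Broadcast a track to per-base arrays with one value per ``bin``-bp region.

    The region value is the coverage-weighted mean of the overlapping interval
    values, with the track's null value filling uncovered bases.  Returns raw
    (unscaled) values: p-values for ``kind='pvalue'``, percentages for
    ``kind='methylation'``.
    """
    out: dict[str, np.ndarray] = {}
    null = raw.null_value
    per_chrom: dict[str, list] = {c: [] for c in chrom_lengths}
    for chrom, start, end, value in raw.intervals:
        if chrom not in chrom_lengths:
            continue
        per_chrom[chrom].append((start, end, value))
    for chrom, clen in chrom_lengths.items():
        arr = np.full(clen, null, dtype=np.float64)
        for start, end, value in per_chrom[chrom]:
            if start >= clen:
                continue
            arr[start : min(end, clen)] = value
        n_blocks = -(-clen // bin)
        padded = np.full(n_blocks * bin, null, dtype=np.float64)
        padded[:clen] = arr
        block_means = padded.reshape(n_blocks, bin).mean(axis=1)
        out[chrom] = np.repeat(block_means, bin)[:clen]
    return out


def scale_pvalue(values: np.ndarray) -> np.ndarray:
    """``-log10`` then min-max scale to [0, 1] over the given values.

    A constant input (min == max) maps to all zeros.
    """
    values = np.asarray(values, dtype=np.float64)
    if np.any(values <= 0) or np.any(values > 1):
        raise ValueError("p-values must lie in (0, 1]")
    neglog = -np.log10(values)
    return _minmax(neglog, float(neglog.min()), float(neglog.max()))


def scale_methylation(values: np.ndarray) -> np.ndarray:
    """Percent methylation in [0, 100] -> fraction in [0, 1]."""
    values = np.asarray(values, dtype=np.float64)
    if np.any(values < 0) or np.any(values > 100):
        raise ValueError("methylation values must lie in [0, 100]")
    return values / 100.0


def _minmax(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros_like(x)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode a DNA string (columns A, C, G, T; N -> all-zero row)."""
    idx = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -2, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        lut[ord(base)] = i
    lut[ord("N")] = -1
    codes = lut[idx]
    if np.any(codes == -2):
        bad = seq[int(np.argmax(codes == -2))]
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    out = np.zeros((len(seq), 4), dtype=np.float32)
    valid = codes >= 0
    out[np.nonzero(valid)[0], codes[valid]] = 1.0
    return out


@dataclass
class GeneInput:
    """Model-ready matrices for one gene over the assembled TSS+TTS windows."""

    gene_id: str
    epigenetic: np.ndarray  # (L, m) in [0, 1]
    sequence: np.ndarray  # (L, 4) binary
    target: float
    tpm: float
    chrom: str
    coords: np.ndarray  # (L,) genomic position of each input row
    strand: str


def _gene_windows(g: GeneAnnotation, spec: RegionSpec) -> list[tuple[int, int]]:
    """Genomic [start, end) of the TSS window then the TTS window.

    For '-' strand genes the windows are the mirror image of the '+' layout:
    the row at signed offset o from the anchor (negative = upstream) sits at
    genomic position anchor - o, so the genomic interval is reversed when the
    matrices are assembled.
    """
    if g.strand == "+":
        return [
            (g.tss - spec.tss_up, g.tss + spec.tss_down),
            (g.tts - spec.tts_up, g.tts + spec.tts_down),
        ]
    return [
        (g.tss - spec.tss_down + 1, g.tss + spec.tss_up + 1),
        (g.tts - spec.tts_down + 1, g.tts + spec.tts_up + 1),
    ]


def build_trackset(
    raws: Sequence[RawTrack],
    chrom_lengths: dict[str, int],
    genes: Sequence[GeneAnnotation],
    spec: RegionSpec,
) -> TrackSet:
    """Regionize and scale every track.

    p-value tracks are min-max scaled over the union of all assembled gene
    windows (the population the model actually sees); the per-track
    (min, max) of the -log10 values is recorded in ``scaling`` so any run is
    reproducible from its sidecar.
    """
    names = [t.name for t in raws]
    if len(set(names)) != len(names):
        raise FormatError("duplicate track names")
    data: dict[str, dict[str, np.ndarray]] = {}
    scaling: dict[str, tuple[float, float]] = {}
    # collect assembled-window index masks once
    window_idx: dict[str, list[np.ndarray]] = {c: [] for c in chrom_lengths}
    for g in genes:
        if g.chrom not in chrom_lengths:
            continue
        clen = chrom_lengths[g.chrom]
        for start, end in _gene_windows(g, spec):
            if 0 <= start and end <= clen:
                window_idx[g.chrom].append(np.arange(start, end))
    for raw in raws:
        per_chrom = regionize_track(raw, chrom_lengths, bin=spec.bin)
        if raw.kind == "pvalue":
            neglog = {c: -np.log10(a) for c, a in per_chrom.items()}
            pooled = [neglog[c][np.concatenate(ix)] for c, ix in window_idx.items() if ix]
            if pooled:
                allv = np.concatenate(pooled)
                lo, hi = float(allv.min()), float(allv.max())
            else:
                lo, hi = 0.0, 0.0
            scaling[raw.name] = (lo, hi)
            data[raw.name] = {
                c: _minmax(a, lo, hi).astype(np.float32) for c, a in neglog.items()
            }
        else:
            scaling[raw.name] = (0.0, 100.0)
            data[raw.name] = {
                c: (a / 100.0).astype(np.float32) for c, a in per_chrom.items()
            }
    return TrackSet(names=names, kinds=[t.kind for t in raws], data=data, scaling=scaling)


def assemble_gene_input(
    g: GeneAnnotation,
    tracks: TrackSet,
    genome: dict[str, str],
    spec: RegionSpec,
    target_transform: str = "log1p",
) -> GeneInput | None:
    """Assemble the (L, m) epigenetic and (L, 4) sequence matrices for one gene.

    Returns ``None`` (with a logged warning) when either window leaves the
    chromosome; genes are skipped rather than zero-padded.
    """
    if g.chrom not in genome:
        logger.warning("gene %s: chromosome %s absent from genome", g.gene_id, g.chrom)
        return None
    clen = len(genome[g.chrom])
    windows = _gene_windows(g, spec)
    for start, end in windows:
        if start < 0 or end > clen:
            logger.warning(
                "gene %s: window [%d,%d) outside chromosome %s (length %d); skipped",
                g.gene_id, start, end, g.chrom, clen,
            )
            return None
    ep_parts, seq_parts, coord_parts = [], [], []
    for start, end in windows:
        ep = np.stack(
            [tracks.values(name, g.chrom, start, end) for name in tracks.names], axis=1
        )
        seq = genome[g.chrom][start:end]
        coords = np.arange(start, end, dtype=np.int64)
        if g.strand == "-":
            ep = ep[::-1]
            seq = seq[::-1].translate(_COMPLEMENT)
            coords = coords[::-1]
        ep_parts.append(ep)
        seq_parts.append(one_hot(seq))
        coord_parts.append(coords)
    if target_transform == "log1p":
        target = float(np.log1p(g.tpm))
    elif target_transform == "raw":
        target = float(g.tpm)
    else:
        raise ValueError(f"unknown target transform {target_transform!r}")
    return GeneInput(
        gene_id=g.gene_id,
        epigenetic=np.ascontiguousarray(np.concatenate(ep_parts), dtype=np.float32),
        sequence=np.concatenate(seq_parts).astype(np.float32),
        target=target,
        tpm=g.tpm,
        chrom=g.chrom,
        coords=np.concatenate(coord_parts),
        strand=g.strand,
    )


def assemble_dataset(
    genes: Sequence[GeneAnnotation],
    tracks: TrackSet,
    genome: dict[str, str],
    spec: RegionSpec,
    target_transform: str = "log1p",
) -> list[GeneInput]:
    inputs = []
    n_skipped = 0
    for g in genes:
        gi = assemble_gene_input(g, tracks, genome, spec, target_transform)
        if gi is None:
            n_skipped += 1
        else:
            inputs.append(gi)
    if n_skipped:
        logger.info("assemble_dataset: skipped %d genes with out-of-bounds windows", n_skipped)
    return inputs


@dataclass
class SplitDataset:
    """Disjoint, exhaustive train/validation/test partition of gene inputs."""

    train: list[GeneInput]
    validation: list[GeneInput]
    test: list[GeneInput]
    fractions: tuple[float, float, float]
    seed: int


def split_dataset(
    inputs: Sequence[GeneInput],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitDataset:
    """Random gene-level partition, deterministic given ``seed``."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(inputs)
    if n < 10:
        raise ValueError(f"need at least 10 genes to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]
    pick = lambda idx: [inputs[i] for i in idx]
    return SplitDataset(
        train=pick(idx_train),
        validation=pick(idx_val),
        test=pick(idx_test),
        fractions=tuple(fractions),
        seed=seed,
    )


def as_arrays(inputs: Sequence[GeneInput]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack gene inputs into (N, L, m), (N, L, 4) and (N,) arrays."""
    ep = np.stack([g.epigenetic for g in inputs]).astype(np.float32)
    seq = np.stack([g.sequence for g in inputs]).astype(np.float32)
    y = np.array([g.target for g in inputs], dtype=np.float32)
    return ep, seq, y


def save_dataset(inputs: Sequence[GeneInput], spec: RegionSpec, tracks: TrackSet, path, seed: int | None = None) -> None:
    """Write the assembled dataset (one record per gene) plus a JSON sidecar."""
    path = Path(path)
    ep, seq, y = as_arrays(inputs)
    np.savez_compressed(
        path,
        gene_ids=np.array([g.gene_id for g in inputs]),
        epigenetic=ep,
        sequence=seq,
        targets=y,
        tpm=np.array([g.tpm for g in inputs]),
        chroms=np.array([g.chrom for g in inputs]),
        coords=np.stack([g.coords for g in inputs]),
        strands=np.array([g.strand for g in inputs]),
    )
    sidecar = {
        "region_spec": spec.to_dict(),
        "track_names": tracks.names,
        "track_kinds": tracks.kinds,
        "scaling": {k: list(v) for k, v in tracks.scaling.items()},
        "seed": seed,
        "scaling_population": "assembled_gene_regions",
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_dataset(path) -> tuple[list[GeneInput], dict]:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        # materialize each array once; per-gene matrices are views into it
        arrays = {k: z[k] for k in z.files}
    inputs = [
        GeneInput(
            gene_id=str(arrays["gene_ids"][i]),
            epigenetic=arrays["epigenetic"][i],
            sequence=arrays["sequence"][i],
            target=float(arrays["targets"][i]),
            tpm=float(arrays["tpm"][i]),
            chrom=str(arrays["chroms"][i]),
            coords=arrays["coords"][i],
            strand=str(arrays["strands"][i]),
        )
        for i in range(len(arrays["gene_ids"]))
    ]
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    return inputs, sidecar
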