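"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention); nothing is
converted silently.  Every reader accepts plain or gzip-compressed text
(detected by the ``.gz`` suffix).  Parsing is strict: malformed lines raise
:class:`FormatError` naming the offending line.
"""

from __future__ import annotations

import gzip
import logging
from io import StringIO
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

__all__ = [
    "FormatError",
    "GeneAnnotation",
    "RawTrack",
    "MotifPFM",
    "GeneSetCollection",
    "read_annotation",
    "write_annotation",
    "read_track",
    "write_track",
    "read_jaspar",
    "write_jaspar",
    "read_gmt",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: identity, coordinates of its biological start/termination, strand, TPM.

    ``tss``/``tts`` are the transcription start and termination sites as
    biological anchors, not min/max coordinates: on the ``-`` strand
    ``tss >= tts``.
    """

    gene_id: str
    chrom: str
    tss: int
    tts: int
    strand: str
    tpm: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.tss < 0 or self.tts < 0:
            raise FormatError(f"gene {self.gene_id}: negative coordinate")
        if self.strand == "+" and self.tss > self.tts:
            raise FormatError(f"gene {self.gene_id}: '+' strand requires tss <= tts")
        if self.strand == "-" and self.tss < self.tts:
            raise FormatError(f"gene {self.gene_id}: '-' strand requires tss >= tts")
        if self.tpm < 0:
            raise FormatError(f"gene {self.gene_id}: negative TPM")


_ANNOT_COLUMNS = ("gene_id", "chrom", "tss", "tts", "strand", "tpm")


def read_annotation(path) -> list[GeneAnnotation]:
    """Read a flat per-gene table (TSV with header gene_id..tpm).

    Genes with zero TPM are removed (their count is logged); duplicate gene
    ids are a hard error.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    n_zero = 0
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:6]) != _ANNOT_COLUMNS:
            expected = "\t".join(_ANNOT_COLUMNS)
            raise FormatError(f"{path}: expected header {expected!r}, got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            gene_id, chrom, tss_s, tts_s, strand, tpm_s = parts[:6]
            try:
                tss, tts = int(tss_s), int(tts_s)
                tpm = float(tpm_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed number: {exc}") from exc
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if tpm == 0:
                n_zero += 1
                continue
            genes.append(GeneAnnotation(gene_id, chrom, tss, tts, strand, tpm))
    if n_zero:
        logger.info("read_annotation: removed %d zero-expression genes", n_zero)
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_ANNOT_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.tts}\t{g.strand}\t{g.tpm:.10g}\n")


# ---------------------------------------------------------------------------
# Signal tracks (bedGraph)
# ---------------------------------------------------------------------------

TRACK_KINDS = ("pvalue", "methylation")


@dataclass
class RawTrack:
    """One modification's signal as sorted, non-overlapping genomic intervals.

    ``kind='pvalue'`` carries MACS-style signal p-values in (0, 1];
    ``kind='methylation'`` carries percent methylation in [0, 100].
    """

    name: str
    kind: str
    intervals: list[tuple[str, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise FormatError(f"track {self.name}: unknown kind {self.kind!r}")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv[0], iv[1]))
        self._validate()

    def _validate(self) -> None:
        prev: tuple[str, int, int, float] | None = None
        for chrom, start, end, value in self.intervals:
            if not 0 <= start < end:
                raise FormatError(f"track {self.name}: bad interval {chrom}:{start}-{end}")
            _check_track_value(self.name, self.kind, chrom, start, end, value)
            if prev is not None and prev[0] == chrom and start < prev[2]:
                raise FormatError(
                    f"track {self.name}: overlapping intervals "
                    f"{chrom}:{prev[1]}-{prev[2]} and {chrom}:{start}-{end}"
                )
            prev = (chrom, start, end, value)

    @property
    def null_value(self) -> float:
        """Value of a base not covered by any interval: p=1 (no signal) or 0% methylated."""
        return 1.0 if self.kind == "pvalue" else 0.0

    def chroms(self) -> list[str]:
        return sorted({iv[0] for iv in self.intervals})


def _check_track_value(name, kind, chrom, start, end, value) -> None:
    if kind == "pvalue" and not 0.0 < value <= 1.0:
        raise FormatError(
            f"track {name}: p-value {value} out of (0,1] at {chrom}:{start}-{end}"
        )
    if kind == "methylation" and not 0.0 <= value <= 100.0:
        raise FormatError(
            f"track {name}: methylation {value} out of [0,100] at {chrom}:{start}-{end}"
        )


def read_track(path, kind: str, name: str | None = None) -> RawTrack:
    """Read a 4-column bedGraph into a :class:`RawTrack` (sorted, overlap-checked)."""
    if name is None:
        name = Path(path).name.split(".")[0]
    intervals: list[tuple[str, int, int, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start_s, end_s, value_s = parts
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed number: {exc}") from exc
            intervals.append((chrom, start, end, value))
    return RawTrack(name=name, kind=kind, intervals=intervals)


def write_track(track: RawTrack, path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, start, end, value in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


# ---------------------------------------------------------------------------
# JASPAR position frequency matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPFM:
    """A position frequency matrix: 4 x w counts, rows ordered A, C, G, T."""

    motif_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise FormatError(f"motif {self.motif_id}: counts must be 4 x w")
        if np.any(counts < 0):
            raise FormatError(f"motif {self.motif_id}: negative count")
        if np.any(counts.sum(axis=0) <= 0):
            raise FormatError(f"motif {self.motif_id}: column with zero total count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[i] for i in np.argmax(self.counts, axis=0))


def read_jaspar(path) -> list[MotifPFM]:
    """Read JASPAR PFM text (">id name" header, 4 labelled rows, any row order).

    Parsing is delegated to Bio.motifs; rows come back ordered A, C, G, T and
    every matrix is validated (equal row widths, no all-zero column).
    """
    from Bio import motifs as bio_motifs

    with _open_text(path) as fh:
        text = fh.read()
    n_headers = sum(line.startswith(">") for line in text.splitlines())
    try:
        parsed = bio_motifs.parse(StringIO(text), "jaspar")
    except Exception as exc:
        raise FormatError(f"{path}: malformed JASPAR matrix: {exc}") from exc
    if len(parsed) != n_headers:
        raise FormatError(
            f"{path}: {n_headers} matrix header(s) but {len(parsed)} complete "
            "matrices parsed; a matrix is missing rows"
        )
    out = []
    for m in parsed:
        motif_id = getattr(m, "matrix_id", None) or m.name
        missing = [b for b in NUCLEOTIDES if b not in m.counts]
        if missing:
            raise FormatError(f"motif {motif_id}: missing row(s) {missing}")
        counts = np.array([list(m.counts[b]) for b in NUCLEOTIDES], dtype=float)
        out.append(MotifPFM(motif_id=motif_id, counts=counts))
    return out


def write_jaspar(motifs: Sequence[MotifPFM], path) -> None:
    with _open_text(path, "wt") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id}\n")
            for base, row in zip(NUCLEOTIDES, m.counts):
                fh.write(f"{base}  [ " + "  ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named sets of gene/TF identifiers (members upper-cased for matching)."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __iter__(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, members")
            name, _desc, *members = parts
            members = [m.strip().upper() for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Genome sequence (FASTA)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Load a (small) genome FASTA into a dict chrom -> upper-case sequence."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
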