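"""Generate complete synthetic regulatory-genomics studies with known ground truth.

The generator emulates the statistical structure the model assumes: m
parallel signal tracks that are piecewise-constant over 20-bp blocks with
values in [0, 1] (p-value tracks are emitted as p = 10^(-v * pscale) so the
preprocessing pipeline inverts them back to the latent v), genes placed
non-overlapping on alternating strands, and expression generated as

    TPM_g = exp( b0 + sum_k w_k * meanSignal(track_k, window_k of g)
                 + motif_effect * 1[motif inserted in g's promoter window]
                 + eps ),        eps ~ Normal(0, noise_sd)

where each causal window carries a gene-specific latent level (uniform on
[0.1, 0.9] plus small per-block jitter) and every other block is independent
uniform noise.  A known motif is inserted, at a configurable rate, only
inside causal promoter windows, so motif-enrichment analyses have a sharp
planted truth.  Everything is deterministic given the seed.

What this does not emulate: realistic nucleotide composition, CpG islands,
spatially autocorrelated background signal, or read-level noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import GeneAnnotation, MotifPFM, RawTrack, write_annotation, write_fasta, write_jaspar
from .preprocess import RegionSpec

__all__ = [
    "CausalWindow",
    "SynthConfig",
    "GroundTruth",
    "SynthStudy",
    "generate_study",
    "oracle_r2",
    "default_planted_motif",
    "decoy_motifs",
    "causal_input_rows",
]

_MU_LO, _MU_HI = 0.1, 0.9  # gene-level latent signal range in causal windows
_BLOCK_JITTER = 0.05


@dataclass(frozen=True)
class CausalWindow:
    """A planted causal window: offsets relative to the TSS or TTS, gene-oriented.

    ``start``/``end`` are signed offsets (negative = upstream) with
    ``start < end``; ``weight`` multiplies the window's mean latent signal in
    the expression model.
    """

    track: str
    anchor: str  # 'tss' or 'tts'
    start: int
    end: int
    weight: float

    def __post_init__(self) -> None:
        if self.anchor not in ("tss", "tts"):
            raise ValueError(f"anchor must be 'tss' or 'tts', got {self.anchor!r}")
        if self.start >= self.end:
            raise ValueError("window start must be < end")


def default_planted_motif() -> MotifPFM:
    """A sharp synthetic 8-bp motif (85% consensus TGACGTCA per column)."""
    consensus = "TGACGTCA"
    counts = np.full((4, len(consensus)), 5.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 85.0
    return MotifPFM(motif_id="PLANTED.1", counts=counts)


def decoy_motifs(n: int, width: int = 8, seed: int = 0) -> list[MotifPFM]:
    """Random sharp consensus motifs (synthetic stand-ins for database motifs)."""
    rng = np.random.default_rng(seed)
    motifs = []
    for i in range(n):
        counts = np.full((4, width), 5.0)
        for j, b in enumerate(rng.integers(0, 4, width)):
            counts[b, j] = 85.0
        motifs.append(MotifPFM(motif_id=f"DECOY.{i + 1}", counts=counts))
    return motifs


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe the reference study: 2000 genes, three tracks of which
    one (H3K4me3) carries a single causal promoter window, a planted motif in
    60% of those windows, and observation noise sized so the oracle R^2 on
    the log scale is about 0.8.
    """

    n_genes: int = 2000
    tracks: tuple[tuple[str, str], ...] = (
        ("H3K4me3", "pvalue"),
        ("H3K27me3", "pvalue"),
        ("WGBS", "methylation"),
    )
    causal_windows: tuple[CausalWindow, ...] = (
        CausalWindow("H3K4me3", "tss", -220, -160, 2.0),
    )
    region_spec: RegionSpec = field(default_factory=lambda: RegionSpec(300, 100, 100, 100))
    motif: MotifPFM = field(default_factory=default_planted_motif)
    motif_rate: float = 0.6
    motif_effect: float = 0.3
    noise_sd: float = 0.24
    intercept: float = 2.5
    pscale: float = 3.0
    block: int = 20
    gene_length: int = 1000
    chrom_length: int | None = None
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        names = [n for n, _ in self.tracks]
        for cw in self.causal_windows:
            if cw.track not in names:
                raise ValueError(f"causal window track {cw.track!r} not among tracks")
            up = self.region_spec.tss_up if cw.anchor == "tss" else self.region_spec.tts_up
            down = self.region_spec.tss_down if cw.anchor == "tss" else self.region_spec.tts_down
            if cw.start < -up or cw.end > down:
                raise ValueError(
                    f"causal window [{cw.start},{cw.end}) outside the "
                    f"[-{up},+{down}) input window around the {cw.anchor}"
                )

    @property
    def slot(self) -> int:
        """Per-gene genomic footprint: windows plus margins, block-aligned."""
        spec = self.region_spec
        pad = max(spec.tss_up, spec.tss_down, spec.tts_up, spec.tts_down) + 2 * self.block
        raw = self.gene_length + 2 * pad
        return -(-raw // self.block) * self.block

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motif"] = {"motif_id": self.motif.motif_id, "counts": self.motif.counts.tolist()}
        d["region_spec"] = self.region_spec.to_dict()
        return d


def oracle_r2(cfg: SynthConfig) -> float:
    """R^2 an oracle (noiseless) predictor attains against the noisy targets.

    Signal variance on the log scale: sum_k w_k^2 Var(U[0.1, 0.9]) plus the
    Bernoulli variance of the motif effect; oracle R^2 = V / (V + noise_sd^2).
    """
    var_mu = (_MU_HI - _MU_LO) ** 2 / 12.0
    v = sum(cw.weight**2 for cw in cfg.causal_windows) * var_mu
    v += cfg.motif_effect**2 * cfg.motif_rate * (1.0 - cfg.motif_rate)
    if v == 0:
        return 0.0
    return v / (v + cfg.noise_sd**2)


@dataclass
class GroundTruth:
    """Per-gene planted truth plus study-level quantities."""

    genes: dict[str, dict]
    weights: dict[str, float]
    noise_sd: float
    oracle_r2: float
    realized_oracle_r2: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "genes": self.genes,
                    "weights": self.weights,
                    "noise_sd": self.noise_sd,
                    "oracle_r2": self.oracle_r2,
                    "realized_oracle_r2": self.realized_oracle_r2,
                },
                fh,
                indent=1,
            )


@dataclass
class SynthStudy:
    """File outputs of one generated study plus its in-memory ground truth."""

    outdir: Path
    fasta: Path
    annotation: Path
    tracks: dict[str, Path]
    expression: Path
    motifs: Path
    ground_truth: GroundTruth
    config: SynthConfig


def _window_span(tss: int, tts: int, strand: str, cw: CausalWindow) -> tuple[int, int]:
    """Genomic [start, end) of a gene-oriented window, mirroring '-' genes."""
    anchor = tss if cw.anchor == "tss" else tts
    if strand == "+":
        return anchor + cw.start, anchor + cw.end
    return anchor - cw.end + 1, anchor - cw.start + 1


def causal_input_rows(cfg: SynthConfig) -> list[tuple[CausalWindow, int, int]]:
    """Input-matrix row range [start, end) of each causal window.

    Row indexing is strand-independent because assembled inputs are
    gene-oriented: row 0 is the most-upstream base of the TSS window.
    """
    spec = cfg.region_spec
    out = []
    for cw in cfg.causal_windows:
        base = spec.tss_up if cw.anchor == "tss" else spec.tss_up + spec.tss_down + spec.tts_up
        out.append((cw, base + cw.start, base + cw.end))
    return out


def _sample_motif(motif: MotifPFM, rng: np.random.Generator) -> str:
    probs = motif.counts / motif.counts.sum(axis=0)
    return "".join("ACGT"[rng.choice(4, p=probs[:, j])] for j in range(motif.width))


_RC = str.maketrans("ACGT", "TGCA")


def generate_study(cfg: SynthConfig, outdir) -> SynthStudy:
    """Write a complete study (FASTA, annotation, tracks, expression, motif, truth).

    All outputs are deterministic given ``cfg.seed``.  Raises if the requested
    ``chrom_length`` cannot host ``n_genes`` non-overlapping genes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # independent streams per purpose, so that e.g. adding a second causal
    # window to a config leaves the sequences, noise, and the first window's
    # values of the same seed untouched (paired study conditions)
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_background, rng_seq, rng_motif, rng_noise = (np.random.default_rng(c) for c in children)
    window_streams = [
        np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(100 + k,)))
        for k in range(len(cfg.causal_windows))
    ]
    spec = cfg.region_spec
    slot = cfg.slot
    needed = cfg.n_genes * slot + 2 * cfg.block
    chrom_length = cfg.chrom_length if cfg.chrom_length is not None else needed
    chrom_length = -(-chrom_length // cfg.block) * cfg.block
    if chrom_length < needed:
        raise ValueError(
            f"chromosome length {chrom_length} cannot host {cfg.n_genes} "
            f"non-overlapping genes (need >= {needed}); use a longer chromosome"
        )
    n_blocks = chrom_length // cfg.block

    # --- latent block values per track -----------------------------------
    track_names = [n for n, _ in cfg.tracks]
    latent = {name: rng_background.uniform(0.0, 1.0, n_blocks) for name in track_names}

    # --- gene placement, alternating strands ------------------------------
    pad = (slot - cfg.gene_length) // 2
    genes: list[dict] = []
    for i in range(cfg.n_genes):
        s0 = cfg.block + i * slot
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss = s0 + pad
            tts = tss + cfg.gene_length
        else:
            tss = s0 + pad + cfg.gene_length
            tts = tss - cfg.gene_length
        genes.append({"gene_id": f"g{i:05d}", "tss": tss, "tts": tts, "strand": strand})

    # --- plant causal windows ---------------------------------------------
    truth_genes: dict[str, dict] = {}
    for g in genes:
        entry = {"strand": g["strand"], "tss": g["tss"], "tts": g["tts"], "windows": []}
        for k, cw in enumerate(cfg.causal_windows):
            wrng = window_streams[k]
            mu = float(wrng.uniform(_MU_LO, _MU_HI))
            w_start, w_end = _window_span(g["tss"], g["tts"], g["strand"], cw)
            b0, b1 = w_start // cfg.block, -(-w_end // cfg.block)
            vals = np.clip(
                mu + wrng.normal(0.0, _BLOCK_JITTER, b1 - b0), 0.02, 0.98
            )
            latent[cw.track][b0:b1] = vals
            # the mean latent signal over the exact window span (the truth
            # the expression model uses)
            base_idx = np.arange(w_start, w_end) // cfg.block
            mean_signal = float(latent[cw.track][base_idx].mean())
            entry["windows"].append(
                {
                    "track": cw.track,
                    "anchor": cw.anchor,
                    "genomic_start": int(w_start),
                    "genomic_end": int(w_end),
                    "weight": cw.weight,
                    "mean_signal": mean_signal,
                }
            )
        truth_genes[g["gene_id"]] = entry

    # --- sequence with motif insertions -----------------------------------
    codes = rng_seq.integers(0, 4, chrom_length).astype(np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytearray(lut[codes].tobytes())
    promoter_windows = [cw for cw in cfg.causal_windows if cw.anchor == "tss"]
    for g in genes:
        entry = truth_genes[g["gene_id"]]
        entry["motif_inserted"] = False
        entry["motif_position"] = None
        if not promoter_windows or rng_motif.random() >= cfg.motif_rate:
            continue
        cw = promoter_windows[0]
        w_start, w_end = _window_span(g["tss"], g["tts"], g["strand"], cw)
        sampled = _sample_motif(cfg.motif, rng_motif)
        if g["strand"] == "-":
            sampled = sampled[::-1].translate(_RC)
        pos = int(rng_motif.integers(w_start, w_end - cfg.motif.width + 1))
        seq[pos : pos + cfg.motif.width] = sampled.encode("ascii")
        entry["motif_inserted"] = True
        entry["motif_position"] = pos
    genome = {cfg.chrom: seq.decode("ascii")}

    # --- expression --------------------------------------------------------
    weights = {f"{cw.track}:{cw.anchor}": cw.weight for cw in cfg.causal_windows}
    noiseless = np.empty(cfg.n_genes)
    tpm = np.empty(cfg.n_genes)
    eps = rng_noise.normal(0.0, cfg.noise_sd, cfg.n_genes)
    for i, g in enumerate(genes):
        entry = truth_genes[g["gene_id"]]
        log_e = cfg.intercept
        log_e += sum(w["weight"] * w["mean_signal"] for w in entry["windows"])
        if entry["motif_inserted"]:
            log_e += cfg.motif_effect
        noiseless[i] = log_e
        tpm[i] = float(np.exp(log_e + eps[i]))
        entry["noiseless_log_expression"] = float(log_e)
        entry["tpm"] = float(tpm[i])
    var_signal = float(np.var(noiseless))
    realized = (var_signal / (var_signal + cfg.noise_sd**2)
                if var_signal + cfg.noise_sd**2 > 0 else 0.0)

    # --- write files --------------------------------------------------------
    fasta_path = outdir / "genome.fa"
    write_fasta(genome, fasta_path)
    annot_path = outdir / "genes.tsv"
    annotation = [
        GeneAnnotation(g["gene_id"], cfg.chrom, g["tss"], g["tts"], g["strand"], float(tpm[i]))
        for i, g in enumerate(genes)
    ]
    write_annotation(annotation, annot_path)
    expr_path = outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene_id\ttpm\n")
        for i, g in enumerate(genes):
            fh.write(f"{g['gene_id']}\t{tpm[i]:.10g}\n")
    track_paths: dict[str, Path] = {}
    starts = np.arange(n_blocks) * cfg.block
    for name, kind in cfg.tracks:
        v = latent[name]
        values = np.power(10.0, -v * cfg.pscale) if kind == "pvalue" else v * 100.0
        path = outdir / f"{name}.bedGraph"
        with open(path, "w") as fh:
            for s, val in zip(starts, values):
                fh.write(f"{cfg.chrom}\t{s}\t{s + cfg.block}\t{val:.10g}\n")
        track_paths[name] = path
    motif_path = outdir / "motifs.jaspar"
    write_jaspar([cfg.motif], motif_path)
    truth = GroundTruth(
        genes=truth_genes,
        weights=weights,
        noise_sd=cfg.noise_sd,
        oracle_r2=oracle_r2(cfg),
        realized_oracle_r2=realized,
    )
    truth.to_json(outdir / "ground_truth.json")
    return SynthStudy(
        outdir=outdir,
        fasta=fasta_path,
        annotation=annot_path,
        tracks=track_paths,
        expression=expr_path,
        motifs=motif_path,
        ground_truth=truth,
        config=cfg,
    )


def read_study(outdir) -> tuple[list[GeneAnnotation], list[RawTrack], dict[str, str]]:
    """Convenience loader: re-read a generated study through the format readers."""
    from .io_formats import read_annotation, read_fasta, read_track

    outdir = Path(outdir)
    genes = read_annotation(outdir / "genes.tsv")
    genome = read_fasta(outdir / "genome.fa")
    tracks = []
    for path in sorted(outdir.glob("*.bedGraph")):
        name = path.stem
        kind = "methylation" if name.upper().startswith("WGBS") else "pvalue"
        tracks.append(read_track(path, kind=kind, name=name))
    return genes, tracks, genome
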