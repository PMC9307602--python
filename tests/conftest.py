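"""Shared fixtures: one reference synthetic study and models trained on it.

The reference study uses a reduced problem size (1000 genes, 600-bp inputs,
32/64-kernel model) so the full suite trains several networks in minutes;
docs/methods.md records these sizes.  Everything downstream (training,
shuffle control, ablations, attribution, the paired second condition) hangs
off these session fixtures so each network is trained exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from chromexpr.attribution import IGConfig, integrated_gradients
from chromexpr.model import Model, ModelConfig, build_model
from chromexpr.preprocess import (
    SplitDataset,
    assemble_dataset,
    build_trackset,
    split_dataset,
)
from chromexpr.synthetic import CausalWindow, SynthConfig, SynthStudy, generate_study, read_study
from chromexpr.training import EvalReport, TrainSpec, evaluate, train

SEED = 2026

REF_CONFIG = SynthConfig(n_genes=1000, seed=SEED)
# spans the whole TTS input window so the planted difference can dominate
# the pooled top-decile of differential sites
EXTRA_WINDOW = CausalWindow("H3K27me3", "tts", -100, 100, 2.0)
COND_B_CONFIG = SynthConfig(
    n_genes=1000, seed=SEED,
    causal_windows=REF_CONFIG.causal_windows + (EXTRA_WINDOW,),
)
MODEL_CONFIG = ModelConfig(k1=32, k2=64, fc_widths=(256, 128, 32, 1),
                           dropout=0.2, lambda_l2=1e-4)
TRAIN_SPEC = TrainSpec(epochs=50, batch=25, learning_rate=1e-3, patience=10, seed=SEED)
IG_STEPS_MAPS = 64  # steps for the bulk per-gene maps; completeness uses 200
N_MAP_GENES = 120


@dataclass
class Study:
    """A generated study plus everything preprocessed from it."""

    study: SynthStudy
    cfg: SynthConfig
    genome: dict
    track_names: list[str]
    split: SplitDataset
    trackset: object


def _prepare(cfg: SynthConfig, outdir) -> Study:
    study = generate_study(cfg, outdir)
    genes, tracks, genome = read_study(outdir)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    trackset = build_trackset(tracks, chrom_lengths, genes, cfg.region_spec)
    inputs = assemble_dataset(genes, trackset, genome, cfg.region_spec)
    split = split_dataset(inputs, seed=SEED)
    return Study(study=study, cfg=cfg, genome=genome, track_names=trackset.names,
                 split=split, trackset=trackset)


@pytest.fixture(scope="session")
def ref_study(tmp_path_factory) -> Study:
    return _prepare(REF_CONFIG, tmp_path_factory.mktemp("ref_study"))


@pytest.fixture(scope="session")
def ref_model(ref_study) -> tuple[Model, EvalReport]:
    model = build_model(MODEL_CONFIG, L=ref_study.cfg.region_spec.length,
                        m=len(ref_study.track_names), seed=SEED)
    model, _ = train(model, ref_study.split, TRAIN_SPEC)
    return model, evaluate(model, ref_study.split.test)


@pytest.fixture(scope="session")
def ref_maps(ref_study, ref_model):
    """IG attribution maps for the first test genes of the reference model."""
    model, _ = ref_model
    genes = ref_study.split.test[:N_MAP_GENES]
    cfg = IGConfig(steps=IG_STEPS_MAPS)
    return {g.gene_id: integrated_gradients(model, g, cfg) for g in genes}


@pytest.fixture(scope="session")
def cond_b(tmp_path_factory) -> tuple[Study, Model]:
    """Paired condition: same seed, one extra causal window, own trained model."""
    data = _prepare(COND_B_CONFIG, tmp_path_factory.mktemp("cond_b"))
    model = build_model(MODEL_CONFIG, L=data.cfg.region_spec.length,
                        m=len(data.track_names), seed=SEED)
    model, _ = train(model, data.split, TRAIN_SPEC)
    return data, model
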