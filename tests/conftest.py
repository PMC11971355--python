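"""Shared fixtures and pipeline helpers for the test suite.

The expensive fixtures (simulated datasets, trained models) are session- or
module-scoped so independent tests can share them.  Every source of
randomness is seeded; reruns are bit-identical.
"""

from __future__ import annotations

import numpy as np
import pytest

import plantmeth as pm


def make_record(kmer: str, label=None, seed: int = 0, read_id: str = "r0",
                chrom: str = "chr1", pos: int = 10, strand: str = "+"):
    """A lightweight FeatureRecord with plausible (seeded) matrices."""
    k = len(kmer)
    rng = np.random.default_rng(seed)
    seq = rng.normal(size=(k, 5))
    seq[:, 2] = 30.0
    seq[:, 3] = 9.0
    seq[:, 4] = [pm.types.BASE_CODES[b] for b in kmer]
    return pm.FeatureRecord(read_id=read_id, chrom=chrom, pos=pos, strand=strand,
                            kmer=kmer, seq_features=seq,
                            signal_features=rng.normal(size=(k, 15)), label=label)


def simulate_labeled_records(delta: float, seed: int, *, genome_length: int = 8000,
                             depth: float = 30.0, read_length_mean: int = 500,
                             mixture=((0.85, 0.0), (0.15, 1.0)), k: int = 9,
                             n_per_class: int = 2500):
    """Simulate a CHH dataset and return a class-balanced labeled record list.

    Labels come from BS-seq-selected reference sites (frequency-0 negatives,
    per-motif high-frequency positives), exactly as real training data would
    be assembled.
    """
    config = pm.SimConfig(genome_length=genome_length, depth=depth,
                          read_length_mean=read_length_mean,
                          meth_level_shift=delta, noise_sd=1.0, seed=seed)
    ref, truth, reads, report = pm.simulate_dataset(config, "CHH", list(mixture))
    sites = {s.key: s for s in pm.locate_motif_sites(ref, "CHH")}
    records = []
    for read in reads:
        if pm.filter_alignment(read).keep:
            records.extend(pm.extract_features(read, sites, k=k))
    truth_map = {s.key: s for s in report}
    positives, negatives = pm.select_reference_sites(truth_map, "CHH", min_coverage=5)
    labeled = pm.label_features(records, positives, negatives)
    rng = np.random.default_rng(seed)
    pos = [r for r in labeled if r.label == 1]
    neg = [r for r in labeled if r.label == 0]
    n = min(n_per_class, len(pos), len(neg))
    pos = [pos[i] for i in rng.choice(len(pos), n, replace=False)]
    neg = [neg[i] for i in rng.choice(len(neg), n, replace=False)]
    return pos + neg


def small_train_config(seed: int, max_epochs: int = 12) -> pm.TrainConfig:
    """Schedule for desk-scale runs: the default per-epoch decay of 0.2
    presumes epochs of ~5e5 optimizer steps; with tens of steps per epoch a
    gentler decay (0.9) over more epochs matches the intended total
    learning budget."""
    return pm.TrainConfig(seed=seed, batch_size=64, max_epochs=max_epochs,
                          lr_decay_per_epoch=0.9, early_stop_patience=max_epochs)


def small_model_config(k: int = 9, encoder: str = "transformer") -> pm.ModelConfig:
    return pm.ModelConfig(encoder_kind=encoder, k=k, seq_dim=24, sig_dim=24,
                          combine_dim=48, dropout_rate=0.0, n_heads=4)


@pytest.fixture(scope="session")
def chh_simulation():
    """A small CHH dataset shared across io/feature tests."""
    config = pm.SimConfig(genome_length=3000, depth=10, read_length_mean=300,
                          meth_level_shift=3.0, noise_sd=1.0, seed=11)
    ref, truth, reads, report = pm.simulate_dataset(
        config, "CHH", [(0.6, 0.0), (0.4, 1.0)])
    return {"config": config, "ref": ref, "truth": truth,
            "reads": reads, "report": report}


@pytest.fixture(scope="session")
def chh_sites(chh_simulation):
    return {s.key: s for s in pm.locate_motif_sites(chh_simulation["ref"], "CHH")}
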