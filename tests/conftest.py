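"""Shared fixtures: PWM libraries and planted-motif sequence datasets."""

from __future__ import annotations

import numpy as np
import pytest

from irdhs import (
    SimulationConfig,
    one_hot_batch,
    plant_motif_sequences,
    random_pwm,
    revcomp,
)


@pytest.fixture(scope="session")
def pwm_library():
    """Eleven sharp 12-bp PWMs with JASPAR-style ids; index 3 is 'causal'."""
    rng = np.random.default_rng(42)
    return [random_pwm(f"MA{i:04d}.1", 12, rng, name=f"TF{i}") for i in range(11)]


@pytest.fixture(scope="session")
def causal_pwm(pwm_library):
    return pwm_library[3]


@pytest.fixture(scope="session")
def separable_seqs(causal_pwm):
    """Separable two-class set: causal motif planted in every IR sequence,
    never in non-IR; 600 bp, n=2000."""
    cfg = SimulationConfig(
        n_ir=1000,
        n_nonir=1000,
        seq_len=600,
        seed=5,
        plant_prob_ir={causal_pwm.id: 1.0},
        plant_prob_nonir={causal_pwm.id: 0.0},
    )
    seqs, labels, log = plant_motif_sequences(cfg, [causal_pwm])
    return seqs, labels, log


@pytest.fixture(scope="session")
def separable_split(separable_seqs):
    """One-hot train/test split of the separable set, training half
    augmented with reverse complements (the loading-time augmentation the
    data pipeline prescribes)."""
    seqs, labels, _ = separable_seqs
    X = one_hot_batch(seqs)
    order = np.random.default_rng(1).permutation(len(X))
    tr, te = order[:1600], order[1600:]
    Xtr = np.concatenate([X[tr], one_hot_batch([revcomp(seqs[i]) for i in tr])])
    ytr = np.concatenate([labels[tr], labels[tr]])
    return Xtr, ytr, X[te], labels[te]


@pytest.fixture(scope="session")
def small_motif_data(causal_pwm):
    """Small 200-bp planted set for fast interpretation unit tests."""
    cfg = SimulationConfig(
        n_ir=120,
        n_nonir=120,
        seq_len=200,
        seed=11,
        plant_prob_ir={causal_pwm.id: 1.0},
        plant_prob_nonir={causal_pwm.id: 0.0},
    )
    seqs, labels, log = plant_motif_sequences(cfg, [causal_pwm])
    return seqs, labels, log
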