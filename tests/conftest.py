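import numpy as np
import pytest

from ceilstop import PopulationSpec, TrainingTrace, calibrate_separation


@pytest.fixture
def u_shaped_trace() -> TrainingTrace:
    """Small hand-built trace with a clear validation-loss minimum at epoch 3."""
    return TrainingTrace.from_arrays(
        val_loss=[1.0, 0.6, 0.4, 0.5, 0.7, 0.9],
        train_loss=[1.0, 0.7, 0.5, 0.35, 0.25, 0.2],
        train_acc=[0.60, 0.70, 0.80, 0.88, 0.94, 0.98],
        val_acc=[0.55, 0.65, 0.75, 0.74, 0.70, 0.66],
    )


@pytest.fixture
def small_spec() -> PopulationSpec:
    """A small, well-separated population for fast training tests."""
    spec = PopulationSpec(
        dim=4,
        mu0=np.zeros(4),
        mu1=np.ones(4),
        sigma=1.0,
        tau=0.3,
        channel_matrix=np.eye(4)[:3],
        channel_noise=0.8,
        n_subjects0=10,
        n_subjects1=12,
        records_per_subject_mean=12.0,
        records_per_subject_sd=3.0,
        seed=7,
    )
    return calibrate_separation(spec, 0.95)


def random_population_spec(rng: np.random.Generator) -> PopulationSpec:
    """Random valid spec for property tests (full-rank channel covariance)."""
    dim = int(rng.integers(1, 7))
    k = int(rng.integers(1, 7))
    return PopulationSpec(
        dim=dim,
        mu0=rng.normal(size=dim),
        mu1=rng.normal(size=dim),
        sigma=float(rng.uniform(0.3, 2.0)),
        tau=float(rng.uniform(0.0, 1.0)),
        channel_matrix=rng.normal(size=(k, dim)),
        channel_noise=float(rng.uniform(0.2, 2.0)),
        n_subjects0=4,
        n_subjects1=4,
        records_per_subject_mean=5.0,
        records_per_subject_sd=2.0,
        seed=int(rng.integers(2**31 - 1)),
    )


def random_trace(rng: np.random.Generator, max_len: int = 500) -> TrainingTrace:
    """Random noisy U-shaped-ish trace with accuracies, for rule fuzzing."""
    n = int(rng.integers(2, max_len + 1))
    t = np.arange(1, n + 1)
    base = 0.2 + rng.uniform(0.5, 1.5) * np.exp(-t / rng.uniform(2, n)) + rng.uniform(
        0, 1
    ) * (1 - np.exp(-t / rng.uniform(2, 2 * n)))
    # floor losses slightly above zero: a zero running minimum followed by a
    # rise makes relative GL undefined (the rules raise on it by contract)
    val = np.clip(base + rng.normal(0, rng.uniform(0, 0.1), n), 1e-6, None)
    train = np.clip(base * rng.uniform(0.5, 1.0) - rng.uniform(0, 0.05), 1e-6, None)
    return TrainingTrace.from_arrays(
        val_loss=val,
        train_loss=train,
        train_acc=1.0 / (1.0 + train),
        val_acc=1.0 / (1.0 + val),
    )
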