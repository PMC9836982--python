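"""Synthetic paired direct/indirect datasets with known Bayes accuracies.

The generator emulates a two-class repeated-measures study: each subject
belongs to class 0 or 1, carries a Gaussian random effect, and contributes
several records. Each record is observed twice — through a *direct*
channel (the latent feature vector itself plus within-subject noise, the
analogue of an invasive physiological measurement) and through an
*indirect* channel (a linear transform of the direct record plus extra
noise, the analogue of a non-invasive surrogate). Because both channels
are Gaussian with equal class covariances, the Bayes-optimal accuracy of
each is available in closed form, and the data-processing inequality —
the indirect channel can never beat the direct one — holds by
construction. That makes the population a controlled test bed for the
information-ceiling stopping criterion.

The module also provides a parametric validation-loss curve simulator
(double-exponential U-shape) whose minimum has a closed form, used for
deterministic testing of stopping rules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trace import EpochRecord, TrainingTrace

__all__ = [
    "PopulationSpec",
    "PairedDataset",
    "LossCurveParams",
    "PARTITIONS",
    "bayes_accuracy",
    "calibrate_separation",
    "sample_paired_dataset",
    "split_grouped",
    "simulate_loss_curve",
]

PARTITIONS = ("train", "val", "test_subset", "test_novel")

# Study-shaped defaults: two classes of 35 and 42 subjects, ~22.63 records
# per subject (SD 7.13), mirroring a repeated-measures cardiac study in
# which each animal contributes many heartbeats.
DEFAULT_N_SUBJECTS = (35, 42)
DEFAULT_RECORDS_PER_SUBJECT = (22.63, 7.13)


@dataclass(frozen=True)
class PopulationSpec:
    """Population and measurement-channel specification.

    Direct records: x = mu_y + u_s + e with subject effect
    u_s ~ N(0, tau²·I) and within-subject noise e ~ N(0, sigma²·I).
    Indirect records: z = A·x + eps with eps ~ N(0, channel_noise²·I).
    Marginally over subjects, x | y ~ N(mu_y, (sigma²+tau²)·I), so both
    channels are homoscedastic Gaussian classification problems with
    closed-form Bayes accuracy (see :func:`bayes_accuracy`).
    """

    dim: int
    mu0: np.ndarray
    mu1: np.ndarray
    sigma: float = 1.0
    tau: float = 0.5
    channel_matrix: Optional[np.ndarray] = None
    channel_noise: float = 1.0
    n_subjects0: int = DEFAULT_N_SUBJECTS[0]
    n_subjects1: int = DEFAULT_N_SUBJECTS[1]
    records_per_subject_mean: float = DEFAULT_RECORDS_PER_SUBJECT[0]
    records_per_subject_sd: float = DEFAULT_RECORDS_PER_SUBJECT[1]
    seed: int = 0

    def __post_init__(self) -> None:
        mu0 = np.asarray(self.mu0, dtype=float)
        mu1 = np.asarray(self.mu1, dtype=float)
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "mu1", mu1)
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if mu0.shape != (self.dim,) or mu1.shape != (self.dim,):
            raise ValueError(f"class means must be vectors of length {self.dim}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.channel_matrix is not None:
            A = np.atleast_2d(np.asarray(self.channel_matrix, dtype=float))
            if A.shape[1] != self.dim:
                raise ValueError(f"channel_matrix must have {self.dim} columns")
            object.__setattr__(self, "channel_matrix", A)
        if self.channel_noise < 0:
            raise ValueError("channel_noise must be >= 0")
        if self.n_subjects0 < 1 or self.n_subjects1 < 1:
            raise ValueError("subject counts must be positive")
        if self.records_per_subject_mean <= 0 or self.records_per_subject_sd <= 0:
            raise ValueError("records-per-subject parameters must be positive")

    @property
    def k(self) -> int:
        """Indirect-channel dimension."""
        A = self._channel()
        return A.shape[0]

    def _channel(self) -> np.ndarray:
        if self.channel_matrix is None:
            return np.eye(self.dim)
        return self.channel_matrix

    @property
    def marginal_var(self) -> float:
        """Per-coordinate class-conditional variance of a direct record."""
        return self.sigma**2 + self.tau**2

    @classmethod
    def study_default(
        cls,
        dim: int = 12,
        k: int = 8,
        target_direct_acc: float = 0.97,
        seed: int = 0,
    ) -> "PopulationSpec":
        """A study-shaped population: 35 + 42 subjects, ~22.63 records each,
        direct channel calibrated to the given Bayes accuracy, and an
        indirect channel that keeps ``k`` of the ``dim`` coordinates and
        adds unit noise (a genuinely degraded surrogate).
        """
        if not 1 <= k <= dim:
            raise ValueError("need 1 <= k <= dim")
        A = np.eye(dim)[:k]
        spec = cls(
            dim=dim,
            mu0=np.zeros(dim),
            mu1=np.ones(dim),
            channel_matrix=A,
            seed=seed,
        )
        return calibrate_separation(spec, target_direct_acc)


def _channel_moments(spec: PopulationSpec, channel: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class means and shared covariance of the chosen channel."""
    v = spec.marginal_var
    if channel == "direct":
        mean0, mean1 = spec.mu0, spec.mu1
        cov = v * np.eye(spec.dim)
    elif channel == "indirect":
        A = spec._channel()
        mean0, mean1 = A @ spec.mu0, A @ spec.mu1
        cov = v * (A @ A.T) + spec.channel_noise**2 * np.eye(A.shape[0])
    else:
        raise ValueError(f"unknown channel '{channel}'")
    return mean0, mean1, cov


def _mahalanobis_delta(spec: PopulationSpec, channel: str) -> float:
    mean0, mean1, cov = _channel_moments(spec, channel)
    diff = mean1 - mean0
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "channel covariance is singular; set channel_noise > 0 so the "
            "indirect covariance is full rank"
        ) from None
    w = np.linalg.solve(L, diff)
    return float(np.sqrt(w @ w))


def bayes_accuracy(
    spec: PopulationSpec,
    channel: str = "direct",
    method: str = "closed_form",
    n_draws: int = 1_000_000,
    seed: Optional[int] = None,
) -> float:
    """Bayes-optimal accuracy of the chosen measurement channel.

    With equal priors and a shared class covariance Σ, the optimal rule is
    linear and its accuracy is Φ(Δ/2) where
    Δ = sqrt((μ₁−μ₀)ᵀ Σ⁻¹ (μ₁−μ₀)) is the Mahalanobis separation between
    the class means. ``method='monte_carlo'`` checks the same number by
    applying the optimal linear rule to simulated draws (use for general
    covariances or unequal priors where the closed form does not apply).
    """
    if method == "closed_form":
        delta = _mahalanobis_delta(spec, channel)
        return float(norm.cdf(delta / 2.0))
    if method != "monte_carlo":
        raise ValueError(f"unknown method '{method}'")
    mean0, mean1, cov = _channel_moments(spec, channel)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "channel covariance is singular; set channel_noise > 0"
        ) from None
    half = n_draws // 2
    w = np.linalg.solve(cov, mean1 - mean0)
    mid = 0.5 * (mean0 + mean1)
    correct = 0
    for mean, want_positive, n in ((mean0, False, half), (mean1, True, n_draws - half)):
        z = mean + rng.standard_normal((n, len(mean))) @ L.T
        score = (z - mid) @ w
        correct += int(np.sum((score > 0) == want_positive))
    return correct / n_draws


def calibrate_separation(spec: PopulationSpec, target_acc: float) -> PopulationSpec:
    """Rescale mu1 − mu0 so the *direct* channel's Bayes accuracy equals
    ``target_acc``; everything else is unchanged.

    The direct separation is Δ = |mu1 − mu0| / sqrt(sigma² + tau²) and
    Bayes accuracy Φ(Δ/2), so the required separation is 2·Φ⁻¹(target).
    """
    if not 0.5 < target_acc < 1:
        raise ValueError("target accuracy must lie in (0.5, 1)")
    diff = spec.mu1 - spec.mu0
    norm_diff = float(np.linalg.norm(diff))
    if norm_diff == 0:
        raise ValueError("cannot calibrate a spec with identical class means")
    target_delta = 2.0 * float(norm.ppf(target_acc))
    scale = target_delta * math.sqrt(spec.marginal_var) / norm_diff
    return replace(spec, mu1=spec.mu0 + scale * diff)


class PairedDataset:
    """Labelled records with subject ids, paired channel features, and
    partition tags, backed by a pandas DataFrame.

    Columns: ``subject_id, label, partition, d1..d<dim>, i1..i<k>``.
    Partition is one of ``train/val/test_subset/test_novel`` once split
    (``unassigned`` before).
    """

    def __init__(self, frame: pd.DataFrame, dim: int, k: int, spec: Optional[PopulationSpec] = None):
        expected = ["subject_id", "label", "partition"]
        expected += [f"d{i+1}" for i in range(dim)] + [f"i{j+1}" for j in range(k)]
        missing = [c for c in expected if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset frame is missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.dim = dim
        self.k = k
        self.spec = spec

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def direct_columns(self) -> list[str]:
        return [f"d{i+1}" for i in range(self.dim)]

    @property
    def indirect_columns(self) -> list[str]:
        return [f"i{j+1}" for j in range(self.k)]

    def channel_columns(self, channel: str) -> list[str]:
        if channel == "direct":
            return self.direct_columns
        if channel == "indirect":
            return self.indirect_columns
        if channel == "combined":
            return self.direct_columns + self.indirect_columns
        raise ValueError(f"unknown channel '{channel}'")

    def subset(self, partition: str) -> pd.DataFrame:
        return self.frame[self.frame["partition"] == partition]

    def features(self, channel: str, partition: Optional[str] = None) -> np.ndarray:
        df = self.frame if partition is None else self.subset(partition)
        return df[self.channel_columns(channel)].to_numpy(dtype=float)

    def labels(self, partition: Optional[str] = None) -> np.ndarray:
        df = self.frame if partition is None else self.subset(partition)
        return df["label"].to_numpy(dtype=int)

    def with_partitions(self, partition: pd.Series) -> "PairedDataset":
        frame = self.frame.copy()
        frame["partition"] = partition.to_numpy()
        return PairedDataset(frame, self.dim, self.k, self.spec)

    def to_csv(self, path: str | Path) -> None:
        """Write records as CSV plus a JSON sidecar with the population spec."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = {"dim": self.dim, "k": self.k}
        if self.spec is not None:
            sidecar["spec"] = _spec_to_dict(self.spec)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedDataset":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        spec = None
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
            dim, k = sidecar["dim"], sidecar["k"]
            if "spec" in sidecar:
                spec = _spec_from_dict(sidecar["spec"])
        else:
            dim = sum(c.startswith("d") and c[1:].isdigit() for c in frame.columns)
            k = sum(c.startswith("i") and c[1:].isdigit() for c in frame.columns)
        return cls(frame, dim, k, spec)


def _spec_to_dict(spec: PopulationSpec) -> dict:
    d = {
        "dim": spec.dim,
        "mu0": spec.mu0.tolist(),
        "mu1": spec.mu1.tolist(),
        "sigma": spec.sigma,
        "tau": spec.tau,
        "channel_matrix": None if spec.channel_matrix is None else spec.channel_matrix.tolist(),
        "channel_noise": spec.channel_noise,
        "n_subjects0": spec.n_subjects0,
        "n_subjects1": spec.n_subjects1,
        "records_per_subject_mean": spec.records_per_subject_mean,
        "records_per_subject_sd": spec.records_per_subject_sd,
        "seed": spec.seed,
    }
    return d


def _spec_from_dict(d: dict) -> PopulationSpec:
    d = dict(d)
    d["mu0"] = np.asarray(d["mu0"], dtype=float)
    d["mu1"] = np.asarray(d["mu1"], dtype=float)
    if d.get("channel_matrix") is not None:
        d["channel_matrix"] = np.asarray(d["channel_matrix"], dtype=float)
    return PopulationSpec(**d)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent named substreams from one seed, so e.g. changing the
    record noise does not perturb subject effects."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_paired_dataset(spec: PopulationSpec) -> PairedDataset:
    """Draw a full paired dataset from the population.

    For each subject: a subject effect u_s ~ N(0, tau²·I); a record count
    from a rounded Normal(records_per_subject_mean, records_per_subject_sd)
    truncated to at least 1; then per record the direct features
    x = mu_y + u_s + e and the indirect features z = A·x + eps.
    Fully reproducible from ``spec.seed``. Partitions start ``unassigned``.
    """
    rng_subjects, rng_counts, rng_direct, rng_channel = _substreams(spec.seed, 4)
    A = spec._channel()
    k = A.shape[0]
    rows_subject, rows_label = [], []
    direct_blocks, indirect_blocks = [], []
    subject_id = 0
    for label, n_subjects in ((0, spec.n_subjects0), (1, spec.n_subjects1)):
        mu = spec.mu0 if label == 0 else spec.mu1
        for _ in range(n_subjects):
            u = rng_subjects.standard_normal(spec.dim) * spec.tau
            m = int(
                round(
                    rng_counts.normal(spec.records_per_subject_mean, spec.records_per_subject_sd)
                )
            )
            m = max(m, 1)
            e = rng_direct.standard_normal((m, spec.dim)) * spec.sigma
            x = mu + u + e
            eps = rng_channel.standard_normal((m, k)) * spec.channel_noise
            z = x @ A.T + eps
            direct_blocks.append(x)
            indirect_blocks.append(z)
            rows_subject.extend([subject_id] * m)
            rows_label.extend([label] * m)
            subject_id += 1
    direct = np.vstack(direct_blocks)
    indirect = np.vstack(indirect_blocks)
    frame = pd.DataFrame({"subject_id": rows_subject, "label": rows_label})
    frame["partition"] = "unassigned"
    for i in range(spec.dim):
        frame[f"d{i+1}"] = direct[:, i]
    for j in range(k):
        frame[f"i{j+1}"] = indirect[:, j]
    return PairedDataset(frame, spec.dim, k, spec)


def _largest_remainder(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Split n items into three groups matching fractions as closely as
    possible (largest-remainder rounding; exact partition of n)."""
    raw = [n * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    remainders = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def split_grouped(
    data: PairedDataset,
    fractions: tuple[float, float, float] = (0.80, 0.16, 0.04),
    mode: str = "record",
    seed: int = 0,
) -> PairedDataset:
    """Assign train/val/test partitions, stratified by class.

    ``record`` mode shuffles and splits individual records (the test
    partition is labelled ``test_subset`` — its subjects also appear in
    training). ``subject`` mode assigns whole subjects to partitions, so
    the test partition (``test_novel``) contains only unseen subjects.
    Counts follow largest-remainder rounding within each class.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions) or abs(sum(fractions) - 1) > 1e-9:
        raise ValueError("fractions must be three positive numbers summing to 1")
    if mode not in {"record", "subject"}:
        raise ValueError(f"unknown split mode '{mode}'")
    test_label = "test_subset" if mode == "record" else "test_novel"
    part_names = ["train", "val", test_label]
    rng = np.random.default_rng(seed)
    partition = pd.Series("unassigned", index=data.frame.index, dtype=object)
    for label in (0, 1):
        cls_mask = data.frame["label"] == label
        if mode == "record":
            idx = data.frame.index[cls_mask].to_numpy()
            rng.shuffle(idx)
            counts = _largest_remainder(len(idx), tuple(fractions))
            _check_counts(counts, part_names, f"class {label}")
            bounds = np.cumsum(counts)
            partition.loc[idx[: bounds[0]]] = "train"
            partition.loc[idx[bounds[0] : bounds[1]]] = "val"
            partition.loc[idx[bounds[1] :]] = test_label
        else:
            subjects = np.sort(data.frame.loc[cls_mask, "subject_id"].unique())
            rng.shuffle(subjects)
            counts = _largest_remainder(len(subjects), tuple(fractions))
            _check_counts(counts, part_names, f"class {label} (subjects)")
            bounds = np.cumsum(counts)
            for name, group in zip(
                part_names,
                (subjects[: bounds[0]], subjects[bounds[0] : bounds[1]], subjects[bounds[1] :]),
            ):
                partition.loc[data.frame["subject_id"].isin(group) & cls_mask] = name
    return data.with_partitions(partition)


def _check_counts(counts: list[int], names: list[str], what: str) -> None:
    for c, name in zip(counts, names):
        if c == 0:
            raise ValueError(
                f"partition '{name}' would be empty for {what}; "
                "provide more data or larger fractions"
            )


@dataclass(frozen=True)
class LossCurveParams:
    """Parametric U-shaped validation-loss curve.

    val_loss(t) = a + b·exp(−t/tau1) + c·(1 − exp(−t/tau2)) + noise, a
    fast-decaying fit term plus a slow-growing overfitting term. With
    b, c > 0 and tau2 > tau1 the noiseless curve has a unique interior
    minimum at t* = ln(b·tau2 / (c·tau1)) / (1/tau1 − 1/tau2).
    """

    a: float = 0.1
    b: float = 1.0
    c: float = 0.5
    tau1: float = 10.0
    tau2: float = 100.0
    noise_sd: float = 0.0
    horizon: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("a, b, c must be >= 0")
        if self.tau1 <= 0 or self.tau2 <= self.tau1:
            raise ValueError("need 0 < tau1 < tau2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")

    def minimum_time(self) -> float:
        """Closed-form stationary point of the noiseless curve."""
        if self.b <= 0 or self.c <= 0:
            raise ValueError("interior minimum requires b > 0 and c > 0")
        return math.log(self.b * self.tau2 / (self.c * self.tau1)) / (1 / self.tau1 - 1 / self.tau2)


def simulate_loss_curve(params: LossCurveParams) -> TrainingTrace:
    """Simulate a training trace from the parametric curve family.

    Training loss decays monotonically (a·exp(−t/tau1)); accuracies are a
    monotone proxy acc = 1/(1 + loss) — only the ordering of values
    matters to the stopping rules. Noisy validation losses are clipped at
    zero to keep them valid losses.
    """
    t = np.arange(1, params.horizon + 1, dtype=float)
    val = (
        params.a
        + params.b * np.exp(-t / params.tau1)
        + params.c * (1.0 - np.exp(-t / params.tau2))
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        val = val + params.noise_sd * rng.standard_normal(params.horizon)
        val = np.clip(val, 0.0, None)
    train = params.a * np.exp(-t / params.tau1)
    records = tuple(
        EpochRecord(
            epoch=int(ti),
            train_loss=float(train[i]),
            val_loss=float(val[i]),
            train_acc=float(1.0 / (1.0 + train[i])),
            val_acc=float(1.0 / (1.0 + val[i])),
        )
        for i, ti in enumerate(t)
    )
    meta = {"curve_params": {k: getattr(params, k) for k in (
        "a", "b", "c", "tau1", "tau2", "noise_sd", "horizon", "seed")}}
    return TrainingTrace(records, meta)
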