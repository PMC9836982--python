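"""Early-stopping criteria for training traces.

Implements the classical trace-derived heuristics — generalization loss
(GL), its strip-smoothed variant (progress quotient, PQ), fixed patience,
and the Deng–Kwok dynamic-patience rule — alongside an *information
ceiling* criterion: stop as soon as the monitored accuracy reaches the
best accuracy attainable from a more direct measurement of the same
biology. Accuracy beyond that ceiling cannot reflect real signal and is
taken as the onset of memorization.

Every rule maps a :class:`~ceilstop.trace.TrainingTrace` to a
:class:`~ceilstop.trace.StopDecision`. Rules scan the trace epoch by
epoch, so applying a rule post hoc to a full trace and replaying it online
yield identical decisions. A rule that never fires reports
``stop_epoch=None`` and falls back to the oracle epoch over the full
horizon, matching post-hoc usage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional

import numpy as np

from .trace import StopDecision, TrainingTrace, oracle_epoch

__all__ = [
    "RuleParams",
    "CeilingSpec",
    "InvalidCeilingError",
    "stop_gl",
    "stop_patience",
    "stop_dk",
    "stop_ceiling",
    "establish_ceiling",
    "RULE_REGISTRY",
    "make_rule",
    "apply_named_rules",
]


@dataclass(frozen=True)
class RuleParams:
    """Parameters shared by all stopping rules.

    gl_threshold
        Trigger level for GL/PQ. In ``relative_percent`` mode it is a
        percentage (default 5, i.e. stop when validation loss sits 5%
        above its running minimum). In ``fraction_of_initial`` mode the
        excess ``E_va(t) − min E_va`` is compared against
        ``gl_threshold · E_va(1)``, so a value like 0.05 means "5% of the
        initial loss".
    strip_n
        Strip length for the PQ smoothing; 1 gives plain GL.
    patience_n
        Consecutive non-improving epochs tolerated by the patience rule.
    dk_initial_patience, dk_multiplier, dk_increment
        Deng–Kwok dynamic patience: an epoch whose validation loss falls
        below ``dk_multiplier`` × (previous minimum) earns
        ``dk_increment · t`` extra patience; training stops when the
        patience budget drops below the epoch index.
    ceiling, ceiling_margin, ceiling_metric
        Information-ceiling rule: stop when the monitored accuracy
        (training accuracy by default) reaches ``ceiling − ceiling_margin``.
    """

    gl_threshold: float = 5.0
    gl_mode: str = "relative_percent"
    strip_n: int = 1
    patience_n: int = 3
    dk_initial_patience: float = 10.0
    dk_multiplier: float = 0.996
    dk_increment: float = 0.3
    ceiling: Optional[float] = None
    ceiling_margin: float = 0.0
    ceiling_metric: str = "train_acc"

    def __post_init__(self) -> None:
        if self.gl_threshold <= 0:
            raise ValueError("gl_threshold must be positive")
        if self.gl_mode not in {"relative_percent", "fraction_of_initial"}:
            raise ValueError(f"unknown gl_mode '{self.gl_mode}'")
        if self.strip_n < 1:
            raise ValueError("strip_n must be >= 1")
        if self.patience_n < 1:
            raise ValueError("patience_n must be >= 1")
        if self.dk_initial_patience <= 0:
            raise ValueError("dk_initial_patience must be positive")
        if not 0 < self.dk_multiplier < 1:
            raise ValueError("dk_multiplier must lie in (0, 1)")
        if self.dk_increment <= 0:
            raise ValueError("dk_increment must be positive")
        if self.ceiling is not None and not 0 < self.ceiling <= 1:
            raise ValueError("ceiling must lie in (0, 1]")
        if self.ceiling_margin < 0:
            raise ValueError("ceiling_margin must be >= 0")
        if self.ceiling_metric not in {"train_acc", "val_acc"}:
            raise ValueError(f"unknown ceiling_metric '{self.ceiling_metric}'")


@dataclass(frozen=True)
class CeilingSpec:
    """An information ceiling with its provenance.

    ``value`` is the accuracy attained on the direct channel;
    ``corroborated`` records whether an independent simpler model (here,
    logistic regression with recursive feature elimination) agreed with it
    to within a tolerance. An uncorroborated ceiling should be treated
    with suspicion.
    """

    value: float
    margin: float = 0.0
    corroborated: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.value <= 1:
            raise InvalidCeilingError(f"ceiling value must lie in (0, 1], got {self.value}")
        if self.margin < 0:
            raise InvalidCeilingError("ceiling margin must be >= 0")
        if self.value - self.margin <= 0:
            raise InvalidCeilingError(
                f"effective trigger level {self.value - self.margin} must be positive"
            )

    @property
    def trigger_level(self) -> float:
        return self.value - self.margin


class InvalidCeilingError(ValueError):
    """The ceiling value/margin combination cannot trigger any rule."""


def _decision(
    name: str,
    params: Mapping,
    trace: TrainingTrace,
    stop_epoch: Optional[int],
) -> StopDecision:
    """Common selection semantics: best-validation epoch up to the stop."""
    if stop_epoch is None:
        return StopDecision(name, dict(params), None, oracle_epoch(trace), False)
    selected = int(np.argmin(trace.val_loss[:stop_epoch])) + 1
    return StopDecision(name, dict(params), stop_epoch, selected, True)


def _gl_series(val_loss: np.ndarray, params: RuleParams) -> np.ndarray:
    """Per-epoch trigger statistic for GL/PQ under the configured mode."""
    running_min = np.minimum.accumulate(val_loss)
    if params.gl_mode == "relative_percent":
        gl = np.zeros_like(val_loss)
        nonzero = running_min > 0
        gl[nonzero] = 100.0 * (val_loss[nonzero] / running_min[nonzero] - 1.0)
        bad = ~nonzero & (val_loss > running_min)
        if np.any(bad):
            raise ZeroDivisionError(
                "division by zero minimum loss: validation loss exceeds a zero running minimum"
            )
        return gl
    # fraction_of_initial: raw excess over the running minimum; the
    # threshold is rescaled by the initial loss at comparison time.
    return val_loss - running_min


def stop_gl(trace: TrainingTrace, params: RuleParams = RuleParams()) -> StopDecision:
    """Generalization-loss rule; ``strip_n > 1`` gives the progress quotient.

    GL(t) = 100·(E_va(t)/min_{t'≤t} E_va(t') − 1) in the default
    relative-percent mode. The rule fires at the first epoch where the
    mean of GL over the last ``strip_n`` epochs exceeds ``gl_threshold``;
    the window only becomes defined at epoch ``strip_n``.
    """
    val_loss = trace.val_loss
    series = _gl_series(val_loss, params)
    if params.gl_mode == "relative_percent":
        threshold = params.gl_threshold
    else:
        threshold = params.gl_threshold * val_loss[0]
    name = "gl" if params.strip_n == 1 else f"pq{params.strip_n}"
    n = params.strip_n
    for t in range(n, len(val_loss) + 1):
        window = series[t - n : t]
        if window.mean() > threshold:
            return _decision(name, _gl_param_dict(params), trace, t)
    return _decision(name, _gl_param_dict(params), trace, None)


def _gl_param_dict(params: RuleParams) -> dict:
    return {
        "gl_threshold": params.gl_threshold,
        "gl_mode": params.gl_mode,
        "strip_n": params.strip_n,
    }


def stop_patience(trace: TrainingTrace, params: RuleParams = RuleParams()) -> StopDecision:
    """Fixed patience: stop after ``patience_n`` consecutive epochs without
    a strictly lower validation loss; keep the best-validation model.

    Equal loss counts as stalled — otherwise a flat plateau would never
    stop training.
    """
    best = np.inf
    counter = 0
    n = params.patience_n
    pdict = {"patience_n": n}
    for r in trace:
        if r.val_loss < best:
            best = r.val_loss
            counter = 0
        else:
            counter += 1
            if counter >= n:
                return _decision(f"patience{n}", pdict, trace, r.epoch)
    return _decision(f"patience{n}", pdict, trace, None)


def stop_dk(trace: TrainingTrace, params: RuleParams = RuleParams()) -> StopDecision:
    """Deng–Kwok dynamic patience.

    The patience budget ``p`` starts at ``dk_initial_patience``. At epoch
    ``t``, a validation loss below ``dk_multiplier`` times the minimum over
    earlier epochs earns ``dk_increment · t`` extra budget; after the
    update, training stops if ``p < t``. At epoch 1 there is no earlier
    minimum, so no increment can be earned there.
    """
    p = params.dk_initial_patience
    best_prev = np.inf
    pdict = {
        "dk_initial_patience": params.dk_initial_patience,
        "dk_multiplier": params.dk_multiplier,
        "dk_increment": params.dk_increment,
    }
    for r in trace:
        t = r.epoch
        if np.isfinite(best_prev) and r.val_loss < params.dk_multiplier * best_prev:
            p += params.dk_increment * t
        if r.val_loss < best_prev:
            best_prev = r.val_loss
        if p < t:
            return _decision("dk", pdict, trace, t)
    return _decision("dk", pdict, trace, None)


def stop_ceiling(trace: TrainingTrace, params: RuleParams) -> StopDecision:
    """Information-ceiling rule: stop once the monitored accuracy reaches
    the ceiling (minus an optional safety margin).

    The ceiling is the accuracy attainable from a more direct measurement
    of the same underlying state; by the data-processing argument an
    indirect channel cannot genuinely do better, so crossing the ceiling
    flags memorization. Training accuracy is monitored by default.
    """
    if params.ceiling is None:
        raise ValueError("ceiling rule requires params.ceiling to be set")
    level = params.ceiling - params.ceiling_margin
    if not 0 < level <= 1:
        raise InvalidCeilingError(f"effective trigger level {level} outside (0, 1]")
    pdict = {
        "ceiling": params.ceiling,
        "ceiling_margin": params.ceiling_margin,
        "ceiling_metric": params.ceiling_metric,
    }
    for r in trace:
        metric = r.train_acc if params.ceiling_metric == "train_acc" else r.val_acc
        if metric >= level:
            return _decision("ceiling", pdict, trace, r.epoch)
    return _decision("ceiling", pdict, trace, None)


def establish_ceiling(
    direct_test_acc: float,
    comparator_acc: float,
    tolerance: float = 0.01,
    margin: float = 0.0,
    provenance: str = "direct-channel novel-subject test accuracy",
) -> CeilingSpec:
    """Turn a direct-channel accuracy into a :class:`CeilingSpec`.

    ``comparator_acc`` is the accuracy of an independent simpler model
    (logistic regression after recursive feature elimination) on the same
    data; agreement within ``tolerance`` corroborates that the direct
    channel has been learned to saturation and its accuracy is a genuine
    information ceiling rather than an artifact of one model family.
    """
    for name, v in (("direct_test_acc", direct_test_acc), ("comparator_acc", comparator_acc)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if tolerance < 0 or margin < 0:
        raise ValueError("tolerance and margin must be >= 0")
    corroborated = abs(direct_test_acc - comparator_acc) <= tolerance
    if not corroborated:
        warnings.warn(
            f"ceiling {direct_test_acc:.4f} not corroborated: comparator accuracy "
            f"{comparator_acc:.4f} differs by more than {tolerance}",
            stacklevel=2,
        )
    return CeilingSpec(
        value=direct_test_acc,
        margin=margin,
        corroborated=corroborated,
        provenance=provenance,
    )


def _preset(fn: Callable, **overrides) -> Callable[[TrainingTrace, RuleParams], StopDecision]:
    def rule(trace: TrainingTrace, params: RuleParams = RuleParams()) -> StopDecision:
        return fn(trace, replace(params, **overrides))

    return rule


#: Named rules addressable from configs and the CLI. The ``ceiling`` entry
#: still needs ``params.ceiling`` supplied by the caller.
RULE_REGISTRY: dict[str, Callable[[TrainingTrace, RuleParams], StopDecision]] = {
    "gl": _preset(stop_gl, strip_n=1),
    "pq3": _preset(stop_gl, strip_n=3),
    "pq6": _preset(stop_gl, strip_n=6),
    "patience3": _preset(stop_patience, patience_n=3),
    "patience6": _preset(stop_patience, patience_n=6),
    "dk": stop_dk,
    "ceiling": stop_ceiling,
}


def make_rule(name: str) -> Callable[[TrainingTrace, RuleParams], StopDecision]:
    try:
        return RULE_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown rule '{name}'; available: {', '.join(sorted(RULE_REGISTRY))}"
        ) from None


def apply_named_rules(
    trace: TrainingTrace,
    names: list[str],
    params: RuleParams = RuleParams(),
) -> list[StopDecision]:
    """Apply a list of registry rules to one trace with shared parameters."""
    return [make_rule(name)(trace, params) for name in names]
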