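"""Performance metrics: accuracy, Wilson and bootstrap confidence intervals,
trial duration, information transfer rate (Wolpaw), signed-r^2, AUC, and
report assembly.

The ITR of an N-class speller with accuracy P is

    R = log2 N + P log2 P + (1 - P) log2((1 - P) / (N - 1))   [bits/trial]
    B = R * 60 / T                                            [bits/min]

with T the selection time in seconds, here T = (Ns - 1) * SOA + Tmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .decision import Decision


# ---------------------------------------------------------------------------
# timing and ITR

@dataclass(frozen=True)
class TimingInputs:
    n_stimuli: int
    soa_s: float = 0.2
    epoch_len_s: float = 1.0  # Tmax


def trial_duration(t: TimingInputs) -> float:
    """Selection time T = (Ns - 1) * SOA + Tmax, in seconds."""
    if t.n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    return (t.n_stimuli - 1) * t.soa_s + t.epoch_len_s


def _xlog2x(p: float) -> float:
    return 0.0 if p == 0.0 else p * np.log2(p)


def itr_bits_per_trial(n_classes: int, p_correct: float) -> float:
    """Wolpaw bits per selection; the P -> 0 and P -> 1 limits are exact."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    n, p = n_classes, p_correct
    return float(np.log2(n) + _xlog2x(p) + (1.0 - p) * (np.log2((1.0 - p) / (n - 1)) if p < 1 else 0.0))


def itr_bits_per_min(bits_per_trial: float, trial_duration_s: float) -> float:
    if trial_duration_s <= 0:
        raise ValueError("trial duration must be positive")
    return bits_per_trial * 60.0 / trial_duration_s


def itr(n_classes: int, p_correct: float, trial_duration_s: float) -> float:
    """Bits per minute for an N-class selection at accuracy P and duration T."""
    return itr_bits_per_min(itr_bits_per_trial(n_classes, p_correct), trial_duration_s)


# ---------------------------------------------------------------------------
# confidence intervals

def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    # the exact bounds at the extremes are 0 and 1; clear float round-off
    lo = 0.0 if k == 0 else min(max(float(lo), 0.0), 1.0)
    hi = 1.0 if k == n else min(max(float(hi), 0.0), 1.0)
    return float(lo), float(hi)


def accuracy_ci_to_itr_ci(
    k: int, n: int, n_classes: int, trial_duration_s: float, level: float = 0.95
) -> tuple[float, float]:
    """Convert the Wilson accuracy bounds into ITR bounds (bits/min)."""
    lo, hi = wilson_interval(k, n, level)
    return (
        itr(n_classes, lo, trial_duration_s),
        itr(n_classes, hi, trial_duration_s),
    )


def bootstrap_mean_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean (participant-level resampling)."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = 1.0 - level
    return (
        float(np.quantile(means, alpha / 2)),
        float(np.quantile(means, 1.0 - alpha / 2)),
    )


# ---------------------------------------------------------------------------
# separability

def signed_r2(x: Sequence[float], y: Sequence[int]) -> float:
    """Signed squared point-biserial correlation between a feature and a
    binary label: sign(r) * r^2 with r the Pearson correlation against the
    0/1 indicator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(y).size != 2:
        raise ValueError("labels must take exactly two values")
    if np.std(x) == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.sign(r) * r * r)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random target score exceeds a random non-target score
    (ties count one half); the normalized Mann-Whitney U statistic."""
    y = np.asarray(labels).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("need both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# report assembly

@dataclass
class ParticipantResult:
    participant: str
    n_trials: int
    n_correct: int
    accuracy: float
    accuracy_ci: tuple[float, float]
    itr_bits_per_min: float
    itr_ci: tuple[float, float]
    mean_selection_time_s: float


@dataclass
class PerformanceReport:
    participants: list[ParticipantResult]
    mean_accuracy: float
    mean_itr: float
    accuracy_boot_ci: tuple[float, float]
    itr_boot_ci: tuple[float, float]
    confusion: pd.DataFrame  # 30 x 30, rows = target, cols = chosen
    excluded: list[str] = field(default_factory=list)
    mean_accuracy_excl: float | None = None
    mean_itr_excl: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": [p.participant for p in self.participants],
                "accuracy": [p.accuracy for p in self.participants],
                "itr_bits_per_min": [p.itr_bits_per_min for p in self.participants],
                "acc_ci_lo": [p.accuracy_ci[0] for p in self.participants],
                "acc_ci_hi": [p.accuracy_ci[1] for p in self.participants],
                "itr_ci_lo": [p.itr_ci[0] for p in self.participants],
                "itr_ci_hi": [p.itr_ci[1] for p in self.participants],
                "mean_selection_time_s": [p.mean_selection_time_s for p in self.participants],
            }
        )


def summarize(
    decisions_per_participant: dict[str, list[tuple[int, Decision]]],
    n_classes: int = 30,
    class_labels: Sequence[str] | None = None,
    fixed_duration_s: float | None = None,
    exclude: Sequence[str] = (),
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> PerformanceReport:
    """Aggregate (target, Decision) pairs into the standard report.

    ITR uses the mean elapsed selection time per participant (dynamic
    stopping) unless ``fixed_duration_s`` pins T (full-length / static).
    """
    if not decisions_per_participant:
        raise ValueError("no participants")
    labels = list(class_labels) if class_labels is not None else [str(i) for i in range(n_classes)]
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    participants: list[ParticipantResult] = []
    for name, pairs in decisions_per_participant.items():
        if not pairs:
            raise ValueError(f"participant {name} has no trials")
        n = len(pairs)
        k = sum(1 for tgt, d in pairs if d.chosen_class == tgt)
        for tgt, d in pairs:
            confusion[tgt, d.chosen_class] += 1
        mean_t = float(np.mean([d.elapsed_s for _, d in pairs]))
        duration = fixed_duration_s if fixed_duration_s is not None else mean_t
        acc_ci = wilson_interval(k, n, level)
        participants.append(
            ParticipantResult(
                participant=name,
                n_trials=n,
                n_correct=k,
                accuracy=k / n,
                accuracy_ci=acc_ci,
                itr_bits_per_min=itr(n_classes, k / n, duration),
                itr_ci=(
                    itr(n_classes, acc_ci[0], duration),
                    itr(n_classes, acc_ci[1], duration),
                ),
                mean_selection_time_s=mean_t,
            )
        )
    accs = [p.accuracy for p in participants]
    itrs = [p.itr_bits_per_min for p in participants]
    rng = np.random.default_rng(seed)
    report = PerformanceReport(
        participants=participants,
        mean_accuracy=float(np.mean(accs)),
        mean_itr=float(np.mean(itrs)),
        accuracy_boot_ci=bootstrap_mean_ci(accs, n_boot, level, rng),
        itr_boot_ci=bootstrap_mean_ci(itrs, n_boot, level, rng),
        confusion=pd.DataFrame(confusion, index=labels, columns=labels),
        excluded=list(exclude),
    )
    kept = [p for p in participants if p.participant not in set(exclude)]
    if exclude and kept:
        report.mean_accuracy_excl = float(np.mean([p.accuracy for p in kept]))
        report.mean_itr_excl = float(np.mean([p.itr_bits_per_min for p in kept]))
    return report
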