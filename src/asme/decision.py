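"""Trial decisions and stopping rules.

A trial yields one classifier score per stimulus.  The letter decision is the
class with the highest mean score over the stimuli considered (ties break to
the lowest class id).  Three protocols:

* full — use all stimuli of the trial,
* static — use the first ``n_sequences`` complete sequences,
* dynamic — after a minimum number of sequences, test after every stimulus
  whether the current best class's scores exceed the pooled scores of all
  other classes (one-sided Welch's t-test); stop at the first p < alpha.

Elapsed selection time follows the trial-duration convention
``T = (Ns - 1) * SOA + Tmax`` with ``Ns`` the number of stimuli used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats


@dataclass
class TrialScores:
    """Per-stimulus classifier outputs for one trial, in presentation order."""

    class_ids: np.ndarray  # int, one per stimulus
    scores: np.ndarray  # float, one per stimulus
    soa_s: float = 0.2
    tmax_s: float = 1.0
    n_classes: int = 30
    target: int | None = None

    def __post_init__(self):
        self.class_ids = np.asarray(self.class_ids, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.class_ids.shape != self.scores.shape:
            raise ValueError("class_ids and scores must have equal length")

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class StoppingRule:
    mode: str = "full"  # full | static | dynamic
    n_sequences: int = 15  # static
    min_sequences: int = 2  # dynamic
    alpha: float = 0.05  # dynamic

    def __post_init__(self):
        if self.mode not in ("full", "static", "dynamic"):
            raise ValueError(f"unknown stopping mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class Decision:
    chosen_class: int
    per_class_means: np.ndarray
    n_stimuli_used: int
    elapsed_s: float
    stopped_early: bool = False
    p_value: float | None = None


def _class_means(trial: TrialScores, upto: int) -> np.ndarray:
    cids = trial.class_ids[:upto]
    sums = np.bincount(cids, weights=trial.scores[:upto], minlength=trial.n_classes)
    counts = np.bincount(cids, minlength=trial.n_classes)
    means = np.full(trial.n_classes, -np.inf)
    seen = counts > 0
    means[seen] = sums[seen] / counts[seen]
    return means


def decide(trial: TrialScores, upto_stimulus: int | None = None, *,
           stopped_early: bool = False, p_value: float | None = None) -> Decision:
    """Argmax of per-class mean score over the first ``upto_stimulus`` stimuli.

    Classes not yet presented are excluded; ties break to the lowest class id
    (numpy argmax takes the first maximum).
    """
    upto = len(trial) if upto_stimulus is None else int(upto_stimulus)
    if not 1 <= upto <= len(trial):
        raise ValueError(f"upto_stimulus must be in 1..{len(trial)}, got {upto}")
    means = _class_means(trial, upto)
    chosen = int(np.argmax(means))
    return Decision(
        chosen_class=chosen,
        per_class_means=means,
        n_stimuli_used=upto,
        elapsed_s=(upto - 1) * trial.soa_s + trial.tmax_s,
        stopped_early=stopped_early,
        p_value=p_value,
    )


def welch_t_one_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """One-sided Welch's t-test (alternative: mean(a) > mean(b)).

    Returns ``(t, df, p)`` with ``t = (ma - mb) / sqrt(sa2/na + sb2/nb)``, the
    Welch-Satterthwaite degrees of freedom, and the upper-tail Student-t
    probability.  With both variances zero: equal means give p = 0.5 by
    convention (warned); otherwise p is 0 or 1 by the sign of the difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least two observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if ma == mb:
            warnings.warn("degenerate Welch test: zero variance and equal means")
            return 0.0, float(na + nb - 2), 0.5
        return (np.inf if ma > mb else -np.inf), float(na + nb - 2), (0.0 if ma > mb else 1.0)
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(scipy.stats.t.sf(t, df))
    return float(t), float(df), p


def static_stop(trial: TrialScores, rule: StoppingRule) -> Decision:
    """Decision from the first ``rule.n_sequences`` complete sequences."""
    if rule.mode != "static":
        raise ValueError("rule.mode must be 'static'")
    upto = rule.n_sequences * trial.n_classes
    if not 1 <= upto <= len(trial):
        raise ValueError(f"n_sequences {rule.n_sequences} out of range for trial")
    return decide(trial, upto)


def dynamic_stop(trial: TrialScores, rule: StoppingRule) -> Decision:
    """Welch-test dynamic stopping.

    After ``min_sequences`` full sequences, evaluate after every subsequent
    stimulus: re-identify the best class from running per-class means and test
    its scores against the pooled scores of all other classes (one-sided
    Welch); terminate at the first p < alpha.  If never significant the trial
    runs to completion and the full-length decision is returned.
    """
    if rule.mode != "dynamic":
        raise ValueError("rule.mode must be 'dynamic'")
    total = len(trial)
    n_min = rule.min_sequences * trial.n_classes
    if n_min >= total:
        raise ValueError("min_sequences must leave room for at least one evaluation")
    for upto in range(n_min + 1, total + 1):
        means = _class_means(trial, upto)
        best = int(np.argmax(means))
        mask = trial.class_ids[:upto] == best
        a = trial.scores[:upto][mask]
        b = trial.scores[:upto][~mask]
        if a.size < 2 or b.size < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, p = welch_t_one_sided(a, b)
        if p < rule.alpha:
            return decide(trial, upto, stopped_early=True, p_value=p)
    return decide(trial, total, stopped_early=False)


def run_protocol(trial: TrialScores, rule: StoppingRule) -> Decision:
    if rule.mode == "full":
        return decide(trial)
    if rule.mode == "static":
        return static_stop(trial, rule)
    return dynamic_stop(trial, rule)
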