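"""End-to-end experiment orchestration on synthetic sessions.

The canonical session mirrors the online protocol: six offline runs of five
trials covering every class once (classifier training), then three online
runs of five trials decoded trial-by-trial.  Post-hoc experiments reuse the
same sessions: static/dynamic stopping sweeps, the class-imbalance
sub-sampling experiment, and the preprocessing parameter grid evaluated with
run-bounded 3-fold cross-validation.

Synthetic "participants" are independent seeds with per-seed SNR multipliers,
so group-level statistics (bootstrap CIs over participants) are meaningful.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import paradigm
from .decision import Decision, StoppingRule, TrialScores, run_protocol
from .decode import make_pipeline
from .metrics import PerformanceReport, auc, itr, summarize
from .paradigm import SessionPlan, default_layout, make_session_plan, session_schedules
from .signal import Epochs, FilterSpec, bandpass, extract_epochs, interval_means, resample
from .synth import Recording, SynthConfig, synthesize_session


@dataclass(frozen=True)
class Participant:
    name: str
    seed: int
    snr_scale: float = 1.0


@dataclass
class ExperimentConfig:
    seed: int = 0
    n_sequences: int = 15
    soa_s: float = 0.2
    offline_runs: int = 6
    online_runs: int = 3
    trials_per_run: int = 5
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    tmin_s: float = -0.1
    tmax_s: float = 1.0
    resample_hz: float | None = None  # post-hoc analyses downsample to 128 Hz
    pipeline: str = "lda"
    stopping: StoppingRule = field(default_factory=StoppingRule)
    participants: list[Participant] = field(default_factory=list)
    imbalance_ratios: tuple[int, ...] = (1, 5, 10, 20, 29)
    imbalance_repeats: int = 10
    grid_hp: tuple[float, ...] = (0.1, 0.5, 1.0)
    grid_lp: tuple[float, ...] = (8.0, 15.0, 20.0, 40.0)
    grid_tmax: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    grid_pipelines: tuple[str, ...] = ("lda", "xdw_lda", "xdwcov_ts_lda")
    fold_plan: tuple[tuple[int, ...], ...] = ((0, 1), (2, 3), (4, 5))

    def __post_init__(self):
        if not self.participants:
            self.participants = [Participant("P01", self.seed)]

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        doc = yaml.safe_load(text) or {}
        kwargs = dict(doc)
        if "synth" in kwargs:
            kwargs["synth"] = SynthConfig(**kwargs["synth"])
        if "filter" in kwargs:
            kwargs["filter"] = FilterSpec(**kwargs["filter"])
        if "stopping" in kwargs:
            kwargs["stopping"] = StoppingRule(**kwargs["stopping"])
        if "participants" in kwargs:
            kwargs["participants"] = [Participant(**p) for p in kwargs["participants"]]
        for key in ("imbalance_ratios", "grid_hp", "grid_lp", "grid_tmax", "grid_pipelines"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "fold_plan" in kwargs:
            kwargs["fold_plan"] = tuple(tuple(f) for f in kwargs["fold_plan"])
        return cls(**kwargs)


@dataclass
class SessionData:
    plan: SessionPlan
    schedules: list  # per run, list of TrialSchedule
    recordings: list[Recording]

    @property
    def offline_indices(self) -> list[int]:
        return [i for i, (phase, _) in enumerate(self.plan.runs) if phase == "offline"]

    @property
    def online_indices(self) -> list[int]:
        return [i for i, (phase, _) in enumerate(self.plan.runs) if phase == "online"]


def validate_fold_plan(folds: Sequence[Sequence[int]], n_runs: int = 6) -> None:
    """Folds must partition the offline runs without splitting any run."""
    flat = sorted(r for f in folds for r in f)
    if flat != list(range(n_runs)):
        raise ValueError(f"fold plan {folds} does not partition runs 0..{n_runs - 1}")


def simulate_session(
    config: ExperimentConfig, participant: Participant | None = None
) -> SessionData:
    """Generate plan, schedules and synthetic recordings for one participant."""
    p = participant or config.participants[0]
    layout = default_layout()
    plan = make_session_plan(
        layout,
        p.seed,
        offline_runs=config.offline_runs,
        online_runs=config.online_runs,
        trials_per_run=config.trials_per_run,
        soa_s=config.soa_s,
        n_sequences=config.n_sequences,
    )
    schedules = session_schedules(plan, layout)
    synth = replace(config.synth, seed=p.seed, snr_scale=config.synth.snr_scale * p.snr_scale)
    recordings = synthesize_session(plan, schedules, synth)
    return SessionData(plan=plan, schedules=schedules, recordings=recordings)


def concat_epochs(parts: Sequence[Epochs]) -> Epochs:
    if not parts:
        raise ValueError("nothing to concatenate")
    first = parts[0]
    return Epochs(
        data=np.concatenate([p.data for p in parts], axis=0),
        tmin_s=first.tmin_s,
        tmax_s=first.tmax_s,
        fs_hz=first.fs_hz,
        channel_labels=first.channel_labels,
        metadata=pd.concat([p.metadata for p in parts], ignore_index=True),
    )


def preprocess_run(
    recording: Recording,
    config: ExperimentConfig,
    filter_spec: FilterSpec | None = None,
    tmax_s: float | None = None,
) -> Epochs:
    """Filter -> epoch -> (optionally) resample, per the fixed pipeline order."""
    spec = filter_spec or config.filter
    tmax = config.tmax_s if tmax_s is None else tmax_s
    filtered = bandpass(recording.eeg(), spec)
    ep = extract_epochs(filtered, tmin_s=config.tmin_s, tmax_s=tmax)
    if config.resample_hz is not None and config.resample_hz != ep.fs_hz:
        ep = resample(ep, config.resample_hz)
    return ep


def train_pipeline(session: SessionData, config: ExperimentConfig, name: str | None = None):
    """Fit the configured scorer on all offline runs."""
    parts = [preprocess_run(session.recordings[i], config) for i in session.offline_indices]
    return make_pipeline(name or config.pipeline).fit(concat_epochs(parts))


def online_trial_scores(
    pipeline, session: SessionData, config: ExperimentConfig
) -> list[TrialScores]:
    """Score every online stimulus and regroup per trial, in presentation order."""
    out: list[TrialScores] = []
    for run_i in session.online_indices:
        ep = preprocess_run(session.recordings[run_i], config)
        scores = pipeline.score(ep)
        md = ep.metadata
        for trial in sorted(md["trial"].unique()):
            sel = md["trial"] == trial
            out.append(
                TrialScores(
                    class_ids=md.loc[sel, "class_id"].to_numpy(),
                    scores=scores[sel.to_numpy()],
                    soa_s=config.soa_s,
                    tmax_s=config.tmax_s,
                    n_classes=paradigm.N_CLASSES,
                    target=int(md.loc[sel, "target"].iloc[0]),
                )
            )
    return out


def run_online_protocol(config: ExperimentConfig) -> PerformanceReport:
    """Replicate the online protocol on synthetic participants.

    Train on the offline runs (no artifact removal), score the online runs,
    decide per trial under the configured stopping rule, and assemble the
    standard performance report.
    """
    decisions: dict[str, list[tuple[int, Decision]]] = {}
    for part in config.participants:
        session = simulate_session(config, part)
        pipe = train_pipeline(session, config)
        trials = online_trial_scores(pipe, session, config)
        decisions[part.name] = [(t.target, run_protocol(t, config.stopping)) for t in trials]
    layout = default_layout()
    return summarize(
        decisions,
        n_classes=paradigm.N_CLASSES,
        class_labels=[c.label for c in layout],
        seed=config.seed,
    )


def _sweep_row(trials: list[TrialScores], rule: StoppingRule) -> tuple[float, float, float]:
    """(accuracy, mean selection time, ITR) for one participant and rule."""
    decs = [run_protocol(t, rule) for t in trials]
    acc = float(np.mean([d.chosen_class == t.target for t, d in zip(trials, decs)]))
    st = float(np.mean([d.elapsed_s for d in decs]))
    return acc, st, itr(paradigm.N_CLASSES, acc, st)


def run_stopping_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Accuracy / selection time / ITR over static (NS 1..15) and dynamic
    (minimum sequences 2..14) stopping, averaged across participants."""
    per_part: dict[str, list[TrialScores]] = {}
    for part in config.participants:
        session = simulate_session(config, part)
        pipe = train_pipeline(session, config)
        per_part[part.name] = online_trial_scores(pipe, session, config)

    rows = []
    rules = [
        ("static", ns, StoppingRule(mode="static", n_sequences=ns))
        for ns in range(1, config.n_sequences + 1)
    ] + [
        ("dynamic", ms, StoppingRule(mode="dynamic", min_sequences=ms, alpha=config.stopping.alpha))
        for ms in range(2, config.n_sequences)
    ]
    for strategy, ns, rule in rules:
        cells = np.array([_sweep_row(trials, rule) for trials in per_part.values()])
        rows.append(
            {
                "strategy": strategy,
                "pipeline": config.pipeline,
                "ns": ns,
                "selection_time_s": cells[:, 1].mean(),
                "accuracy": cells[:, 0].mean(),
                "accuracy_sd": cells[:, 0].std(ddof=0),
                "itr_bits_per_min": cells[:, 2].mean(),
            }
        )
    return pd.DataFrame(rows)


def select_optimal(sweep: pd.DataFrame, min_accuracy: float = 0.7) -> pd.DataFrame:
    """The three row-selection criteria applied per strategy: max accuracy,
    max ITR, and max ITR subject to accuracy >= ``min_accuracy``."""
    out = []
    for strategy, grp in sweep.groupby("strategy", sort=False):
        out.append(grp.loc[grp["accuracy"].idxmax()].to_dict() | {"criterion": "accuracy"})
        out.append(grp.loc[grp["itr_bits_per_min"].idxmax()].to_dict() | {"criterion": "itr"})
        ok = grp[grp["accuracy"] >= min_accuracy]
        if len(ok):
            out.append(
                ok.loc[ok["itr_bits_per_min"].idxmax()].to_dict()
                | {"criterion": f"itr_acc>={min_accuracy}"}
            )
    return pd.DataFrame(out)


def run_imbalance_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Sub-sample non-targets to each target:non-target ratio, retrain the LDA
    on interval-mean features, decode the online trials full-length, and
    average accuracy over seeded repeats."""
    results = {r: [] for r in config.imbalance_ratios}
    for part in config.participants:
        session = simulate_session(config, part)
        off = concat_epochs(
            [preprocess_run(session.recordings[i], config) for i in session.offline_indices]
        )
        feats = interval_means(off, 0.0, config.tmax_s)
        labels = feats.labels
        tgt_idx = np.flatnonzero(labels == 1)
        non_idx = np.flatnonzero(labels == 0)
        online_feats, online_meta = [], []
        for run_i in session.online_indices:
            ep = preprocess_run(session.recordings[run_i], config)
            f = interval_means(ep, 0.0, config.tmax_s)
            online_feats.append(f.values)
            online_meta.append(f.metadata)

        for ratio in config.imbalance_ratios:
            n_non = ratio * tgt_idx.size
            if n_non > non_idx.size:
                raise ValueError(f"ratio {ratio} exceeds available non-targets")
            for rep in range(config.imbalance_repeats):
                rng = np.random.default_rng(
                    np.random.SeedSequence(part.seed, spawn_key=(3, ratio, rep))
                )
                keep = (
                    non_idx
                    if n_non == non_idx.size
                    else rng.choice(non_idx, size=n_non, replace=False)
                )
                idx = np.concatenate([tgt_idx, keep])
                from .decode import fit_shrinkage_lda, lda_score

                model = fit_shrinkage_lda(feats.values[idx], labels[idx])
                correct = []
                for values, md in zip(online_feats, online_meta):
                    scores = lda_score(model, values)
                    for trial in sorted(md["trial"].unique()):
                        sel = (md["trial"] == trial).to_numpy()
                        ts = TrialScores(
                            class_ids=md.loc[sel, "class_id"].to_numpy(),
                            scores=scores[sel],
                            soa_s=config.soa_s,
                            tmax_s=config.tmax_s,
                            target=int(md.loc[sel, "target"].iloc[0]),
                        )
                        correct.append(run_protocol(ts, StoppingRule("full")).chosen_class == ts.target)
                results[ratio].append(float(np.mean(correct)))
    return pd.DataFrame(
        {
            "ratio": list(config.imbalance_ratios),
            "n_target": [len(tgt_idx)] * len(config.imbalance_ratios),
            "n_nontarget": [r * len(tgt_idx) for r in config.imbalance_ratios],
            "accuracy": [float(np.mean(results[r])) for r in config.imbalance_ratios],
        }
    )


def run_parameter_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Preprocessing grid with run-bounded 3-fold CV on the offline runs.

    For every (high-pass, low-pass, Tmax, pipeline) cell: filter, epoch,
    resample; train on the runs outside the fold and compute stimulus-level
    AUC on the fold's runs; report the fold mean.
    """
    validate_fold_plan(config.fold_plan, config.offline_runs)
    rows = []
    for part in config.participants:
        session = simulate_session(config, part)
        offline = [session.recordings[i] for i in session.offline_indices]
        for hp, lp, tmax in itertools.product(config.grid_hp, config.grid_lp, config.grid_tmax):
            spec = FilterSpec(hp_hz=hp, lp_hz=lp)
            eps = [
                preprocess_run(rec, config, filter_spec=spec, tmax_s=tmax) for rec in offline
            ]
            for name in config.grid_pipelines:
                fold_aucs = []
                for fold in config.fold_plan:
                    train = concat_epochs([eps[i] for i in range(len(eps)) if i not in fold])
                    test = concat_epochs([eps[i] for i in fold])
                    pipe = make_pipeline(name).fit(train)
                    fold_aucs.append(auc(pipe.score(test), test.labels))
                rows.append(
                    {
                        "participant": part.name,
                        "hp_hz": hp,
                        "lp_hz": lp,
                        "tmax_s": tmax,
                        "pipeline": name,
                        "auc": float(np.mean(fold_aucs)),
                    }
                )
    table = (
        pd.DataFrame(rows)
        .groupby(["hp_hz", "lp_hz", "tmax_s", "pipeline"], as_index=False)["auc"]
        .mean()
    )
    return table


def best_grid_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Argmax AUC row per pipeline."""
    return table.loc[table.groupby("pipeline")["auc"].idxmax()].reset_index(drop=True)
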