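"""End-to-end orchestration: simulation (or real inputs) through the three-step
EEG statistics and the behavioral metacognition analyses."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import montage
from .bayes import DEFAULT_PRIORS, fit_cluster_model, summarize_terms
from .config import RunConfig
from .eegproc import preprocess_epochs, exclude_participants_by_variance
from .epochs import EpochArray
from .massuni import (
    cluster_regression,
    effect_amplitude,
    scan_responsive_electrodes,
)
from .metacog import (
    confidence_rt_model,
    counts_from_trials,
    fit_hierarchical_mratio,
    group_compare,
)
from .synth import (
    CohortSpec,
    NoiseSpec,
    ObserverSpec,
    simulate_behavior,
    simulate_epochs,
    study_templates,
    trajectories_for_trials,
)

#: contrast used for each term's effect amplitude
CONTRAST_BY_TERM = {"correctness": "correctness", "z_confidence": "confidence",
                    "z_movementRT": "movementRT"}
BAYES_MODEL_BY_TERM = {"correctness": 4, "z_confidence": 5, "z_movementRT": 5}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage tag for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ResultBundle:
    config: RunConfig
    trials: pd.DataFrame
    retained_trials: pd.DataFrame
    behavioral_summary: pd.DataFrame
    mratio: dict
    confidence_rt: pd.DataFrame
    scans: dict
    clusters: pd.DataFrame
    bayes_tables: dict
    retention: list
    excluded_participants: list = field(default_factory=list)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        h = self.config.config_hash
        self.config.to_yaml(out / "config.yaml")

        def _stamp(df: pd.DataFrame) -> pd.DataFrame:
            df = df.copy()
            df["config_hash"] = h
            return df

        _stamp(self.trials).to_csv(out / "trials.csv", index=False)
        _stamp(self.behavioral_summary).to_csv(out / "behavioral_summary.csv", index=False)
        _stamp(self.confidence_rt).to_csv(out / "confidence_rt_model.csv", index=False)
        _stamp(self.clusters).to_csv(out / "clusters.csv", index=False)
        for term, grid in self.scans.items():
            _stamp(grid.to_frame()).to_csv(out / f"scan_{term}.csv", index=False)
        for term, table in self.bayes_tables.items():
            _stamp(table).to_csv(out / f"bayes_{term}.csv", index=False)
        with open(out / "mratio.json", "w") as f:
            json.dump({**self.mratio, "config_hash": h}, f, indent=2)
        with open(out / "retention.json", "w") as f:
            json.dump({"config_hash": h, "participants": self.retention,
                       "excluded_participants": self.excluded_participants}, f, indent=2)


def default_channels(config: RunConfig) -> list[str]:
    if config.channels:
        return list(config.channels)
    roi = montage.frontocentral_roi()
    # off-ROI channels keep the scan honest and absorb topography counterweights
    extras = ["CP3", "CPz", "CP4", "P3", "Pz", "P4", "PO3", "POz", "PO4",
              "O1", "Oz", "O2"]
    return roi + extras


def simulate_stage(config: RunConfig) -> pd.DataFrame:
    cohort = CohortSpec(
        n_group_a=config.n_group_a, n_group_b=config.n_group_b,
        trials_per_participant=config.trials_per_participant, seed=config.seed,
    )
    obs_a = ObserverSpec(confidence_rt_coupling=config.coupling_a,
                         confidence_noise_sd=config.confidence_noise_sd)
    obs_b = ObserverSpec(confidence_rt_coupling=config.coupling_b,
                         confidence_noise_sd=config.confidence_noise_sd)
    return simulate_behavior(cohort, obs_a, obs_b, rng=config.module_rng("behavior"))


def kinematics_stage(trials: pd.DataFrame, config: RunConfig,
                     use_trajectories: bool = False) -> pd.DataFrame:
    """Attach exclusion labels; optionally via full trajectory analysis."""
    if use_trajectories:
        rows = []
        for pid, sub in trials.groupby("participant", sort=False):
            trajs = trajectories_for_trials(sub)
            for (_, row), traj in zip(sub.iterrows(), trajs):
                side = "right" if row["response"] > 0 else "left"
                res = kin.analyze_trajectory(traj, side, confidence=row["confidence"])
                rows.append({"onset_detected": res.onset, "exclusion": res.exclusion})
        det = pd.DataFrame(rows, index=trials.index)
        out = trials.copy()
        out["onset_detected"] = det["onset_detected"]
        out["exclusion"] = det["exclusion"]
        return out
    return kin.apply_trial_exclusions(trials)


def eeg_stage(retained: pd.DataFrame, config: RunConfig) -> tuple[EpochArray, list, list]:
    channels = default_channels(config)
    templates = study_templates(channels)
    if config.erp_gain_scale != 1.0:
        from dataclasses import replace

        templates = type(templates)(components=tuple(
            replace(c, gain=c.gain * config.erp_gain_scale)
            for c in templates.components
        ))
    noise = NoiseSpec(pink_sd=config.pink_sd, white_sd=config.white_sd,
                      intercept_sd=config.intercept_sd)
    epochs = simulate_epochs(retained, templates, noise, channels,
                             fs=config.fs, window=config.epoch_window,
                             rng=config.module_rng("epochs"))
    epochs, logs = preprocess_epochs(epochs)
    by_pid = {pid: epochs.select_trials((epochs.metadata["participant"] == pid).to_numpy())
              for pid in epochs.metadata["participant"].unique()}
    excluded = exclude_participants_by_variance(by_pid)
    if excluded:
        keep = ~epochs.metadata["participant"].isin(excluded).to_numpy()
        epochs = epochs.select_trials(keep)
    return epochs, logs, excluded


def _strip_z(meta: pd.DataFrame) -> pd.DataFrame:
    """Remove precomputed z columns so they are re-standardized on a subset."""
    return meta.drop(columns=[c for c in ("z_confidence", "z_onset") if c in meta],
                     errors="ignore")


def eeg_statistics(epochs: EpochArray, config: RunConfig,
                   bayes_seed: int | None = None) -> tuple[dict, pd.DataFrame, dict]:
    roi = [ch for ch in montage.frontocentral_roi() if ch in epochs.channels]
    scans, cluster_rows, bayes_tables = {}, [], {}
    for term in config.terms:
        ep = epochs
        if term == "z_confidence":
            # confidence effects are assessed among correct trials only
            keep = (epochs.metadata["correct"] == 1).to_numpy()
            ep = epochs.select_trials(keep)
            ep.metadata = _strip_z(ep.metadata)
        grid = scan_responsive_electrodes(ep, term, roi,
                                          window=config.scan_window,
                                          alpha=config.alpha)
        scans[term] = grid
        if not grid.selected:
            continue
        cs = cluster_regression(ep, term, grid.selected,
                                window=config.cluster_window, alpha=config.alpha)
        for cl in cs.clusters:
            mean, sd, _ = effect_amplitude(ep, cl, CONTRAST_BY_TERM[term])
            cl.amplitude, cl.amplitude_sd = mean, sd
            cluster_rows.append(cl.as_dict())
        if cs.clusters:
            main = max(cs.clusters, key=lambda c: abs(c.peak_stat))
            from .bayes.models import cluster_amplitude_table

            table = cluster_amplitude_table(ep, main)
            summary = fit_cluster_model(
                table, BAYES_MODEL_BY_TERM[term], priors=DEFAULT_PRIORS,
                n_chains=config.n_chains, n_iter=config.n_iter,
                n_warmup=config.n_warmup, seed=bayes_seed,
            )
            bayes_tables[term] = summarize_terms(summary)
    clusters = pd.DataFrame(cluster_rows) if cluster_rows else pd.DataFrame(
        columns=["term", "electrodes", "t_start", "t_end", "peak_time",
                 "peak_stat", "n_samples", "amplitude", "amplitude_sd"])
    return scans, clusters, bayes_tables


def behavioral_stage(retained: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    per = retained.groupby(["participant", "group"]).agg(
        accuracy=("correct", "mean"),
        confidence_mean=("confidence", lambda s: s.mean() / 100.0),
        confidence_sd=("confidence", lambda s: s.std(ddof=1) / 100.0),
        onset_mean=("onset", "mean"),
    ).reset_index()
    onsets_correct = retained[retained["correct"] == 1].groupby(
        ["participant", "group"])["onset"].mean().rename("onset_correct").reset_index()
    onsets_incorrect = retained[retained["correct"] == 0].groupby(
        ["participant", "group"])["onset"].mean().rename("onset_incorrect").reset_index()
    per = per.merge(onsets_correct, on=["participant", "group"], how="left")
    per = per.merge(onsets_incorrect, on=["participant", "group"], how="left")

    rows = []
    for measure in ("accuracy", "confidence_mean", "confidence_sd",
                    "onset_correct", "onset_incorrect"):
        a = per.loc[per["group"] == "ssd", measure].dropna().to_numpy()
        b = per.loc[per["group"] == "control", measure].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        cmp = group_compare(a, b)
        rows.append({
            "measure": measure,
            "ssd_mean": cmp.mean_a, "ssd_ci_lo": cmp.ci95_a[0], "ssd_ci_hi": cmp.ci95_a[1],
            "control_mean": cmp.mean_b, "control_ci_lo": cmp.ci95_b[0],
            "control_ci_hi": cmp.ci95_b[1],
            "t": cmp.t, "p": cmp.p, "bf10": cmp.bf10,
        })
    summary = pd.DataFrame(rows)

    counts = {}
    groups = {}
    for pid, sub in retained.groupby("participant"):
        try:
            counts[pid] = counts_from_trials(sub)
            groups[pid] = str(sub["group"].iloc[0])
        except ValueError:
            continue
    fit = fit_hierarchical_mratio(counts, groups, seed=config.module_seed("metacog"),
                                  n_chains=config.n_chains, n_iter=config.n_iter,
                                  n_warmup=config.n_warmup)
    mratio = {
        "group_mean": fit.group_mean,
        "group_hdi": {g: list(v) for g, v in fit.group_hdi.items()},
        "bf01_difference": fit.bf01_difference,
        "warnings": fit.warnings,
    }

    _, rt_table = confidence_rt_model(retained, seed=config.module_seed("metacog"),
                                      n_chains=config.n_chains, n_iter=config.n_iter,
                                      n_warmup=config.n_warmup)
    return summary, mratio, rt_table


def run_pipeline(config: RunConfig, use_trajectories: bool = False) -> ResultBundle:
    """Run the full synthetic pipeline and return the result bundle."""
    if config.mode != "synthetic":
        raise StageError("config", "real-data mode requires explicit EDF/trial inputs; "
                                   "use the stage functions directly")
    try:
        trials = simulate_stage(config)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("simulate", str(exc)) from exc
    labeled = kinematics_stage(trials, config, use_trajectories=use_trajectories)
    retained = labeled[labeled["exclusion"] == "none"].reset_index(drop=True)
    if retained.empty:
        raise StageError("kinematics", "no trials retained after exclusions")

    epochs, logs, excluded = eeg_stage(retained, config)
    bayes_seed = config.module_seed("bayes")
    scans, clusters, bayes_tables = eeg_statistics(epochs, config, bayes_seed)
    summary, mratio, rt_table = behavioral_stage(retained, config)

    return ResultBundle(
        config=config, trials=labeled, retained_trials=retained,
        behavioral_summary=summary, mratio=mratio, confidence_rt=rt_table,
        scans=scans, clusters=clusters, bayes_tables=bayes_tables,
        retention=logs, excluded_participants=excluded,
    )
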