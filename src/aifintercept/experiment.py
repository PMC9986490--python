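"""Trial orchestration and the headline analyses.

A *trial* is one full training run of sequential interception episodes.  This
module trains agents online, logs one record per episode (success, returns,
reward components, and the time-to-contact triplet captured at the onset of
the target's speed change), and computes the summary analyses: windowed
success curves, final success rates, and the TTC-based anticipation analysis
grouped by target initial speed.

The anticipation index locates the agent's median onset TTC on the segment
between the target's first-order TTC (pure reactive behavior: 0) and the
target's actual ramp-aware TTC (full anticipation: 1).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agent import ActiveInferenceAgent, AgentConfig
from .baselines import BaselineConfig, build_agent
from .env import (EnvConfig, EpisodeSetup, InterceptionEnv, SUCCESS,
                  actual_ttc_from_onset, first_order_ttc)
from .priors import PriorConfig

__all__ = [
    "TrialLog",
    "ExperimentConfig",
    "run_trial",
    "evaluate",
    "windowed_average",
    "success_rate",
    "ttc_at_onset",
    "summarize_ttc",
    "anticipation_index",
    "run_grid",
]


@dataclass
class TrialLog:
    """Per-episode records of one trial plus the run's resolved metadata."""

    episodes: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.episodes)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"meta": self.meta}) + "\n")
            for rec in self.episodes.to_dict(orient="records"):
                fh.write(json.dumps(rec, default=float) + "\n")


def _onset_triplet(state, setup: EpisodeSetup) -> tuple[float, float, float]:
    """(agent first-order TTC, target first-order TTC, target actual TTC)
    evaluated at the step where the speed ramp begins."""
    agent_ttc = (first_order_ttc(max(state.x_s, 0.0), state.v_s)
                 if state.v_s > 0 else math.inf)
    target_fo = first_order_ttc(max(state.x_t, 0.0), setup.target_init_speed)
    target_actual = actual_ttc_from_onset(
        max(state.x_t, 0.0), setup.target_init_speed,
        setup.target_final_speed, setup.ramp_duration)
    return agent_ttc, target_fo, target_actual


def ttc_at_onset(trace: pd.DataFrame,
                 setup: EpisodeSetup) -> tuple[float, float, float]:
    """TTC triplet from a recorded episode trace.

    Uses the first trace row at or after the change onset; the agent's TTC is
    an infinity sentinel if the agent is stationary at that step.
    """
    rows = trace[trace["t"] >= setup.change_onset]
    if rows.empty:
        raise ValueError("trace ends before the target's speed-change onset")
    row = rows.iloc[0]
    agent_ttc = (first_order_ttc(max(row["x_s"], 0.0), row["v_s"])
                 if row["v_s"] > 0 else math.inf)
    target_fo = first_order_ttc(max(row["x_t"], 0.0), setup.target_init_speed)
    target_actual = actual_ttc_from_onset(
        max(row["x_t"], 0.0), setup.target_init_speed,
        setup.target_final_speed, setup.ramp_duration)
    return agent_ttc, target_fo, target_actual


def run_trial(agent: ActiveInferenceAgent,
              env_config: Optional[EnvConfig] = None,
              n_episodes: int = 3000,
              seed: Optional[int] = None,
              train: bool = True,
              greedy: bool = False,
              log_path=None) -> TrialLog:
    """Run ``n_episodes`` sequential interception episodes with one agent.

    With ``train=True`` the agent learns online (one gradient update per
    environment step after warm-up).  Deterministic given the seed and the
    agent's own seeded state.
    """
    env_config = env_config or EnvConfig()
    env = InterceptionEnv(env_config, rng=np.random.default_rng(seed))
    records = []
    for ep in range(int(n_episodes)):
        if hasattr(agent, "begin_episode"):
            agent.begin_episode(ep)
        obs, info = env.reset()
        setup = info["setup"]
        triplet = (math.nan, math.nan, math.nan)
        onset_seen = False
        ep_return = sum_ri = sum_re = 0.0
        steps = 0
        terminal = False
        while not terminal:
            if not onset_seen and env.state.t >= setup.change_onset:
                triplet = _onset_triplet(env.state, setup)
                onset_seen = True
            a = agent.act(obs, greedy=greedy)
            obs_next, _, terminal, _, step_info = env.step(a)
            r, r_i, r_e = agent.compute_reward(obs_next,
                                               step_info["outcome"], terminal)
            agent.observe(obs, a, r, obs_next, terminal, train=train)
            ep_return += r
            sum_ri += r_i
            sum_re += r_e
            steps += 1
            obs = obs_next
        success = env.state.outcome == SUCCESS
        records.append({
            "episode": ep,
            "success": bool(success),
            "outcome": env.state.outcome,
            "return": ep_return,
            "mean_instrumental": sum_ri / steps,
            "mean_epistemic": sum_re / steps,
            "steps": steps,
            "epsilon": float(getattr(agent, "epsilon", 0.0)),
            "buffer_fill": len(agent.buffer),
            "agent_ttc": triplet[0],
            "target_fo_ttc": triplet[1],
            "target_actual_ttc": triplet[2],
            "target_init_speed": setup.target_init_speed,
            "target_final_speed": setup.target_final_speed,
            "change_onset": setup.change_onset,
            "agent_init_distance": setup.agent_init_distance,
        })
    meta = {
        "seed": seed,
        "n_episodes": int(n_episodes),
        "train": train,
        "greedy": greedy,
        "gamma": agent.config.gamma,
        "lag_multiplier": env_config.lag_multiplier,
        "env_config": env_config.to_dict(),
        "agent_config": agent.config.to_dict(),
    }
    log = TrialLog(pd.DataFrame.from_records(records), meta)
    if log_path is not None:
        log.to_jsonl(log_path)
    return log


def evaluate(agent: ActiveInferenceAgent,
             env_config: Optional[EnvConfig] = None,
             n_episodes: int = 200,
             seed: Optional[int] = None) -> TrialLog:
    """Frozen greedy-policy evaluation on fresh episodes (no learning)."""
    return run_trial(agent, env_config, n_episodes, seed=seed,
                     train=False, greedy=True)


def windowed_average(series, window: int) -> np.ndarray:
    """Trailing moving average; the leading edge averages the available
    prefix."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if window < 1:
        raise ValueError("window must be >= 1")
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def success_rate(log: TrialLog, last_n: Optional[int] = None) -> float:
    """Mean success flag over the final ``last_n`` episodes (all if None)."""
    s = log.episodes["success"].to_numpy(dtype=float)
    if last_n is not None:
        if last_n > s.size:
            raise ValueError("last_n exceeds the number of logged episodes")
        s = s[-last_n:]
    return float(s.mean())


def summarize_ttc(log: TrialLog | pd.DataFrame,
                  min_episode: int = 0) -> pd.DataFrame:
    """Boxplot statistics of the onset-TTC triplet, grouped by target
    initial speed.

    Episodes before ``min_episode`` (pre-convergence) and episodes whose
    agent TTC is non-finite (stationary agent at onset, flagged in the log)
    are excluded.  Per group and TTC type: median, quartiles, and Tukey
    whiskers (1.5 IQR), plus the anticipation index
    ``(fo_median - agent_median) / (fo_median - actual_median)``.
    """
    df = log.episodes if isinstance(log, TrialLog) else log
    df = df[df["episode"] >= min_episode]
    df = df[np.isfinite(df["agent_ttc"])]
    rows = []
    for speed, grp in df.groupby("target_init_speed"):
        if len(grp) == 0:
            warnings.warn(f"empty TTC group for initial speed {speed}")
            continue
        row = {"target_init_speed": speed, "n": len(grp)}
        for name, col in (("agent", "agent_ttc"),
                          ("target_fo", "target_fo_ttc"),
                          ("target_actual", "target_actual_ttc")):
            v = grp[col].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            row[f"{name}_median"] = med
            row[f"{name}_q1"] = q1
            row[f"{name}_q3"] = q3
            row[f"{name}_whisker_lo"] = float(
                v[v >= q1 - 1.5 * iqr].min())
            row[f"{name}_whisker_hi"] = float(
                v[v <= q3 + 1.5 * iqr].max())
        denom = row["target_fo_median"] - row["target_actual_median"]
        row["anticipation_index"] = (
            (row["target_fo_median"] - row["agent_median"]) / denom
            if abs(denom) > 1e-12 else math.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("target_init_speed")


def anticipation_index(summary: pd.DataFrame) -> float:
    """Mean anticipation index across initial-speed groups."""
    return float(summary["anticipation_index"].mean())


@dataclass
class ExperimentConfig:
    """Condition grid over (gamma, lag multiplier, agent kind)."""

    gammas: tuple[float, ...] = (0.0, 0.99)
    lag_multipliers: tuple[float, ...] = (1.0, 0.5)
    kinds: tuple[str, ...] = ("aif_full",)
    n_trials: int = 20
    episodes_per_trial: int = 3000
    window: int = 100
    eval_episodes: int = 200
    ttc_cutoff_episode: int = 1500
    master_seed: int = 0
    trial_seeds: Optional[Sequence[int]] = None

    def validate(self) -> None:
        if self.window > self.episodes_per_trial:
            raise ValueError("window must not exceed episodes_per_trial")
        if self.trial_seeds is not None:
            if len(set(self.trial_seeds)) != len(self.trial_seeds):
                raise ValueError("duplicate seeds across trials")
            if len(self.trial_seeds) != self.n_trials:
                raise ValueError("trial_seeds length must equal n_trials")


def _trial_seed_pairs(config: ExperimentConfig, condition_index: int):
    """Independent (env_seed, agent_seed) pairs per trial of one condition."""
    if config.trial_seeds is not None:
        return [(int(s), int(s) + 1_000_003) for s in config.trial_seeds]
    ss = np.random.SeedSequence(
        entropy=config.master_seed, spawn_key=(condition_index,))
    children = ss.spawn(config.n_trials)
    return [tuple(int(x) for x in c.generate_state(2) % (2 ** 31))
            for c in children]


def run_grid(config: ExperimentConfig,
             env_config: Optional[EnvConfig] = None,
             agent_config: Optional[AgentConfig] = None,
             prior: Optional[PriorConfig] = None):
    """Run every condition in the grid and summarize.

    Returns ``(per_trial, summary)``: one row per (condition, trial) with the
    final windowed success rate, greedy-evaluation success rate, and
    anticipation index; and one row per condition with across-trial mean and
    sd of those metrics.
    """
    from dataclasses import replace

    config.validate()
    env_config = env_config or EnvConfig()
    base_agent_config = agent_config or AgentConfig()
    rows = []
    cond_idx = 0
    for kind in config.kinds:
        for gamma in config.gammas:
            for mult in config.lag_multipliers:
                seeds = _trial_seed_pairs(config, cond_idx)
                cond_idx += 1
                ec = replace(env_config, lag_multiplier=mult)
                for trial, (env_seed, agent_seed) in enumerate(seeds):
                    acfg = replace(base_agent_config, gamma=gamma,
                                   seed=agent_seed)
                    agent = build_agent(
                        BaselineConfig(kind=kind, agent=acfg), prior=prior)
                    log = run_trial(agent, ec, config.episodes_per_trial,
                                    seed=env_seed)
                    wa = windowed_average(
                        log.episodes["success"].to_numpy(dtype=float),
                        config.window)
                    ev = evaluate(agent, ec, config.eval_episodes,
                                  seed=env_seed + 500_009)
                    summ = summarize_ttc(log, config.ttc_cutoff_episode)
                    rows.append({
                        "kind": kind, "gamma": gamma, "lag_multiplier": mult,
                        "trial": trial, "env_seed": env_seed,
                        "agent_seed": agent_seed,
                        "final_window_success": float(wa[-1]),
                        "eval_success": success_rate(ev),
                        "anticipation_index": anticipation_index(summ),
                    })
    per_trial = pd.DataFrame(rows)
    summary = (per_trial
               .groupby(["kind", "gamma", "lag_multiplier"])
               [["final_window_success", "eval_success",
                 "anticipation_index"]]
               .agg(["mean", "std"]))
    return per_trial, summary
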