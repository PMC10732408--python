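"""Generative simulator: observer-model cohorts and null agents.

Cohorts are simulated from any model variant. Stimuli are drawn i.i.d.
(fair Bernoulli categories for the binary dialect, a symmetric 7-level
signed-contrast grid for the mouse-style dialect), the observer's forward
pass yields trialwise choice probabilities y_p, and choices are Bernoulli
draws from y_p. The absolute log posterior ratio |L| is recorded as the
simulated confidence report. Trial counts per agent are drawn uniformly
from [300, 700] unless configured otherwise.

The default parameters are the group posterior means of the fitted
bimodal-inference model (human set: alpha=0.5, H=0.45, a_llr=0.5,
a_psi=1.44, f=0.11, p=2.72, zeta=4.63); per-agent jitter is off by default
so the cohort represents those exact study conditions. Besides the model
variants, a ``no_accumulation`` configuration pins H at 0.5 while keeping
the fitted oscillation parameters (the control in which serial dependence
must vanish), and simple null agents (random, globally biased,
stimulus-only, always-repeat) are provided for falsification tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    PARAM_BOUNDS,
    PARAM_NAMES,
    VARIANTS,
    ModelFit,
    ModelParams,
    ModelVariant,
    fit_subject,
    forward_pass,
)
from .trialdata import BINARY_CATEGORY, SIGNED_CONTRAST, CohortDataset, TrialSeries

#: group posterior means of the fitted model (human / mouse datasets)
POSTERIOR_MEANS_HUMAN = ModelParams(
    alpha=0.5, hazard=0.45, amp_llr=0.5, amp_psi=1.44,
    freq=0.11, phase=2.72, zeta=4.63, dialect=BINARY_CATEGORY,
)
POSTERIOR_MEANS_MOUSE = ModelParams(
    alpha=1.06, hazard=0.46, amp_llr=0.39, amp_psi=1.71,
    freq=0.11, phase=2.83, zeta=4.82, dialect=SIGNED_CONTRAST,
)

#: symmetric signed-contrast grid (IBL-style contrast levels)
CONTRAST_GRID = np.array([-1.0, -0.25, -0.125, -0.0625, 0.0, 0.0625, 0.125, 0.25, 1.0])

#: special simulation configurations beyond the fitted variants
NO_ACCUMULATION = "no_accumulation"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort."""

    n_agents: int
    params: ModelParams = field(default_factory=lambda: replace(POSTERIOR_MEANS_HUMAN))
    variant: str = "M1"  # M1..M5 or "no_accumulation"
    trials_min: int = 300
    trials_max: int = 700
    jitter_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    group_id: str = "sim"

    def __post_init__(self) -> None:
        if self.trials_min > self.trials_max:
            raise ValueError("trials_min must not exceed trials_max")
        if self.variant not in set(VARIANTS) | {NO_ACCUMULATION}:
            raise ValueError(f"unknown variant/config {self.variant!r}")

    def effective_params(self) -> ModelParams:
        """Parameters after applying the variant's/config's constraints."""
        p = replace(self.params)
        if self.variant == NO_ACCUMULATION:
            p.hazard = 0.5
        else:
            for name, v in VARIANTS[self.variant].fixed.items():
                if name in ("freq", "phase"):
                    continue
                setattr(p, name, v)
        return p


@dataclass
class SimulatedCohort:
    """Simulated trial tables plus latents and ground-truth parameters."""

    cohort: CohortDataset
    latents: dict[str, pd.DataFrame]
    truth: dict[str, ModelParams]
    config: SimulationConfig | None = None


def _draw_stimuli(n: int, dialect: str, rng: np.random.Generator) -> np.ndarray:
    if dialect == BINARY_CATEGORY:
        return rng.integers(0, 2, size=n).astype(float)
    return rng.choice(CONTRAST_GRID, size=n)


def simulate_agent(
    params: ModelParams,
    n_trials: int,
    rng: np.random.Generator | int | None,
    subject_id: str = "agent",
    group_id: str = "sim",
) -> tuple[TrialSeries, ModelFit]:
    """Simulate one agent: i.i.d. stimuli, forward pass, Bernoulli choices.

    Returns the trial series (confidence = |L_t|) and the forward-pass
    latents. The posterior recursion depends on the stimuli only, so the
    latents are computed once and choices drawn from y_p.
    """
    rng = np.random.default_rng(rng)
    stimuli = _draw_stimuli(n_trials, params.dialect, rng)
    probe = TrialSeries(
        subject_id=subject_id, group_id=group_id,
        stimulus=stimuli, choice=np.zeros(n_trials, dtype=int), dialect=params.dialect,
    )
    fit = forward_pass(probe, params)
    choices = (rng.random(n_trials) < fit.y_p).astype(int)
    series = TrialSeries(
        subject_id=subject_id, group_id=group_id,
        stimulus=stimuli, choice=choices, dialect=params.dialect,
        confidence=np.abs(fit.L),
    )
    return series, fit


def _jittered(params: ModelParams, jitter_sd: dict[str, float], rng: np.random.Generator) -> ModelParams:
    if not jitter_sd:
        return replace(params)
    p = replace(params)
    for name, sd in jitter_sd.items():
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        lo, hi = PARAM_BOUNDS[name]
        if sd > 0:
            # truncated normal around the mean via resampling
            for _ in range(1000):
                v = rng.normal(getattr(params, name), sd)
                if lo <= v <= hi:
                    setattr(p, name, float(v))
                    break
            else:
                setattr(p, name, float(np.clip(getattr(params, name), lo, hi)))
    return p


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate ``n_agents`` independent agents under one configuration.

    Per-agent trial counts are uniform on [trials_min, trials_max]; all
    randomness derives from ``config.seed`` through spawned substreams, so
    the same configuration reproduces bit-identical cohorts.
    """
    base = config.effective_params()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_agents)
    series_list, latents, truth = [], {}, {}
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        n_trials = int(rng.integers(config.trials_min, config.trials_max + 1))
        params = _jittered(base, config.jitter_sd, rng)
        sid = f"agent{i:04d}"
        series, fit = simulate_agent(params, n_trials, rng, subject_id=sid,
                                     group_id=config.group_id)
        series_list.append(series)
        latents[sid] = fit.latents_frame()
        truth[sid] = params
    cohort = CohortDataset(series_list, base.dialect,
                           provenance={"generator": config.variant, "seed": config.seed})
    return SimulatedCohort(cohort, latents, truth, config)


def null_agents(
    kind: str,
    n_agents: int,
    n_trials: int,
    seed: int = 0,
    q: float | None = None,
    dialect: str = BINARY_CATEGORY,
) -> SimulatedCohort:
    """Model-free null cohorts on i.i.d. stimuli.

    ``random``: choices i.i.d. Bernoulli(0.5). ``global_bias``: i.i.d.
    Bernoulli(q), q in (0.5, 1). ``stimulus_only``: choice = stimulus
    category. ``always_repeat``: choice = previous choice (first trial
    random).
    """
    if kind == "global_bias":
        if q is None or not (0.5 < q < 1.0):
            raise ValueError("global_bias requires q in (0.5, 1)")
    elif kind not in ("random", "stimulus_only", "always_repeat"):
        raise ValueError(f"unknown null agent kind {kind!r}")
    root = np.random.SeedSequence(seed)
    series_list = []
    for i, ss in enumerate(root.spawn(n_agents)):
        rng = np.random.default_rng(ss)
        stimuli = _draw_stimuli(n_trials, dialect, rng)
        if kind == "random":
            choices = rng.integers(0, 2, size=n_trials)
        elif kind == "global_bias":
            choices = (rng.random(n_trials) < q).astype(int)
        elif kind == "stimulus_only":
            cat = np.where(stimuli > 0.5 if dialect == BINARY_CATEGORY else stimuli > 0, 1, 0)
            choices = cat.astype(int)
        else:  # always_repeat
            first = int(rng.integers(0, 2))
            choices = np.full(n_trials, first, dtype=int)
        series_list.append(
            TrialSeries(subject_id=f"{kind}{i:04d}", group_id=kind,
                        stimulus=stimuli, choice=choices, dialect=dialect)
        )
    cohort = CohortDataset(series_list, dialect, provenance={"generator": kind, "seed": seed})
    return SimulatedCohort(cohort, {}, {})


def recovery_study(
    truth_config: SimulationConfig,
    fit_variant: str | ModelVariant | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate agents and refit them; tabulate truth vs estimate.

    Returns one row per agent x free parameter with columns ``truth``,
    ``estimate``, ``error``; fit failures are recorded with NaN estimates.
    """
    if fit_variant is None:
        fit_variant = truth_config.variant
    if isinstance(fit_variant, str):
        fit_variant = VARIANTS[fit_variant]
    sim = simulate_cohort(truth_config)
    rows = []
    for i, series in enumerate(sim.cohort):
        truth = sim.truth[series.subject_id]
        try:
            fit = fit_subject(series, fit_variant, n_starts=n_starts, seed=seed + i)
            est = {n: getattr(fit.params, n) for n in fit_variant.free}
        except Exception as exc:  # propagate per-agent failures into the table
            est = {n: np.nan for n in fit_variant.free}
            rows.append({"subject_id": series.subject_id, "parameter": "__error__",
                         "truth": np.nan, "estimate": np.nan, "error": np.nan,
                         "note": str(exc)})
        for name in fit_variant.free:
            t = getattr(truth, name)
            rows.append({"subject_id": series.subject_id, "parameter": name,
                         "truth": t, "estimate": est[name],
                         "error": est[name] - t, "note": ""})
    return pd.DataFrame(rows)


def recovery_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Bias and RMSE per parameter from a recovery table."""
    tab = table[table["parameter"] != "__error__"]
    out = (
        tab.groupby("parameter")["error"]
        .agg(bias="mean", rmse=lambda e: float(np.sqrt(np.mean(np.square(e)))))
        .reset_index()
    )
    return out
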