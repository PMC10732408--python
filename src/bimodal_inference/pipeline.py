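"""End-to-end orchestration: cohort in, per-stage artifacts and report out.

``run_pipeline`` executes read/simulate -> congruence -> seriality ->
spectral (-> psychometric -> model fitting/comparison) and writes CSV/JSON
artifacts into an output directory; every artifact records the seed and the
stage parameters. ``make_report`` renders the artifacts as a plain-text
summary. The analysis drivers under analysis/ are thin wrappers over these
functions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import congruence as cg
from . import seriality as sr
from . import spectral as sp
from .model import VARIANTS, compare_models, fit_subject
from .psychometric import fit_psychometric
from .simulate import SimulationConfig, simulate_cohort
from .trialdata import CohortDataset, read_cohort, write_cohort


@dataclass
class PipelineConfig:
    """Validated stage parameters for one pipeline run."""

    input_path: str | None = None
    dialect: str = "binary_category"
    simulation: SimulationConfig | None = None
    halfwidth: int = 5
    max_lag: int = 20
    n_perm: int = 100
    daniell_width: int = 50
    band_fmax: float = 0.1
    fit_variants: tuple[str, ...] = ()
    fit_n_starts: int = 10
    psychometric: bool = False
    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("provide exactly one of input_path or simulation")
        for v in self.fit_variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown model variant {v!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        from .model import ModelParams

        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("simulation") is not None:
            sim = dict(raw["simulation"])
            if isinstance(sim.get("params"), dict):
                sim["params"] = ModelParams(**sim["params"])
            raw["simulation"] = SimulationConfig(**sim)
        if "fit_variants" in raw:
            raw["fit_variants"] = tuple(raw["fit_variants"])
        return cls(**raw)


def _congruence_stage(cohort: CohortDataset, halfwidth: int):
    return [cg.congruence_series(s, halfwidth) for s in cohort]


def _seriality_stage(cohort, cong, max_lag, n_perm, seed):
    root = np.random.SeedSequence(seed)
    profiles = {"stim": [], "hist": []}
    for s, c, ss in zip(cohort, cong, root.spawn(len(cong))):
        rng = np.random.default_rng(ss)
        x = c.stim_congruent[np.isfinite(c.stim_congruent)]
        if x.size > max_lag:
            profiles["stim"].append(
                sr.AutocorrelationProfile.from_series(
                    x, max_lag, n_perm=n_perm, rng=rng,
                    subject_id=s.subject_id, group_id=s.group_id,
                )
            )
        if s.n_trials - 1 > max_lag:
            profiles["hist"].append(
                sr.AutocorrelationProfile.from_choice_history(
                    s.choice, max_lag, n_perm=n_perm, rng=rng,
                    subject_id=s.subject_id, group_id=s.group_id,
                )
            )
    return profiles


def _spectral_stage(cong, daniell_width):
    profiles = []
    for c in cong:
        ok = np.isfinite(c.p_stim) & np.isfinite(c.p_hist)
        if ok.sum() < 3:
            continue
        profiles.append(
            sp.spectral_profile(c.p_stim, c.p_hist, daniell_width,
                                subject_id=c.subject_id, group_id=c.group_id)
        )
    return profiles


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; write artifacts; return them in memory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    if config.simulation is not None:
        sim = simulate_cohort(config.simulation)
        cohort = sim.cohort
        artifacts["truth"] = sim.truth
    else:
        cohort = read_cohort(config.input_path, config.dialect)
    artifacts["cohort"] = cohort
    write_cohort(cohort, out / "cohort.csv")

    cong = _congruence_stage(cohort, config.halfwidth)
    artifacts["congruence"] = cong
    pd.concat([c.to_frame() for c in cong], ignore_index=True).to_csv(
        out / "congruence.csv", index=False
    )
    summary = {
        "stim_congruence": float(np.nanmean(np.concatenate([c.stim_congruent for c in cong]))),
        "hist_congruence": float(np.nanmean(np.concatenate([c.hist_congruent for c in cong]))),
    }

    profiles = _seriality_stage(cohort, cong, config.max_lag, config.n_perm, config.seed)
    artifacts["autocorrelation"] = profiles
    frames = [p.to_frame().assign(indicator=key)
              for key in profiles for p in profiles[key]]
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(out / "autocorrelation.csv", index=False)
    for key in profiles:
        if profiles[key]:
            summary[f"individual_lag_{key}"] = float(
                np.mean([p.individual_lag for p in profiles[key]])
            )

    spec_profiles = _spectral_stage(cong, config.daniell_width)
    artifacts["spectral"] = spec_profiles
    if spec_profiles:
        pd.concat([p.to_frame() for p in spec_profiles], ignore_index=True).to_csv(
            out / "spectral.csv", index=False
        )
        for which in ("stim", "hist"):
            try:
                summary[f"powerlaw_beta_{which}"] = sp.powerlaw_exponent(
                    spec_profiles, config.band_fmax, which=which
                )["beta"]
            except ValueError:
                pass
        bands = [sp.band_summary(p, config.band_fmax) for p in spec_profiles]
        summary["band_mean_phase"] = sp.circular_mean(np.array([b[0] for b in bands]))
        summary["band_mean_sq_coherence"] = float(np.nanmean([b[1] for b in bands]))

    if config.psychometric:
        rows = []
        for s in cohort:
            try:
                p = fit_psychometric(s, seed=config.seed)
                rows.append({"subject_id": s.subject_id, **p.__dict__})
            except ValueError as exc:
                warnings.warn(f"psychometric fit skipped for {s.subject_id}: {exc}")
        artifacts["psychometric"] = pd.DataFrame(rows)
        if rows:
            artifacts["psychometric"].to_csv(out / "psychometric.csv", index=False)

    if config.fit_variants:
        fits: dict[str, dict] = {}
        for s in cohort:
            fits[s.subject_id] = {}
            for v in config.fit_variants:
                fits[s.subject_id][v] = fit_subject(
                    s, v, n_starts=config.fit_n_starts, seed=config.seed
                )
        artifacts["fits"] = fits
        table = compare_models(fits)
        artifacts["model_comparison"] = table
        table.to_csv(out / "model_comparison.csv", index=False)

    artifacts["summary"] = summary
    meta = {"seed": config.seed, "config": _config_dict(config), "summary": summary}
    (out / "summary.json").write_text(json.dumps(meta, indent=2, default=str))
    return artifacts


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    if config.simulation is not None:
        d["simulation"]["params"] = config.simulation.params.__dict__
    return d


def make_report(out_dir: str | Path) -> str:
    """Render the artifact directory as a human-readable text summary."""
    out = Path(out_dir)
    lines = [f"Pipeline report: {out}"]
    summary_path = out / "summary.json"
    if summary_path.exists():
        meta = json.loads(summary_path.read_text())
        lines.append(f"seed: {meta.get('seed')}")
        for key, val in meta.get("summary", {}).items():
            lines.append(f"  {key}: {val:.4f}" if isinstance(val, float) else f"  {key}: {val}")
    else:
        lines.append("  [no summary.json]")
    for name, label in [
        ("congruence.csv", "per-trial congruence table"),
        ("autocorrelation.csv", "autocorrelation profiles"),
        ("spectral.csv", "spectral profiles"),
        ("psychometric.csv", "psychometric fits"),
        ("model_comparison.csv", "model comparison"),
    ]:
        path = out / name
        if path.exists():
            n = max(len(pd.read_csv(path)), 0)
            lines.append(f"  {label}: {n} rows ({name})")
        else:
            lines.append(f"  {label}: missing")
    return "\n".join(lines)
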