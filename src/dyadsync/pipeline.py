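"""End-to-end pipeline: simulate/ingest -> preprocess -> synchrony ->
pseudo-pair null -> inference, with a manifest for reproducibility.

Two named profiles mirror the two study designs:

* ``study1_smile`` — 25 Hz smile intensity, round + 4-sample (160 ms)
  smooth, WCLC with a 60-s window, 1-s step, +/-1-s lag in 1-sample
  (0.04-s) steps, any-scope pseudo pairs;
* ``study2_hr`` — 0.5 Hz heart rate, AR prewhitening, WCLC with a 60-s
  window, 2-s step (one sample), +/-2-s lag (one sample), round-matched
  pseudo pairs, six Bonferroni-corrected pair-vs-pseudo t-tests at
  alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    dyad_change_scores,
    fit_ols_formula,
    hr_change_model,
    hr_changes_from_signals,
    pair_vs_pseudo_tests,
    standardize,
)
from .pseudonull import synchrony_table
from .synchrony import peak_timecourse, wclc
from .synthdata import SimConfig, simulate_study
from .studyio import read_study, write_study

__all__ = ["PipelineConfig", "PROFILES", "run_pipeline", "PipelineError"]

# Rendered into the manifest for plotting against dictator-game allocations;
# meta-analytic average share given (percent). Reference only, never computed on.
META_ANALYTIC_DICTATOR_SHARE_PCT = 29.6


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    profile: str = "study1_smile"
    modality: str = "smile"
    method: str = "pearson"
    smooth_window: int = 4
    round_smile: bool = True
    prewhiten_max_order: int | None = None
    wclc_window_s: float = 60.0
    wclc_step_s: float = 1.0
    wclc_max_lag_s: float = 1.0
    wclc_lag_step_samples: int = 1
    wclc_pseudo_cap: int = 60
    pseudo_scope: str = "any"
    pseudo_cap: int | None = None
    within_session_only: bool = False
    exclude_familiar: bool = False
    alpha: float = 0.05
    run_ttests: bool = False
    run_hr_change: bool = False
    outcome_measures: tuple[str, ...] = ("closeness", "warmth", "competence", "attractiveness")
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        self.outcome_measures = tuple(self.outcome_measures)
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    def wclc_grid_samples(self) -> dict:
        rate = self.sim.smile_rate_hz if self.modality == "smile" else self.sim.hr_rate_hz
        return {
            "rate_hz": rate,
            "window_samples": int(round(self.wclc_window_s * rate)),
            "step_samples": int(round(self.wclc_step_s * rate)),
            "max_lag_samples": int(round(self.wclc_max_lag_s * rate)),
            "lag_step_samples": self.wclc_lag_step_samples,
            "lag_step_s": self.wclc_lag_step_samples / rate,
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["outcome_measures"] = list(self.outcome_measures)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_profile(cls, profile: str, **overrides) -> "PipelineConfig":
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; available: {sorted(PROFILES)}")
        base = dict(PROFILES[profile])
        sim_overrides = overrides.pop("sim", {})
        base.update(overrides)
        sim_kwargs = dict(base.pop("sim", {}))
        if isinstance(sim_overrides, SimConfig):
            base["sim"] = sim_overrides
        else:
            sim_kwargs.update(sim_overrides)
            base["sim"] = SimConfig(**sim_kwargs)
        return cls(profile=profile, **base)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        profile = data.pop("profile", "custom")
        if profile in PROFILES:
            return cls.from_profile(profile, **data)
        sim = data.pop("sim", {})
        return cls(profile=profile, sim=SimConfig(**sim) if isinstance(sim, dict) else sim, **data)


PROFILES: dict[str, dict] = {
    # Smile study: 25 Hz, round to integers, 160-ms (4-sample) smoothing,
    # 60-s window / 1-s step / +/-1-s lag in 1-sample (0.04 s) steps.
    "study1_smile": dict(
        modality="smile",
        smooth_window=4,
        wclc_window_s=60.0,
        wclc_step_s=1.0,
        wclc_max_lag_s=1.0,
        wclc_lag_step_samples=1,
        pseudo_scope="any",
        run_ttests=False,
        run_hr_change=False,
        outcome_measures=("closeness", "warmth", "competence", "attractiveness"),
        sim=dict(conditions=("Gazing", "JLM"), modalities=("smile",)),
    ),
    # HR study: 0.5 Hz, prewhiten, 60-s window / 2-s step (1 sample) /
    # +/-2-s lag (1 sample), round-matched pseudo pairs, m=6 t-tests.
    "study2_hr": dict(
        modality="hr",
        wclc_window_s=60.0,
        wclc_step_s=2.0,
        wclc_max_lag_s=2.0,
        wclc_lag_step_samples=1,
        pseudo_scope="round_matched",
        run_ttests=True,
        run_hr_change=True,
        alpha=0.05,
        outcome_measures=("closeness", "warmth", "competence", "friendship"),
        sim=dict(conditions=("Gazing", "JLM", "Eyes Closed"), modalities=("hr",)),
    ),
}


def _outcome_models(config: PipelineConfig, bundle, table: pd.DataFrame) -> pd.DataFrame:
    """Dyad-level models linking synchrony and condition to outcome changes."""
    ratings = bundle.ratings
    for measure in set(ratings["measure"]):
        ratings = standardize(ratings, measure)
    changes, _excluded = dyad_change_scores(ratings)

    real = table[(table["pair_type"] == "real") & table["eligible"]].copy()
    real = real.rename(columns={"pair_id": "dyad_id"})
    data = changes.merge(real[["dyad_id", "r", "mean_pair"]], on="dyad_id", how="inner")
    if len(data) < 8:
        return pd.DataFrame()

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    data["sync_z"] = _z(data["r"])
    data["mean_level_z"] = _z(data["mean_pair"])
    reference = config.sim.conditions[0]
    frames = []
    for measure in config.outcome_measures:
        col = f"change_{measure}"
        if col not in data.columns:
            continue
        sub = data.dropna(subset=[col])
        if len(sub) < 8 or sub["condition"].nunique() < 1:
            continue
        if sub["condition"].nunique() > 1:
            formula = f"Q('{col}') ~ sync_z * mean_level_z * C(condition, Treatment('{reference}'))"
            fallback = f"Q('{col}') ~ sync_z + mean_level_z + C(condition, Treatment('{reference}'))"
        else:
            formula = f"Q('{col}') ~ sync_z * mean_level_z"
            fallback = f"Q('{col}') ~ sync_z + mean_level_z"
        try:
            fit = fit_ols_formula(sub, formula, descriptor=f"change in {measure} ~ synchrony")
        except ValueError:
            fit = fit_ols_formula(sub, fallback, descriptor=f"change in {measure} ~ synchrony (additive)")
        frames.append(fit.to_frame())
    if "mean_dictator_give" in data.columns:
        sub = data.dropna(subset=["mean_dictator_give"])
        if len(sub) >= 8:
            if sub["condition"].nunique() > 1:
                formula = f"mean_dictator_give ~ sync_z * mean_level_z * C(condition, Treatment('{reference}'))"
                fallback = f"mean_dictator_give ~ sync_z + mean_level_z + C(condition, Treatment('{reference}'))"
            else:
                formula = "mean_dictator_give ~ sync_z * mean_level_z"
                fallback = "mean_dictator_give ~ sync_z + mean_level_z"
            try:
                fit = fit_ols_formula(sub, formula, descriptor="dictator allocation ~ synchrony")
            except ValueError:
                fit = fit_ols_formula(sub, fallback, descriptor="dictator allocation ~ synchrony (additive)")
            frames.append(fit.to_frame())
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_pipeline(config: PipelineConfig, outdir, study_dir=None) -> Path:
    """Run every stage and write tables plus a manifest; returns the run dir.

    ``study_dir`` ingests an existing study instead of simulating one.
    Reruns with the same config are bit-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "profile": config.profile,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "wclc_grid": config.wclc_grid_samples(),
        "meta_analytic_dictator_share_pct": META_ANALYTIC_DICTATOR_SHARE_PCT,
        "versions": {
            "dyadsync": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
        "counts": {},
    }

    # -- simulate / ingest
    stage = "simulate"
    try:
        if study_dir is None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            bundle = simulate_study(sim)
        else:
            bundle = read_study(study_dir)
        write_study(bundle, outdir / "study")
        manifest["stages"].append(stage)
        manifest["counts"]["real_dyads"] = int(len(bundle.roster))
        manifest["counts"]["participants"] = int(
            len(set(bundle.roster["member_a"]) | set(bundle.roster["member_b"]))
        )
    except Exception as exc:  # noqa: BLE001 - stage-labeled abort
        raise PipelineError(stage, str(exc)) from exc

    # -- preprocess + synchrony + pseudo null (one pass)
    stage = "synchrony"
    try:
        table = synchrony_table(
            bundle,
            modality=config.modality,
            method=config.method,
            scope=config.pseudo_scope,
            smooth_window=config.smooth_window,
            prewhiten_max_order=config.prewhiten_max_order,
            pseudo_cap=config.pseudo_cap,
            exclude_familiar=config.exclude_familiar,
            within_session_only=config.within_session_only,
            seed=config.seed,
        )
        table.to_csv(outdir / "synchrony.csv", index=False)
        manifest["stages"].append(stage)
        manifest["counts"]["synchrony_records"] = int(len(table))
        manifest["counts"]["pseudo_records"] = int((table["pair_type"] == "pseudo").sum())
        manifest["counts"]["ineligible_records"] = int((~table["eligible"]).sum())
        manifest["counts"]["missing_recordings"] = int(table.attrs.get("n_missing", 0))
        by_reason = (
            table.loc[~table["eligible"], "exclusion_reason"].value_counts().to_dict()
        )
        manifest["counts"]["exclusions_by_reason"] = {str(k): int(v) for k, v in by_reason.items()}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- WCLC time course
    stage = "wclc"
    try:
        from .pseudonull import _preprocess_cache, enumerate_pseudo_pairs  # local reuse

        cache = _preprocess_cache(
            bundle, config.modality, config.smooth_window, config.prewhiten_max_order
        )
        if config.modality == "hr" and cache:
            # residual lengths vary with the selected AR order; align every
            # recording's tail to a common length so all window grids agree
            n_common = min(proc.n_samples for _raw, proc in cache.values())
            cache = {
                k: (raw, proc.replace(values=proc.values[-n_common:]))
                for k, (raw, proc) in cache.items()
            }
        results = []

        def _wclc_for(member_a, round_a, member_b, round_b, pair_id, condition, pair_type):
            ka, kb = (member_a, int(round_a)), (member_b, int(round_b))
            if ka not in cache or kb not in cache:
                return
            raw_a, proc_a = cache[ka]
            raw_b, proc_b = cache[kb]
            if config.modality == "smile":
                ok, _reason = (True, None) if pair_type == "pseudo" else (True, None)
                from .synchrony import smile_eligibility

                ok, _reason = smile_eligibility(raw_a, raw_b)
                if not ok:
                    return
                a, b = proc_a, proc_b
            else:
                n = min(proc_a.n_samples, proc_b.n_samples)
                a = proc_a.replace(values=proc_a.values[-n:])
                b = proc_b.replace(values=proc_b.values[-n:])
            res = wclc(
                a,
                b,
                config.wclc_window_s,
                config.wclc_step_s,
                config.wclc_max_lag_s,
                config.wclc_lag_step_samples,
                method=config.method,
                pair_id=pair_id,
                pair_type=pair_type,
            )
            res.condition = condition
            results.append(res)

        for row in bundle.roster.itertuples(index=False):
            _wclc_for(
                row.member_a, row.round, row.member_b, row.round, row.dyad_id, row.condition, "real"
            )
        rng = np.random.default_rng(config.seed)
        for condition in dict.fromkeys(bundle.roster["condition"]):
            pseudo = enumerate_pseudo_pairs(
                bundle.roster,
                condition,
                scope=config.pseudo_scope,
                within_session_only=config.within_session_only,
            )
            if len(pseudo) > config.wclc_pseudo_cap:
                keep = np.sort(rng.choice(len(pseudo), config.wclc_pseudo_cap, replace=False))
                pseudo = pseudo.iloc[keep]
            for row in pseudo.itertuples(index=False):
                _wclc_for(
                    row.member_a,
                    row.round_a,
                    row.member_b,
                    row.round_b,
                    row.pair_id,
                    row.condition,
                    "pseudo",
                )
        if results:
            pd.concat([r.to_frame() for r in results], ignore_index=True).to_csv(
                outdir / "wclc.csv", index=False
            )
            peak_timecourse(results).to_csv(outdir / "timecourse.csv", index=False)
        manifest["stages"].append(stage)
        manifest["counts"]["wclc_pairs"] = len(results)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- inference
    stage = "inference"
    try:
        eligible = table[table["eligible"]].copy()
        frames = []
        # synchrony ~ type x condition x mean level (reference: pseudo pairs,
        # first condition)
        if eligible["pair_type"].nunique() > 1 and len(eligible) >= 12:
            z = eligible.copy()
            sd = z["mean_pair"].std(ddof=1)
            z["mean_level_z"] = (z["mean_pair"] - z["mean_pair"].mean()) / (sd if sd > 0 else 1.0)
            reference = config.sim.conditions[0]
            if z["condition"].nunique() > 1:
                formula = (
                    "r ~ C(pair_type, Treatment('pseudo')) * "
                    f"C(condition, Treatment('{reference}')) * mean_level_z"
                )
                # small studies can leave interaction cells empty; fall back
                # to the additive model rather than aborting the run
                fallback = (
                    "r ~ C(pair_type, Treatment('pseudo')) + "
                    f"C(condition, Treatment('{reference}')) + mean_level_z"
                )
            else:
                formula = "r ~ C(pair_type, Treatment('pseudo')) * mean_level_z"
                fallback = "r ~ C(pair_type, Treatment('pseudo')) + mean_level_z"
            try:
                fit = fit_ols_formula(z, formula, descriptor="synchrony ~ type x condition x mean level")
            except ValueError:
                fit = fit_ols_formula(
                    z, fallback, descriptor="synchrony ~ type + condition + mean level (additive)"
                )
            frames.append(fit.to_frame())
        outcome = _outcome_models(config, bundle, table)
        if len(outcome):
            frames.append(outcome)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(outdir / "models.csv", index=False)
        if config.run_ttests:
            tests = pair_vs_pseudo_tests(eligible, alpha=config.alpha)
            tests.to_csv(outdir / "ttests.csv", index=False)
            manifest["counts"]["t_tests"] = int(len(tests))
            manifest["bonferroni_threshold"] = float(tests["threshold"].iloc[0])
        if config.run_hr_change and config.modality == "hr":
            changes = hr_changes_from_signals(bundle.signals)
            fits = hr_change_model(changes)
            pd.concat([f.to_frame() for f in fits.values()], ignore_index=True).to_csv(
                outdir / "hr_change.csv", index=False
            )
        manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
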