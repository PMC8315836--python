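"""Reproducible end-to-end runs: config files, orchestration, manifests.

``run_pipeline`` chains the stages — synthetic design, agent-model
simulation, sensitivity restriction, hurdle / saturation / cusp fits,
accuracy tables, bootstrap error bars — into one seeded run writing
stable CSV/JSON artifacts plus a manifest with checksums, so a run is
reproducible byte for byte from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy as accuracy_mod
from . import design as design_mod
from . import distance as distance_mod
from . import sensitivity as sensitivity_mod
from .bootstrap import bootstrap_ci
from .model import TreatmentParams, load_presets, simulate

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = None  # filled after RunConfig definition


@dataclass(frozen=True)
class RunConfig:
    """Flat, fully explicit configuration of one pipeline run.

    Defaults reproduce the reference experimental geometry: 18 groups of
    12 subjects (6 groups per treatment), 42 questions in blocks of 6,
    tau in {1, 3, 5, 7, 9, 11}.
    """

    n_groups_per_treatment: int = 6
    group_size: int = 12
    tau_levels: tuple[int, ...] = (1, 3, 5, 7, 9, 11)
    n_questions: int = 42
    center_mean: float = -0.3
    center_sd: float = 0.35
    width_low: float = 0.3
    width_high: float = 0.8
    log_truth_low: float = 2.0
    log_truth_high: float = 9.0
    n_runs: int = 10
    seed: int = 0
    estimator: str = "ml"
    bootstrap_n_exp: int = 1000
    params_sorted: str | None = None      # JSON path; None = packaged preset
    params_unsorted: str | None = None
    params_aggregated: str | None = None

    def __post_init__(self) -> None:
        if max(self.tau_levels) >= self.group_size:
            raise ValueError("every tau level must be smaller than the group size")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def question_config(self) -> design_mod.QuestionConfig:
        return design_mod.QuestionConfig(
            center_mean=self.center_mean,
            center_sd=self.center_sd,
            width_low=self.width_low,
            width_high=self.width_high,
            log_truth_low=self.log_truth_low,
            log_truth_high=self.log_truth_high,
        )

    def treatment_params(self) -> dict[str, TreatmentParams]:
        presets = load_presets()
        out = {}
        for t in design_mod.TREATMENTS:
            path = getattr(self, f"params_{t}")
            out[t] = (
                TreatmentParams.from_json(Path(path).read_text()) if path else presets[t]
            )
        return out


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load and validate a flat YAML key-value config; unknown keys are
    rejected by name and defaults are materialised."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat mapping of keys to values")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "tau_levels" in data:
        data["tau_levels"] = tuple(int(t) for t in data["tau_levels"])
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["tau_levels"] = list(config.tau_levels)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage and write the artifact directory.

    Outputs: questions.csv, records.csv (all simulated runs), fits.json
    (hurdle, saturation and cusp fits keyed by treatment), accuracy.csv
    (stratified), bootstrap.json (mean-S error bars per treatment) and
    manifest.json with a checksum per file.  A stage failure aborts with
    the stage name; artifacts written so far are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()

        stage = "design"
        questions = design_mod.generate_questions(
            config.n_questions, config.question_config(), seed=config.seed
        )
        design = design_mod.build_design(
            config.n_groups_per_treatment,
            config.group_size,
            config.tau_levels,
            config.n_questions,
            seed=config.seed,
        )
        design_mod.questions_to_frame(questions).to_csv(
            outdir / "questions.csv", index=False, float_format="%.12g"
        )
        timings[stage] = time.perf_counter() - t0

        stage = "simulate"
        t0 = time.perf_counter()
        params = config.treatment_params()
        result = simulate(
            design, questions, params, n_runs=config.n_runs, seed=config.seed
        )
        records = result.records
        design_mod.write_records(records.drop(columns=["run"]), outdir / "records.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "sensitivity"
        t0 = time.perf_counter()
        kept, excluded, undefined = sensitivity_mod.restrict_sensitivities(records)
        logger.info(
            "restriction kept %d of %d records (excluded %.3f%%, undefined %.3f%%)",
            len(kept), len(records), 100 * excluded, 100 * undefined,
        )
        hurdle = sensitivity_mod.fit_hurdle_by_condition(kept, estimator=config.estimator)
        fits: dict[str, dict] = {"exclusion": {"excluded": excluded, "undefined": undefined}}
        for tr, table in hurdle.groupby("treatment"):
            sat = sensitivity_mod.fit_saturation(table)
            cusps = distance_mod.fit_cusp_by_condition(kept[kept["treatment"] == tr])
            alpha1, alpha_inf = distance_mod.fit_alpha_saturation(
                {tau: f.alpha for tau, f in cusps.items()}, sat.epsilon
            )
            d0, beta_minus, beta_plus = distance_mod.summarize_constants(
                list(cusps.values())
            )
            fits[tr] = {
                "hurdle": table.drop(columns="treatment").to_dict(orient="records"),
                "saturation": dataclasses.asdict(sat),
                "cusp_by_tau": {
                    str(tau): dataclasses.asdict(f) for tau, f in cusps.items()
                },
                "parameters": {
                    "epsilon": sat.epsilon,
                    "mg1": sat.mg1,
                    "mg_inf": sat.mg_inf,
                    "sg1": sat.sg1,
                    "sg_inf": sat.sg_inf,
                    "alpha1": alpha1,
                    "alpha_inf": alpha_inf,
                    "d0": d0,
                    "beta_minus": beta_minus,
                    "beta_plus": beta_plus,
                },
            }
        (outdir / "fits.json").write_text(json.dumps(fits, indent=2))
        timings[stage] = time.perf_counter() - t0

        stage = "accuracy"
        t0 = time.perf_counter()
        acc = accuracy_mod.stratified_accuracy(kept)
        acc.to_csv(outdir / "accuracy.csv", index=False, float_format="%.12g")
        timings[stage] = time.perf_counter() - t0

        stage = "bootstrap"
        t0 = time.perf_counter()
        boots = {}
        for tr, g in kept.groupby("treatment"):
            ci = bootstrap_ci(
                g,
                lambda f: float(f["sensitivity"].mean()),
                n_exp=config.bootstrap_n_exp,
                seed=config.seed,
            )
            boots[tr] = dataclasses.asdict(ci)
        (outdir / "bootstrap.json").write_text(json.dumps(boots, indent=2))
        timings[stage] = time.perf_counter() - t0

        stage = "manifest"
        files = sorted(
            p.name for p in outdir.iterdir() if p.name not in ("manifest.json", "run.log")
        )
        manifest = {
            "package": "crowdwise",
            "seed": config.seed,
            "n_runs": config.n_runs,
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
            "files": {name: _sha256(outdir / name) for name in files},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return outdir
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
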