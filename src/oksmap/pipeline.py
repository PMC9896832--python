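"""End-to-end run orchestration: simulate -> features/tournament -> evaluate.

A run is fully determined by a :class:`RunConfig` plus its master seed:
the master seed is fanned out deterministically to the simulation,
tournament and bootstrap stages, every artifact is written under the
run's output directory, and a manifest records specs, seeds and file
checksums so a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path

import joblib
import yaml

from . import evaluation as ev
from .features import PREDICTOR_SET_IDS
from .instruments import DOMAINS, ValueSet, read_value_set
from .selection import GridOptions, SelectionReport, reduced_grid_options, run_tournament
from .simulate import default_study_spec, generate_cohort, read_cohort, write_cohort

__all__ = ["RunConfig", "run_simulate", "run_map", "run_evaluate", "run_full",
           "load_config", "write_config_template"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run (with the seed)."""

    output_dir: str = "oksmap_run"
    seed: int = 0
    n_estimation: int = 456
    n_validation: int = 115
    reduced_grid: bool = True
    folds: int | None = None
    repeats: int | None = None
    boot_B: int = 2000
    value_sets_dir: str | None = None  # None -> the bundled toy tariffs
    domains: tuple = DOMAINS
    include_sets: tuple = PREDICTOR_SET_IDS
    families: tuple = ("cumulative", "penalized", "ocart", "oforest")
    stratify_by: str = "observed"

    def grid_options(self) -> GridOptions:
        opts = reduced_grid_options() if self.reduced_grid else GridOptions()
        updates = {
            "domains": tuple(self.domains),
            "include_sets": tuple(self.include_sets),
            "include_families": tuple(self.families),
        }
        if self.folds is not None:
            updates["folds"] = self.folds
        if self.repeats is not None:
            updates["repeats"] = self.repeats
        return replace(opts, **updates)

    def out(self) -> Path:
        return Path(self.output_dir)


def _stage_seed(master: int, stage: str) -> int:
    h = int.from_bytes(hashlib.sha256(f"{master}:{stage}".encode()).digest()[:4], "big")
    return h % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("domains", "include_sets", "families"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


CONFIG_TEMPLATE = """\
# oksmap run configuration (YAML).  A run is reproducible from this
# file plus the master seed alone.

output_dir: oksmap_run   # all artifacts are written under this directory
seed: 0                  # master seed, fanned out per stage

# synthetic cohort sizes (the study's estimation / external-validation sizes)
n_estimation: 456
n_validation: 115

# grid sizing: true = desk-scale grid (5 cp values, scaled-down forests,
# 3-fold CV x 1 repeat); false = the full 133-structure / 532-trial grid
# with 5-fold x 3-repeat CV
reduced_grid: true
# folds: 5               # override CV folds (optional)
# repeats: 3             # override CV repeats (optional)

boot_B: 2000             # bootstrap resamples for all confidence intervals

# directory of value-set CSVs (additive or lookup dialect, auto-detected
# from the header); omit to use the bundled toy tariffs
# value_sets_dir: /path/to/value_sets

# which domains and predictor sets to run
domains: [MO, SC, UA, PD, AD]
include_sets: [all, rfe, model_based, pca]

# median-split stratification for the utility-error report:
# 'observed' (default) or 'predicted'
stratify_by: observed
"""


def write_config_template(path) -> None:
    Path(path).write_text(CONFIG_TEMPLATE)


def run_simulate(config: RunConfig) -> dict:
    """Write the estimation and validation cohorts plus a manifest."""
    out = config.out()
    out.mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(config.seed, "simulate")
    spec_est = replace(default_study_spec("estimation"), n_patients=config.n_estimation, seed=seed)
    spec_val = replace(default_study_spec("validation"), n_patients=config.n_validation, seed=seed + 1)
    paths = {}
    manifest = {"seed": config.seed, "stage_seed": seed, "cohorts": {}}
    for role, spec in (("estimation", spec_est), ("validation", spec_val)):
        cohort = generate_cohort(spec)
        path = out / f"cohort_{role}.csv"
        write_cohort(cohort, path)
        paths[role] = path
        manifest["cohorts"][role] = {
            "path": path.name,
            "n_patients": spec.n_patients,
            "spec_seed": spec.seed,
            "noise_sd": spec.noise_sd,
            "sha256": _sha256(path),
        }
    (out / "simulate_manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths


def run_map(config: RunConfig) -> SelectionReport:
    """Run the tournament on the estimation cohort; persist the
    leaderboard and the serialized winners."""
    out = config.out()
    est_path = out / "cohort_estimation.csv"
    if not est_path.exists():
        raise FileNotFoundError(f"missing estimation cohort {est_path}; run simulate first")
    oks, eq = read_cohort(est_path)
    seed = _stage_seed(config.seed, "map")
    t0 = time.perf_counter()
    log_lines = []

    def progress(domain, g_idx, total, res):
        log_lines.append(
            f"{domain}\t{g_idx + 1}/{total}\t{res.spec.label()}\t{res.predictor_set_id}\t"
            f"acc={res.cv_accuracy_mean:.4f}\tconverged={res.converged}"
            + (f"\tnote={res.note}" if res.note else "")
        )

    report = run_tournament(oks, eq, seed=seed, options=config.grid_options(), progress=progress)
    elapsed = time.perf_counter() - t0
    report.leaderboard().to_csv(out / "leaderboard.csv", index=False)
    (out / "map_log.txt").write_text(
        f"tournament seed {seed}, elapsed {elapsed:.1f} s\n" + "\n".join(log_lines) + "\n"
    )
    winners_meta = {}
    for domain, model in report.models.items():
        winner = report.winners[domain]
        sets = report.predictor_sets[domain]
        key = (("model_based", winner.spec.family)
               if winner.predictor_set_id == "model_based" else winner.predictor_set_id)
        bundle = {"model": model, "predictor_set": sets[key]}
        joblib.dump(bundle, out / f"winner_{domain}.joblib")
        winners_meta[domain] = {
            "structure": winner.spec.label(),
            "predictor_set": winner.predictor_set_id,
            "cv_accuracy_mean": winner.cv_accuracy_mean,
            "cv_accuracy_sd": winner.cv_accuracy_sd,
            "cv_cv": winner.cv_cv,
        }
    (out / "winners.json").write_text(json.dumps(winners_meta, indent=2))
    return report


def _load_value_sets(config: RunConfig) -> list[ValueSet]:
    import pandas as pd

    if config.value_sets_dir is None:
        from .instruments import bundled_value_sets

        return bundled_value_sets()
    vs_dir = Path(config.value_sets_dir)
    paths = sorted(vs_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(
            f"no value-set CSVs in {vs_dir}; expected additive files with columns "
            "(domain, level, decrement) incl. a 'constant' row, or lookup files "
            "with columns (profile_code, utility) covering all 3125 profiles"
        )
    out = []
    for path in paths:
        header = pd.read_csv(path, nrows=0).columns
        dialect = "lookup" if "profile_code" in header else "additive"
        tariff_type = "CW" if "cw" in path.stem.lower() else "VT"
        out.append(read_value_set(path, dialect, tariff_type=tariff_type))
    return out


def run_evaluate(config: RunConfig) -> dict:
    """Accuracy (per domain and sample) and utility-error tables for the
    persisted winners."""
    out = config.out()
    winners = {}
    for domain in config.domains:
        path = out / f"winner_{domain}.joblib"
        if not path.exists():
            raise FileNotFoundError(f"missing winner {path}; run map first")
        winners[domain] = joblib.load(path)
    seed = _stage_seed(config.seed, "evaluate")

    samples = {}
    for role in ("estimation", "validation"):
        path = out / f"cohort_{role}.csv"
        if path.exists():
            samples[role] = read_cohort(path)
    if not samples:
        raise FileNotFoundError("no cohort files found; run simulate first")

    acc_reports = []
    predictions = {}  # (role) -> domain -> predicted levels
    for role, (oks, eq) in samples.items():
        predictions[role] = {}
        for d_idx, domain in enumerate(DOMAINS):
            if domain not in config.domains:
                continue
            bundle = winners[domain]
            X = bundle["predictor_set"].apply(oks)
            pred = bundle["model"].predict(X)
            predictions[role][domain] = pred
            acc_reports.append(
                ev.crude_accuracy(pred, eq[:, d_idx], domain=domain, sample=role,
                                  boot_B=config.boot_B, seed=seed + d_idx)
            )
    ev.accuracy_table(acc_reports).to_csv(out / "accuracy.csv", index=False)

    results = {"accuracy": acc_reports}
    if set(predictions.get("validation", {})) == set(DOMAINS):
        oks, eq = samples["validation"]
        actual = ev.assemble_profiles([eq[:, d] for d in range(5)])
        predicted = ev.assemble_profiles([predictions["validation"][d] for d in DOMAINS])
        value_sets = _load_value_sets(config)
        err_reports = [
            ev.utility_errors(actual, predicted, vs, boot_B=config.boot_B,
                              seed=seed + 1000 + i, stratify_by=config.stratify_by)
            for i, vs in enumerate(value_sets)
        ]
        ev.error_table(err_reports).to_csv(out / "utility_errors.csv", index=False)
        ev.multi_valueset_summary(err_reports).to_csv(out / "utility_error_summary.csv")
        results["utility_errors"] = err_reports
    return results


def run_full(config: RunConfig) -> dict:
    """simulate + map + evaluate with one master seed."""
    run_simulate(config)
    report = run_map(config)
    results = run_evaluate(config)
    results["selection"] = report
    return results
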