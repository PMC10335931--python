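"""End-to-end reproducible runs: generate/load -> select -> train -> validate.

A :class:`PipelineConfig` (constructible from YAML) describes one run:
the visit, the input source (a cohort CSV or a synthetic-generator spec),
the selection and training settings, and a master seed. ``run_pipeline``
executes the three development steps in order and writes every artifact
(votes.json, model.json, report.json, predictions.csv, plots) plus a
manifest with seeds and SHA-256 hashes, so identical config + seed yields
byte-identical model and report files.

Seed policy: the master seed spawns one child seed per stage, in the
fixed order (generate, select, train, validate), so any stage can be
re-run in isolation with its recorded seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .cohort import Visit, load_cohort, write_cohort
from .crossval import CVSpec
from .estimator import FatMassModel
from .linmodel import LinearFMModel
from .published import score_batch
from .selection import SelectionSpec
from .synthetic import GeneratorSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_report", "spawn_stage_seeds"]

_STAGES = ("generate", "select", "train", "validate")


def spawn_stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (order: generate, select, train, validate)."""
    children = np.random.SeedSequence(master_seed).generate_state(len(_STAGES)) % (2**31)
    return {stage: int(s) for stage, s in zip(_STAGES, children)}


@dataclass
class PipelineConfig:
    """One reproducible run of the three-step development procedure."""

    visit: Union[Visit, str]
    output_dir: Union[str, Path]
    input_csv: Optional[Union[str, Path]] = None
    generator: Optional[dict] = None  # GeneratorSpec overrides when generating
    selection: dict = field(default_factory=dict)  # SelectionSpec overrides
    cv: dict = field(default_factory=dict)  # CVSpec overrides
    fm_exclusion_pct: float = 5.0
    variance_ratio: float = 1.0
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.visit = Visit.coerce(self.visit)
        self.output_dir = Path(self.output_dir)
        if self.input_csv is not None and self.generator is not None:
            raise ValueError("give either input_csv or generator, not both")
        # validate stage specs eagerly so config errors surface before any work
        self.selection_spec()
        self.cv_spec()

    def selection_spec(self, seed: int = 0) -> SelectionSpec:
        return SelectionSpec(**{**self.selection, "seed": seed})

    def cv_spec(self, seed: int = 0) -> CVSpec:
        return CVSpec(**{**self.cv, "seed": seed})

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "visit": self.visit.value,
            "output_dir": str(self.output_dir),
            "input_csv": str(self.input_csv) if self.input_csv else None,
            "generator": self.generator,
            "selection": self.selection,
            "cv": self.cv,
            "fm_exclusion_pct": self.fm_exclusion_pct,
            "variance_ratio": self.variance_ratio,
            "make_plots": self.make_plots,
            "seed": self.seed,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _log_stage(stage: str, seed: int, n: int, t0: float) -> None:
    logger.info(
        "stage=%s seed=%d n=%d wall_s=%.2f", stage, seed, n, time.perf_counter() - t0
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute generate/load -> filter -> select -> train -> validate.

    Returns the manifest (also written to ``manifest.json``): config echo,
    package version, per-stage seeds, and SHA-256 hashes of every output.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    seeds = spawn_stage_seeds(config.seed)

    log_file = out / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("infantfm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        # --- input stage -------------------------------------------------
        t0 = time.perf_counter()
        if config.input_csv is not None:
            cohort = load_cohort(config.input_csv, config.visit)
            input_desc = {"source": str(config.input_csv)}
        else:
            gen_kwargs = dict(config.generator or {})
            gen_kwargs.setdefault("seed", seeds["generate"])
            spec = GeneratorSpec(visit=config.visit, **gen_kwargs)
            cohort = generate_cohort(spec)
            write_cohort(cohort, out / "cohort.csv")
            input_desc = {"source": "synthetic", "generator_seed": spec.seed, "n": spec.n}
        _log_stage("generate", seeds["generate"], len(cohort), t0)

        # --- selection + training through the estimator ------------------
        t0 = time.perf_counter()
        fm = FatMassModel(cohort, fm_exclusion_pct=config.fm_exclusion_pct)
        selection = config.selection_spec(seed=seeds["select"])
        cv = config.cv_spec(seed=seeds["train"])
        results = fm.fit(selection=selection, cv=cv)
        _write_json(out / "votes.json", results.vote_table.to_dict())
        _log_stage("select", seeds["select"], len(fm.cohort), t0)

        t0 = time.perf_counter()
        results.final_model.save(out / "model.json")
        _log_stage("train", seeds["train"], len(fm.cohort), t0)

        # --- validation ---------------------------------------------------
        t0 = time.perf_counter()
        report = results.validate(
            variance_ratio=config.variance_ratio,
            plots_dir=(out / "plots") if config.make_plots else None,
        )
        _write_json(out / "report.json", report.to_dict())
        preds = score_batch(fm.cohort, model=results.final_model)
        preds["measured_fm_kg"] = fm.cohort.fm_array()
        preds.to_csv(out / "predictions.csv", index=False)
        _log_stage("validate", seeds["validate"], report.n, t0)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    artifacts = ["votes.json", "model.json", "report.json", "predictions.csv"]
    if config.input_csv is None:
        artifacts.append("cohort.csv")
    manifest = {
        "package": "infantfm",
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "input": input_desc,
        "n_records": len(cohort),
        "n_excluded_low_fm": fm.n_excluded,
        "selected_variables": results.selected,
        "out_of_fold_r2": results.out_of_fold_r2(),
        "hashes": {name: _sha256(out / name) for name in sorted(artifacts)},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def make_report(run_dir: Union[str, Path]) -> str:
    """One-page markdown summary of a completed pipeline run.

    Reads manifest.json, votes.json, model.json and report.json from
    `run_dir`; raises if any is missing.
    """
    run_dir = Path(run_dir)
    paths = {
        name: run_dir / f"{name}.json"
        for name in ("manifest", "votes", "model", "report")
    }
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline artifact: {p}")
    manifest = json.loads(paths["manifest"].read_text())
    if not manifest.get("selected_variables"):
        return (
            f"# Fat-mass equation run — visit {manifest['config']['visit']}\n\n"
            "**Run failed: no candidate variable reached the vote threshold.**\n\n"
            "No equation was produced. Consider lowering the vote threshold, "
            "enlarging the cohort, or revisiting the candidate set.\n"
        )
    votes = json.loads(paths["votes"].read_text())
    model = LinearFMModel.load(paths["model"])
    report = json.loads(paths["report"].read_text())

    lines = [
        f"# Fat-mass equation run — visit {manifest['config']['visit']}",
        "",
        f"- package: infantfm {manifest['version']}",
        f"- records: {manifest['n_records']} "
        f"(excluded for %FM < 5: {manifest['n_excluded_low_fm']})",
        f"- master seed: {manifest['config']['seed']}",
        "",
        "## Selected variables (votes / total repetitions)",
        "",
    ]
    selected = set(manifest["selected_variables"])
    total = votes["total_reps"]
    for name in votes["variables"]:
        mark = "**" if name in selected else ""
        lines.append(f"- {mark}{name}{mark}: {votes['votes'][name]}/{total}")
    lines += [
        "",
        "## Final equation",
        "",
        "    " + model.equation_string(decimals=3),
        "",
        "## Agreement with the reference FM",
        "",
        f"- bias: {report['bias']:.3f} kg "
        f"(95% CI {report['ci_bias'][0]:.3f} to {report['ci_bias'][1]:.3f})",
        f"- limits of agreement: {report['loa_lower']:.3f} to {report['loa_upper']:.3f} kg",
        f"- outside LoA: {report['pct_below_loa']:.2f}% below, "
        f"{report['pct_above_loa']:.2f}% above",
        f"- Deming slope {report['deming_slope']:.3f} "
        f"(p vs 1: {report['p_slope_vs_1']:.3g}), "
        f"intercept {report['deming_intercept']:.3f} "
        f"(p vs 0: {report['p_intercept_vs_0']:.3g})",
        f"- Pearson r = {report['pearson_r']:.3f}, R^2 = {report['r_squared']:.3f}",
        f"- mean predicted vs measured: {report['mean_predicted']:.3f} vs "
        f"{report['mean_measured']:.3f} kg "
        f"({report['mean_comparison_test']}, p = {report['mean_comparison_p']:.3g})",
        "",
    ]
    return "\n".join(lines)
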