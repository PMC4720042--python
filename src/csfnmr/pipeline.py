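"""Pipeline orchestration: simulate -> align -> bucket -> fit -> validate ->
quantify -> report, configured from a single YAML file and fully seeded.

The default run mirrors the study design: five nested case-control models
(minimum follow-up 0/6/12/18/24 months at the most advanced sample, the
24-month model additionally with the PLS patients) plus a slow-vs-fast
progression split, each a one-component Pareto-scaled PLS-DA with 7-fold
q2 cross-validation and 200-permutation validation, followed by summed-
integral metabolite quantification against control.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import cohort as coh
from . import quantify as quant
from . import synthetic as synth
from .spectra import (
    BucketTable,
    DEFAULT_EXCLUSIONS,
    ExclusionWindow,
    align_spectra,
    build_bucket_table,
)

__all__ = [
    "PipelineConfig",
    "BucketingConfig",
    "AlignmentConfig",
    "ModelConfig",
    "CohortModelSpec",
    "ModelReport",
    "RunReport",
    "ConfigError",
    "StageError",
    "annotate_buckets",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("csfnmr")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class BucketingConfig:
    low: float = 0.2
    high: float = 9.6
    width: float = 0.02
    exclusions: list[list[float]] = field(
        default_factory=lambda: [[w.low, w.high] for w in DEFAULT_EXCLUSIONS]
    )

    def windows(self) -> tuple[ExclusionWindow, ...]:
        return tuple(ExclusionWindow(lo, hi) for lo, hi in self.exclusions)


@dataclass
class AlignmentConfig:
    enabled: bool = True
    segment_width: float = 0.08
    max_shift: float = 0.01


@dataclass
class ModelConfig:
    n_components: int = 1
    n_folds: int = 7
    n_perm: int = 200
    vip_threshold: float = 2.0
    seed: int = 0


@dataclass
class CohortModelSpec:
    name: str
    min_months: float | None = None
    min_duration: float | None = None
    include_pls: bool = False
    progression_split: bool = False

    def to_cohort_spec(self) -> coh.CohortSpec:
        return coh.CohortSpec(self.min_months, self.min_duration, self.include_pls)


def _default_models() -> list[CohortModelSpec]:
    specs = [
        CohortModelSpec("ge_baseline", min_months=0.0),
        CohortModelSpec("ge_06_months", min_months=6.0),
        CohortModelSpec("ge_12_months", min_months=12.0),
        CohortModelSpec("ge_18_months", min_months=18.0),
        CohortModelSpec("ge_24_months", min_months=24.0),
        CohortModelSpec("ge_24_months_with_pls", min_months=24.0, include_pls=True),
        CohortModelSpec("slow_vs_fast", progression_split=True),
    ]
    return specs


@dataclass
class PipelineConfig:
    bucketing: BucketingConfig = field(default_factory=BucketingConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    cohorts: list[CohortModelSpec] = field(default_factory=_default_models)
    metabolites: list[quant.MetaboliteDefinition] = field(
        default_factory=lambda: list(quant.DEFAULT_METABOLITES)
    )
    simulate: bool = True
    effect: str = "als_ge12"
    spectra_dir: str | None = None
    roster_path: str | None = None


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top
    if unknown:
        raise ConfigError(f"config: unknown keys {sorted(unknown)}")
    cfg = PipelineConfig()
    if "bucketing" in raw:
        cfg.bucketing = _from_mapping(BucketingConfig, raw["bucketing"], "bucketing")
    if "alignment" in raw:
        cfg.alignment = _from_mapping(AlignmentConfig, raw["alignment"], "alignment")
    if "model" in raw:
        cfg.model = _from_mapping(ModelConfig, raw["model"], "model")
    if "cohorts" in raw:
        cfg.cohorts = [
            _from_mapping(CohortModelSpec, c, f"cohorts[{i}]") for i, c in enumerate(raw["cohorts"])
        ]
    if "metabolites" in raw:
        cfg.metabolites = [
            quant.MetaboliteDefinition(m["name"], tuple(tuple(r) for r in m["regions"]))
            for m in raw["metabolites"]
        ]
    for key in ("simulate", "effect", "spectra_dir", "roster_path"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


# ---------------------------------------------------------------------------
# Reporting types


@dataclass
class ModelReport:
    name: str
    n_case: int
    n_control: int
    case_label: str
    control_label: str
    q2: float
    r2y: float
    n_components: int
    permutation_threshold: float
    permutation_percentile: float
    significant: bool
    selected_buckets: list[tuple[float, float, str]]  # (midpoint, vip, annotation)
    vip_table: list[tuple[float, float, bool]] | None = None  # (midpoint, vip, selected)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "case_label": self.case_label,
            "control_label": self.control_label,
            "q2": round(self.q2, 6),
            "r2y": round(self.r2y, 6),
            "n_components": self.n_components,
            "permutation_threshold": round(self.permutation_threshold, 6),
            "permutation_percentile": round(self.permutation_percentile, 6),
            "significant": self.significant,
            "selected_buckets": [
                {"midpoint": round(m, 3), "vip": round(v, 4), "metabolite": a}
                for m, v, a in self.selected_buckets
            ],
            "vip_table": [
                {"midpoint": round(m, 3), "vip": round(v, 4), "selected": s}
                for m, v, s in (self.vip_table or [])
            ],
        }


@dataclass
class RunReport:
    seed: int
    models: list[ModelReport]
    comparison: pd.DataFrame
    config_echo: dict

    def to_text(self) -> str:
        lines = ["CSF 1H-NMR discrimination pipeline report", ""]
        lines.append(f"seed: {self.seed}")
        lines.append(f"models: {len(self.models)}")
        lines.append("")
        for m in self.models:
            flag = "significant" if m.significant else "not significant"
            lines.append(
                f"[{m.name}] {m.case_label} (n={m.n_case}) vs {m.control_label} "
                f"(n={m.n_control}): q2={m.q2:.4f} r2y={m.r2y:.4f} "
                f"perm95={m.permutation_threshold:.4f} "
                f"percentile={m.permutation_percentile:.3f} -> {flag}"
            )
            for mid, vip, anno in m.selected_buckets:
                lines.append(f"    bucket {mid:.3f} ppm  VIP={vip:.2f}  {anno}")
        lines.append("")
        lines.append("metabolite abundance vs control (ANOVA + Dunnett):")
        if len(self.comparison):
            lines.append(
                self.comparison.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.4g}",
                )
            )
        return "\n".join(lines) + "\n"


def annotate_buckets(
    midpoints: Sequence[float],
    metabolites: Sequence[quant.MetaboliteDefinition] = quant.DEFAULT_METABOLITES,
    width: float = 0.02,
) -> list[str]:
    """Label each bucket with the metabolite whose region contains it."""
    labels = []
    for mid in midpoints:
        name = "unassigned"
        for m in metabolites:
            if m.contains_bucket(float(mid), width):
                name = m.name
                break
        labels.append(name)
    return labels


# ---------------------------------------------------------------------------
# Stages


def _fit_one_model(
    name: str,
    table: BucketTable,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    case_label: str,
    control_label: str,
    cfg: ModelConfig,
    metabolites: Sequence[quant.MetaboliteDefinition],
) -> ModelReport:
    ids = list(case_ids) + list(control_ids)
    sub = table.subset(ids)
    y = np.array([case_label] * len(case_ids) + [control_label] * len(control_ids))
    try:
        q2 = chem.q2_cross_validate(sub.values, y, cfg.n_folds, cfg.n_components)
        model = chem.fit_plsda(chem.pareto_scale(sub.values), y, cfg.n_components)
        model.q2 = q2
        perm = chem.permutation_validate(
            sub.values, y, cfg.n_perm, cfg.seed, cfg.n_folds, cfg.n_components
        )
        vip = chem.vip_scores(model, cfg.vip_threshold)
    except ValueError as exc:
        raise StageError(f"model {name!r}: {exc}") from exc
    annos = annotate_buckets(sub.bucket_midpoints[vip.selected], metabolites, sub.width)
    selected = [
        (float(sub.bucket_midpoints[j]), float(vip.vip[j]), a)
        for j, a in zip(vip.selected, annos)
    ]
    selected.sort(key=lambda t: -t[1])
    selected_set = set(vip.selected.tolist())
    vip_table = [
        (float(m), float(v), j in selected_set)
        for j, (m, v) in enumerate(zip(sub.bucket_midpoints, vip.vip))
    ]
    return ModelReport(
        name,
        len(case_ids),
        len(control_ids),
        case_label,
        control_label,
        q2,
        model.r2y,
        cfg.n_components,
        perm.threshold_q2,
        perm.percentile,
        perm.significant,
        selected,
        vip_table,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute every configured stage; optionally write report + intermediates."""
    if config.simulate:
        log.info("stage simulate: effect column %s, seed %d", config.effect, config.model.seed)
        data = synth.generate_cohort(
            synth.default_group_model(config.effect), seed=config.model.seed
        )
        patients, spectra = data.patients, data.spectra
    else:
        if not config.spectra_dir or not config.roster_path:
            raise ConfigError("simulate=false requires spectra_dir and roster_path")
        from .spectra import read_spectrum

        patients = coh.load_roster(config.roster_path)
        paths = sorted(Path(config.spectra_dir).glob("*.txt"))
        if not paths:
            raise StageError(f"load: no spectra in {config.spectra_dir}")
        spectra = [read_spectrum(p) for p in paths]

    if config.alignment.enabled:
        log.info("stage align: %d spectra", len(spectra))
        spectra = align_spectra(
            spectra, config.alignment.segment_width, config.alignment.max_shift
        )
    log.info("stage bucket: %d spectra", len(spectra))
    table = build_bucket_table(
        spectra,
        config.bucketing.low,
        config.bucketing.high,
        config.bucketing.width,
        config.bucketing.windows(),
    )

    reports: list[ModelReport] = []
    for spec in config.cohorts:
        log.info("stage fit/validate: %s", spec.name)
        if spec.progression_split:
            slow, fast = coh.split_by_progression(patients)
            if len(slow) < 2 or len(fast) < 2:
                raise StageError(f"model {spec.name!r}: a progression arm has < 2 patients")
            reports.append(
                _fit_one_model(
                    spec.name, table, fast, slow, "fast", "slow",
                    config.model, config.metabolites,
                )
            )
        else:
            try:
                sel = coh.build_cohort(patients, spec.to_cohort_spec())
            except coh.CohortError as exc:
                raise StageError(f"model {spec.name!r}: {exc}") from exc
            reports.append(
                _fit_one_model(
                    spec.name, table, sel.case_sample_ids, sel.control_sample_ids,
                    "case", "control", config.model, config.metabolites,
                )
            )

    log.info("stage quantify")
    control_ids = [
        p.visits[0].sample_id for p in patients if p.group == "control"
    ]
    abundances = quant.abundance_table(table, config.metabolites)
    normalized = quant.normalize_to_control(abundances, control_ids)
    groups: dict[str, list[str]] = {"control": control_ids}
    for spec in config.cohorts:
        if spec.progression_split:
            continue
        sel = coh.build_cohort(patients, spec.to_cohort_spec())
        groups[spec.name] = sel.case_sample_ids
    comparison = quant.group_comparison(normalized, groups, reference="control")

    echo = dataclasses.asdict(config.model) | {
        "bucketing": dataclasses.asdict(config.bucketing),
        "alignment": dataclasses.asdict(config.alignment),
        "effect": config.effect,
        "simulate": config.simulate,
    }
    report = RunReport(config.model.seed, reports, comparison, echo)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_tsv(outdir / "bucket_table.tsv")
        normalized.to_tsv(outdir / "abundance_normalized.tsv")
        comparison.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        (outdir / "models").mkdir(exist_ok=True)
        for m in reports:
            with open(outdir / "models" / f"{m.name}.json", "w") as fh:
                json.dump(m.to_dict(), fh, indent=2, sort_keys=True)
        with open(outdir / "report.txt", "w") as fh:
            fh.write(report.to_text())
        if config.simulate:
            coh.save_roster(patients, outdir / "roster.csv")
    return report
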