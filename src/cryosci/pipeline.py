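"""End-to-end study runs: generate -> quantify -> test -> prognose -> report.

A run is a pure function of its :class:`RunConfig`: one master seed fans out
into per-stage seeds through a fixed ``numpy.random.SeedSequence`` spawn
order (cohort, treadmill, phantoms), so any stage can be re-run
independently and two runs with the same config produce byte-identical
report bodies (no timestamps enter the report; provenance carries the config
hash, the seed and the package version).

The imaging arm mirrors the study's longitudinal design: per outcome group
and imaging day one phantom is generated whose lesion geometry follows the
observed course — large hypo/hyper lesions in the acute phase shrinking with
recovery, with the adverse group keeping larger lesions and developing a
syringomyelic cyst from day 21 on — then quantified and scored blind to the
ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mri import (
    CystConfig,
    ScoringRubric,
    SegmentationConfig,
    quantification_record,
    quantify_timepoint,
)
from .outcome import OutcomeConfig, classify_outcome
from .panel import reference_specs
from .prognostic import derive_cutoffs, fit_ipi, identify_prognostic_markers, score_cohort
from .stats import compare_groups, empirical_roc, summarize_cohort
from .synth import (
    Ellipsoid,
    PhantomSpec,
    Sphere,
    generate_cytokine_cohort,
    generate_phantom,
    generate_treadmill_series,
)

_GROUP_PAIRS = (("favorable", "intact"), ("adverse", "intact"), ("adverse", "favorable"))

# Lesion geometry course (semi-axes in mm) per outcome group and day.
# Acute lesions are common to both groups; recovery shrinks them, faster in
# the favorable group; the adverse group grows a cyst from day 21.
_LESION_COURSE: dict[tuple[str, int], dict] = {
    ("favorable", 7): {"hyper": (2.5, 1.6, 1.2), "hypo": (2.0, 1.3, 1.0), "cyst": False},
    ("adverse", 7): {"hyper": (2.5, 1.6, 1.2), "hypo": (2.0, 1.3, 1.0), "cyst": False},
    ("favorable", 14): {"hyper": (2.0, 1.3, 1.0), "hypo": (1.6, 1.1, 0.85), "cyst": False},
    ("adverse", 14): {"hyper": (2.4, 1.5, 1.15), "hypo": (1.9, 1.25, 0.95), "cyst": False},
    ("favorable", 21): {"hyper": (1.8, 1.15, 0.9), "hypo": (1.45, 1.0, 0.8), "cyst": False},
    ("adverse", 21): {"hyper": (2.3, 1.45, 1.1), "hypo": (1.8, 1.2, 0.9), "cyst": True},
    ("favorable", 30): {"hyper": (1.6, 1.0, 0.8), "hypo": (1.3, 0.9, 0.7), "cyst": False},
    ("adverse", 30): {"hyper": (2.2, 1.4, 1.1), "hypo": (1.7, 1.1, 0.9), "cyst": True},
    ("favorable", 60): {"hyper": (1.2, 0.8, 0.6), "hypo": (1.0, 0.7, 0.55), "cyst": False},
    ("adverse", 60): {"hyper": (2.0, 1.3, 1.0), "hypo": (1.5, 1.0, 0.8), "cyst": True},
}


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration of one study run."""

    seed: int = 0
    alpha: float = 0.05
    ci_level: float = 0.95
    cutoff_rule: str = "adverse-min"
    mri_days: tuple[int, ...] = (7, 30, 60)
    phantom_shape: tuple[int, int, int] = (64, 64, 48)
    phantom_spacing: tuple[float, float, float] = (0.25, 0.25, 0.5)
    lesion_offset: float = 40.0  # signed magnitude for hypo/hyper lesions
    cyst_offset: float = 120.0
    noise_sigma: float = 4.0  # 0.1 x lesion offset
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    cyst: CystConfig = field(default_factory=CystConfig)
    rubric: ScoringRubric = field(default_factory=ScoringRubric)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("outcome", OutcomeConfig),
            ("segmentation", SegmentationConfig),
            ("cyst", CystConfig),
            ("rubric", ScoringRubric),
        ):
            if key in d and isinstance(d[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
                }
                d[key] = typ(**sub)
        for key in ("mri_days", "phantom_shape", "phantom_spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, ensure_ascii=False)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (spawn order: cohort, treadmill, phantoms)."""
    children = np.random.SeedSequence(master_seed).spawn(3)
    names = ("cohort", "treadmill", "phantoms")
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _phantom_spec(config: RunConfig, group: str, day: int, seed: int) -> PhantomSpec:
    course = _LESION_COURSE[(group, day)]
    extent = tuple(n * s for n, s in zip(config.phantom_shape, config.phantom_spacing))
    # hemorrhagic/necrotic focus, surrounding edema/scar and cyst at
    # craniocaudally separated positions so regions do not overlap
    mid = (extent[0] / 2.0, extent[1] / 2.0)
    hypo_center = (*mid, 5.5)
    hyper_center = (*mid, 11.0)
    cyst_center = (*mid, 17.5)
    return PhantomSpec(
        shape=config.phantom_shape,
        spacing_mm=config.phantom_spacing,
        hypo=Ellipsoid(hypo_center, course["hypo"], -config.lesion_offset),
        hyper=Ellipsoid(hyper_center, course["hyper"], +config.lesion_offset),
        cyst=Sphere(cyst_center, 1.0, config.cyst_offset) if course["cyst"] else None,
        noise_sigma=config.noise_sigma,
        seed=seed,
    )


def run_study(config: RunConfig = RunConfig(), out_dir=None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report.

    The report bundle contains the cohort summary, per-analyte group
    comparisons with exact p values and median CIs, outcome ROC/AUC per
    analyte, decision cutoffs, the prognostic marker set, the fitted IPI
    model with per-animal scores, per-day severity scores per outcome
    group, the treadmill classification, and a provenance block.
    """
    seeds = stage_seeds(config.seed)

    # --- cohort -----------------------------------------------------------
    cohort = generate_cytokine_cohort(reference_specs(), seeds["cohort"])

    # --- treadmill + outcome labelling ------------------------------------
    tread_rng = np.random.SeedSequence(seeds["treadmill"])
    animals = (
        cohort[["animal_id", "group"]].drop_duplicates().sort_values("animal_id")
    )
    treadmill_rows = []
    outcome_rows = []
    agree = 0
    n_sci = 0
    for (animal, group), child in zip(
        animals.itertuples(index=False), tread_rng.spawn(len(animals))
    ):
        series = generate_treadmill_series(group, int(child.generate_state(1)[0] % 2**31))
        for day, speed in series.itertuples(index=False):
            treadmill_rows.append({"animal_id": animal, "day": int(day), "max_speed": speed})
        if group == "intact":
            continue
        n_sci += 1
        lab = classify_outcome(series, config.outcome, animal_id=animal)
        agree += lab.label == group
        outcome_rows.append(
            {
                "animal_id": animal,
                "true_group": group,
                "label": lab.label,
                "final_speed": lab.final_speed,
                "slope": lab.slope,
            }
        )

    # --- imaging arm -------------------------------------------------------
    phantom_rng = np.random.SeedSequence(seeds["phantoms"])
    mri_records: dict[str, dict[str, dict]] = {}
    keys = [(g, d) for g in ("favorable", "adverse") for d in config.mri_days]
    for (group, day), child in zip(keys, phantom_rng.spawn(len(keys))):
        spec = _phantom_spec(config, group, day, int(child.generate_state(1)[0] % 2**31))
        phantom = generate_phantom(spec)
        quant, score = quantify_timepoint(
            phantom.volume, config.segmentation, config.cyst, config.rubric
        )
        mri_records.setdefault(group, {})[str(day)] = quantification_record(quant, score)

    # --- cytokine statistics ----------------------------------------------
    summary = summarize_cohort(cohort)
    comparisons = []
    roc_auc = {}
    for analyte in pd.unique(cohort["analyte"]):
        for ga, gb in _GROUP_PAIRS:
            cmp_ = compare_groups(cohort, analyte, ga, gb, config.ci_level)
            comparisons.append(
                {
                    "analyte": analyte,
                    "groups": [ga, gb],
                    "medians": [cmp_.median_a, cmp_.median_b],
                    "fold_change": cmp_.fold_change,
                    "U": cmp_.u,
                    "p_value": cmp_.p_value,
                    "ci": {
                        ga: [cmp_.ci_a.lower, cmp_.ci_a.upper] if cmp_.ci_a else None,
                        gb: [cmp_.ci_b.lower, cmp_.ci_b.upper] if cmp_.ci_b else None,
                    },
                }
            )
        fav = cohort.loc[
            (cohort["analyte"] == analyte) & (cohort["group"] == "favorable"), "value_pg_ml"
        ]
        adv = cohort.loc[
            (cohort["analyte"] == analyte) & (cohort["group"] == "adverse"), "value_pg_ml"
        ]
        roc_auc[analyte] = empirical_roc(fav, adv).auc

    # --- prognosis ---------------------------------------------------------
    cutoffs = derive_cutoffs(cohort, rule=config.cutoff_rule)
    markers = identify_prognostic_markers(cohort, alpha=config.alpha)
    ipi = fit_ipi(
        cohort,
        markers,
        provenance={"config_hash": config.hash(), "seed": config.seed},
    )
    scores = score_cohort(ipi, cohort)
    training_accuracy = float((scores["call"] == scores["group"]).mean())
    training_auc = empirical_roc(
        scores.loc[scores["group"] == "favorable", "ipi_score"],
        scores.loc[scores["group"] == "adverse", "ipi_score"],
    ).auc

    report = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "stage_seeds": seeds,
            "version": __version__,
        },
        "cohort_summary": summary.to_dict(orient="records"),
        "comparisons": comparisons,
        "roc_auc_favorable_vs_adverse": roc_auc,
        "cutoffs": {
            a: (None if d is None else {"threshold": d.threshold, "rule": d.rule})
            for a, d in cutoffs.items()
        },
        "markers": markers,
        "ipi": {
            "markers": list(ipi.markers),
            "coefficients": list(ipi.coefficients),
            "intercept": ipi.intercept,
            "threshold": ipi.threshold,
            "training_accuracy": training_accuracy,
            "training_auc": training_auc,
            "scores": scores.to_dict(orient="records"),
        },
        "outcome": {
            "agreement_with_generator": agree / n_sci if n_sci else None,
            "animals": outcome_rows,
        },
        "mri_severity": mri_records,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report_json(report))
        (out_dir / "report.md").write_text(report_markdown(report))
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        pd.DataFrame(treadmill_rows).to_csv(out_dir / "treadmill.csv", index=False)
        (out_dir / "ipi_model.json").write_text(ipi.to_json())
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, ensure_ascii=False)


def report_markdown(report: dict) -> str:
    """Human-readable study summary."""
    lines = ["# Cryoinjury study report", ""]
    prov = report["provenance"]
    lines += [
        f"Seed {prov['seed']}, config `{prov['config_hash']}`, cryosci {prov['version']}.",
        "",
        "## Prognostic markers",
        "",
        ", ".join(report["markers"]) or "(none)",
        "",
        "## Decision cutoffs (pg/mL, value >= cutoff => adverse)",
        "",
    ]
    for analyte, cut in sorted(report["cutoffs"].items()):
        if cut is not None:
            lines.append(f"- {analyte}: {cut['threshold']:g}")
    ipi = report["ipi"]
    lines += [
        "",
        "## Integral prognostic index",
        "",
        f"- markers: {', '.join(ipi['markers'])}",
        f"- decision threshold: {ipi['threshold']:.4g}",
        f"- training accuracy: {ipi['training_accuracy']:.0%}, AUC {ipi['training_auc']:.2f}",
        "",
        "## Severity scores by outcome group",
        "",
    ]
    for group, days in report["mri_severity"].items():
        per_day = ", ".join(f"day {d}: {rec['total']}" for d, rec in sorted(days.items(), key=lambda kv: int(kv[0])))
        lines.append(f"- {group}: {per_day}")
    lines += [
        "",
        "## Treadmill outcome classification",
        "",
        f"Agreement with generating labels: {report['outcome']['agreement_with_generator']:.0%}",
        "",
    ]
    return "\n".join(lines)
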