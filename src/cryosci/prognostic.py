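"""Prognostic marker selection, decision cutoffs, and the integral prognostic index.

A plasma analyte is prognostically significant when (a) it separates the
favorable and adverse outcome groups completely (empirical AUC = 1.0, adverse
values higher) and (b) the adverse group is significantly elevated over
intact animals (exact Mann-Whitney p below alpha with adverse median above
the intact median).  Criterion (b) is what excludes GM-CSF, whose outcome
groups are disjoint but whose adverse levels simply return to the intact
baseline.  On cohorts pinned to the published panel the rule selects exactly
IL-1α, IL-1β, TNFα, GRO/KC, G-CSF, IFNγ and IL-13.

For a completely separating analyte the adverse-outcome cutoff is the
minimum of the adverse sample — every published threshold (221.5, 413, 118,
318, 137, 126.5, 177.5 pg/mL) equals the printed adverse-group minimum, so
that rule is adopted as the default, with the separation-gap midpoint as a
configurable alternative.  Values at or above the cutoff are called adverse.

The integral prognostic index (IPI) is an affine score over the selected
markers: ordinary least squares of the 0/1 adverse indicator on marker
concentrations (pg/mL), with the decision threshold at the midpoint between
the largest favorable and smallest adverse training score.  Scores above the
threshold call an adverse outcome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import empirical_roc, mann_whitney_exact
from .synth import validate_cohort

CUTOFF_RULES = ("adverse-min", "gap-midpoint")


# --------------------------------------------------------------------------
# single-analyte cutoffs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffDecision:
    """Adverse-outcome decision threshold for one analyte.

    Values ``>= threshold`` are called adverse (the derivation cohort's
    smallest adverse value sits exactly at an "adverse-min" threshold, and
    the tie goes to adverse).
    """

    analyte: str
    threshold: float
    rule: str
    direction: str = "above => adverse"


def select_cutoff(
    negatives: Sequence[float],
    positives: Sequence[float],
    rule: str = "adverse-min",
    analyte: str = "",
) -> Optional[CutoffDecision]:
    """Cutoff for a completely separating analyte; None when not separable.

    ``negatives`` are favorable-outcome values, ``positives`` adverse.
    Requires complete separation (min(positives) > max(negatives), i.e.
    AUC = 1); overlapping samples admit no perfect cutoff and yield None.
    """
    if rule not in CUTOFF_RULES:
        raise ValueError(f"unknown cutoff rule {rule!r}; choose from {CUTOFF_RULES}")
    neg = np.asarray(negatives, dtype=float)
    pos = np.asarray(positives, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both samples must be non-empty")
    if pos.min() <= neg.max():
        return None  # not separable
    if rule == "adverse-min":
        threshold = float(pos.min())
    else:
        threshold = float((neg.max() + pos.min()) / 2.0)
    return CutoffDecision(analyte=analyte, threshold=threshold, rule=rule)


def apply_cutoff(decision: CutoffDecision, values: Sequence[float]) -> np.ndarray:
    """Boolean adverse calls for values (>= threshold => adverse)."""
    return np.asarray(values, dtype=float) >= decision.threshold


# --------------------------------------------------------------------------
# marker identification
# --------------------------------------------------------------------------

def _pivot(cohort: pd.DataFrame, groups: Sequence[str]) -> pd.DataFrame:
    sub = cohort[cohort["group"].isin(groups)]
    wide = sub.pivot_table(
        index=["animal_id", "group"], columns="analyte", values="value_pg_ml"
    ).reset_index()
    wide.columns.name = None
    return wide


def identify_prognostic_markers(cohort: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Analytes that separate the outcome groups and are elevated vs intact.

    Returns the sorted list of analytes with favorable-vs-adverse AUC = 1.0
    (adverse positive) AND exact Mann-Whitney p < alpha for adverse vs intact
    with adverse median above intact median.
    """
    validate_cohort(cohort)
    present = set(cohort["group"])
    missing = {"intact", "favorable", "adverse"} - present
    if missing:
        raise ValueError(f"cohort lacks required groups: {sorted(missing)}")
    markers = []
    for analyte in pd.unique(cohort["analyte"]):
        by_group = {
            g: cohort.loc[
                (cohort["analyte"] == analyte) & (cohort["group"] == g), "value_pg_ml"
            ].to_numpy(dtype=float)
            for g in ("intact", "favorable", "adverse")
        }
        if any(v.size == 0 for v in by_group.values()):
            continue
        roc = empirical_roc(by_group["favorable"], by_group["adverse"])
        if roc.auc < 1.0 - 1e-12:
            continue
        mw = mann_whitney_exact(by_group["adverse"], by_group["intact"])
        if mw.p_value < alpha and np.median(by_group["adverse"]) > np.median(by_group["intact"]):
            markers.append(analyte)
    return sorted(markers)


def derive_cutoffs(
    cohort: pd.DataFrame,
    analytes: Optional[Sequence[str]] = None,
    rule: str = "adverse-min",
) -> dict[str, Optional[CutoffDecision]]:
    """Per-analyte cutoffs from the favorable/adverse groups (None = overlap)."""
    analytes = list(pd.unique(cohort["analyte"])) if analytes is None else list(analytes)
    out: dict[str, Optional[CutoffDecision]] = {}
    for analyte in analytes:
        fav = cohort.loc[
            (cohort["analyte"] == analyte) & (cohort["group"] == "favorable"), "value_pg_ml"
        ].to_numpy(dtype=float)
        adv = cohort.loc[
            (cohort["analyte"] == analyte) & (cohort["group"] == "adverse"), "value_pg_ml"
        ].to_numpy(dtype=float)
        out[analyte] = select_cutoff(fav, adv, rule=rule, analyte=analyte)
    return out


# --------------------------------------------------------------------------
# integral prognostic index
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IPIModel:
    """Affine prognostic score over marker concentrations (pg/mL)."""

    markers: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    threshold: float  # score units; score > threshold => adverse
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.coefficients):
            raise ValueError("marker list and coefficient list differ in length")

    def to_json(self) -> str:
        return json.dumps(
            {
                "markers": list(self.markers),
                "coefficients": list(self.coefficients),
                "intercept": self.intercept,
                "threshold": self.threshold,
                "provenance": self.provenance,
            },
            indent=2,
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "IPIModel":
        d = json.loads(text)
        return cls(
            markers=tuple(d["markers"]),
            coefficients=tuple(d["coefficients"]),
            intercept=float(d["intercept"]),
            threshold=float(d["threshold"]),
            provenance=d.get("provenance", {}),
        )


def fit_ipi(
    cohort: pd.DataFrame,
    markers: Sequence[str],
    ridge: float = 0.0,
    provenance: Optional[dict] = None,
) -> IPIModel:
    """Least-squares fit of the 0/1 adverse indicator on marker levels.

    Requires more favorable+adverse animals than markers and a full-rank
    design; rank-deficient designs are rejected with guidance to set
    ``ridge > 0`` (L2 penalty on the marker coefficients, not the
    intercept).
    """
    markers = list(markers)
    if not markers:
        raise ValueError("marker list is empty")
    wide = _pivot(validate_cohort(cohort), ("favorable", "adverse"))
    if wide.empty:
        raise ValueError("cohort has no favorable/adverse animals")
    absent = [m for m in markers if m not in wide.columns or wide[m].isna().any()]
    if absent:
        raise ValueError(f"markers not measured on all animals: {absent}")
    X = wide[markers].to_numpy(dtype=float)
    y = (wide["group"] == "adverse").to_numpy(dtype=float)
    n, m = X.shape
    X_aug = np.column_stack([np.ones(n), X])
    deficient = n < m + 1 or np.linalg.matrix_rank(X_aug) < m + 1
    if deficient and ridge <= 0:
        raise ValueError(
            f"design is rank deficient ({n} animals, {m} markers); "
            "use the ridge-regularized fallback (ridge > 0)"
        )
    if ridge > 0:
        penalty = ridge * np.eye(m + 1)
        penalty[0, 0] = 0.0
        beta = np.linalg.solve(X_aug.T @ X_aug + penalty, X_aug.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(X_aug, y, rcond=None)
    scores = X_aug @ beta
    fav_max = scores[y == 0].max()
    adv_min = scores[y == 1].min()
    threshold = float((fav_max + adv_min) / 2.0)
    return IPIModel(
        markers=tuple(markers),
        coefficients=tuple(float(b) for b in beta[1:]),
        intercept=float(beta[0]),
        threshold=threshold,
        provenance=provenance or {},
    )


def ipi_score(model: IPIModel, measurements: Mapping[str, float]) -> tuple[float, str]:
    """Score one animal; adverse iff score > threshold."""
    missing = [m for m in model.markers if m not in measurements]
    if missing:
        raise ValueError(f"measurements missing marker(s): {missing}")
    score = model.intercept + sum(
        c * float(measurements[m]) for m, c in zip(model.markers, model.coefficients)
    )
    return float(score), ("adverse" if score > model.threshold else "favorable")


def score_cohort(model: IPIModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """IPI score and outcome call for every favorable/adverse animal."""
    wide = _pivot(validate_cohort(cohort), ("favorable", "adverse"))
    rows = []
    for _, row in wide.iterrows():
        score, call = ipi_score(model, row)
        rows.append(
            {
                "animal_id": row["animal_id"],
                "group": row["group"],
                "ipi_score": score,
                "call": call,
            }
        )
    return pd.DataFrame(rows)
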