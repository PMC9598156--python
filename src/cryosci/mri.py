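"""Lesion segmentation, volumetry, cyst detection and the 10-grade severity score.

On T2-weighted-like spinal images the acute lesion appears as a hypointense
focus (hemorrhage/necrosis) surrounded by hyperintense signal (edema, later
glial scar and syringomyelic cysts).  The quantification pipeline is:

1. threshold segmentation into hypo-/hyperintense regions (semiautomatic in
   the original workflow; here background median +/- k*MAD with an explicit
   threshold override),
2. volumes in mm^3 and their dimensionless ratio VHyper/VHypo,
3. a geometric cyst detector (round, highly hyperintense, bounded volume),
4. the 0-10 severity score: up to 3 points each for the hyperintense volume,
   hypointense volume and their ratio, plus 1 point for a visible cyst.

The published rubric brackets are open at the printed boundaries ("5-10" vs
"<5" vs ">10"); this implementation adopts closed inner brackets (hyper
[5, 10], hypo [2, 5], ratio (1, 2] / (2, 3]) so every non-negative value maps
to exactly one bracket.  The convention is configurable via ScoringRubric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from scipy import ndimage

from .synth import PhantomVolume

#: Face adjacency (6-connectivity) for 3D connected components.
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold segmentation settings.

    When both explicit thresholds are given they are used as-is; otherwise
    thresholds are ``median(volume) -/+ k_mad * MAD(volume)`` (MAD = median
    absolute deviation, unscaled).  Connected components (6-connectivity)
    smaller than ``min_voxels`` are discarded as noise.
    """

    low_threshold: Optional[float] = None
    high_threshold: Optional[float] = None
    k_mad: float = 5.0
    min_voxels: int = 5


def _clean(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT6)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_voxels)
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def segment_lesions(
    volume: PhantomVolume, config: SegmentationConfig = SegmentationConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Segment (hypo, hyper) lesion masks; the two masks are disjoint.

    A constant-intensity volume yields two empty masks in MAD mode (MAD = 0,
    thresholds collapse onto the median, and strict inequalities exclude
    every voxel).
    """
    if config.min_voxels <= 0:
        raise ValueError(f"min_voxels must be > 0, got {config.min_voxels}")
    data = volume.data
    if config.low_threshold is not None and config.high_threshold is not None:
        low, high = float(config.low_threshold), float(config.high_threshold)
        if low > high:
            raise ValueError("low threshold exceeds high threshold")
    else:
        med = float(np.median(data))
        mad = float(np.median(np.abs(data - med)))
        low, high = med - config.k_mad * mad, med + config.k_mad * mad
    hypo = _clean(data < low, config.min_voxels)
    hyper = _clean(data > high, config.min_voxels)
    return hypo, hyper


def compute_volume(mask: np.ndarray, spacing_mm) -> float:
    """Volume of a binary mask in mm^3 (voxel count x per-voxel volume)."""
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != np.asarray(mask).ndim:
        raise ValueError("mask and spacing dimensionality differ")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be > 0, got {spacing}")
    return float(np.count_nonzero(mask)) * float(np.prod(spacing))


def hyper_hypo_ratio(v_hyper: float, v_hypo: float) -> float:
    """Dimensionless VHyper/VHypo.

    Conventions for degenerate volumetry: both volumes zero -> NaN
    ("undefined", scores 0 ratio points); VHypo zero with VHyper positive ->
    +inf ("infinite", scores the top ratio bracket).
    """
    if v_hyper < 0 or v_hypo < 0:
        raise ValueError("volumes must be >= 0")
    if v_hypo == 0:
        return math.nan if v_hyper == 0 else math.inf
    return v_hyper / v_hypo


# --------------------------------------------------------------------------
# cyst detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CystConfig:
    """Operational stand-in for the visual cyst criterion.

    A hyperintense component is called a syringomyelic cyst when it is
    round (sphericity = sqrt(smallest/largest covariance eigenvalue) of its
    voxel coordinates in mm, >= ``sphericity_min``), brighter than the rest
    of the hyperintense region (component median intensity >= the
    ``intensity_quantile`` of the remaining hyper voxels), and of plausible
    size (volume within ``volume_bounds_mm3``).
    """

    sphericity_min: float = 0.6
    intensity_quantile: float = 0.9
    volume_bounds_mm3: tuple[float, float] = (0.5, 20.0)


def _sphericity(coords_mm: np.ndarray) -> float:
    if coords_mm.shape[0] < 2:
        return 1.0
    eig = np.linalg.eigvalsh(np.cov(coords_mm.T))
    eig = np.clip(eig, 0.0, None)
    if eig[-1] <= 0:
        return 1.0
    return float(np.sqrt(eig[0] / eig[-1]))


def detect_cyst(
    volume: PhantomVolume, hyper_mask: np.ndarray, config: CystConfig = CystConfig()
) -> bool:
    """True iff some hyperintense component passes all cyst criteria."""
    if not np.any(hyper_mask):
        return False
    labels, n = ndimage.label(hyper_mask, structure=_STRUCT6)
    voxvol = volume.voxel_volume_mm3
    lo, hi = config.volume_bounds_mm3
    for lab in range(1, n + 1):
        comp = labels == lab
        vol = np.count_nonzero(comp) * voxvol
        if not lo <= vol <= hi:
            continue
        coords = np.argwhere(comp) * np.asarray(volume.spacing_mm)
        if _sphericity(coords) < config.sphericity_min:
            continue
        rest = hyper_mask & ~comp
        if np.any(rest):
            ref = float(np.quantile(volume.data[rest], config.intensity_quantile))
            if float(np.median(volume.data[comp])) < ref:
                continue
        return True
    return False


# --------------------------------------------------------------------------
# severity scoring
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringRubric:
    """Bracket edges of the 10-grade severity scale.

    Volume criteria score 0 at zero volume, 1 below the first edge, 2 on the
    closed inner bracket, 3 above the second edge.  The ratio criterion
    scores 0 on [0, e0] (and for an undefined ratio), 1 on (e0, e1], 2 on
    (e1, e2], 3 above e2 (and for an infinite ratio).  A detected cyst adds
    ``cyst_points``.
    """

    hyper_edges: tuple[float, float] = (5.0, 10.0)
    hypo_edges: tuple[float, float] = (2.0, 5.0)
    ratio_edges: tuple[float, float, float] = (1.0, 2.0, 3.0)
    cyst_points: int = 1

    @property
    def max_total(self) -> int:
        return 9 + self.cyst_points

    def to_dict(self) -> dict:
        return {
            "hyper_edges": list(self.hyper_edges),
            "hypo_edges": list(self.hypo_edges),
            "ratio_edges": list(self.ratio_edges),
            "cyst_points": self.cyst_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringRubric":
        kwargs = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d.items()}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ScoringRubric":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _volume_points(v: float, edges: tuple[float, float]) -> int:
    if v < 0:
        raise ValueError(f"volume must be >= 0, got {v}")
    if v == 0:
        return 0
    if v < edges[0]:
        return 1
    if v <= edges[1]:
        return 2
    return 3


def _ratio_points(r: float, edges: tuple[float, float, float]) -> int:
    if math.isnan(r):  # undefined: no lesion at all
        return 0
    if math.isinf(r):  # infinite: hyper without hypo, top bracket
        return 3
    if r < 0:
        raise ValueError(f"ratio must be >= 0, got {r}")
    if r <= edges[0]:
        return 0
    if r <= edges[1]:
        return 1
    if r <= edges[2]:
        return 2
    return 3


@dataclass(frozen=True)
class LesionQuantification:
    """Volumetry of one imaging timepoint."""

    v_hypo_mm3: float
    v_hyper_mm3: float
    ratio: float
    cyst_present: bool
    hypo_mask: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    hyper_mask: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.v_hypo_mm3 < 0 or self.v_hyper_mm3 < 0:
            raise ValueError("volumes must be >= 0")


@dataclass(frozen=True)
class SeverityScore:
    hyper_points: int
    hypo_points: int
    ratio_points: int
    cyst_points: int
    total: int


def severity_score(
    quant: LesionQuantification, rubric: ScoringRubric = ScoringRubric()
) -> SeverityScore:
    """Apply the severity rubric to one quantification; total in 0..10."""
    hyper = _volume_points(quant.v_hyper_mm3, rubric.hyper_edges)
    hypo = _volume_points(quant.v_hypo_mm3, rubric.hypo_edges)
    ratio = _ratio_points(quant.ratio, rubric.ratio_edges)
    cyst = rubric.cyst_points if quant.cyst_present else 0
    return SeverityScore(hyper, hypo, ratio, cyst, hyper + hypo + ratio + cyst)


def quantify_timepoint(
    volume: PhantomVolume,
    seg_config: SegmentationConfig = SegmentationConfig(),
    cyst_config: CystConfig = CystConfig(),
    rubric: ScoringRubric = ScoringRubric(),
) -> tuple[LesionQuantification, SeverityScore]:
    """Segment, measure and score one imaging timepoint (deterministic)."""
    hypo_mask, hyper_mask = segment_lesions(volume, seg_config)
    v_hypo = compute_volume(hypo_mask, volume.spacing_mm)
    v_hyper = compute_volume(hyper_mask, volume.spacing_mm)
    ratio = hyper_hypo_ratio(v_hyper, v_hypo)
    cyst = detect_cyst(volume, hyper_mask, cyst_config)
    quant = LesionQuantification(v_hypo, v_hyper, ratio, cyst, hypo_mask, hyper_mask)
    return quant, severity_score(quant, rubric)


def quantification_record(quant: LesionQuantification, score: SeverityScore) -> dict:
    """JSON-serializable per-timepoint record."""
    ratio = quant.ratio
    if math.isnan(ratio):
        ratio_out: "float | str | None" = "undefined"
    elif math.isinf(ratio):
        ratio_out = "infinite"
    else:
        ratio_out = ratio
    return {
        "VHypo_mm3": quant.v_hypo_mm3,
        "VHyper_mm3": quant.v_hyper_mm3,
        "ratio": ratio_out,
        "cyst": quant.cyst_present,
        "points": {
            "hyper": score.hyper_points,
            "hypo": score.hypo_points,
            "ratio": score.ratio_points,
            "cyst": score.cyst_points,
        },
        "total": score.total,
    }
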