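"""Synthetic study data: cytokine cohorts, MRI-like phantoms, treadmill series.

The study's raw per-animal data are not deposited; what is printed are group
summaries (median [min; max] per analyte), the MRI geometry (0.5 mm axial
slices) and the treadmill protocol (speed ceiling 50 m/min at days 7, 14, 21,
30, 60).  This module generates cohorts and images that honour those printed
facts exactly, with known ground truth, so every downstream stage can be
exercised and scored without any download.

Cohort construction pins order statistics: the sample minimum, maximum and
median of every generated analyte/group equal the published summary *exactly*
(for even n both central order statistics are set to the published median).
Remaining values are drawn uniformly inside the two sub-ranges — the study
gives no within-group distribution shape, so uniform fill is an explicit
modelling assumption, not an inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

GROUPS = ("intact", "favorable", "adverse")
COHORT_COLUMNS = ("animal_id", "group", "analyte", "value_pg_ml")

#: Treadmill protocol: test days and the speed ceiling (m/min).
TREADMILL_DAYS = (7, 14, 21, 30, 60)
SPEED_CEILING = 50.0

_ID_PREFIX = {"intact": "I", "favorable": "F", "adverse": "A"}


# --------------------------------------------------------------------------
# cytokine cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyteDistributionSpec:
    """Published summary (median [minimum; maximum], pg/mL) of one analyte in one group."""

    analyte: str
    group: str
    median: float
    minimum: float
    maximum: float
    n: int

    def __post_init__(self) -> None:
        tag = f"{self.analyte}/{self.group}"
        if self.n < 1:
            raise ValueError(f"{tag}: group size must be >= 1, got {self.n}")
        if self.minimum < 0:
            raise ValueError(f"{tag}: concentrations must be >= 0, got minimum {self.minimum}")
        if not (self.minimum <= self.median <= self.maximum):
            raise ValueError(
                f"{tag}: requires minimum <= median <= maximum, got "
                f"[{self.minimum}; {self.median}; {self.maximum}]"
            )


def _pinned_sample(spec: AnalyteDistributionSpec, rng: np.random.Generator) -> np.ndarray:
    """n values whose sample min/median/max equal the spec exactly (sorted)."""
    n, lo, med, hi = spec.n, spec.minimum, spec.median, spec.maximum
    tag = f"{spec.analyte}/{spec.group}"
    if n == 1:
        if not lo == med == hi:
            raise ValueError(f"{tag}: n=1 requires minimum = median = maximum")
        return np.array([med])
    if n == 2:
        if (lo + hi) / 2.0 != med:
            raise ValueError(f"{tag}: n=2 requires median = (minimum+maximum)/2")
        return np.array([lo, hi])
    values = [lo, hi]
    if n % 2:
        values.append(med)
        n_free = (n - 1) // 2 - 1
    else:
        # both central order statistics pinned to the published median
        values.extend([med, med])
        n_free = n // 2 - 2
    values.extend(rng.uniform(lo, med, n_free))
    values.extend(rng.uniform(med, hi, n_free))
    return np.sort(np.asarray(values, dtype=float))


def generate_cytokine_cohort(
    specs: Iterable[AnalyteDistributionSpec], seed: int
) -> pd.DataFrame:
    """Generate a per-animal cohort table from group summaries.

    Returns a long-format table with columns ``animal_id, group, analyte,
    value_pg_ml``.  For every analyte/group the sample minimum, maximum and
    median equal the spec exactly; values are shuffled across animals within
    a group so animals are not rank-correlated across analytes.
    """
    specs = sorted(set(specs), key=lambda s: (s.group, s.analyte))
    if not specs:
        raise ValueError("no distribution specs given")
    group_n: dict[str, int] = {}
    for s in specs:
        if group_n.setdefault(s.group, s.n) != s.n:
            raise ValueError(
                f"inconsistent group size for {s.group!r}: {s.n} vs {group_n[s.group]}"
            )
    rng = np.random.default_rng(seed)
    records = []
    for s in specs:
        prefix = _ID_PREFIX.get(s.group, s.group + "-")
        animals = [f"{prefix}{i + 1}" for i in range(s.n)]
        values = _pinned_sample(s, rng)
        for animal, value in zip(animals, values[rng.permutation(s.n)]):
            records.append((animal, s.group, s.analyte, float(value)))
    return pd.DataFrame.from_records(records, columns=COHORT_COLUMNS)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check cohort-table invariants; returns the table for chaining."""
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    if cohort.duplicated(subset=["animal_id", "analyte"]).any():
        raise ValueError("duplicate (animal, analyte) measurements")
    if (cohort["value_pg_ml"] < 0).any():
        raise ValueError("negative concentrations in cohort table")
    return cohort


def read_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    validate_cohort(cohort).to_csv(path, index=False)


# --------------------------------------------------------------------------
# MRI-like phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid lesion in millimetre coordinates."""

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    offset: float  # signed intensity offset on the background

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes_mm):
            raise ValueError(f"semi-axes must be > 0, got {self.semiaxes_mm}")


@dataclass(frozen=True)
class Sphere:
    """Spherical cyst-like structure in millimetre coordinates."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    offset: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"radius must be > 0, got {self.radius_mm}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of a single-channel spinal MRI phantom.

    One scalar channel stands for a T2-weighted-like image; hypointense and
    hyperintense lesions are signed offsets on a common background.  Default
    grid is 64x64x48 voxels at 0.25x0.25x0.5 mm (axial slices 0.5 mm thick,
    in-plane finer, a scaled-down 60 mm field of view).
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (0.25, 0.25, 0.5)
    background: float = 100.0
    hypo: Optional[Ellipsoid] = None
    hyper: Optional[Ellipsoid] = None
    cyst: Optional[Sphere] = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be > 0, got {self.spacing_mm}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        extent = tuple(n * s for n, s in zip(self.shape, self.spacing_mm))
        for name, lesion in (("hypo", self.hypo), ("hyper", self.hyper)):
            if lesion is not None:
                for c, a, e in zip(lesion.center_mm, lesion.semiaxes_mm, extent):
                    if c - a < 0 or c + a > e:
                        raise ValueError(f"{name} lesion exceeds grid bounds (extent {extent} mm)")
        if self.cyst is not None:
            for c, e in zip(self.cyst.center_mm, extent):
                if c - self.cyst.radius_mm < 0 or c + self.cyst.radius_mm > e:
                    raise ValueError(f"cyst exceeds grid bounds (extent {extent} mm)")

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key, typ in (("hypo", Ellipsoid), ("hyper", Ellipsoid), ("cyst", Sphere)):
            if d.get(key) is not None and not isinstance(d[key], typ):
                sub = dict(d[key])
                for f in ("center_mm", "semiaxes_mm"):
                    if f in sub:
                        sub[f] = tuple(sub[f])
                d[key] = typ(**sub)
        for f in ("shape", "spacing_mm"):
            if f in d:
                d[f] = tuple(d[f])
        return cls(**d)


@dataclass
class PhantomVolume:
    """3D scalar intensity grid with voxel spacing in mm."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "T2w-like"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be > 0, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


class Phantom(NamedTuple):
    volume: PhantomVolume
    hypo_mask: np.ndarray
    hyper_mask: np.ndarray
    cyst_mask: np.ndarray


def _voxel_centers(shape, spacing):
    idx = np.indices(shape, dtype=float)
    return [(idx[k] + 0.5) * spacing[k] for k in range(3)]


def _ellipsoid_mask(shape, spacing, center, semiaxes) -> np.ndarray:
    x, y, z = _voxel_centers(shape, spacing)
    return (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize the phantom and return intensities plus ground-truth masks.

    A voxel belongs to a mask when its centre lies inside the analytic
    ellipsoid/sphere; intensity = background + applicable offsets + seeded
    Gaussian noise.
    """
    empty = np.zeros(spec.shape, dtype=bool)
    hypo = (
        _ellipsoid_mask(spec.shape, spec.spacing_mm, spec.hypo.center_mm, spec.hypo.semiaxes_mm)
        if spec.hypo is not None
        else empty
    )
    hyper = (
        _ellipsoid_mask(spec.shape, spec.spacing_mm, spec.hyper.center_mm, spec.hyper.semiaxes_mm)
        if spec.hyper is not None
        else empty
    )
    cyst = (
        _ellipsoid_mask(
            spec.shape, spec.spacing_mm, spec.cyst.center_mm, (spec.cyst.radius_mm,) * 3
        )
        if spec.cyst is not None
        else empty
    )
    data = np.full(spec.shape, spec.background, dtype=float)
    if spec.hypo is not None:
        data[hypo] += spec.hypo.offset
    if spec.hyper is not None:
        data[hyper] += spec.hyper.offset
    if spec.cyst is not None:
        data[cyst] += spec.cyst.offset
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, spec.shape)
    return Phantom(PhantomVolume(data, spec.spacing_mm), hypo, hyper, cyst)


# --- NIfTI I/O -------------------------------------------------------------

def save_volume(volume: PhantomVolume, path) -> None:
    affine = np.diag([*volume.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


def load_volume(path, modality: str = "T2w-like") -> PhantomVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PhantomVolume(np.asarray(img.get_fdata(), dtype=float), spacing, modality)


def save_mask(mask: np.ndarray, spacing_mm, path) -> None:
    affine = np.diag([*spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


# --------------------------------------------------------------------------
# treadmill recovery series
# --------------------------------------------------------------------------

def generate_treadmill_series(
    outcome: str,
    seed: int,
    plateau: "float | None" = None,
    days: Sequence[int] = TREADMILL_DAYS,
) -> pd.DataFrame:
    """Maximum treadmill speed (m/min) per test day for one animal.

    Intact animals run at the 50 m/min ceiling on every day.  Injured animals
    recover along a saturating curve toward ``plateau`` (default 45 m/min for
    a favorable outcome, 12 for adverse), with mild seeded jitter; series are
    monotone non-decreasing and clipped to [0, 50].
    """
    days = np.asarray(sorted(days), dtype=float)
    if len(days) == 0 or len(np.unique(days)) != len(days):
        raise ValueError("test days must be distinct")
    if outcome == "intact":
        speeds = np.full(days.shape, SPEED_CEILING)
    elif outcome in ("favorable", "adverse"):
        if plateau is None:
            plateau = 45.0 if outcome == "favorable" else 12.0
        if not 0 < plateau <= SPEED_CEILING:
            raise ValueError(f"plateau must be in (0, {SPEED_CEILING}], got {plateau}")
        rng = np.random.default_rng(seed)
        t_half = rng.uniform(5.0, 15.0)  # days to reach half the plateau
        speeds = plateau * days / (days + t_half)
        speeds = speeds + rng.normal(0.0, 0.03 * plateau, days.shape)
        speeds = np.clip(speeds, 0.0, min(plateau, SPEED_CEILING))
        speeds = np.maximum.accumulate(speeds)
    else:
        raise ValueError(f"unknown outcome label {outcome!r}")
    return pd.DataFrame({"day": days.astype(int), "max_speed": speeds})
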