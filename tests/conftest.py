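import numpy as np
import pytest

from cryosci.panel import reference_specs
from cryosci.synth import Ellipsoid, PhantomSpec, Sphere, generate_cytokine_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """One cohort pinned to the published 21-analyte panel."""
    return generate_cytokine_cohort(reference_specs(), seed=11)


def two_lesion_spec(noise_sigma: float = 0.0, cyst: bool = False, seed: int = 3) -> PhantomSpec:
    """Phantom with disjoint hypo and hyper ellipsoids (and optionally a cyst)."""
    return PhantomSpec(
        hypo=Ellipsoid((8.0, 8.0, 5.5), (2.0, 1.3, 1.0), -40.0),
        hyper=Ellipsoid((8.0, 8.0, 11.0), (2.5, 1.6, 1.2), +40.0),
        cyst=Sphere((8.0, 8.0, 17.5), 1.0, +120.0) if cyst else None,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom
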