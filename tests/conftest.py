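"""Shared fixtures: published parameter sets used as generator ground truths."""

import numpy as np
import pytest

from aortamech import TensileSpecimen
from aortamech.synthetic import TensileGenConfig

# (region, group, direction) -> four bilinear parameters, as reported for
# the lamb-aorta study conditions this package emulates.
TENSILE_SETS = {
    ("DTA", "Control", "longitudinal"): dict(E1=65.24, E2=204.1, lambda_t=1.36, sigma_t=39.50),
    ("DTA", "Control", "circumferential"): dict(E1=58.10, E2=395.7, lambda_t=1.57, sigma_t=63.61),
    ("DTA", "Hemin", "longitudinal"): dict(E1=92.05, E2=256.9, lambda_t=1.61, sigma_t=62.89),
    ("DTA", "Hemin", "circumferential"): dict(E1=85.49, E2=505.9, lambda_t=1.61, sigma_t=80.36),
    ("DTA", "Sildenafil", "longitudinal"): dict(E1=119.7, E2=279.1, lambda_t=1.52, sigma_t=69.61),
    ("DTA", "Sildenafil", "circumferential"): dict(E1=129.7, E2=954.7, lambda_t=1.52, sigma_t=113.5),
    ("DAA", "Control", "longitudinal"): dict(E1=120.5, E2=1451.0, lambda_t=1.50, sigma_t=156.9),
    ("DAA", "Control", "circumferential"): dict(E1=126.1, E2=1198.0, lambda_t=1.41, sigma_t=89.63),
    ("DAA", "Hemin", "longitudinal"): dict(E1=162.2, E2=1303.0, lambda_t=1.45, sigma_t=128.7),
    ("DAA", "Hemin", "circumferential"): dict(E1=295.6, E2=2437.0, lambda_t=1.48, sigma_t=251.1),
    ("DAA", "Sildenafil", "longitudinal"): dict(E1=222.5, E2=2051.0, lambda_t=1.50, sigma_t=230.1),
    ("DAA", "Sildenafil", "circumferential"): dict(E1=361.7, E2=2171.0, lambda_t=1.49, sigma_t=304.4),
}

CONTROL_DTA_LONG = TENSILE_SETS[("DTA", "Control", "longitudinal")]


def interpolated_tensile_grid(n_extra: int = 8) -> list[dict]:
    """The 12 reported parameter sets plus interpolations between them,
    spanning the reported range of all four parameters."""
    base = [dict(p) for p in TENSILE_SETS.values()]
    keys = ("E1", "E2", "lambda_t", "sigma_t")
    rng = np.random.default_rng(20_240_703)
    out = list(base)
    while len(out) < len(base) + n_extra:
        a, b = rng.choice(len(base), size=2, replace=False)
        w = rng.uniform(0.25, 0.75)
        cand = {k: w * base[a][k] + (1 - w) * base[b][k] for k in keys}
        if cand["E2"] > cand["E1"] > 0 and 1.05 < cand["lambda_t"] < 1.75:
            out.append(cand)
    return out


@pytest.fixture
def specimen() -> TensileSpecimen:
    return TensileSpecimen(width_w0=5.0, gauge_length_l0=6.0, thickness_t0=2.0,
                           specimen_id="fixture")


@pytest.fixture
def control_dta_long_config() -> TensileGenConfig:
    return TensileGenConfig(**CONTROL_DTA_LONG, smoothing_s=1e-4, n_points=200,
                            lambda_max=1.8)
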