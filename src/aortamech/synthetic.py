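"""Synthetic inputs with controllable ground truths for every pipeline stage.

No raw measurements are deposited for the study conditions this package
targets, so every analysis stage is validated by parameter recovery on
generated data: tensile records from a smoothed-bilinear stress-stretch
law, opened-ring landmarks at a known opening angle, pre-stretch marks
encoding a known per-segment profile, trichrome slides painted through the
forward Beer-Lambert model at a known collagen fraction and nuclei density,
and group samples from stated distributions.  Every generator is a pure
function of its config (seeds included) and records its ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeneratorError
from .geometry import OpenedRingLandmarks, PrestretchMarks
from .groupstats import GroupSample
from .histology import MASSON_STAIN_OD, TrichromeImage
from .tensile import KPA_PER_MPA, ForceDisplacementCurve, TensileSpecimen

__all__ = [
    "TensileGenConfig",
    "SceneConfig",
    "gen_tensile_curve",
    "smoothed_bilinear_stress",
    "exponential_toe_stress",
    "gen_opened_ring",
    "gen_prestretch_marks",
    "gen_trichrome_slide",
    "gen_group_dataset",
]


# --------------------------------------------------------------------------
# tensile curves
# --------------------------------------------------------------------------

DEFAULT_SPECIMEN = TensileSpecimen(
    width_w0=5.0, gauge_length_l0=6.0, thickness_t0=2.0, specimen_id="synthetic"
)


@dataclass(frozen=True)
class TensileGenConfig:
    """Ground truth and sampling settings for one synthetic tensile record.

    The stress law is a smoothed-bilinear blend with corner sharpness
    ``smoothing_s`` (in stretch units): ``s -> 0`` recovers an exact corner
    at ``(lambda_t, sigma_t)`` with slopes ``E1`` below and ``E2`` above.
    Force noise is Gaussian with SD ``noise_sd_frac`` of the peak force.
    """

    E1: float
    E2: float
    lambda_t: float
    sigma_t: float
    lambda_max: float = 1.8
    smoothing_s: float = 0.01
    n_points: int = 200
    noise_sd_frac: float = 0.0
    rupture_drop_frac: float = 0.0
    seed: int = 0
    specimen: TensileSpecimen = DEFAULT_SPECIMEN

    def __post_init__(self) -> None:
        if not (self.E2 > self.E1 > 0):
            raise GeneratorError("strain stiffening requires E2 > E1 > 0")
        if not (1.0 < self.lambda_t < self.lambda_max):
            raise GeneratorError("need 1 < lambda_t < lambda_max")
        if not self.smoothing_s > 0:
            raise GeneratorError("smoothing_s must be positive")
        if self.n_points < 20:
            raise GeneratorError("n_points must be >= 20")

    def ground_truth(self) -> dict:
        return {
            "E1_kPa": self.E1,
            "E2_kPa": self.E2,
            "lambda_t": self.lambda_t,
            "sigma_t_kPa": self.sigma_t,
        }


def smoothed_bilinear_stress(
    lam: np.ndarray, e1: float, e2: float, lam_t: float, sig_t: float, s: float
) -> np.ndarray:
    """Smoothed-bilinear Cauchy stress law (kPa).

    sigma(lambda) = sigma_t + E1 (lambda - lambda_t)
                    + (E2 - E1) * s * log(1 + exp((lambda - lambda_t)/s))
    """
    z = (np.asarray(lam, dtype=float) - lam_t) / s
    return sig_t + e1 * (lam - lam_t) + (e2 - e1) * s * np.logaddexp(0.0, z)


def exponential_toe_stress(
    lam: np.ndarray, a: float, b: float
) -> tuple[np.ndarray, dict]:
    """Exponential-toe law sigma = a (exp(b (lambda-1)) - 1) with closed-form
    tangent ground truths at the domain ends (optional realism generator)."""
    lam = np.asarray(lam, dtype=float)
    sig = a * (np.exp(b * (lam - 1.0)) - 1.0)
    truth = {
        "tangent_at_1_kPa": a * b,
        "tangent_at_end_kPa": a * b * math.exp(b * (lam[-1] - 1.0)),
    }
    return sig, truth


def gen_tensile_curve(
    config: TensileGenConfig,
) -> tuple[ForceDisplacementCurve, dict]:
    """Synthesize a force-displacement record and return it with its ground truth.

    Stress is evaluated on a uniform stretch grid in [1, lambda_max],
    clipped at zero, converted to force through the specimen geometry, with
    optional seeded Gaussian force noise and an optional appended post-peak
    drop segment for rupture-detection testing.
    """
    sp = config.specimen
    lam = np.linspace(1.0, config.lambda_max, config.n_points)
    sig = smoothed_bilinear_stress(
        lam, config.E1, config.E2, config.lambda_t, config.sigma_t, config.smoothing_s
    )
    if np.all(sig <= 0):
        raise GeneratorError("infeasible config: stress non-positive over whole domain")
    sig = np.clip(sig, 0.0, None)

    force = sig / KPA_PER_MPA * sp.cross_section_mm2 / lam  # N
    disp = (lam - 1.0) * sp.gauge_length_l0  # mm

    rupture_index = len(lam) - 1
    if config.rupture_drop_frac > 0:
        n_drop = 5
        dlam = lam[1] - lam[0]
        lam_drop = lam[-1] + dlam * np.arange(1, n_drop + 1)
        # force decays linearly well below the configured drop fraction
        f_end = force[-1]
        f_drop = f_end * np.linspace(1.0, 1.0 - 1.5 * config.rupture_drop_frac, n_drop + 1)[1:]
        f_drop = np.clip(f_drop, 0.0, None)
        force = np.concatenate([force, f_drop])
        disp = np.concatenate([disp, (lam_drop - 1.0) * sp.gauge_length_l0])

    if config.noise_sd_frac > 0:
        rng = np.random.default_rng(config.seed)
        force = force + rng.normal(0.0, config.noise_sd_frac * force.max(), force.shape)
        force = np.clip(force, 0.0, None)

    truth = config.ground_truth()
    truth["rupture_index"] = rupture_index
    curve = ForceDisplacementCurve(disp, force, sp)
    return curve, truth


# --------------------------------------------------------------------------
# residual-strain geometry
# --------------------------------------------------------------------------


def gen_opened_ring(
    alpha_deg: float, ray_length_mm: float = 5.0, seed: int = 0
) -> OpenedRingLandmarks:
    """Landmarks of an opened ring with a known opening angle.

    The vertex sits at a seeded random offset; the two cut-end landmarks
    lie on rays of ``ray_length_mm`` at +/- alpha/2 about a seeded random
    orientation, so recovery must be rotation- and translation-invariant.
    """
    if not 0.0 < alpha_deg < 180.0:
        raise GeneratorError("alpha must be in (0, 180) degrees")
    if not ray_length_mm > 0:
        raise GeneratorError("ray length must be positive")
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    offset = rng.uniform(-10.0, 10.0, size=2)
    half = math.radians(alpha_deg) / 2.0
    end_a = offset + ray_length_mm * np.array(
        [math.cos(theta0 + half), math.sin(theta0 + half)]
    )
    end_b = offset + ray_length_mm * np.array(
        [math.cos(theta0 - half), math.sin(theta0 - half)]
    )
    return OpenedRingLandmarks(
        vertex=tuple(offset), end_a=tuple(end_a), end_b=tuple(end_b)
    )


def gen_prestretch_marks(
    lambda_profile,
    in_vivo_total_mm: float = 50.0,
    seed: int = 0,
    jitter_mm: float = 0.0,
) -> PrestretchMarks:
    """Six in-vivo/ex-vivo mark positions encoding a per-segment pre-stretch profile.

    In-vivo marks are equidistant over ``in_vivo_total_mm``; ex-vivo
    segment i is the in-vivo segment length divided by ``lambda_profile[i]``.
    Optional seeded jitter perturbs the interior marks of both
    configurations by up to ``jitter_mm``.
    """
    prof = np.asarray(lambda_profile, dtype=float)
    if prof.shape != (5,) or np.any(prof <= 0):
        raise GeneratorError("lambda_profile must be 5 positive ratios")
    seg_in = np.full(5, in_vivo_total_mm / 5.0)
    seg_ex = seg_in / prof
    in_vivo = np.concatenate([[0.0], np.cumsum(seg_in)])
    ex_vivo = np.concatenate([[0.0], np.cumsum(seg_ex)])
    if jitter_mm > 0:
        rng = np.random.default_rng(seed)
        min_seg = min(seg_in.min(), seg_ex.min())
        amp = min(jitter_mm, 0.4 * min_seg)  # keep marks strictly increasing
        in_vivo[1:-1] += rng.uniform(-amp, amp, 4)
        ex_vivo[1:-1] += rng.uniform(-amp, amp, 4)
    return PrestretchMarks(tuple(in_vivo), tuple(ex_vivo))


# --------------------------------------------------------------------------
# trichrome slides
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneConfig:
    """Ground truth and rendering settings of one synthetic trichrome slide.

    Stain densities are in OD units along the module's stain vectors; the
    tissue region is a centred rectangle leaving a white border of
    ``tissue_margin_px``.  Classes are painted disjointly: nuclei ellipses
    first (non-touching, 8-connectivity-safe gap), then exactly the target
    fraction of the remaining tissue pixels as collagen, cytoplasm
    elsewhere.
    """

    image_size: int = 512
    pixel_size_mm: float = 0.001
    collagen_fraction: float = 0.4375
    nuclei_density_per_mm2: float = 2718.0
    nuclei_axes_px: tuple[int, int] = (3, 2)  # semi-axes (rows, cols)
    tissue_margin_px: int = 16
    collagen_od: float = 1.0
    cytoplasm_od: float = 0.6
    nuclei_od: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.collagen_fraction <= 1.0:
            raise GeneratorError("collagen_fraction must be in [0, 1]")
        if self.nuclei_density_per_mm2 < 0 or self.pixel_size_mm <= 0:
            raise GeneratorError("invalid density or pixel size")
        if self.image_size - 2 * self.tissue_margin_px < 8 * max(self.nuclei_axes_px):
            raise GeneratorError("tissue region too small for the requested nuclei")


def _ellipse_footprint(ry: int, rx: int) -> np.ndarray:
    yy, xx = np.mgrid[-ry : ry + 1, -rx : rx + 1]
    return (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0


def gen_trichrome_slide(scene: SceneConfig) -> tuple[TrichromeImage, dict]:
    """Render a synthetic trichrome slide through the forward Beer-Lambert model.

    Returns the 8-bit image and a ground-truth dict with the painted
    collagen percentage, nuclei count and density, and tissue area.
    """
    rng = np.random.default_rng(scene.seed)
    h = w = scene.image_size
    m = scene.tissue_margin_px
    tissue = np.zeros((h, w), dtype=bool)
    tissue[m : h - m, m : w - m] = True
    n_tissue = int(tissue.sum())
    tissue_area_mm2 = n_tissue * scene.pixel_size_mm**2

    # --- nuclei: non-overlapping ellipses with a >= 1 px gap (8-conn safe)
    n_nuclei = int(round(scene.nuclei_density_per_mm2 * tissue_area_mm2))
    ry, rx = scene.nuclei_axes_px
    foot = _ellipse_footprint(ry, rx)
    # pad before dilating: binary_dilation keeps the array shape, and the
    # gap guarantee needs the full dilated footprint, uncropped
    dil = ndimage.binary_dilation(np.pad(foot, 1), structure=np.ones((3, 3), bool))
    dh, dw = dil.shape
    nuclei_mask = np.zeros((h, w), dtype=bool)
    occupied = np.zeros((h, w), dtype=bool)
    placed = 0
    attempts = 0
    max_attempts = max(200 * n_nuclei, 10_000)
    lo_y, hi_y = m + ry + 1, h - m - ry - 1
    lo_x, hi_x = m + rx + 1, w - m - rx - 1
    while placed < n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise GeneratorError(
                f"could not pack {n_nuclei} nuclei (placed {placed}); lower the density"
            )
        cy = int(rng.integers(lo_y, hi_y))
        cx = int(rng.integers(lo_x, hi_x))
        sl = (slice(cy - ry - 1, cy - ry - 1 + dh), slice(cx - rx - 1, cx - rx - 1 + dw))
        if np.any(occupied[sl] & dil):
            continue
        occupied[sl] |= dil
        nuclei_mask[cy - ry : cy + ry + 1, cx - rx : cx + rx + 1] |= foot
        placed += 1

    # --- collagen: exact pixel count among the non-nucleus tissue pixels
    free = tissue & ~nuclei_mask
    free_idx = np.flatnonzero(free.ravel())
    n_collagen = int(round(scene.collagen_fraction * n_tissue))
    if n_collagen > len(free_idx):
        raise GeneratorError("collagen fraction infeasible after nuclei packing")
    chosen = rng.permutation(free_idx)[:n_collagen]
    collagen_mask = np.zeros(h * w, dtype=bool)
    collagen_mask[chosen] = True
    collagen_mask = collagen_mask.reshape(h, w)

    densities = np.zeros((h, w, 3), dtype=float)
    densities[..., 0][collagen_mask] = scene.collagen_od
    densities[..., 1][tissue & ~nuclei_mask & ~collagen_mask] = scene.cytoplasm_od
    densities[..., 2][nuclei_mask] = scene.nuclei_od

    od = densities @ MASSON_STAIN_OD
    rgb = np.clip(np.rint(256.0 * np.exp(-od) - 1.0), 0, 255).astype(np.uint8)

    image = TrichromeImage(rgb=rgb, pixel_size_mm=scene.pixel_size_mm)
    truth = {
        "collagen_pct": 100.0 * n_collagen / n_tissue,
        "nuclei_count": placed,
        "nuclei_density_per_mm2": placed / tissue_area_mm2,
        "nuclei_area_pct": 100.0 * nuclei_mask.sum() / n_tissue,
        "tissue_area_mm2": tissue_area_mm2,
    }
    return image, truth


# --------------------------------------------------------------------------
# group samples
# --------------------------------------------------------------------------


def gen_group_dataset(spec: list[dict], seed: int = 0) -> list[GroupSample]:
    """Seeded group samples from stated distributions.

    ``spec`` is a list of dicts with keys ``group``, ``n``, ``dist``
    ('normal' or 'lognormal') and distribution parameters (``mean``/``sd``
    for normal, ``mu``/``sigma`` for lognormal).
    """
    rng = np.random.default_rng(seed)
    samples = []
    for entry in spec:
        n = int(entry["n"])
        dist = entry.get("dist", "normal")
        if dist == "normal":
            vals = rng.normal(entry.get("mean", 0.0), entry.get("sd", 1.0), n)
        elif dist == "lognormal":
            vals = rng.lognormal(entry.get("mu", 0.0), entry.get("sigma", 1.0), n)
        else:
            raise GeneratorError(f"unknown distribution {dist!r}")
        samples.append(GroupSample(tuple(vals), group=entry.get("group", f"g{len(samples)}")))
    return samples
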