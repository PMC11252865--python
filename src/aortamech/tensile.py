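"""Uniaxial tensile analysis of arterial wall strips.

A rectangular strip of artery wall (width ``w0``, gauge length ``l0``,
thickness ``t0``, all in mm) is stretched to rupture while force (N) and
crosshead displacement (mm) are recorded.  Under the incompressibility
assumption standard for arterial tissue the record maps to a Cauchy
stress-stretch curve

    lambda = (l0 + d) / l0
    sigma  = F * lambda / (w0 * t0)        [N/mm^2 = MPa, reported in kPa]

Arterial stress-stretch curves are bilinear to good approximation: a
compliant low-stretch regime with elastic modulus ``E1`` (elastin
dominated), a stiff high-stretch regime with modulus ``E2`` (collagen
recruitment), and a transition point ``(lambda_t, sigma_t)`` between them.
:class:`BilinearModel` extracts the four parameters by an automated
two-window search: the longest window anchored at the curve start (and,
symmetrically, at the last pre-rupture sample) whose ordinary least-squares
fit reaches a configurable coefficient of determination, followed by an
iterative refinement that pins each window to its own side of the estimated
transition.  The transition point is the intersection of the two fitted
lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateTransitionError,
    InsufficientDataError,
    InvalidSpecimenError,
    MalformedRecordError,
)

__all__ = [
    "TensileSpecimen",
    "ForceDisplacementCurve",
    "StressStretchCurve",
    "LinearWindowFit",
    "BilinearConfig",
    "BilinearFit",
    "BilinearModel",
    "compute_stretch",
    "compute_cauchy_stress",
    "to_stress_stretch",
    "truncate_at_rupture",
    "fit_linear_window",
    "extract_bilinear_parameters",
]

KPA_PER_MPA = 1000.0

DIRECTIONS = ("longitudinal", "circumferential")
REGIONS = ("DTA", "DAA")


@dataclass(frozen=True)
class TensileSpecimen:
    """Geometry and identity of one tensile strip.

    Dimensions are in mm.  ``direction`` is the loading direction relative
    to the arterial duct; ``region`` identifies the aortic zone
    (descending thoracic ``DTA`` or distal abdominal ``DAA``).
    """

    width_w0: float
    gauge_length_l0: float
    thickness_t0: float
    direction: str = "longitudinal"
    region: str = "DTA"
    group: str = "Control"
    specimen_id: str = ""
    displacement_rate_mm_min: float | None = None  # metadata only

    def __post_init__(self) -> None:
        if not (self.width_w0 > 0 and self.gauge_length_l0 > 0 and self.thickness_t0 > 0):
            raise InvalidSpecimenError(
                f"specimen dimensions must be positive, got w0={self.width_w0}, "
                f"l0={self.gauge_length_l0}, t0={self.thickness_t0}"
            )
        if self.direction not in DIRECTIONS:
            raise InvalidSpecimenError(f"direction must be one of {DIRECTIONS}")
        if self.region not in REGIONS:
            raise InvalidSpecimenError(f"region must be one of {REGIONS}")

    @property
    def cross_section_mm2(self) -> float:
        return self.width_w0 * self.thickness_t0


@dataclass
class ForceDisplacementCurve:
    """Raw tensile record: displacement (mm) and force (N) plus specimen geometry."""

    displacement: np.ndarray
    force: np.ndarray
    specimen: TensileSpecimen
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape or self.displacement.ndim != 1:
            raise MalformedRecordError("displacement and force must be 1-D and aligned")
        if len(self.displacement) < 2:
            raise MalformedRecordError("record needs at least 2 samples")
        if len(self.displacement) < 20:
            self.flags.add("short_record")
        if abs(self.displacement[0]) > 1e-9:
            raise MalformedRecordError("displacement must start at 0")
        if np.any(np.diff(self.displacement) < 0):
            raise MalformedRecordError("displacement must be non-decreasing")
        fmax = float(np.max(self.force)) if len(self.force) else 0.0
        if np.any(self.force < -1e-9 * max(fmax, 1.0)):
            raise MalformedRecordError("negative forces after baseline correction")

    def __len__(self) -> int:
        return len(self.displacement)


@dataclass
class StressStretchCurve:
    """Cauchy stress (kPa) versus stretch, with the rupture sample marked."""

    stretch: np.ndarray
    stress_kpa: np.ndarray
    rupture_index: int
    specimen: TensileSpecimen | None = None
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.stress_kpa = np.asarray(self.stress_kpa, dtype=float)
        if self.stretch.shape != self.stress_kpa.shape or self.stretch.ndim != 1:
            raise MalformedRecordError("stretch and stress must be 1-D and aligned")

    def __len__(self) -> int:
        return len(self.stretch)

    @property
    def pre_rupture(self) -> tuple[np.ndarray, np.ndarray]:
        """(stretch, stress) up to and including the rupture sample."""
        k = self.rupture_index + 1
        return self.stretch[:k], self.stress_kpa[:k]


def compute_stretch(curve: ForceDisplacementCurve) -> np.ndarray:
    """Stretch lambda = (l0 + d) / l0 for every sample of the record."""
    l0 = curve.specimen.gauge_length_l0
    if not l0 > 0:
        raise InvalidSpecimenError("gauge length must be positive")
    return (l0 + curve.displacement) / l0


def compute_cauchy_stress(
    curve: ForceDisplacementCurve, stretch: np.ndarray | None = None
) -> np.ndarray:
    """Cauchy stress sigma = F * lambda / (w0 * t0), returned in kPa.

    N and mm inputs yield MPa; the result is scaled by 1000 so parameter
    magnitudes match conventional reporting for arterial tissue.
    """
    area = curve.specimen.cross_section_mm2
    if not area > 0:
        raise InvalidSpecimenError("cross-section w0*t0 must be positive")
    lam = compute_stretch(curve) if stretch is None else np.asarray(stretch, dtype=float)
    if lam.shape != curve.force.shape:
        raise MalformedRecordError("stretch not aligned with force samples")
    return curve.force * lam / area * KPA_PER_MPA


def to_stress_stretch(curve: ForceDisplacementCurve) -> StressStretchCurve:
    """Convert a raw record to a stress-stretch curve (no rupture truncation)."""
    lam = compute_stretch(curve)
    sig = compute_cauchy_stress(curve, lam)
    return StressStretchCurve(
        stretch=lam,
        stress_kpa=sig,
        rupture_index=int(np.argmax(sig)),
        specimen=curve.specimen,
        flags=set(curve.flags),
    )


def truncate_at_rupture(
    ss: StressStretchCurve, drop_fraction: float = 0.2
) -> StressStretchCurve:
    """Cut the curve at the rupture peak.

    The rupture sample is the global stress maximum.  Samples after it are
    discarded only when the post-peak stress falls below
    ``(1 - drop_fraction) * sigma_max`` somewhere — a genuine rupture rather
    than terminal noise.  A curve whose maximum is the last sample is
    returned unchanged with a ``no_rupture`` flag; an interior maximum with
    only a shallow post-peak dip keeps the full curve with a
    ``no_clear_rupture`` flag.
    """
    if len(ss) == 0:
        raise MalformedRecordError("empty stress-stretch curve")
    sig = ss.stress_kpa
    imax = int(np.argmax(sig))
    flags = set(ss.flags)
    if imax == len(sig) - 1:
        flags.add("no_rupture")
        return replace(ss, rupture_index=imax, flags=flags)
    post_min = float(np.min(sig[imax:]))
    if post_min < (1.0 - drop_fraction) * sig[imax]:
        return StressStretchCurve(
            stretch=ss.stretch[: imax + 1],
            stress_kpa=sig[: imax + 1],
            rupture_index=imax,
            specimen=ss.specimen,
            flags=flags,
        )
    flags.add("no_clear_rupture")
    return replace(ss, rupture_index=imax, flags=flags)


@dataclass(frozen=True)
class LinearWindowFit:
    """OLS fit of stress on stretch over one contiguous index window (inclusive)."""

    slope: float  # kPa per unit stretch
    intercept: float  # kPa
    window: tuple[int, int]
    r2: float
    flags: frozenset = frozenset()

    @property
    def n_points(self) -> int:
        return self.window[1] - self.window[0] + 1


def _window_stats(cx, cy, cxx, cxy, cyy, i: int, j: int) -> tuple[float, float, float]:
    """Slope, intercept, R^2 of window [i, j] from cumulative sums (index 0-based,
    cumulative arrays carry a leading zero)."""
    n = j - i + 1
    sx = cx[j + 1] - cx[i]
    sy = cy[j + 1] - cy[i]
    sxx = cxx[j + 1] - cxx[i]
    sxy = cxy[j + 1] - cxy[i]
    syy = cyy[j + 1] - cyy[i]
    sxx_c = sxx - sx * sx / n
    sxy_c = sxy - sx * sy / n
    syy_c = syy - sy * sy / n
    if sxx_c <= 0:
        return math.nan, math.nan, -math.inf
    slope = sxy_c / sxx_c
    intercept = (sy - slope * sx) / n
    if syy_c <= 1e-18:
        return slope, intercept, 1.0  # constant y: the flat line fits exactly
    r2 = 1.0 - max(syy_c - sxy_c * sxy_c / sxx_c, 0.0) / syy_c
    return slope, intercept, r2


def fit_linear_window(
    ss: StressStretchCurve,
    anchor: str = "start",
    r2_min: float = 0.999,
    min_points: int = 5,
) -> LinearWindowFit:
    """Longest compliant anchored linear window of the pre-rupture curve.

    Scans every contiguous window anchored at the first sample
    (``anchor='start'``) or at the last pre-rupture sample
    (``anchor='end'``) and returns the longest one whose OLS fit of stress
    on stretch reaches ``r2 >= r2_min``.  If none of at least ``min_points``
    complies, the window maximising R^2 is returned with an ``r2_relaxed``
    flag — real noisy records rarely sustain R^2 at the default 0.999.
    """
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    x, y = ss.pre_rupture
    n = len(x)
    if n < min_points:
        raise InsufficientDataError(
            f"need at least min_points={min_points} pre-rupture samples, have {n}"
        )
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))

    best = None  # longest compliant
    best_relaxed = None  # max R^2 fallback
    for length in range(min_points, n + 1):
        if anchor == "start":
            i, j = 0, length - 1
        else:
            i, j = n - length, n - 1
        slope, intercept, r2 = _window_stats(cx, cy, cxx, cxy, cyy, i, j)
        if not math.isfinite(slope):
            continue
        if r2 >= r2_min:
            best = LinearWindowFit(slope, intercept, (i, j), r2)
        if best_relaxed is None or r2 > best_relaxed.r2:
            best_relaxed = LinearWindowFit(
                slope, intercept, (i, j), r2, flags=frozenset({"r2_relaxed"})
            )
    if best is not None:
        return best
    if best_relaxed is None:
        raise InsufficientDataError("no window admits a finite regression slope")
    return best_relaxed


@dataclass(frozen=True)
class BilinearConfig:
    """Tunables of the bilinear extraction.

    ``r2_min`` is the compliance threshold of the window search (default
    0.999); ``min_points`` the smallest admissible window; ``drop_fraction``
    the post-peak stress drop that marks a rupture; ``refine_iters`` the
    number of transition-refinement passes (0 disables refinement).
    """

    r2_min: float = 0.999
    min_points: int = 5
    drop_fraction: float = 0.2
    refine_iters: int = 3
    report_units: str = "kPa"


@dataclass
class BilinearFit:
    """Results of the bilinear parameterization of one stress-stretch curve.

    ``E1``/``E2`` are the low-/high-stretch elastic moduli (kPa), and
    ``(lambda_t, sigma_t)`` the transition point where the two regression
    lines intersect.  Windows are inclusive index pairs into the
    pre-rupture curve.
    """

    E1: float
    E2: float
    lambda_t: float
    sigma_t: float
    low_window: tuple[int, int]
    high_window: tuple[int, int]
    r2_low: float
    r2_high: float
    intercept_low: float
    intercept_high: float
    flags: set = field(default_factory=set)
    specimen: TensileSpecimen | None = None
    config: BilinearConfig = field(default_factory=BilinearConfig)
    model: "BilinearModel | None" = None

    def summary(self) -> str:
        """Human-readable parameter table."""
        sp = self.specimen
        head = "Bilinear tensile parameterization"
        ident = (
            f"specimen: {sp.specimen_id or '<unnamed>'}  group: {sp.group}  "
            f"region: {sp.region}  direction: {sp.direction}"
            if sp is not None
            else "specimen: <unknown>"
        )
        rows = [
            ("E1 (low-stretch modulus)", f"{self.E1:12.4g} kPa", f"R2={self.r2_low:.6f}"),
            ("E2 (high-stretch modulus)", f"{self.E2:12.4g} kPa", f"R2={self.r2_high:.6f}"),
            ("lambda_t (transition stretch)", f"{self.lambda_t:12.4g} -", ""),
            ("sigma_t (transition stress)", f"{self.sigma_t:12.4g} kPa", ""),
        ]
        lines = [head, "=" * len(head), ident, "-" * 64]
        for name, val, extra in rows:
            lines.append(f"{name:<32}{val}  {extra}")
        lines.append("-" * 64)
        lines.append(
            f"low window  [{self.low_window[0]}, {self.low_window[1]}]   "
            f"high window [{self.high_window[0]}, {self.high_window[1]}]"
        )
        lines.append(f"flags: {sorted(self.flags) if self.flags else 'none'}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "E1_kPa": self.E1,
            "E2_kPa": self.E2,
            "lambda_t": self.lambda_t,
            "sigma_t_kPa": self.sigma_t,
            "r2_low": self.r2_low,
            "r2_high": self.r2_high,
            "flags": ";".join(sorted(self.flags)),
        }

    def plot(self, ax=None):
        """Overlay the curve, the two fitted lines and the transition point."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            x, y = self.model.stress_stretch.pre_rupture
            ax.plot(x, y, ".", ms=3, color="0.6", label="data")
            for (i, j), slope, b, lbl in (
                (self.low_window, self.E1, self.intercept_low, "E1 fit"),
                (self.high_window, self.E2, self.intercept_high, "E2 fit"),
            ):
                xs = np.array([x[i], x[j]])
                ax.plot(xs, slope * xs + b, lw=2, label=lbl)
        ax.plot([self.lambda_t], [self.sigma_t], "k*", ms=10, label="transition")
        ax.set_xlabel("stretch $\\lambda$ (-)")
        ax.set_ylabel("Cauchy stress $\\sigma$ (kPa)")
        ax.legend()
        return ax


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 of a plain OLS line fit."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx <= 0:
        raise InsufficientDataError("degenerate abscissa in OLS window")
    sxy = float(np.sum((x - xm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 1.0 if syy <= 1e-18 else 1.0 - max(syy - sxy * sxy / sxx, 0.0) / syy
    return slope, intercept, r2


def _intersect(e1: float, b1: float, e2: float, b2: float) -> tuple[float, float]:
    denom = e1 - e2
    scale = max(abs(e1), abs(e2), 1.0)
    if abs(denom) <= 1e-9 * scale:
        raise DegenerateTransitionError(
            f"regression lines are parallel (E1={e1:.6g}, E2={e2:.6g})"
        )
    lam_t = (b2 - b1) / denom
    return lam_t, e1 * lam_t + b1


def extract_bilinear_parameters(
    ss: StressStretchCurve, config: BilinearConfig | None = None
) -> BilinearFit:
    """Extract (E1, E2, lambda_t, sigma_t) from a truncated stress-stretch curve.

    Procedure: (1) longest compliant window anchored at the curve start
    gives the low-stretch line, and anchored at the last pre-rupture sample
    the high-stretch line; (2) if the two windows overlap they are split at
    the midpoint of the overlap and re-fit (``window_overlap`` flag);
    (3) the transition point is the intersection of the two lines;
    (4) the windows are refined to lambda <= lambda_t and lambda > lambda_t
    respectively and re-fit, iterating to stability, which keeps
    transition-zone samples out of both moduli.
    """
    cfg = config or BilinearConfig()
    x, y = ss.pre_rupture
    n = len(x)
    if n < 2 * cfg.min_points:
        raise InsufficientDataError(
            f"pre-rupture range has {n} samples; need >= {2 * cfg.min_points}"
        )
    flags = set(ss.flags)

    low = fit_linear_window(ss, "start", cfg.r2_min, cfg.min_points)
    high = fit_linear_window(ss, "end", cfg.r2_min, cfg.min_points)
    flags |= set(low.flags) | set(high.flags)

    lo_win, hi_win = low.window, high.window
    if lo_win[1] >= hi_win[0]:  # overlapping windows: split at overlap midpoint
        flags.add("window_overlap")
        mid = (hi_win[0] + lo_win[1]) // 2
        mid = min(max(mid, cfg.min_points - 1), n - cfg.min_points - 1)
        lo_win, hi_win = (0, mid), (mid + 1, n - 1)

    def fit_windows(lw, hw):
        s1, b1, r1 = _ols(x[lw[0] : lw[1] + 1], y[lw[0] : lw[1] + 1])
        s2, b2, r2 = _ols(x[hw[0] : hw[1] + 1], y[hw[0] : hw[1] + 1])
        return s1, b1, r1, s2, b2, r2

    e1, b1, r2_low, e2, b2, r2_high = fit_windows(lo_win, hi_win)
    lam_t, sig_t = _intersect(e1, b1, e2, b2)

    for _ in range(cfg.refine_iters):
        if not (x[0] < lam_t < x[-1]):
            flags.add("transition_out_of_range")
            break
        i_low = int(np.searchsorted(x, lam_t, side="right")) - 1  # last lambda <= lam_t
        new_lo, new_hi = (0, i_low), (i_low + 1, n - 1)
        if new_lo[1] + 1 < cfg.min_points or n - new_hi[0] < cfg.min_points:
            flags.add("refine_truncated")
            break
        if (new_lo, new_hi) == (lo_win, hi_win):
            break
        lo_win, hi_win = new_lo, new_hi
        e1, b1, r2_low, e2, b2, r2_high = fit_windows(lo_win, hi_win)
        lam_t, sig_t = _intersect(e1, b1, e2, b2)

    if min(r2_low, r2_high) < cfg.r2_min:
        flags.add("r2_relaxed")
    if not (x[lo_win[1]] - 1e-12 <= lam_t <= x[hi_win[0]] + 1e-12):
        flags.add("transition_outside_gap")

    return BilinearFit(
        E1=e1,
        E2=e2,
        lambda_t=lam_t,
        sigma_t=sig_t,
        low_window=lo_win,
        high_window=hi_win,
        r2_low=r2_low,
        r2_high=r2_high,
        intercept_low=b1,
        intercept_high=b2,
        flags=flags,
        specimen=ss.specimen,
        config=cfg,
    )


class BilinearModel:
    """Bilinear stress-stretch model for one tensile record.

    Parameters
    ----------
    data : ForceDisplacementCurve or StressStretchCurve
        Raw record (converted and truncated at rupture automatically) or an
        already-prepared stress-stretch curve.
    config : BilinearConfig, optional
        Extraction tunables.

    Examples
    --------
    >>> model = BilinearModel(curve)          # doctest: +SKIP
    >>> res = model.fit()                     # doctest: +SKIP
    >>> print(res.summary())                  # doctest: +SKIP
    """

    def __init__(self, data, config: BilinearConfig | None = None):
        self.config = config or BilinearConfig()
        if isinstance(data, ForceDisplacementCurve):
            ss = to_stress_stretch(data)
            ss = truncate_at_rupture(ss, self.config.drop_fraction)
        elif isinstance(data, StressStretchCurve):
            ss = data
        else:
            raise TypeError(
                "data must be a ForceDisplacementCurve or StressStretchCurve"
            )
        self.stress_stretch = ss

    @classmethod
    def from_record(
        cls,
        displacement_mm,
        force_n,
        specimen: TensileSpecimen,
        config: BilinearConfig | None = None,
    ) -> "BilinearModel":
        curve = ForceDisplacementCurve(displacement_mm, force_n, specimen)
        return cls(curve, config)

    def fit(self, **overrides) -> BilinearFit:
        cfg = replace(self.config, **overrides) if overrides else self.config
        res = extract_bilinear_parameters(self.stress_stretch, cfg)
        res.model = self
        return res
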