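"""EGFP skin-coverage quantification and the chimerism-coverage curve.

Coverage of the body surface by donor-derived (EGFP+) skin is measured as
an area fraction — from a label mask directly, or from an intensity image
thresholded by Otsu's method or a fixed cutoff.  The relationship between
global chimerism ``c`` (percent, proxied by splenocyte chimerism) and
expected coverage is modelled as a logistic in log10-chimerism,

    coverage(c) = 100 / (1 + exp(-slope * (log10 c - log10 c50)))

whose location parameter ``c50`` is directly interpretable: the global
chimerism at which half the body surface is expected to be covered by
donor skin.  Uncertainty on ``c50`` comes from a percentile bootstrap that
resamples animals (the independent unit), never pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitConvergenceError, UndefinedFractionError, ValidationError
from .io import LabelMask


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageRecord:
    """One animal's (chimerism %, coverage %) observation."""

    animal_id: str
    chimerism_pct: float
    coverage_pct: float

    def __post_init__(self) -> None:
        if not (0.0 < self.chimerism_pct <= 100.0):
            raise ValidationError(
                f"chimerism_pct must be in (0, 100], got {self.chimerism_pct}"
            )
        if not (0.0 <= self.coverage_pct <= 100.0):
            raise ValidationError(
                f"coverage_pct must be in [0, 100], got {self.coverage_pct}"
            )


@dataclass
class CoverageFit:
    """Fitted chimerism-coverage curve.

    ``method`` is ``"logistic"`` for the standard fit or ``"linear_log"``
    when the logistic optimizer fails and the linear-in-log10 fallback is
    reported instead.  ``ci_c50`` is the percentile bootstrap interval over
    animals; it is flagged wide (and may be huge) when the curve is flat
    and ``c50`` weakly identified.
    """

    c50_pct: float
    slope: float
    residual_sd: float
    n_animals: int
    ci_c50: tuple[float, float]
    n_boot: int
    seed: int
    method: str = "logistic"


@dataclass(frozen=True)
class AreaFraction:
    """EGFP+ area fraction with an audit trail of how it was obtained."""

    pct: float
    method: str
    threshold: float | None


# ---------------------------------------------------------------------------
# area fraction
# ---------------------------------------------------------------------------

def egfp_area_fraction(
    image: LabelMask | np.ndarray,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: float | None = None,
) -> AreaFraction:
    """EGFP+ (donor) area as a percentage of the evaluated area.

    For a :class:`LabelMask`, the fraction is donor pixels over all
    non-background pixels and ``method`` is ignored.  For an intensity
    raster, pixels above the threshold (Otsu-derived or fixed) count as
    EGFP+ over the whole image; the effective threshold is recorded.
    """
    if isinstance(image, LabelMask):
        n_pos = int((image.pixels == 1).sum())
        n_neg = int((image.pixels == 2).sum())
        if n_pos + n_neg == 0:
            raise UndefinedFractionError(
                f"mask {image.source_id!r} has no non-background pixels"
            )
        return AreaFraction(
            pct=100.0 * n_pos / (n_pos + n_neg), method="label_mask",
            threshold=None,
        )
    pixels = np.asarray(image)
    if pixels.size == 0:
        raise ValidationError("intensity image is empty")
    if method == "otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(pixels))
    elif method == "fixed":
        if threshold is None:
            raise ValidationError("fixed method requires an explicit threshold")
        thr = float(threshold)
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    pct = 100.0 * float((pixels > thr).mean())
    return AreaFraction(pct=pct, method=method, threshold=thr)


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------

def _logistic(log10_c: np.ndarray, log10_c50: float, slope: float) -> np.ndarray:
    return 100.0 / (1.0 + np.exp(-slope * (log10_c - log10_c50)))


def _fit_once(
    log10_c: np.ndarray, coverage: np.ndarray
) -> tuple[float, float, str]:
    """Fit (log10_c50, slope); fall back to a linear-in-log10 line."""
    x0 = np.array([np.median(log10_c), 1.0])
    sol = least_squares(
        lambda p: _logistic(log10_c, p[0], p[1]) - coverage,
        x0=x0,
        method="lm",
        max_nfev=2000,
    )
    if sol.success and np.isfinite(sol.x).all():
        return float(sol.x[0]), float(sol.x[1]), "logistic"
    # linear fallback: coverage = a + b * log10 c, c50 where the line hits 50
    b, a = np.polyfit(log10_c, coverage, 1)
    if b == 0:
        raise FitConvergenceError(
            f"logistic fit failed (status {sol.status}: {sol.message}) and the "
            f"linear fallback is flat (n={coverage.size}, coverage "
            f"range [{coverage.min():.3g}, {coverage.max():.3g}])"
        )
    return float((50.0 - a) / b), float(b * 4.0 / 100.0), "linear_log"


def fit_coverage_curve(
    records: Sequence[CoverageRecord],
    n_boot: int = 2000,
    seed: int | None = None,
) -> CoverageFit:
    """Least-squares logistic fit of coverage against log10-chimerism.

    ``c50`` and ``slope`` are estimated jointly; the confidence interval on
    ``c50`` is a seeded percentile bootstrap over animals.  Needs at least
    three records with two distinct chimerism values.
    """
    if seed is None:
        raise ValidationError("fit_coverage_curve requires an explicit seed")
    records = list(records)
    if len(records) < 3:
        raise ValidationError(f"need >= 3 records, got {len(records)}")
    chimerism = np.array([r.chimerism_pct for r in records])
    coverage = np.array([r.coverage_pct for r in records])
    if np.unique(chimerism).size < 2:
        raise ValidationError("need >= 2 distinct chimerism values")
    log10_c = np.log10(chimerism)

    log10_c50, slope, method = _fit_once(log10_c, coverage)
    if method == "logistic":
        fitted = _logistic(log10_c, log10_c50, slope)
    else:
        z = slope * 100.0 / 4.0
        fitted = np.clip(50.0 + z * (log10_c - log10_c50), 0.0, 100.0)
    dof = max(len(records) - 2, 1)
    residual_sd = float(np.sqrt(((coverage - fitted) ** 2).sum() / dof))

    rng = np.random.default_rng(seed)
    boot_c50 = []
    n = len(records)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.unique(chimerism[idx]).size < 2:
            continue
        try:
            b_log10_c50, _, _ = _fit_once(log10_c[idx], coverage[idx])
        except FitConvergenceError:
            continue
        boot_c50.append(10.0 ** b_log10_c50)
    if boot_c50:
        lo, hi = np.percentile(boot_c50, [2.5, 97.5])
    else:
        lo, hi = 0.0, math.inf
    c50 = 10.0 ** log10_c50
    ci = (min(float(lo), c50), max(float(hi), c50))
    return CoverageFit(
        c50_pct=c50,
        slope=slope,
        residual_sd=residual_sd,
        n_animals=len(records),
        ci_c50=ci,
        n_boot=n_boot,
        seed=seed,
        method=method,
    )


def coverage_at(fit: CoverageFit, chimerism_pct: float) -> float:
    """Expected coverage (%) at a given chimerism under the fitted curve.

    Exactly 50.0 at ``chimerism_pct == c50_pct``.
    """
    c = np.asarray(chimerism_pct, dtype=float)
    if np.any(c <= 0):
        raise ValidationError("chimerism must be positive")
    z = fit.slope * (np.log10(c) - math.log10(fit.c50_pct))
    if fit.method == "linear_log":
        value = np.clip(50.0 + (fit.slope * 100.0 / 4.0) * (np.log10(c) - math.log10(fit.c50_pct)), 0.0, 100.0)
    else:
        value = 100.0 / (1.0 + np.exp(-z))
    return float(value) if value.ndim == 0 else value


def chimerism_for_coverage(fit: CoverageFit, coverage_pct: float) -> float:
    """Invert the fitted curve: chimerism giving an expected coverage."""
    if not (0.0 < coverage_pct < 100.0):
        raise ValidationError("coverage must lie strictly in (0, 100)")
    if fit.slope == 0:
        raise ValidationError("flat curve: coverage level not attainable")
    if fit.method == "linear_log":
        z = (coverage_pct - 50.0) / (fit.slope * 100.0 / 4.0)
    else:
        z = math.log(coverage_pct / (100.0 - coverage_pct)) / fit.slope
    return float(10.0 ** (z + math.log10(fit.c50_pct)))
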