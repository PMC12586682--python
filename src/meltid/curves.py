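"""Curve representations derived from raw fluorescence, plus the LOI filter.

Three representations feed the image classifiers:

* standard melt curve: smoothed -dF/dT (peaks mark melting transitions, Tm);
* normalized HRM curve: fluorescence rescaled between fitted pre-melt and
  post-melt baselines, expressed 0-100%;
* derivative HRM curve: -d(normalized)/dT.

A difference plot (sample minus a reference genotype, both normalized)
amplifies small shape differences.  Runs whose amplification signal falls
below the limit of identification (8 normalized fluorescence units above
baseline) are flagged invalid and excluded from reference databases.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import savgol_filter

from .meltsim import MeltRun

__all__ = [
    "CurveSet",
    "SignalQualityError",
    "negative_derivative",
    "hrm_normalize",
    "derivative_hrm",
    "difference_curve",
    "loi_check",
    "build_curveset",
    "LOI_THRESHOLD_NFU",
    "DEFAULT_PRE_WINDOW",
    "DEFAULT_POST_WINDOW",
    "DEFAULT_SMOOTH_WINDOW",
]

#: Limit of identification: minimum amplification signal, in NFU.
LOI_THRESHOLD_NFU = 8.0
#: Pre-melt (fully double-stranded) normalization window, degC.
DEFAULT_PRE_WINDOW = (61.0, 65.0)
#: Post-melt (fully dissociated) normalization window, degC.
DEFAULT_POST_WINDOW = (86.0, 89.0)
#: Savitzky-Golay smoothing window for derivatives, degC.
DEFAULT_SMOOTH_WINDOW = 2.1


class SignalQualityError(ValueError):
    """Raised when a curve has no usable dynamic range for normalization."""


@dataclasses.dataclass
class CurveSet:
    """Derived representations for one run, all on the same temperature grid."""

    run_id: str
    grid: np.ndarray
    melt_derivative: np.ndarray
    hrm_normalized: np.ndarray
    derivative_hrm: np.ndarray
    difference: np.ndarray | None = None
    loi_pass: bool = True
    loi_value: float = float("nan")
    species_label: str = ""

    def __post_init__(self) -> None:
        n = self.grid.size
        for name in ("melt_derivative", "hrm_normalized", "derivative_hrm"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match grid")
        if self.difference is not None and self.difference.size != n:
            raise ValueError("difference length does not match grid")


def _window_points(window_degc: float, step: float) -> int:
    """Odd point count spanning at least window_degc on the grid."""
    pts = int(round(window_degc / step)) + 1
    if pts % 2 == 0:
        pts += 1
    return max(pts, 5)


def negative_derivative(run: MeltRun,
                        smooth_window: float = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Smoothed -dF/dT on the run's grid (Savitzky-Golay, cubic).

    Interior points use a centered local-polynomial fit; edges are handled by
    polynomial extrapolation of the boundary fits so the output length equals
    the input length.
    """
    if run.stage != "melt":
        raise ValueError("negative_derivative expects a melt-stage run")
    pts = _window_points(smooth_window, run.step)
    if pts > run.x.size:
        raise ValueError(f"smoothing window ({pts} points) exceeds grid ({run.x.size})")
    deriv = savgol_filter(run.fluorescence, window_length=pts, polyorder=3,
                          deriv=1, delta=run.step, mode="interp")
    return -deriv


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def hrm_normalize(run: MeltRun,
                  pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
                  post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
                  ) -> np.ndarray:
    """Two-line baseline normalization to a 0-100% helicity-like scale.

    Lines are fitted to fluorescence over the pre-melt and post-melt windows;
    each temperature's signal is expressed as percent of the distance between
    the two lines.  Raises :class:`SignalQualityError` when the fitted
    baselines cross or coincide anywhere on the grid (no dynamic range).
    """
    if run.stage != "melt":
        raise ValueError("hrm_normalize expects a melt-stage run")
    if not (pre_window[0] < pre_window[1] <= post_window[0] < post_window[1]):
        raise ValueError("windows must be disjoint with pre below post")
    T, F = run.x, run.fluorescence
    pre_mask = (T >= pre_window[0]) & (T <= pre_window[1])
    post_mask = (T >= post_window[0]) & (T <= post_window[1])
    if pre_mask.sum() < 5 or post_mask.sum() < 5:
        raise ValueError("each normalization window must contain >= 5 grid points")
    s_pre, i_pre = _fit_line(T[pre_mask], F[pre_mask])
    s_post, i_post = _fit_line(T[post_mask], F[post_mask])
    line_pre = s_pre * T + i_pre
    line_post = s_post * T + i_post
    span = line_pre - line_post
    if np.any(span <= 0):
        raise SignalQualityError(
            "pre-melt baseline does not stay above post-melt baseline; "
            "curve has no usable melt transition")
    return 100.0 * (F - line_post) / span


def derivative_hrm(normalized: np.ndarray, grid: np.ndarray,
                   smooth_window: float = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """-d(normalized)/dT, same smoothing convention as :func:`negative_derivative`."""
    step = float(grid[1] - grid[0])
    pts = _window_points(smooth_window, step)
    if pts > grid.size:
        raise ValueError(f"smoothing window ({pts} points) exceeds grid ({grid.size})")
    return -savgol_filter(normalized, window_length=pts, polyorder=3,
                          deriv=1, delta=step, mode="interp")


def difference_curve(sample_normalized: np.ndarray,
                     reference_normalized: np.ndarray) -> np.ndarray:
    """Pointwise sample minus reference (both already normalized, same grid)."""
    if sample_normalized.shape != reference_normalized.shape:
        raise ValueError("sample and reference grids do not match")
    return sample_normalized - reference_normalized


def loi_check(amplification: MeltRun,
              threshold_nfu: float = LOI_THRESHOLD_NFU) -> tuple[bool, float]:
    """Limit-of-identification check on an amplification-stage run.

    The normalized signal is the mean of the last three cycles minus the mean
    of cycles 1-5 (plateau minus baseline).  A run passes iff the signal
    reaches ``threshold_nfu``; anything strictly below fails.
    """
    if amplification.stage != "amplification":
        raise ValueError("loi_check expects an amplification-stage run")
    F = amplification.fluorescence
    if F.size < 8:
        raise ValueError("amplification run needs at least 8 cycles")
    loi_value = max(float(F[-3:].mean() - F[:5].mean()), 0.0)
    # guard against float roundoff at the exact threshold; 7.9 still fails
    return loi_value >= threshold_nfu - 1e-9, loi_value


def build_curveset(melt: MeltRun,
                   amplification: MeltRun | None = None,
                   reference_normalized: np.ndarray | None = None,
                   pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
                   post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
                   smooth_window: float = DEFAULT_SMOOTH_WINDOW,
                   threshold_nfu: float = LOI_THRESHOLD_NFU) -> CurveSet:
    """Derive all representations for one run in a single call."""
    norm = hrm_normalize(melt, pre_window, post_window)
    loi_pass, loi_value = True, float("nan")
    if amplification is not None:
        loi_pass, loi_value = loi_check(amplification, threshold_nfu)
    diff = None
    if reference_normalized is not None:
        diff = difference_curve(norm, reference_normalized)
    return CurveSet(
        run_id=melt.run_id,
        grid=melt.x.copy(),
        melt_derivative=negative_derivative(melt, smooth_window),
        hrm_normalized=norm,
        derivative_hrm=derivative_hrm(norm, melt.x, smooth_window),
        difference=diff,
        loi_pass=loi_pass,
        loi_value=loi_value,
        species_label=melt.species_label,
    )
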