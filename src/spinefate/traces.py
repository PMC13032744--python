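"""Fluorescence trace conditioning.

The conditioning chain applied to every per-ROI fluorescence time series is
fixed: polynomial baseline estimation and subtraction, Okada denoising,
conversion to ΔF/F, and z-scoring.  :func:`process_trace` runs the whole
chain and records the configuration used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessedTrace",
    "fit_baseline_poly",
    "okada_filter",
    "to_dff",
    "zscore_trace",
    "process_trace",
]


@dataclass
class ProcessedTrace:
    """A raw trace together with every intermediate of the conditioning chain.

    Attributes
    ----------
    raw, baseline, detrended, denoised, dff, z
        Arrays of identical length: the input, the fitted polynomial
        baseline, raw − baseline, the Okada-filtered detrended trace,
        the ΔF/F trace, and the z-scored ΔF/F trace.
    config
        The parameters the chain ran with (baseline order, Okada
        iterations, ΔF/F floor, z-score convention, chain order); written
        alongside every exported table.
    """

    raw: np.ndarray
    baseline: np.ndarray
    detrended: np.ndarray
    denoised: np.ndarray
    dff: np.ndarray
    z: np.ndarray
    frame_rate_hz: float
    noise_sd_z: float = float("nan")
    config: dict = field(default_factory=dict)


def fit_baseline_poly(values: np.ndarray, order: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial baseline fit and subtraction.

    The fit is performed on a centred/scaled abscissa (the default domain
    mapping of :class:`numpy.polynomial.Polynomial.fit`) for numerical
    stability at order 10.

    Returns ``(baseline, detrended)`` with ``detrended = values - baseline``.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("trace contains non-finite values")
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    if values.size <= order:
        raise ValueError(
            f"trace length {values.size} too short for polynomial order {order}"
        )
    x = np.arange(values.size, dtype=float)
    poly = npoly.Polynomial.fit(x, values, deg=order)
    baseline = poly(x)
    return baseline, values - baseline


def okada_filter(
    values: np.ndarray, iterations: int = 4, *, synchronous: bool = True
) -> np.ndarray:
    """Iterative single-point-extremum denoiser.

    Per iteration, every interior sample that is a strict local extremum
    relative to its two neighbours, i.e. ``(x_t - x_{t-1})(x_t - x_{t+1}) > 0``,
    is replaced by the mean of its neighbours.  Endpoints never change and
    ``iterations=0`` is the identity.

    By default each iteration evaluates the extremum condition against the
    pre-iteration array (synchronous / Jacobi update) so the result does not
    depend on scan order; ``synchronous=False`` switches to the in-place
    sequential scan for sensitivity checks.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    x = np.array(values, dtype=float)
    if x.size < 3:
        if x.size > 0:
            logger.warning("okada_filter: trace shorter than 3 samples, returned unchanged")
        return x
    for _ in range(iterations):
        if synchronous:
            left, mid, right = x[:-2], x[1:-1], x[2:]
            is_ext = (mid - left) * (mid - right) > 0
            new_mid = np.where(is_ext, 0.5 * (left + right), mid)
            if np.array_equal(new_mid, x[1:-1]):
                break
            x[1:-1] = new_mid
        else:
            changed = False
            for t in range(1, x.size - 1):
                if (x[t] - x[t - 1]) * (x[t] - x[t + 1]) > 0:
                    x[t] = 0.5 * (x[t - 1] + x[t + 1])
                    changed = True
            if not changed:
                break
    return x


def to_dff(
    detrended: np.ndarray, baseline: np.ndarray, floor_eps: float = 0.01
) -> np.ndarray:
    """Convert a detrended trace to ΔF/F using the fitted baseline as F0.

    ``dff_t = detrended_t / max(baseline_t, floor_eps * median(baseline))``.
    The pointwise floor guards against the polynomial dipping towards zero
    at the trace edges.
    """
    detrended = np.asarray(detrended, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    med = np.median(baseline)
    if not np.isfinite(med) or med <= 0:
        raise ValueError("non-positive median baseline; trace unusable for ΔF/F")
    f0 = np.maximum(baseline, floor_eps * med)
    return detrended / f0


def zscore_trace(values: np.ndarray) -> np.ndarray:
    """z-score with the population (n-denominator) standard deviation."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance trace cannot be z-scored")
    return (values - values.mean()) / sd


def process_trace(
    raw: np.ndarray,
    frame_rate_hz: float = 20.0,
    *,
    baseline_order: int = 10,
    okada_iterations: int = 4,
    dff_floor_eps: float = 0.01,
    synchronous_okada: bool = True,
) -> ProcessedTrace:
    """Run the full conditioning chain: baseline → Okada → ΔF/F → z-score.

    The recording's noise floor is estimated on the pre-denoising ΔF/F
    trace (where detection noise is still white) and expressed in z-units
    of the final trace; event detection thresholds scale with it.
    """
    from .events import estimate_noise_sd  # local import, no cycle at module load

    baseline, detrended = fit_baseline_poly(raw, order=baseline_order)
    denoised = okada_filter(detrended, okada_iterations, synchronous=synchronous_okada)
    dff = to_dff(denoised, baseline, floor_eps=dff_floor_eps)
    z = zscore_trace(dff)
    dff_raw = to_dff(detrended, baseline, floor_eps=dff_floor_eps)
    noise_sd_z = estimate_noise_sd(dff_raw) / dff.std()
    config = {
        "chain": "baseline_poly->okada->dff->zscore",
        "baseline_order": baseline_order,
        "okada_iterations": okada_iterations,
        "okada_update": "synchronous" if synchronous_okada else "sequential",
        "dff_floor_eps": dff_floor_eps,
        "zscore_convention": "population_sd",
    }
    return ProcessedTrace(
        raw=np.asarray(raw, float),
        baseline=baseline,
        detrended=detrended,
        denoised=denoised,
        dff=dff,
        z=z,
        frame_rate_hz=frame_rate_hz,
        noise_sd_z=float(noise_sd_z),
        config=config,
    )
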