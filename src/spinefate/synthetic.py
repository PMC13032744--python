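"""Ground-truth synthetic data with the structure of a longitudinal
synaptic-imaging study.

Three levels are generated, each carrying full ground truth so every
analysis stage can be validated by parameter recovery:

* event trains — homogeneous Poisson processes per spine and session;
* fluorescence traces — a forward model of a 60-s dendritic-spine
  recording: GECI transient kernel, slow polynomial baseline drift,
  biexponential photobleaching, additive Gaussian noise;
* a spine population — animals × slices × dendrites × spines with a
  within-animal four-arm treatment design (Aβ± × TBOA±), astrocyte
  proximity, logistic spine survival, treatment-dependent rate changes
  and phosphatidylserine-probe (PsVue) intensity changes.

All randomness flows through one :class:`numpy.random.Generator`;
identical config + seed give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventTrain

logger = logging.getLogger(__name__)

__all__ = [
    "GECIKernel",
    "KERNELS",
    "PsVueEffects",
    "SimulationConfig",
    "GroundTruth",
    "ProximityScene",
    "simulate_event_train",
    "make_drift",
    "render_trace",
    "simulate_spine_population",
    "simulate_traces",
    "simulate_proximity_stack",
]

SESSIONS = ("PRE", "POST", "24h")
TREATMENT_ARMS = ("Abeta+/veh", "Abeta+/TBOA", "Abeta-/veh", "Abeta-/TBOA")


@dataclass(frozen=True)
class GECIKernel:
    """Unitary calcium-transient shape: a difference of exponentials with
    unit-normalised peak, scaled to ``amplitude_dff`` (peak ΔF/F of one
    event)."""

    name: str
    amplitude_dff: float
    rise_s: float
    decay_s: float

    def __post_init__(self) -> None:
        if self.amplitude_dff <= 0:
            raise ValueError("amplitude_dff must be > 0")
        if not 0 < self.rise_s < self.decay_s:
            raise ValueError("require 0 < rise_s < decay_s")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Kernel values (ΔF/F units) at times ``t`` seconds after onset."""
        t = np.asarray(t, dtype=float)
        r, d = self.rise_s, self.decay_s
        t_peak = r * d / (d - r) * np.log(d / r)
        peak = np.exp(-t_peak / d) - np.exp(-t_peak / r)
        tp = np.clip(t, 0.0, None)
        out = np.where(t >= 0, np.exp(-tp / d) - np.exp(-tp / r), 0.0) / peak
        return self.amplitude_dff * out

    @property
    def support_s(self) -> float:
        """Time after which the kernel has decayed to <0.1% of its peak."""
        return 7.0 * self.decay_s


#: Indicator presets with literature-flavoured kinetics: jGCaMP7b-like
#: transients are larger and slow, jGCaMP8s-like are fast and brief.
KERNELS = {
    "6s-like": GECIKernel("6s-like", amplitude_dff=1.0, rise_s=0.10, decay_s=1.0),
    "7b-like": GECIKernel("7b-like", amplitude_dff=1.5, rise_s=0.12, decay_s=1.2),
    "8s-like": GECIKernel("8s-like", amplitude_dff=1.2, rise_s=0.03, decay_s=0.25),
}


@dataclass(frozen=True)
class PsVueEffects:
    """Mean relative PsVue change (POST vs PRE) by condition, plus its sd.

    The realised per-spine change is ``baseline + abeta·[Aβ+] +
    lost·[Aβ+ and lost] + nonproximal·[Aβ+ and astrocyte-free] + ε`` with
    ``ε ~ N(0, sd)``.
    """

    baseline: float = 0.05
    abeta: float = 0.15
    lost: float = 0.30
    nonproximal: float = 0.15
    sd: float = 0.10


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the study-structure simulation.

    The survival model is logistic:
    ``logit P(survive) = b0 + bA·[Aβ+] + bP·[proximal] + bAP·[Aβ+∧proximal]
    + bTAP·[TBOA∧Aβ+∧proximal]`` with coefficients in ``survival_logit``.
    Defaults put Aβ− survival at 0.90, Aβ+/astrocyte-free at 0.60,
    Aβ+/astrocyte-proximal at 0.85 under vehicle, and abolish the
    proximity protection under TBOA.
    """

    n_animals: int = 10
    slices_per_animal: int = 4
    dendrites_per_slice: int = 1
    spines_per_dendrite: int = 15
    duration_s: float = 60.0
    frame_rate_hz: float = 20.0
    recordings_per_session: int = 2
    baseline_rate_hz: float = 0.1
    abeta_rate_multiplier: float = 2.0
    lost_rate_boost: float = 1.5
    kernel: GECIKernel = KERNELS["7b-like"]
    drift_order: int = 3
    drift_amplitude: float = 0.05
    noise_sd: float = 0.1
    bleach: tuple[float, float, float, float] = (0.15, 3.0, 0.85, 400.0)
    p_proximity: float = 0.5
    survival_logit: tuple[float, float, float, float, float] = (
        2.1972, -1.7918, 0.0, 1.3294, -1.3294
    )
    psvue_effects: PsVueEffects = PsVueEffects()
    rate_cv_animal: float = 0.1
    rate_cv_slice: float = 0.1
    rate_cv_spine: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_proximity <= 1.0:
            raise ValueError("p_proximity must lie in [0, 1]")
        if self.abeta_rate_multiplier < 1.0:
            raise ValueError("abeta_rate_multiplier must be >= 1")
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be >= 0")
        a, t1, b, t2 = self.bleach
        if t1 <= 0 or t2 <= 0:
            raise ValueError("bleach time constants must be > 0")
        n_frames = self.duration_s * self.frame_rate_hz
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("duration_s × frame_rate_hz must be an integer frame count")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


@dataclass
class GroundTruth:
    """True generative values the analysis pipeline must recover.

    ``spines`` holds one row per spine with the true rate parameters
    (λ, Hz) per session, survival and proximity flags and the true mean
    PsVue change; ``event_times`` maps
    ``(animal, slice, dendrite, roi, session, recording)`` to the true
    event-time array (seconds).
    """

    spines: pd.DataFrame
    event_times: dict[tuple, np.ndarray]
    config: SimulationConfig


def simulate_event_train(
    rate_hz: float,
    duration_s: float,
    seed: int | np.random.Generator = 0,
) -> EventTrain:
    """Homogeneous Poisson event train on ``[0, duration_s)``."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    n = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    times = np.unique(times)  # strict monotonicity (ties have measure zero)
    return EventTrain(
        times=times, amplitudes=np.ones(times.size), duration_s=duration_s,
        source="ground_truth",
    )


def make_drift(
    n_frames: int,
    order: int,
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Slow fractional baseline drift: a random polynomial of the given
    order on [-1, 1], rescaled so its maximum absolute value equals
    ``amplitude`` (a fraction of F0)."""
    if order < 0:
        raise ValueError("drift order must be >= 0")
    if amplitude == 0 or order == 0:
        return np.zeros(n_frames)
    x = np.linspace(-1.0, 1.0, n_frames)
    coeffs = rng.standard_normal(order + 1)
    coeffs[0] = 0.0  # no DC offset; drift is deviation around F0
    y = np.polynomial.polynomial.polyval(x, coeffs)
    peak = np.max(np.abs(y))
    return amplitude * y / peak if peak > 0 else y


def render_trace(
    events: EventTrain,
    kernel: GECIKernel,
    *,
    drift: np.ndarray | None = None,
    bleach: tuple[float, float, float, float] | None = None,
    noise_sd: float = 0.0,
    frame_rate_hz: float = 20.0,
    duration_s: float = 60.0,
    f0: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Forward model of one recording.

    ``trace = F0 · bleach(t) · (1 + drift(t) + Σ_i kernel(t − t_i)) + ε``
    with ``ε ~ N(0, (noise_sd·F0)²)`` per frame.  Bleaching multiplies the
    whole fluorescent signal (baseline and transients alike); noise is
    additive detection noise.  ``drift`` and ``noise_sd`` are fractions of
    F0; ``bleach`` is ``(A, τ1, B, τ2)`` of ``A·e^(−t/τ1) + B·e^(−t/τ2)``.
    """
    n_frames = int(round(duration_s * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz
    if kernel.support_s > duration_s:
        logger.warning(
            "kernel support (%.1f s) exceeds recording (%.1f s); transients truncated",
            kernel.support_s, duration_s,
        )
    signal = np.ones(n_frames)
    if drift is not None:
        drift = np.asarray(drift, dtype=float)
        if drift.size != n_frames:
            raise ValueError("drift length does not match the frame grid")
        signal = signal + drift
    for t_i in events.times:
        signal = signal + kernel(t - t_i)
    if bleach is not None:
        a, tau1, b, tau2 = bleach
        signal = signal * (a * np.exp(-t / tau1) + b * np.exp(-t / tau2))
    trace = f0 * signal
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requested but no rng/seed given")
        rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
        trace = trace + rng.normal(0.0, noise_sd * f0, size=n_frames)
    return trace


def _survival_prob(cfg: SimulationConfig, abeta: bool, tboa: bool, prox: bool) -> float:
    b0, ba, bp, bap, btap = cfg.survival_logit
    logit = (
        b0
        + ba * abeta
        + bp * prox
        + bap * (abeta and prox)
        + btap * (tboa and abeta and prox)
    )
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_spine_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the full nested study population.

    Treatment arms are assigned to slices within each animal (every animal
    contributes every arm, cycling when ``slices_per_animal`` exceeds four).
    Per-spine PRE rates carry lognormal animal/slice/spine heterogeneity
    around ``baseline_rate_hz``; POST (and, for survivors, 24 h) rates are
    multiplied by ``abeta_rate_multiplier`` in Aβ+ arms, with an extra
    ``lost_rate_boost`` on Aβ+ spines destined to be lost.  Observed rates
    are event counts over ``recordings_per_session`` recordings.

    Returns the observable spine table and the :class:`GroundTruth`.
    """
    if min(config.n_animals, config.slices_per_animal,
           config.dendrites_per_slice, config.spines_per_dendrite) <= 0:
        raise ValueError("population is empty; all counts must be >= 1")
    rng = np.random.default_rng(config.seed)
    rows, truth_rows = [], []
    event_times: dict[tuple, np.ndarray] = {}

    def lognorm(cv: float) -> float:
        if cv <= 0:
            return 1.0
        sigma = np.sqrt(np.log(1.0 + cv * cv))
        return float(rng.lognormal(-0.5 * sigma * sigma, sigma))

    for animal in range(config.n_animals):
        sex = "F" if rng.random() < 0.5 else "M"
        animal_eff = lognorm(config.rate_cv_animal)
        arm_order = rng.permutation(len(TREATMENT_ARMS))
        for sl in range(config.slices_per_animal):
            arm = TREATMENT_ARMS[arm_order[sl % len(TREATMENT_ARMS)]]
            abeta = arm.startswith("Abeta+")
            tboa = arm.endswith("TBOA")
            slice_eff = lognorm(config.rate_cv_slice)
            for dend in range(config.dendrites_per_slice):
                for roi in range(config.spines_per_dendrite):
                    spine_eff = lognorm(config.rate_cv_spine)
                    lam_pre = (
                        config.baseline_rate_hz * animal_eff * slice_eff * spine_eff
                    )
                    prox = bool(rng.random() < config.p_proximity)
                    p_surv = _survival_prob(config, abeta, tboa, prox)
                    survived = bool(rng.random() < p_surv)
                    mult = config.abeta_rate_multiplier if abeta else 1.0
                    if abeta and not survived:
                        mult *= config.lost_rate_boost
                    lam_post = lam_pre * mult
                    lam_24h = lam_post if survived else np.nan

                    obs_rate = {}
                    for session, lam in (
                        ("PRE", lam_pre), ("POST", lam_post), ("24h", lam_24h),
                    ):
                        if not np.isfinite(lam):
                            obs_rate[session] = np.nan
                            continue
                        counts = []
                        for rec in range(config.recordings_per_session):
                            train = simulate_event_train(
                                lam, config.duration_s, rng
                            )
                            key = (animal, sl, dend, roi, session, rec)
                            event_times[key] = train.times
                            counts.append(len(train))
                        obs_rate[session] = float(
                            np.mean(counts) / config.duration_s
                        )

                    eff = config.psvue_effects
                    true_dpsvue = (
                        eff.baseline
                        + eff.abeta * abeta
                        + eff.lost * (abeta and not survived)
                        + eff.nonproximal * (abeta and not prox)
                    )
                    psvue_pre = float(rng.normal(100.0, 10.0))
                    psvue_post = psvue_pre * (
                        1.0 + true_dpsvue + rng.normal(0.0, eff.sd)
                    )
                    sessions_present = "PRE;POST" + (";24h" if survived else "")
                    rows.append({
                        "animal": animal, "slice": sl, "dendrite": dend,
                        "roi": roi, "treatment": arm, "abeta": abeta,
                        "tboa": tboa, "sex": sex, "proximity": prox,
                        "survived": survived,
                        "sessions_present": sessions_present,
                        "rate_pre": obs_rate["PRE"],
                        "rate_post": obs_rate["POST"],
                        "rate_24h": obs_rate["24h"],
                        "psvue_pre": psvue_pre, "psvue_post": psvue_post,
                    })
                    truth_rows.append({
                        "animal": animal, "slice": sl, "dendrite": dend,
                        "roi": roi, "treatment": arm,
                        "true_rate_pre": lam_pre, "true_rate_post": lam_post,
                        "true_rate_24h": lam_24h, "survived": survived,
                        "proximity": prox, "p_survival": p_surv,
                        "true_dpsvue": true_dpsvue,
                    })
    spines = pd.DataFrame(rows)
    truth = GroundTruth(
        spines=pd.DataFrame(truth_rows), event_times=event_times, config=config
    )
    return spines, truth


def simulate_traces(
    spines: pd.DataFrame,
    truth: GroundTruth,
    sessions: tuple[str, ...] = ("PRE",),
    f0: float = 100.0,
) -> pd.DataFrame:
    """Render raw fluorescence traces for the recorded sessions of a
    simulated population, in long format (one row per frame)."""
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_frames
    frames = np.arange(n)
    parts = []
    for _, row in spines.iterrows():
        for session in sessions:
            if session not in row["sessions_present"].split(";"):
                continue
            for rec in range(cfg.recordings_per_session):
                key = (row["animal"], row["slice"], row["dendrite"],
                       row["roi"], session, rec)
                times = truth.event_times[key]
                train = EventTrain(times, np.ones(times.size), cfg.duration_s,
                                   source="ground_truth")
                drift = make_drift(n, cfg.drift_order, cfg.drift_amplitude, rng)
                trace = render_trace(
                    train, cfg.kernel, drift=drift, bleach=cfg.bleach,
                    noise_sd=cfg.noise_sd, frame_rate_hz=cfg.frame_rate_hz,
                    duration_s=cfg.duration_s, f0=f0, rng=rng,
                )
                parts.append(pd.DataFrame({
                    "animal": row["animal"], "slice": row["slice"],
                    "dendrite": row["dendrite"], "roi": row["roi"],
                    "session": session, "recording_idx": rec,
                    "frame": frames, "intensity": trace,
                }))
    return pd.concat(parts, ignore_index=True)


@dataclass
class ProximityScene:
    """A synthetic two-channel field of view with its geometry and truth.

    ``stack`` is (2, H, W): channel 0 the astrocyte signal, channel 1 the
    spine signal.  ``labels`` are the true proximity flags computed by
    exhaustive pixel distance from each centroid to the astrocyte mask
    (positive iff the nearest mask pixel lies within twice the spine
    radius, boundary inclusive).
    """

    stack: np.ndarray
    centroids: np.ndarray
    radii: np.ndarray
    astro_mask: np.ndarray
    labels: np.ndarray


def simulate_proximity_stack(
    n_spines: int,
    image_size: int = 256,
    spine_radius_px: float = 3.0,
    astro_coverage: float = 0.3,
    seed: int | np.random.Generator = 0,
    max_tries: int = 10_000,
) -> ProximityScene:
    """Random non-overlapping spines over a blob-like astrocyte mask."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    if not 0.0 <= astro_coverage <= 1.0:
        raise ValueError("astro_coverage must lie in [0, 1]")
    margin = spine_radius_px + 1
    centroids = []
    tries = 0
    while len(centroids) < n_spines:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_spines} non-overlapping spines in a "
                f"{image_size}px field after {max_tries} tries"
            )
        c = rng.uniform(margin, image_size - margin, size=2)
        if all(np.hypot(*(c - q)) > 2.5 * spine_radius_px for q in centroids):
            centroids.append(c)
    centroids = np.array(centroids)
    radii = np.full(n_spines, float(spine_radius_px))

    # astrocyte mask: thresholded smoothed noise field at the requested coverage
    from scipy.ndimage import gaussian_filter

    if astro_coverage == 0:
        mask = np.zeros((image_size, image_size), dtype=bool)
    elif astro_coverage == 1:
        mask = np.ones((image_size, image_size), dtype=bool)
    else:
        fieldv = gaussian_filter(
            rng.standard_normal((image_size, image_size)), image_size / 16
        )
        thr = np.quantile(fieldv, 1.0 - astro_coverage)
        mask = fieldv >= thr

    yy, xx = np.mgrid[0:image_size, 0:image_size]
    spine_ch = np.zeros((image_size, image_size))
    for (cx, cy), r in zip(centroids, radii):
        spine_ch += np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * (r / 1.5) ** 2)))
    astro_ch = mask.astype(float)
    stack = np.stack([astro_ch, spine_ch])
    stack = (stack / max(stack.max(), 1e-12) * 60000).astype(np.uint16)

    # brute-force ground-truth labels: nearest mask-pixel distance per centroid
    labels = np.zeros(n_spines, dtype=bool)
    mask_pts = np.argwhere(mask)  # (row=y, col=x)
    if mask_pts.size:
        for i, ((cx, cy), r) in enumerate(zip(centroids, radii)):
            d2 = (mask_pts[:, 1] - cx) ** 2 + (mask_pts[:, 0] - cy) ** 2
            labels[i] = bool(d2.min() <= (2.0 * r) ** 2)
    return ProximityScene(stack, centroids, radii, mask, labels)
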