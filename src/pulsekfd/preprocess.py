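"""PPG preprocessing chain: segmentation, normalization, denoising, quality.

The pipeline order is: beat segmentation (multi-scale trough detection) ->
per-beat min-max normalization -> denoising (median / Kaiser FIR bandpass /
knowledge-based multi-Gaussian fit) -> amplitude-time scaling -> KFD.
Normalization records the per-beat pulsatile amplitude delta_v before the
rescale, since the fractal measure is gain-invariant but the volume
amplitude is physiologically meaningful on its own.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import least_squares
from scipy.signal import firwin, kaiserord, oaconvolve

from pulsekfd.errors import DataError, DetectionError, FitError, ParameterError

BANDPASS_LOW_HZ = 0.665
BANDPASS_HIGH_HZ = 35.0
BANDPASS_ATTEN_DB = 40.0
BANDPASS_WIDTH_LOW_HZ = 0.3
BANDPASS_WIDTH_HIGH_HZ = 5.0
SQI_THRESHOLD = 0.86
MEDIAN_WINDOW = 15

GAUSSIAN_ROLES = ("forward_1", "forward_2", "reflect_1", "reflect_2", "reflect_3")

__all__ = [
    "PulseBeat",
    "GaussianDecomposition",
    "segment_beats",
    "extract_beats",
    "normalize_beat",
    "median_denoise",
    "bandpass_denoise",
    "gaussian_denoise",
    "sqi_screen",
    "estimate_residual_snr",
]


@dataclass
class PulseBeat:
    """One cardiac cycle of uniformly sampled PPG.

    ``delta_v`` is the pulsatile amplitude before normalization: mL for
    simulated volume beats, device units for measured PPG.
    """

    samples: np.ndarray
    fs: float
    HR: float
    delta_v: Optional[float] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0 or self.HR <= 0:
            raise ParameterError("fs and HR must be positive")
        if self.samples.ndim != 1 or self.samples.size < 4:
            raise DataError("beat must be a 1-D series of >= 4 samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    @property
    def is_normalized(self) -> bool:
        return (
            abs(float(np.min(self.samples))) < 1e-9
            and abs(float(np.max(self.samples)) - 1.0) < 1e-9
        )


@dataclass
class GaussianDecomposition:
    """Five-component Gaussian model of one normalized beat.

    Components model two forward (ejection) waves and three progressively
    attenuated, progressively delayed reflected waves:
    amplitude(reflect_i) < amplitude(forward_1), amplitudes of reflections
    non-increasing, reflection centers non-decreasing.  ``centers`` and
    ``widths`` are in seconds from beat onset.
    """

    amplitudes: dict[str, float]
    centers: dict[str, float]
    widths: dict[str, float]
    rmse: float

    def reconstruct(self, t: np.ndarray) -> np.ndarray:
        y = np.zeros_like(np.asarray(t, dtype=float))
        for role in GAUSSIAN_ROLES:
            a, c, w = self.amplitudes[role], self.centers[role], self.widths[role]
            y = y + a * np.exp(-((t - c) ** 2) / (2.0 * w**2))
        return y


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _ampd_minima(x: np.ndarray, max_scale: int) -> np.ndarray:
    """Multi-scale local-minima detection (AMPD applied to troughs).

    For each window scale k a sample is marked if it is strictly below both
    neighbours at distance k; the operating scale is the one marking the
    most samples, and troughs are samples marked at every scale up to it.
    """
    n = x.size
    L = min(max_scale, n // 2 - 1)
    if L < 1:
        raise DetectionError("signal too short for multi-scale detection")
    rows = np.zeros((L, n), dtype=bool)
    for k in range(1, L + 1):
        seg = x[k : n - k]
        rows[k - 1, k : n - k] = (seg < x[: n - 2 * k]) & (seg < x[2 * k :])
    gamma = rows.sum(axis=1)
    lam = int(np.argmax(gamma)) + 1
    detected = rows[:lam].all(axis=0)
    return np.flatnonzero(detected)


def segment_beats(signal: np.ndarray, fs: float) -> list[tuple[int, int]]:
    """Trough-to-trough beat segmentation via multi-scale extrema detection.

    Returns half-open ``[onset, offset)`` intervals in 0-based sample
    coordinates; the per-beat heart rate is ``fs / (offset - onset)``.
    """
    x = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if x.size < fs:
        raise DetectionError("need at least 1 s of signal")
    if np.ptp(x) == 0:
        raise DetectionError("constant signal: no extrema to segment")
    # linear detrend so slow drift does not mask the multi-scale minima
    i = np.arange(x.size)
    coef = np.polyfit(i, x, 1)
    xd = x - np.polyval(coef, i)
    troughs = _ampd_minima(xd, max_scale=int(2 * fs))
    if troughs.size < 2:
        raise DetectionError("fewer than two troughs detected")
    return [(int(a), int(b)) for a, b in zip(troughs[:-1], troughs[1:])]


def extract_beats(
    signal: np.ndarray,
    fs: float,
    intervals: Optional[Sequence[tuple[int, int]]] = None,
) -> list[PulseBeat]:
    """Slice a signal into PulseBeat objects (segmenting first if needed)."""
    x = np.asarray(signal, dtype=float)
    if intervals is None:
        intervals = segment_beats(x, fs)
    beats = []
    for onset, offset in intervals:
        seg = x[onset:offset]
        beats.append(
            PulseBeat(
                samples=seg.copy(),
                fs=fs,
                HR=fs / (offset - onset),
                delta_v=float(np.ptp(seg)),
            )
        )
    return beats


# ---------------------------------------------------------------------------
# normalization & denoising
# ---------------------------------------------------------------------------


def normalize_beat(beat: PulseBeat) -> PulseBeat:
    """Affine rescale to min 0 / max 1, recording delta_v beforehand."""
    lo = float(np.min(beat.samples))
    hi = float(np.max(beat.samples))
    if hi <= lo:
        raise DataError("flat beat cannot be normalized")
    delta_v = beat.delta_v if beat.delta_v is not None else hi - lo
    return replace(beat, samples=(beat.samples - lo) / (hi - lo), delta_v=delta_v)


def median_denoise(beat: PulseBeat, window: int = MEDIAN_WINDOW) -> PulseBeat:
    """Running-median smoothing with edge replication."""
    if window % 2 == 0 or window < 1:
        raise ParameterError("window must be odd and >= 1")
    if window >= beat.n:
        raise ParameterError("window must be smaller than the beat")
    if window == 1:
        return replace(beat, samples=beat.samples.copy())
    return replace(beat, samples=median_filter(beat.samples, size=window, mode="nearest"))


@functools.lru_cache(maxsize=8)
def _bandpass_taps(fs: float) -> tuple[np.ndarray, np.ndarray]:
    nyq = fs / 2.0
    n_hp, beta_hp = kaiserord(BANDPASS_ATTEN_DB, BANDPASS_WIDTH_LOW_HZ / nyq)
    n_hp += 1 - n_hp % 2  # odd length -> type-I linear phase
    hp = firwin(n_hp, BANDPASS_LOW_HZ, window=("kaiser", beta_hp), pass_zero=False, fs=fs)
    n_lp, beta_lp = kaiserord(BANDPASS_ATTEN_DB, BANDPASS_WIDTH_HIGH_HZ / nyq)
    n_lp += 1 - n_lp % 2
    lp = firwin(n_lp, BANDPASS_HIGH_HZ, window=("kaiser", beta_lp), pass_zero=True, fs=fs)
    return hp, lp


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # symmetric (type-I) FIR applied centered => zero phase in one pass;
    # odd-reflect padding keeps the extension continuous at the edges
    pad = min(x.size - 1, taps.size // 2)
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2 : -pad - 2 : -1]
    xp = np.concatenate([left, x, right])
    y = oaconvolve(xp, taps, mode="same")
    return y[pad : pad + x.size]


def bandpass_denoise(signal: np.ndarray, fs: float) -> np.ndarray:
    """Kaiser-window FIR band-pass (0.665-35 Hz), applied with zero phase.

    Designed as a high-pass / low-pass cascade with 40 dB stopband
    attenuation and transition widths of 0.3 Hz (low edge) and 5 Hz (high
    edge); the symmetric taps are applied centered so morphology is not
    phase-shifted.
    """
    if fs <= 2 * BANDPASS_HIGH_HZ:
        raise ParameterError("fs must exceed 70 Hz for the 35 Hz band edge")
    x = np.asarray(signal, dtype=float)
    if x.size < 8:
        raise DataError("signal too short to filter")
    hp, lp = _bandpass_taps(float(fs))
    return _zero_phase_fir(_zero_phase_fir(x, hp), lp)


# ---------------------------------------------------------------------------
# knowledge-based multi-Gaussian denoising
# ---------------------------------------------------------------------------
#
# Parameterization (phase units, beat mapped to [0, 1)):
#   forward_1: a1, c1, w1 free within bounds
#   forward_2: amplitude a2 free; center c2 = c1 + d2 (d2 >= 0)
#   reflections: amplitudes a_r1 = 0.95 a1 u1, a_r2 = a_r1 u2,
#     a_r3 = a_r2 u3 with u in (0, 1]  -> a_ri < a1, non-increasing;
#     centers nested between c1 and 0.98: c_r1 = c1 + (0.98 - c1) v1,
#     c_r(i+1) = c_ri + (0.98 - c_ri) v(i+1), v in [0, 1] -> ordered,
#     inside the beat, after the principal forward wave.
# All decomposition invariants therefore hold for any admissible vector.

_W_LO, _W_HI = 0.02, 0.4  # width bounds, fractions of the cycle

_PARAM_LOWER = np.array(
    [0.2, 0.02, _W_LO, 1e-3, 0.0, _W_LO, 1e-3, 0.0, _W_LO, 1e-3, 0.0, _W_LO, 1e-3, 0.0, _W_LO]
)
_PARAM_UPPER = np.array(
    [1.5, 0.6, _W_HI, 1.5, 0.5, _W_HI, 1.0, 1.0, _W_HI, 1.0, 1.0, _W_HI, 1.0, 1.0, _W_HI]
)


def _theta_to_components(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a1, c1, w1, a2, d2, w2, u1, v1, wr1, u2, v2, wr2, u3, v3, wr3 = theta
    amps = np.empty(5)
    cens = np.empty(5)
    wids = np.array([w1, w2, wr1, wr2, wr3])
    amps[0], cens[0] = a1, c1
    amps[1], cens[1] = a2, c1 + d2
    amps[2] = 0.95 * a1 * u1
    amps[3] = amps[2] * u2
    amps[4] = amps[3] * u3
    cens[2] = c1 + (0.98 - c1) * v1
    cens[3] = cens[2] + (0.98 - cens[2]) * v2
    cens[4] = cens[3] + (0.98 - cens[3]) * v3
    return amps, cens, wids


def _gaussian_sum(tau: np.ndarray, amps, cens, wids) -> np.ndarray:
    y = np.zeros_like(tau)
    for a, c, w in zip(amps, cens, wids):
        y = y + a * np.exp(-((tau - c) ** 2) / (2.0 * w**2))
    return y


def admissible_theta(
    a1, c1, w1, a2, d2, w2, u1, v1, wr1, u2, v2, wr2, u3, v3, wr3
) -> np.ndarray:
    """Pack an admissible multi-Gaussian parameter vector (phase units)."""
    theta = np.array([a1, c1, w1, a2, d2, w2, u1, v1, wr1, u2, v2, wr2, u3, v3, wr3])
    if np.any(theta < _PARAM_LOWER - 1e-12) or np.any(theta > _PARAM_UPPER + 1e-12):
        raise ParameterError("parameters outside admissible bounds")
    return theta


def synth_gaussian_beat(theta: np.ndarray, n: int, fs: float, HR: float) -> PulseBeat:
    """Synthesize a beat from an admissible parameter vector (test oracle)."""
    tau = np.arange(n) / n
    amps, cens, wids = _theta_to_components(theta)
    return PulseBeat(samples=_gaussian_sum(tau, amps, cens, wids), fs=fs, HR=HR)


def _greedy_components(tau: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """Peel off up to five Gaussian bumps (amplitude, center, width)."""
    resid = y.copy()
    comps = []
    for _ in range(5):
        j = int(np.argmax(resid))
        a = float(resid[j])
        if a < 0.01:
            break
        half = a / 2.0
        li = j
        while li > 0 and resid[li] > half:
            li -= 1
        ri = j
        while ri < resid.size - 1 and resid[ri] > half:
            ri += 1
        w = float(np.clip((tau[ri] - tau[li]) / 2.355, _W_LO, _W_HI))
        comps.append((a, float(tau[j]), w))
        resid = resid - a * np.exp(-((tau - tau[j]) ** 2) / (2.0 * w**2))
    return comps


def _components_to_theta(comps: list[tuple[float, float, float]]) -> np.ndarray:
    """Map peeled components onto the constrained parameter vector."""
    comps = list(comps)
    while len(comps) < 5:
        last = comps[-1]
        comps.append((max(0.02, 0.3 * last[0]), min(0.9, last[1] + 0.1), 0.1))
    lead = max(comps, key=lambda c: c[0])
    rest = sorted((c for c in comps if c is not lead), key=lambda c: c[1])
    a1 = float(np.clip(lead[0], 0.2, 1.5))
    c1 = float(np.clip(lead[1], 0.02, 0.6))
    w1 = lead[2]
    f2, r1, r2, r3 = rest
    a2 = float(np.clip(f2[0], 1e-3, 1.5))
    d2 = float(np.clip(f2[1] - c1, 0.0, 0.5))
    u1 = float(np.clip(r1[0] / (0.95 * a1), 1e-3, 1.0))
    ar1 = 0.95 * a1 * u1
    u2 = float(np.clip(r2[0] / max(ar1, 1e-9), 1e-3, 1.0))
    u3 = float(np.clip(r3[0] / max(ar1 * u2, 1e-9), 1e-3, 1.0))
    cr = []
    prev = c1
    for comp in (r1, r2, r3):
        span = 0.98 - prev
        v = float(np.clip((comp[1] - prev) / span if span > 0 else 0.0, 0.0, 1.0))
        cr.append(v)
        prev = prev + span * v
    return np.array(
        [a1, c1, w1, a2, d2, f2[2], u1, cr[0], r1[2], u2, cr[1], r2[2], u3, cr[2], r3[2]]
    )


def _landmark_starts(tau: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    starts = []
    comps = _greedy_components(tau, y)
    if comps:
        starts.append(_components_to_theta(comps))
    c1 = float(tau[int(np.argmax(y))])
    c1 = min(max(c1, 0.05), 0.55)
    a1 = min(max(float(np.max(y)), 0.25), 1.4)
    base = [a1, c1, 0.08, 0.4 * a1, 0.3 * c1 + 0.05, 0.1,
            0.5, 0.25, 0.08, 0.6, 0.35, 0.1, 0.6, 0.4, 0.12]
    starts.append(np.array(base))
    for w_scale, u_scale in ((1.6, 0.8), (0.7, 0.3)):
        alt = list(base)
        alt[2] = min(_W_HI, base[2] * w_scale)
        alt[6] = u_scale
        starts.append(np.array(alt))
    return starts


def gaussian_denoise(beat: PulseBeat) -> tuple[PulseBeat, GaussianDecomposition]:
    """Constrained five-Gaussian fit; the reconstruction is the denoised beat.

    The beat must be normalized to [0, 1].  The fit is a bounded nonlinear
    least squares over a parameterization that satisfies the decomposition
    invariants by construction, started from waveform landmarks (systolic
    peak) plus two deterministic perturbed restarts.
    """
    lo, hi = float(np.min(beat.samples)), float(np.max(beat.samples))
    if not (-0.05 <= lo <= 0.25 and 0.85 <= hi <= 1.15):
        raise DataError("gaussian_denoise expects an (approximately) normalized beat")
    y = beat.samples
    n = beat.n
    tau = np.arange(n) / n

    def residual(theta):
        amps, cens, wids = _theta_to_components(theta)
        return _gaussian_sum(tau, amps, cens, wids) - y

    best = None
    for x0 in _landmark_starts(tau, y):
        try:
            sol = least_squares(
                residual,
                np.clip(x0, _PARAM_LOWER, _PARAM_UPPER),
                bounds=(_PARAM_LOWER, _PARAM_UPPER),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=4000,
            )
        except Exception as exc:  # pragma: no cover - optimizer internal failure
            raise FitError(f"Gaussian fit failed: {exc}") from exc
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("Gaussian fit did not produce a finite solution")

    amps, cens, wids = _theta_to_components(best.x)
    recon = _gaussian_sum(tau, amps, cens, wids)
    rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
    T = n / beat.fs
    decomp = GaussianDecomposition(
        amplitudes={r: float(a) for r, a in zip(GAUSSIAN_ROLES, amps)},
        centers={r: float(c * T) for r, c in zip(GAUSSIAN_ROLES, cens)},
        widths={r: float(w * T) for r, w in zip(GAUSSIAN_ROLES, wids)},
        rmse=rmse,
    )
    denoised = replace(beat, samples=recon)
    return denoised, decomp


# ---------------------------------------------------------------------------
# quality screening & residual noise
# ---------------------------------------------------------------------------


def sqi_screen(
    beats: Sequence[PulseBeat],
    threshold: float = SQI_THRESHOLD,
    template_length: int = 100,
) -> np.ndarray:
    """Template-matching signal-quality index.

    Beats are length-resampled, the template is their pointwise mean, and a
    beat passes when its Pearson correlation with the template reaches
    ``threshold``.  Returns a boolean pass mask.
    """
    if len(beats) < 3:
        raise ParameterError("need at least 3 beats to form a template")
    grid = np.linspace(0.0, 1.0, template_length)
    resampled = np.stack(
        [
            np.interp(grid, np.linspace(0.0, 1.0, b.n), b.samples)
            for b in beats
        ]
    )
    template = resampled.mean(axis=0)
    t_c = template - template.mean()
    t_norm = np.sqrt(np.sum(t_c**2))
    mask = np.zeros(len(beats), dtype=bool)
    for i, row in enumerate(resampled):
        r_c = row - row.mean()
        denom = t_norm * np.sqrt(np.sum(r_c**2))
        mask[i] = denom > 0 and float(np.dot(r_c, t_c) / denom) >= threshold
    if not mask.any():
        warnings.warn("all beats failed the SQI screen", stacklevel=2)
    return mask


def estimate_residual_snr(noisy: np.ndarray, fs: float) -> float:
    """Residual SNR in dB: band-pass output as clean, remainder as noise.

    SNR = 10 log10( var(filtered) / var(noisy - filtered) ).  Returns +inf
    when the residual variance is zero.
    """
    x = np.asarray(noisy, dtype=float)
    if x.size < 2 * fs:
        raise ParameterError("need at least 2 s of signal")
    filtered = bandpass_denoise(x, fs)
    resid_var = float(np.var(x - filtered))
    if resid_var == 0:
        return np.inf
    return float(10.0 * np.log10(np.var(filtered) / resid_var))
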