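"""Classical PPG morphology indices: stiffness, reflection, aging.

These are the characteristic-point comparators against which the fractal
measure is judged.  All three depend on fiducial points of a single
normalized beat: the systolic peak, the dicrotic notch / diastolic peak,
and the a-e waves of the second derivative.  Missing points are flagged,
never fabricated, and flagged beats are excluded from correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from pulsekfd.errors import DetectionError
from pulsekfd.preprocess import PulseBeat

DEFAULT_HEIGHT_M = 1.75  # adult subject height for SI on virtual cohorts

__all__ = [
    "FiducialPoints",
    "MorphologyFeatures",
    "detect_fiducials",
    "second_derivative",
    "stiffness_index",
    "reflection_index",
    "aging_index",
    "extract_morphology",
    "filter_morphology_outliers",
]


@dataclass
class FiducialPoints:
    """Sample indices of the beat's characteristic points (None = missing)."""

    systolic_peak: int
    dicrotic_notch: Optional[int] = None
    diastolic_peak: Optional[int] = None
    spdw_a: Optional[int] = None
    spdw_b: Optional[int] = None
    spdw_c: Optional[int] = None
    spdw_d: Optional[int] = None
    spdw_e: Optional[int] = None

    def abcde(self) -> tuple:
        return (self.spdw_a, self.spdw_b, self.spdw_c, self.spdw_d, self.spdw_e)


@dataclass
class MorphologyFeatures:
    SI: Optional[float]  # m/s
    RI: Optional[float]  # dimensionless
    AGI: Optional[float]  # dimensionless

    @property
    def si_valid(self) -> bool:
        return self.SI is not None

    @property
    def ri_valid(self) -> bool:
        return self.RI is not None

    @property
    def agi_valid(self) -> bool:
        return self.AGI is not None


def _smooth(beat: PulseBeat) -> np.ndarray:
    win = max(5, int(round(beat.n / 20)) | 1)
    win = min(win, beat.n - 1 if (beat.n - 1) % 2 == 1 else beat.n - 2)
    return savgol_filter(beat.samples, window_length=win, polyorder=3)


def second_derivative(beat: PulseBeat) -> np.ndarray:
    """Second derivative of the smoothed beat by central differences."""
    y = _smooth(beat)
    return np.gradient(np.gradient(y))


def detect_fiducials(beat: PulseBeat) -> FiducialPoints:
    """Locate systolic/diastolic peaks, dicrotic notch and a-e waves.

    Systolic peak is the global maximum; the dicrotic notch is the first
    local minimum after it and the diastolic peak the first local maximum
    after the notch.  Beats without a distinct secondary wave (common in
    stiff subjects and in smooth lumped-model output) fall back to the
    first-derivative shoulder: the first local maximum of dy/dt after
    systole marks the diastolic wave, the preceding d1 minimum the notch
    region.  The a-e waves are alternating extrema of the second
    derivative, anchored at the dominant early maximum (a-wave).
    """
    if beat.n < 50:
        raise DetectionError("beat too short for fiducial detection (< 50 samples)")
    y = _smooth(beat)
    n = beat.n
    sys_peak = int(np.argmax(y))

    notch = dia = None
    if sys_peak < n - 3:
        minima, _ = find_peaks(-y[sys_peak:])
        if minima.size:
            notch = int(sys_peak + minima[0])
            maxima, _ = find_peaks(y[notch:])
            if maxima.size:
                dia = int(notch + maxima[0])
        if dia is None:
            # inflection fallback: local max of dy/dt on the falling limb
            d1 = np.gradient(y)
            search_from = sys_peak + max(3, n // 50)
            search_to = n - max(3, n // 20)
            if search_to > search_from + 3:
                d1_seg = d1[search_from:search_to]
                shoulders, _ = find_peaks(d1_seg)
                if shoulders.size:
                    dia = int(search_from + shoulders[0])
                    d1_before = d1[sys_peak:dia]
                    if d1_before.size:
                        notch = int(sys_peak + np.argmin(d1_before))

    d2 = np.gradient(np.gradient(y))
    waves = _abcde_waves(d2, sys_peak)

    return FiducialPoints(
        systolic_peak=sys_peak,
        dicrotic_notch=notch,
        diastolic_peak=dia,
        spdw_a=waves[0],
        spdw_b=waves[1],
        spdw_c=waves[2],
        spdw_d=waves[3],
        spdw_e=waves[4],
    )


def _abcde_waves(d2: np.ndarray, sys_peak: int) -> list[Optional[int]]:
    n = d2.size
    maxima, _ = find_peaks(d2)
    minima, _ = find_peaks(-d2)
    # a-wave: dominant second-derivative maximum before (or at) the systolic
    # peak region
    early = maxima[maxima <= max(sys_peak, 2)]
    if early.size == 0:
        early = maxima
    if early.size == 0:
        return [None] * 5
    a = int(early[np.argmax(d2[early])])
    waves: list[Optional[int]] = [a]
    pos = a
    for want_max in (False, True, False, True):  # b, c, d, e alternate
        pool = maxima if want_max else minima
        nxt = pool[pool > pos]
        if nxt.size == 0:
            waves.append(None)
            pos = n  # everything later is missing too
        else:
            pos = int(nxt[0])
            waves.append(pos)
    return waves


def stiffness_index(
    fid: FiducialPoints, beat: PulseBeat, height: float = DEFAULT_HEIGHT_M
) -> Optional[float]:
    """SI = height / (systolic-to-diastolic peak transit time), m/s."""
    if fid.diastolic_peak is None or fid.systolic_peak is None:
        return None
    dt = (fid.diastolic_peak - fid.systolic_peak) / beat.fs
    if dt <= 0:
        return None
    return float(height / dt)


def reflection_index(fid: FiducialPoints, beat: PulseBeat) -> Optional[float]:
    """RI = diastolic-peak amplitude / systolic-peak amplitude."""
    if fid.diastolic_peak is None:
        return None
    sys_amp = float(beat.samples[fid.systolic_peak])
    if sys_amp <= 0:
        return None
    return float(beat.samples[fid.diastolic_peak] / sys_amp)


def aging_index(fid: FiducialPoints, d2: np.ndarray) -> Optional[float]:
    """AGI = (b - c - d - e) / a from signed second-derivative amplitudes."""
    idx = fid.abcde()
    if any(i is None for i in idx):
        return None
    a, b, c, d, e = (float(d2[i]) for i in idx)
    if a == 0:
        return None
    return float((b - c - d - e) / a)


def extract_morphology(
    beat: PulseBeat, height: float = DEFAULT_HEIGHT_M
) -> MorphologyFeatures:
    """All three morphology indices of one beat; failures become None."""
    try:
        fid = detect_fiducials(beat)
    except DetectionError:
        return MorphologyFeatures(SI=None, RI=None, AGI=None)
    d2 = second_derivative(beat)
    return MorphologyFeatures(
        SI=stiffness_index(fid, beat, height),
        RI=reflection_index(fid, beat),
        AGI=aging_index(fid, d2),
    )


_OUTLIER_SD_MULTIPLES = {"SI": 1.0, "RI": 2.0, "AGI": 2.0}


def filter_morphology_outliers(
    table: pd.DataFrame, columns: Optional[dict[str, float]] = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Mask per-feature outliers around the median (NaN out, keep the row).

    SI beyond 1 SD of the median is removed; RI and AGI, having smaller
    spread, use 2 SD.  Returns the filtered copy and a per-feature count of
    removals.
    """
    rules = dict(_OUTLIER_SD_MULTIPLES) if columns is None else dict(columns)
    out = table.copy()
    removed: dict[str, int] = {}
    for col, k in rules.items():
        if col not in out.columns:
            continue
        vals = out[col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if finite.sum() == 0:
            removed[col] = 0
            continue
        med = float(np.median(vals[finite]))
        sd = float(np.std(vals[finite]))
        bad = finite & (np.abs(vals - med) > k * sd)
        out.loc[bad, col] = np.nan
        removed[col] = int(bad.sum())
    return out, removed
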