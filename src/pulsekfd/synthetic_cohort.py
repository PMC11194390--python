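"""Virtual-subject cohorts for the WK4 correlation experiments.

Profiles are drawn from independent truncated Gaussians whose defaults
match the reference virtual population: stroke volume 61.7 +/- 4.1 mL,
central compliance (AC) 1.03 +/- 0.26 mL/mmHg, peripheral resistance
0.78 +/- 0.07 mmHg s/mL, and a mean cardiac cycle of 0.82 s (heart rate
1/0.82 Hz, SD 0.1 Hz).  Dependent parameters follow the simulator's
conventions: C2 = 0.08 C1_baseline and L = 0.02 mmHg s^2/mL.

The cohort builder simulates every subject (batch engine), extracts the
peripheral volume beat, and attaches the derived features (PP, delta_v,
KFD, SI, RI, AGI) used by the correlation and sensitivity experiments.
The reference "AC" column is the time-average of C1(t), which reduces to
C1_baseline for the fixed-C1 model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from pulsekfd import _batch
from pulsekfd.errors import DataError, ParameterError
from pulsekfd.kfd_core import KfdConfig, kfd_of_beat
from pulsekfd.morphology_features import DEFAULT_HEIGHT_M, extract_morphology
from pulsekfd.preprocess import PulseBeat, normalize_beat
from pulsekfd.wk4_simulator import (
    DEFAULT_C1_MODULATION,
    DEFAULT_C2_RATIO,
    DEFAULT_FS,
    DEFAULT_L_INERTANCE,
    DEFAULT_T_SYSTOLE_FRACTION,
    HemodynamicProfile,
)

logger = logging.getLogger(__name__)

MEAN_CYCLE_S = 0.82

__all__ = ["CohortSpec", "CohortTable", "sample_profiles", "build_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Sampling specification for a virtual cohort."""

    n_subjects: int = 4374
    seed: int = 0
    SV_mean_sd: tuple[float, float] = (61.7, 4.1)
    AC_mean_sd: tuple[float, float] = (1.03, 0.26)
    R_mean_sd: tuple[float, float] = (0.78, 0.07)
    HR_mean_sd: tuple[float, float] = (1.0 / MEAN_CYCLE_S, 0.1)
    model: str = "varying"  # "fixed" | "varying"
    truncation_sd: float = 3.0
    C1_modulation: float = DEFAULT_C1_MODULATION
    C2_ratio: float = DEFAULT_C2_RATIO
    L_inertance: float = DEFAULT_L_INERTANCE
    T_systole_fraction: float = DEFAULT_T_SYSTOLE_FRACTION

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        if self.model not in ("fixed", "varying"):
            raise ParameterError("model must be 'fixed' or 'varying'")
        if self.truncation_sd <= 0:
            raise ParameterError("truncation_sd must be positive")
        for name in ("SV_mean_sd", "AC_mean_sd", "R_mean_sd", "HR_mean_sd"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ParameterError(f"{name} SD must be nonnegative")
            if mean - self.truncation_sd * sd <= 0:
                raise ParameterError(
                    f"{name}: truncation at {self.truncation_sd} SD does not "
                    "keep samples positive"
                )


@dataclass
class CohortTable:
    """Per-subject parameters plus derived features, with retained beats."""

    table: pd.DataFrame
    beats: list[Optional[PulseBeat]]
    spec: CohortSpec
    fs: float = DEFAULT_FS
    alpha: float = 0.3

    def __len__(self) -> int:
        return len(self.table)


def _draw(rng, mean, sd, n, k):
    if sd == 0:
        return np.full(n, mean)
    return truncnorm.rvs(-k, k, loc=mean, scale=sd, size=n, random_state=rng)


def sample_profiles(spec: CohortSpec) -> list[HemodynamicProfile]:
    """Independent truncated-Gaussian draws per parameter, seeded."""
    rng = np.random.default_rng(spec.seed)
    k = spec.truncation_sd
    n = spec.n_subjects
    sv = _draw(rng, *spec.SV_mean_sd, n, k)
    ac = _draw(rng, *spec.AC_mean_sd, n, k)
    r = _draw(rng, *spec.R_mean_sd, n, k)
    hr = _draw(rng, *spec.HR_mean_sd, n, k)
    m = spec.C1_modulation if spec.model == "varying" else 0.0
    return [
        HemodynamicProfile(
            C1_baseline=float(ac[i]),
            C2=float(spec.C2_ratio * ac[i]),
            R=float(r[i]),
            SV=float(sv[i]),
            HR=float(hr[i]),
            L_inertance=spec.L_inertance,
            C1_modulation=m,
            T_systole_fraction=spec.T_systole_fraction,
        )
        for i in range(n)
    ]


def build_cohort(
    spec: CohortSpec,
    fs: float = DEFAULT_FS,
    alpha: float = 0.3,
    height: float = DEFAULT_HEIGHT_M,
    compute_morphology: bool = True,
    max_nonconverged_frac: float = 0.05,
) -> CohortTable:
    """Simulate every sampled profile and assemble the cohort table.

    Non-converged subjects are logged and their feature columns set to NaN
    (their beats to None); more than ``max_nonconverged_frac`` of them
    raises a :class:`DataError`.
    """
    profiles = sample_profiles(spec)
    n = len(profiles)
    C1b = np.array([p.C1_baseline for p in profiles])
    C2 = np.array([p.C2 for p in profiles])
    R = np.array([p.R for p in profiles])
    L = np.array([p.L_inertance for p in profiles])
    SV = np.array([p.SV for p in profiles])
    HR = np.array([p.HR for p in profiles])

    batch = _batch.simulate_cohort(
        C1b,
        C2,
        R,
        L,
        SV,
        HR,
        T_systole_fraction=spec.T_systole_fraction,
        C1_modulation=spec.C1_modulation if spec.model == "varying" else 0.0,
        varying=spec.model == "varying",
    )
    conv = batch["converged"]
    n_bad = int((~conv).sum())
    if n_bad:
        logger.warning("%d/%d subjects did not converge; dropping", n_bad, n)
    if n_bad > max_nonconverged_frac * n:
        raise DataError(
            f"{n_bad}/{n} subjects failed to converge "
            f"(> {max_nonconverged_frac:.0%} allowed)"
        )

    cfg_cols = {
        "SV": SV,
        "HR": HR,
        "R": R,
        "C1_baseline": C1b,
        "C2": C2,
        "L_inertance": L,
        "AC": batch["mean_c1"],
        "converged": conv,
    }
    pp = np.full(n, np.nan)
    delta_v = np.full(n, np.nan)
    kfd = np.full(n, np.nan)
    si = np.full(n, np.nan)
    ri = np.full(n, np.nan)
    agi = np.full(n, np.nan)
    beats: list[Optional[PulseBeat]] = [None] * n

    for i in range(n):
        if not conv[i]:
            continue
        sub = _batch.resample_subject(batch, i, fs)
        p_p = sub["p_p"]
        pp[i] = float(np.max(p_p) - np.min(p_p))
        delta_v[i] = float(C2[i] * pp[i])
        raw = PulseBeat(samples=C2[i] * p_p, fs=fs, HR=sub["HR"], delta_v=delta_v[i])
        beat = normalize_beat(raw)
        beats[i] = beat
        try:
            kfd[i] = kfd_of_beat(beat, KfdConfig(alpha=alpha, fs=fs)).kfd
        except Exception:
            pass
        if compute_morphology:
            feats = extract_morphology(beat, height=height)
            si[i] = np.nan if feats.SI is None else feats.SI
            ri[i] = np.nan if feats.RI is None else feats.RI
            agi[i] = np.nan if feats.AGI is None else feats.AGI

    table = pd.DataFrame(
        {
            **cfg_cols,
            "PP": pp,
            "delta_v": delta_v,
            "KFD": kfd,
            "SI": si,
            "RI": ri,
            "AGI": agi,
        }
    )
    return CohortTable(table=table, beats=beats, spec=spec, fs=fs, alpha=alpha)
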