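"""Relative individual sensitivity of KFD and SI to hemodynamic changes.

For each virtual subject one input parameter (AC, R or SV) is shifted by
+/- one population SD, the subject is re-simulated, and the relative
individual sensitivity index is

    I_individual = ((V - V0) / divisor) / v * 100,

with V0 / V the baseline / perturbed feature value and v the signed
perturbation.  Because a smooth noiseless beat has KFD barely above the
straight-line floor of 1, the KFD divisor is V0 - 1 (the fractal excess);
SI uses the conventional divisor V0.  Subjects are then grouped by the
sign of the index and their baseline hemodynamics compared by Welch
t-tests, exposing how the direction of a feature's response depends on
hemodynamic status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from pulsekfd import _batch
from pulsekfd.errors import ParameterError
from pulsekfd.estimation_eval import welch_t_test
from pulsekfd.kfd_core import KfdConfig, kfd_of_beat
from pulsekfd.morphology_features import DEFAULT_HEIGHT_M, extract_morphology
from pulsekfd.preprocess import PulseBeat, normalize_beat
from pulsekfd.synthetic_cohort import CohortTable

PARAM_SD_DEFAULTS = {"AC": 0.26, "R": 0.07, "SV": 4.1}

__all__ = [
    "SensitivityRecord",
    "sensitivity_index",
    "individual_sensitivity",
    "summarize_by_sign",
]


def sensitivity_index(V0: float, V: float, v: float, feature: str = "KFD") -> float:
    """Relative individual sensitivity in percent.

    I = ((V - V0) / divisor) / v * 100 with divisor V0 - 1 for KFD (the
    fractal excess above the straight-line floor) and V0 for SI.
    """
    if v == 0:
        raise ParameterError("perturbation v must be nonzero")
    divisor = V0 - 1.0 if feature == "KFD" else V0
    if abs(divisor) < 1e-12:
        raise ParameterError("divisor is zero at this baseline")
    return float(((V - V0) / divisor) / v * 100.0)


@dataclass
class SensitivityRecord:
    feature: str
    parameter: str
    v: float  # signed perturbation, parameter units
    V0: float
    V: float
    I_individual: float  # percent
    valid: bool
    baseline_SV: float
    baseline_AC: float
    baseline_R: float


def _cohort_feature(
    batch: dict, C2: np.ndarray, fs: float, alpha: float, feature: str, height: float
) -> np.ndarray:
    n = batch["p_p"].shape[1]
    vals = np.full(n, np.nan)
    for i in range(n):
        if not batch["converged"][i]:
            continue
        sub = _batch.resample_subject(batch, i, fs)
        beat = normalize_beat(
            PulseBeat(samples=C2[i] * sub["p_p"], fs=fs, HR=sub["HR"])
        )
        if feature == "KFD":
            try:
                vals[i] = kfd_of_beat(beat, KfdConfig(alpha=alpha, fs=fs)).kfd
            except Exception:
                pass
        else:  # SI
            feats = extract_morphology(beat, height=height)
            vals[i] = np.nan if feats.SI is None else feats.SI
    return vals


def individual_sensitivity(
    cohort: CohortTable,
    feature: str = "KFD",
    parameter: str = "AC",
    sd: Optional[float] = None,
    directions: Sequence[int] = (1, -1),
    height: float = DEFAULT_HEIGHT_M,
) -> list[SensitivityRecord]:
    """Per-subject sensitivity records for +SD and -SD perturbations.

    ``parameter = "AC"`` perturbs C1_baseline (C2 keeps the cohort's fixed
    C2/C1 ratio).  Subjects whose KFD baseline sits at the divisor
    singularity V0 = 1 are flagged invalid.
    """
    if feature not in ("KFD", "SI"):
        raise ParameterError("feature must be 'KFD' or 'SI'")
    if parameter not in ("AC", "R", "SV"):
        raise ParameterError("parameter must be 'AC', 'R' or 'SV'")
    if sd is None:
        sd = PARAM_SD_DEFAULTS[parameter]
    if sd <= 0:
        raise ParameterError("sd must be positive")

    t = cohort.table
    base = {
        "C1b": t["C1_baseline"].to_numpy(float),
        "C2": t["C2"].to_numpy(float),
        "R": t["R"].to_numpy(float),
        "L": t["L_inertance"].to_numpy(float),
        "SV": t["SV"].to_numpy(float),
        "HR": t["HR"].to_numpy(float),
    }
    spec = cohort.spec
    varying = spec.model == "varying"
    m = spec.C1_modulation if varying else 0.0
    c2_ratio = spec.C2_ratio

    col = "KFD" if feature == "KFD" else "SI"
    V0 = t[col].to_numpy(float)

    records: list[SensitivityRecord] = []
    for direction in directions:
        v = direction * sd
        C1b, C2, R, SV = (base["C1b"].copy(), base["C2"].copy(),
                          base["R"].copy(), base["SV"].copy())
        if parameter == "AC":
            C1b = C1b + v
            C2 = c2_ratio * C1b
        elif parameter == "R":
            R = R + v
        else:
            SV = SV + v
        if np.any(C1b <= 0) or np.any(R <= 0) or np.any(SV <= 0):
            raise ParameterError("perturbation drives a parameter non-positive")

        pert = _batch.simulate_cohort(
            C1b, C2, R, base["L"], SV, base["HR"],
            T_systole_fraction=spec.T_systole_fraction,
            C1_modulation=m,
            varying=varying,
        )
        V = _cohort_feature(pert, C2, cohort.fs, cohort.alpha, feature, height)

        for i in range(len(t)):
            v0, vi = V0[i], V[i]
            valid = bool(np.isfinite(v0) and np.isfinite(vi))
            if feature == "KFD":
                valid = valid and abs(v0 - 1.0) > 1e-9
            else:
                valid = valid and abs(v0) > 1e-12
            I = sensitivity_index(v0, vi, v, feature) if valid else np.nan
            records.append(
                SensitivityRecord(
                    feature=feature,
                    parameter=parameter,
                    v=v,
                    V0=float(v0),
                    V=float(vi),
                    I_individual=float(I) if valid else np.nan,
                    valid=valid,
                    baseline_SV=float(t["SV"].iloc[i]),
                    baseline_AC=float(t["AC"].iloc[i]),
                    baseline_R=float(t["R"].iloc[i]),
                )
            )
    return records


def summarize_by_sign(
    records: Sequence[SensitivityRecord],
    direction: Optional[int] = 1,
) -> pd.DataFrame:
    """Group records by sign of I_individual and compare hemodynamics.

    ``direction = +1`` (default) keeps only +SD records, ``-1`` only -SD,
    ``None`` pools both.  Returns one row per sign group with percentage,
    group means +/- SD of SV / AC / R, and Welch t-test p-values between
    the groups (NaN when a group is empty).
    """
    recs = [
        r
        for r in records
        if r.valid and np.isfinite(r.I_individual)
        and (direction is None or np.sign(r.v) == direction)
    ]
    if len(recs) < 10:
        raise ParameterError("need >= 10 valid records to summarize")
    I = np.array([r.I_individual for r in recs])
    sv = np.array([r.baseline_SV for r in recs])
    ac = np.array([r.baseline_AC for r in recs])
    rr = np.array([r.baseline_R for r in recs])
    nonzero = I != 0
    I, sv, ac, rr = I[nonzero], sv[nonzero], ac[nonzero], rr[nonzero]
    pos = I > 0

    p_vals = {}
    for name, arr in (("SV", sv), ("AC", ac), ("R", rr)):
        if pos.sum() >= 2 and (~pos).sum() >= 2:
            try:
                p_vals[name] = welch_t_test(arr[pos], arr[~pos])[1]
            except Exception:
                p_vals[name] = np.nan
        else:
            p_vals[name] = np.nan

    rows = []
    for label, mask in (("positive", pos), ("negative", ~pos)):
        n = int(mask.sum())
        rows.append(
            {
                "sign": label,
                "percent": 100.0 * n / I.size,
                "n": n,
                "SV_mean": float(np.mean(sv[mask])) if n else np.nan,
                "SV_sd": float(np.std(sv[mask])) if n else np.nan,
                "AC_mean": float(np.mean(ac[mask])) if n else np.nan,
                "AC_sd": float(np.std(ac[mask])) if n else np.nan,
                "R_mean": float(np.mean(rr[mask])) if n else np.nan,
                "R_sd": float(np.std(rr[mask])) if n else np.nan,
                "p_SV": p_vals["SV"],
                "p_AC": p_vals["AC"],
                "p_R": p_vals["R"],
            }
        )
    return pd.DataFrame(rows)
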