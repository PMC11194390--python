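"""Surrogate regression models, noise-robustness harness, statistics.

Two linear surrogates connect the fractal measure to compliance through
pulse pressure:

    AC_est   = intercept + a * delta_v + b / PP        (target "AC")
    1/PP_est = intercept + c * delta_v + d * KFD       (target "inv_PP")

Composing the second into the first expresses AC_est directly in KFD and
delta_v, the chain-of-surrogates argument evaluated by the noise harness.

The noise experiment injects white Gaussian noise at fixed SNR into the
simulated volume beats, band-pass filters (optionally multi-Gaussian
refits), recomputes KFD and the morphology indices, applies each feature's
outlier rule, and reports Pearson correlations with the reference AC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pulsekfd.errors import DataError, FitError, ParameterError
from pulsekfd.kfd_core import KfdConfig, clean_kfd_outliers, kfd_of_beat
from pulsekfd.morphology_features import (
    extract_morphology,
    filter_morphology_outliers,
)
from pulsekfd.preprocess import (
    PulseBeat,
    bandpass_denoise,
    gaussian_denoise,
    normalize_beat,
)
from pulsekfd.synthetic_cohort import CohortTable

__all__ = [
    "LinearSurrogateModel",
    "CorrelationReport",
    "fit_surrogate",
    "pearson_with_ci",
    "add_noise",
    "welch_t_test",
    "partial_correlation",
    "noise_robustness_experiment",
    "kfd_compliance_correlation",
]


def kfd_compliance_correlation(
    n_subjects: int,
    seed: int,
    model: str,
    alpha: float = 0.3,
) -> CorrelationReport:
    """Full cohort experiment: simulate, clean outliers, correlate KFD with AC.

    Builds a virtual cohort of the given model, removes KFD outliers by the
    transition-probability + median +/- 3 SD rules and AC outliers by the
    median +/- 3 SD rule, and returns the Pearson correlation report of the
    retained subjects.
    """
    from pulsekfd.synthetic_cohort import CohortSpec, build_cohort

    cohort = build_cohort(
        CohortSpec(n_subjects=n_subjects, seed=seed, model=model),
        alpha=alpha,
        compute_morphology=False,
    )
    t = cohort.table
    ok = np.isfinite(t["KFD"]) & np.isfinite(t["AC"])
    kfd = t.loc[ok, "KFD"].to_numpy(float)
    ac = t.loc[ok, "AC"].to_numpy(float)
    keep = clean_kfd_outliers(kfd)
    med, sd = np.median(ac), np.std(ac)
    keep &= np.abs(ac - med) <= 3.0 * sd
    return pearson_with_ci(kfd[keep], ac[keep], names=("KFD", "AC"))


@dataclass(frozen=True)
class LinearSurrogateModel:
    """Two-regressor OLS surrogate: target ~ delta_v + main regressor."""

    intercept: float
    coef_dvppg: float
    coef_main: float
    target: str  # "AC" (main regressor 1/PP) or "inv_PP" (main regressor KFD)
    r_insample: float
    n: int

    def predict(self, delta_v: np.ndarray, main: np.ndarray) -> np.ndarray:
        return self.intercept + self.coef_dvppg * np.asarray(delta_v) + (
            self.coef_main * np.asarray(main)
        )


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    ci_low: float
    ci_high: float
    n: int
    variables: tuple[str, str] = ("x", "y")


def fit_surrogate(table: pd.DataFrame, target: str = "AC") -> LinearSurrogateModel:
    """OLS fit of the AC or 1/PP surrogate on complete cohort rows."""
    if target not in ("AC", "inv_PP"):
        raise ParameterError("target must be 'AC' or 'inv_PP'")
    dv = np.asarray(table["delta_v"], dtype=float)
    pp = np.asarray(table["PP"], dtype=float)
    if target == "AC":
        y = np.asarray(table["AC"], dtype=float)
        main = 1.0 / pp
    else:
        y = 1.0 / pp
        main = np.asarray(table["KFD"], dtype=float)
    ok = np.isfinite(dv) & np.isfinite(main) & np.isfinite(y)
    if ok.sum() < 10:
        raise FitError("need >= 10 complete rows to fit the surrogate")
    X = np.column_stack([np.ones(ok.sum()), dv[ok], main[ok]])
    if np.linalg.matrix_rank(X) < 3 or np.std(y[ok]) == 0:
        raise FitError("rank-deficient design or constant target")
    coef, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    pred = X @ coef
    r = float(stats.pearsonr(pred, y[ok])[0])
    return LinearSurrogateModel(
        intercept=float(coef[0]),
        coef_dvppg=float(coef[1]),
        coef_main=float(coef[2]),
        target=target,
        r_insample=r,
        n=int(ok.sum()),
    )


def pearson_with_ci(
    x: np.ndarray,
    y: np.ndarray,
    names: tuple[str, str] = ("x", "y"),
    confidence: float = 0.95,
) -> CorrelationReport:
    """Pearson r with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ParameterError("need matched samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y)[0])
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationReport(r=r, ci_low=r, ci_high=r, n=x.size, variables=names)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    zc = stats.norm.ppf(0.5 + confidence / 2.0)
    return CorrelationReport(
        r=r,
        ci_low=float(np.tanh(z - zc * se)),
        ci_high=float(np.tanh(z + zc * se)),
        n=x.size,
        variables=names,
    )


def add_noise(signal: np.ndarray, snr_db: float, seed) -> np.ndarray:
    """Add zero-mean white Gaussian noise at the requested SNR (dB).

    Noise variance is var(signal) / 10^(snr_db / 10); ``seed`` may be an
    int or a Generator.  ``snr_db = inf`` returns the signal unchanged.
    """
    x = np.asarray(signal, dtype=float)
    if np.isinf(snr_db):
        return x.copy()
    var = float(np.var(x))
    if var == 0:
        raise ParameterError("cannot set an SNR for a constant signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = np.sqrt(var / 10.0 ** (snr_db / 10.0))
    return x + rng.normal(0.0, sigma, size=x.shape)


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Unequal-variance two-sided t-test (statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise DataError("both groups degenerate with different means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    controls: Optional[np.ndarray] = None,
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationReport:
    """Correlation of residuals after regressing x and y on the controls.

    ``controls`` is an (n, k) matrix (or None / empty for the plain
    Pearson correlation).  The Fisher-z interval uses n - k - 3 degrees.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (hasattr(controls, "size") and np.size(controls) == 0):
        return pearson_with_ci(x, y, names=names)
    C = np.atleast_2d(np.asarray(controls, dtype=float))
    if C.shape[0] != x.size:
        C = C.T
    n, k = C.shape
    if x.size != n or y.size != n:
        raise ParameterError("controls must have one row per observation")
    if n <= k + 3:
        raise ParameterError("need n > n_controls + 3")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("collinear controls")
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    # residuals at floating-point noise level mean the variable is fully
    # explained by the controls: report zero partial correlation
    if np.std(rx) <= 1e-10 * max(np.std(x), 1e-30) or np.std(ry) <= 1e-10 * max(
        np.std(y), 1e-30
    ):
        return CorrelationReport(r=0.0, ci_low=0.0, ci_high=0.0, n=n, variables=names)
    r = float(stats.pearsonr(rx, ry)[0])
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationReport(r=r, ci_low=r, ci_high=r, n=n, variables=names)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - k - 3)
    zc = stats.norm.ppf(0.975)
    return CorrelationReport(
        r=r,
        ci_low=float(np.tanh(z - zc * se)),
        ci_high=float(np.tanh(z + zc * se)),
        n=n,
        variables=names,
    )


# ---------------------------------------------------------------------------
# noise robustness harness
# ---------------------------------------------------------------------------


def _noisy_features(
    beat: PulseBeat,
    snr_db: float,
    rng: np.random.Generator,
    denoise: str,
    alpha: float,
    n_tile: int = 8,
) -> tuple[float, float, float, float]:
    """Noise-inject one beat, filter, and recompute (KFD, SI, RI, AGI).

    The beat is tiled periodically so the band-pass filter sees realistic
    context, noise is added to the tiled record, and the middle cycle is
    extracted and renormalized before feature extraction.
    """
    tiled = np.tile(beat.samples, n_tile)
    noisy = add_noise(tiled, snr_db, rng) if np.isfinite(snr_db) else tiled
    if np.isfinite(snr_db):
        filtered = bandpass_denoise(noisy, beat.fs)
    else:
        filtered = noisy
    mid = (n_tile // 2) * beat.n
    seg = filtered[mid : mid + beat.n]
    try:
        clean = normalize_beat(PulseBeat(samples=seg, fs=beat.fs, HR=beat.HR))
    except DataError:
        return np.nan, np.nan, np.nan, np.nan
    if denoise == "gaussian":
        try:
            clean, _ = gaussian_denoise(clean)
            clean = normalize_beat(clean)
        except (FitError, DataError):
            return np.nan, np.nan, np.nan, np.nan
    try:
        kfd = kfd_of_beat(clean, KfdConfig(alpha=alpha, fs=beat.fs)).kfd
    except Exception:
        kfd = np.nan
    feats = extract_morphology(clean)
    si = np.nan if feats.SI is None else feats.SI
    ri = np.nan if feats.RI is None else feats.RI
    agi = np.nan if feats.AGI is None else feats.AGI
    return kfd, si, ri, agi


def _feature_correlations(
    df: pd.DataFrame, reference: str = "AC"
) -> list[dict]:
    """Outlier-cleaned correlations of KFD / 1/SI / RI / AGI with the reference."""
    out = []
    ref_all = df[reference].to_numpy(dtype=float)

    kfd = df["KFD"].to_numpy(dtype=float)
    ok = np.isfinite(kfd) & np.isfinite(ref_all)
    if ok.sum() >= 20:
        keep = clean_kfd_outliers(kfd[ok])
        sub_k, sub_r = kfd[ok][keep], ref_all[ok][keep]
        if sub_k.size >= 4 and np.std(sub_k) > 0:
            rep = pearson_with_ci(sub_k, sub_r, names=("KFD", reference))
            out.append({"feature": "KFD", **rep.__dict__})

    morph, _ = filter_morphology_outliers(df)
    for feature, col, transform in (
        ("inv_SI", "SI", lambda v: 1.0 / v),
        ("RI", "RI", lambda v: v),
        ("AGI", "AGI", lambda v: v),
    ):
        vals = morph[col].to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(ref_all) & (vals != 0)
        if ok.sum() >= 4 and np.std(transform(vals[ok])) > 0:
            rep = pearson_with_ci(
                transform(vals[ok]), ref_all[ok], names=(feature, reference)
            )
            out.append({"feature": feature, **rep.__dict__})
    return out


def noise_robustness_experiment(
    cohort: CohortTable,
    snrs: Sequence[float] = (15.0, 20.0, 30.0),
    n_seeds: int = 1,
    base_seed: int = 0,
    denoise: str = "bandpass",
    alpha: float = 0.3,
    reference: str = "AC",
) -> pd.DataFrame:
    """Per-SNR, per-seed correlations of each feature with the reference.

    Rows with ``snr = inf`` are the noiseless baseline (computed once).
    Returns a DataFrame with columns feature, snr, seed, r, ci_low,
    ci_high, n.
    """
    if denoise not in ("bandpass", "gaussian"):
        raise ParameterError("denoise must be 'bandpass' or 'gaussian'")
    rows: list[dict] = []

    base = cohort.table.copy()
    for rec in _feature_correlations(base, reference):
        rows.append({"snr": np.inf, "seed": -1, **rec})

    for snr in snrs:
        for seed_i in range(n_seeds):
            rng = np.random.default_rng([base_seed, int(round(snr * 10)), seed_i])
            kfd = np.full(len(cohort), np.nan)
            si = np.full(len(cohort), np.nan)
            ri = np.full(len(cohort), np.nan)
            agi = np.full(len(cohort), np.nan)
            for i, beat in enumerate(cohort.beats):
                if beat is None:
                    continue
                kfd[i], si[i], ri[i], agi[i] = _noisy_features(
                    beat, snr, rng, denoise, alpha
                )
            df = base.copy()
            df["KFD"], df["SI"], df["RI"], df["AGI"] = kfd, si, ri, agi
            for rec in _feature_correlations(df, reference):
                rows.append({"snr": snr, "seed": seed_i, **rec})

    out = pd.DataFrame(rows)
    cols = ["feature", "snr", "seed", "r", "ci_low", "ci_high", "n"]
    return out[[c for c in cols if c in out.columns]]
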