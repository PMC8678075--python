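"""CBF quantification, region summaries and test-retest statistics.

The reliability metrics follow standard test-retest practice: single-measure
absolute-agreement intra-class correlation ICC(2,1), within-subject
coefficient of variation from paired differences, and Bland-Altman limits of
agreement (mean difference +/- 1.96 SD of the differences).  Negative ICC
values are reported as computed, never truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .constants import TissueConstants
from .inference import SENTINEL
from .types import EncodedSeries

__all__ = [
    "RegionSummary",
    "ReliabilityReport",
    "quantify_cbf",
    "region_summary",
    "icc",
    "within_subject_cov",
    "wscov_bootstrap_ci",
    "bland_altman",
    "session_average",
    "reliability_report",
    "model_difference_ttest",
]


@dataclass(frozen=True)
class RegionSummary:
    mean: float
    sd: float
    n_voxels: int
    label: str = ""


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    icc_p: float
    cov_percent: float
    bland_altman: dict
    pairing: str = ""


def quantify_cbf(f_raw: np.ndarray, m0: np.ndarray,
                 constants: TissueConstants = TissueConstants()) -> np.ndarray:
    """Calibrate a fitted perfusion-amplitude map to CBF in ml/100 g/min.

    Fits are run with unit M0 and unit labelling efficiency inside the
    forward model, so the fitted amplitude carries the voxel's true
    ``alpha * M0`` scaling.  Quantification divides it out voxel-wise:
    ``CBF = f_raw * lambda / (alpha * M0)``, with the M0 image understood as
    the tissue-equivalent equilibrium magnetization (lambda times the
    arterial M0).  Voxels with non-positive M0 are flagged with the sentinel.
    """
    f_raw = np.asarray(f_raw, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if f_raw.shape != m0.shape:
        raise ValueError("f_raw and m0 shapes differ")
    out = np.full(f_raw.shape, SENTINEL)
    ok = (m0 > 0) & (f_raw != SENTINEL)
    out[ok] = (f_raw[ok] * constants.partition_coeff
               / (constants.label_efficiency * m0[ok]))
    return out


def region_summary(param_map: np.ndarray, mask: np.ndarray,
                   threshold: float = 0.5, label: str = "") -> RegionSummary:
    """Mean/SD of a parameter map over ``mask >= threshold`` voxels,
    excluding sentinel (non-converged) values.  Sample SD (ddof=1)."""
    param_map = np.asarray(param_map, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if param_map.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    sel = (mask >= threshold) & (param_map != SENTINEL) & np.isfinite(param_map)
    vals = param_map[sel]
    if vals.size == 0:
        raise ValueError("region is empty after thresholding/exclusion")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RegionSummary(mean=float(vals.mean()), sd=sd,
                         n_voxels=int(vals.size), label=label)


def _paired(measurements) -> np.ndarray:
    arr = np.asarray(measurements, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("paired measurements must have shape (n, 2)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("missing values are not allowed")
    return arr


def icc(measurements, form: str = "agreement") -> Tuple[float, float]:
    """Two-way absolute-agreement single-measure ICC(2,1) with one-sided p.

    ``measurements`` is an ``(n_subjects, 2)`` array (two sessions).  Values
    may be negative when the within-subject variance dominates; they are
    reported as computed.  ``form="consistency"`` switches to ICC(3,1).
    Degenerate (zero total variance) input raises.
    """
    arr = _paired(measurements)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if np.allclose(arr, arr.flat[0]):
        raise ValueError("zero total variance; ICC undefined")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "session": np.tile([0, 1], n),
            "value": arr.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="session", ratings="value"
    ).set_index("Type")
    row = table.loc["ICC(A,1)" if form == "agreement" else "ICC(C,1)"]
    return float(row["ICC"]), float(row["pval"])


def within_subject_cov(measurements) -> float:
    """Within-subject coefficient of variation, percent.

    ``wsSD = sqrt(sum(d_i^2) / (2 n))`` over paired differences, divided by
    the grand mean.  Undefined (raises) for non-positive grand mean.
    """
    arr = _paired(measurements)
    grand = float(arr.mean())
    if grand <= 0:
        raise ValueError("grand mean must be positive for a CoV")
    d = arr[:, 0] - arr[:, 1]
    ws_sd = float(np.sqrt(np.sum(d**2) / (2 * arr.shape[0])))
    return 100.0 * ws_sd / grand


def wscov_bootstrap_ci(measurements, n_resamples: int = 1000,
                       level: float = 0.99, seed: int = 0) -> Tuple[float, float]:
    """Bootstrap confidence interval for the within-subject CoV.

    Subjects are resampled with replacement and the interval is formed on
    the log scale by the basic (reflected-percentile) construction — the
    CoV is a positive scale statistic with a right-skewed small-sample
    distribution, for which the plain percentile interval is badly
    anti-conservative at typical study sizes (n ~ 10).  The default level
    is 0.99.
    """
    arr = _paired(measurements)
    n = arr.shape[0]
    est = within_subject_cov(arr)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, (n_resamples, n))
    samples = arr[idx]
    d = samples[..., 0] - samples[..., 1]
    ws_sd = np.sqrt(np.sum(d**2, axis=-1) / (2 * n))
    grand = samples.mean(axis=(-1, -2))
    boots = 100.0 * ws_sd / grand
    boots = boots[np.isfinite(boots) & (boots > 0)]
    a = 100.0 * (1.0 - level) / 2.0
    lo_q, hi_q = np.percentile(np.log(boots), [a, 100.0 - a])
    log_est = np.log(est) if est > 0 else np.log(boots).mean()
    return float(np.exp(2 * log_est - hi_q)), float(np.exp(2 * log_est - lo_q))


def within_subject_cov_meancv(measurements) -> float:
    """Alternative estimator: mean of per-subject CV (SD/mean of the pair),
    percent."""
    arr = _paired(measurements)
    means = arr.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("per-subject means must be positive")
    sds = np.abs(arr[:, 0] - arr[:, 1]) / np.sqrt(2.0)
    return float(100.0 * np.mean(sds / means))


def bland_altman(measurements) -> dict:
    """Mean difference and 1.96-SD limits of agreement of paired data."""
    arr = _paired(measurements)
    d = arr[:, 0] - arr[:, 1]
    mean_diff = float(d.mean())
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return {
        "mean_diff": mean_diff,
        "loa_low": mean_diff - 1.96 * sd,
        "loa_high": mean_diff + 1.96 * sd,
    }


def session_average(a: EncodedSeries, b: EncodedSeries) -> EncodedSeries:
    """Frame-wise mean of two encoded acquisitions (back-to-back repeats are
    averaged on the *encoded* data, before decoding, to improve SNR)."""
    if not a.frame_meta.reset_index(drop=True).equals(
            b.frame_meta.reset_index(drop=True)):
        raise ValueError("frame metadata of the two series differ")
    if a.volumes.shape != b.volumes.shape:
        raise ValueError("series shapes differ")
    return EncodedSeries(volumes=0.5 * (a.volumes + b.volumes),
                         frame_meta=a.frame_meta.copy())


def reliability_report(measurements, pairing: str = "",
                       cov_estimator: str = "paired_diff") -> ReliabilityReport:
    """Bundle ICC(2,1), wsCoV and Bland-Altman for one pairing of sessions."""
    est = {"paired_diff": within_subject_cov,
           "mean_cv": within_subject_cov_meancv}[cov_estimator]
    i, p = icc(measurements)
    return ReliabilityReport(
        icc=i, icc_p=p, cov_percent=est(measurements),
        bland_altman=bland_altman(measurements), pairing=pairing,
    )


def model_difference_ttest(values_a, values_b) -> Tuple[float, float]:
    """Convenience two-tailed independent t-test between per-subject means of
    two models (routine statistics, not a contract of this package)."""
    t, p = sps.ttest_ind(np.asarray(values_a, float), np.asarray(values_b, float))
    return float(t), float(p)
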