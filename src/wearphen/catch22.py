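"""The 22 canonical time-series characteristics, computed from scratch in NumPy.

Each standardized heart-rate segment (active/sedentary/sleep) is z-scored and
summarized by 22 minimally redundant features spanning seven property classes:
value distribution, extreme-event timing, symbolic transitions, linear and
nonlinear autocorrelation, successive differences, and fluctuation analysis
(scaling of detrended fluctuations with window size).

The implementation follows the canonical published definitions of the feature
set, including its specific numerical conventions (biased FFT autocorrelation
normalized at lag zero, MATLAB-style quantiles for symbolization, rectangular
single-window Welch spectra, two-piece log-log regression for the fluctuation
features).  Agreement with the published reference implementation is part of
the test suite.

Degenerate inputs (constant segments, segments shorter than a feature's
minimum supported length, non-finite intermediate results) are mapped to 0.0
with a per-feature degeneracy flag so that downstream tree ensembles always
receive finite design matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "HighResFeatures",
    "zscore",
    "compute_catch22",
    "high_res_features",
    "co_trev_1_num",
    "dn_histogram_mode",
    "segment_length_sensitivity",
    "pairwise_state_correlations",
]

#: Canonical names, in canonical order.
FEATURE_NAMES: tuple[str, ...] = (
    "DN_HistogramMode_5",
    "DN_HistogramMode_10",
    "CO_f1ecac",
    "CO_FirstMin_ac",
    "CO_HistogramAMI_even_2_5",
    "CO_trev_1_num",
    "MD_hrv_classic_pnn40",
    "SB_BinaryStats_mean_longstretch1",
    "SB_BinaryStats_diff_longstretch0",
    "SB_TransitionMatrix_3ac_sumdiagcov",
    "PD_PeriodicityWang_th0_01",
    "CO_Embed2_Dist_tau_d_expfit_meandiff",
    "IN_AutoMutualInfoStats_40_gaussian_fmmi",
    "FC_LocalSimple_mean1_tauresrat",
    "FC_LocalSimple_mean3_stderr",
    "DN_OutlierInclude_p_001_mdrmd",
    "DN_OutlierInclude_n_001_mdrmd",
    "SP_Summaries_welch_rect_area_5_1",
    "SP_Summaries_welch_rect_centroid",
    "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1",
    "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1",
    "SB_MotifThree_quantile_hh",
)


# ---------------------------------------------------------------------------
# basic transforms
# ---------------------------------------------------------------------------

def zscore(values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Standardize to mean 0 and unit sample (n-1) standard deviation.

    Returns ``(z, degenerate)``; a constant input yields all zeros with
    ``degenerate=True`` instead of dividing by zero.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("z-scoring requires a 1-d sequence of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def _nextpow2(n: int) -> int:
    p = 1
    while p < n:
        p <<= 1
    return p


def _acf_fft(y: np.ndarray) -> np.ndarray:
    """Biased autocorrelation via zero-padded FFT, normalized at lag 0."""
    n = y.size
    nfft = _nextpow2(n) << 1
    f = np.fft.fft(y - y.mean(), nfft)
    acov = np.real(np.fft.ifft(f * np.conj(f)))
    return acov / acov[0]


def _first_zero_ac(y: np.ndarray, maxtau: int) -> int:
    """Index of the first non-positive autocorrelation, capped at ``maxtau``."""
    acf = _acf_fft(y)
    tau = 0
    while tau < maxtau and acf[tau] > 0:
        tau += 1
    return tau


def _matlab_quantile(y: np.ndarray, q: float) -> float:
    """Quantile with the (k - 1/2)/n plotting convention and edge clamping."""
    n = y.size
    srt = np.sort(y)
    lim = 0.5 / n
    if q < lim:
        return float(srt[0])
    if q > 1 - lim:
        return float(srt[-1])
    pos = n * q - 0.5
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    if hi == lo:
        return float(srt[lo])
    return float(srt[lo] + (pos - lo) * (srt[hi] - srt[lo]) / (hi - lo))


def _coarse_grain_quantile(y: np.ndarray, n_groups: int) -> np.ndarray:
    """Symbolize into ``n_groups`` equiprobable labels 1..n_groups."""
    edges = [_matlab_quantile(y, q) for q in np.linspace(0, 1, n_groups + 1)]
    edges[0] -= 1
    labels = np.zeros(y.size, dtype=int)
    for i in range(n_groups):
        labels[(y > edges[i]) & (y <= edges[i + 1])] = i + 1
    return labels


def _linreg(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = x.size
    sumx = x.sum()
    sumx2 = (x * x).sum()
    sumxy = (x * y).sum()
    sumy = y.sum()
    denom = n * sumx2 - sumx * sumx
    if denom == 0:
        return 0.0, 0.0
    m = (n * sumxy - sumx * sumy) / denom
    b = (sumy * sumx2 - sumx * sumxy) / denom
    return m, b


# ---------------------------------------------------------------------------
# distribution shape
# ---------------------------------------------------------------------------

def _hist_counts(y: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram spanning [min, max]; ties to the lower bin by
    floating-point truncation, top edge closed."""
    lo = y.min()
    hi = y.max()
    step = (hi - lo) / n_bins
    idx = ((y - lo) / step).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = lo + step * np.arange(n_bins + 1)
    return counts, edges


def dn_histogram_mode(z: Sequence[float], n_bins: int = 5) -> float:
    """Center of the most populated of ``n_bins`` equal-width bins.

    Ties in the maximal count average the centers of all tied bins.
    """
    y = np.asarray(z, dtype=float)
    counts, edges = _hist_counts(y, n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    top = counts == counts.max()
    return float(centers[top].mean())


def _dn_outlier_include(y: np.ndarray, sign: int) -> float:
    """Median timing drift of increasingly extreme above-threshold events."""
    inc = 0.01
    yw = sign * y
    if np.all(y == y[0]):
        return 0.0
    tot = int(np.sum(yw >= 0))
    max_val = yw.max()
    if max_val < inc:
        return 0.0
    n = y.size
    n_thresh = int(max_val / inc) + 1
    counts = np.empty(n_thresh, dtype=int)
    med_drift = np.empty(n_thresh)
    for j in range(n_thresh):
        r = np.nonzero(yw >= j * inc)[0] + 1
        counts[j] = r.size
        med_drift[j] = np.median(r) / (n / 2) - 1
    pct = (counts - 1) * 100.0 / tot
    over = np.nonzero(pct > 2)[0]
    mj = int(over[-1]) if over.size else 0
    singletons = np.nonzero(counts == 1)[0]
    fbi = int(singletons[0]) if singletons.size else n_thresh - 1
    trim = min(mj, fbi)
    return float(np.median(med_drift[: trim + 1]))


# ---------------------------------------------------------------------------
# linear autocorrelation
# ---------------------------------------------------------------------------

def _co_f1ecac(y: np.ndarray) -> float:
    acf = _acf_fft(y)
    thresh = 1.0 / math.e
    n = y.size
    for i in range(n - 2):
        if acf[i + 1] < thresh:
            m = acf[i + 1] - acf[i]
            return i + (thresh - acf[i]) / m
    return float(n)


def _co_first_min_ac(y: np.ndarray) -> float:
    acf = _acf_fft(y)
    n = y.size
    for i in range(1, n - 1):
        if acf[i] < acf[i - 1] and acf[i] < acf[i + 1]:
            return float(i)
    return float(n)


# ---------------------------------------------------------------------------
# nonlinear autocorrelation / information
# ---------------------------------------------------------------------------

def co_trev_1_num(z: Sequence[float]) -> float:
    """Time-reversibility statistic: mean cubed successive difference."""
    y = np.asarray(z, dtype=float)
    if y.size < 2:
        raise ValueError("trev requires length >= 2")
    return float(np.mean(np.diff(y) ** 3))


def _co_histogram_ami_even_2_5(y: np.ndarray) -> float:
    tau, n_bins = 2, 5
    y1 = y[:-tau]
    y2 = y[tau:]
    lo = y.min()
    hi = y.max()
    step = (hi - lo + 0.2) / n_bins
    edges = lo - 0.1 + step * np.arange(n_bins + 1)
    # first edge strictly above the value; all values fall below the last edge
    b1 = np.searchsorted(edges, y1, side="right")
    b2 = np.searchsorted(edges, y2, side="right")
    joint = np.zeros((n_bins, n_bins))
    for i, j in zip(b1 - 1, b2 - 1):
        joint[i, j] += 1
    pij = joint / joint.sum()
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    mask = pij > 0
    return float(np.sum(pij[mask] * np.log(pij[mask] / np.outer(pi, pj)[mask])))


def _in_ami_gaussian_fmmi(y: np.ndarray) -> float:
    n = y.size
    tau = min(40, (n + 1) // 2)
    if tau < 3:
        return float(tau)

    def ami(lag: int) -> float:
        a = y[: n - lag]
        b = y[lag:]
        r = np.corrcoef(a, b)[0, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            return float(-0.5 * np.log(1 - r * r))

    prev, curr = ami(1), ami(2)
    for i in range(1, tau - 1):
        nxt = ami(i + 2)
        if curr < prev and curr < nxt:
            return float(i)
        prev, curr = curr, nxt
    return float(tau)


def _co_embed2_dist_expfit_meandiff(y: np.ndarray) -> float:
    n = y.size
    tau = _first_zero_ac(y, n)
    if tau > n / 10:
        tau = n // 10
    m = n - tau - 1
    d = np.sqrt(np.diff(y[: m + 1]) ** 2 + np.diff(y[tau : tau + m + 1]) ** 2)
    ell = d.mean()
    sd = d.std(ddof=1)
    if sd < 0.001:
        return 0.0
    n_bins = int(math.ceil((d.max() - d.min()) / (3.5 * sd / m ** (1 / 3))))
    counts, edges = _hist_counts(d, n_bins)
    probs = counts / m
    centers = 0.5 * (edges[:-1] + edges[1:])
    expf = np.maximum(np.exp(-centers / ell) / ell, 0)
    return float(np.mean(np.abs(probs - expf)))


# ---------------------------------------------------------------------------
# successive differences
# ---------------------------------------------------------------------------

def _md_hrv_classic_pnn40(y: np.ndarray) -> float:
    dy = np.abs(np.diff(y)) * 1000
    return float(np.mean(dy > 40))


def _fc_local_simple_mean_residuals(y: np.ndarray, train: int) -> np.ndarray:
    n = y.size - train
    window_means = np.convolve(y, np.ones(train) / train, mode="valid")[:n]
    return y[train:] - window_means


def _fc_local_simple_mean1_tauresrat(y: np.ndarray) -> float:
    res = _fc_local_simple_mean_residuals(y, 1)
    return _first_zero_ac(res, res.size) / _first_zero_ac(y, y.size)


def _fc_local_simple_mean3_stderr(y: np.ndarray) -> float:
    res = _fc_local_simple_mean_residuals(y, 3)
    return float(res.std(ddof=1))


# ---------------------------------------------------------------------------
# symbolic
# ---------------------------------------------------------------------------

def _sb_binary_stats_mean_longstretch1(y: np.ndarray) -> float:
    b = (y[:-1] > y.mean()).astype(int)
    return _longest_stretch(b, target=1)


def _sb_binary_stats_diff_longstretch0(y: np.ndarray) -> float:
    b = (np.diff(y) >= 0).astype(int)
    return _longest_stretch(b, target=0)


def _longest_stretch(b: np.ndarray, target: int) -> float:
    # stretch bookkeeping mirrors the reference scan, including its
    # treatment of the first run and the final position
    n = b.size
    longest = 0
    last_hit = 0
    for i in range(n):
        if b[i] != target or i == n - 1:
            stretch = i - last_hit
            if stretch > longest:
                longest = stretch
            last_hit = i
    return float(longest)


def _sb_transition_matrix_3ac_sumdiagcov(y: np.ndarray) -> float:
    n = y.size
    if np.all(y == y[0]):
        return math.nan
    tau = _first_zero_ac(y, n)
    down = y[::tau] if tau > 0 else y.copy()
    nd = down.size
    labels = _coarse_grain_quantile(down, 3)
    T = np.zeros((3, 3))
    for a, b in zip(labels[:-1], labels[1:]):
        T[a - 1, b - 1] += 1
    T /= nd - 1
    # covariance matrix of the three column vectors; its trace
    return float(np.trace(np.cov(T.T, ddof=1)))


def _sb_motif_three_quantile_hh(y: np.ndarray) -> float:
    labels = _coarse_grain_quantile(y, 3)
    n = y.size
    p = np.zeros((3, 3))
    for a, b in zip(labels[:-1], labels[1:]):
        p[a - 1, b - 1] += 1
    p /= n - 1
    mask = p > 0
    return float(-np.sum(p[mask] * np.log(p[mask])))


# ---------------------------------------------------------------------------
# periodicity
# ---------------------------------------------------------------------------

def _spline_detrend(y: np.ndarray) -> np.ndarray:
    """Least-squares cubic B-spline fit with interior break at mid-series."""
    n = y.size
    breaks = np.array([0.0, math.floor(n / 2) - 1, n - 1])
    h = np.diff(breaks)
    # knots extended by reflecting the break spacings outward
    knots = np.concatenate(
        (
            breaks[0] - np.array([h[1] + h[0] + h[1], h[1] + h[0], h[1]]),
            breaks,
            breaks[2] + np.array([h[0], h[0] + h[1], h[0] + h[1] + h[0]]),
        )
    )
    x = np.arange(n, dtype=float)
    design = BSpline.design_matrix(x, knots, 3).toarray()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return design @ coef


def _pd_periodicity_wang(y: np.ndarray) -> float:
    th = 0.01
    n = y.size
    ysub = y - _spline_detrend(y)
    acmax = int(math.ceil(n / 3))
    acf = np.array(
        [np.dot(ysub[: n - t], ysub[t:]) / (n - t) for t in range(1, acmax + 1)]
    )
    troughs: list[int] = []
    for i in range(1, acmax - 1):
        slope_in = acf[i] - acf[i - 1]
        slope_out = acf[i + 1] - acf[i]
        if slope_in < 0 and slope_out > 0:
            troughs.append(i)
        elif slope_in > 0 and slope_out < 0:
            if not troughs:
                continue
            peak = acf[i]
            trough = acf[troughs[-1]]
            if peak - trough < th or peak < 0:
                continue
            return float(i)
    return 0.0


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------

def _welch_rect(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-segment rectangular-window Welch periodogram (Fs = 1)."""
    n = y.size
    nfft = _nextpow2(n)
    f = np.fft.fft(y - y.mean(), nfft)
    p = np.abs(f) ** 2
    n_out = nfft // 2 + 1
    pxx = p[:n_out] / n
    pxx[1 : n_out - 1] *= 2
    freq = np.arange(n_out) / nfft
    return pxx, freq


def _sp_summaries_welch_rect(y: np.ndarray, what: str) -> float:
    pxx, freq = _welch_rect(y)
    w = 2 * math.pi * freq
    sw = pxx / (2 * math.pi)
    if not np.all(np.isfinite(sw)):
        return 0.0
    dw = w[1] - w[0]
    if what == "centroid":
        cs = np.cumsum(sw)
        over = np.nonzero(cs > cs[-1] * 0.5)[0]
        return float(w[over[0]]) if over.size else 0.0
    if what == "area_5_1":
        return float(np.sum(sw[: sw.size // 5]) * dw)
    raise ValueError(what)


# ---------------------------------------------------------------------------
# fluctuation analysis
# ---------------------------------------------------------------------------

def _sc_fluct_anal(y: np.ndarray, lag: int, how: str) -> float:
    n = y.size
    lin_lo = math.log(5)
    lin_hi = math.log(n // 2)
    taus = np.unique(
        np.round(np.exp(lin_lo + np.arange(50) * (lin_hi - lin_lo) / 49)).astype(int)
    )
    ntt = taus.size
    if ntt < 12:
        return 0.0
    cs = np.cumsum(y[::lag][: n // lag])
    F = np.empty(ntt)
    for k, t in enumerate(taus):
        nbuf = cs.size // t
        x = np.arange(1, t + 1, dtype=float)
        windows = cs[: nbuf * t].reshape(nbuf, t)
        acc = 0.0
        for w in windows:
            m, b = _linreg(x, w)
            resid = w - (m * x + b)
            if how == "dfa":
                acc += float(np.sum(resid**2))
            else:
                d = resid.max() - resid.min()
                acc += d * d
        F[k] = math.sqrt(acc / (nbuf * t)) if how == "dfa" else math.sqrt(acc / nbuf)
    logt = np.log(taus)
    logF = np.log(F)
    min_points = 6
    best_i = 0
    best_err = math.inf
    for i in range(min_points, ntt - min_points + 1):
        m1, b1 = _linreg(logt[:i], logF[:i])
        m2, b2 = _linreg(logt[i - 1 :], logF[i - 1 :])
        err = float(
            np.linalg.norm(logt[:i] * m1 + b1 - logF[:i])
            + np.linalg.norm(logt[i - 1 :] * m2 + b2 - logF[i - 1 :])
        )
        if err < best_err:
            best_err = err
            best_i = i
    return best_i / ntt


# ---------------------------------------------------------------------------
# the full vector
# ---------------------------------------------------------------------------

_DISPATCH = {
    "DN_HistogramMode_5": lambda z: dn_histogram_mode(z, 5),
    "DN_HistogramMode_10": lambda z: dn_histogram_mode(z, 10),
    "CO_f1ecac": _co_f1ecac,
    "CO_FirstMin_ac": _co_first_min_ac,
    "CO_HistogramAMI_even_2_5": _co_histogram_ami_even_2_5,
    "CO_trev_1_num": co_trev_1_num,
    "MD_hrv_classic_pnn40": _md_hrv_classic_pnn40,
    "SB_BinaryStats_mean_longstretch1": _sb_binary_stats_mean_longstretch1,
    "SB_BinaryStats_diff_longstretch0": _sb_binary_stats_diff_longstretch0,
    "SB_TransitionMatrix_3ac_sumdiagcov": _sb_transition_matrix_3ac_sumdiagcov,
    "PD_PeriodicityWang_th0_01": _pd_periodicity_wang,
    "CO_Embed2_Dist_tau_d_expfit_meandiff": _co_embed2_dist_expfit_meandiff,
    "IN_AutoMutualInfoStats_40_gaussian_fmmi": _in_ami_gaussian_fmmi,
    "FC_LocalSimple_mean1_tauresrat": _fc_local_simple_mean1_tauresrat,
    "FC_LocalSimple_mean3_stderr": _fc_local_simple_mean3_stderr,
    "DN_OutlierInclude_p_001_mdrmd": lambda z: _dn_outlier_include(z, 1),
    "DN_OutlierInclude_n_001_mdrmd": lambda z: _dn_outlier_include(z, -1),
    "SP_Summaries_welch_rect_area_5_1": lambda z: _sp_summaries_welch_rect(z, "area_5_1"),
    "SP_Summaries_welch_rect_centroid": lambda z: _sp_summaries_welch_rect(z, "centroid"),
    "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1": lambda z: _sc_fluct_anal(z, 1, "rsrangefit"),
    "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1": lambda z: _sc_fluct_anal(z, 2, "dfa"),
    "SB_MotifThree_quantile_hh": _sb_motif_three_quantile_hh,
}

#: shortest input each feature supports without hitting an empty intermediate
_MIN_LENGTH = {name: 5 for name in FEATURE_NAMES}
_MIN_LENGTH["IN_AutoMutualInfoStats_40_gaussian_fmmi"] = 5
_MIN_LENGTH["FC_LocalSimple_mean3_stderr"] = 6


@dataclass(frozen=True)
class FeatureVector:
    """The 22 named feature values for one segment, plus degeneracy flags."""

    values: Mapping[str, float]
    degenerate: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector must carry exactly the 22 canonical names")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES])


def compute_catch22(values: Sequence[float]) -> FeatureVector:
    """Z-score a gap-free segment and evaluate all 22 characteristics.

    Non-finite results and too-short or constant inputs fall back to 0.0,
    with the affected feature names recorded in ``degenerate``.
    """
    x = np.asarray(getattr(values, "values", values), dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("a segment of length >= 2 is required")
    z, flat = zscore(x)
    out: dict[str, float] = {}
    degenerate: set[str] = set()
    for name in FEATURE_NAMES:
        if flat or x.size < _MIN_LENGTH[name]:
            out[name] = 0.0
            degenerate.add(name)
            continue
        val = float(_DISPATCH[name](z))
        if not np.isfinite(val):
            val = 0.0
            degenerate.add(name)
        out[name] = val
    return FeatureVector(values=out, degenerate=frozenset(degenerate))


@dataclass(frozen=True)
class HighResFeatures:
    """Per-state feature vectors for one participant; absent states omitted."""

    participant_id: str
    states: Mapping[str, FeatureVector]

    def to_row(self) -> dict[str, float]:
        """Flatten to ``<feature>.<state>`` naming (state in lower case)."""
        row: dict[str, float] = {}
        for state, vec in self.states.items():
            for name in FEATURE_NAMES:
                row[f"{name}.{state.lower()}"] = vec[name]
        return row


def high_res_features(series) -> HighResFeatures:
    """Standardized segments -> up to three 22-feature blocks.

    ``series`` is an annotated :class:`~wearphen.io.MinuteSeries`; states whose
    longest uninterrupted run is shorter than the standard segment length are
    omitted from the result.
    """
    from .annotation import STANDARD_LENGTHS, extract_standard_segment

    states = {}
    for state in STANDARD_LENGTHS:
        seg = extract_standard_segment(series, state)
        if seg is not None:
            states[state] = compute_catch22(seg.values)
    return HighResFeatures(participant_id=series.participant_id, states=states)


# ---------------------------------------------------------------------------
# cohort-level diagnostics
# ---------------------------------------------------------------------------

def segment_length_sensitivity(cohort, state: str, lengths: Iterable[int]):
    """Cross-participant correlation of each feature at two segment lengths.

    For every pair of candidate lengths, each participant's longest run in
    ``state`` is truncated to both lengths, featurized, and each feature's
    values are correlated across participants.  Constant feature vectors make
    the correlation undefined (NA).
    """
    import pandas as pd

    from .annotation import longest_uninterrupted_run

    lengths = sorted(set(int(v) for v in lengths))
    per_length: dict[int, dict[str, np.ndarray]] = {}
    runs = []
    for series in cohort:
        run = longest_uninterrupted_run(series, state)
        if run is not None and len(run.values) >= max(lengths):
            runs.append(run)
    if len(runs) < 3:
        raise ValueError(
            "segment-length sensitivity requires >= 3 participants with runs "
            f"covering {max(lengths)} minutes"
        )
    for L in lengths:
        vecs = [compute_catch22(run.values[:L]) for run in runs]
        per_length[L] = {
            name: np.array([v[name] for v in vecs]) for name in FEATURE_NAMES
        }
    rows = []
    for i, la in enumerate(lengths):
        for lb in lengths[i:]:
            for name in FEATURE_NAMES:
                a = per_length[la][name]
                b = per_length[lb][name]
                if a.std() == 0 or b.std() == 0:
                    r = math.nan
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                rows.append(
                    {"feature": name, "length_a": la, "length_b": lb, "correlation": r}
                )
    return pd.DataFrame(rows)


def pairwise_state_correlations(features: Iterable[HighResFeatures]):
    """Pearson correlation of each feature between pairs of activity states.

    Mirrors the population-level redundancy check: a feature that is constant
    within a state (for example the fluctuation-analysis features on 20-minute
    active segments) yields an undefined correlation, reported as NA.
    """
    import pandas as pd

    feats = list(features)
    state_names = sorted({s for f in feats for s in f.states})
    rows = []
    for i, sa in enumerate(state_names):
        for sb in state_names[i + 1 :]:
            both = [f for f in feats if sa in f.states and sb in f.states]
            for name in FEATURE_NAMES:
                a = np.array([f.states[sa][name] for f in both])
                b = np.array([f.states[sb][name] for f in both])
                if len(both) < 3 or a.std() == 0 or b.std() == 0:
                    r = math.nan
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                rows.append(
                    {"feature": name, "state_a": sa, "state_b": sb, "correlation": r}
                )
    return pd.DataFrame(rows)
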