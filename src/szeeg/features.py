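"""Nonlinear feature extractors for 1-D signals and feature-matrix assembly.

Nine scalar statistics are provided, each quantifying a different facet of
signal irregularity:

==================  =====================================================
``dfa``             detrended fluctuation analysis scaling exponent alpha
``hurst_rs``        rescaled-range (R/S) Hurst exponent
``rqa_measures``    recurrence rate / determinism of the embedded orbit
``sample_entropy``  SampEn(m, r): conditional template-match irregularity
``katz_fd``         Katz fractal dimension log10(L)/log10(d)
``kolmogorov_complexity``  normalized LZ76 phrase count, mean binarized
``hjorth_params``   activity / mobility / complexity
``lz_complexity``   normalized LZ76 phrase count, median binarized
``lyapunov_rosenstein``    largest Lyapunov exponent, nearest-neighbor
                    divergence method
==================  =====================================================

All tolerances and thresholds are defined relative to the signal's own
scale (SD, mean or median), so sample entropy and the LZ-based measures
are invariant under affine rescaling ``x -> a x + b`` (a != 0).

``feature_matrix`` evaluates one method over the rows of a
:class:`~szeeg.synthetic.SegmentMatrix` under a 10-column grid of
parameter variants, producing the per-method per-channel observation
matrix consumed by the feature-selection stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateInputError, ParameterError
from .synthetic import SegmentMatrix

__all__ = [
    "METHODS",
    "FeatureMatrix",
    "dfa",
    "hurst_rs",
    "rqa_measures",
    "sample_entropy",
    "katz_fd",
    "kolmogorov_complexity",
    "hjorth_params",
    "lz_complexity",
    "lyapunov_rosenstein",
    "lz76_phrase_count",
    "default_variants",
    "feature_matrix",
    "extract_scalar",
]

#: Canonical method keys, in the order used throughout the pipeline.
METHODS = (
    "dfa",
    "hurst",
    "rqa",
    "sampen",
    "katz",
    "kolmogorov",
    "hjorth",
    "lzc",
    "lle",
)


def _as_1d(signal) -> np.ndarray:
    x = np.asarray(signal, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ParameterError("signal contains non-finite values")
    return x


# ---------------------------------------------------------------------------
# scaling exponents
# ---------------------------------------------------------------------------

def dfa(signal, scales: Sequence[int] | None = None, detrend_order: int = 1) -> float:
    """Detrended fluctuation analysis scaling exponent.

    The signal is integrated (cumulative sum of the mean-removed series),
    cut into non-overlapping windows of each scale, polynomially detrended
    per window, and alpha is the least-squares slope of log F(s) against
    log s, F(s) being the RMS residual fluctuation.

    White noise gives alpha ~ 0.5, fGn with Hurst exponent H gives
    alpha ~ H, Brownian-like signals alpha ~ 1.5.
    """
    x = _as_1d(signal)
    n = x.size
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant signal has no fluctuation to scale")
    if scales is None:
        scales = default_dfa_scales(n)
    scales_arr = np.unique(np.asarray(scales, dtype=int))
    if scales_arr.size < 2:
        raise ParameterError("need at least two distinct scales")
    if scales_arr.min() < detrend_order + 2:
        raise ParameterError("smallest scale too short for the detrend order")
    if scales_arr.max() > n // 4:
        raise ParameterError("scales must not exceed n/4")
    profile = np.cumsum(x - x.mean())
    fluct = np.empty(scales_arr.size)
    for i, s in enumerate(scales_arr):
        n_win = n // s
        seg = profile[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        vand = np.vander(t, detrend_order + 1)
        coef, *_ = np.linalg.lstsq(vand, seg.T, rcond=None)
        resid = seg.T - vand @ coef
        fluct[i] = np.sqrt(np.mean(resid**2))
    good = fluct > 0
    if good.sum() < 2:
        raise DegenerateInputError("zero fluctuation at almost all scales")
    slope = np.polyfit(np.log(scales_arr[good]), np.log(fluct[good]), 1)[0]
    return float(slope)


def default_dfa_scales(n: int, n_scales: int = 10, max_frac: float = 0.25) -> np.ndarray:
    """Log-spaced window sizes in [4, n * max_frac] (capped at n/4)."""
    hi = min(int(n * max_frac), n // 4)
    if hi < 4:
        raise ParameterError("signal too short for DFA")
    return np.unique(np.geomspace(4, hi, n_scales).astype(int))


def _expected_rs(b: int) -> float:
    """E[R/S] of an iid Gaussian block of size b (Anis-Lloyd, Peters factor)."""
    from scipy.special import gammaln

    i = np.arange(1, b)
    s = float(np.sum(np.sqrt((b - i) / i)))
    if b <= 340:
        pref = math.exp(gammaln((b - 1) / 2.0) - gammaln(b / 2.0)) / math.sqrt(math.pi)
    else:
        pref = 1.0 / math.sqrt(b * math.pi / 2.0)
    return (b - 0.5) / b * pref * s


def hurst_rs(signal, block_sizes: Sequence[int] | None = None,
             corrected: bool = True) -> float:
    """Rescaled-range Hurst exponent.

    For each block size the range of the mean-adjusted cumulative sum is
    divided by the block SD.  With ``corrected=False`` H is the raw slope
    of log mean(R/S) against log block size; the default applies the
    Anis-Lloyd-Peters small-sample correction, H = 1/2 + slope of
    log(R/S) - log E[R/S_iid], which removes most of the raw estimator's
    upward bias at small blocks.  H ~ 0.5 for memoryless noise, > 0.5 for
    persistent signals, near 1 for a monotone ramp.
    """
    x = _as_1d(signal)
    n = x.size
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant signal has undefined R/S")
    if block_sizes is None:
        block_sizes = default_hurst_blocks(n)
    blocks = np.unique(np.asarray(block_sizes, dtype=int))
    if blocks.size < 2:
        raise ParameterError("need at least two distinct block sizes")
    if blocks.min() < 4:
        raise ParameterError("block sizes must be >= 4")
    if blocks.max() > n // 2:
        raise ParameterError("block sizes must not exceed n/2")
    log_b, log_rs = [], []
    for b in blocks:
        nb = n // b
        seg = x[: nb * b].reshape(nb, b)
        z = seg - seg.mean(axis=1, keepdims=True)
        y = np.cumsum(z, axis=1)
        r = y.max(axis=1) - y.min(axis=1)
        s = seg.std(axis=1)
        ok = s > 0
        if not ok.any():
            continue
        rs = np.mean(r[ok] / s[ok])
        if rs > 0:
            log_b.append(math.log(b))
            if corrected:
                log_rs.append(math.log(rs) - math.log(_expected_rs(int(b))))
            else:
                log_rs.append(math.log(rs))
    if len(log_b) < 2:
        raise DegenerateInputError("R/S undefined at almost all block sizes")
    slope = float(np.polyfit(log_b, log_rs, 1)[0])
    return 0.5 + slope if corrected else slope


def default_hurst_blocks(n: int, max_frac: float = 0.25) -> np.ndarray:
    """Powers of two in [8, n * max_frac] (capped at n/2)."""
    hi = min(int(n * max_frac), n // 2)
    if hi < 8:
        raise ParameterError("signal too short for R/S analysis")
    exps = np.arange(3, int(math.floor(math.log2(hi))) + 1)
    return (2 ** exps).astype(int)


# ---------------------------------------------------------------------------
# recurrence analysis
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_points = x.size - (m - 1) * tau
    if n_points < 2:
        raise ParameterError("signal too short for the requested embedding")
    idx = np.arange(n_points)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def autocorr_delay(signal, cap: int = 10) -> int:
    """First zero crossing of the autocorrelation, capped; at least 1."""
    x = _as_1d(signal)
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom == 0:
        return 1
    for lag in range(1, min(cap, x.size - 1) + 1):
        if np.dot(x[:-lag], x[lag:]) / denom <= 0:
            return lag
    return max(1, min(cap, x.size - 1))


def rqa_measures(signal, m: int = 3, tau: int | None = None,
                 eps: float | None = None, theiler: int | None = None) -> dict:
    """Recurrence rate and determinism of the time-delay embedded orbit.

    A pair of embedded points (i, j), j - i > theiler, recurs when their
    Euclidean distance is <= eps.  Determinism is the fraction of recurrent
    points lying on diagonal line structures of length >= 2.

    By default ``tau`` is the first autocorrelation zero crossing (capped
    at 10), ``theiler = tau``, and ``eps`` is 0.2 x the SD of all embedded
    pairwise distances.
    """
    x = _as_1d(signal)
    if m < 1:
        raise ParameterError("embedding dimension m must be >= 1")
    if tau is None:
        tau = autocorr_delay(x)
    if tau < 1:
        raise ParameterError("delay tau must be >= 1")
    if theiler is None:
        theiler = tau
    pts = _embed(x, m, tau)
    n_e = pts.shape[0]
    if n_e < 10:
        raise ParameterError("fewer than 10 embedded points")
    dists = pdist(pts)
    if eps is None:
        eps = 0.2 * float(dists.std())
    elif eps <= 0:
        raise ParameterError("radius eps must be > 0")
    dmat = squareform(dists)
    rec = dmat <= eps
    offsets = np.arange(theiler + 1, n_e)
    total_pairs = 0
    rec_pairs = 0
    det_pairs = 0
    for k in offsets:
        diag = np.diagonal(rec, offset=k)
        total_pairs += diag.size
        nrec = int(diag.sum())
        rec_pairs += nrec
        if nrec:
            padded = np.concatenate([[False], diag, [False]])
            changes = np.flatnonzero(padded[1:] != padded[:-1])
            run_lengths = changes[1::2] - changes[::2]
            det_pairs += int(run_lengths[run_lengths >= 2].sum())
    recurrence_rate = rec_pairs / total_pairs if total_pairs else 0.0
    determinism = det_pairs / rec_pairs if rec_pairs else 0.0
    return {"recurrence_rate": float(recurrence_rate), "determinism": float(determinism)}


# ---------------------------------------------------------------------------
# entropy and complexity
# ---------------------------------------------------------------------------

def sample_entropy(signal, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy -ln(A/B) with Chebyshev distance.

    B counts template pairs (i < j over the first n - m start indices)
    matching within tolerance r = r_frac * SD at length m; A counts the
    same pairs at length m + 1.  Self-matches are excluded by the i < j
    pairing.  A constant signal returns 0 by convention (every template
    matches); if no m+1 matches exist the +inf sentinel is returned.
    """
    x = _as_1d(signal)
    n = x.size
    if m < 1:
        raise ParameterError("m must be >= 1")
    if r_frac <= 0:
        raise ParameterError("r_frac must be > 0")
    if n < m + 2:
        raise ParameterError("signal shorter than m + 2")
    r = r_frac * float(x.std())
    if r == 0:
        return 0.0
    n_templates = n - m
    # Chebyshev distances accumulated one embedding coordinate at a time.
    cheb_m = np.zeros((n_templates, n_templates))
    for k in range(m):
        v = x[k : k + n_templates]
        cheb_m = np.maximum(cheb_m, np.abs(v[:, None] - v[None, :]))
    iu = np.triu_indices(n_templates, k=1)
    match_m = cheb_m[iu] <= r
    v = x[m : m + n_templates]
    cheb_m1 = np.maximum(cheb_m, np.abs(v[:, None] - v[None, :]))
    match_m1 = cheb_m1[iu] <= r
    b = int(match_m.sum())
    a = int(match_m1.sum())
    if b == 0 or a == 0:
        return math.inf
    return float(-math.log(a / b))


def katz_fd(signal) -> float:
    """Katz fractal dimension log10(L) / log10(d).

    L is the curve length (sum of successive point-to-point Euclidean
    distances with unit abscissa spacing) and d the farthest Euclidean
    distance from the first point to any other.  A straight ramp has
    L = d, hence dimension exactly 1.
    """
    x = _as_1d(signal)
    n = x.size
    if n < 2:
        raise ParameterError("need at least two points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all points identical")
    diffs = np.diff(x)
    length = float(np.sum(np.sqrt(1.0 + diffs**2)))
    idx = np.arange(1, n, dtype=float)
    d = float(np.max(np.sqrt(idx**2 + (x[1:] - x[0]) ** 2)))
    if length <= 0 or d <= 0:
        raise DegenerateInputError("degenerate curve: zero length or diameter")
    log_d = math.log10(d)
    log_l = math.log10(length)
    if log_d == 0.0:
        if log_l == 0.0:
            return 1.0
        raise DegenerateInputError("unit diameter makes the log ratio undefined")
    return float(log_l / log_d)


def lz76_phrase_count(symbols) -> int:
    """Number of complete phrases in the LZ76 exhaustive production.

    Greedy parsing: at each position the longest block reproducible from
    the already-seen prefix (copying with overlap allowed) is extended by
    one novel symbol to close a phrase.  A trailing block that ends the
    sequence while still reproducible does not open a new phrase.  A
    constant sequence therefore has count 1.
    """
    s = "".join("1" if b else "0" for b in np.asarray(symbols).astype(bool).ravel())
    n = len(s)
    if n == 0:
        raise ParameterError("empty symbol sequence")
    c = 0
    p = 0
    while p < n:
        l = 1
        while p + l <= n and s[p : p + l] in s[: p + l - 1]:
            l += 1
        if p + l <= n:
            c += 1  # phrase closed by a novel symbol
        p += l
    return max(c, 1)


def kolmogorov_complexity(signal) -> float:
    """Normalized description-length proxy c(n) * log2(n) / n.

    The signal is binarized at its mean and parsed with LZ76; more random
    signals need more phrases, pushing the value toward ~1.
    """
    x = _as_1d(signal)
    n = x.size
    if n < 10:
        raise ParameterError("need at least 10 samples")
    c = lz76_phrase_count(x >= x.mean())
    return float(c * math.log2(n) / n)


def lz_complexity(signal) -> float:
    """Normalized Lempel-Ziv complexity c(n) / (n / log2 n).

    Binarization is at the median (distinct from the mean rule used by
    :func:`kolmogorov_complexity`).  Values near 0 indicate repetitive
    structure; values near 1, incompressible randomness.
    """
    x = _as_1d(signal)
    n = x.size
    if n < 10:
        raise ParameterError("need at least 10 samples")
    c = lz76_phrase_count(x > np.median(x))
    return float(c / (n / math.log2(n)))


def hjorth_params(signal) -> dict:
    """Hjorth activity, mobility and complexity.

    activity = var(x); mobility = sqrt(var(dx)/var(x)) -- a dominant
    angular-frequency proxy in rad/sample; complexity = mobility(dx) /
    mobility(x) -- a bandwidth proxy, ~1 for a pure sinusoid.
    """
    x = _as_1d(signal)
    if x.size < 3:
        raise ParameterError("need at least 3 samples")
    var_x = float(np.var(x))
    if var_x == 0:
        raise DegenerateInputError("zero-variance signal has undefined mobility")
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_dx = float(np.var(dx))
    mobility = math.sqrt(var_dx / var_x)
    if var_dx == 0:
        complexity = math.nan  # e.g. a perfect ramp
    else:
        complexity = math.sqrt(float(np.var(ddx)) / var_dx) / mobility
    return {"activity": var_x, "mobility": mobility, "complexity": complexity}


# ---------------------------------------------------------------------------
# largest Lyapunov exponent
# ---------------------------------------------------------------------------

def lyapunov_rosenstein(signal, m: int = 5, tau: int | None = None,
                        mean_period: int | None = None,
                        fit_range: tuple[int, int] = (1, 8),
                        min_points: int = 100) -> float:
    """Largest Lyapunov exponent via nearest-neighbor divergence.

    Each embedded point is paired with its nearest neighbor separated in
    time by more than ``mean_period``; the exponent is the least-squares
    slope (per sample step) of the mean log divergence over
    ``fit_range = (k_min, k_max)`` steps.  Positive values indicate
    sensitive dependence (the logistic map at r=4 has lambda = ln 2).
    """
    x = _as_1d(signal)
    if tau is None:
        tau = autocorr_delay(x)
    if mean_period is None:
        mean_period = _mean_period(x)
    pts = _embed(x, m, tau)
    n_e = pts.shape[0]
    if n_e < min_points:
        raise ParameterError(f"only {n_e} embedded points; need >= {min_points}")
    k_min, k_max = fit_range
    if not 0 <= k_min < k_max:
        raise ParameterError("fit_range must satisfy 0 <= k_min < k_max")
    if n_e - k_max < 10:
        raise ParameterError("fit_range too long for the embedded orbit")
    dmat = squareform(pdist(pts))
    band = np.abs(np.subtract.outer(np.arange(n_e), np.arange(n_e))) <= mean_period
    dmat[band] = np.inf
    usable = n_e - k_max
    nn = np.argmin(dmat[:usable], axis=1)
    valid = nn < usable
    base = np.arange(usable)[valid]
    nn = nn[valid]
    if base.size < 10:
        raise ParameterError("too few temporally separated neighbor pairs")
    ks = np.arange(k_min, k_max + 1)
    mean_log = np.empty(ks.size)
    for i, k in enumerate(ks):
        d = np.linalg.norm(pts[base + k] - pts[nn + k], axis=1)
        d = d[d > 0]
        if d.size < 5:
            mean_log[i] = np.nan
        else:
            mean_log[i] = np.mean(np.log(d))
    ok = np.isfinite(mean_log)
    if ok.sum() < 2:
        raise DegenerateInputError("divergence curve undefined (identical trajectories)")
    return float(np.polyfit(ks[ok], mean_log[ok], 1)[0])


def _mean_period(x: np.ndarray) -> int:
    """Mean oscillation period estimated from mean-crossings of the signal."""
    z = x - x.mean()
    crossings = int(np.sum(np.signbit(z[:-1]) != np.signbit(z[1:])))
    if crossings == 0:
        return 1
    return max(1, int(round(2.0 * z.size / crossings / 2.0)))


# ---------------------------------------------------------------------------
# feature-matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Observation-by-variant matrix of one feature method on one channel."""

    method: str
    channel: int
    values: np.ndarray                 # rows x n_variants, finite after imputation
    variants: list[dict]               # exact parameter set per column
    segment_index: np.ndarray          # source segment of each row
    n_imputed: int = 0
    mode: str = "subwindow"

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]


def extract_scalar(method: str, window: np.ndarray, params: dict) -> float:
    """Evaluate one method on one window under one variant's parameters.

    ``window_frac`` (if present) restricts the window to its leading
    fraction before the statistic is computed; other keys are forwarded to
    the extractor.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown feature method {method!r}")
    p = dict(params)
    frac = p.pop("window_frac", None)
    w = window
    if frac is not None:
        w = window[: max(int(len(window) * float(frac)), 1)]
    if method == "dfa":
        n = w.size
        scales = default_dfa_scales(n, max_frac=p.pop("max_scale_frac", 0.25))
        return dfa(w, scales=scales, detrend_order=p.pop("detrend_order", 1))
    if method == "hurst":
        blocks = default_hurst_blocks(n=w.size, max_frac=p.pop("max_block_frac", 0.25))
        return hurst_rs(w, block_sizes=blocks)
    if method == "rqa":
        eps_frac = p.pop("eps_frac", 0.2)
        m = p.pop("m", 3)
        tau = p.pop("tau", None)
        out = rqa_measures(w, m=m, tau=tau, eps=None if eps_frac is None else _rqa_eps(w, m, tau, eps_frac))
        return out[p.pop("measure", "recurrence_rate")]
    if method == "sampen":
        return sample_entropy(w, m=p.pop("m", 2), r_frac=p.pop("r_frac", 0.2))
    if method == "katz":
        return katz_fd(w)
    if method == "kolmogorov":
        return kolmogorov_complexity(w)
    if method == "hjorth":
        return hjorth_params(w)[p.pop("which", "mobility")]
    if method == "lzc":
        return lz_complexity(w)
    if method == "lle":
        return lyapunov_rosenstein(
            w,
            m=p.pop("m", 5),
            tau=p.pop("tau", None),
            mean_period=p.pop("mean_period", None),
            fit_range=tuple(p.pop("fit_range", (1, 8))),
            min_points=p.pop("min_points", 100),
        )
    raise ParameterError(f"unknown feature method {method!r}")  # pragma: no cover


def _rqa_eps(w: np.ndarray, m: int, tau: int | None, eps_frac: float) -> float:
    if tau is None:
        tau = autocorr_delay(w)
    d = pdist(_embed(_as_1d(w), m, tau))
    return max(float(eps_frac) * float(d.std()), np.finfo(float).tiny)


def default_variants(method: str) -> list[dict]:
    """The documented 10-column parameter grid for one method.

    Each grid varies the single most salient parameter of its method:
    scale range for DFA/R-S, tolerance for SampEn, radius for RQA, and
    analysis-window fraction for the window-local statistics.
    """
    if method == "dfa":
        return [{"max_scale_frac": round(f, 4)} for f in np.geomspace(1 / 16, 1 / 4, 10)]
    if method == "hurst":
        return [{"max_block_frac": round(f, 4)} for f in np.geomspace(1 / 8, 1 / 2, 10)]
    if method == "sampen":
        return [{"m": 2, "r_frac": round(r, 4)} for r in np.linspace(0.10, 0.325, 10)]
    if method == "rqa":
        return [{"m": 3, "eps_frac": round(e, 4)} for e in np.linspace(0.10, 0.55, 10)]
    if method in ("katz", "kolmogorov", "lzc"):
        return [{"window_frac": round(f, 4)} for f in np.linspace(0.3, 1.0, 10)]
    if method == "hjorth":
        return [{"which": "mobility", "window_frac": round(f, 4)}
                for f in np.linspace(0.3, 1.0, 10)]
    if method == "lle":
        return [{"window_frac": round(f, 4)} for f in np.linspace(0.6, 1.0, 10)]
    raise ParameterError(f"unknown feature method {method!r}")


def feature_matrix(segment_matrix: SegmentMatrix, method: str,
                   variant_params: Sequence[dict] | None = None,
                   mode: str = "subwindow", n_subwindows: int = 10,
                   dense_window: int = 250) -> FeatureMatrix:
    """Assemble the observation x variant matrix for one method and channel.

    mode="subwindow" (default): each segment is split into
    ``n_subwindows`` equal non-overlapping sub-windows and the method is
    evaluated once per sub-window per variant, giving
    (n_segments * n_subwindows) rows.

    mode="dense": a stride-1 sliding window of length ``dense_window``
    (reflect-padded at the edges) is evaluated at every sample of each
    segment, giving segment_length rows per segment.

    Sub-windows that violate a method's preconditions yield flagged cells
    imputed by the column median; the count is kept in ``n_imputed``.
    """
    if variant_params is None:
        variant_params = default_variants(method)
    variants = [dict(v) for v in variant_params]
    if len(variants) != 10:
        raise ParameterError("variant_params must have exactly 10 entries")
    if mode not in ("subwindow", "dense"):
        raise ParameterError(f"unknown mode {mode!r}")

    windows: list[np.ndarray] = []
    seg_idx: list[int] = []
    if mode == "subwindow":
        if n_subwindows < 1 or segment_matrix.segment_length < n_subwindows:
            raise ParameterError("invalid n_subwindows for this segment length")
        sub_len = segment_matrix.segment_length // n_subwindows
        for k in range(segment_matrix.n_segments):
            seg = segment_matrix.segment(k)
            for s in range(n_subwindows):
                windows.append(seg[s * sub_len : (s + 1) * sub_len])
                seg_idx.append(k)
    else:
        if dense_window < 4:
            raise ParameterError("dense_window too short")
        half = dense_window // 2
        for k in range(segment_matrix.n_segments):
            seg = segment_matrix.segment(k)
            padded = np.pad(seg, half, mode="reflect")
            for c in range(segment_matrix.segment_length):
                windows.append(padded[c : c + dense_window])
                seg_idx.append(k)

    values = np.full((len(windows), len(variants)), np.nan)
    for j, params in enumerate(variants):
        for i, w in enumerate(windows):
            try:
                v = extract_scalar(method, w, params)
            except (DegenerateInputError, ParameterError):
                continue
            if np.isfinite(v):
                values[i, j] = v
    n_imputed = int(np.isnan(values).sum())
    if n_imputed:
        med = np.nanmedian(values, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        nan_r, nan_c = np.nonzero(np.isnan(values))
        values[nan_r, nan_c] = med[nan_c]
    return FeatureMatrix(
        method=method,
        channel=segment_matrix.channel,
        values=values,
        variants=variants,
        segment_index=np.asarray(seg_idx, dtype=int),
        n_imputed=n_imputed,
        mode=mode,
    )
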