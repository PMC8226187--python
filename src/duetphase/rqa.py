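"""Recurrence quantification analysis with data-driven parameter selection.

A scalar (or circular) series is delay-embedded with dimension ``m`` and delay
``τ``; a recurrence plot marks pairs of times whose embedded states lie within
a radius ε (Euclidean norm).  Circular signals are mapped to (cos, sin) pairs
before embedding so the 0/2π wrap introduces no spurious distances.  Metrics:

* RR  — fraction of recurrent pairs outside the Theiler band,
* DET — fraction of recurrent points lying on diagonal lines of length ≥ lmin,
* TT  — mean vertical line length among verticals of length ≥ vmin.

Embedding parameters can be chosen from the data: the delay from the first
local minimum of average mutual information, the dimension from the false
nearest-neighbour fraction (Kennel criteria), and the radius by bisection to a
target recurrence rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field
from scipy.spatial.distance import cdist

from .errors import AlignmentError, CalibrationError, InsufficientDataError


class RQAConfig(BaseModel):
    """Embedding, radius and line-length parameters for recurrence analysis.

    Defaults follow the phase-series convention (m=4, τ=0.3 s, ε=0.55); for
    postural sway use m=5, τ=0.35 s and calibrate the radius to ``target_rr``.
    """

    m: int = Field(4, ge=1)
    tau_s: float = Field(0.3, gt=0)
    radius: float = Field(0.55, gt=0)
    lmin_s: float = Field(0.3, gt=0)
    vmin_s: float = Field(0.3, gt=0)
    theiler_s: float | None = None  # default m·τ
    target_rr: float = Field(0.10, gt=0, lt=1)

    @property
    def theiler(self) -> float:
        return self.m * self.tau_s if self.theiler_s is None else self.theiler_s


@dataclass(frozen=True)
class RecurrencePlot:
    """(Joint) recurrence matrix plus the sampling metadata metrics need."""

    matrix: np.ndarray  # bool when thresholded, float distances otherwise
    fs: float
    theiler: int  # samples; |i-j| <= theiler excluded from all counts
    thresholded: bool

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class RQAMetrics:
    rr: float
    det: float
    tt: float
    windowed: list[tuple[float, float, float, float]] | None = None


def delay_embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay embedding of a scalar or vector series.

    ``x`` of shape (n,) or (n, d) → (n − (m−1)τ, m·d).
    """
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0] - (m - 1) * tau
    if n < 1:
        raise InsufficientDataError(
            f"series of {x.shape[0]} samples too short for m={m}, tau={tau}"
        )
    return np.concatenate([x[i * tau : i * tau + n] for i in range(m)], axis=1)


def _embedded(series: np.ndarray, cfg: RQAConfig, fs: float, circular: bool):
    x = np.asarray(series, float)
    if circular:
        x = np.column_stack([np.cos(x), np.sin(x)])
    tau = max(1, int(round(cfg.tau_s * fs)))
    emb = delay_embed(x, cfg.m, tau)
    if emb.shape[0] < 10:
        raise InsufficientDataError(
            f"only {emb.shape[0]} embedded points; need at least 10"
        )
    return emb


def recurrence_matrix(
    series: np.ndarray,
    cfg: RQAConfig,
    fs: float,
    circular: bool = False,
    threshold: bool = True,
) -> RecurrencePlot:
    """Recurrence plot of a delay-embedded series.

    With ``threshold=False`` the raw pairwise distance matrix is returned
    (for normalized unthresholded plots).
    """
    emb = _embedded(series, cfg, fs, circular)
    dist = cdist(emb, emb)
    theiler = int(round(cfg.theiler * fs))
    if threshold:
        return RecurrencePlot(dist <= cfg.radius, fs, theiler, True)
    return RecurrencePlot(dist, fs, theiler, False)


def joint_recurrence(r1: RecurrencePlot, r2: RecurrencePlot) -> RecurrencePlot:
    """Joint recurrence plot: elementwise AND of two thresholded plots."""
    if r1.matrix.shape != r2.matrix.shape:
        raise AlignmentError(
            f"recurrence plots have different shapes {r1.matrix.shape} vs "
            f"{r2.matrix.shape}"
        )
    if not (r1.thresholded and r2.thresholded):
        raise ValueError("joint recurrence requires thresholded plots")
    return RecurrencePlot(
        r1.matrix & r2.matrix, r1.fs, max(r1.theiler, r2.theiler), True
    )


def _line_lengths(runs_arrays: list[np.ndarray]) -> np.ndarray:
    """Lengths of True-runs across a list of 1-D boolean arrays."""
    if not runs_arrays:
        return np.array([], int)
    sep = np.zeros(1, bool)
    flat = np.concatenate([np.concatenate((a, sep)) for a in runs_arrays])
    padded = np.concatenate((sep, flat))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges[1::2] - edges[0::2]


def _metrics_from_matrix(
    mat: np.ndarray, theiler: int, lmin: int, vmin: int
) -> tuple[float, float, float]:
    n = mat.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    off = np.abs(i - j) > theiler
    n_off = int(off.sum())
    if n_off == 0:
        return 0.0, 0.0, 0.0
    rec = mat & off
    n_rec = int(rec.sum())
    rr = n_rec / n_off
    if n_rec == 0:
        return rr, 0.0, 0.0
    # diagonal lines strictly outside the Theiler band (both triangles)
    diags = [np.diagonal(rec, k) for k in range(theiler + 1, n)]
    diags += [np.diagonal(rec, -k) for k in range(theiler + 1, n)]
    dlen = _line_lengths([d for d in diags if d.size])
    det = float(dlen[dlen >= lmin].sum() / n_rec) if dlen.size else 0.0
    # vertical lines on the Theiler-masked matrix
    vlen = _line_lengths(list(rec.T))
    long_v = vlen[vlen >= vmin]
    tt = float(long_v.mean()) if long_v.size else 0.0
    return rr, det, tt


def rqa_metrics(
    rp: RecurrencePlot,
    cfg: RQAConfig,
    windowed: bool = False,
    window_s: float = 10.0,
    step_s: float = 1.0,
) -> RQAMetrics:
    """RR, DET and TT of a recurrence plot, optionally windowed in time.

    Windowed metrics are computed inside square windows centered on the main
    diagonal, fully interior to the plot, advancing by ``step_s``.
    """
    if not rp.thresholded:
        raise ValueError("rqa_metrics requires a thresholded recurrence plot")
    lmin = max(1, int(round(cfg.lmin_s * rp.fs)))
    vmin = max(1, int(round(cfg.vmin_s * rp.fs)))
    rr, det, tt = _metrics_from_matrix(rp.matrix, rp.theiler, lmin, vmin)
    windows = None
    if windowed:
        w = int(round(window_s * rp.fs))
        step = max(1, int(round(step_s * rp.fs)))
        windows = []
        for start in range(0, rp.n - w + 1, step):
            sub = rp.matrix[start : start + w, start : start + w]
            wrr, wdet, wtt = _metrics_from_matrix(sub, rp.theiler, lmin, vmin)
            t_center = (start + w / 2.0) / rp.fs
            windows.append((t_center, wrr, wdet, float(wtt / rp.fs)))
    return RQAMetrics(rr=rr, det=det, tt=float(tt / rp.fs), windowed=windows)


def calibrate_radius(
    series: np.ndarray,
    cfg: RQAConfig,
    fs: float,
    target_rr: float | None = None,
    tol: float = 0.005,
    circular: bool = False,
    max_iter: int = 60,
) -> tuple[float, float]:
    """Bisect the radius until RR hits the target within ``tol``.

    RR is monotone non-decreasing in the radius, so bisection on
    [0, max pairwise distance] converges.  Returns (radius, achieved RR).
    """
    target = cfg.target_rr if target_rr is None else target_rr
    if not 0.0 < target < 0.5:
        raise ValueError(f"target_rr must be in (0, 0.5), got {target}")
    emb = _embedded(series, cfg, fs, circular)
    dist = cdist(emb, emb).astype(np.float32)
    theiler = int(round(cfg.theiler * fs))
    n = emb.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    off = np.abs(i - j) > theiler
    d_off = dist[off]
    d_max = float(d_off.max()) if d_off.size else 0.0
    if d_max == 0.0:
        raise CalibrationError("series is constant after embedding; cannot calibrate")
    lo, hi = 0.0, d_max
    rr = 0.0
    radius = d_max
    for _ in range(max_iter):
        radius = 0.5 * (lo + hi)
        rr = float((d_off <= radius).mean())
        if abs(rr - target) <= tol:
            break
        if rr < target:
            lo = radius
        else:
            hi = radius
    return radius, rr


def _ami(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Average mutual information (nats) with equiquantile binning."""
    edges_x = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    edges_y = np.quantile(y, np.linspace(0, 1, bins + 1)[1:-1])
    bx = np.searchsorted(edges_x, x)
    by = np.searchsorted(edges_y, y)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))


_COPULA_RHO_MAX = 0.999


def _ami_copula(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian rank-copula mutual information (nats)."""
    from scipy.stats import norm, rankdata

    a = norm.ppf(rankdata(x) / (len(x) + 1))
    b = norm.ppf(rankdata(y) / (len(y) + 1))
    rho2 = min(float(np.corrcoef(a, b)[0, 1]) ** 2, _COPULA_RHO_MAX**2)
    return -0.5 * np.log(1.0 - rho2)


def select_delay_ami(
    series: np.ndarray,
    fs: float,
    max_lag_s: float = 2.0,
    method: str = "copula",
) -> float:
    """Embedding delay from the first minimum of average mutual information.

    The default estimator is the Gaussian rank-copula MI, which is smooth in
    the lag for deterministic signals (a sinusoid's first minimum falls at a
    quarter period); ``method="histogram"`` uses equiquantile binning with
    ⌊√(n/5)⌋ bins instead.  Selection rule: if the MI already sits below 1/e
    of its lag-0 value at lag 1, the series decorrelates within one sample
    and lag 1 is returned (broadband noise); otherwise the first strict local
    minimum wins; failing that, the first drop below the 1/e floor, then the
    largest scanned lag.  Returns the delay in seconds.
    """
    x = np.asarray(series, float)
    n = len(x)
    if n < 200:
        raise InsufficientDataError(f"need at least 200 samples for AMI, got {n}")
    if np.ptp(x) == 0:
        raise InsufficientDataError("constant series has zero entropy")
    if method == "copula":
        ami0 = -0.5 * np.log(1.0 - _COPULA_RHO_MAX**2)

        def ami_at(lag: int) -> float:
            return _ami_copula(x[:-lag], x[lag:])

    elif method == "histogram":
        bins = max(2, int(np.sqrt(n / 5)))
        ami0 = _ami(x, x, bins)

        def ami_at(lag: int) -> float:
            return _ami(x[:-lag], x[lag:], bins)

    else:
        raise ValueError(f"unknown AMI method {method!r}")
    floor = ami0 / np.e
    max_lag = max(2, min(int(round(max_lag_s * fs)), n - 2))
    ami = np.array([ami0] + [ami_at(lag) for lag in range(1, max_lag + 1)])
    if ami[1] < floor:
        return 1.0 / fs
    for k in range(1, max_lag):
        if ami[k - 1] > ami[k] < ami[k + 1]:
            return k / fs
    below = np.flatnonzero(ami[1:] < floor)
    if below.size:
        return float(below[0] + 1) / fs
    return max_lag / fs


def select_dim_fnn(
    series: np.ndarray,
    tau_s: float,
    fs: float,
    max_dim: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    fnn_threshold: float = 0.01,
) -> tuple[int, bool]:
    """Embedding dimension by false nearest neighbours (Kennel criteria).

    Returns (m, warning): the smallest dimension whose FNN fraction falls
    below ``fnn_threshold``; if none qualifies, (max_dim, True).
    """
    from scipy.spatial import cKDTree

    x = np.asarray(series, float)
    if len(x) < 500:
        raise InsufficientDataError(
            f"need at least 500 samples for FNN, got {len(x)}"
        )
    tau = max(1, int(round(tau_s * fs)))
    sigma = float(np.std(x))
    if sigma == 0:
        raise InsufficientDataError("constant series")
    for m in range(1, max_dim + 1):
        emb_m = delay_embed(x, m, tau)
        n_next = len(x) - m * tau  # points that survive embedding in m+1
        if n_next < 10:
            return m, True
        emb_m = emb_m[:n_next]
        tree = cKDTree(emb_m)
        dist, idx = tree.query(emb_m, k=2)
        d_m = dist[:, 1]
        nn = idx[:, 1]
        extra = np.abs(x[m * tau : m * tau + n_next] - x[nn + m * tau])
        valid = d_m > 0
        false1 = np.zeros(n_next, bool)
        false1[valid] = extra[valid] / d_m[valid] > rtol
        d_m1 = np.sqrt(d_m**2 + extra**2)
        false2 = d_m1 / sigma > atol
        frac = float((false1 | false2)[valid].mean()) if valid.any() else 1.0
        if frac < fnn_threshold:
            return m, False
    return max_dim, True
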