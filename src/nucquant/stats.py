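"""Population statistics on per-nucleus measurements.

Four readouts:

* **Constant-concentration fit** — through-origin least squares of total
  signal on volume (slope = population concentration, the "radial
  iso-concentration line"), with a Spearman test of per-cell concentration
  against volume as the constancy diagnostic (rho ~ 0 when concentration is
  volume-independent). A free-intercept fit is reported as a diagnostic too.
* **Between-population concentration ratio** with a seeded bootstrap CI
  (e.g. glia vs neuron, expected ~20% under a 5:1 contrast).
* **Ploidy peak calling** — Gaussian-KDE density of integrated DNA totals,
  local maxima above a prominence floor, positions normalized to the lowest
  peak; the second peak should sit at 2 for a cycling population.
* **Spearman rank correlation** between two channels' totals, with an exact
  full-enumeration permutation p-value at small n and the t-approximation
  otherwise.

Plus rectangle-volume gel densitometry with local background subtraction and
fold changes normalized to a reference condition.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .errors import DegenerateInputError, GeometryError
from .quant import NucleusMeasurement

__all__ = [
    "ConcentrationFit",
    "RatioResult",
    "PloidyResult",
    "CorrelationResult",
    "DensitometryResult",
    "fit_constant_concentration",
    "concentration_ratio",
    "ploidy_peaks",
    "spearman_correlation",
    "blot_volume",
]

#: largest n for which the exact permutation null of Spearman's rho is enumerated
EXACT_SPEARMAN_N = 10


def _extract(measurements, channel):
    """(volumes, totals) arrays from measurements or a (V, T) pair of arrays."""
    if isinstance(measurements, (tuple, list)) and len(measurements) == 2 and not isinstance(
        measurements[0], NucleusMeasurement
    ):
        v = np.asarray(measurements[0], dtype=float)
        t = np.asarray(measurements[1], dtype=float)
        return v, t
    ms = list(measurements)
    ch = channel or next(iter(ms[0].total_signal))
    v = np.array([m.volume for m in ms], dtype=float)
    t = np.array([m.total_signal[ch] for m in ms], dtype=float)
    return v, t


def _percentile_ci(samples, level=0.95):
    lo = 100 * (1 - level) / 2
    return (float(np.percentile(samples, lo)), float(np.percentile(samples, 100 - lo)))


# -- constant concentration --------------------------------------------------


@dataclass
class ConcentrationFit:
    """Through-origin fit of total signal on volume plus constancy diagnostics."""

    slope: float  # a.u./µm³ = population concentration
    slope_ci: tuple[float, float]
    r2_through_origin: float
    per_cell_concentrations: np.ndarray
    volume_concentration_spearman: float | None
    volume_concentration_spearman_ci: tuple[float, float] | None
    intercept_free: float  # free-intercept diagnostic fit
    slope_free: float
    n: int


def fit_constant_concentration(
    measurements,
    channel: str | None = None,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> ConcentrationFit:
    """Fit a single shared concentration to (volume, total-signal) pairs.

    Through-origin least squares: ``slope = sum(T*V) / sum(V**2)``. The
    bootstrap CI (percentile, seeded) and the Spearman rho between per-cell
    concentration (T/V) and volume quantify how well "constant concentration"
    describes the population: rho near 0 is the constancy signature,
    rho near 1 flags totals growing faster than volume.
    """
    v, t = _extract(measurements, channel)
    if v.size < 5:
        raise ValueError("need >= 5 measurements")
    slope = float(np.sum(t * v) / np.sum(v * v))
    resid = t - slope * v
    r2 = 1.0 - float(np.sum(resid**2) / np.sum(t**2))
    conc = t / v
    A = np.vstack([v, np.ones_like(v)]).T
    slope_free, intercept_free = np.linalg.lstsq(A, t, rcond=None)[0]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    n = v.size
    idx = rng.integers(0, n, size=(n_boot, n))
    bs = np.sum(t[idx] * v[idx], axis=1) / np.sum(v[idx] ** 2, axis=1)
    slope_ci = _percentile_ci(bs)

    if np.ptp(v) == 0:
        warnings.warn("all volumes equal: constancy diagnostic unavailable", stacklevel=2)
        rho, rho_ci = None, None
    elif np.ptp(conc) <= 1e-12 * float(np.mean(np.abs(conc))):
        # perfectly constant concentration: no rank trend by construction
        rho, rho_ci = 0.0, (0.0, 0.0)
    else:
        rho = float(_stats.spearmanr(conc, v).statistic)
        rhos = []
        for row in idx:
            cv, vv = conc[row], v[row]
            if np.ptp(vv) > 0 and np.ptp(cv) > 0:
                rhos.append(_stats.spearmanr(cv, vv).statistic)
        rho_ci = _percentile_ci(rhos) if rhos else None
    return ConcentrationFit(
        slope=slope,
        slope_ci=slope_ci,
        r2_through_origin=r2,
        per_cell_concentrations=conc,
        volume_concentration_spearman=rho,
        volume_concentration_spearman_ci=rho_ci,
        intercept_free=float(intercept_free),
        slope_free=float(slope_free),
        n=int(n),
    )


# -- group ratio -------------------------------------------------------------


@dataclass
class RatioResult:
    """Ratio of group-A to group-B mean concentrations (and totals)."""

    ratio: float  # mean_conc_A / mean_conc_B
    ratio_ci: tuple[float, float]
    percent: float  # 100 * ratio
    percent_ci: tuple[float, float]
    inverse: float  # mean_conc_B / mean_conc_A
    totals_ratio: float  # ratio of mean total signals
    n_a: int
    n_b: int


def concentration_ratio(
    group_a,
    group_b,
    channel: str | None = None,
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> RatioResult:
    """Ratio of mean per-nucleus concentrations between two populations.

    Both orientations are reported (``ratio`` = A/B and ``inverse`` = B/A;
    ``percent`` = 100*A/B), alongside the ratio of mean total signals. CIs are
    percentile bootstrap, resampling within each group, seeded.
    """
    va, ta = _extract(group_a, channel)
    vb, tb = _extract(group_b, channel)
    if va.size < 3 or vb.size < 3:
        raise ValueError("each group needs >= 3 measurements")
    ca, cb = ta / va, tb / vb
    if np.mean(cb) == 0 or np.mean(ca) == 0:
        raise ZeroDivisionError("zero mean concentration in a group")
    ratio = float(np.mean(ca) / np.mean(cb))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 211]))
    ia = rng.integers(0, ca.size, size=(n_boot, ca.size))
    ib = rng.integers(0, cb.size, size=(n_boot, cb.size))
    bs = np.mean(ca[ia], axis=1) / np.mean(cb[ib], axis=1)
    ci = _percentile_ci(bs)
    return RatioResult(
        ratio=ratio,
        ratio_ci=ci,
        percent=100.0 * ratio,
        percent_ci=(100.0 * ci[0], 100.0 * ci[1]),
        inverse=1.0 / ratio,
        totals_ratio=float(np.mean(ta) / np.mean(tb)),
        n_a=int(va.size),
        n_b=int(vb.size),
    )


# -- ploidy ------------------------------------------------------------------


@dataclass
class PloidyResult:
    """KDE peaks of integrated DNA totals, normalized to the lowest peak."""

    peak_positions: np.ndarray  # normalized, ascending, first = 1
    second_peak: float | None
    peak_ratio_ci: tuple[float, float] | None
    bandwidth: float  # KDE bandwidth in a.u.
    raw_peak_positions: np.ndarray


def _kde_peaks(totals, bw_factor, grid, prominence_frac):
    kde = _stats.gaussian_kde(totals, bw_method=bw_factor)
    dens = kde(grid)
    peaks, _ = _signal.find_peaks(dens, prominence=prominence_frac * dens.max())
    return grid[peaks]


def ploidy_peaks(
    totals: Sequence[float],
    *,
    bandwidth: float | None = None,
    prominence_frac: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
    grid_points: int = 1024,
) -> PloidyResult:
    """Call DNA-content peaks from per-nucleus integrated DNA totals.

    Gaussian-kernel density estimate (Silverman bandwidth unless ``bandwidth``
    is given in a.u.), local maxima above ``prominence_frac`` of the density
    maximum, positions divided by the lowest peak. For a cycling population the
    second peak sits at 2 (DNA doubling). The peak ratio CI is a seeded
    bootstrap over nuclei.
    """
    x = np.asarray(totals, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 totals")
    if x.size < 50:
        warnings.warn(f"only {x.size} nuclei; >= 50 recommended", stacklevel=2)
    std = float(np.std(x, ddof=1))
    if std == 0:
        raise DegenerateInputError("all totals identical")
    if bandwidth is None:
        bw_factor = "silverman"
        bw_au = (x.size * 3.0 / 4.0) ** (-1.0 / 5.0) * min(
            std, float(np.subtract(*np.percentile(x, [75, 25]))) / 1.349
        )
    else:
        bw_factor = float(bandwidth) / std
        bw_au = float(bandwidth)
    pad = 4 * bw_au
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_points)
    raw = _kde_peaks(x, bw_factor, grid, prominence_frac)
    if raw.size == 0:
        raise DegenerateInputError("no density peaks found")
    norm = np.sort(raw) / np.sort(raw)[0]
    if norm.size < 2:
        warnings.warn("single population: fewer than 2 peaks found", stacklevel=2)
        second, ci = None, None
    else:
        second = float(norm[1])
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 307]))
        ratios = []
        for _ in range(n_boot):
            xb = rng.choice(x, size=x.size, replace=True)
            if np.std(xb, ddof=1) == 0:
                continue
            pk = _kde_peaks(xb, bw_factor, grid, prominence_frac)
            if pk.size >= 2:
                pk = np.sort(pk)
                ratios.append(pk[1] / pk[0])
        ci = _percentile_ci(ratios) if len(ratios) >= 10 else None
    return PloidyResult(
        peak_positions=norm,
        second_peak=second,
        peak_ratio_ci=ci,
        bandwidth=bw_au,
        raw_peak_positions=np.sort(raw),
    )


# -- Spearman ----------------------------------------------------------------


@dataclass
class CorrelationResult:
    """Spearman rank correlation between two per-nucleus channels."""

    rho: float
    n: int
    p_value: float
    channel_pair: tuple[str, str]
    method: str  # "exact-permutation" or "t-approximation"


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
    channel_pair: tuple[str, str] = ("ch1", "ch2"),
) -> CorrelationResult:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    For ``n <= 10`` the p-value is exact: the full permutation null of rho is
    enumerated and ``p = P(|rho_perm| >= |rho|)``. For larger n the standard
    t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("rho undefined for a constant variable")
    rx = _stats.rankdata(x)
    ry = _stats.rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    if n <= EXACT_SPEARMAN_N:
        target = abs(rho) - 1e-12
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rho_from_ranks(rx, ry[list(perm)])) >= target:
                hits += 1
        return CorrelationResult(rho, n, hits / total, tuple(channel_pair), "exact-permutation")
    tstat = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-15))
    p = 2.0 * _stats.t.sf(abs(tstat), df=n - 2)
    return CorrelationResult(rho, n, min(p, 1.0), tuple(channel_pair), "t-approximation")


def spearman_bootstrap_ci(
    x, y, *, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of Spearman's rho."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 401]))
    rhos = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue
        rhos.append(_rho_from_ranks(_stats.rankdata(xb), _stats.rankdata(yb)))
    return _percentile_ci(rhos, level)


# -- densitometry ------------------------------------------------------------


@dataclass
class DensitometryResult:
    """Rectangle-volume band quantification with local background subtraction."""

    lane_volumes: dict[str, float]
    local_background: dict[str, float]
    normalized: dict[str, float] | None
    fold_change: dict[str, float] | None
    reference: str | None


def _rect_volume(image: np.ndarray, rect, frame_px: int):
    r0, c0, h, w = (int(v) for v in rect)
    if h <= 0 or w <= 0 or r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
        raise GeometryError(f"rectangle {rect} outside image {image.shape}")
    f = frame_px
    if r0 - f < 0 or c0 - f < 0 or r0 + h + f > image.shape[0] or c0 + w + f > image.shape[1]:
        raise GeometryError(
            f"{f}-pixel background frame around rectangle {rect} exits image bounds"
        )
    outer = image[r0 - f : r0 + h + f, c0 - f : c0 + w + f].astype(np.float64)
    inner = image[r0 : r0 + h, c0 : c0 + w].astype(np.float64)
    frame_sum = outer.sum() - inner.sum()
    frame_n = outer.size - inner.size
    bg = frame_sum / frame_n
    return float(inner.sum() - bg * inner.size), float(bg)


def blot_volume(
    gel_image: np.ndarray,
    lane_rectangles: Mapping[str, Sequence[int]],
    *,
    loading_rectangles: Mapping[str, Sequence[int]] | None = None,
    reference: str | None = None,
    frame_px: int = 2,
) -> DensitometryResult:
    """Method-of-volumes (rectangle) densitometry with local subtraction.

    Each band's volume is the rectangle intensity sum minus (mean intensity of
    a ``frame_px``-wide frame around it) x rectangle area — invariant to a
    global intensity offset. With ``loading_rectangles`` the volumes are
    normalized per lane by the loading-control volume, and with ``reference``
    fold changes relative to that condition are reported (reference lane = 1).

    Rectangles are ``(row0, col0, height, width)`` and must be disjoint and,
    with their frames, inside the image.
    """
    image = np.asarray(gel_image)
    if image.ndim != 2:
        raise GeometryError("gel image must be 2D")
    occupied = np.zeros(image.shape, dtype=bool)
    all_rects = dict(lane_rectangles)
    if loading_rectangles:
        all_rects.update({f"__load__{k}": v for k, v in loading_rectangles.items()})
    for name, rect in all_rects.items():
        r0, c0, h, w = (int(v) for v in rect)
        region = occupied[r0 : r0 + h, c0 : c0 + w]
        if region.any():
            raise GeometryError(f"rectangle {name!r} overlaps another rectangle")
        region[:] = True
    volumes, backgrounds = {}, {}
    for name, rect in lane_rectangles.items():
        volumes[name], backgrounds[name] = _rect_volume(image, rect, frame_px)
    normalized = None
    if loading_rectangles is not None:
        missing = set(lane_rectangles) - set(loading_rectangles)
        if missing:
            raise GeometryError(f"no loading-control rectangle for lanes {missing}")
        normalized = {}
        for name in lane_rectangles:
            load, _ = _rect_volume(image, loading_rectangles[name], frame_px)
            if load == 0:
                raise ZeroDivisionError(f"zero loading-control volume in lane {name!r}")
            normalized[name] = volumes[name] / load
    fold = None
    if reference is not None:
        basis = normalized if normalized is not None else volumes
        if reference not in basis:
            raise GeometryError(f"reference condition {reference!r} not among lanes")
        ref = basis[reference]
        if ref == 0:
            raise ZeroDivisionError("zero reference volume")
        fold = {name: val / ref for name, val in basis.items()}
    return DensitometryResult(volumes, backgrounds, normalized, fold, reference)
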