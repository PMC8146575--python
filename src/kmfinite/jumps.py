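"""Recovery of jump-diffusion parameters from corrected KM coefficients.

For the process dX = -aX dt + b dW + xi dJ with Gaussian amplitudes
xi ~ N(0, s) and Poisson rate lambda, the KM coefficients are

    D1(x) = -a x,    D2(x) = (b^2 + s*lambda) / 2,
    D_{2n}(x) = s^n lambda / (2^n n!)          (state-independent),

since <xi^{2n}> = (2n)!/(2^n n!) s^n.  In particular D4 = s^2 lambda / 8
and D6 = s^3 lambda / 48, so

    s = 6 D6 / D4,    lambda = 8 D4 / s^2,    b^2 = 2 D2 - s*lambda.

Ratios of bin-wise values are unstable, so each D_n is first averaged over
a central state window (occupancy-weighted), which is exact here because
the jump terms are state-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimate import (
    BinningConfig,
    KMEstimate,
    conditional_moments,
    km_coefficients,
)
from .simulate import TimeSeries

__all__ = [
    "RecoveredParams",
    "ClassificationRecord",
    "fit_linear_drift",
    "weighted_average",
    "recover_jump",
    "classify",
    "dbar_standard_error",
]


@dataclass
class RecoveredParams:
    """Process parameters inferred from a full-order KM estimate.

    s_hat and lambda_hat are reported as NaN with a flag when the averaged
    D4 or D6 is non-positive (no evidence of jumps); b2_hat then absorbs
    the whole second coefficient.
    """

    a_hat: float
    b2_hat: float
    s_hat: float
    lambda_hat: float
    fit_range: tuple[float, float]
    d_bar: dict = field(default_factory=dict)     # averaged D2, D4, D6
    flags: list = field(default_factory=list)

    @property
    def jumps_present(self) -> bool:
        return np.isfinite(self.s_hat) and np.isfinite(self.lambda_hat)

    def report(self) -> str:
        lines = [
            f"a_hat={self.a_hat:.6g}",
            f"b2_hat={self.b2_hat:.6g}",
            f"s_hat={self.s_hat:.6g}",
            f"lambda_hat={self.lambda_hat:.6g}",
            f"fit_range={self.fit_range[0]:.6g}:{self.fit_range[1]:.6g}",
        ]
        for k in sorted(self.d_bar):
            lines.append(f"{k}={self.d_bar[k]:.6g}")
        lines.append("flags=" + (";".join(self.flags) if self.flags else "none"))
        return "\n".join(lines)


@dataclass
class ClassificationRecord:
    verdict: str                   # "diffusion" | "jump_diffusion"
    d4_bar: float
    d4_se: float
    d6_bar: float
    d6_se: float
    threshold: float

    def report(self) -> str:
        return "\n".join(
            [
                f"verdict={self.verdict}",
                f"d4_bar={self.d4_bar:.6g}",
                f"d4_se={self.d4_se:.6g}",
                f"d6_bar={self.d6_bar:.6g}",
                f"d6_se={self.d6_se:.6g}",
                f"threshold={self.threshold:.6g}",
            ]
        )


def _default_range(estimate: KMEstimate) -> tuple[float, float]:
    """|x| <= 2 sigma of the state distribution, from the bin occupancies."""
    c, w = estimate.bin_centers, estimate.counts
    tot = w.sum()
    if tot == 0:
        raise ValueError("empty estimate: no occupied bins")
    mu = float(np.dot(c, w) / tot)
    sd = float(np.sqrt(np.dot((c - mu) ** 2, w) / tot))
    return (mu - 2.0 * sd, mu + 2.0 * sd)


def _in_range(estimate: KMEstimate, fit_range) -> np.ndarray:
    lo, hi = fit_range
    c = estimate.bin_centers
    return (c >= lo) & (c <= hi) & ~estimate.excluded


def fit_linear_drift(estimate: KMEstimate, fit_range=None) -> float:
    """Mean-reversion strength: minus the WLS slope of D1(x) against x."""
    fit_range = fit_range if fit_range is not None else _default_range(estimate)
    sel = _in_range(estimate, fit_range)
    sel &= np.isfinite(estimate.D[0])
    if sel.sum() < 3:
        raise ValueError(
            f"need at least 3 included bins in {fit_range}, have {int(sel.sum())}"
        )
    x = estimate.bin_centers[sel]
    y = estimate.D[0][sel]
    w = estimate.counts[sel]
    slope, _ = np.polyfit(x, y, 1, w=np.sqrt(w))
    return -float(slope)


def weighted_average(estimate: KMEstimate, n: int, fit_range=None) -> float:
    """Occupancy-weighted average of D_n over the fit range."""
    fit_range = fit_range if fit_range is not None else _default_range(estimate)
    sel = _in_range(estimate, fit_range) & np.isfinite(estimate.coefficient(n))
    if not sel.any():
        raise ValueError(f"no usable bins for D{n} in {fit_range}")
    w = estimate.counts[sel]
    return float(np.dot(estimate.coefficient(n)[sel], w) / w.sum())


def recover_jump(estimate: KMEstimate, fit_range=None) -> RecoveredParams:
    """Invert the even-coefficient relations for (b^2, s, lambda).

    Requires a full-order estimate with n_max >= 6.
    """
    if estimate.n_max < 6:
        raise ValueError(f"jump recovery needs D2, D4, D6; n_max={estimate.n_max}")
    if estimate.order_m != "full":
        raise ValueError("jump recovery requires the full-order correction")
    fit_range = fit_range if fit_range is not None else _default_range(estimate)
    d2 = weighted_average(estimate, 2, fit_range)
    d4 = weighted_average(estimate, 4, fit_range)
    d6 = weighted_average(estimate, 6, fit_range)
    a_hat = fit_linear_drift(estimate, fit_range)
    flags: list[str] = []
    if d4 <= 0 or d6 <= 0:
        flags.append("jump_terms_nonpositive:jump_inference_suppressed")
        s_hat = float("nan")
        lam_hat = float("nan")
        b2_hat = 2.0 * d2
    else:
        s_hat = 6.0 * d6 / d4
        lam_hat = 8.0 * d4 / s_hat**2
        b2_hat = 2.0 * d2 - s_hat * lam_hat
        if b2_hat < 0:
            flags.append("negative_b2:diffusion_smaller_than_jump_activity")
    return RecoveredParams(
        a_hat=a_hat,
        b2_hat=b2_hat,
        s_hat=s_hat,
        lambda_hat=lam_hat,
        fit_range=tuple(fit_range),
        d_bar={"D2_bar": d2, "D4_bar": d4, "D6_bar": d6},
        flags=flags,
    )


def dbar_standard_error(
    series: TimeSeries,
    n: int = 4,
    fit_range=None,
    n_max: int = 6,
    lag: int = 1,
    binning: BinningConfig | None = None,
    method: str = "batch",
    n_batches: int = 20,
    n_boot: int = 200,
    block_len: int | None = None,
    seed: int = 0,
) -> float:
    """Standard error of the averaged full-order D_n.

    method="batch" (default): split the series into n_batches contiguous
    segments, run the full pipeline per segment, and take the standard error
    of the segment means.  method="block_bootstrap": moving-block bootstrap
    of (state, increment) pairs with n_boot replicates.
    """
    values = series.values
    binning = binning or BinningConfig()
    if binning.range is None:
        # freeze one common grid so segment estimates are comparable
        edges = binning.edges(values[:-lag])
        binning = BinningConfig(
            bins=binning.bins,
            range=(float(edges[0]), float(edges[-1])),
            width_sigmas=binning.width_sigmas,
            min_count=max(1, binning.min_count // n_batches),
        )

    def dbar(ts: TimeSeries) -> float:
        table = conditional_moments(ts, n_max=n_max, lag=lag, binning=binning)
        est = km_coefficients(table, "full")
        return weighted_average(est, n, fit_range)

    if method == "batch":
        seg = values.size // n_batches
        if seg <= lag + 1:
            raise ValueError("series too short for the requested batch count")
        means = []
        for i in range(n_batches):
            chunk = values[i * seg : (i + 1) * seg]
            means.append(dbar(TimeSeries(chunk, series.dt)))
        means = np.asarray(means)
        return float(np.std(means, ddof=1) / np.sqrt(n_batches))
    if method == "block_bootstrap":
        rng = np.random.default_rng(seed)
        x = values[:-lag]
        dx = values[lag:] - x
        m = x.size
        if block_len is None:
            block_len = max(1, min(m // 50, 200))
        n_blocks = int(np.ceil(m / block_len))
        reps = []
        for _ in range(n_boot):
            starts = rng.integers(0, m - block_len + 1, size=n_blocks)
            take = (starts[:, None] + np.arange(block_len)[None, :]).ravel()[:m]
            xb, dxb = x[take], dx[take]
            reps.append(_dbar_pairs(xb, dxb, series.dt * lag, n_max, binning, n, fit_range))
        return float(np.std(np.asarray(reps), ddof=1))
    raise ValueError(f"unknown method {method!r}")


def _dbar_pairs(x, dx, tau, n_max, binning, n, fit_range) -> float:
    """Average full-order D_n from explicit (state, increment) pairs."""
    edges = binning.edges(x)
    n_bins = edges.size - 1
    idx = np.digitize(x, edges) - 1
    ok = (idx >= 0) & (idx < n_bins) & (x < edges[-1])
    idx, dxo = idx[ok], dx[ok]
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    nz = counts > 0
    moments = np.full((n_max, n_bins), np.nan)
    power = np.ones_like(dxo)
    for k in range(1, n_max + 1):
        power = power * dxo
        sums = np.bincount(idx, weights=power, minlength=n_bins)
        moments[k - 1, nz] = sums[nz] / counts[nz]
    from .algebra import invert_numeric

    D = np.vstack(invert_numeric(list(moments), tau, "full"))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if fit_range is None:
        mu = float(np.dot(centers, counts) / counts.sum())
        sd = float(np.sqrt(np.dot((centers - mu) ** 2, counts) / counts.sum()))
        fit_range = (mu - 2 * sd, mu + 2 * sd)
    sel = (
        (centers >= fit_range[0])
        & (centers <= fit_range[1])
        & (counts >= binning.min_count)
        & np.isfinite(D[n - 1])
    )
    w = counts[sel]
    return float(np.dot(D[n - 1][sel], w) / w.sum())


def classify(
    estimate: KMEstimate,
    fit_range=None,
    threshold: float = 3.0,
    se: float | None = None,
    series: TimeSeries | None = None,
    **se_kwargs,
) -> ClassificationRecord:
    """Diffusion vs jump-diffusion from the averaged D4 and its error.

    The verdict is "jump_diffusion" when the averaged full-order D4 exceeds
    ``threshold`` times its standard error, else "diffusion".  The error is
    either supplied (``se``), or computed from ``series`` by batch means.
    """
    d4 = weighted_average(estimate, 4, fit_range)
    d6 = weighted_average(estimate, 6, fit_range) if estimate.n_max >= 6 else float("nan")
    if se is None:
        if series is None:
            raise ValueError("classify needs either se= or series= to obtain errors")
        se = dbar_standard_error(series, n=4, fit_range=fit_range, **se_kwargs)
    d6_se = float("nan")
    verdict = "jump_diffusion" if d4 > threshold * se else "diffusion"
    return ClassificationRecord(verdict, d4, se, d6, d6_se, threshold)
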