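"""Non-parametric conditional moments and finite-time-corrected KM coefficients.

The empirical n-th conditional moment at lag ell is the per-bin average of
(X_{t+ell} - X_t)^n over all t whose X_t falls in the bin; tau = ell * dt.
KM coefficients follow by the exact Bell inversion of the moment/coefficient
polynomial at any truncation order: order 1 is the naive M_n/(n! tau),
order n ("full") the complete finite-time correction.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .algebra import invert_numeric
from .simulate import TimeSeries

__all__ = [
    "BinningConfig",
    "ConditionalMomentTable",
    "KMEstimate",
    "conditional_moments",
    "km_coefficients",
    "write_table",
    "read_table",
]

DEFAULT_MIN_COUNT = 100


@dataclass(frozen=True)
class BinningConfig:
    """Equal-width binning over an explicit or data-driven state range.

    With range=None the bins span mean +/- width_sigmas standard deviations
    of the state distribution.
    """

    bins: int = 30
    range: tuple[float, float] | None = None
    width_sigmas: float = 4.0
    min_count: int = DEFAULT_MIN_COUNT

    def edges(self, x: np.ndarray) -> np.ndarray:
        if self.range is not None:
            lo, hi = self.range
        else:
            mu, sd = float(np.mean(x)), float(np.std(x))
            if sd == 0.0:
                # degenerate (constant) state: one unit-wide window
                return np.linspace(mu - 0.5, mu + 0.5, self.bins + 1)
            lo, hi = mu - self.width_sigmas * sd, mu + self.width_sigmas * sd
        if not hi > lo:
            raise ValueError(f"empty bin range [{lo}, {hi})")
        return np.linspace(lo, hi, self.bins + 1)


@dataclass
class ConditionalMomentTable:
    """Per-bin empirical conditional moments M_1..M_{n_max} with counts."""

    bin_edges: np.ndarray          # length n_bins + 1; bins are [lo, hi)
    counts: np.ndarray             # transition samples per bin
    moments: np.ndarray            # shape (n_max, n_bins)
    tau: float
    lag: int
    dt: float
    n_max: int
    estimator_kind: str = "histogram"
    binning: BinningConfig = field(default_factory=BinningConfig)
    meta: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def excluded(self) -> np.ndarray:
        """Bins too sparsely populated for reliable high-order moments."""
        return self.counts < self.binning.min_count


@dataclass
class KMEstimate:
    """Finite-time-corrected KM coefficients D_1..D_{n_max} per bin."""

    bin_edges: np.ndarray
    counts: np.ndarray
    D: np.ndarray                  # shape (n_max, n_bins)
    tau: float
    order_m: int | str             # 1, 2, ... or "full"
    dt: float
    n_max: int
    excluded: np.ndarray
    negative_even: np.ndarray      # warning flag: D2 or D4 < 0 in a bin
    meta: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def coefficient(self, n: int) -> np.ndarray:
        if not 1 <= n <= self.n_max:
            raise ValueError(f"order {n} outside 1..{self.n_max}")
        return self.D[n - 1]


def conditional_moments(
    series: TimeSeries,
    n_max: int = 6,
    lag: int = 1,
    binning: BinningConfig | None = None,
    estimator: str = "histogram",
    bandwidth: float | None = None,
) -> ConditionalMomentTable:
    """Estimate per-bin conditional moments M_1..M_{n_max} at lag*dt.

    estimator="histogram" averages increments within half-open bins;
    estimator="kernel" uses a Nadaraya-Watson estimator with an Epanechnikov
    kernel evaluated at the bin centers (Silverman's rule bandwidth unless
    given).
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    if not isinstance(lag, int) or lag < 1:
        raise ValueError(f"lag must be a positive integer, got {lag!r}")
    values = series.values
    if values.size <= lag:
        raise ValueError(f"series of length {values.size} too short for lag {lag}")
    if estimator not in ("histogram", "kernel"):
        raise ValueError(f"unknown estimator {estimator!r}")
    binning = binning or BinningConfig()

    x = values[:-lag]
    dx = values[lag:] - x
    edges = binning.edges(x)
    n_bins = edges.size - 1
    moments = np.full((n_max, n_bins), np.nan)

    if estimator == "histogram":
        idx = np.digitize(x, edges) - 1          # [lo, hi) half-open bins
        ok = (idx >= 0) & (idx < n_bins) & (x < edges[-1])
        idx, dxo = idx[ok], dx[ok]
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        nz = counts > 0
        power = np.ones_like(dxo)
        for n in range(1, n_max + 1):
            power = power * dxo
            sums = np.bincount(idx, weights=power, minlength=n_bins)
            moments[n - 1, nz] = sums[nz] / counts[nz]
    else:
        h = bandwidth if bandwidth is not None else _silverman(x)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.zeros(n_bins)
        for i, c in enumerate(centers):
            u = (x - c) / h
            w = np.maximum(0.0, 1.0 - u * u)      # Epanechnikov, unnormalised
            sw = w.sum()
            counts[i] = float(np.count_nonzero(w))
            if sw > 0:
                dpow = np.ones_like(dx)
                for n in range(1, n_max + 1):
                    dpow = dpow * dx
                    moments[n - 1, i] = float(np.dot(w, dpow) / sw)

    return ConditionalMomentTable(
        bin_edges=edges,
        counts=counts,
        moments=moments,
        tau=lag * series.dt,
        lag=lag,
        dt=series.dt,
        n_max=n_max,
        estimator_kind=estimator,
        binning=binning,
        meta=dict(series.meta),
    )


def _silverman(x: np.ndarray) -> float:
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * x.size ** (-0.2)


def km_coefficients(table: ConditionalMomentTable, order_m: int | str = "full") -> KMEstimate:
    """Invert the moment table bin-wise into KM coefficients.

    order_m=1 is the naive estimator D_n = M_n/(n! tau); order_m="full"
    applies the complete Bell inversion (order n for each D_n).  D_1 is
    identical at every order: the drift needs no finite-time correction.
    """
    if order_m != "full":
        if not isinstance(order_m, int) or order_m < 1:
            raise ValueError(f"order_m must be 'full' or a positive integer, got {order_m!r}")
        if order_m > table.n_max:
            raise ValueError(
                f"order_m={order_m} exceeds available moments (n_max={table.n_max})"
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN in excluded bins
        D = np.vstack(invert_numeric(list(table.moments), table.tau, order_m))

    neg = np.zeros(D.shape[1], dtype=bool)
    for n in (2, 4):
        if n <= table.n_max:
            with np.errstate(invalid="ignore"):
                neg |= np.nan_to_num(D[n - 1], nan=0.0) < 0
    neg &= ~table.excluded
    if neg.any():
        warnings.warn(
            f"negative D2/D4 in {int(neg.sum())} bin(s); reported as-is "
            "(sampling noise, not clipped)",
            stacklevel=2,
        )
    return KMEstimate(
        bin_edges=table.bin_edges.copy(),
        counts=table.counts.copy(),
        D=D,
        tau=table.tau,
        order_m=order_m,
        dt=table.dt,
        n_max=table.n_max,
        excluded=table.excluded.copy(),
        negative_even=neg,
        meta=dict(table.meta),
    )


# --------------------------------------------------------------------------
# delimited-text serialisation (tab-separated, '#' headers)
# --------------------------------------------------------------------------

def _g(v: float) -> str:
    return format(v, ".17g")


def write_table(obj: ConditionalMomentTable | KMEstimate, path) -> None:
    """Lossless TSV round trip; excluded bins carry a flag, never dropped."""
    is_km = isinstance(obj, KMEstimate)
    buf = io.StringIO()
    buf.write(f"# kind={'km' if is_km else 'moments'}\n")
    buf.write(f"# dt={obj.dt!r}\n")
    buf.write(f"# tau={obj.tau!r}\n")
    if not is_km:
        buf.write(f"# lag={obj.lag}\n")
        buf.write(f"# estimator_kind={obj.estimator_kind}\n")
        b = obj.binning
        rng = "auto" if b.range is None else f"{b.range[0]!r}:{b.range[1]!r}"
        buf.write(
            f"# binning=bins={b.bins},range={rng},"
            f"width_sigmas={b.width_sigmas!r},min_count={b.min_count}\n"
        )
    else:
        buf.write(f"# order_m={obj.order_m}\n")
    buf.write(f"# n_max={obj.n_max}\n")
    sym = "D" if is_km else "M"
    cols = ["bin_lo", "bin_hi", "center", "count", "excluded"] + [
        f"{sym}{n}" for n in range(1, obj.n_max + 1)
    ]
    buf.write("# columns=" + "\t".join(cols) + "\n")
    data = obj.D if is_km else obj.moments
    excl = obj.excluded
    centers = obj.bin_centers
    for i in range(obj.bin_edges.size - 1):
        row = [
            _g(obj.bin_edges[i]),
            _g(obj.bin_edges[i + 1]),
            _g(centers[i]),
            str(int(obj.counts[i])),
            str(int(excl[i])),
        ] + [_g(data[n, i]) for n in range(obj.n_max)]
        buf.write("\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_table(path) -> ConditionalMomentTable | KMEstimate:
    headers: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                headers[key.strip()] = val
            else:
                rows.append(line.split("\t"))
    for req in ("kind", "dt", "tau", "n_max"):
        if req not in headers:
            raise ValueError(f"table missing required header {req!r}")
    n_max = int(headers["n_max"])
    dt = float(headers["dt"])
    tau = float(headers["tau"])
    edges = np.array([float(r[0]) for r in rows] + [float(rows[-1][1])])
    counts = np.array([float(r[3]) for r in rows])
    excl = np.array([bool(int(r[4])) for r in rows])
    data = np.array(
        [[float(r[5 + n]) for r in rows] for n in range(n_max)]
    )
    if headers["kind"] == "moments":
        binning = _parse_binning(headers.get("binning", ""))
        table = ConditionalMomentTable(
            bin_edges=edges,
            counts=counts,
            moments=data,
            tau=tau,
            lag=int(headers.get("lag", round(tau / dt))),
            dt=dt,
            n_max=n_max,
            estimator_kind=headers.get("estimator_kind", "histogram"),
            binning=binning,
        )
        return table
    order_raw = headers.get("order_m", "full")
    order_m: int | str = order_raw if order_raw == "full" else int(order_raw)
    return KMEstimate(
        bin_edges=edges,
        counts=counts,
        D=data,
        tau=tau,
        order_m=order_m,
        dt=dt,
        n_max=n_max,
        excluded=excl,
        negative_even=np.zeros(len(rows), dtype=bool),
    )


def _parse_binning(text: str) -> BinningConfig:
    cfg: dict = {}
    for part in text.split(","):
        if "=" not in part:
            continue
        key, _, val = part.partition("=")
        cfg[key.strip()] = val.strip()
    bins = int(cfg.get("bins", 30))
    rng = cfg.get("range", "auto")
    if rng == "auto":
        range_ = None
    else:
        lo, _, hi = rng.partition(":")
        range_ = (float(lo), float(hi))
    return BinningConfig(
        bins=bins,
        range=range_,
        width_sigmas=float(cfg.get("width_sigmas", 4.0)),
        min_count=int(cfg.get("min_count", DEFAULT_MIN_COUNT)),
    )
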