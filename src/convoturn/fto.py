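"""Floor-transfer-offset distributions: fitting, sampling, transforms, overlap.

FTO collections are characterised by their median and interquartile range,
and modelled with the logistic distribution, whose location ``mu`` equals
its median and whose scale ``sigma`` sets the spread. Two reference
parameterisations ship with the package: turn timing of normal-hearing
interlocutors conversing in quiet (NHQ: mu = 139.8 ms, sigma = 239.3 ms)
and of hearing-impaired interlocutors conversing in babble noise
(HIN: mu = 454.7 ms, sigma = 382.5 ms). Two constant-FTO schemes use
190 ms (the empirical NHQ median) and 50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "LogisticParams",
    "FTOSummary",
    "NHQ_LOGISTIC",
    "HIN_LOGISTIC",
    "CONNHQ_FTO_MS",
    "CONLOW_FTO_MS",
    "fit_logistic",
    "sample_ftos",
    "transform_to_distribution",
    "overlapping_index",
    "summarize",
]


@dataclass(frozen=True)
class LogisticParams:
    """Location/scale (mu, sigma) of a logistic FTO distribution, in ms."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def frozen(self) -> stats.rv_continuous:
        """The corresponding frozen scipy distribution."""
        return stats.logistic(loc=self.mu, scale=self.sigma)


class FTOSummary(NamedTuple):
    """Median and interquartile range (ms) of an FTO collection."""

    median: float
    iqr: float
    n: int


#: Fitted logistic FTO distribution of normal-hearing interlocutors in quiet.
NHQ_LOGISTIC = LogisticParams(mu=139.8, sigma=239.3)
#: Fitted logistic FTO distribution of hearing-impaired interlocutors in noise.
HIN_LOGISTIC = LogisticParams(mu=454.7, sigma=382.5)
#: Constant FTO of the conNHQ scheme: the empirical NHQ median, ms.
CONNHQ_FTO_MS = 190.0
#: Constant FTO of the conLow scheme, ms.
CONLOW_FTO_MS = 50.0


def fit_logistic(
    ftos, method: str = "mle", hist_bin_width_ms: float = 50.0
) -> LogisticParams:
    """Fit a logistic distribution to FTO values (ms).

    ``method="mle"`` (default) maximises the likelihood on the raw values.
    ``method="histogram"`` least-squares fits the logistic density to a
    fixed-bin-width histogram; both agree closely on clean logistic data.

    Requires at least 10 finite values with non-zero spread.
    """
    x = np.asarray(ftos, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >= 10 finite FTO values to fit, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("FTO values have zero variance; logistic fit undefined")
    if method == "mle":
        loc, scale = stats.logistic.fit(x)
        return LogisticParams(mu=float(loc), sigma=float(scale))
    if method == "histogram":
        lo = np.floor(x.min() / hist_bin_width_ms) * hist_bin_width_ms
        hi = np.ceil(x.max() / hist_bin_width_ms) * hist_bin_width_ms
        edges = np.arange(lo, hi + hist_bin_width_ms, hist_bin_width_ms)
        dens, edges = np.histogram(x, bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        p0 = (np.median(x), np.std(x) * np.sqrt(3) / np.pi)
        popt, _ = optimize.curve_fit(
            lambda t, mu, sig: stats.logistic.pdf(t, loc=mu, scale=sig),
            centers,
            dens,
            p0=p0,
        )
        return LogisticParams(mu=float(popt[0]), sigma=float(abs(popt[1])))
    raise ValueError(f"unknown fit method {method!r}")


def sample_ftos(
    params: LogisticParams, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. logistic FTO values via the inverse CDF.

    Uses ``x = mu + sigma * ln(u / (1 - u))`` with uniform ``u``; two calls
    with the same seed return identical sequences.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(size=n)
    return params.mu + params.sigma * np.log(u / (1.0 - u))


def transform_to_distribution(
    values, from_params: LogisticParams, to_params: LogisticParams
) -> np.ndarray:
    """Scale and shift values from one logistic distribution to another.

    ``x' = to.mu + (to.sigma / from.sigma) * (x - from.mu)``; order-preserving
    and exactly invertible by the reverse transform. Because the logistic
    family is closed under affine maps, draws from ``from_params`` become
    draws from ``to_params``.
    """
    x = np.asarray(values, dtype=float)
    return to_params.mu + (to_params.sigma / from_params.sigma) * (x - from_params.mu)


def overlapping_index(p1: LogisticParams, p2: LogisticParams) -> float:
    """Overlap coefficient of two logistic densities, in [0, 1].

    Computes ``eta = integral of min(f1, f2)`` by adaptive quadrature split
    at the density crossing points, over the union of the two distributions'
    mu +/- 12 sigma spans. 1 means identical distributions, 0 disjoint.
    """
    lo = min(p1.mu - 12 * p1.sigma, p2.mu - 12 * p2.sigma)
    hi = max(p1.mu + 12 * p1.sigma, p2.mu + 12 * p2.sigma)
    f1, f2 = p1.frozen().pdf, p2.frozen().pdf

    def fmin(x):
        return np.minimum(f1(x), f2(x))

    # locate crossings of the two densities on a coarse grid for quad split points
    grid = np.linspace(lo, hi, 4097)
    diff = f1(grid) - f2(grid)
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    points = [0.5 * (grid[i] + grid[i + 1]) for i in sign_change]
    val, err = integrate.quad(fmin, lo, hi, points=points or None, limit=200, epsabs=1e-6)
    if err > 1e-4:
        raise RuntimeError(f"overlap integration error {err:g} exceeds 1e-4")
    return float(min(val, 1.0))


def summarize(ftos) -> FTOSummary:
    """Median and IQR (linear-interpolation quantiles) of FTO values in ms."""
    x = np.asarray(ftos, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("cannot summarize an empty FTO collection")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return FTOSummary(median=float(med), iqr=float(q3 - q1), n=int(x.size))
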