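"""Intensity histograms and univariate Gaussian mixture models fitted by EM.

The mixture density over image intensity x is

    p(x) = sum_l pi_l * N(x; mu_l, sigma2_l),   sum_l pi_l = 1,  0 <= pi_l <= 1,

fitted by expectation-maximization on (optionally weighted) intensity
samples.  Histogram bin centers with counts as weights enter every sum as
multiplicities, so fitting a histogram is exact rather than an approximate
resampling of it.

Components are kept in canonical order (ascending mean) so that "darkest"
and "brightest" component labels are stable across runs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "SampleSet",
    "Histogram",
    "GaussianComponent",
    "GMMParams",
    "EMConfig",
    "EMTrace",
    "build_histogram",
    "gaussian_pdf",
    "log_gaussian_pdf",
    "mixture_density",
    "mixture_log_density",
    "e_step_responsibilities",
    "m_step_update",
    "log_likelihood",
    "q_function",
    "fit_gmm_em",
    "select_components",
    "HistogramGMM",
]

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSet:
    """Weighted intensity samples x_1..x_M with nonnegative multiplicities.

    ``M`` is the total effective sample count, i.e. the sum of the weights.
    """

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        if self.weights is None:
            weights = np.ones_like(values)
        else:
            weights = np.asarray(self.weights, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("SampleSet requires at least one sample")
        if weights.shape != values.shape:
            raise ValueError("values and weights must have identical shapes")
        if not np.all(np.isfinite(values)):
            raise ValueError("sample values must be finite")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        if weights.sum() <= 0:
            raise ValueError("total weight must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def from_values(cls, values, weights=None) -> "SampleSet":
        values = np.asarray(values, dtype=float).ravel()
        if weights is None:
            weights = np.ones_like(values)
        return cls(values=values, weights=weights)

    @property
    def M(self) -> float:
        """Total effective sample count (sum of weights)."""
        return float(self.weights.sum())

    def n_distinct(self) -> int:
        return int(np.unique(self.values[self.weights > 0]).size)


@dataclass(frozen=True)
class Histogram:
    """Binned intensity counts.

    Bins are half-open ``[lo, hi)`` except the last, which is closed, so a
    pixel equal to the upper range limit lands in the last bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float).ravel()
        counts = np.asarray(self.counts, dtype=np.int64).ravel()
        if edges.size != counts.size + 1:
            raise ValueError("need n_bins + 1 bin edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_sample_set(self) -> SampleSet:
        """Bin centers as values, counts as weights (nonempty bins only)."""
        keep = self.counts > 0
        return SampleSet(values=self.bin_centers[keep],
                         weights=self.counts[keep].astype(float))

    def to_csv(self, path) -> None:
        """Two-column CSV ``bin_center,count``."""
        arr = np.column_stack([self.bin_centers, self.counts])
        np.savetxt(path, arr, fmt=["%.10g", "%d"], delimiter=",",
                   header="bin_center,count", comments="")


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: weight pi, mean mu, variance sigma2."""

    pi: float
    mu: float
    sigma2: float

    def __post_init__(self):
        if not (0.0 <= self.pi <= 1.0 + 1e-12):
            raise ValueError(f"mixing coefficient out of [0, 1]: {self.pi}")
        if self.sigma2 <= 0:
            raise ValueError(f"variance must be positive: {self.sigma2}")


@dataclass(frozen=True)
class GMMParams:
    """Ordered component list; canonical order is ascending mean."""

    components: tuple

    def __post_init__(self):
        comps = tuple(self.components)
        if len(comps) < 1:
            raise ValueError("need at least one component")
        total = sum(c.pi for c in comps)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mixing coefficients sum to {total}, not 1")
        object.__setattr__(self, "components", comps)

    @classmethod
    def from_arrays(cls, pis, mus, sigma2s) -> "GMMParams":
        comps = tuple(
            GaussianComponent(pi=float(p), mu=float(m), sigma2=float(s))
            for p, m, s in zip(pis, mus, sigma2s, strict=True)
        )
        return cls(components=comps)

    @property
    def L(self) -> int:
        return len(self.components)

    @property
    def pis(self) -> np.ndarray:
        return np.array([c.pi for c in self.components])

    @property
    def mus(self) -> np.ndarray:
        return np.array([c.mu for c in self.components])

    @property
    def sigma2s(self) -> np.ndarray:
        return np.array([c.sigma2 for c in self.components])

    def sorted_by_mean(self) -> "GMMParams":
        order = np.argsort(self.mus, kind="stable")
        return GMMParams(components=tuple(self.components[i] for i in order))

    def to_json(self, path=None) -> str:
        payload = {"components": [
            {"pi": c.pi, "mu": c.mu, "sigma2": c.sigma2}
            for c in self.components
        ]}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "GMMParams":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls.from_arrays(
            [c["pi"] for c in payload["components"]],
            [c["mu"] for c in payload["components"]],
            [c["sigma2"] for c in payload["components"]],
        )


@dataclass(frozen=True)
class EMConfig:
    """Knobs of the EM fit.

    ``tol`` is the relative log-likelihood change below which iteration
    stops; ``sigma2_floor`` guards against singular collapse onto a single
    sample.  ``sigma2_floor=None`` resolves to ``1e-6 * (data range)**2``.
    """

    max_iter: int = 500
    tol: float = 1e-6
    sigma2_floor: float | None = None
    seed: int = 0
    init_method: str = "kmeans"

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.sigma2_floor is not None and self.sigma2_floor <= 0:
            raise ValueError("sigma2_floor must be positive")
        if self.init_method not in ("quantile", "kmeans", "random"):
            raise ValueError(f"unknown init_method: {self.init_method}")


@dataclass
class EMTrace:
    """Per-iteration record of an EM run.

    The log-likelihood sequence is nondecreasing up to numerical slack;
    tests assert this on every fit.
    """

    log_likelihood_per_iter: list = field(default_factory=list)
    q_values_per_iter: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_histogram(image, n_bins: int = 256, value_range=None) -> Histogram:
    """Histogram the finite pixels of a 2-D/3-D image.

    The default range is [min, max] of the finite values; the last bin is
    closed so the maximum falls inside it.  Counts always sum to the number
    of finite pixels.
    """
    data = np.asarray(image, dtype=float).ravel()
    data = data[np.isfinite(data)]
    if data.size == 0:
        raise ValueError("image contains no finite values")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if value_range is None:
        lo, hi = float(data.min()), float(data.max())
        if lo == hi:  # constant image: give the single value a real-width bin
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = float(value_range[0]), float(value_range[1])
        if not lo < hi:
            raise ValueError(f"invalid range: [{lo}, {hi})")
        data = data[(data >= lo) & (data <= hi)]
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts)


def log_gaussian_pdf(x, mu, sigma2):
    """Log of the univariate normal density."""
    if np.any(np.asarray(sigma2) <= 0):
        raise ValueError("sigma2 must be positive")
    x = np.asarray(x, dtype=float)
    return -0.5 * (_LOG_2PI + np.log(sigma2) + (x - mu) ** 2 / sigma2)


def gaussian_pdf(x, mu, sigma2):
    """Univariate normal density N(x; mu, sigma2)."""
    return np.exp(log_gaussian_pdf(x, mu, sigma2))


def _component_log_densities(x, params: GMMParams) -> np.ndarray:
    """log(pi_l) + log N(x_i; mu_l, sigma2_l), shape (n, L)."""
    x = np.asarray(x, dtype=float).ravel()[:, None]
    with np.errstate(divide="ignore"):
        log_pis = np.log(params.pis)[None, :]
    return log_pis + log_gaussian_pdf(x, params.mus[None, :],
                                      params.sigma2s[None, :])


def mixture_log_density(x, params: GMMParams):
    """log p(x) under the mixture, via log-sum-exp over components."""
    out = logsumexp(_component_log_densities(x, params), axis=1)
    return out if np.ndim(x) else float(out[0])


def mixture_density(x, params: GMMParams):
    """Mixture density p(x) = sum_l pi_l N(x; mu_l, sigma2_l)."""
    return np.exp(mixture_log_density(x, params))


def e_step_responsibilities(samples: SampleSet, params: GMMParams) -> np.ndarray:
    """Posterior component probabilities r[i, l] = p(l | x_i).

    Computed in log space so that simultaneous underflow of all component
    densities at an outlying sample never divides by zero.
    """
    log_joint = _component_log_densities(samples.values, params)
    log_norm = logsumexp(log_joint, axis=1, keepdims=True)
    return np.exp(log_joint - log_norm)


def m_step_update(samples: SampleSet, resp: np.ndarray,
                  sigma2_floor: float = 1e-12,
                  prev_params: GMMParams | None = None) -> GMMParams:
    """Maximum-likelihood parameter update given responsibilities.

    pi_l    <- sum_i w_i r_il / M
    mu_l    <- sum_i w_i r_il x_i / sum_i w_i r_il
    sigma2_l <- sum_i w_i r_il (x_i - mu_l)^2 / sum_i w_i r_il, floored.

    A component whose effective count vanishes is reseeded at the sample
    the current mixture explains worst instead of crashing.
    """
    resp = np.asarray(resp, dtype=float)
    x, w = samples.values, samples.weights
    if resp.shape[0] != x.size:
        raise ValueError("responsibility rows must match sample count")
    M = samples.M
    wr = resp * w[:, None]                      # (n, L)
    eff = wr.sum(axis=0)                        # effective counts N_l
    L = resp.shape[1]

    pis = np.empty(L)
    mus = np.empty(L)
    sig2 = np.empty(L)
    pooled_var = max(float(np.average((x - np.average(x, weights=w)) ** 2,
                                      weights=w)), sigma2_floor)
    for l in range(L):
        if eff[l] <= M * 1e-12:
            # degenerate component: reseed where the mixture density is lowest
            if prev_params is not None:
                scores = mixture_log_density(x, prev_params)
            else:
                scores = logsumexp(np.log(np.maximum(resp, 1e-300)), axis=1)
            i = int(np.argmin(scores))
            logger.warning("reseeding empty component %d at x=%.4g", l, x[i])
            pis[l] = 1.0 / max(M, 1.0)
            mus[l] = x[i]
            sig2[l] = pooled_var
        else:
            pis[l] = eff[l] / M
            mus[l] = float(wr[:, l] @ x) / eff[l]
            sig2[l] = float(wr[:, l] @ (x - mus[l]) ** 2) / eff[l]
    pis = pis / pis.sum()
    sig2 = np.maximum(sig2, sigma2_floor)
    return GMMParams.from_arrays(pis, mus, sig2)


def log_likelihood(samples: SampleSet, params: GMMParams) -> float:
    """Weighted data log-likelihood sum_i w_i log p(x_i)."""
    return float(samples.weights @ mixture_log_density(samples.values, params))


def q_function(samples: SampleSet, params_new: GMMParams,
               resp_old: np.ndarray) -> float:
    """EM surrogate objective (complete-data expected log-likelihood).

    Q = sum_l sum_i w_i r_il [ log pi_l + log N(x_i; mu_l, sigma2_l) ],
    with responsibilities held at their previous-iterate values.  The M-step
    maximizes this in the parameters.
    """
    resp_old = np.asarray(resp_old, dtype=float)
    log_joint = _component_log_densities(samples.values, params_new)
    # 0 * -inf -> 0: a dead responsibility contributes nothing
    terms = np.where(resp_old > 0, resp_old * log_joint, 0.0)
    return float(samples.weights @ terms.sum(axis=1))


def _resolve_floor(samples: SampleSet, config: EMConfig) -> float:
    if config.sigma2_floor is not None:
        return config.sigma2_floor
    span = float(np.ptp(samples.values))
    return 1e-6 * span**2 if span > 0 else 1e-12


def _init_params(samples: SampleSet, L: int, config: EMConfig,
                 floor: float) -> GMMParams:
    x, w = samples.values, samples.weights
    rng = np.random.default_rng(config.seed)
    if config.init_method == "quantile":
        # weighted quantiles at (l + 0.5) / L: deterministic, spread out
        order = np.argsort(x)
        cum = np.cumsum(w[order])
        cum = cum / cum[-1]
        qs = (np.arange(L) + 0.5) / L
        mus = np.interp(qs, cum, x[order])
    elif config.init_method == "kmeans":
        km = KMeans(n_clusters=L, n_init=3, random_state=config.seed)
        km.fit(x[:, None], sample_weight=w)
        mus = np.sort(km.cluster_centers_.ravel())
    else:  # random
        mus = rng.choice(x, size=L, replace=False, p=w / w.sum())
    mean = np.average(x, weights=w)
    pooled = max(float(np.average((x - mean) ** 2, weights=w)) / max(L, 1),
                 floor)
    # tiny deterministic jitter so coincident quantiles stay distinct
    mus = np.sort(np.asarray(mus, dtype=float))
    for l in range(1, L):
        if mus[l] <= mus[l - 1]:
            mus[l] = mus[l - 1] + 1e-6 * (1.0 + abs(mus[l - 1]))
    return GMMParams.from_arrays(np.full(L, 1.0 / L), mus, np.full(L, pooled))


def fit_gmm_em(data, L: int, config: EMConfig | None = None):
    """Fit an L-component mixture by EM on samples or on a histogram.

    Returns ``(params, responsibilities, trace)`` with components in
    canonical ascending-mean order.  Histogram input is converted to
    weighted samples (bin centers, counts), which makes the histogram fit
    exact rather than a resampling.
    """
    config = config or EMConfig()
    if isinstance(data, Histogram):
        samples = data.to_sample_set()
    elif isinstance(data, SampleSet):
        samples = data
    else:
        samples = SampleSet.from_values(data)
    if L < 1:
        raise ValueError("L must be >= 1")
    if L > samples.n_distinct():
        raise ValueError(
            f"L={L} exceeds the {samples.n_distinct()} distinct sample values")

    floor = _resolve_floor(samples, config)
    params = _init_params(samples, L, config, floor)
    trace = EMTrace()
    prev_ll = -np.inf
    resp = e_step_responsibilities(samples, params)
    for it in range(config.max_iter):
        params = m_step_update(samples, resp, sigma2_floor=floor,
                               prev_params=params)
        ll = log_likelihood(samples, params)
        trace.log_likelihood_per_iter.append(ll)
        trace.q_values_per_iter.append(q_function(samples, params, resp))
        trace.n_iter = it + 1
        if np.isfinite(prev_ll):
            if abs(ll - prev_ll) <= config.tol * (abs(prev_ll) + 1e-300):
                trace.converged = True
                break
        prev_ll = ll
        resp = e_step_responsibilities(samples, params)

    params = params.sorted_by_mean()
    resp = e_step_responsibilities(samples, params)
    return params, resp, trace


def select_components(samples, L_candidates, config: EMConfig | None = None):
    """Choose the component count by the Bayesian information criterion.

    BIC = -2 logL + k log M with k = 3L - 1 free parameters; ties break
    toward the smaller L.  A candidate whose fit fails is skipped with a
    warning; if every candidate fails, an error is raised.
    """
    config = config or EMConfig()
    cands = list(L_candidates)
    if not cands:
        raise ValueError("L_candidates must be nonempty")
    if isinstance(samples, Histogram):
        samples = samples.to_sample_set()
    elif not isinstance(samples, SampleSet):
        samples = SampleSet.from_values(samples)
    scores = []
    fitted = []
    for L in cands:
        try:
            params, _, _ = fit_gmm_em(samples, L, config)
            ll = log_likelihood(samples, params)
            k = 3 * L - 1
            scores.append(-2.0 * ll + k * np.log(samples.M))
            fitted.append(L)
        except Exception as exc:  # noqa: BLE001 - candidate skipped, not fatal
            warnings.warn(f"component count {L} failed to fit: {exc}",
                          stacklevel=2)
            scores.append(np.inf)
    if not fitted:
        raise RuntimeError("every candidate component count failed to fit")
    scores = np.asarray(scores)
    order = np.lexsort((cands, scores))  # smallest score, then smallest L
    return int(cands[order[0]]), list(scores)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class HistogramGMM(DensityMixin, BaseEstimator):
    """Univariate Gaussian mixture density fitted by EM.

    scikit-learn-style estimator over :func:`fit_gmm_em`.  ``X`` may be a
    1-D array of intensities or an ``(n, 1)`` column; ``sample_weight``
    carries histogram counts so fitting a binned histogram is exact.

    Parameters
    ----------
    n_components : number of Gaussian components L.
    init : 'kmeans' (seeded, deterministic default), 'quantile' or 'random'.
        Quantile placement is cheap but can merge minority classes on
        heavily imbalanced histograms; weighted k-means is robust to them.
    max_iter, tol : EM stopping rule (relative log-likelihood change).
    sigma2_floor : variance floor; None means ``1e-6 * range(X)**2``.
    random_state : seed for 'kmeans'/'random' initialization.

    Attributes
    ----------
    weights_, means_, variances_ : arrays of length ``n_components`` in
        ascending-mean order.
    params_ : the fitted :class:`GMMParams`.
    trace_ : :class:`EMTrace` with the per-iteration log-likelihood.
    n_iter_, converged_ : EM iteration count and convergence flag.
    """

    def __init__(self, n_components=2, init="kmeans", max_iter=500,
                 tol=1e-6, sigma2_floor=None, random_state=0):
        self.n_components = n_components
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.sigma2_floor = sigma2_floor
        self.random_state = random_state

    def _config(self) -> EMConfig:
        return EMConfig(max_iter=self.max_iter, tol=self.tol,
                        sigma2_floor=self.sigma2_floor,
                        seed=self.random_state, init_method=self.init)

    def fit(self, X, y=None, sample_weight=None):
        samples = SampleSet.from_values(np.asarray(X, dtype=float).ravel(),
                                        weights=sample_weight)
        params, resp, trace = fit_gmm_em(samples, self.n_components,
                                         self._config())
        self.params_ = params
        self.weights_ = params.pis
        self.means_ = params.mus
        self.variances_ = params.sigma2s
        self.trace_ = trace
        self.n_iter_ = trace.n_iter
        self.converged_ = trace.converged
        return self

    def predict_proba(self, X):
        """Posterior responsibilities, shape (n, n_components)."""
        samples = SampleSet.from_values(np.asarray(X, dtype=float).ravel())
        return e_step_responsibilities(samples, self.params_)

    def predict(self, X):
        """Hard component assignment (argmax responsibility)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X):
        return mixture_log_density(np.asarray(X, dtype=float).ravel(),
                                   self.params_)

    def score(self, X, y=None):
        """Mean log-likelihood per sample (scikit-learn convention)."""
        return float(np.mean(self.score_samples(X)))

    def bic(self, X):
        X = np.asarray(X, dtype=float).ravel()
        k = 3 * self.n_components - 1
        return -2.0 * float(self.score_samples(X).sum()) + k * np.log(X.size)
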