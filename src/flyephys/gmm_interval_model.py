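"""Second-order Gaussian-mixture model of adjacent PSP intervals.

The serial structure of a PSP train beyond its rate is captured by the joint
distribution of adjacent inter-event intervals.  Intervals are normalized by
each cell's mean event rate (making them dimensionless with mean 1),
log-transformed, paired as (log u_i, log u_{i+1}), and aggregated across
cells.  A full-covariance bivariate Gaussian mixture is fitted to the pairs
by expectation-maximization, with the component count chosen by BIC; a
22 x 22 log-binned histogram of the pairs is kept for visualization and
goodness-of-fit checks.

Surrogate, rate-matched PSP trains are generated from the fitted model by a
first-order chain: the next log-interval is drawn from the mixture's
conditional density given the current one, via rejection sampling against a
gridded envelope (an exact closed-form conditional sampler is kept alongside
as an independent oracle).  The first 200 chain draws are discarded as
burn-in, intervals are exponentiated and scaled to a target mean frequency
drawn from a beta rate model, and the resulting train is binned into 10-ms
binary signals for downstream transmission analysis.

The module follows a Model/Results split: build a
:class:`SecondOrderIntervalModel` from pair data (or from event series via
``from_event_series``), call :meth:`~SecondOrderIntervalModel.fit`, and use
the returned :class:`SecondOrderIntervalResults` for sampling, validation,
surrogate generation and reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _mixture

N_BINS = 22          # fixed histogram grid per axis
BURN_IN = 200        # chain draws discarded before the train is kept
BIN_WIDTH_S = 0.010  # width of the binary-signal bins


class GmmFitError(RuntimeError):
    """Raised when every EM restart fails."""


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PairData:
    """Rate-normalized adjacent log-interval pairs plus their 2D histogram."""

    pairs: np.ndarray
    histogram: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_cells_used: int
    n_cells_skipped: int

    @property
    def log_range_x(self) -> tuple[float, float]:
        return float(self.x_edges[0]), float(self.x_edges[-1])

    @property
    def log_range_y(self) -> tuple[float, float]:
        return float(self.y_edges[0]), float(self.y_edges[-1])


def preprocess_pairs(
    series_list,
    n_bins: int = N_BINS,
    percentile_range: tuple[float, float] = (1.0, 99.0),
    log_range_x: tuple[float, float] | None = None,
    log_range_y: tuple[float, float] | None = None,
) -> PairData:
    """Normalize, log, pair and histogram inter-event intervals.

    Each cell's intervals are multiplied by that cell's mean event rate, so a
    1-Hz and a 10-Hz cell with identical normalized structure contribute
    identical pair clouds.  Cells with fewer than three events (two intervals)
    cannot form a pair and are skipped.  The histogram grid spans the
    [1st, 99th] percentile range of the pooled log pairs per axis unless
    explicit ranges are given (different experimental conditions get their own
    ranges by default).
    """
    xs, ys = [], []
    skipped = 0
    for s in series_list:
        ivals = np.asarray(
            s.inter_event_intervals_s if hasattr(s, "inter_event_intervals_s") else s,
            dtype=float,
        )
        if ivals.size < 2:
            skipped += 1
            continue
        u = ivals / np.mean(ivals)  # x mean rate == / mean interval
        logu = np.log(u)
        xs.append(logu[:-1])
        ys.append(logu[1:])
    if not xs:
        raise ValueError("no cell contributed at least 3 events")
    pairs = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
    lo, hi = percentile_range
    rx = log_range_x or tuple(np.percentile(pairs[:, 0], [lo, hi]))
    ry = log_range_y or tuple(np.percentile(pairs[:, 1], [lo, hi]))
    hist, x_edges, y_edges = np.histogram2d(
        pairs[:, 0], pairs[:, 1], bins=n_bins, range=[rx, ry]
    )
    return PairData(
        pairs=pairs,
        histogram=hist,
        x_edges=x_edges,
        y_edges=y_edges,
        n_cells_used=len(xs),
        n_cells_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# EM


def _em_fit(x, k, rng, tol=1e-6, max_iter=500, reg=1e-6):
    """One EM run on (n, 2) data; returns (weights, means, covs, ll_path).

    Means are initialized from k distinct data points, covariances from the
    data covariance.  The per-point log-likelihood trajectory is recorded and
    must be non-decreasing (up to floating slack); a violation indicates a
    broken update and raises.  Near-singular covariances are ridged with
    ``reg`` on the diagonal.
    """
    n = x.shape[0]
    means = x[rng.choice(n, size=k, replace=False)].copy()
    base_cov = np.cov(x, rowvar=False) + reg * np.eye(2)
    covs = np.repeat(base_cov[None], k, axis=0)
    weights = np.full(k, 1.0 / k)
    ll_path = []
    prev = -np.inf
    ridged_prev = False
    prev_params = (weights.copy(), means.copy(), covs.copy())
    for _ in range(max_iter):
        log_comp = _mixture.component_logpdf(x, means, covs) + np.log(weights)
        log_norm = _mixture._logsumexp(log_comp, axis=1)
        ll = float(np.mean(log_norm))
        if ll < prev - 1e-9 * max(1.0, abs(prev)):
            if ridged_prev:
                # a regularized M-step is not an exact EM step; a tiny drop
                # after ridging means we are on the singular boundary — stop
                # at the previous (monotone) iterate
                return (*prev_params, np.asarray(ll_path))
            raise GmmFitError(f"EM log-likelihood decreased: {prev} -> {ll}")
        ll_path.append(ll)
        prev_params = (weights.copy(), means.copy(), covs.copy())
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise GmmFitError("a component collapsed to zero responsibility")
        weights = nk / n
        means = resp.T @ x / nk[:, None]
        ridged_prev = False
        for j in range(k):
            d = x - means[j]
            c = (resp[:, j, None] * d).T @ d / nk[j]
            # ridge only when near-singular, so regular steps are exact EM
            if np.linalg.eigvalsh(c)[0] < reg:
                c = c + reg * np.eye(2)
                ridged_prev = True
            if np.linalg.eigvalsh(c)[0] <= 0:
                raise GmmFitError("singular covariance in M-step")
            covs[j] = c
        if ll - prev < tol:
            prev = ll
            break
        prev = ll
    return weights, means, covs, np.asarray(ll_path)


def fit_gmm(
    pairs,
    k_range=(3, 4, 5),
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """EM over continuous log pairs for each k; select k by lowest BIC.

    Returns a :class:`SecondOrderIntervalResults`.  Each k gets ``n_restarts``
    random restarts, keeping the best log-likelihood; restarts that hit a
    singular covariance are retried with diagonal regularization already
    built into the updates, and a k for which all restarts fail raises
    GmmFitError.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    k_range = tuple(int(k) for k in k_range)
    if x.shape[0] < 10 * max(k_range):
        raise ValueError("need at least 10 pairs per component of the largest k")
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    fits = {}
    bics = {}
    for k in k_range:
        best = None
        errors = []
        for _ in range(n_restarts):
            try:
                w, mu, cov, ll_path = _em_fit(x, k, rng, tol=tol, max_iter=max_iter)
            except GmmFitError as err:
                errors.append(err)
                continue
            if best is None or ll_path[-1] > best[3][-1]:
                best = (w, mu, cov, ll_path)
        if best is None:
            raise GmmFitError(f"all {n_restarts} restarts failed for k={k}: {errors}")
        fits[k] = best
        n_params = 6 * k - 1  # k-1 weights + 2k means + 3k covariance entries
        bics[k] = -2.0 * best[3][-1] * n + n_params * np.log(n)
    k_best = min(bics, key=bics.get)
    w, mu, cov, ll_path = fits[k_best]
    return SecondOrderIntervalResults(
        weights=w,
        means=mu,
        covariances=cov,
        n_components=k_best,
        loglik_path=ll_path,
        bic_by_k=bics,
        n_obs=n,
        log_range_x=tuple(np.percentile(x[:, 0], [1, 99])),
        log_range_y=tuple(np.percentile(x[:, 1], [1, 99])),
        training_pairs=x,
    )


# ---------------------------------------------------------------------------
# rate model


@dataclass
class BetaRateModel:
    """Beta model of the average PSP frequency.

    Frequencies are scaled into (0, 1) by ``scale_Hz`` (1.05 x the largest
    observed frequency when fitted, so the support strictly contains the
    data) and a Beta(a, b) is fitted by moment matching.  ``sample`` returns
    a frequency in Hz.
    """

    a: float
    b: float
    scale_Hz: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.scale_Hz <= 0:
            raise ValueError("beta parameters and scale must be positive")

    @classmethod
    def fit(cls, frequencies_Hz, scale_Hz: float | None = None) -> "BetaRateModel":
        f = np.asarray(frequencies_Hz, dtype=float)
        if f.size < 2 or np.any(f <= 0):
            raise ValueError("need >= 2 positive frequencies")
        if scale_Hz is None:
            scale_Hz = 1.05 * float(f.max())
        y = f / scale_Hz
        m, v = float(np.mean(y)), float(np.var(y, ddof=1))
        if v <= 0 or v >= m * (1 - m):
            raise ValueError("frequencies incompatible with a beta fit")
        common = m * (1 - m) / v - 1.0
        return cls(a=m * common, b=(1 - m) * common, scale_Hz=scale_Hz)

    def sample(self, rng) -> float:
        return float(rng.beta(self.a, self.b) * self.scale_Hz)

    def mean_Hz(self) -> float:
        return self.a / (self.a + self.b) * self.scale_Hz


# ---------------------------------------------------------------------------
# surrogate trains


def binarize(times_s, bin_s: float = BIN_WIDTH_S, duration_s: float | None = None):
    """0/1 vector: bin i is 1 iff at least one event falls in [i, i+1) bins."""
    t = np.asarray(times_s, dtype=float)
    if duration_s is None:
        duration_s = (t.max() if t.size else 0.0) + bin_s
    n = int(np.ceil(duration_s / bin_s))
    sig = np.zeros(n, dtype=np.int8)
    idx = np.floor(t / bin_s).astype(int)
    sig[idx[(idx >= 0) & (idx < n)]] = 1
    return sig


@dataclass
class SurrogateTrain:
    """A rate-matched surrogate PSP train and its 10-ms binary signal."""

    psp_times_s: np.ndarray
    binary_signal: np.ndarray
    target_frequency_Hz: float
    n_burn_in: int
    seed: int
    bin_s: float = BIN_WIDTH_S

    def realized_frequency_Hz(self) -> float:
        return float(1.0 / np.mean(np.diff(self.psp_times_s)))


# ---------------------------------------------------------------------------
# model / results


class SecondOrderIntervalModel:
    """Gaussian-mixture model of adjacent log-interval pairs (unfitted).

    Parameters
    ----------
    pairs : (n, 2) array of adjacent log normalized intervals, e.g. from
        :func:`preprocess_pairs`.
    """

    def __init__(self, pairs):
        self.pairs = np.asarray(pairs, dtype=float)
        self.pair_data: PairData | None = None

    @classmethod
    def from_event_series(cls, series_list, **preprocess_kwargs):
        pd_ = preprocess_pairs(series_list, **preprocess_kwargs)
        model = cls(pd_.pairs)
        model.pair_data = pd_
        return model

    def fit(self, k_range=(3, 4, 5), seed: int = 0, n_restarts: int = 3, **kwargs):
        res = fit_gmm(self.pairs, k_range=k_range, seed=seed, n_restarts=n_restarts, **kwargs)
        res.pair_data = self.pair_data
        if self.pair_data is not None:
            res.log_range_x = self.pair_data.log_range_x
            res.log_range_y = self.pair_data.log_range_y
        return res


@dataclass
class SecondOrderIntervalResults:
    """Fitted second-order interval mixture: estimates, selection, simulators."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    n_components: int
    loglik_path: np.ndarray
    bic_by_k: dict
    n_obs: int
    log_range_x: tuple[float, float]
    log_range_y: tuple[float, float]
    training_pairs: np.ndarray = field(repr=False, default=None)
    pair_data: PairData | None = field(repr=False, default=None)

    # -- densities ---------------------------------------------------------

    def joint_logpdf(self, xy):
        return _mixture.joint_logpdf(xy, self.weights, self.means, self.covariances)

    def conditional_pdf(self, y, x):
        return _mixture.conditional_pdf(y, x, self.weights, self.means, self.covariances)

    def mean_normalized_interval(self) -> float:
        """Model-implied E[u] = E[exp(log u)] (lognormal-mixture closed form)."""
        return _mixture.mean_exp_marginal(self.weights, self.means, self.covariances, axis=1)

    # -- sampling ----------------------------------------------------------

    def sample_pairs(self, n: int | None = None, seed: int = 0) -> np.ndarray:
        """iid pairs from the joint mixture; size-matched to training by default."""
        if n is None:
            n = self.n_obs
        rng = np.random.default_rng(seed)
        return _mixture.sample_joint(self.weights, self.means, self.covariances, n, rng)

    def sample_validation(self, seed: int = 0, n: int | None = None) -> dict:
        """Size-matched sample plus two-sample KS statistics on both marginals."""
        if self.training_pairs is None:
            raise ValueError("no training pairs stored on this results object")
        sample = self.sample_pairs(n=n, seed=seed)
        report = {"n": sample.shape[0], "sample": sample}
        for axis, name in ((0, "x"), (1, "y")):
            ks = stats.ks_2samp(sample[:, axis], self.training_pairs[:, axis])
            report[f"ks_{name}"] = float(ks.statistic)
            report[f"ks_{name}_pvalue"] = float(ks.pvalue)
        return report

    def proposal_range_y(self) -> tuple[float, float]:
        """Support bounds for the rejection proposal: component means +- 8 SD.

        Deliberately wider than the histogram's percentile range so no
        appreciable conditional mass is truncated by the uniform proposal.
        """
        sd = np.sqrt(self.covariances[:, 1, 1])
        return (
            float((self.means[:, 1] - 8.0 * sd).min()),
            float((self.means[:, 1] + 8.0 * sd).max()),
        )

    def sample_chain(self, n: int, seed: int = 0, method: str = "rejection", burn_in: int = BURN_IN):
        """Log-interval chain draws (post burn-in) from the conditional kernel."""
        rng = np.random.default_rng(seed)
        return _mixture.sample_chain(
            self.weights,
            self.means,
            self.covariances,
            n,
            rng,
            burn_in=burn_in,
            method=method,
            y_range=self.proposal_range_y() if method == "rejection" else None,
        )

    def simulate_train(
        self,
        rate_model: BetaRateModel,
        n_events: int,
        seed: int = 0,
        method: str = "rejection",
        duration_s: float | None = None,
    ) -> SurrogateTrain:
        """Generate a rate-matched surrogate PSP train.

        Draws a target frequency f from the beta rate model, runs the
        conditional chain (discarding the first 200 burn-in draws),
        exponentiates the log-intervals and scales them by 1/(f * m) with m
        the model-implied mean normalized interval — so the realized mean
        frequency matches f — then cumulates to event times and bins them
        into 10-ms binary signals.
        """
        if n_events < 2:
            raise ValueError("n_events must be at least 2")
        rng = np.random.default_rng(seed)
        f = rate_model.sample(rng)
        draws = _mixture.sample_chain(
            self.weights,
            self.means,
            self.covariances,
            n_events,
            rng,
            burn_in=BURN_IN,
            method=method,
            y_range=self.proposal_range_y() if method == "rejection" else None,
        )
        intervals = np.exp(draws) / (f * self.mean_normalized_interval())
        times = np.cumsum(intervals)
        return SurrogateTrain(
            psp_times_s=times,
            binary_signal=binarize(times, duration_s=duration_s),
            target_frequency_Hz=f,
            n_burn_in=BURN_IN,
            seed=seed,
        )

    # -- reporting ---------------------------------------------------------

    def histogram_chi2(self, seed: int = 0, n: int | None = None):
        """Chi-square of the training 22x22 histogram vs model bin masses."""
        if self.pair_data is None:
            raise ValueError("no histogram available; build via from_event_series")
        hist = self.pair_data.histogram
        xe, ye = self.pair_data.x_edges, self.pair_data.y_edges
        xc = (xe[:-1] + xe[1:]) / 2
        yc = (ye[:-1] + ye[1:]) / 2
        gx, gy = np.meshgrid(xc, yc, indexing="ij")
        dens = np.exp(self.joint_logpdf(np.column_stack([gx.ravel(), gy.ravel()])))
        cell = (xe[1] - xe[0]) * (ye[1] - ye[0])
        expected = dens.reshape(hist.shape) * cell
        expected = expected / expected.sum() * hist.sum()
        mask = expected > 1e-9
        chi2 = float(((hist[mask] - expected[mask]) ** 2 / expected[mask]).sum())
        return chi2, int(mask.sum())

    def summary(self) -> str:
        lines = [
            "Second-order interval mixture (EM, full covariance)",
            "=" * 55,
            f"components: {self.n_components}   observations: {self.n_obs}",
            f"final log-likelihood/pt: {self.loglik_path[-1]:.6f}  "
            f"iterations: {self.loglik_path.size}",
            "BIC by k: "
            + ", ".join(f"{k}: {v:.1f}" for k, v in sorted(self.bic_by_k.items())),
            f"log range x: [{self.log_range_x[0]:.3f}, {self.log_range_x[1]:.3f}]  "
            f"y: [{self.log_range_y[0]:.3f}, {self.log_range_y[1]:.3f}]",
            "",
            f"{'comp':>4} {'weight':>8} {'mean_x':>8} {'mean_y':>8} "
            f"{'var_x':>8} {'var_y':>8} {'cov_xy':>8}",
        ]
        for j in range(self.n_components):
            c = self.covariances[j]
            lines.append(
                f"{j:>4} {self.weights[j]:>8.4f} {self.means[j, 0]:>8.4f} "
                f"{self.means[j, 1]:>8.4f} {c[0, 0]:>8.4f} {c[1, 1]:>8.4f} {c[0, 1]:>8.4f}"
            )
        return "\n".join(lines)

    def plot_pair_histogram(self, ax=None):
        """22x22 log-binned pair histogram with component means overlaid."""
        import matplotlib.pyplot as plt

        if self.pair_data is None:
            raise ValueError("no histogram available; build via from_event_series")
        if ax is None:
            _, ax = plt.subplots()
        pd_ = self.pair_data
        ax.pcolormesh(pd_.x_edges, pd_.y_edges, pd_.histogram.T, cmap="viridis")
        ax.plot(self.means[:, 0], self.means[:, 1], "r+", markersize=10)
        ax.set_xlabel("log normalized interval i")
        ax.set_ylabel("log normalized interval i+1")
        return ax

    # -- persistence -------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "n_components": self.n_components,
            "bic_by_k": {str(k): v for k, v in self.bic_by_k.items()},
            "n_obs": self.n_obs,
            "log_range_x": list(self.log_range_x),
            "log_range_y": list(self.log_range_y),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SecondOrderIntervalResults":
        import os

        if isinstance(source, os.PathLike) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        return cls(
            weights=np.asarray(payload["weights"]),
            means=np.asarray(payload["means"]),
            covariances=np.asarray(payload["covariances"]),
            n_components=int(payload["n_components"]),
            loglik_path=np.asarray([np.nan]),
            bic_by_k={int(k): v for k, v in payload["bic_by_k"].items()},
            n_obs=int(payload["n_obs"]),
            log_range_x=tuple(payload["log_range_x"]),
            log_range_y=tuple(payload["log_range_y"]),
        )
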