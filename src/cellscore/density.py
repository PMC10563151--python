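"""Density-based initial cell scores via Bayes' rule, and network pretraining.

For a positive sample with burden y_i, the posterior probability that cell
x is pathogenic decomposes by Bayes' rule as

    s'(x) = 1 - P(x | z=0, y>0) * P(z=0 | y>0) / P(x | y>0)
          = 1 - phat_healthy(x) * (1 - y_i) / phat_sample(x),

where phat_healthy is a KDE fit on the pooled cells of all negative training
samples (healthy cells look the same in positive and negative samples, and
negatives contain only healthy cells) and phat_sample is a KDE fit on the
positive sample's own cells.  All cells of negative samples get s' = 0 by
definition.  When only binary labels are available, 1 - y_i is replaced by a
configurable fixed prior.  The ratio can exceed 1/(1-y), so s' is clipped to
[0, 1]; arithmetic stays in log-density space throughout.

The KDE uses a product-of-Gaussians kernel with a per-channel bandwidth
(Scott's rule by default) — full-covariance kernels are numerically fragile
in 10-16 channels.  When a KDE is evaluated at its own fit points (every
per-sample estimate), the evaluation is leave-one-out: each point's own
kernel otherwise inflates the sample density against the pooled healthy
density, biasing s' upward.

A feedforward network pretrained to reproduce s' (mean squared error on
cells) provides the weights phi' used to initialize end-to-end training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from . import _nn
from .cohort import Cohort, SampleRecord
from .model import ScoringNet, ScoringNetSpec


@dataclass
class ProductKDE:
    """Gaussian-product-kernel density estimate with per-channel bandwidths.

    `fit_indices`, when set, records which rows of the source event matrix
    the fit points came from (identity subsample bookkeeping used for
    leave-one-out evaluation at the KDE's own cells).
    """

    points: np.ndarray  # (m, D) fit cells
    bandwidths: np.ndarray  # (D,) positive
    fit_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.bandwidths = np.asarray(self.bandwidths, dtype=float).ravel()
        if self.points.shape[1] != self.bandwidths.size:
            raise ValueError("one bandwidth per channel required")
        if np.any(self.bandwidths <= 0) or not np.all(np.isfinite(self.bandwidths)):
            raise ValueError("bandwidths must be positive and finite")

    @property
    def n_fit(self) -> int:
        return self.points.shape[0]

    def _log_const(self) -> float:
        D = self.bandwidths.size
        return float(-np.sum(np.log(self.bandwidths)) - 0.5 * D * np.log(2.0 * np.pi))

    def _kernel_logsum(self, Xs: np.ndarray, drop_diagonal: bool) -> np.ndarray:
        """logsumexp_j -||x - p_j||^2/2 over fit points, chunked.

        Xs is already bandwidth-scaled.  Pairwise squared distances go through
        the Gram expansion (BLAS matmul) in float32 — the kernel sum is
        insensitive to the ~1e-4 absolute distance error this costs — with a
        per-row max shift so isolated points do not underflow to -inf.
        """
        P = (self.points / self.bandwidths).astype(np.float32)
        pp = np.einsum("ij,ij->i", P, P)
        Xs32 = Xs.astype(np.float32)
        xx = np.einsum("ij,ij->i", Xs32, Xs32)
        n = Xs32.shape[0]
        out = np.empty(n)
        chunk = max(256, int(2 ** 26 // max(self.n_fit, 1)))
        for a in range(0, n, chunk):
            b = min(a + chunk, n)
            logk = Xs32[a:b] @ P.T
            logk *= 2.0
            logk -= xx[a:b, None]
            logk -= pp[None, :]
            logk *= 0.5  # now -d2/2 up to roundoff
            np.minimum(logk, 0.0, out=logk)
            if drop_diagonal:
                logk[np.arange(b - a), np.arange(a, b)] = -np.inf
            shift = logk.max(axis=1)
            np.exp(logk - shift[:, None], out=logk)
            out[a:b] = shift.astype(float) + np.log(logk.sum(axis=1, dtype=np.float64))
        return out

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        """Log density at rows of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.bandwidths.size:
            raise ValueError(f"expected {self.bandwidths.size} channels, got {X.shape[1]}")
        logsum = self._kernel_logsum(X / self.bandwidths, drop_diagonal=False)
        return logsum - np.log(self.n_fit) + self._log_const()

    def logpdf_loo(self) -> np.ndarray:
        """Leave-one-out log density at the KDE's own fit points.

        Each point's own kernel is excluded from its sum; without this, a
        KDE queried at its fit cells is biased upward by the self-kernel
        mass, which materially distorts healthy-vs-sample density ratios in
        10+ channels.
        """
        if self.n_fit < 2:
            raise ValueError("leave-one-out evaluation needs at least 2 fit points")
        logsum = self._kernel_logsum(self.points / self.bandwidths, drop_diagonal=True)
        return logsum - np.log(self.n_fit - 1) + self._log_const()


def _bandwidths(X: np.ndarray, rule: str, fixed, channel_names) -> np.ndarray:
    m, D = X.shape
    if rule == "fixed":
        if fixed is None:
            raise ValueError("bandwidth_rule='fixed' requires a bandwidth value")
        h = np.broadcast_to(np.asarray(fixed, dtype=float), (D,)).copy()
        if np.any(h <= 0):
            raise ValueError("fixed bandwidths must be positive")
        return h
    sigma = X.std(axis=0, ddof=1) if m > 1 else np.zeros(D)
    zero = np.flatnonzero(sigma <= 0)
    if zero.size:
        names = [channel_names[d] for d in zero] if channel_names else list(zero)
        raise ValueError(f"degenerate (zero-variance) channel(s) for KDE: {names}")
    factor = m ** (-1.0 / (D + 4))
    if rule == "scott":
        return sigma * factor
    if rule == "silverman":
        return sigma * (4.0 / (D + 2)) ** (1.0 / (D + 4)) * factor
    raise ValueError(f"unknown bandwidth rule {rule!r}; expected scott|silverman|fixed")


def _fit_kde(X: np.ndarray, rule: str, fixed, max_fit_cells: int,
             rng: np.random.Generator, channel_names=None) -> ProductKDE:
    if max_fit_cells is not None and X.shape[0] > max_fit_cells:
        idx = np.sort(rng.choice(X.shape[0], size=max_fit_cells, replace=False))
        X = X[idx]
    else:
        idx = np.arange(X.shape[0])
    return ProductKDE(points=X, bandwidths=_bandwidths(X, rule, fixed, channel_names),
                      fit_indices=idx)


@dataclass
class DensityModel:
    """Pooled-healthy KDE plus one KDE per positive training sample."""

    healthy_kde: ProductKDE
    per_sample_kde: Dict[str, ProductKDE]
    bandwidth_rule: str = "scott"
    fixed_bandwidth: Optional[float] = None
    max_fit_cells: int = 50000
    seed: int = 0
    channel_names: Optional[list] = None
    _log_ratio_cache: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def sample_kde(self, sample: SampleRecord) -> ProductKDE:
        """The sample's own KDE (fit on the fly for samples outside training)."""
        kde = self.per_sample_kde.get(sample.sample_id)
        if kde is None:
            rng = np.random.default_rng(self.seed)
            kde = _fit_kde(sample.events.values, self.bandwidth_rule, self.fixed_bandwidth,
                           self.max_fit_cells, rng, self.channel_names)
        return kde

    def log_ratio(self, sample: SampleRecord) -> np.ndarray:
        """log phat_healthy(x) - log phat_sample(x) at every cell of the sample.

        The sample KDE is evaluated leave-one-out at its own fit cells.
        Cached per sample id; a density model is tied to one cohort's event
        matrices and must not be reused across cohorts that share ids.
        """
        cached = self._log_ratio_cache.get(sample.sample_id)
        if cached is not None and cached.size == sample.events.n_cells:
            return cached
        X = sample.events.values
        kde = self.sample_kde(sample)
        loo_valid = (
            kde.fit_indices is not None
            and kde.n_fit >= 2
            and kde.fit_indices.size == kde.n_fit
            and (kde.fit_indices.max() < X.shape[0])
            and np.array_equal(X[kde.fit_indices], kde.points)
        )
        if loo_valid and kde.n_fit == X.shape[0]:
            log_f = kde.logpdf_loo()  # KDE fit on every cell: LOO covers all rows
        else:
            log_f = kde.logpdf(X)
            if loo_valid:
                log_f[kde.fit_indices] = kde.logpdf_loo()
        ratio = self.healthy_kde.logpdf(X) - log_f
        self._log_ratio_cache[sample.sample_id] = ratio
        return ratio


@dataclass
class InitScores:
    """Density-derived pretraining targets s' per sample, each in [0, 1]."""

    scores: Dict[str, np.ndarray] = field(default_factory=dict)
    prior_mode: str = "burden"

    def __post_init__(self) -> None:
        for sid, v in self.scores.items():
            v = np.asarray(v, dtype=float)
            if v.size and (v.min() < 0 or v.max() > 1):
                raise ValueError(f"init scores for {sid!r} outside [0, 1]")
            self.scores[sid] = v


def fit_density_model(
    train_cohort: Cohort,
    bandwidth_rule: str = "scott",
    max_fit_cells: int = 50000,
    seed: int = 0,
    fixed_bandwidth: Optional[float] = None,
) -> DensityModel:
    """Fit the pooled-healthy KDE and one KDE per positive training sample.

    Cells are subsampled to `max_fit_cells` (deterministic given seed) before
    fitting.  Requires at least one negative and one positive sample.
    """
    negatives = train_cohort.negatives()
    positives = train_cohort.positives()
    if not negatives:
        raise ValueError("density model needs at least one negative (healthy) training sample")
    if not positives:
        raise ValueError("density model needs at least one positive training sample")
    rng = np.random.default_rng(seed)
    names = train_cohort.panel.names
    pooled = np.vstack([s.events.values for s in negatives])
    healthy = _fit_kde(pooled, bandwidth_rule, fixed_bandwidth, max_fit_cells, rng, names)
    healthy.fit_indices = None  # pooled rows; never evaluated leave-one-out
    per_sample = {
        s.sample_id: _fit_kde(s.events.values, bandwidth_rule, fixed_bandwidth,
                              max_fit_cells, rng, names)
        for s in positives
    }
    return DensityModel(
        healthy_kde=healthy,
        per_sample_kde=per_sample,
        bandwidth_rule=bandwidth_rule,
        fixed_bandwidth=fixed_bandwidth,
        max_fit_cells=max_fit_cells,
        seed=seed,
        channel_names=list(names),
    )


def _sample_init_scores(model: DensityModel, sample: SampleRecord, log_prior0: float) -> np.ndarray:
    return np.clip(1.0 - np.exp(model.log_ratio(sample) + log_prior0), 0.0, 1.0)


def bayes_init_scores(
    model: DensityModel,
    cohort: Cohort,
    prior_mode: str = "burden",
    fixed_prior: float = 0.9,
) -> InitScores:
    """Initial cell scores s' for every sample of a cohort.

    Negative samples get all-zero scores.  For positive samples,
    s' = clip(1 - exp(log phat_healthy(x) + log prior0 - log phat_sample(x)), 0, 1)
    with prior0 = 1 - y_i (burden mode) or the fixed prior P(z=0 | y>0)
    (fixed_prior mode, the binary-label case).
    """
    if prior_mode not in ("burden", "fixed_prior"):
        raise ValueError("prior_mode must be 'burden' or 'fixed_prior'")
    if prior_mode == "fixed_prior" and not (0.0 < fixed_prior < 1.0):
        raise ValueError("fixed_prior must lie in (0, 1)")
    out: Dict[str, np.ndarray] = {}
    for s in cohort.samples:
        if s.effective_label == 0:
            out[s.sample_id] = np.zeros(s.events.n_cells)
            continue
        if prior_mode == "burden":
            if s.burden is None:
                raise ValueError(
                    f"positive sample {s.sample_id!r} lacks a burden (required in burden mode)"
                )
            prior0 = 1.0 - s.burden
            if prior0 <= 0:  # burden exactly 1: every cell pathogenic
                out[s.sample_id] = np.ones(s.events.n_cells)
                continue
        else:
            prior0 = fixed_prior
        out[s.sample_id] = _sample_init_scores(model, s, np.log(prior0))
    return InitScores(scores=out, prior_mode=prior_mode)


def density_only_predict(
    model: DensityModel,
    sample: SampleRecord,
    prior_mode: str = "burden",
    fixed_prior: float = 0.9,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> float:
    """Burden prediction from densities alone: the mean of the sample's s'.

    The sample's own KDE stands in for P(x | y>0).  In burden mode the
    sample's recorded burden sets the prior when available; for an unlabeled
    sample the prior is solved self-consistently (y = mean s'(y) by damped
    fixed-point iteration, which reduces to the recorded-burden case when the
    estimate is exact).  This is the ablation baseline, not the trained model.
    """
    log_ratio = model.log_ratio(sample)

    def mean_score(prior0: float) -> float:
        if prior0 <= 0:
            return 1.0
        return float(np.mean(np.clip(1.0 - np.exp(log_ratio + np.log(prior0)), 0.0, 1.0)))

    if prior_mode == "fixed_prior":
        if not (0.0 < fixed_prior < 1.0):
            raise ValueError("fixed_prior must lie in (0, 1)")
        return mean_score(fixed_prior)
    if prior_mode != "burden":
        raise ValueError("prior_mode must be 'burden' or 'fixed_prior'")
    if sample.burden is not None:
        return mean_score(1.0 - sample.burden)
    y = 0.5
    for _ in range(max_iter):
        y_new = mean_score(1.0 - y)
        if abs(y_new - y) < tol:
            return y_new
        y = 0.5 * (y + y_new)
    return y


def pretrain_scoring_net(
    init_scores: InitScores,
    cohort: Cohort,
    net_spec: ScoringNetSpec,
    epochs: int = 150,
    lr: float = 5e-3,
    seed: int = 0,
    cells_per_sample_cap: Optional[int] = 2000,
) -> Tuple[ScoringNet, float]:
    """Train phi' to reproduce the density-based scores (MSE over cells).

    Returns (pretrained network, final fit loss).  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    params = _nn.init_params(net_spec.layer_sizes, rng)
    flat = _nn.flatten(params)
    opt = _nn.Adam([a.shape for a in flat], lr=lr)

    Xs, ts = [], []
    for s in cohort.samples:
        if s.sample_id not in init_scores.scores:
            raise ValueError(f"no init scores for sample {s.sample_id!r}")
        t = init_scores.scores[s.sample_id]
        if t.size != s.events.n_cells:
            raise ValueError(f"init scores misaligned for sample {s.sample_id!r}")
        Xs.append(s.events.values)
        ts.append(t)

    final_loss = np.inf
    for epoch in range(epochs):
        if cells_per_sample_cap is not None:
            xb, tb = [], []
            for X, t in zip(Xs, ts):
                if X.shape[0] > cells_per_sample_cap:
                    idx = rng.choice(X.shape[0], size=cells_per_sample_cap, replace=False)
                    xb.append(X[idx]); tb.append(t[idx])
                else:
                    xb.append(X); tb.append(t)
            Xb, Tb = np.vstack(xb), np.concatenate(tb)
        else:
            Xb, Tb = np.vstack(Xs), np.concatenate(ts)
        scores, acts = _nn.forward(params, Xb, want_cache=True)
        resid = scores - Tb
        loss = float(np.mean(resid ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite pretraining loss at epoch {epoch}")
        dscore = 2.0 * resid / resid.size
        grads = _nn.backward(params, acts, dscore)
        params = _nn.unflatten(opt.step(_nn.flatten(params), _nn.flatten(grads)))
        final_loss = loss
    return ScoringNet(net_spec, params), final_loss
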