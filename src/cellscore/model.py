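"""Scoring network, aggregation, training objectives and prediction.

The model scores each cell with a small feedforward network s(x; phi) in
(0, 1) and represents a sample by the mean score s̄_i.  Two weakly-supervised
objectives tie the cell level to sample-level targets:

* regression (burden targets y_i in [0, 1]):
      L = sum_{y_i>0} (s̄_i - y_i)^2 + lambda * sum_{y_i=0} s̄_i^2,
  lambda > 1 upweights healthy samples so their burden estimates are pushed
  to zero;

* classification (binary labels), through a logistic head
      P(y=1 | X_i) = 1 / (1 + exp(alpha + beta * s̄_i)),
  trained with (optionally positive-class-weighted) binary cross-entropy.

Both are sums over samples, not means, so the lambda / class-weight
semantics are scale-free in cohort size.  Note the logistic head as written
is *decreasing* in s̄ for beta > 0; the reported "oriented" pathogenicity
score is s when P increases with s̄ and 1 - s otherwise, so high oriented
score always means pathogenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from . import _nn
from .cohort import Cohort, EventMatrix

_EPS = 1e-12


@dataclass
class ScoringNetSpec:
    """Architecture of the per-cell scoring network."""

    input_dim: int
    hidden_sizes: Tuple[int, ...] = (64, 32)

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be a non-empty tuple of positive ints")

    @property
    def layer_sizes(self) -> Tuple[int, ...]:
        return (self.input_dim, *self.hidden_sizes, 1)


@dataclass
class ScoringNet:
    """Spec plus trained weights phi."""

    spec: ScoringNetSpec
    params: _nn.Params

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected (n, {self.spec.input_dim}) input, got {X.shape}"
            )
        s, _ = _nn.forward(self.params, X)
        return s

    def copy(self) -> "ScoringNet":
        return ScoringNet(self.spec, _nn.clone_params(self.params))


@dataclass
class LogisticHead:
    """Sample-level logistic parameters (alpha, beta)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("logistic head parameters must be finite")

    @property
    def orientation(self) -> int:
        """+1 when P(y=1) increases with s̄ (beta < 0), else -1."""
        return 1 if self.beta < 0 else -1


@dataclass
class TrainConfig:
    """Training hyperparameters for either objective."""

    mode: str = "reg"  # "reg" | "class"
    lam: float = 4.0  # lambda, reg mode; must exceed 1
    class_weight: float = 1.0  # w, class mode positive-class weight
    lr: float = 5e-3
    epochs: int = 200
    n_restarts: int = 5
    seed: int = 0
    use_density_init: bool = True
    cells_per_sample_cap: Optional[int] = 1000  # per-epoch subsample; None = all cells

    def __post_init__(self) -> None:
        if self.mode not in ("reg", "class"):
            raise ValueError(f"mode must be 'reg' or 'class', got {self.mode!r}")
        if self.mode == "reg" and self.lam <= 1:
            raise ValueError(f"lambda must be > 1 in reg mode, got {self.lam}")
        if self.class_weight <= 0:
            raise ValueError("class_weight must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class CellScores:
    """Per-sample raw cell scores and their means."""

    scores: Dict[str, np.ndarray]
    sbar: Dict[str, float]


@dataclass
class FitResult:
    """Trained network, optional head, and the restart protocol's record."""

    net: ScoringNet
    head: Optional[LogisticHead]
    config: TrainConfig
    train_loss_history: List[float]
    restart_losses: List[float]
    selected_restart: int

    @property
    def orientation(self) -> int:
        return self.head.orientation if self.head is not None else 1


@dataclass
class Predictions:
    """Sample-level predictions plus per-cell scores (raw and oriented)."""

    sample_ids: List[str]
    sbar: Dict[str, float]
    probability: Optional[Dict[str, float]]
    scores: Dict[str, np.ndarray]
    oriented_scores: Dict[str, np.ndarray]
    orientation: int

    @property
    def burden(self) -> Dict[str, float]:
        """Burden estimate per sample (the mean cell score)."""
        return self.sbar


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def score_cells(net: ScoringNet, events: EventMatrix) -> np.ndarray:
    """Score every cell of one sample; order-independent per-cell map."""
    return net.score(events.values)


def aggregate(scores: np.ndarray) -> float:
    """Sample-level mean score s̄ = (1/n) sum_j s_j.

    Scores are sorted before summation so the result is bit-identical under
    any permutation of the cells (float addition is order-sensitive).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot aggregate an empty score vector")
    return float(np.mean(np.sort(scores)))


def logistic_prob(sbar, head: LogisticHead):
    """P(y=1 | s̄) = 1 / (1 + exp(alpha + beta s̄)), overflow-safe."""
    t = np.asarray(head.alpha + head.beta * np.asarray(sbar, dtype=float))
    out = np.empty_like(t, dtype=float)
    neg = t < 0
    out[neg] = 1.0 / (1.0 + np.exp(t[neg]))
    et = np.exp(-t[~neg])
    out[~neg] = et / (1.0 + et)
    return float(out) if out.ndim == 0 else out


def loss_reg(sbars: np.ndarray, burdens: np.ndarray, lam: float) -> float:
    """Weighted squared-error objective (sum over samples)."""
    if lam <= 1:
        raise ValueError(f"lambda must be > 1, got {lam}")
    sbars = np.asarray(sbars, dtype=float)
    burdens = np.asarray(burdens, dtype=float)
    pos = burdens > 0
    return float(np.sum((sbars[pos] - burdens[pos]) ** 2) + lam * np.sum(sbars[~pos] ** 2))


def loss_class(sbars: np.ndarray, labels: np.ndarray, head: LogisticHead,
               class_weight: float = 1.0) -> float:
    """Binary cross-entropy over samples; positive term weighted by w."""
    sbars = np.asarray(sbars, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be 0/1")
    P = np.clip(logistic_prob(sbars, head), _EPS, 1.0 - _EPS)
    pos = labels == 1
    return float(-class_weight * np.sum(np.log(P[pos])) - np.sum(np.log(1.0 - P[~pos])))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stack_cohort(cohort: Cohort, cap: Optional[int], rng: Optional[np.random.Generator]):
    """Concatenate (optionally per-sample subsampled) cells.

    Returns (X, sample_slices) where sample_slices[i] = (start, stop).
    """
    mats = []
    slices = []
    start = 0
    for s in cohort.samples:
        V = s.events.values
        if cap is not None and rng is not None and V.shape[0] > cap:
            idx = rng.choice(V.shape[0], size=cap, replace=False)
            V = V[idx]
        mats.append(V)
        slices.append((start, start + V.shape[0]))
        start += V.shape[0]
    return np.vstack(mats), slices


def _sbar_from_scores(scores: np.ndarray, slices) -> np.ndarray:
    return np.array([scores[a:b].mean() for a, b in slices])


def _cohort_loss(net: ScoringNet, head: Optional[LogisticHead], cohort: Cohort,
                 config: TrainConfig) -> float:
    sbars = np.array([aggregate(net.score(s.events.values)) for s in cohort.samples])
    if config.mode == "reg":
        burdens = np.array([s.burden for s in cohort.samples], dtype=float)
        return loss_reg(sbars, burdens, config.lam)
    return loss_class(sbars, cohort.labels, head, config.class_weight)


def _cohort_auroc(net: ScoringNet, head: Optional[LogisticHead], cohort: Cohort,
                  config: TrainConfig) -> float:
    sbars = np.array([aggregate(net.score(s.events.values)) for s in cohort.samples])
    stat = logistic_prob(sbars, head) if (config.mode == "class" and head is not None) else sbars
    labels = cohort.labels
    if len(set(labels.tolist())) < 2:
        return float("nan")
    return float(roc_auc_score(labels, stat))


def _check_targets(cohort: Cohort, mode: str, what: str) -> None:
    for s in cohort.samples:
        if mode == "reg" and s.burden is None:
            raise ValueError(f"{what} sample {s.sample_id!r} lacks a burden (required in reg mode)")
        if mode == "class" and s.label is None and s.burden is None:
            raise ValueError(f"{what} sample {s.sample_id!r} lacks a label")


def _train_one_restart(cohort: Cohort, spec: ScoringNetSpec, config: TrainConfig,
                       init: Optional[_nn.Params], restart_seed: int):
    """One gradient-descent run.  Returns (net, head, loss_history) or raises
    FloatingPointError on divergence."""
    rng = np.random.default_rng(restart_seed)
    if config.use_density_init and init is not None:
        params = _nn.clone_params(init)
    else:
        params = _nn.init_params(spec.layer_sizes, rng)

    is_class = config.mode == "class"
    if is_class:
        # beta starts negative so P initially increases with s̄; alpha small.
        head_vec = np.array([rng.normal(0.0, 0.1), rng.normal(-2.0, 0.5)])
    else:
        head_vec = None

    burdens = np.array([s.burden if s.burden is not None else float(s.effective_label)
                        for s in cohort.samples], dtype=float)
    labels = cohort.labels.astype(float)

    flat = _nn.flatten(params)
    shapes = [a.shape for a in flat] + ([head_vec.shape] if is_class else [])
    opt = _nn.Adam(shapes, lr=config.lr)

    history: List[float] = []
    for epoch in range(config.epochs):
        X, slices = _stack_cohort(cohort, config.cells_per_sample_cap, rng)
        scores, acts = _nn.forward(params, X, want_cache=True)
        sbars = _sbar_from_scores(scores, slices)

        if config.mode == "reg":
            pos = burdens > 0
            resid = sbars - burdens
            loss = float(np.sum(resid[pos] ** 2) + config.lam * np.sum(sbars[~pos] ** 2))
            dsbar = np.where(pos, 2.0 * resid, 2.0 * config.lam * sbars)
            dhead = None
        else:
            alpha, beta = head_vec
            t = alpha + beta * sbars
            P = np.clip(logistic_prob(sbars, LogisticHead(alpha, beta)), _EPS, 1.0 - _EPS)
            w = config.class_weight
            loss = float(-w * np.sum(labels * np.log(P)) - np.sum((1 - labels) * np.log(1.0 - P)))
            # dL/dt: w(1-P) for positives, -P for negatives (t = alpha + beta s̄)
            dt = np.where(labels == 1, w * (1.0 - P), -P)
            dsbar = dt * beta
            dhead = np.array([np.sum(dt), np.sum(dt * sbars)])

        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history.append(loss)

        n_sub = np.array([b - a for a, b in slices], dtype=float)
        dscore = np.empty(len(scores))
        for i, (a, b) in enumerate(slices):
            dscore[a:b] = dsbar[i] / n_sub[i]
        grads = _nn.backward(params, acts, dscore)

        flat = _nn.flatten(params)
        gflat = _nn.flatten(grads)
        if is_class:
            flat = flat + [head_vec]
            gflat = gflat + [dhead]
        new = opt.step(flat, gflat)
        if is_class:
            head_vec = new[-1]
            params = _nn.unflatten(new[:-1])
        else:
            params = _nn.unflatten(new)

    net = ScoringNet(spec, params)
    head = LogisticHead(float(head_vec[0]), float(head_vec[1])) if is_class else None
    return net, head, history


def fit(train_cohort: Cohort, val_cohort: Optional[Cohort], net_spec: ScoringNetSpec,
        config: TrainConfig, init: Optional[ScoringNet] = None) -> FitResult:
    """Train with restarts and return the restart with the lowest validation
    loss (training loss when no validation cohort is given; validation AUROC
    breaks ties).  Deterministic given config.seed."""
    _check_targets(train_cohort, config.mode, "training")
    if config.use_density_init and init is not None and init.spec.layer_sizes != net_spec.layer_sizes:
        raise ValueError("density-init network architecture does not match net_spec")
    init_params = init.params if init is not None else None

    candidates = []
    for r in range(config.n_restarts):
        try:
            net, head, history = _train_one_restart(
                train_cohort, net_spec, config, init_params, config.seed + r
            )
        except FloatingPointError:
            candidates.append(None)  # restart failed
            continue
        eval_cohort = val_cohort if val_cohort is not None else train_cohort
        sel_loss = _cohort_loss(net, head, eval_cohort, config)
        sel_auroc = _cohort_auroc(net, head, eval_cohort, config)
        candidates.append((sel_loss, sel_auroc, net, head, history))

    ok = [(i, c) for i, c in enumerate(candidates) if c is not None]
    if not ok:
        raise RuntimeError("all restarts diverged")
    # lowest selection loss; higher AUROC breaks ties
    auroc_key = lambda c: -c[1] if np.isfinite(c[1]) else 0.0
    best_i, best = min(ok, key=lambda ic: (ic[1][0], auroc_key(ic[1])))
    restart_losses = [float(c[0]) if c is not None else float("inf") for c in candidates]
    return FitResult(
        net=best[2],
        head=best[3],
        config=config,
        train_loss_history=[float(v) for v in best[4]],
        restart_losses=restart_losses,
        selected_restart=best_i,
    )


def predict(fit_result: FitResult, cohort: Cohort) -> Predictions:
    """Sample-level burden/probability predictions plus per-cell scores."""
    scores: Dict[str, np.ndarray] = {}
    oriented: Dict[str, np.ndarray] = {}
    sbar: Dict[str, float] = {}
    prob: Optional[Dict[str, float]] = {} if fit_result.head is not None else None
    orient = fit_result.orientation
    for s in cohort.samples:
        sc = score_cells(fit_result.net, s.events)
        scores[s.sample_id] = sc
        oriented[s.sample_id] = sc if orient == 1 else 1.0 - sc
        sbar[s.sample_id] = aggregate(sc)
        if prob is not None:
            prob[s.sample_id] = float(logistic_prob(sbar[s.sample_id], fit_result.head))
    return Predictions(
        sample_ids=cohort.sample_ids,
        sbar=sbar,
        probability=prob,
        scores=scores,
        oriented_scores=oriented,
        orientation=orient,
    )


def sample_auroc(predictions: Predictions, cohort: Cohort) -> float:
    """AUROC of the sample-level statistic against diagnosis labels."""
    labels = cohort.labels
    if predictions.probability is not None:
        stat = [predictions.probability[i] for i in cohort.sample_ids]
    else:
        stat = [predictions.sbar[i] for i in cohort.sample_ids]
    return float(roc_auc_score(labels, stat))


def hyperparameter_search(
    train_cohort: Cohort,
    grid: Sequence[TrainConfig],
    n_folds: int,
    seed: int,
    net_spec: Optional[ScoringNetSpec] = None,
    init: Optional[ScoringNet] = None,
) -> Tuple[TrainConfig, FitResult, List[dict]]:
    """Stratified-CV grid search by mean validation AUROC, then refit on all.

    Returns (best config, refit on the full training cohort, per-point table).
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    from .cohort import make_splits

    spec = net_spec or ScoringNetSpec(input_dim=train_cohort.panel.size)
    folded = make_splits(train_cohort, n_folds, seed)
    table: List[dict] = []
    for gi, cfg in enumerate(grid):
        aurocs = []
        for fold in range(n_folds):
            val_ids = [i for i, f in folded.split_assignment.items() if f == fold]
            tr_ids = [i for i in folded.sample_ids if i not in set(val_ids)]
            val_c, tr_c = folded.subset(val_ids), folded.subset(tr_ids)
            if len(set(val_c.labels.tolist())) < 2 or len(set(tr_c.labels.tolist())) < 2:
                raise ValueError(f"fold {fold} is missing a class")
            try:
                res = fit(tr_c, val_c, spec, replace(cfg, seed=seed + 1000 * gi + fold), init=init)
            except RuntimeError:
                aurocs.append(0.0)  # every restart diverged: worst possible score
                continue
            pred = predict(res, val_c)
            aurocs.append(sample_auroc(pred, val_c))
        table.append({"config": cfg, "mean_val_auroc": float(np.mean(aurocs)),
                      "fold_aurocs": [float(a) for a in aurocs]})
    best_idx = int(np.argmax([row["mean_val_auroc"] for row in table]))
    best_cfg = grid[best_idx]
    final = fit(train_cohort, None, spec, replace(best_cfg, seed=seed), init=init)
    return best_cfg, final, table
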