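"""High-level runs: density init -> training -> prediction -> interpretation.

Thin orchestration used by the command-line interface, the examples and the
reproduction script; all substance lives in the other modules.  Checkpoints
are single JSON files carrying the network weights, logistic head, panel
(with fitted transform parameters) and training configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .cohort import Cohort, train_val_split
from .density import DensityModel, bayes_init_scores, fit_density_model, pretrain_scoring_net
from .model import (
    FitResult,
    LogisticHead,
    Predictions,
    ScoringNet,
    ScoringNetSpec,
    TrainConfig,
    fit,
    predict,
    sample_auroc,
)
from .panel import MarkerPanel


def prepare_density_init(
    train_cohort: Cohort,
    net_spec: ScoringNetSpec,
    seed: int,
    bandwidth_rule: str = "scott",
    max_fit_cells: int = 50000,
    prior_mode: str = "burden",
    fixed_prior: float = 0.9,
    pretrain_epochs: int = 150,
    pretrain_lr: float = 5e-3,
) -> Tuple[DensityModel, ScoringNet, float]:
    """Fit the density model, compute s', pretrain phi'.

    Returns (density model, pretrained net, final pretraining loss).
    """
    dm = fit_density_model(train_cohort, bandwidth_rule=bandwidth_rule,
                           max_fit_cells=max_fit_cells, seed=seed)
    init = bayes_init_scores(dm, train_cohort, prior_mode=prior_mode, fixed_prior=fixed_prior)
    net0, pre_loss = pretrain_scoring_net(
        init, train_cohort, net_spec, epochs=pretrain_epochs, lr=pretrain_lr, seed=seed
    )
    return dm, net0, pre_loss


def train_pipeline(
    train_cohort: Cohort,
    config: TrainConfig,
    net_spec: Optional[ScoringNetSpec] = None,
    val_cohort: Optional[Cohort] = None,
    val_fraction: Optional[float] = 0.25,
    density_kwargs: Optional[dict] = None,
) -> Tuple[FitResult, Optional[DensityModel], dict]:
    """Full training run on an (already transformed) cohort.

    When no validation cohort is given and `val_fraction` is set, a stratified
    slice of the training cohort is held out for restart selection.  Density
    initialization (when enabled) is fit on the training part only.
    """
    spec = net_spec or ScoringNetSpec(input_dim=train_cohort.panel.size)
    if val_cohort is None and val_fraction:
        tr, val = train_val_split(train_cohort, val_fraction, config.seed)
    else:
        tr, val = train_cohort, val_cohort

    dm: Optional[DensityModel] = None
    init_net: Optional[ScoringNet] = None
    pre_loss = None
    if config.use_density_init:
        kw = dict(density_kwargs or {})
        if config.mode == "class":
            kw.setdefault("prior_mode", "fixed_prior")
        dm, init_net, pre_loss = prepare_density_init(tr, spec, config.seed, **kw)

    result = fit(tr, val, spec, config, init=init_net)
    metrics = {
        "mode": config.mode,
        "use_density_init": config.use_density_init,
        "pretrain_loss": pre_loss,
        "selected_restart": result.selected_restart,
        "restart_losses": result.restart_losses,
        "final_train_loss": result.train_loss_history[-1],
    }
    if val is not None:
        metrics["val_loss"] = result.restart_losses[result.selected_restart]
        preds = predict(result, val)
        try:
            metrics["val_auroc"] = sample_auroc(preds, val)
        except ValueError:
            metrics["val_auroc"] = None
    return result, dm, metrics


def save_checkpoint(path, fit_result: FitResult, panel: MarkerPanel) -> None:
    doc = {
        "spec": {"input_dim": fit_result.net.spec.input_dim,
                 "hidden_sizes": list(fit_result.net.spec.hidden_sizes)},
        "params": [[W.tolist(), b.tolist()] for W, b in fit_result.net.params],
        "head": (None if fit_result.head is None
                 else {"alpha": fit_result.head.alpha, "beta": fit_result.head.beta}),
        "config": asdict(fit_result.config),
        "panel": panel.to_dict(),
        "selected_restart": fit_result.selected_restart,
        "restart_losses": fit_result.restart_losses,
        "train_loss_history": fit_result.train_loss_history,
    }
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path) -> Tuple[FitResult, MarkerPanel]:
    doc = json.loads(Path(path).read_text())
    spec = ScoringNetSpec(input_dim=doc["spec"]["input_dim"],
                          hidden_sizes=tuple(doc["spec"]["hidden_sizes"]))
    params = [(np.asarray(W, dtype=float), np.asarray(b, dtype=float))
              for W, b in doc["params"]]
    head = None
    if doc["head"] is not None:
        head = LogisticHead(alpha=doc["head"]["alpha"], beta=doc["head"]["beta"])
    cfg_doc = dict(doc["config"])
    cfg_doc["cells_per_sample_cap"] = cfg_doc.get("cells_per_sample_cap")
    config = TrainConfig(**cfg_doc)
    result = FitResult(
        net=ScoringNet(spec, params),
        head=head,
        config=config,
        train_loss_history=list(doc.get("train_loss_history", [])),
        restart_losses=list(doc.get("restart_losses", [])),
        selected_restart=int(doc.get("selected_restart", 0)),
    )
    return result, MarkerPanel.from_dict(doc["panel"])


def predictions_frame(predictions: Predictions, cohort: Cohort):
    """Tidy per-sample prediction table."""
    import pandas as pd

    rows = []
    for s in cohort.samples:
        sid = s.sample_id
        rows.append({
            "sample_id": sid,
            "burden_pred": predictions.sbar[sid],
            "probability": None if predictions.probability is None else predictions.probability[sid],
            "label": s.effective_label,
            "burden_true": s.burden,
        })
    return pd.DataFrame(rows)
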