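"""Shared fixtures.

The "standard" benchmark cohort (8 markers, 3 healthy populations, 2
pathogenic endotypes, 40 training + 20 test samples at 5000-10000 cells) and
the model fits on it are expensive, so they are built once per session and
shared by the recovery, ablation, interpretation and acceptance tests.
Smaller cohorts are rebuilt per module.
"""

from __future__ import annotations

import numpy as np
import pytest

import cellscore as cs
from cellscore.cohort import train_val_split

BASE_SEED = 7


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for unit tests: 4+4 samples, 400-700 cells."""
    cfg = cs.standard_fixture_config(seed=BASE_SEED, n_pos=4, n_neg=4,
                                     cells_per_sample=(400, 700))
    return cs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def standard_cohorts():
    """The full-size benchmark: (train, test, truth_train, truth_test)."""
    train, truth_tr = cs.generate_cohort(
        cs.standard_fixture_config(seed=BASE_SEED * 1000 + 1, n_pos=20, n_neg=20, id_prefix="tr_")
    )
    test, truth_te = cs.generate_cohort(
        cs.standard_fixture_config(seed=BASE_SEED * 1000 + 2, n_pos=10, n_neg=10, id_prefix="te_")
    )
    return train, test, truth_tr, truth_te


@pytest.fixture(scope="session")
def standard_fits(standard_cohorts):
    """Density model + fitted models on the standard benchmark.

    Returns a dict with the density model, the density-initialized regression
    fit, the no-init ablation fit, the classification fit, and the train/val
    split used for restart selection.
    """
    train_full, _, _, _ = standard_cohorts
    tr, val = train_val_split(train_full, 0.25, BASE_SEED)
    spec = cs.ScoringNetSpec(8)

    dm = cs.fit_density_model(tr, max_fit_cells=20000, seed=BASE_SEED)
    init_reg = cs.bayes_init_scores(dm, tr, prior_mode="burden")
    net0_reg, pre_loss = cs.pretrain_scoring_net(init_reg, tr, spec, epochs=150, seed=BASE_SEED)

    cfg_reg = cs.TrainConfig(mode="reg", lam=4.0, epochs=200, n_restarts=5, seed=BASE_SEED)
    fit_reg = cs.fit(tr, val, spec, cfg_reg, init=net0_reg)

    cfg_off = cs.TrainConfig(mode="reg", lam=4.0, epochs=200, n_restarts=5, seed=BASE_SEED,
                             use_density_init=False)
    fit_reg_noinit = cs.fit(tr, val, spec, cfg_off)

    init_cls = cs.bayes_init_scores(dm, tr, prior_mode="fixed_prior", fixed_prior=0.9)
    net0_cls, _ = cs.pretrain_scoring_net(init_cls, tr, spec, epochs=150, seed=BASE_SEED)
    cfg_cls = cs.TrainConfig(mode="class", epochs=200, n_restarts=5, seed=BASE_SEED)
    fit_cls = cs.fit(tr, val, spec, cfg_cls, init=net0_cls)

    return {
        "train": tr,
        "val": val,
        "spec": spec,
        "density_model": dm,
        "pretrain_loss": pre_loss,
        "reg": fit_reg,
        "reg_noinit": fit_reg_noinit,
        "class": fit_cls,
    }


@pytest.fixture(scope="session")
def standard_test_predictions(standard_cohorts, standard_fits):
    _, test, _, _ = standard_cohorts
    return cs.predict(standard_fits["reg"], test)
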