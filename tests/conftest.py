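"""Shared fixtures.

The expensive end-to-end fixtures (desk-scale trainings over five seeds)
are session-scoped so the parameter-recovery and band-attribution checks
share them; everything else is cheap and rebuilt per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from n2gnet.evaluate import kendall_tau
from n2gnet.model import variant_config
from n2gnet.pipeline import (
    DESK_SCALE_SUBSAMPLE,
    desk_scale_configs,
    run_participant,
    synthetic_participant,
)

SEEDS = (1, 2, 3, 4, 5)


def _run(seed: int, variant: str, attribution: bool) -> dict:
    raw = synthetic_participant(seed=seed)
    mcfg, tcfg = desk_scale_configs(seed=seed)
    mcfg = variant_config(variant, mcfg)
    return run_participant(raw, mcfg, tcfg,
                           subsample=DESK_SCALE_SUBSAMPLE,
                           attribution=attribution)


def _summarize(seed: int, res: dict) -> dict:
    report = res["test_report"]
    test_ds = res["data"]["test"]
    pred = res["model"].predict(test_ds.inputs)
    shuffled = np.random.default_rng(seed).permutation(test_ds.labels)
    out = {
        "seed": seed,
        "tau_model": report.tau_model,
        "tau_beta_higher": report.tau_beta_higher,
        "tau_shuffled": kendall_tau(pred, shuffled),
        "test_mae": report.mae,
        "test_mse": report.mse,
    }
    if "variance_ratio" in res:
        out["dominant_band"] = res["variance_ratio"].dominant_band
        out["ratio_sum"] = float(res["variance_ratio"].ratios.sum())
    return out


@pytest.fixture(scope="session")
def seed1_canonical_run() -> dict:
    """One full canonical desk-scale run kept whole for reuse."""
    return _run(SEEDS[0], "N2GNet", attribution=False)


@pytest.fixture(scope="session")
def canonical_summaries(seed1_canonical_run) -> list[dict]:
    """Five-seed canonical-model recovery results (summaries only)."""
    out = [_summarize(SEEDS[0], seed1_canonical_run)]
    for seed in SEEDS[1:]:
        out.append(_summarize(seed, _run(seed, "N2GNet",
                                         attribution=False)))
    return out


@pytest.fixture(scope="session")
def nodiv_summaries() -> list[dict]:
    """Five-seed no-division-variant runs with band attribution."""
    return [_summarize(seed, _run(seed, "FExt-Div+SE+Bi",
                                  attribution=True))
            for seed in SEEDS]


@pytest.fixture()
def tiny_model_config():
    """A minimal but structurally complete configuration for fast tests."""
    from n2gnet.model import ModelConfig

    return ModelConfig(n_filters_per_lead=4, kernel_len=7, pool_len=5,
                       pool_stride=3, se_reduction=2, lstm_hidden=3,
                       lstm_layers=3, head_channels=4, head_kernel_len=3,
                       seed=123)
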