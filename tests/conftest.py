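"""Shared fixtures: trained models are expensive, so training runs are
session-scoped and reused across the acceptance tests that need them."""

import numpy as np
import pytest

from chromnet.architecture import ModelConfig
from chromnet.evaluation import insulation_correlation
from chromnet.genomic_io import ContactMap
from chromnet.synthetic import ScenarioConfig, build_bundle
from chromnet.training import (
    NoiseConfig,
    TrainConfig,
    prepare_windows,
    predict_window,
    train,
)

# ---------------------------------------------------------------------------
# study conditions (fixed; see docs/methods.md)
# ---------------------------------------------------------------------------

OVERFIT_SCENARIO = dict(
    n_bins=288, bin_size=1024, n_boundaries=12,
    shared_boundary_fraction=0.5, min_gap=16, seed=3,
)
OVERFIT_EPOCHS = 60

CROSS_SCENARIO = dict(
    n_bins=96, bin_size=1024, n_boundaries=4,
    shared_boundary_fraction=0.5, min_gap=10,
    cell_gain_sd=0.3, cell_noise_sd=1.0,
)
CROSS_SEEDS = (0, 1, 2, 3, 4)


def small_model_config(n_bins=32):
    """32-bin sibling of the toy geometry for the multi-seed experiments."""
    return ModelConfig(
        encoder_conv_channels=(8, 12, 16), pool_factors=(4, 4, 4),
        topk_patch=4, topk_k=10, lstm_seq_dim=32, lstm_hidden=48,
        recon_initial_channels=24, recon_group_channels=(24, 12),
        blocks_per_group=2, classifier_conv_channels=(16, 8),
        classifier_fc_dim=32, n_cell_types=2,
        n_bins=n_bins, bin_size=1024, window_length=n_bins * 1024,
    )


def window_insulation_pearson(model, bundle, wds, cell, window_bins=5):
    """Mean insulation Pearson of model predictions vs that cell's truth."""
    ps = []
    for wd in wds:
        pred = predict_window(model, wd, cell).contact_pred
        truth_full = bundle.contact_maps[(wd.window.chrom, cell)]
        lo = wd.window.start // wd.window.bin_size
        hi = wd.window.end // wd.window.bin_size
        sub = truth_full.matrix[lo:hi, lo:hi]
        truth = ContactMap(wd.window, np.log1p(sub), "log")
        p, _ = insulation_correlation(pred, truth, window_bins)
        ps.append(p)
    return float(np.mean(ps))


@pytest.fixture(scope="session")
def overfit_run():
    """Toy 64-bin model fit to 8 synthetic windows (the overfit fixture)."""
    cfg = ModelConfig.toy()
    bundle = build_bundle({"chr1": ScenarioConfig(**OVERFIT_SCENARIO)})
    wds = prepare_windows(bundle, cfg, target="cellA", step=32 * 1024)
    assert len(wds) == 8
    result = train(
        wds, cfg, NoiseConfig(), TrainConfig(epochs=OVERFIT_EPOCHS, base_lr=5e-3),
        "cellA", bundle.cell_types, seed=0,
    )
    return {"config": cfg, "bundle": bundle, "windows": wds, "result": result}


@pytest.fixture(scope="session")
def cross_cell_runs():
    """Matched-seed training runs: noise+aux vs base, 5 seeds, 32-bin model."""
    cfg = small_model_config()
    runs = {}
    for seed in CROSS_SEEDS:
        scen = ScenarioConfig(**CROSS_SCENARIO, seed=200 + seed)
        bundle = build_bundle({"chr1": scen})
        wds = prepare_windows(bundle, cfg, target="cellA", step=16 * 1024)
        held = prepare_windows(bundle, cfg, target="cellA", step=8 * 1024)
        held = [h for h in held if h.window.start % (16 * 1024) != 0]
        models = {}
        for name, tc in [
            ("aux", TrainConfig(epochs=50, base_lr=5e-3)),
            ("base", TrainConfig(epochs=50, base_lr=5e-3,
                                 no_noise=True, no_aux=True)),
        ]:
            models[name] = train(
                wds, cfg, NoiseConfig(), tc, "cellA", bundle.cell_types, seed=seed
            ).model
        runs[seed] = {
            "bundle": bundle, "windows": wds, "held": held, "models": models,
        }
    return {"config": cfg, "runs": runs}
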