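"""Canned end-to-end experiments on synthetic canopy scenes.

These are the package's reference benchmarks: generate a labeled scene, run
the full preprocessing chain (band reduction, entropy-rate superpixels,
optional smoothing), train a classifier variant under a given training
fraction Tr, and score the held-out pixels.

They run a reduced-capacity model (9x9 window, 8 reduced bands, two 3-D and
two 2-D convolution stages, one 32-unit dense layer) so a full experiment
fits in CPU minutes; scene conditions (64x64 pixels, 6 species, difficulty,
noise, Tr) are the quantities of interest and are not scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import ConfusionMatrix, confusion, metrics_report
from .patch_dataset import SplitSpec, extract_patches, split_train_test
from .sscnn import ModelConfig, TrainedModel, train
from .superpixel import ers_features, ers_segment, reduce_bands, superpixel_smooth
from .synthetic import SceneSpec, default_grid, make_scene, make_signatures

__all__ = ["scaled_model_config", "ExperimentResult", "run_scene_experiment"]


def scaled_model_config(
    variant: str = "SS", seed: int = 0, epochs: int = 20, n_classes: int = 6
) -> ModelConfig:
    """Reduced-capacity configuration for CPU-scale experiments."""
    return ModelConfig(
        variant=variant,
        window=9,
        bands=8,
        n_classes=n_classes,
        conv3d_filters=(4, 8),
        conv3d_kernels=((3, 3, 5), (3, 3, 3)),
        conv2d_filters=(8, 16),
        dense_units=(32,),
        se_reduction=4,
        lr=1e-3,
        epochs=epochs,
        batch_size=32,
        seed=seed,
    )


@dataclass
class ExperimentResult:
    oa: float
    aa: float
    kappa: float
    n_train: int
    n_test: int
    confusion: ConfusionMatrix
    model: TrainedModel


def run_scene_experiment(
    difficulty: float,
    tr: float,
    variant: str = "SS",
    seed: int = 0,
    epochs: int = 20,
    M: int = 64,
    N: int = 64,
    K: int = 6,
    noise_sd: float = 0.01,
    n_superpixels: int = 200,
) -> ExperimentResult:
    """Scene -> reduce -> (ERS smooth) -> Tr split -> train -> held-out metrics.

    The seed drives scene synthesis, the split and weight initialization, so
    one integer reproduces the whole experiment.
    """
    grid = default_grid()
    sigs = make_signatures(K, grid, difficulty=difficulty, seed=seed)
    cube, labels = make_scene(
        SceneSpec(M=M, N=N, K=K, noise_sd=noise_sd, seed=seed), sigs
    )
    cfg = scaled_model_config(variant=variant, seed=seed, epochs=epochs, n_classes=K)
    rc = reduce_bands(cube, cfg.bands)
    if cfg.smooths_superpixels:
        seg = ers_segment(ers_features(cube), K=n_superpixels)
        data = superpixel_smooth(rc, seg)
    else:
        data = rc
    ps = extract_patches(data, labels, cfg.window)
    ps.n_classes = K
    train_ps, test_ps = split_train_test(ps, SplitSpec(tr=tr, seed=seed))
    model = train(cfg, train_ps)
    pred = model.predict_labels(test_ps.windows)
    cm = confusion(test_ps.labels, pred, K)
    rep = metrics_report(cm)
    return ExperimentResult(
        oa=rep.oa,
        aa=rep.aa,
        kappa=rep.kappa,
        n_train=len(train_ps),
        n_test=len(test_ps),
        confusion=cm,
        model=model,
    )
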