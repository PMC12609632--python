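"""The electrode-displacement robustness experiment.

Trains reconstructors on datasets with different electrode-disarrangement
levels and evaluates every (train level, test level) combination with the
four pixel metrics.  The headline effect: a network trained only on rigid
(equidistant-electrode) data degrades sharply as test-time displacement
grows, while a network whose training data includes displaced electrodes
stays robust.

The default configuration is desk-scale — a few hundred samples, a narrow
generator and a handful of epochs — chosen as the smallest setting where
adversarially trained reconstruction is still meaningful; the full-scale
study (hundreds of thousands of samples, GPU training) uses the same code
path with a larger :class:`RobustnessConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics, recon
from .dataset import Dataset, DatasetSpec, build_dataset

__all__ = ["RobustnessConfig", "build_level_datasets", "run_robustness"]

LEVEL_ORDER = ("none", "small", "medium", "large")


@dataclass
class RobustnessConfig:
    """Problem sizes for the robustness experiment.

    Training sets mix thorax and random-ellipse scenes roughly 3:1 (the
    composition of the full study's training data); test sets contain thorax
    scenes only.  ``train_levels`` picks which disarrangement levels get a
    trained network.
    """

    train_size: int = 384  # per level, thorax + ellipses combined
    ellipse_fraction: float = 0.25
    test_size: int = 48  # per level, thorax only
    train_levels: tuple[str, ...] = ("none", "large")
    test_levels: tuple[str, ...] = LEVEL_ORDER
    noise_snr_db: float = 30.0
    solver_n: int = 64
    epochs: int = 10
    base_width: int = 8
    batch_size: int = 16
    patience: int = 30


def build_level_datasets(cfg: RobustnessConfig, seed: int, progress=False):
    """Generate the training and test datasets for every requested level."""
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(64) % (2 ** 31))
    train = {}
    for level in cfg.train_levels:
        n_ell = int(round(cfg.train_size * cfg.ellipse_fraction))
        parts = [
            build_dataset(DatasetSpec(
                content="thorax", target_size=cfg.train_size - n_ell,
                level=level, noise_snr_db=cfg.noise_snr_db,
                seed=int(next(seeds)), solver_n=cfg.solver_n), progress),
            build_dataset(DatasetSpec(
                content="ellipses", target_size=n_ell, level=level,
                noise_snr_db=cfg.noise_snr_db, seed=int(next(seeds)),
                solver_n=cfg.solver_n), progress),
        ]
        train[level] = Dataset.concatenate(parts)
    test = {
        level: build_dataset(DatasetSpec(
            content="thorax", target_size=cfg.test_size, level=level,
            noise_snr_db=cfg.noise_snr_db, seed=int(next(seeds)),
            solver_n=cfg.solver_n), progress)
        for level in cfg.test_levels
    }
    return train, test


def run_robustness(seed: int = 0, cfg: RobustnessConfig | None = None,
                   verbose: bool = False) -> dict:
    """Run the full experiment; returns a dict with the metric grid and the
    summary quantities of interest.

    Keys: ``grid`` (the (train, test) -> metric table), ``ssim`` /
    ``rmse`` nested dicts ``[train][test] -> mean``, and ``history`` per
    trained level.
    """
    cfg = cfg if cfg is not None else RobustnessConfig()
    train_sets, test_sets = build_level_datasets(cfg, seed, progress=verbose)
    networks = {}
    histories = {}
    for i, (level, ds) in enumerate(train_sets.items()):
        tc = recon.TrainConfig(
            max_epochs=cfg.epochs, patience=cfg.patience,
            batch_size=cfg.batch_size, base_width=cfg.base_width,
            seed=seed + 1000 * (i + 1))
        if verbose:
            print(f"training level={level} on {len(ds)} samples", flush=True)
        networks[level], histories[level] = recon.train(ds, tc, verbose=verbose)

    grid = metrics.evaluate_grid(
        networks, test_sets,
        lambda model, meas: recon.reconstruct(model, meas, seed=seed))
    out = {"grid": grid, "history": histories}
    for m in ("ssim", "rmse"):
        out[m] = {
            tr: {te: grid[(tr, te)][m]["mean"] for te in cfg.test_levels}
            for tr in cfg.train_levels
        }
    return out
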