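"""Pixel-to-pixel reconstruction quality: SSIM, PSNR, RMSE, 2D correlation.

RMSE and PSNR are computed on 8-bit-scaled intensities: image pairs are
min-max scaled to 0..255 over the dataset being evaluated before metric
computation, so an RMSE of 8 and a PSNR near 29 dB describe the same
reconstruction (20*log10(255/8.06) ~ 30 dB).  SSIM follows the standard
reference implementation (11x11 Gaussian window, default stabilization
constants on the declared dynamic range); the 2D correlation coefficient is
the Pearson correlation of the flattened pixel vectors.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

__all__ = [
    "METRIC_NAMES",
    "corr2",
    "evaluate_grid",
    "evaluate_pairs",
    "psnr",
    "rescale_to_8bit",
    "rmse",
    "save_grid_csv",
    "save_grid_json",
    "ssim",
]

METRIC_NAMES = ("ssim", "psnr", "rmse", "corr2")
EIGHT_BIT = 255.0


def _check_shapes(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"image shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def rescale_to_8bit(images: np.ndarray, lo: float | None = None,
                    hi: float | None = None) -> np.ndarray:
    """Min-max scale a stack of images to 0..255 (shared bounds)."""
    images = np.asarray(images, dtype=float)
    lo = float(images.min()) if lo is None else lo
    hi = float(images.max()) if hi is None else hi
    if hi <= lo:
        raise ValueError("degenerate intensity range")
    return (images - lo) / (hi - lo) * EIGHT_BIT


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square error, in the images' intensity units."""
    x, y = _check_shapes(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def psnr(x: np.ndarray, y: np.ndarray, data_range: float = EIGHT_BIT) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    x, y = _check_shapes(x, y)
    if np.array_equal(x, y):
        return float("inf")
    return float(peak_signal_noise_ratio(x, y, data_range=data_range))


def ssim(x: np.ndarray, y: np.ndarray, data_range: float = EIGHT_BIT) -> float:
    """Mean structural similarity over 11x11 Gaussian windows, in [-1, 1]."""
    x, y = _check_shapes(x, y)
    return float(structural_similarity(
        x, y, data_range=data_range, gaussian_weights=True, win_size=11,
        sigma=1.5, use_sample_covariance=False))


def corr2(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of flattened pixels; errors on constant images."""
    x, y = _check_shapes(x, y)
    xf, yf = x.ravel(), y.ravel()
    if np.std(xf) == 0.0 or np.std(yf) == 0.0:
        raise ValueError("2D correlation undefined for a constant image")
    return float(np.corrcoef(xf, yf)[0, 1])


def evaluate_pairs(truth: np.ndarray, recon: np.ndarray,
                   rescale: bool = True) -> dict[str, np.ndarray]:
    """Per-sample metrics for matched stacks of ground-truth/reconstruction.

    With ``rescale=True`` both stacks are jointly min-max scaled to 0..255
    (bounds from the ground-truth stack), the scale on which RMSE/PSNR are
    reported."""
    truth = np.asarray(truth, dtype=float)
    recon = np.asarray(recon, dtype=float)
    if truth.shape != recon.shape:
        raise ValueError("stack shape mismatch")
    if rescale:
        lo, hi = float(truth.min()), float(truth.max())
        truth = rescale_to_8bit(truth, lo, hi)
        recon = rescale_to_8bit(recon, lo, hi)
    out = {m: np.empty(len(truth)) for m in METRIC_NAMES}
    for i in range(len(truth)):
        out["ssim"][i] = ssim(truth[i], recon[i])
        out["psnr"][i] = psnr(truth[i], recon[i])
        out["rmse"][i] = rmse(truth[i], recon[i])
        out["corr2"][i] = corr2(truth[i], recon[i])
    return out


def evaluate_grid(networks: dict, testsets: dict, reconstruct_fn) -> dict:
    """Mean +/- SD of the four metrics over every (train level, test level)
    combination.

    ``networks`` maps train-level name -> model, ``testsets`` maps test-level
    name -> object with ``images`` and ``measurements`` arrays, and
    ``reconstruct_fn(model, measurements) -> images`` runs inference.
    Returns ``{(train, test): {metric: {"mean": .., "sd": ..}}}``.
    """
    if not networks or not testsets:
        raise ValueError("need at least one network and one test set")
    grid = {}
    for tr_name, model in networks.items():
        for te_name, ds in testsets.items():
            recon = reconstruct_fn(model, ds.measurements)
            per = evaluate_pairs(ds.images, recon)
            grid[(tr_name, te_name)] = {
                m: {"mean": float(np.mean(v)), "sd": float(np.std(v))}
                for m, v in per.items()
            }
    return grid


def save_grid_json(grid: dict, path) -> None:
    flat = {f"{a}|{b}": cell for (a, b), cell in grid.items()}
    with open(path, "w") as f:
        json.dump(flat, f, indent=2)


def save_grid_csv(grid: dict, path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["train_level", "test_level"]
                   + [f"{m}_{s}" for m in METRIC_NAMES for s in ("mean", "sd")])
        for (a, b), cell in grid.items():
            w.writerow([a, b] + [f"{cell[m][s]:.6g}"
                                 for m in METRIC_NAMES for s in ("mean", "sd")])


def plot_grid(grid: dict, path) -> None:
    """Optional Fig.-10-style bar rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trains = sorted({a for a, _ in grid})
    tests = sorted({b for _, b in grid})
    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    for ax, m in zip(axes.ravel(), METRIC_NAMES):
        width = 0.8 / len(trains)
        for i, tr in enumerate(trains):
            means = [grid[(tr, te)][m]["mean"] for te in tests]
            sds = [grid[(tr, te)][m]["sd"] for te in tests]
            ax.bar(np.arange(len(tests)) + i * width, means, width,
                   yerr=sds, label=f"train={tr}", capsize=2)
        ax.set_xticks(np.arange(len(tests)) + 0.4 - width / 2)
        ax.set_xticklabels(tests)
        ax.set_title(m.upper())
        ax.set_xlabel("test displacement level")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
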