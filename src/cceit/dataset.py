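"""Dataset assembly: noise, normalization, and the HDF5 sample container.

Each sample pairs a 64x64 conductivity image with its 992-element simulated
capacitance vector.  Measurements are normalized with the two-reference ECT
scheme — a uniform low-permittivity (air) scene maps to 0 and a uniform
background-tissue scene to 1 on every channel — and Gaussian noise is then
added at an SNR of 30 dB referenced to the diametrically opposite electrode
pairs, which carry the smallest capacitances; every other channel therefore
sees an SNR of at least 30 dB, mirroring real acquisition behaviour.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from . import band, phantom
from .forward import ORDERING, SensorMeshConfig, sensitivity_for_layout, simulate_capacitance

__all__ = [
    "Dataset",
    "DatasetSpec",
    "add_noise",
    "build_dataset",
    "normalize",
    "reference_vectors",
    "train_test_split",
]


@dataclass(frozen=True)
class DatasetSpec:
    """What to generate: content, size, displacement level, noise, seed."""

    content: str = "thorax"  # thorax | ellipses
    target_size: int = 100
    level: str = "none"  # none | small | medium | large
    noise_snr_db: float | None = 30.0
    seed: int = 0
    solver_n: int = 64
    image_n: int = 64

    def __post_init__(self):
        if self.content not in ("thorax", "ellipses"):
            raise ValueError(f"unknown content {self.content!r}")
        if self.level not in band.LEVELS:
            raise ValueError(f"unknown displacement level {self.level!r}")
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")


@dataclass
class Dataset:
    """In-memory dataset; one row per accepted sample."""

    images: np.ndarray  # (n, 64, 64) float32, conductivity S/m
    measurements: np.ndarray  # (n, 992) float32, normalized (+ noise)
    labels: np.ndarray  # (n, 2) bytes, per-lung pathology ('' for ellipses)
    layouts: list[str]  # JSON records per sample
    seeds: np.ndarray  # (n,) uint32 per-sample child seed
    spec: DatasetSpec | None = None
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.images)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            kw = dict(track_times=False, compression="gzip", compression_opts=4)
            f.create_dataset("images", data=self.images.astype(np.float32), **kw)
            f.create_dataset("measurements",
                             data=self.measurements.astype(np.float32), **kw)
            f.create_dataset("labels", data=self.labels, track_times=False)
            f.create_dataset(
                "layouts", data=np.array(self.layouts, dtype=h5py.string_dtype()),
                track_times=False)
            f.create_dataset("seeds", data=self.seeds.astype(np.uint32),
                             track_times=False)
            f.attrs["n_rejected"] = self.n_rejected
            if self.spec is not None:
                f.attrs["spec"] = json.dumps(asdict(self.spec))

    @classmethod
    def load(cls, path) -> "Dataset":
        with h5py.File(path, "r") as f:
            spec = (DatasetSpec(**json.loads(f.attrs["spec"]))
                    if "spec" in f.attrs else None)
            return cls(
                images=f["images"][:],
                measurements=f["measurements"][:],
                labels=f["labels"][:],
                layouts=[s.decode() if isinstance(s, bytes) else s
                         for s in f["layouts"][:]],
                seeds=f["seeds"][:],
                spec=spec,
                n_rejected=int(f.attrs["n_rejected"]),
            )

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            images=self.images[idx],
            measurements=self.measurements[idx],
            labels=self.labels[idx],
            layouts=[self.layouts[i] for i in idx],
            seeds=self.seeds[idx],
            spec=self.spec,
            n_rejected=self.n_rejected,
        )

    @classmethod
    def concatenate(cls, parts: list["Dataset"]) -> "Dataset":
        return cls(
            images=np.concatenate([p.images for p in parts]),
            measurements=np.concatenate([p.measurements for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            layouts=[s for p in parts for s in p.layouts],
            seeds=np.concatenate([p.seeds for p in parts]),
            spec=parts[0].spec,
            n_rejected=sum(p.n_rejected for p in parts),
        )


def add_noise(
    C: np.ndarray,
    snr_db: float | None,
    rng: np.random.Generator | int,
    opposite_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Additive i.i.d. Gaussian noise calibrated on the opposite channels.

    One sigma for the whole vector: ``sigma = |C_opp| / 10^(snr_db/20)`` with
    ``|C_opp|`` the mean absolute value over the diametrically opposite pairs.
    ``snr_db=None`` (or +inf) disables noise.
    """
    C = np.asarray(C, dtype=float)
    if snr_db is None or np.isinf(snr_db):
        return C.copy()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    opp = opposite_idx if opposite_idx is not None else ORDERING.opposite_channels()
    c_opp = float(np.mean(np.abs(C[opp])))
    if c_opp <= 0.0:
        raise ValueError("opposite-channel reference level is non-positive")
    sigma = c_opp / 10.0 ** (snr_db / 20.0)
    return C + rng.normal(0.0, sigma, size=C.shape)


def normalize(C: np.ndarray, C_low: np.ndarray, C_high: np.ndarray) -> np.ndarray:
    """Two-reference per-channel affine normalization.

    ``(C - C_low) / (C_high - C_low)`` computed in the complex plane, then
    projected to its real part; exactly 0 for the uniform low scene, 1 for
    the uniform high scene, and linear in the permittivity vector (a midpoint
    scene lands on 0.5 on every channel).
    """
    denom = np.asarray(C_high) - np.asarray(C_low)
    if np.any(np.abs(denom) == 0.0):
        raise ValueError("zero denominator in normalization references")
    return np.real((np.asarray(C) - np.asarray(C_low)) / denom)


def reference_vectors(S: np.ndarray, image_n: int = 64):
    """Simulated calibration vectors (C_low, C_high) for a sensitivity matrix:
    uniform air scene and uniform background-tissue scene."""
    _, eps_low = phantom.rasterize(
        phantom.uniform_scene(phantom.TISSUES["air"]),
        phantom.GridSpec(image_n, image_n))
    _, eps_high = phantom.rasterize(
        phantom.uniform_scene(phantom.TISSUES["background"]),
        phantom.GridSpec(image_n, image_n))
    return S @ eps_low.ravel(), S @ eps_high.ravel()


def _sample_once(spec: DatasetSpec, rng: np.random.Generator, mesh_cfg,
                 s_cache: dict):
    """One accepted sample or an exception from the scene/layout draws.

    Normalization always uses the *rigid* (equidistant) layout's reference
    vectors: a wearable system is calibrated against the nominal sensor
    model, so electrode displacement perturbs the normalized measurements
    instead of being silently calibrated away.
    """
    layout, params, shifts = band.sample_layout(spec.level, rng)
    if None not in s_cache:
        rigid, _, _ = band.sample_layout("none", 0)
        S0 = sensitivity_for_layout(rigid, mesh_cfg)
        s_cache[None] = (S0, *reference_vectors(S0, spec.image_n))
    S0, C_low, C_high = s_cache[None]
    if spec.level == "none":
        S = S0  # every rigid sample shares the cached sensitivity matrix
    else:
        S = sensitivity_for_layout(layout, mesh_cfg)

    if spec.content == "thorax":
        scene = phantom.sample_thorax(rng)
        scene = phantom.assign_pathologies(scene, rng)
        labels = (scene.lung_labels["left"], scene.lung_labels["right"])
    else:
        scene = phantom.sample_random_ellipses(rng)
        labels = ("", "")
    cmap, eps_img = phantom.rasterize(
        scene, phantom.GridSpec(spec.image_n, spec.image_n))
    C = simulate_capacitance(S, eps_img.ravel())
    Cn = normalize(C, C_low, C_high)
    Cn = add_noise(Cn, spec.noise_snr_db, rng)
    meta = {
        "level": spec.level,
        "stretch": dict(zip(("a1", "b1", "a2", "b2"), params.as_tuple())),
        "global_shift": shifts["global"],
        "local_shifts": [float(v) for v in np.atleast_1d(shifts["local"])],
        "layout": layout.to_json_dict(),
    }
    return cmap.values, Cn, labels, json.dumps(meta)


def build_dataset(spec: DatasetSpec, progress: bool = False) -> Dataset:
    """Generate ``target_size`` samples (minus rejections) at the requested
    displacement level.  Each sample draws its own electrode layout; at
    ``level='none'`` all samples share the equidistant layout and its cached
    sensitivity matrix.  Deterministic under ``spec.seed``."""
    mesh_cfg = SensorMeshConfig(solver_n=spec.solver_n, image_n=spec.image_n)
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.generate_state(spec.target_size).astype(np.uint32)

    images, meas, labels, layouts, seeds = [], [], [], [], []
    n_rejected = 0
    s_cache: dict = {}
    for i in range(spec.target_size):
        rng = np.random.default_rng(int(child_seeds[i]))
        try:
            img, C, lab, meta = _sample_once(spec, rng, mesh_cfg, s_cache)
        except (phantom.RejectedSample, band.LayoutError):
            n_rejected += 1
            continue
        images.append(img)
        meas.append(C)
        labels.append(lab)
        layouts.append(meta)
        seeds.append(child_seeds[i])
        if progress and (i + 1) % 100 == 0:
            print(f"  {i + 1}/{spec.target_size} samples "
                  f"({n_rejected} rejected)", flush=True)
    return Dataset(
        images=np.asarray(images, dtype=np.float32),
        measurements=np.asarray(meas, dtype=np.float32),
        labels=np.array(labels, dtype="S20"),
        layouts=layouts,
        seeds=np.asarray(seeds, dtype=np.uint32),
        spec=spec,
        n_rejected=n_rejected,
    )


def train_test_split(dataset: Dataset, fraction: float, seed: int):
    """Seed-deterministic disjoint, exhaustive split into (train, validation).

    ``fraction`` is the training share.  Held-out *test* sets are always
    generated independently (different spec seeds), never split from training.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(dataset)
    perm = np.random.default_rng(seed).permutation(n)
    k = int(round(fraction * n))
    return dataset.subset(np.sort(perm[:k])), dataset.subset(np.sort(perm[k:]))
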