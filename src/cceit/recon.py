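"""Measurement-conditioned adversarial reconstructor (992 -> 64x64).

The generator is U-Net shaped: a learned affine projection turns the
992-element capacitance vector into a 64x64 single-channel plane, six strided
convolutional blocks (conv + optional batch-norm + leaky-ReLU) contract it to
1x1, six transposed-convolution blocks (deconv + batch-norm + 50% dropout on
the first three + leaky-ReLU) expand it back with skip concatenations, and a
final convolution reduces the last block's channels to one.  Dropout stays
active at inference, standing in for the latent noise vector of a classic
conditional GAN (Pix2Pix convention).

The discriminator sees two inputs — the image and the measurement vector
(projected to a second 64x64 plane) — and outputs patch probabilities through
a sigmoid.  Training alternates a generator step (discriminator frozen,
target 1) and a discriminator step (generator frozen; fake target 0, real
target 1); the generator loss is

    L = BCE(D(G(x)), 1) + 100 * L1(G(x), y) + 100 * L2(G(x), y).

Both optimizers are Adam with cosine-annealing warm restarts stepped per
iteration; training stops early when the monitored validation loss stalls.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataset import Dataset, train_test_split

__all__ = [
    "Discriminator",
    "Generator",
    "TrainConfig",
    "generator_loss",
    "reconstruct",
    "train",
    "train_step",
]

MEAS_LEN = 992
IMG_N = 64


@dataclass
class TrainConfig:
    """Adversarial training hyperparameters (generator/discriminator)."""

    lr_gen: float = 1e-3
    lr_disc: float = 1e-6
    weight_decay: float = 0.1
    beta1: float = 0.5
    beta2: float = 0.999
    T0: int = 1000
    T_mult: int = 2
    max_epochs: int = 150
    patience: int = 30
    improvement_tol: float = 1e-3  # relative val-loss improvement that counts
    batch_size: int = 64
    base_width: int = 64
    val_fraction: float = 0.1
    seed: int = 0


class Generator:
    """U-Net generator: 992-vector -> 64x64 image."""

    def __init__(self, base_width: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        b = base_width
        self.base_width = b
        self.proj = nn.Dense(MEAS_LEN, IMG_N * IMG_N, rng)
        enc_w = [b, 2 * b, 4 * b, 8 * b, 8 * b, 8 * b]
        dec_w = [8 * b, 8 * b, 4 * b, 2 * b, b, b]
        self.enc = []
        cin = 1
        for i, w in enumerate(enc_w):
            block = {"conv": nn.Conv2d(cin, w, rng),
                     "bn": nn.BatchNorm2d(w) if i > 0 else None,
                     "act": nn.LeakyReLU(0.2)}
            self.enc.append(block)
            cin = w
        self.dec = []
        cin = enc_w[-1]
        for i, w in enumerate(dec_w):
            block = {"deconv": nn.ConvTranspose2d(cin, w, rng),
                     "bn": nn.BatchNorm2d(w),
                     "drop": nn.Dropout(0.5, seed + 101 + i) if i < 3 else None,
                     "act": nn.LeakyReLU(0.2)}
            self.dec.append(block)
            # next input: this output concatenated with the mirrored skip
            cin = w + (enc_w[4 - i] if i < 5 else 0)
        self.final = nn.Conv2d(dec_w[-1], 1, rng, k=3, stride=1, pad=1)
        self._cache = None
        self.training = True

    # -- plumbing ------------------------------------------------------------
    def _modules(self):
        mods = [self.proj]
        for blk in self.enc + self.dec:
            mods.extend(m for m in blk.values() if m is not None)
        mods.append(self.final)
        return mods

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def zero_grad(self):
        for m in self._modules():
            m.zero_grad()

    def set_training(self, flag: bool):
        self.training = flag
        for m in self._modules():
            m.set_training(flag)

    def reseed_dropout(self, seed: int):
        for i, blk in enumerate(self.dec):
            if blk["drop"] is not None:
                blk["drop"].reseed(seed + 101 + i)

    def state_dict(self) -> dict:
        state = {}
        for i, m in enumerate(self._modules()):
            for j, p in enumerate(m.params()):
                state[f"p{i}_{j}"] = p.value.copy()
            if isinstance(m, nn.BatchNorm2d):
                state[f"rm{i}"] = m.running_mean.copy()
                state[f"rv{i}"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        for i, m in enumerate(self._modules()):
            for j, p in enumerate(m.params()):
                p.value[...] = state[f"p{i}_{j}"]
            if isinstance(m, nn.BatchNorm2d):
                m.running_mean[...] = state[f"rm{i}"]
                m.running_var[...] = state[f"rv{i}"]

    # -- computation ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != MEAS_LEN:
            raise ValueError(f"measurement vector length {x.shape[1]} != {MEAS_LEN}")
        h = self.proj.forward(x).reshape(-1, 1, IMG_N, IMG_N)
        skips = []
        for blk in self.enc:
            h = blk["conv"].forward(h)
            if blk["bn"] is not None:
                h = blk["bn"].forward(h)
            h = blk["act"].forward(h)
            skips.append(h)
        splits = []
        for i, blk in enumerate(self.dec):
            h = blk["deconv"].forward(h)
            h = blk["bn"].forward(h)
            if blk["drop"] is not None:
                h = blk["drop"].forward(h)
            h = blk["act"].forward(h)
            if i < 5:
                skip = skips[4 - i]
                splits.append(h.shape[1])
                h = np.concatenate([h, skip], axis=1)
        y = self.final.forward(h)
        self._cache = splits
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        splits = self._cache
        dh = self.final.backward(dy)
        dskips = [None] * 6
        for i in reversed(range(6)):
            blk = self.dec[i]
            if i < 5:
                c = splits[i]
                dh, dskip = dh[:, :c], dh[:, c:]
                dskips[4 - i] = dskip
            dh = blk["act"].backward(dh)
            if blk["drop"] is not None:
                dh = blk["drop"].backward(dh)
            dh = blk["bn"].backward(dh)
            dh = blk["deconv"].backward(dh)
        for i in reversed(range(6)):
            blk = self.enc[i]
            if dskips[i] is not None:
                dh = dh + dskips[i]
            dh = blk["act"].backward(dh)
            if blk["bn"] is not None:
                dh = blk["bn"].backward(dh)
            dh = blk["conv"].backward(dh)
        dx = self.proj.backward(dh.reshape(dh.shape[0], -1))
        return dx


class Discriminator:
    """Conditioned patch discriminator: (image, measurements) -> (0, 1)."""

    def __init__(self, base_width: int = 64, seed: int = 1):
        rng = np.random.default_rng(seed)
        b = base_width
        self.proj = nn.Dense(MEAS_LEN, IMG_N * IMG_N, rng)
        self.blocks = []
        widths = [b, 2 * b, 4 * b]
        cin = 2  # image plane + projected measurement plane
        for i, w in enumerate(widths):
            self.blocks.append({"conv": nn.Conv2d(cin, w, rng),
                                "bn": nn.BatchNorm2d(w) if i > 0 else None,
                                "act": nn.LeakyReLU(0.2)})
            cin = w
        self.mid_conv = nn.Conv2d(cin, cin, rng, k=4, stride=1, pad=1)
        self.mid_bn = nn.BatchNorm2d(cin)
        self.mid_act = nn.LeakyReLU(0.2)
        self.out_conv = nn.Conv2d(cin, 1, rng, k=4, stride=1, pad=1)
        self.sigmoid = nn.Sigmoid()
        self.training = True

    def _modules(self):
        mods = [self.proj]
        for blk in self.blocks:
            mods.extend(m for m in blk.values() if m is not None)
        mods.extend([self.mid_conv, self.mid_bn, self.mid_act,
                     self.out_conv, self.sigmoid])
        return mods

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def zero_grad(self):
        for m in self._modules():
            m.zero_grad()

    def set_training(self, flag: bool):
        self.training = flag
        for m in self._modules():
            m.set_training(flag)

    def forward(self, img: np.ndarray, meas: np.ndarray) -> np.ndarray:
        meas = np.atleast_2d(np.asarray(meas, dtype=np.float64))
        plane = self.proj.forward(meas).reshape(-1, 1, IMG_N, IMG_N)
        h = np.concatenate([img, plane], axis=1)
        for blk in self.blocks:
            h = blk["conv"].forward(h)
            if blk["bn"] is not None:
                h = blk["bn"].forward(h)
            h = blk["act"].forward(h)
        h = self.mid_act.forward(self.mid_bn.forward(self.mid_conv.forward(h)))
        return self.sigmoid.forward(self.out_conv.forward(h))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Returns the gradient with respect to the *image* input (the path
        the generator needs); the measurement path ends at the projection."""
        dh = self.out_conv.backward(self.sigmoid.backward(dout))
        dh = self.mid_conv.backward(self.mid_bn.backward(self.mid_act.backward(dh)))
        for blk in reversed(self.blocks):
            dh = blk["act"].backward(dh)
            if blk["bn"] is not None:
                dh = blk["bn"].backward(dh)
            dh = blk["conv"].backward(dh)
        dimg, dplane = dh[:, :-1], dh[:, -1:]
        self.proj.backward(dplane.reshape(dplane.shape[0], -1))
        return dimg


def generator_loss(D_out: np.ndarray, G_out: np.ndarray, y: np.ndarray):
    """Composite generator loss BCE(D(G(x)), 1) + 100 L1 + 100 L2.

    Returns ``(total, parts)`` with parts = dict(bce=..., l1=..., l2=...).
    Raises if ``D_out`` is not strictly inside (0, 1).
    """
    bce, _ = nn.bce_loss(D_out, 1.0)
    diff = G_out - y
    l1 = float(np.mean(np.abs(diff)))
    l2 = float(np.mean(diff * diff))
    return bce + 100.0 * l1 + 100.0 * l2, {"bce": bce, "l1": l1, "l2": l2}


def train_step(batch, gen: Generator, disc: Discriminator,
               opt_g: nn.Adam, opt_d: nn.Adam) -> dict:
    """One alternating update: generator step (discriminator frozen, target 1)
    then discriminator step (generator frozen; fake 0, real 1)."""
    meas, imgs = batch
    imgs = imgs.reshape(-1, 1, IMG_N, IMG_N).astype(np.float64)

    # --- generator step ---
    gen.zero_grad()
    disc.zero_grad()
    fake = gen.forward(meas)
    d_fake = disc.forward(fake, meas)
    loss_g, parts = generator_loss(d_fake, fake, imgs)
    _, d_bce = nn.bce_loss(d_fake, 1.0)
    dimg = disc.backward(d_bce)  # grads reach disc params but are discarded
    diff = fake - imgs
    dimg = dimg + 100.0 * np.sign(diff) / diff.size + 200.0 * diff / diff.size
    gen.backward(dimg)
    opt_g.step()
    disc.zero_grad()  # frozen discriminator: accumulated grads dropped

    # --- discriminator step ---
    fake = gen.forward(meas)  # generator frozen: no generator backward
    d_fake = disc.forward(fake, meas)
    bce_f, dpf = nn.bce_loss(d_fake, 0.0)
    disc.backward(0.5 * dpf)
    d_real = disc.forward(imgs, meas)
    bce_r, dpr = nn.bce_loss(d_real, 1.0)
    disc.backward(0.5 * dpr)
    opt_d.step()
    loss_d = 0.5 * (bce_f + bce_r)
    return {"loss_g": float(loss_g), "loss_d": float(loss_d), **parts}


def _validation_loss(gen: Generator, disc: Discriminator, meas, imgs,
                     batch_size: int, seed: int) -> float:
    """Monitored quantity for early stopping: full generator loss on the
    validation split, batch-statistics forward, dropout reseeded so the
    value is comparable across epochs."""
    gen.reseed_dropout(seed)
    total, nb = 0.0, 0
    for i in range(0, len(meas), batch_size):
        m = meas[i:i + batch_size]
        y = imgs[i:i + batch_size].reshape(-1, 1, IMG_N, IMG_N)
        fake = gen.forward(m)
        d_out = disc.forward(fake, m)
        loss, _ = generator_loss(d_out, fake, y)
        total += loss
        nb += 1
    return total / max(nb, 1)


def train(dataset: Dataset, cfg: TrainConfig | None = None,
          verbose: bool = False):
    """Train the reconstructor; returns ``(generator, history)``.

    Runs at most ``max_epochs`` epochs and stops early once the validation
    loss has not improved by a relative ``improvement_tol`` for ``patience``
    consecutive epochs; the weights with the lowest validation loss are
    restored before returning.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    tr, va = train_test_split(dataset, 1.0 - cfg.val_fraction, cfg.seed)
    gen = Generator(cfg.base_width, seed=cfg.seed)
    disc = Discriminator(cfg.base_width, seed=cfg.seed + 1)
    opt_g = nn.Adam(gen.params(), cfg.lr_gen, (cfg.beta1, cfg.beta2),
                    cfg.weight_decay)
    opt_d = nn.Adam(disc.params(), cfg.lr_disc, (cfg.beta1, cfg.beta2),
                    cfg.weight_decay)
    sched_g = nn.CosineAnnealingWarmRestarts(opt_g, cfg.T0, cfg.T_mult)
    sched_d = nn.CosineAnnealingWarmRestarts(opt_d, cfg.T0, cfg.T_mult)

    rng = np.random.default_rng(cfg.seed + 7)
    meas_tr = tr.measurements.astype(np.float64)
    imgs_tr = tr.images.astype(np.float64)
    meas_va = va.measurements.astype(np.float64)
    imgs_va = va.images.astype(np.float64)

    history = {"train_g": [], "train_d": [], "val": [], "lr_g": []}
    best = np.inf
    best_state = gen.state_dict()
    stall = 0
    for epoch in range(cfg.max_epochs):
        t0 = time.time()
        order = rng.permutation(len(meas_tr))
        eg, ed, nb = 0.0, 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            logs = train_step((meas_tr[sel], imgs_tr[sel]), gen, disc,
                              opt_g, opt_d)
            if not np.isfinite(logs["loss_g"]):
                raise RuntimeError(
                    f"non-finite generator loss at epoch {epoch}: {logs}")
            sched_g.step()
            sched_d.step()
            eg += logs["loss_g"]
            ed += logs["loss_d"]
            nb += 1
        val = _validation_loss(gen, disc, meas_va, imgs_va, cfg.batch_size,
                               cfg.seed)
        history["train_g"].append(eg / nb)
        history["train_d"].append(ed / nb)
        history["val"].append(val)
        history["lr_g"].append(float(sched_g.lr))
        if verbose:
            print(f"epoch {epoch:3d}  G {eg / nb:8.4f}  D {ed / nb:6.4f}  "
                  f"val {val:8.4f}  ({time.time() - t0:.1f}s)", flush=True)
        if val < best * (1.0 - cfg.improvement_tol):
            best = val
            best_state = gen.state_dict()
            stall = 0
        else:
            stall += 1
            if stall >= max(cfg.patience, 1):
                break
    gen.load_state_dict(best_state)
    history["best_val"] = float(best)
    return gen, history


def reconstruct(gen: Generator, measurements: np.ndarray,
                seed: int = 0, batch_size: int = 64) -> np.ndarray:
    """Reconstruct conductivity maps from normalized 992-vectors.

    Deterministic given weights and ``seed`` (dropout stays active, with its
    rng reseeded here); batch normalization uses running statistics.  A 1-D
    input yields a single 64x64 map, a 2-D input one map per row.
    """
    x = np.asarray(measurements, dtype=np.float64)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != MEAS_LEN:
        raise ValueError(f"measurement vector length {x.shape[1]} != {MEAS_LEN}")
    gen.set_training(False)
    gen.reseed_dropout(seed)
    outs = [gen.forward(x[i:i + batch_size])[:, 0]
            for i in range(0, len(x), batch_size)]
    gen.set_training(True)
    out = np.concatenate(outs)
    return out[0] if single else out
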