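"""Desk-scale end-to-end training of the coarse-to-fine pipeline on phantoms.

The network is optimized with the weighted two-stage objective
alpha * L_KsPC + (1 - alpha) * L_CNN (alpha = 0.7), both stages using the
F-loss with beta = 2. The CNN loss compares the coarse probability map with
the truth. The KsPC loss compares a *soft* kernel-density segmentation with
the truth: the hard level set {f_hat > lambda} is not differentiable, so
during training it is relaxed to sigmoid((f_hat - lambda) / T) with a
temperature proportional to the density peak; the quantile threshold lambda
and the bounding box are treated as constants within a step (both are
piecewise-constant functions of the weights). The gradient reaches the
bandwidth head analytically through the Gaussian kernel taps.

Optimizer: Adam, batch size 1, cosine-annealed learning rate from 1e-3 down
to 1e-5 cycled every 10 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from ..coarse_to_fine import CoarseOutput, aggregate_bandwidth, bounding_box
from ..grid import Bandwidth, EmptyCoarseMaskError, SegmentationMask, VolumetricImage
from ..kde import kernel_taps
from ..metrics import f_loss, final_loss
from .layers import _sigmoid
from .litese import LiteSENet

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


# -- inference ---------------------------------------------------------------

def _pad_to_multiple(values: np.ndarray, multiple: int):
    pads = [(0, (-n) % multiple) for n in values.shape]
    return np.pad(values, pads), pads


def predict_coarse(
    model: LiteSENet, image: VolumetricImage, prob_cutoff: float = 0.5,
    quantile_threshold: float = 0.10,
) -> CoarseOutput:
    """Run the backbone on an image and package the coarse-phase outputs.

    The input is max-normalized, zero-padded to a multiple of the network's
    total downsampling factor, and the outputs cropped back. Raises
    :class:`EmptyCoarseMaskError` when no voxel clears ``prob_cutoff`` —
    the caller decides the fallback.
    """
    vmax = image.values.max()
    if vmax <= 0:
        raise EmptyCoarseMaskError("all-zero image cannot be segmented")
    x, _ = _pad_to_multiple(image.values / vmax, model.DOWNSAMPLE_FACTOR)
    probs, bw = model.forward(x)
    sl = tuple(slice(0, n) for n in image.dims)
    probs = probs[sl]
    mask = SegmentationMask(
        indicator=probs > prob_cutoff, spacing=image.spacing, origin=image.origin
    )
    if mask.is_empty():
        raise EmptyCoarseMaskError(
            f"coarse prediction has no voxel above prob_cutoff={prob_cutoff}"
        )
    bw_vol = np.moveaxis(bw[(slice(None),) + sl], 0, -1) if bw is not None else None
    bandwidth = aggregate_bandwidth(bw_vol) if bw_vol is not None else Bandwidth(2, 2, 2)
    return CoarseOutput(
        coarse_mask=mask,
        bandwidth=bandwidth,
        bandwidth_volume=bw_vol,
        quantile_threshold=quantile_threshold,
    )


# -- differentiable KsPC stage ----------------------------------------------

def _soft_kspc(crop_suv, spacing, h, coarse_crop, robust_fraction, truncation_radius,
               temperature_fraction, lam=None, temperature=None):
    """Soft kernel-density segmentation of a cropped volume.

    ``lam`` and ``temperature`` may be pinned externally (both are treated as
    constants by the gradient). Returns (soft mask, cache for the h-gradient).
    """
    tot = crop_suv.sum()
    taps = [kernel_taps(spacing[d], h[d], truncation_radius) for d in range(3)]
    # axis-wise correlations; keep the two-axis partials for the h-gradient
    c01 = correlate1d(correlate1d(crop_suv, taps[0], axis=0, mode="constant"),
                      taps[1], axis=1, mode="constant")
    c02 = correlate1d(correlate1d(crop_suv, taps[0], axis=0, mode="constant"),
                      taps[2], axis=2, mode="constant")
    c12 = correlate1d(correlate1d(crop_suv, taps[1], axis=1, mode="constant"),
                      taps[2], axis=2, mode="constant")
    raw = correlate1d(c01, taps[2], axis=2, mode="constant")
    norm = h[0] * h[1] * h[2] * tot
    f = raw / norm
    if lam is None:
        vals = np.sort(f[coarse_crop])
        rank = max(int(np.ceil(robust_fraction * vals.size)) - 1, 0)
        lam = float(vals[rank])
    T = temperature if temperature is not None else max(
        temperature_fraction * float(f.max()), 1e-30
    )
    soft = _sigmoid((f - lam) / T)
    cache = dict(partials=(c12, c02, c01), f=f, norm=norm, taps=taps, h=h,
                 spacing=spacing, T=T, soft=soft,
                 truncation_radius=truncation_radius)
    return soft, cache


def _soft_kspc_h_gradient(dsoft, cache):
    """Gradient of the loss w.r.t. the bandwidth vector h (3,)."""
    soft, T, f = cache["soft"], cache["T"], cache["f"]
    g = dsoft * soft * (1.0 - soft) / T  # dL/df
    h, spacing, norm = cache["h"], cache["spacing"], cache["norm"]
    dh = np.zeros(3)
    gf = float((g * f).sum())
    for d in range(3):
        radius = (len(cache["taps"][d]) - 1) // 2
        offsets = np.arange(-radius, radius + 1)
        u = offsets * spacing[d] / h[d]
        dtaps = _INV_SQRT_2PI * np.exp(-0.5 * u * u) * u * u / h[d]
        deriv = correlate1d(cache["partials"][d], dtaps, axis=d, mode="constant")
        dh[d] = float((g * deriv).sum()) / norm - gf / h[d]
    return dh


def _f_loss_grad(y, y_hat, beta=2.0, eps=1e-8):
    b2 = beta * beta
    num = (1.0 + b2) * float((y_hat * y).sum())
    den = float(y_hat.sum()) + b2 * float(y.sum()) + eps
    return -((1.0 + b2) * y * den - num) / (den * den)


# -- optimizer ---------------------------------------------------------------

class Adam:
    def __init__(self, model: LiteSENet, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.state = {}
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, layer, pname, arr in self.model.parameters():
            g = layer.grads[pname]
            m, v = self.state.setdefault(name, (np.zeros_like(arr), np.zeros_like(arr)))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self.state[name] = (m, v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            arr -= lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_annealed_lr(epoch: int, lr_max=1e-3, lr_min=1e-5, cycle=10) -> float:
    """Cosine-annealed learning rate, restarting every ``cycle`` epochs."""
    phase = (epoch % cycle) / cycle
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * phase))


# -- training loop -----------------------------------------------------------

@dataclass
class TrainingLog:
    epoch_losses: list = field(default_factory=list)  # mean final loss per epoch
    epoch_cnn_losses: list = field(default_factory=list)
    epoch_kspc_losses: list = field(default_factory=list)

    def __len__(self):
        return len(self.epoch_losses)


def train_smoke(
    model: LiteSENet,
    dataset,
    epochs: int = 20,
    seed: int = 0,
    alpha: float = 0.7,
    beta: float = 2.0,
    robust_fraction: float = 0.10,
    margin_voxels: int = 4,
    truncation_radius: float = 4.0,
    temperature_fraction: float = 0.05,
) -> TrainingLog:
    """Train the pipeline end-to-end on (image, truth) phantom pairs.

    Deterministic for a fixed model seed and dataset; ``seed`` only sets the
    (fixed) sample visiting order. Returns per-epoch mean losses.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    order = np.random.default_rng(seed).permutation(len(dataset))
    opt = Adam(model)
    log = TrainingLog()
    for epoch in range(epochs):
        lr = cosine_annealed_lr(epoch)
        tot, tot_cnn, tot_kspc = 0.0, 0.0, 0.0
        for idx in order:
            image, truth = dataset[idx]
            y = truth.indicator.astype(float)
            x = image.values / image.values.max()
            probs, bw = model.forward(x)

            loss_cnn = f_loss(y, probs, beta=beta)
            dprobs = (1.0 - alpha) * _f_loss_grad(y, probs, beta=beta)

            coarse = probs > 0.5
            if not coarse.any():
                coarse = probs >= probs.max()
            mask = SegmentationMask(coarse, spacing=image.spacing, origin=image.origin)
            box = bounding_box(mask, margin_voxels)
            sl = box.slices
            h = bw.reshape(3, -1).mean(axis=1)
            soft, cache = _soft_kspc(
                image.values[sl], image.spacing, h, coarse[sl],
                robust_fraction, truncation_radius, temperature_fraction,
            )
            soft_full = np.zeros_like(y)
            soft_full[sl] = soft
            loss_kspc = f_loss(y, soft_full, beta=beta)
            dsoft_full = alpha * _f_loss_grad(y, soft_full, beta=beta)
            dh = _soft_kspc_h_gradient(dsoft_full[sl], cache)
            # h is the spatial mean of the (post-softplus) bandwidth volume
            dbw = np.broadcast_to(
                (dh / bw[0].size)[:, None, None, None], bw.shape
            ).copy()

            model.zero_grad()
            model.backward(dprobs, dbw)
            opt.step(lr)

            tot += final_loss(loss_kspc, loss_cnn, alpha)
            tot_cnn += loss_cnn
            tot_kspc += loss_kspc
        n = len(dataset)
        log.epoch_losses.append(tot / n)
        log.epoch_cnn_losses.append(tot_cnn / n)
        log.epoch_kspc_losses.append(tot_kspc / n)
    return log
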