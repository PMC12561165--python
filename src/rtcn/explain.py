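"""Grad-CAM attribution over time–frequency inputs.

The gradient of the target-class score w.r.t. a chosen layer's activations is
spatially averaged into per-channel importance weights; the rectified weighted
activation sum, bilinearly upsampled to the input size and max-normalized, is
the relevance heatmap.  Registered layers are the last backbone stage
(``conv5``) and the last encoder layer's token grid (``tokens``), whose 49
token relevances are reshaped to 7 x 7 before upsampling.
"""
from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stransform import TimeFreqImage, resize_bilinear


@dataclass
class Heatmap:
    values: np.ndarray       # >= 0, max 1 unless all-zero
    target_class: int
    source_layer: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("heatmap must be non-negative")


def grad_cam(model, image: np.ndarray, target_class: int,
             layer: str = "conv5") -> Heatmap:
    """Gradient-weighted class activation map for one input image.

    ``image`` is (3, side, side); ``layer`` must be registered on the model
    (unknown names raise an error listing the registered layers).
    """
    layers = model.registered_layers()
    if layer not in layers:
        raise KeyError(f"unknown layer {layer!r}; registered: {sorted(layers)}")
    module = layers[layer]

    model.eval()
    x = np.asarray(image, dtype=float)[None]
    logits = model(x)
    g = np.zeros_like(logits)
    g[0, int(target_class)] = 1.0
    model.zero_grad()
    model.backward(g)

    act, grad = module._out, module._out_grad
    if act.ndim == 3:  # token grid (N, n_tokens + 1, d): drop the class token
        side = int(round(np.sqrt(act.shape[1] - 1)))
        act = act[:, 1:, :].transpose(0, 2, 1).reshape(1, -1, side, side)
        grad = grad[:, 1:, :].transpose(0, 2, 1).reshape(1, -1, side, side)
    weights = grad[0].mean(axis=(1, 2))                      # (C,)
    cam = np.maximum((weights[:, None, None] * act[0]).sum(axis=0), 0.0)
    cam = resize_bilinear(cam, x.shape[2], x.shape[3])
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(cam, int(target_class), layer)


def band_energy_fraction(heatmap: Heatmap, freq_axis_hz: np.ndarray,
                         band_hz: tuple) -> float:
    """Fraction of total heatmap mass inside a frequency band.

    Heatmap rows are mapped linearly onto ``freq_axis_hz`` (row 0 = lowest
    frequency).
    """
    total = heatmap.values.sum()
    if total == 0:
        return 0.0
    freqs = np.asarray(freq_axis_hz, dtype=float)
    row_freq = np.interp(np.linspace(0, 1, heatmap.values.shape[0]),
                         np.linspace(0, 1, freqs.size), freqs)
    mask = (row_freq >= band_hz[0]) & (row_freq <= band_hz[1])
    return float(heatmap.values[mask].sum() / total)


def overlay(heatmap: Heatmap, image: TimeFreqImage, path) -> str:
    """Render the heatmap over the time–frequency magnitude and save a figure.

    Time is on x (seconds), frequency on y (Hz); relevance is drawn with an
    alpha channel proportional to the heatmap so a zero heatmap reproduces the
    base rendering.
    """
    if heatmap.values.size == 0 or image.values.size == 0:
        raise ValueError("empty heatmap or image")
    hm = resize_bilinear(heatmap.values, *image.values.shape)
    extent = (float(image.time_axis_s[0]), float(image.time_axis_s[-1]),
              float(image.freq_axis_hz[0]), float(image.freq_axis_hz[-1]))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(image.values, origin="lower", aspect="auto", extent=extent,
              cmap="gray")
    ax.imshow(hm, origin="lower", aspect="auto", extent=extent, cmap="jet",
              alpha=np.clip(0.6 * hm, 0.0, 1.0), vmin=0.0, vmax=1.0)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("frequency [Hz]")
    ax.set_title(f"Grad-CAM ({heatmap.source_layer}, class {heatmap.target_class})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return str(path)
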