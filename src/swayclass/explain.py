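"""Grad-CAM attribution on the spectrogram classifier.

Gradient-weighted class activation maps are computed at the last
convolutional layer: per feature channel, the gradient of the target
class score is averaged over space to give a channel weight, the
weighted activation sum is rectified, and the map is bilinearly
upsampled to the input size.  Class-averaged maps over a validation
batch (grouped by *decoded*, i.e. predicted, class) are then summarized
as the fraction of heatmap mass lying above a frequency threshold —
quantifying where on the frequency axis the model looks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["ClassHeatmap", "BandAttribution", "gradcam", "class_average",
           "band_attribution", "time_consistency"]


@dataclass
class ClassHeatmap:
    """Average Grad-CAM heatmap of samples decoded as one class.

    ``weights`` is nonnegative with the same axes semantics as the input
    spectrogram samples (rows = frequency bands, descending; columns =
    time).  ``n_averaged == 0`` flags an empty (undefined) map.
    """

    weights: np.ndarray
    decoded_class: str
    n_averaged: int
    freqs: np.ndarray = None

    @property
    def empty(self) -> bool:
        return self.n_averaged == 0


@dataclass(frozen=True)
class BandAttribution:
    """Share of heatmap mass at frequencies above ``threshold`` Hz; NaN
    (``defined=False``) when the heatmap has zero total mass."""

    fraction_above: float
    threshold: float
    defined: bool = True


def _gradcam_batch(core, x, target_class):
    """Raw per-sample Grad-CAM maps at the last conv layer, upsampled to
    the input size.  Returns (maps, all_zero_flags)."""
    act, grad, _ = core.last_conv_activations_and_grads(x, target_class)
    alpha = grad.mean(axis=(1, 2))                      # (n, channels)
    cam = np.einsum("nhwc,nc->nhw", act, alpha)
    np.maximum(cam, 0.0, out=cam)                       # rectification
    h, w = core.input_hw
    zoom = (1.0, h / cam.shape[1], w / cam.shape[2])
    maps = ndimage.zoom(cam, zoom, order=1, grid_mode=True, mode="nearest")
    np.maximum(maps, 0.0, out=maps)  # bilinear can ring slightly below 0
    flags = maps.reshape(len(maps), -1).sum(axis=1) == 0
    return maps, flags


def gradcam(model, sample, target_class):
    """Grad-CAM heatmap of one (normalized) sample for ``target_class``
    (0 = HC, 1 = PD).  All-zero gradients yield an all-zero map, flagged
    via the returned ``(heatmap, is_zero)`` tuple."""
    x = np.asarray(sample, dtype=np.float32)[None, ...]
    maps, flags = _gradcam_batch(model.core, x, target_class)
    return maps[0], bool(flags[0])


def class_average(model, val_samples, freqs=None, class_names=("HC", "PD")):
    """Average Grad-CAM maps of a validation batch per *decoded* class.

    Each sample contributes to the heatmap of the class the model assigns
    it (not its true label); maps are averaged unnormalized.  A class with
    no decoded samples yields an empty, flagged heatmap.
    """
    x = np.asarray(val_samples, dtype=np.float32)
    if len(x) == 0:
        raise ValueError("empty validation batch")
    decoded = model.predict(x)
    out = {}
    for cls_idx, cls_name in enumerate(class_names):
        mask = decoded == cls_idx
        if not mask.any():
            out[cls_name] = ClassHeatmap(
                weights=np.zeros(model.core.input_hw), decoded_class=cls_name,
                n_averaged=0, freqs=freqs,
            )
            continue
        maps, _ = _gradcam_batch(model.core, x[mask], cls_idx)
        out[cls_name] = ClassHeatmap(
            weights=maps.mean(axis=0), decoded_class=cls_name,
            n_averaged=int(mask.sum()), freqs=freqs,
        )
    return out


def band_attribution(heatmap, freqs=None, threshold=1.0) -> BandAttribution:
    """Fraction of heatmap mass at frequency rows above ``threshold`` Hz."""
    if isinstance(heatmap, ClassHeatmap):
        weights = heatmap.weights
        freqs = heatmap.freqs if freqs is None else freqs
    else:
        weights = np.asarray(heatmap)
    if freqs is None:
        raise ValueError("frequency axis required for band attribution")
    freqs = np.asarray(freqs)
    if len(freqs) != weights.shape[0]:
        raise ValueError("frequency axis length must match heatmap rows")
    total = float(weights.sum())
    if total == 0:
        return BandAttribution(np.nan, threshold, defined=False)
    above = float(weights[freqs > threshold].sum())
    return BandAttribution(above / total, threshold)


def time_consistency(heatmap) -> float:
    """Coefficient of variation of column (time) means — small values mean
    the attribution is stationary over the segment."""
    weights = heatmap.weights if isinstance(heatmap, ClassHeatmap) else heatmap
    col = np.asarray(weights).mean(axis=0)
    m = col.mean()
    if m == 0:
        return np.nan
    return float(col.std() / m)
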