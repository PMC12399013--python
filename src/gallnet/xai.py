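"""From-scratch Grad-CAM and LIME explainers.

Grad-CAM weights a convolutional stage's activation maps A_k by the
spatial mean of the gradient of the target class *logit* (pre-softmax —
the standard, better-conditioned choice) with respect to them, rectifies
the weighted sum, upsamples bilinearly to the input resolution and
min-max normalizes to [0, 1].

LIME segments the image into superpixels, draws random binary keep/drop
masks over them, replaces dropped regions by a baseline intensity (the
image mean by default — black is a meaningful, anechoic signal in
ultrasound), queries the model on the perturbed images and fits a
weighted ridge regression of the class probability on the mask vectors.
Positive-coefficient regions among the top-k by magnitude are rendered
green (supporting the prediction), negative ones red (opposing it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy import ndimage
from skimage.transform import resize

from .model_core import Model

__all__ = [
    "ExplainerConfig",
    "GradCAMResult",
    "LIMEResult",
    "gradcam",
    "segment_superpixels",
    "lime_explain",
    "render_overlay",
]


@dataclass(frozen=True)
class ExplainerConfig:
    gradcam_layer: str | None = None   # default: deepest conv stage
    superpixels: int = 50
    samples: int = 1000
    kernel_width: float = 0.25
    ridge: float = 1e-3
    top_k: int = 5
    baseline: float | None = None      # None -> image mean intensity
    #: spatial/intensity trade-off of the superpixel clustering
    compactness: float = 3.0

    def __post_init__(self):
        if self.superpixels < 2 or self.samples < 1 or self.top_k < 1:
            raise ValueError("counts must be positive (superpixels >= 2)")
        if self.kernel_width <= 0 or self.ridge < 0:
            raise ValueError("kernel width must be positive, ridge nonnegative")


@dataclass
class GradCAMResult:
    heatmap: np.ndarray        # input resolution, [0, 1]
    raw: np.ndarray            # layer resolution, nonnegative (post-ReLU)
    layer_name: str
    class_index: int


@dataclass
class LIMEResult:
    segments: np.ndarray       # superpixel label map
    coefficients: np.ndarray   # one per superpixel
    intercept: float
    top_regions: list[int]
    positive_mask: np.ndarray  # union of top-k regions with coef > 0
    negative_mask: np.ndarray  # union of top-k regions with coef < 0
    seed: int


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def gradcam(model: Model, image: np.ndarray, class_index: int,
            layer_name: str | None = None) -> GradCAMResult:
    """Grad-CAM saliency for one image and class.

    Channel weights are alpha_k = mean_{i,j} d logit_c / d A_k[i, j]; the
    raw map is ReLU(sum_k alpha_k A_k), upsampled and normalized.
    """
    if layer_name is None:
        layer_name = model.conv_stage_names[-1]
    image = np.asarray(image)
    acts, grads, _ = model.activation_and_gradient(image, class_index,
                                                   layer_name)
    a, g = acts[0], grads[0]                      # (h, w, channels)
    alpha = g.mean(axis=(0, 1))                   # spatial mean per channel
    raw = np.maximum((a * alpha).sum(axis=-1), 0.0)
    size = model.config.input_size
    up = resize(raw.astype(float), (size, size), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    return GradCAMResult(heatmap=_minmax(up), raw=raw,
                         layer_name=layer_name, class_index=class_index)


def _kmeans_superpixels(image: np.ndarray, target: int,
                        compactness: float, iterations: int = 10) -> np.ndarray:
    h, w = image.shape
    # cluster on a lightly smoothed intensity so single-pixel speckle does
    # not fragment the regions
    image = ndimage.gaussian_filter(image, 1.5)
    rows = max(1, int(round(np.sqrt(target * h / w))))
    cols = max(1, int(round(target / rows)))
    spacing = np.sqrt(h * w / (rows * cols))
    cy = (np.arange(rows) + 0.5) * h / rows
    cx = (np.arange(cols) + 0.5) * w / cols
    gy, gx = np.meshgrid(cy, cx, indexing="ij")
    yy, xx = np.mgrid[0:h, 0:w]
    feats = np.stack([yy.ravel() / spacing, xx.ravel() / spacing,
                      compactness * image.ravel()], axis=1)
    centers = np.stack([gy.ravel() / spacing, gx.ravel() / spacing,
                        compactness * image[np.clip(gy.ravel().astype(int), 0, h - 1),
                                            np.clip(gx.ravel().astype(int), 0, w - 1)]],
                       axis=1)
    labels = None
    for _ in range(iterations):
        d2 = ((feats[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        for k in range(len(centers)):
            members = feats[labels == k]
            if len(members):
                centers[k] = members.mean(axis=0)
    return labels.reshape(h, w)


def segment_superpixels(image: np.ndarray, target_count: int,
                        compactness: float = 3.0) -> np.ndarray:
    """Partition an image into contiguous intensity-aware superpixels.

    Grid-initialized Lloyd iterations on (y, x, intensity) features,
    followed by a connectivity cleanup that merges stray fragments into
    the neighboring region with the longest shared boundary.  Labels are
    consecutive integers from 0; deterministic per image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if target_count < 2:
        raise ValueError("target_count must be >= 2")
    labels = _kmeans_superpixels(image, target_count, compactness)
    # keep only the largest connected component of every cluster; merge
    # the rest into their most frequent touching neighbor
    cleaned = np.full_like(labels, -1)
    next_label = 0
    fragments = []
    for k in np.unique(labels):
        comp, n_comp = ndimage.label(labels == k)
        if n_comp == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        cleaned[comp == keep] = next_label
        for extra in range(1, n_comp + 1):
            if extra != keep:
                fragments.append(comp == extra)
        next_label += 1
    # merge fragments into assigned neighbors; defer fragments that only
    # touch other fragments until a neighbor has been resolved
    pending = fragments
    while pending:
        deferred = []
        merged_any = False
        for frag in pending:
            ring = ndimage.binary_dilation(frag) & ~frag
            neighbors = cleaned[ring]
            neighbors = neighbors[neighbors >= 0]
            if len(neighbors):
                values, counts = np.unique(neighbors, return_counts=True)
                cleaned[frag] = values[np.argmax(counts)]
                merged_any = True
            else:
                deferred.append(frag)
        if not merged_any:  # fully isolated island: keep one label for it
            cleaned[deferred[0]] = next_label
            next_label += 1
            deferred = deferred[1:]
        pending = deferred
    # relabel consecutively
    _, consecutive = np.unique(cleaned, return_inverse=True)
    return consecutive.reshape(image.shape)


def _ridge_fit(masks: np.ndarray, responses: np.ndarray, weights: np.ndarray,
               ridge: float) -> tuple[np.ndarray, float]:
    """Weighted ridge regression with unpenalized intercept, solved by
    the normal equations."""
    s, n = masks.shape
    xa = np.column_stack([np.ones(s), masks.astype(float)])
    wx = xa * weights[:, None]
    a = xa.T @ wx
    a[1:, 1:] += ridge * np.eye(n)
    coef = np.linalg.solve(a, wx.T @ responses)
    return coef[1:], float(coef[0])


def lime_explain(model, image: np.ndarray, class_index: int,
                 config: ExplainerConfig | None = None,
                 seed: int = 0) -> LIMEResult:
    """Local surrogate explanation of one prediction.

    ``model`` is either a trained :class:`~gallnet.model_core.Model`
    (perturbed *images* are classified) or, for surrogate-recovery
    studies, a callable taking the (samples, regions) binary mask matrix
    and returning one response per row.

    Each region is kept with probability 0.5 (the all-ones mask is always
    included as the first sample); masked-out regions are replaced by the
    baseline intensity.  Sample weight is exp(-d^2 / width^2) with d the
    fraction of dropped regions.  Deterministic per seed.
    """
    if config is None:
        config = ExplainerConfig()
    image = np.asarray(image, dtype=float)
    segments = segment_superpixels(image, config.superpixels,
                                   config.compactness)
    n_regions = int(segments.max()) + 1
    if config.samples < n_regions:
        raise ValueError(
            f"need at least as many samples ({config.samples}) as regions "
            f"({n_regions}) for a determined surrogate")
    rng = np.random.default_rng(seed)
    masks = (rng.random((config.samples, n_regions)) < 0.5)
    masks[0, :] = True

    if isinstance(model, Model):
        baseline = float(image.mean()) if config.baseline is None \
            else config.baseline
        region_maps = masks[:, segments]              # (samples, h, w)
        perturbed = np.where(region_maps, image[None], baseline)
        responses = model.predict_proba(perturbed[..., None])[:, class_index]
    elif callable(model):
        responses = np.asarray(model(masks), dtype=float).reshape(-1)
        if len(responses) != config.samples:
            raise ValueError("black box must return one response per mask")
    else:
        raise TypeError("model must be a Model or a callable over masks")

    d = 1.0 - masks.mean(axis=1)                      # fraction dropped
    weights = np.exp(-(d ** 2) / config.kernel_width ** 2)
    coefficients, intercept = _ridge_fit(masks, responses, weights,
                                         config.ridge)

    order = np.argsort(-np.abs(coefficients))
    top = [int(i) for i in order[:config.top_k]]
    positive = np.isin(segments, [i for i in top if coefficients[i] > 0])
    negative = np.isin(segments, [i for i in top if coefficients[i] < 0])
    return LIMEResult(segments=segments, coefficients=coefficients,
                      intercept=intercept, top_regions=top,
                      positive_mask=positive, negative_mask=negative,
                      seed=seed)


def _boundaries(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def render_overlay(base: np.ndarray, result, alpha: float = 0.4) -> np.ndarray:
    """Blend an explanation over a grayscale base image.

    Grad-CAM results get a jet-style colormap at opacity ``alpha``; LIME
    results get a green tint over positive regions, red over negative,
    with region boundaries drawn at double strength.  Returns an RGB
    float array in [0, 1]; pixels untouched by the explanation equal the
    base.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    base = np.asarray(base, dtype=float)
    if base.ndim != 2:
        raise ValueError("base image must be 2-D grayscale")
    rgb = np.repeat(base[:, :, None], 3, axis=2)
    if isinstance(result, GradCAMResult):
        if result.heatmap.shape != base.shape:
            raise ValueError("heatmap and base image shapes differ")
        colors = colormaps["jet"](result.heatmap)[..., :3]
        return (1 - alpha) * rgb + alpha * colors
    if isinstance(result, LIMEResult):
        if result.segments.shape != base.shape:
            raise ValueError("segment map and base image shapes differ")
        out = rgb.copy()
        for mask, color in ((result.positive_mask, (0.0, 1.0, 0.0)),
                            (result.negative_mask, (1.0, 0.0, 0.0))):
            if mask.any():
                tint = np.array(color)
                out[mask] = (1 - alpha) * out[mask] + alpha * tint
                edge = _boundaries(mask)
                strong = min(1.0, 2.0 * alpha)
                out[edge] = (1 - strong) * rgb[edge] + strong * tint
        return np.clip(out, 0.0, 1.0)
    raise TypeError("result must be a GradCAMResult or LIMEResult")
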