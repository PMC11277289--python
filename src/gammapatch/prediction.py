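"""Predict gamma responses to images from patch approximations.

Each (image, electrode) pair carries a patch approximation; uniform hue
patches are pushed through the hue product model (with the pooled median
shape parameters) to yield an unscaled prediction, while unmatched patches
(R = 0) and chromatic Gabors predict 0.  Predictions are compared with
actual band responses by Pearson correlation over all images of a set
(r_full) and over the selected patches only (r_sel); an electrode-category
set qualifies for population averaging when at least 8 of its 16 images
were selected.  Gain and offset are omitted throughout: correlation is
invariant to affine rescaling of the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .exceptions import DegenerateInputError, ValidationError
from .image_features import PatchApproximation, patch_hsv
from .io_formats import HSVImage
from .tuning_models import HuePatchStimulus, HueShape, hue_product

__all__ = [
    "PredictionRecord",
    "CorrelationSummary",
    "predict_image_gamma",
    "feature_ablation",
    "correlate_predictions",
    "fixed_radius_model",
    "QUALIFY_MIN_SELECTED",
]

#: minimum number of selected patches (of 16) for a set to qualify
QUALIFY_MIN_SELECTED = 8

_ABLATION_DEFAULTS = {"H": 0.0, "S": 1.0, "V": 100.0, "R": 10.0}


@dataclass
class PredictionRecord:
    """Predicted vs actual gamma response for one image at one electrode."""

    image_id: str
    electrode_id: str
    predicted: float
    actual_gamma: float | None = None
    actual_high_gamma: float | None = None
    selected: bool = False


@dataclass
class CorrelationSummary:
    r_full: float
    r_sel: float | None
    n_selected: int
    n_total: int
    qualifies: bool


def _patch_stimulus(patch: PatchApproximation) -> HuePatchStimulus | None:
    if patch.kind == "hue_patch" and patch.R and patch.R > 0:
        return HuePatchStimulus(H=patch.H, S=patch.S, V=patch.V * 100.0, R=patch.R)
    return None


def predict_image_gamma(patch: PatchApproximation, shape: HueShape) -> float:
    """Unscaled hue-model prediction for one patch approximation.

    Hue patches evaluate the product model on (H, S, V, R); unmatched
    patches and Gabors (chromatic regions cannot be predicted by the
    achromatic grating model here) yield 0.
    """
    if patch.kind not in ("hue_patch", "gabor", "none"):
        raise ValidationError(f"unknown patch kind {patch.kind!r}")
    stim = _patch_stimulus(patch)
    if stim is None:
        return 0.0
    return hue_product(stim, shape)


def feature_ablation(
    patch: PatchApproximation, shape: HueShape, use: set[str]
) -> float:
    """Prediction with only a subset of {H, S, V, R} taken from the patch.

    Unused features are pinned to hue 0 deg (red), saturation 1, value
    100 % and size 10 dva.  ``use`` of all four features reproduces
    :func:`predict_image_gamma`.
    """
    use = set(use)
    if not use or not use <= set("HSVR"):
        raise ValidationError("use must be a nonempty subset of {'H','S','V','R'}")
    stim = _patch_stimulus(patch)
    if stim is None:
        return 0.0
    values = dict(_ABLATION_DEFAULTS)
    actual = {"H": stim.H, "S": stim.S, "V": stim.V, "R": stim.R}
    for feat in use:
        values[feat] = actual[feat]
    return hue_product(HuePatchStimulus(**values), shape)


def correlate_predictions(
    records: list[PredictionRecord], response: str = "gamma"
) -> CorrelationSummary:
    """Pearson correlation of predicted vs actual responses.

    ``response`` selects the actual-response variant: 'gamma',
    'high_gamma', or 'gamma_minus_high_gamma' (the linear gamma ratio minus
    the linear high-gamma ratio, discounting broadband power increases).
    """
    if response not in ("gamma", "high_gamma", "gamma_minus_high_gamma"):
        raise ValidationError(f"unknown response variant {response!r}")
    usable = [r for r in records if r.actual_gamma is not None]
    if response != "gamma":
        usable = [r for r in usable if r.actual_high_gamma is not None]
    if len(usable) < 3:
        raise ValidationError("need >= 3 records with actual responses")

    def actual(rec: PredictionRecord) -> float:
        if response == "gamma":
            return rec.actual_gamma
        if response == "high_gamma":
            return rec.actual_high_gamma
        return rec.actual_gamma - rec.actual_high_gamma

    pred = np.array([r.predicted for r in usable])
    act = np.array([actual(r) for r in usable])
    if np.ptp(pred) == 0 or np.ptp(act) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r_full = float(pearsonr(pred, act).statistic)
    sel = [i for i, r in enumerate(usable) if r.selected]
    r_sel = None
    if len(sel) >= 3 and np.ptp(pred[sel]) > 0 and np.ptp(act[sel]) > 0:
        r_sel = float(pearsonr(pred[sel], act[sel]).statistic)
    n_selected = len(sel)
    return CorrelationSummary(
        r_full=r_full,
        r_sel=r_sel,
        n_selected=n_selected,
        n_total=len(usable),
        qualifies=n_selected >= QUALIFY_MIN_SELECTED,
    )


def fixed_radius_model(
    image: HSVImage,
    center: tuple[int, int],
    fixed_R: float,
    shape: HueShape,
) -> float:
    """Basic model: average H, S, V over a disk of fixed radius and
    evaluate the hue product model with R = fixed_R."""
    if fixed_R <= 0:
        raise ValidationError("fixed_R must be > 0")
    H, S, V, _ = patch_hsv(image, center, fixed_R)
    return hue_product(HuePatchStimulus(H=H, S=S, V=V * 100.0, R=fixed_R), shape)
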