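"""External representations: raster images as HSV layers, receptive-field
tables, epoched-signal containers, and parameter/result tables.

Conventions (fixed, see also the methods note):

* Pixel coordinates are 0-based ``(row, col)``.
* Visual-field azimuth increases rightward and elevation upward, so an RF at
  (azimuth, elevation) dva maps to the pixel
  ``fixation_px + (-elevation, +azimuth) * pixels_per_degree``.
* Hue is carried in degrees in [0, 360); saturation and value as fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv

from .exceptions import ValidationError
from .spectral import TrialEnsemble

__all__ = [
    "HSVImage",
    "load_image_hsv",
    "save_image_png",
    "rf_to_pixel",
    "read_rf_table",
    "write_rf_table",
    "save_hsv_container",
    "load_hsv_container",
    "save_trials",
    "load_trials",
]


@dataclass
class HSVImage:
    """An image held as separate hue/saturation/value layers.

    ``hue_layer`` is in degrees [0, 360); ``sat_layer`` and ``val_layer`` are
    fractions in [0, 1].  ``pixels_per_degree`` converts between pixels and
    degrees of visual angle; ``fixation_px`` is the (row, col) pixel of the
    fixation point (screen center).
    """

    hue_layer: np.ndarray
    sat_layer: np.ndarray
    val_layer: np.ndarray
    pixels_per_degree: float
    fixation_px: tuple[int, int]

    def __post_init__(self) -> None:
        self.hue_layer = np.asarray(self.hue_layer, dtype=float) % 360.0
        self.sat_layer = np.asarray(self.sat_layer, dtype=float)
        self.val_layer = np.asarray(self.val_layer, dtype=float)
        if not (self.hue_layer.shape == self.sat_layer.shape == self.val_layer.shape):
            raise ValidationError("HSV layers must share identical dimensions")
        if self.pixels_per_degree <= 0:
            raise ValidationError("pixels_per_degree must be positive")
        for name, layer in (("sat", self.sat_layer), ("val", self.val_layer)):
            if np.any(layer < 0) or np.any(layer > 1):
                raise ValidationError(f"{name} layer must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue_layer.shape


def load_image_hsv(
    path: str | Path,
    pixels_per_degree: float,
    fixation_px: tuple[int, int] | None = None,
) -> HSVImage:
    """Read a raster image (PNG/JPEG/TIFF) into HSV layers.

    RGB images are converted to HSV with hue scaled to degrees.  Grayscale
    images keep only the value layer (hue = 0, saturation = 0).  When
    ``fixation_px`` is omitted the image center is used.
    """
    if pixels_per_degree <= 0:
        raise ValidationError("pixels_per_degree must be positive")
    try:
        img = Image.open(path)
        arr = np.asarray(img)
    except OSError as exc:
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim == 2:  # grayscale
        val = arr.astype(float) / 255.0
        hue = np.zeros_like(val)
        sat = np.zeros_like(val)
    else:
        rgb = arr[..., :3].astype(float) / 255.0
        hsv = rgb2hsv(rgb)
        hue = hsv[..., 0] * 360.0
        sat = hsv[..., 1]
        val = hsv[..., 2]
    if fixation_px is None:
        fixation_px = (hue.shape[0] // 2, hue.shape[1] // 2)
    return HSVImage(hue, sat, val, pixels_per_degree, tuple(fixation_px))


def save_image_png(image: HSVImage, path: str | Path) -> None:
    """Write an HSVImage back to an 8-bit RGB PNG."""
    hsv = np.stack(
        [image.hue_layer / 360.0, image.sat_layer, image.val_layer], axis=-1
    )
    rgb = np.clip(hsv2rgb(hsv) * 255.0, 0, 255).round().astype(np.uint8)
    Image.fromarray(rgb).save(path)


def rf_to_pixel(
    azimuth_dva: float, elevation_dva: float, image: HSVImage
) -> tuple[int, int]:
    """Map an RF center in visual-field coordinates to an image pixel.

    Returns ``fixation_px + (-elevation, +azimuth) * pixels_per_degree``
    rounded to the nearest pixel; raises if the result falls outside the
    image.
    """
    row = image.fixation_px[0] - elevation_dva * image.pixels_per_degree
    col = image.fixation_px[1] + azimuth_dva * image.pixels_per_degree
    px = (int(round(row)), int(round(col)))
    nrow, ncol = image.shape
    if not (0 <= px[0] < nrow and 0 <= px[1] < ncol):
        raise ValidationError(
            f"RF at azimuth={azimuth_dva}, elevation={elevation_dva} dva maps to "
            f"pixel {px}, outside the {image.shape} image"
        )
    return px


_RF_COLUMNS = ["electrode_id", "azimuth_dva", "elevation_dva"]


def read_rf_table(path: str | Path) -> pd.DataFrame:
    """Read a receptive-field center table (CSV with header
    ``electrode_id,azimuth_dva,elevation_dva``)."""
    df = pd.read_csv(path)
    missing = [c for c in _RF_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"RF table missing columns {missing}")
    if df["electrode_id"].duplicated().any():
        raise ValidationError("electrode_id values must be unique")
    coords = df[["azimuth_dva", "elevation_dva"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("RF coordinates must be finite")
    return df[_RF_COLUMNS]


def write_rf_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_RF_COLUMNS].to_csv(path, index=False)


def save_hsv_container(image: HSVImage, path: str | Path) -> None:
    """Write an HSVImage to an HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("hue", data=image.hue_layer)
        f.create_dataset("sat", data=image.sat_layer)
        f.create_dataset("val", data=image.val_layer)
        f.attrs["pixels_per_degree"] = image.pixels_per_degree
        f.attrs["fixation_px"] = image.fixation_px


def load_hsv_container(path: str | Path) -> HSVImage:
    with h5py.File(path, "r") as f:
        return HSVImage(
            f["hue"][...],
            f["sat"][...],
            f["val"][...],
            float(f.attrs["pixels_per_degree"]),
            tuple(int(v) for v in f.attrs["fixation_px"]),
        )


def save_trials(trials: TrialEnsemble, path: str | Path) -> None:
    """Write a TrialEnsemble to HDF5: dataset ``/signal`` [trials x samples],
    attributes ``fs_hz`` and ``onset_sample``, and a ``/labels`` dataset."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signal", data=trials.samples)
        ds.attrs["fs_hz"] = trials.fs
        ds.attrs["onset_sample"] = trials.onset_sample
        f.create_dataset(
            "labels",
            data=np.array([trials.electrode_id, trials.condition], dtype="S"),
        )


def load_trials(path: str | Path) -> TrialEnsemble:
    with h5py.File(path, "r") as f:
        ds = f["signal"]
        labels = [s.decode() for s in f["labels"][...]]
        return TrialEnsemble(
            samples=ds[...],
            fs=float(ds.attrs["fs_hz"]),
            onset_sample=int(ds.attrs["onset_sample"]),
            electrode_id=labels[0] if labels else "",
            condition=labels[1] if len(labels) > 1 else "",
        )
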