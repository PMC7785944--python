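"""Calibrated R:G anthocyanin color index from linear-RGB pixel data.

The index mirrors the photographic protocol used for field scoring of petal and sepal
pigmentation: a patch of linear RGB pixel values is first put on a common scale by a
two-point linear calibration against two gray standards, then summarized as the mean
red-channel value divided by the mean green-channel value.  Higher ratios indicate
higher anthocyanin concentration (pinker petals, redder calyces).

The computational contract is array-based; :func:`read_raster` is a thin reader that
converts 8/16-bit TIFF or PNG rasters to float arrays in [0, 1].  Values are assumed
to be linear already — no gamma decoding is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RGBPatch", "GrayStandardPair", "calibrate_channels", "rg_ratio", "read_raster"]

_CHANNELS = ("red", "green", "blue")


@dataclass
class RGBPatch:
    """Equal-shape arrays of linear channel values >= 0, with an optional region mask."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        self.blue = np.asarray(self.blue, dtype=float)
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("channel arrays must have identical shapes")
        if self.red.size < 1:
            raise ValueError("patch must contain at least one pixel")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.red.shape:
                raise ValueError("mask shape must match the channel arrays")
            if not self.mask.any():
                raise ValueError("mask selects no pixels")

    def channels(self):
        return {"red": self.red, "green": self.green, "blue": self.blue}

    def selected(self, name):
        arr = getattr(self, name)
        return arr[self.mask] if self.mask is not None else arr


@dataclass
class GrayStandardPair:
    """Per-channel (measured, expected) values for two gray reference patches.

    ``measured`` and ``expected`` are mappings channel -> (value_standard_1,
    value_standard_2); the expected reflectances of the two standards are configuration
    inputs (they depend on the reference chart used).
    """

    measured: dict
    expected: dict

    def __post_init__(self):
        for ch in _CHANNELS:
            m = self.measured.get(ch)
            e = self.expected.get(ch)
            if m is None or e is None or len(m) != 2 or len(e) != 2:
                raise ValueError(f"two (measured, expected) values required for {ch!r}")
            if m[0] == m[1]:
                raise ValueError(
                    f"degenerate calibration for {ch!r}: measured standard values are equal"
                )

    @classmethod
    def from_gray_levels(cls, measured_pair, expected_pair):
        """Convenience: the same two gray levels apply to all three channels."""
        return cls(
            measured={ch: tuple(measured_pair) for ch in _CHANNELS},
            expected={ch: tuple(expected_pair) for ch in _CHANNELS},
        )


def calibrate_channels(patch, standards):
    """Two-point linear calibration of each channel against the gray standards.

    Per channel, the affine map sending the measured standard values to their expected
    values is applied to every pixel.  Mapped values below zero are clamped to 0 and
    reported in a warning.  Returns a new patch; the input is not modified.
    """
    out = {}
    n_clamped = 0
    for ch in _CHANNELS:
        m1, m2 = standards.measured[ch]
        e1, e2 = standards.expected[ch]
        a = (e2 - e1) / (m2 - m1)
        b = e1 - a * m1
        mapped = a * getattr(patch, ch) + b
        n_clamped += int(np.count_nonzero(mapped < 0))
        out[ch] = np.maximum(mapped, 0.0)
    if n_clamped:
        warnings.warn(f"calibration clamped {n_clamped} negative pixel values to 0")
    return RGBPatch(mask=None if patch.mask is None else patch.mask.copy(), **out)


def rg_ratio(patch):
    """Mean red over mean green of the selected region (the whole patch if unmasked).

    The ratio of channel means — not the mean of per-pixel ratios — is used, which is
    robust to dark pixels with tiny green values.
    """
    red = patch.selected("red")
    green = patch.selected("green")
    g = float(np.mean(green))
    if g <= 0:
        raise ValueError("mean green over the selected region must be positive")
    return float(np.mean(red)) / g


def read_raster(path, mask=None):
    """Read an 8/16-bit RGB raster (TIFF/PNG/...) into an :class:`RGBPatch` in [0, 1]."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB raster with three channels")
    if img.dtype == np.uint8:
        arr = img.astype(float) / 255.0
    elif img.dtype == np.uint16:
        arr = img.astype(float) / 65535.0
    else:
        arr = img.astype(float)
    return RGBPatch(red=arr[..., 0], green=arr[..., 1], blue=arr[..., 2], mask=mask)
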