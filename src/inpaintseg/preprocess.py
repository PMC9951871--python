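"""CT window/level channel construction and intensity normalization.

CT slices in raw Hounsfield Units are expanded into three channels that
emphasize different contrasts -- soft tissue (W/L = 400/50), bone
(W/L = 1800/40) and a custom setting (W/L = 500/50) -- by clipping to
``[L - W/2, L + W/2]``; values inside a window pass through unchanged, so
windowing is monotone and idempotent.  All images are then standardized to
zero mean and unit standard deviation: MR images per volume (each 2D image
is its own unit in slice datasets), CT images per channel.  Clinical HU
metrics are always computed on the raw un-windowed image, never on these
model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WindowLevel",
    "CT_WINDOWS",
    "window_ct",
    "stack_ct_channels",
    "Standardizer",
    "normalize",
]


@dataclass(frozen=True)
class WindowLevel:
    """A HU display window: width ``window`` centered on ``level``."""

    window: float
    level: float

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError(f"window width must be > 0, got {self.window}")

    @property
    def lo(self) -> float:
        return self.level - self.window / 2

    @property
    def hi(self) -> float:
        return self.level + self.window / 2


#: channel order for CT inputs: soft tissue, bone, custom
CT_WINDOWS = (
    ("soft_tissue", WindowLevel(400, 50)),
    ("bone", WindowLevel(1800, 40)),
    ("custom", WindowLevel(500, 50)),
)


def window_ct(hu_image: np.ndarray, wl: WindowLevel) -> np.ndarray:
    """Clip a raw-HU image to ``[L - W/2, L + W/2]``; output stays in HU."""
    hu_image = np.asarray(hu_image)
    if not np.all(np.isfinite(hu_image)):
        raise ValueError("HU image contains non-finite values")
    return np.clip(hu_image, wl.lo, wl.hi)


def stack_ct_channels(hu_image: np.ndarray) -> np.ndarray:
    """Expand a single-channel raw-HU image into the 3 windowed channels
    (soft-tissue 400/50, bone 1800/40, custom 500/50), shape ``(3, H, W)``."""
    hu_image = np.asarray(hu_image)
    if hu_image.ndim != 2:
        raise ValueError(f"expected a single-channel (H, W) image, got shape {hu_image.shape}")
    return np.stack([window_ct(hu_image, wl) for _, wl in CT_WINDOWS])


class Standardizer(BaseEstimator, TransformerMixin):
    """Zero-mean / unit-std standardization per normalization unit.

    ``mode='per_volume'`` treats the whole array as one unit (MRI);
    ``mode='per_channel'`` standardizes each leading-axis channel
    independently (3-channel CT).  The fitted ``mean_`` and ``std_`` are kept
    for exact inversion and for serializing into experiment logs.
    """

    def __init__(self, mode: Literal["per_volume", "per_channel"] = "per_volume"):
        self.mode = mode

    def fit(self, X: np.ndarray, y=None) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        if self.mode == "per_volume":
            mean = np.array([X.mean()])
            std = np.array([X.std()])
        elif self.mode == "per_channel":
            if X.ndim < 3:
                raise ValueError("per_channel mode expects a (C, H, W) array")
            mean = X.reshape(X.shape[0], -1).mean(axis=1)
            std = X.reshape(X.shape[0], -1).std(axis=1)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if np.any(std == 0):
            raise ValueError("zero standard deviation within a normalization unit")
        self.mean_, self.std_ = mean, std
        return self

    def _shaped(self, X):
        if self.mode == "per_volume":
            return self.mean_[0], self.std_[0]
        extra = (1,) * (X.ndim - 1)
        return self.mean_.reshape(-1, *extra), self.std_.reshape(-1, *extra)

    def transform(self, X: np.ndarray) -> np.ndarray:
        m, s = self._shaped(np.asarray(X))
        return ((np.asarray(X, dtype=np.float64) - m) / s).astype(np.float32)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        m, s = self._shaped(np.asarray(X))
        return (np.asarray(X, dtype=np.float64) * s + m).astype(np.float32)

    def record(self) -> dict:
        """JSON-serializable (mean, std) record."""
        return {"mode": self.mode, "mean": self.mean_.tolist(), "std": self.std_.tolist()}


def normalize(
    image: np.ndarray, mode: Literal["per_volume", "per_channel"] = "per_volume"
) -> tuple[np.ndarray, dict]:
    """Standardize an image; returns ``(normalized, record)`` where the record
    holds the (mean, std) used, for inversion."""
    st = Standardizer(mode).fit(image)
    return st.transform(image), st.record()
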