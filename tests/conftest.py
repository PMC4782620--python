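"""Shared fixtures and independent naive oracles.

The morphology oracles implement erosion/dilation directly as min/max
over explicitly shifted copies of the padded input — no scipy morphology
involved — so they can serve as an independent reference for the
library's operators.
"""

import numpy as np
import pytest

from mcdetect import GrayImage, generate_line_ses

_PAD_MODE = {"reflect": "symmetric", "replicate": "edge"}


def _pad(f: np.ndarray, pad_r: int, pad_c: int, border: str, cval: float) -> np.ndarray:
    if border == "constant":
        return np.pad(f, ((pad_r, pad_r), (pad_c, pad_c)), constant_values=cval)
    return np.pad(f, ((pad_r, pad_r), (pad_c, pad_c)), mode=_PAD_MODE[border])


def _window_min(p: np.ndarray, mask: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Min over the SE window at each of the out_h x out_w 'valid' pixels."""
    half_r = (mask.shape[0] - 1) // 2
    half_c = (mask.shape[1] - 1) // 2
    stacks = [
        p[half_r + dr : half_r + dr + out_h, half_c + dc : half_c + dc + out_w]
        for dr, dc in (np.argwhere(mask) - [half_r, half_c])
    ]
    return np.min(stacks, axis=0)


def _window_max(p: np.ndarray, mask: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    half_r = (mask.shape[0] - 1) // 2
    half_c = (mask.shape[1] - 1) // 2
    stacks = [
        p[half_r + dr : half_r + dr + out_h, half_c + dc : half_c + dc + out_w]
        for dr, dc in (np.argwhere(mask) - [half_r, half_c])
    ]
    return np.max(stacks, axis=0)


def naive_opening(f: np.ndarray, mask: np.ndarray, border: str = "reflect",
                  cval: float = 0.0) -> np.ndarray:
    """Erosion-then-dilation computed as explicit sliding-window min/max
    over a single border-policy extension of the input, cropped back.
    The 'clip' policy restricts each window to the image domain instead."""
    h, w = f.shape
    half_r = (mask.shape[0] - 1) // 2
    half_c = (mask.shape[1] - 1) // 2
    if border == "clip":
        p = np.pad(f, ((half_r, half_r), (half_c, half_c)), constant_values=np.inf)
        eroded = _window_min(p, mask, h, w)
        q = np.pad(eroded, ((half_r, half_r), (half_c, half_c)), constant_values=-np.inf)
        return _window_max(q, mask, h, w)
    p = _pad(f, 2 * half_r, 2 * half_c, border, cval)
    eroded = _window_min(p, mask, h + 2 * half_r, w + 2 * half_c)
    opened = _window_max(eroded, mask, h, w)
    return opened


@pytest.fixture(scope="session")
def se_bank():
    """The default 8-orientation, 15x15 line-SE bank."""
    return generate_line_ses(15, 8)


@pytest.fixture
def rng():
    return np.random.default_rng(20231504)


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.uniform(size=(24, 24)))
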