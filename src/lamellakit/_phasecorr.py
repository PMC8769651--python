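"""Shared subpixel phase-correlation offset estimator.

Plain upsampled phase correlation is exact for periodic content (integer
rolls are recovered perfectly) but suffers from two failure modes: fill
borders bias it by a fraction of a pixel, and the cyclic correlation is
blind to the wrap-around ambiguity (a shift of -240 rows on a 400-row
image is indistinguishable from +160).  A Hann-windowed estimate fixes the
border bias but cannot see shifts that move content out of the window.

The estimator therefore gathers candidates -- the plain estimate, its
wrap-around aliases along each axis, and the windowed estimate -- and,
unless they all agree, verifies each candidate by un-shifting the moving
image and scoring its correlation with the reference on the valid overlap.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation


def _verify(ref: np.ndarray, mov: np.ndarray, shift_rc) -> float:
    """Overlap-weighted correlation of ref with mov un-shifted by the candidate.

    The Pearson correlation on the valid overlap is scaled by the square
    root of the overlap fraction, so a candidate explaining the whole image
    beats a wrap-around alias that matches only a sliver equally well.
    """
    back = ndimage.shift(mov, shift_rc, order=1, cval=np.nan)
    valid = np.isfinite(back) & (back != 0)
    if valid.sum() < 256:
        return -np.inf
    a, b = ref[valid], back[valid]
    if a.std() == 0 or b.std() == 0:
        return -np.inf
    corr = float(np.corrcoef(a, b)[0, 1])
    return corr * float(np.sqrt(valid.mean()))


def subpixel_offset(ref: np.ndarray, mov: np.ndarray,
                    upsample: int = 10) -> np.ndarray:
    """Displacement (dy, dx) of ``mov`` relative to ``ref``.

    Shifting ``mov`` by the negative of the returned vector registers it
    onto ``ref``.  Note phase_cross_correlation returns the shift to apply,
    i.e. the negative displacement; the sign is normalized here.
    """
    shape = np.asarray(ref.shape, dtype=float)
    plain, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample,
                                          normalization=None)
    window = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    windowed, _, _ = phase_cross_correlation(ref * window, mov * window,
                                             upsample_factor=upsample,
                                             normalization=None)
    candidates = [np.asarray(plain)]
    for axis in (0, 1):
        if abs(plain[axis]) > 0.5:
            alias = np.asarray(plain).copy()
            alias[axis] -= np.sign(alias[axis]) * shape[axis]
            candidates.append(alias)
    candidates.append(np.asarray(windowed))

    if all(np.abs(c - candidates[0]).max() <= 0.05 for c in candidates[1:]):
        return -candidates[0]
    scores = [_verify(ref, mov, c) for c in candidates]
    best = int(np.argmax(scores))
    return -candidates[best]
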