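"""Peak-frequency-contour resampling.

Measurement software exports one peak-frequency value per spectrogram slice,
so the raw contour length varies with call duration.  Downstream statistics
need a fixed-length feature vector, so every contour is reduced to ``k``
values spread evenly in time across the call (endpoints included), by linear
interpolation of the original samples.  The feature vector is those ``k``
frequencies followed by the call duration in seconds.

Even-in-time resampling deliberately replaces any pairwise time-warping
alignment: it normalises calls of different durations onto a common time
base while keeping each call's features independent of every other call.
"""

from __future__ import annotations

import numpy as np

__all__ = ["resample_evenly", "build_feature_vector"]


def resample_evenly(contour, k: int = 10) -> np.ndarray:
    """Resample a contour to ``k`` evenly spaced samples.

    Parameters
    ----------
    contour : RawContour
        Validated contour (``begin_s``, ``end_s``, ``freqs_hz``); the
        original samples are taken to be uniformly spaced over
        ``[begin_s, end_s]`` with both endpoints sampled.
    k : int, default 10
        Number of output samples; must be at least 2.

    Returns
    -------
    numpy.ndarray
        ``k`` frequencies in Hz.  The first and last values equal the
        contour's first and last samples; interior values are linear
        interpolants, so the output never leaves ``[min, max]`` of the
        input and preserves monotonicity of monotone contours.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    freqs = np.asarray(contour.freqs_hz, dtype=float)
    if freqs.size < 2:
        raise ValueError("contour must have at least 2 samples")
    t_in = np.linspace(contour.begin_s, contour.end_s, freqs.size)
    t_out = np.linspace(contour.begin_s, contour.end_s, k)
    return np.interp(t_out, t_in, freqs)


def build_feature_vector(contour, k: int = 10) -> np.ndarray:
    """Build the per-call feature vector: ``k`` PFC values + duration.

    Positions ``0..k-1`` are the evenly resampled contour in Hz, position
    ``k`` is the call duration ``end_s - begin_s`` in seconds.
    """
    pfc = resample_evenly(contour, k=k)
    return np.append(pfc, contour.end_s - contour.begin_s)
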