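"""Angular helpers shared across the pipeline.

All angles are radians, anticlockwise positive, wrapped to [0, 2*pi).
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angle(s) to [0, 2*pi)."""
    return np.mod(theta, TWO_PI)


def circdiff(a, b):
    """Signed circular difference a - b, wrapped to [-pi, pi)."""
    return np.mod(np.asarray(a) - np.asarray(b) + np.pi, TWO_PI) - np.pi


def circdist(a, b):
    """Absolute circular distance between angles, in [0, pi]."""
    return np.abs(circdiff(a, b))


def circular_mean(angles):
    """Mean direction of a sample of angles, in [0, 2*pi)."""
    angles = np.asarray(angles, dtype=float)
    z = np.exp(1j * angles).mean()
    return float(wrap_angle(np.angle(z)))


def circular_sd(angles):
    """Circular standard deviation sqrt(-2 ln R) of a sample of angles.

    R is the mean resultant length; R -> 1 gives SD -> 0, R -> 0 gives
    SD -> inf.
    """
    angles = np.asarray(angles, dtype=float)
    r = np.abs(np.exp(1j * angles).mean())
    if r <= 0:
        return np.inf
    return float(np.sqrt(-2.0 * np.log(r)))


def spawn_rng(seed, *keys):
    """Derive an independent Generator from a master seed and string keys.

    Deterministic: the same (seed, keys) always yields the same stream.
    """
    # str hash() is salted per-process, so roll a stable one
    entropy = [int(seed)]
    for k in keys:
        h = 0
        for ch in str(k):
            h = (h * 31 + ord(ch)) % (2**31)
        entropy.append(h)
    return np.random.default_rng(np.random.SeedSequence(entropy))
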