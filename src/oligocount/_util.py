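"""Shared helpers: rounding convention, seed derivation, exceptions."""

from __future__ import annotations

import hashlib
import math

import numpy as np

__all__ = [
    "round_half_away",
    "substream_seed",
    "rng_for",
    "OligocountError",
    "ConfigError",
    "FitError",
    "CalibrationError",
    "TraceError",
    "SegmentationError",
]


class OligocountError(Exception):
    """Base class for all package errors."""


class ConfigError(OligocountError):
    """Invalid configuration or invalid parameter values."""


class FitError(OligocountError):
    """A model fit could not be performed or did not converge."""


class CalibrationError(OligocountError):
    """Unit-step calibration failed (too few usable steps)."""


class TraceError(OligocountError):
    """A bleaching trace is malformed or uninformative."""


class SegmentationError(OligocountError):
    """Image segmentation failed (e.g. blank channel)."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used for step multiplicities and for N = I0/a, so that e.g. 2.5 -> 3
    and -2.5 -> -3 (numpy's banker's rounding would give 2 / -2).
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def substream_seed(root_seed: int, stream: str) -> int:
    """Derive a reproducible per-stage seed from a root seed and a stage name.

    The stage name is hashed so that adding a stage to a pipeline does not
    perturb the draws of the others. The result is kept below 2**31.
    """
    h = hashlib.sha256(stream.encode("utf-8")).digest()
    offset = int.from_bytes(h[:4], "big")
    return (int(root_seed) ^ offset) % (2**31)


def rng_for(root_seed: int, stream: str) -> np.random.Generator:
    """A numpy Generator seeded from ``substream_seed(root_seed, stream)``."""
    return np.random.default_rng(substream_seed(root_seed, stream))
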