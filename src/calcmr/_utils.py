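"""Shared numerics and error types."""

from __future__ import annotations

import numpy as np
from scipy import stats

#: normal quantile used for all 95% intervals (matched to reported tables)
Z95 = 1.96


class CalcmrError(Exception):
    """Base class for package errors."""


class InputError(CalcmrError, ValueError):
    """Invalid or unusable input data."""


class ConfigError(CalcmrError, ValueError):
    """Invalid configuration (missing columns, bad thresholds...)."""


class EstimationError(CalcmrError, RuntimeError):
    """An estimator's preconditions are violated or the fit is degenerate."""


def two_sided_normal_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided p-value of a z-score under the standard normal."""
    return 2.0 * stats.norm.sf(np.abs(z))


def safe_z_p(beta: float, se: float) -> float:
    """Two-sided normal p that tolerates se == 0 (degenerate fits)."""
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(two_sided_normal_p(beta / se))


def spawn_int_seed(seed_seq: np.random.SeedSequence) -> int:
    """Derive a small integer seed (< 2^31) from a SeedSequence."""
    return int(seed_seq.generate_state(1, np.uint32)[0] % (2**31))
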