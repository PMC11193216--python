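"""Two-step mediation MR: indirect effect and proportion mediated.

The two-step design estimates the exposure-to-mediator effect beta1 and the
mediator-to-outcome effect beta2 in separate MR analyses; the indirect
(mediated) effect is the product beta1*beta2 and the proportion mediated is
(beta1*beta2)/beta0, where beta0 is the total exposure-to-outcome effect.
A mediator is eligible for the second step only if both links are causal
(IVW p < alpha) and neither shows directional pleiotropy (Egger intercept
p >= 0.05).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._utils import Z95, InputError, safe_z_p
from .mr_core import MREstimate
from .sensitivity import SensitivityReport

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """Product-of-coefficients mediation decomposition."""

    beta0: float
    se0: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    proportion: float
    proportion_ci_low: float
    proportion_ci_high: float
    proportion_p: float
    eligible: bool = True
    reason: str = "eligible"

    @property
    def proportion_pct(self) -> float:
        """Proportion mediated as a percentage."""
        return 100.0 * self.proportion


def mediation_eligibility(
    step1: tuple[MREstimate, Optional[SensitivityReport]],
    step2: tuple[MREstimate, Optional[SensitivityReport]],
    alpha: float = 0.05,
) -> tuple[bool, str]:
    """Second-step eligibility: both links causal, neither pleiotropic.

    ``step1`` is the exposure-to-mediator analysis, ``step2`` the
    mediator-to-outcome analysis; each is an (estimate, sensitivity report)
    pair. Eligible iff both IVW p-values are < ``alpha`` and neither Egger
    intercept p is < 0.05.
    """
    reasons = []
    est1, sens1 = step1
    est2, sens2 = step2
    if not est1.pval < alpha:
        reasons.append("exposure->mediator not causal")
    if not est2.pval < alpha:
        reasons.append("mediator->outcome not causal")
    if sens1 is not None and sens1.egger_intercept_p < 0.05:
        reasons.append("pleiotropy detected (exposure->mediator)")
    if sens2 is not None and sens2.egger_intercept_p < 0.05:
        reasons.append("pleiotropy detected (mediator->outcome)")
    if reasons:
        return False, "; ".join(reasons)
    return True, "eligible"


def proportion_mediated(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    beta0: float,
    se0: float,
    ci_method: str = "fixed-denominator",
    n_draws: int = 100_000,
    seed: int = 0,
) -> MediationResult:
    """Indirect effect beta1*beta2 and proportion mediated (beta1*beta2)/beta0.

    The indirect-effect SE uses the product delta method,
    sqrt(beta1^2 se2^2 + beta2^2 se1^2). The proportion CI treats beta0 as
    fixed by default (``ci_method="fixed-denominator"``: the indirect CI
    divided by beta0, endpoints ordered); ``"delta"`` adds the beta0
    variance term; ``"bootstrap"`` draws (beta1, beta2, beta0) from
    independent normals and takes percentile limits. A proportion outside
    [0, 1] (inconsistent mediation) is reported verbatim with a warning.
    """
    if beta0 == 0:
        raise InputError("proportion mediated undefined: total effect beta0 = 0")
    indirect = beta1 * beta2
    se_indirect = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    proportion = indirect / beta0
    lo_ind = indirect - Z95 * se_indirect
    hi_ind = indirect + Z95 * se_indirect

    if ci_method == "fixed-denominator":
        ci = sorted((lo_ind / beta0, hi_ind / beta0))
    elif ci_method == "delta":
        var_p = se_indirect**2 / beta0**2 + indirect**2 * se0**2 / beta0**4
        half = Z95 * math.sqrt(var_p)
        ci = [proportion - half, proportion + half]
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        b1 = rng.normal(beta1, se1, n_draws)
        b2 = rng.normal(beta2, se2, n_draws)
        b0 = rng.normal(beta0, se0, n_draws)
        props = b1 * b2 / b0
        ci = list(np.percentile(props, [2.5, 97.5]))
    else:
        raise InputError(f"unknown ci_method: {ci_method!r}")

    p = safe_z_p(indirect, se_indirect)
    if not (0 <= proportion <= 1):
        warnings.warn(
            f"inconsistent mediation: proportion mediated {proportion:.4g} "
            "outside [0, 1]; reported verbatim",
            stacklevel=2,
        )
    return MediationResult(
        beta0=beta0,
        se0=se0,
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        indirect=indirect,
        se_indirect=se_indirect,
        proportion=proportion,
        proportion_ci_low=float(ci[0]),
        proportion_ci_high=float(ci[1]),
        proportion_p=p,
    )
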