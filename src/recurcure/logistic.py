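"""Logistic-link dependent-frailty mixture cure model (two-stage estimator).

The logistic variant fixes the log-frailty correlation at 1/sqrt(2) by
construction and is estimated by alternating two stages: (beta, alpha) from
the event terms plus the conditional log-gamma frailty prior, then gamma
from the censored survival terms at frozen (beta, alpha).  See
:mod:`recurcure.mcem` for the shared machinery and ``docs/methods.md`` for
why the stage-2 objective retains the event contribution.
"""

from __future__ import annotations

import numpy as np

from .mcem import fit_logistic

__all__ = ["fit_logistic", "logistic_hazard_multiplier"]


def logistic_hazard_multiplier(pairs):
    """e^{omega1} = u1 * u2: the latency hazard multiplier of the logistic
    model, used identically in simulation and estimation (E[u1 u2] = 1)."""
    return np.asarray(pairs.u1, dtype=float) * np.asarray(pairs.u2, dtype=float)
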