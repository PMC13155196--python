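"""Shared (identical) frailty mixture cure comparator model.

A single gamma frailty u ~ Gamma(alpha, alpha) enters both the clog-log
incidence linear predictor (omega2 = log u) and the latency hazard
(multiplier u).  Estimated with the same MCEM machinery as the dependent
clog-log model; alpha maximises the univariate log-gamma block.
"""

from __future__ import annotations

import numpy as np

from .mcem import fit_identical

__all__ = ["fit_identical", "identical_density_check"]


def identical_density_check(t, zbeta, vgamma, u, baseline):
    """Evaluate the closed-form overall gap-time density of the
    shared-frailty model,

        f(t | u) = lambda0(t) u e^{Z'beta}
                   * exp(-Lambda0(t) e^{Z'beta} u - e^{V'gamma}),

    in which the clog-log cure weight appears inside the exponent.  This is
    a numerical-consistency check against pi * f1 (the mixture event
    density) — note exp(-e^{V'gamma}) is pi at omega2 = 0, so this
    form equals pi|_{omega2=0} * f1(t | u); it is exposed for unit testing,
    not used in estimation.
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    rate = np.exp(np.asarray(zbeta, dtype=float)) * u
    return (
        baseline.hazard_at(t)
        * rate
        * np.exp(-baseline.cumulative(t) * rate
                 - np.exp(np.asarray(vgamma, dtype=float)))
    )
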