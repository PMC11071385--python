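"""Synthesize datasets from a fitted model.

Under the Gaussian assumption, a fitted signal/noise decomposition fully
specifies a generative model; sampling from it closes the fit-simulate
loop and supports model checks (e.g. comparing histograms of synthesized
and measured responses).
"""

from __future__ import annotations

import numpy as np

from .data import ResponseData
from .gsn import GSNResult
from .psd import is_psd
from .simulate import sample_mvn

__all__ = ["synthesize_from_fit"]


def synthesize_from_fit(fit: GSNResult, c: int, t: int, seed=None) -> ResponseData:
    """Generate ``(n, c, t)`` responses from a fitted decomposition:
    per-condition draws from N(mu_signal, Sigma_signal) plus per-trial
    draws from N(0, Sigma_noise).

    Rank-deficient fitted covariances are sampled via eigendecomposition
    with zero-variance directions fixed at zero.
    """
    if c < 2 or t < 2:
        raise ValueError("need c >= 2 conditions and t >= 2 trials")
    for label, cov in (("signal", fit.signal.covariance), ("noise", fit.noise.covariance)):
        if not is_psd(cov):
            raise ValueError(f"fitted {label} covariance is not PSD")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = fit.signal.n_units
    sig = sample_mvn(fit.signal.mean, fit.signal.covariance, c, rng)
    noi = sample_mvn(np.zeros(n), fit.noise.covariance, c * t, rng).reshape(c, t, n)
    return ResponseData((sig[:, None, :] + noi).transpose(2, 0, 1))
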