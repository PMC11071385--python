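"""Ground-truth scenarios, Gaussian data synthesis, and the recovery
benchmark.

Scenarios pair a known signal distribution with a known noise
distribution.  Synthetic measurements are generated per the additive
model: one signal draw per condition, plus an independent noise draw per
trial.  The benchmark fits a registry of estimation methods to many
synthetic datasets and scores recovery of covariance values (R^2 over the
upper triangle including the diagonal), effective dimensionality, and
power-law exponent of the eigenspectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GaussianMoments, ResponseData, naive_estimates
from .eigen import effective_dimensionality, eigendecompose, fit_power_law
from .psd import is_psd

__all__ = [
    "Scenario",
    "make_simple_scenario",
    "make_powerlaw_scenario",
    "synthesize",
    "sample_mvn",
    "recovery_r2",
    "run_benchmark",
    "METHOD_NAMES",
]

#: registry of estimation methods usable in the benchmark (fixed integers
#: key the per-method random substreams, so adding a method never perturbs
#: data generation or other methods' seeds)
_METHOD_IDS = {
    "naive": 1,
    "gsn": 2,
    "gsn-noshrink": 3,
    "splithalf": 4,
    "cvpca": 5,
    "meme": 6,
}
METHOD_NAMES = tuple(_METHOD_IDS)


@dataclass
class Scenario:
    """Ground-truth signal and noise distributions plus metadata."""

    name: str
    signal: GaussianMoments
    noise: GaussianMoments
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal.n_units != self.noise.n_units:
            raise ValueError("signal and noise dimensions differ")
        for label, mom in (("signal", self.signal), ("noise", self.noise)):
            if not is_psd(mom.covariance):
                raise ValueError(f"{label} covariance is not PSD")

    @property
    def n_units(self) -> int:
        return self.signal.n_units


def make_simple_scenario() -> Scenario:
    """Ten-unit scenario with block-correlated signal and noise.

    Signal: unit variance everywhere, covariance 0.5 (r = 0.5) among units
    1-5.  Noise: variance 2 everywhere, covariance 1 (r = 0.5) among units
    4-8.  Both distributions are zero-mean.  The two correlated blocks
    overlap on units 4-5, so signal and noise structure are entangled in
    the raw measurements.
    """
    n = 10
    sig = np.eye(n)
    sig[:5, :5] = 0.5
    np.fill_diagonal(sig[:5, :5], 1.0)
    noi = 2.0 * np.eye(n)
    noi[3:8, 3:8] = 1.0
    np.fill_diagonal(noi[3:8, 3:8], 2.0)
    zero = np.zeros(n)
    return Scenario(
        "simple",
        GaussianMoments(zero, sig),
        GaussianMoments(zero, noi),
        {"n": n},
    )


def _random_orthonormal(n: int, seed_key) -> np.ndarray:
    """Deterministic random orthonormal basis (QR of a seeded standard
    normal matrix, R-diagonal signs fixed)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    Q, R = np.linalg.qr(rng.standard_normal((n, n)))
    return Q * np.sign(np.diag(R))


def make_powerlaw_scenario(
    n: int, alpha_signal: float, alpha_noise: float, seed: int = 0
) -> Scenario:
    """Zero-mean scenario whose signal and noise eigenspectra follow
    ``d**(-alpha)``.

    Eigenvectors are random orthonormal bases determined by ``(n, seed)``
    and the role (signal vs noise): scenarios sharing ``(n, seed)`` have
    identical eigenvectors across different exponents, so the exponent is
    the only thing that varies between them.
    """
    if n < 2:
        raise ValueError("need at least 2 units")
    if alpha_signal <= 0 or alpha_noise <= 0:
        raise ValueError("power-law exponents must be positive")
    d = np.arange(1, n + 1, dtype=float)
    covs = {}
    for role, alpha, tag in (("signal", alpha_signal, 1), ("noise", alpha_noise, 2)):
        V = _random_orthonormal(n, [n, seed, tag])
        covs[role] = (V * d ** (-alpha)) @ V.T
    zero = np.zeros(n)
    return Scenario(
        f"powerlaw-n{n}-s{alpha_signal}-n{alpha_noise}",
        GaussianMoments(zero, 0.5 * (covs["signal"] + covs["signal"].T)),
        GaussianMoments(zero, 0.5 * (covs["noise"] + covs["noise"].T)),
        {
            "n": n,
            "alpha_signal": alpha_signal,
            "alpha_noise": alpha_noise,
            "seed": seed,
        },
    )


def sample_mvn(mean, cov, size: int, rng) -> np.ndarray:
    """Draw from a multivariate normal via eigendecomposition.

    Handles rank-deficient covariances by fixing zero-variance directions
    at zero (tiny negative eigenvalues from round-off are clipped).
    """
    mean = np.asarray(mean, dtype=float).ravel()
    w, V = np.linalg.eigh(np.asarray(cov, dtype=float))
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)
    return mean + rng.standard_normal((size, mean.size)) @ A.T


def synthesize(scenario: Scenario, c: int, t: int, seed=None) -> ResponseData:
    """Generate an ``(n, c, t)`` dataset: ``c`` independent signal draws,
    each combined with ``t`` independent noise draws."""
    if c < 2 or t < 2:
        raise ValueError("need c >= 2 conditions and t >= 2 trials")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scenario.n_units
    sig = sample_mvn(scenario.signal.mean, scenario.signal.covariance, c, rng)
    noi = sample_mvn(
        np.zeros(n), scenario.noise.covariance, c * t, rng
    ).reshape(c, t, n)
    values = (sig[:, None, :] + noi).transpose(2, 0, 1)
    return ResponseData(values)


def recovery_r2(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Coefficient of determination over the upper triangle (including
    the diagonal) of a covariance matrix, relative to ground truth."""
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.shape != truth.shape or estimated.ndim != 2:
        raise ValueError("matrices must have the same square shape")
    iu = np.triu_indices(truth.shape[0])
    e, g = estimated[iu], truth[iu]
    denom = float(np.sum((g - g.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("constant ground-truth covariance; R^2 undefined")
    return 1.0 - float(np.sum((e - g) ** 2)) / denom


def _fit_method(name: str, data: ResponseData, rng) -> dict:
    """Fit one registry method; returns whichever of signal/noise
    covariance or eigenspectrum the method provides."""
    from .baselines import (
        cvpca_signal_eigenspectrum,
        meme_signal_eigenspectrum,
        split_half_signal_cov,
    )
    from .gsn import GSN

    if name == "naive":
        s, n_ = naive_estimates(data)
        return {"signal_cov": s, "noise_cov": n_}
    if name == "gsn":
        fit = GSN(want_shrinkage=True, random_state=rng).fit(data)
        return {"signal_cov": fit.signal_cov_, "noise_cov": fit.noise_cov_}
    if name == "gsn-noshrink":
        fit = GSN(want_shrinkage=False, random_state=rng).fit(data)
        return {"signal_cov": fit.signal_cov_, "noise_cov": fit.noise_cov_}
    if name == "splithalf":
        return {"signal_cov": split_half_signal_cov(data, random_state=rng)}
    if name == "cvpca":
        return {"signal_spectrum": cvpca_signal_eigenspectrum(data, random_state=rng)}
    if name == "meme":
        spec, expo, icept, ok = meme_signal_eigenspectrum(data, random_state=rng)
        return {"signal_spectrum": spec, "meme_exponent": expo, "meme_converged": ok}
    raise ValueError(f"unknown method {name!r}; known: {METHOD_NAMES}")


def _spectrum_metrics(spectrum: np.ndarray) -> tuple[float, float]:
    """(effective dimensionality, power-law exponent) of a spectrum."""
    ed = effective_dimensionality(spectrum)
    slope, _, _ = fit_power_law(np.sort(spectrum)[::-1])
    return ed, -slope


def run_benchmark(
    scenarios,
    c_grid,
    t_grid,
    methods,
    n_sims: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery benchmark over scenarios x conditions x trials x methods.

    For each cell, ``n_sims`` datasets are synthesized from deterministic
    per-(cell, sim) substreams of the master seed, every method is fit,
    and recovery metrics are averaged across simulations.  Returns a
    long-form table with one row per (scenario, method, c, t), including
    the ground-truth ED and exponent for reference.
    """
    scenarios = list(scenarios)
    c_grid, t_grid = list(c_grid), list(t_grid)
    methods = list(methods)
    if not (scenarios and c_grid and t_grid and methods):
        raise ValueError("scenario, grid and method lists must be non-empty")
    for m in methods:
        if m not in _METHOD_IDS:
            raise ValueError(f"unknown method {m!r}; known: {METHOD_NAMES}")

    rows = []
    for si, scen in enumerate(scenarios):
        truth = {
            "signal": scen.signal.covariance,
            "noise": scen.noise.covariance,
        }
        tru_spec = {
            role: np.sort(np.linalg.eigvalsh(cov))[::-1]
            for role, cov in truth.items()
        }
        tru_metrics = {role: _spectrum_metrics(s) for role, s in tru_spec.items()}
        for c in c_grid:
            for t in t_grid:
                cell: dict[str, dict[str, list]] = {
                    m: {k: [] for k in (
                        "r2_signal", "r2_noise", "ed_signal", "ed_noise",
                        "exp_signal", "exp_noise",
                    )}
                    for m in methods
                }
                for sim in range(n_sims):
                    data_rng = np.random.default_rng(
                        np.random.SeedSequence([seed, si, int(c), int(t), sim])
                    )
                    data = synthesize(scen, int(c), int(t), data_rng)
                    for m in methods:
                        m_rng = np.random.default_rng(
                            np.random.SeedSequence(
                                [seed, si, int(c), int(t), sim, _METHOD_IDS[m]]
                            )
                        )
                        est = _fit_method(m, data, m_rng)
                        rec = cell[m]
                        if "signal_cov" in est:
                            rec["r2_signal"].append(
                                recovery_r2(est["signal_cov"], truth["signal"])
                            )
                            spec = eigendecompose(est["signal_cov"]).eigenvalues
                            ed, ex = _spectrum_metrics(spec)
                            rec["ed_signal"].append(ed)
                            rec["exp_signal"].append(ex)
                        if "noise_cov" in est:
                            rec["r2_noise"].append(
                                recovery_r2(est["noise_cov"], truth["noise"])
                            )
                            spec = eigendecompose(est["noise_cov"]).eigenvalues
                            ed, ex = _spectrum_metrics(spec)
                            rec["ed_noise"].append(ed)
                            rec["exp_noise"].append(ex)
                        if "signal_spectrum" in est:
                            ed, ex = _spectrum_metrics(est["signal_spectrum"])
                            rec["ed_signal"].append(ed)
                            rec["exp_signal"].append(ex)
                for m in methods:
                    rec = cell[m]

                    def _mean(key):
                        return float(np.mean(rec[key])) if rec[key] else np.nan

                    rows.append(
                        {
                            "scenario": scen.name,
                            "method": m,
                            "c": int(c),
                            "t": int(t),
                            "n_sims": n_sims,
                            "r2_signal": _mean("r2_signal"),
                            "r2_noise": _mean("r2_noise"),
                            "ed_signal_mean": _mean("ed_signal"),
                            "ed_noise_mean": _mean("ed_noise"),
                            "exponent_signal_mean": _mean("exp_signal"),
                            "exponent_noise_mean": _mean("exp_noise"),
                            "ed_signal_true": tru_metrics["signal"][0],
                            "ed_noise_true": tru_metrics["noise"][0],
                            "exponent_signal_true": tru_metrics["signal"][1],
                            "exponent_noise_true": tru_metrics["noise"][1],
                        }
                    )
    return pd.DataFrame(rows)
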