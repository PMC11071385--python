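"""gsnkit: generative modeling of signal and noise (GSN).

Decomposes repeated-trial multivariate measurements — an array of shape
(units, conditions, trials) — into a signal distribution (covariance
across conditions of the noiseless responses) and a noise distribution
(trial-to-trial covariance), with shrinkage regularization, a positive
semi-definite constraint, baseline estimators, eigenspectrum analytics,
and a ground-truth simulation benchmark.
"""

from .baselines import (
    CVPCA,
    MEMESpectrum,
    SplitConfig,
    SplitHalfCovariance,
    cvpca_signal_eigenspectrum,
    estimate_signal_eigenmoments,
    meme_signal_eigenspectrum,
    split_half_signal_cov,
)
from .data import (
    GaussianMoments,
    ResponseData,
    covariance_to_correlation,
    naive_estimates,
    pooled_noise_covariance,
    sample_covariance,
    trial_average,
    zscore_units,
)
from .eigen import (
    Eigenspectrum,
    align_pc_signs,
    cross_subject_consistency,
    effective_dimensionality,
    eigendecompose,
    fit_power_law,
    project_scores,
    splithalf_pc_reliability,
)
from .gsn import GSN, GSNResult, convergence_check, noise_update, perform_gsn
from .psd import is_psd, nearest_psd
from .shrinkage import (
    ShrinkageFit,
    ShrunkCovarianceCV,
    apply_shrinkage,
    cv_select_shrinkage,
    default_fraction_grid,
    gaussian_nll,
)
from .simulate import (
    Scenario,
    make_powerlaw_scenario,
    make_simple_scenario,
    recovery_r2,
    run_benchmark,
    sample_mvn,
    synthesize,
)
from .synthesis import synthesize_from_fit

__version__ = "0.1.0"

# naive estimation exposed under the same registry shape as the estimator
# classes for symmetry in user code
class NaiveDecomposition:
    """Naive signal/noise covariance estimates (trial-averaged sample
    covariance; aggregated residual covariance with denominator c*t - 1).

    Attributes (after fit): ``signal_cov_``, ``noise_cov_``.
    """

    def fit(self, X, y=None):
        self.signal_cov_, self.noise_cov_ = naive_estimates(X)
        return self

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self
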