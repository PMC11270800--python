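"""Bayesian bivariate GLMM for arm-based meta-analysis of binary outcomes.

The model: for study i with event counts X_ik ~ Binomial(n_ik, pi_ik) in
arms k = 0 (control) and k = 1 (experimental), the logit-transformed event
probabilities share a bivariate normal random effect

    (logit(pi_i0), logit(pi_i1)) ~ N((mu0, mu1), Sigma),
    Sigma = [[s0^2, rho*s0*s1], [rho*s0*s1, s1^2]].

rho is the between-arm correlation: it links the two arms across studies
and is the channel through which single-arm studies borrow strength.
Priors (weakly informative): mu_k ~ N(0, mu_sd^2), sigma_k ~ U(0,
sigma_upper), rho ~ U(rho_lower, rho_upper); rho may instead be fixed at a
constant, which is how the tipping-point grid refits are performed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln, logit
from sklearn.base import BaseEstimator

from . import _sampler
from .data import MetaDataset

__all__ = [
    "ModelConfig",
    "PriorConfig",
    "McmcConfig",
    "BGLMM",
    "fit",
    "compute_dic",
    "select_model",
    "summarize",
    "retained_draws",
]

PARAMS = list(_sampler.PAR_COLS)

RHAT_THRESHOLD = 1.05


# ---------------------------------------------------------------------------
# configuration containers (thin; the estimator holds the same fields flat)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    link: str = "logit"
    variance_structure: str = "equal"      # equal | unequal | auto
    rho_mode: str = "free"                 # free | fixed
    rho_value: float | None = None

    def __post_init__(self):
        if self.link != "logit":
            raise ValueError("only the logit link is supported")
        if self.variance_structure not in ("equal", "unequal", "auto"):
            raise ValueError(f"unknown variance structure {self.variance_structure!r}")
        if self.rho_mode not in ("free", "fixed"):
            raise ValueError(f"unknown rho mode {self.rho_mode!r}")
        if (self.rho_value is None) != (self.rho_mode == "free"):
            raise ValueError("rho_value is required iff rho_mode='fixed'")
        if self.rho_value is not None and not -1 < self.rho_value < 1:
            raise ValueError("rho_value must lie strictly inside (-1, 1)")


@dataclass(frozen=True)
class PriorConfig:
    mu_sd: float = 100.0
    sigma_upper: float = 10.0
    rho_lower: float = -1.0
    rho_upper: float = 1.0

    def __post_init__(self):
        if self.mu_sd <= 0 or self.sigma_upper <= 0:
            raise ValueError("mu_sd and sigma_upper must be positive")
        if not (-1 <= self.rho_lower < self.rho_upper <= 1):
            raise ValueError("need -1 <= rho_lower < rho_upper <= 1")


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 3
    adaptation: int = 10_000
    iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1 or self.iterations < 1 or self.thin < 1:
            raise ValueError("chains, iterations and thin must be positive")
        if self.adaptation < 0 or self.burn_in < 0:
            raise ValueError("adaptation and burn_in must be nonnegative")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")


def retained_draws(chains: int, iterations: int, burn_in: int, thin: int) -> int:
    """Total retained posterior draws across chains."""
    return chains * ((iterations - burn_in) // thin)


def summarize(draws) -> tuple[float, float, float]:
    """Posterior median and equal-tailed 95% credible interval.

    Returns (median, 2.5% quantile, 97.5% quantile).
    """
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot summarize an empty draw vector")
    lo, med, hi = np.quantile(arr, [0.025, 0.5, 0.975])
    return float(med), float(lo), float(hi)


def _dataset_digest(d: MetaDataset) -> str:
    return hashlib.sha256(d.to_csv().encode()).hexdigest()[:16]


def _log_binom_pmf(x, n, theta):
    """log Binomial(x; n, expit(theta)), numerically stable in theta."""
    return (gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
            + x * theta - n * np.logaddexp(0.0, theta))


def _deviance(x, n, obs, theta):
    """Conditional deviance -2 log L given the study-level latents.

    ``theta`` may be (N, 2) or (M, N, 2); observed arms only.
    """
    ll = _log_binom_pmf(x, n, theta)
    ll = np.where(obs, ll, 0.0)
    return -2.0 * ll.sum(axis=(-2, -1))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class BGLMM(BaseEstimator):
    """Arm-based bivariate GLMM fitted by MCMC.

    Follows the scikit-learn estimator protocol: hyperparameters in
    ``__init__``, data passed to :meth:`fit`, results in trailing-underscore
    attributes.

    Parameters
    ----------
    variance_structure : {'equal', 'unequal', 'auto'}
        Whether the two arms share one between-study SD.  ``'auto'`` fits
        both variants and keeps the one preferred by the DIC rule
        (the simpler model is kept unless its DIC exceeds the other's by
        more than ``dic_threshold``).
    rho_mode : {'free', 'fixed'}
        ``'free'`` places a uniform prior on the between-arm correlation;
        ``'fixed'`` holds it at ``rho_value`` (used by the tipping grid).
    rho_value : float, optional
        Value of rho when ``rho_mode='fixed'``.
    mu_sd, sigma_upper, rho_lower, rho_upper : float
        Prior hyperparameters: N(0, mu_sd^2) on the fixed effects,
        U(0, sigma_upper) on the between-study SDs, U(rho_lower, rho_upper)
        on rho.
    chains, adaptation, iterations, burn_in, thin : int
        MCMC schedule.  The defaults (3 chains of 100,000 iterations with
        10,000 adaptation, 10,000 burn-in, thinning 2) retain 135,000 draws.
    seed : int
        Base seed; per-chain seeds are derived deterministically.
    keep_latent : bool
        Retain per-draw study-level latents (required for DIC; on by
        default).
    dic_threshold : float
        Absolute-difference DIC rule margin used when
        ``variance_structure='auto'``.

    Attributes
    ----------
    draws_ : pandas.DataFrame
        Retained draws with columns mu0, mu1, sigma0, sigma1, rho.
    latent_ : ndarray of shape (n_draws, N, 2) or None
        Retained latent logit event probabilities.
    summaries_ : pandas.DataFrame
        Posterior median and equal-tailed 95% CrI per parameter.
    dic_, pd_ : float
        Deviance information criterion and its effective-parameter penalty.
    rhat_ : dict
        Split-chain potential scale reduction factor per parameter.
    converged_ : bool
        True when every R-hat is below 1.05; a failing fit is flagged and
        warned about, never discarded silently.
    selected_structure_ : str
        Variance structure actually fitted (resolves 'auto').
    candidates_ : dict
        Present after an 'auto' fit: the two candidate fits keyed by
        structure name.
    """

    def __init__(self, variance_structure="equal", rho_mode="free",
                 rho_value=None, mu_sd=100.0, sigma_upper=10.0,
                 rho_lower=-1.0, rho_upper=1.0, chains=3, adaptation=10_000,
                 iterations=100_000, burn_in=10_000, thin=2, seed=0,
                 keep_latent=True, dic_threshold=3.0):
        self.variance_structure = variance_structure
        self.rho_mode = rho_mode
        self.rho_value = rho_value
        self.mu_sd = mu_sd
        self.sigma_upper = sigma_upper
        self.rho_lower = rho_lower
        self.rho_upper = rho_upper
        self.chains = chains
        self.adaptation = adaptation
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.keep_latent = keep_latent
        self.dic_threshold = dic_threshold

    # -- configuration plumbing -----------------------------------------
    @classmethod
    def from_configs(cls, model: ModelConfig | None = None,
                     prior: PriorConfig | None = None,
                     mcmc: McmcConfig | None = None, **extra) -> "BGLMM":
        model = model or ModelConfig()
        prior = prior or PriorConfig()
        mcmc = mcmc or McmcConfig()
        return cls(variance_structure=model.variance_structure,
                   rho_mode=model.rho_mode, rho_value=model.rho_value,
                   mu_sd=prior.mu_sd, sigma_upper=prior.sigma_upper,
                   rho_lower=prior.rho_lower, rho_upper=prior.rho_upper,
                   chains=mcmc.chains, adaptation=mcmc.adaptation,
                   iterations=mcmc.iterations, burn_in=mcmc.burn_in,
                   thin=mcmc.thin, seed=mcmc.seed, **extra)

    def _validate_params(self):
        ModelConfig(variance_structure=self.variance_structure,
                    rho_mode=self.rho_mode, rho_value=self.rho_value)
        PriorConfig(self.mu_sd, self.sigma_upper, self.rho_lower,
                    self.rho_upper)
        McmcConfig(self.chains, self.adaptation, self.iterations,
                   self.burn_in, self.thin, int(self.seed))

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None):
        """Sample the posterior for the dataset ``X``.

        ``X`` is a :class:`~armtip.data.MetaDataset` or a DataFrame with
        columns study_id, x0, n0, x1, n1.
        """
        self._validate_params()
        d = X if isinstance(X, MetaDataset) else MetaDataset.from_frame(X)

        if self.variance_structure == "auto":
            return self._fit_auto(d)

        if self.rho_mode == "free" and len(d) < 2:
            warnings.warn("a free between-arm correlation is not "
                          "identifiable from a single study", UserWarning)

        x, n, obs = d.arm_arrays()
        n_keep = (self.iterations - self.burn_in) // self.thin
        seeds = np.random.SeedSequence(int(self.seed)).generate_state(
            self.chains * 2).astype(np.int64) % (2 ** 31)
        chain_seeds = seeds[: self.chains]
        init_seeds = seeds[self.chains:]

        # crude observed logits for initialisation
        with np.errstate(divide="ignore"):
            emp = logit((x + 0.5) / (n + 1.0))
        emp[~obs] = np.nanmean(emp[obs]) if obs.any() else 0.0

        par_chains = []
        theta_chains = []
        equal = self.variance_structure == "equal"
        fixed = self.rho_mode == "fixed"
        for c in range(self.chains):
            rng = np.random.default_rng(int(init_seeds[c]))
            theta0 = emp + rng.normal(0.0, 0.5, size=emp.shape)
            mu0 = theta0.mean(axis=0) + rng.normal(0.0, 0.5, size=2)
            sig0 = rng.uniform(0.3, min(2.0, self.sigma_upper), size=2)
            rho0 = float(np.clip(rng.uniform(-0.5, 0.5),
                                 self.rho_lower + 0.01,
                                 self.rho_upper - 0.01))
            par, theta = _sampler.run_chain(
                x, n, obs, float(self.mu_sd), float(self.sigma_upper),
                float(self.rho_lower), float(self.rho_upper),
                equal, fixed, float(self.rho_value or 0.0),
                int(self.adaptation), int(self.iterations),
                int(self.burn_in), int(self.thin), int(chain_seeds[c]),
                theta0, mu0, sig0, rho0)
            par_chains.append(par)
            theta_chains.append(theta)

        par_all = np.concatenate(par_chains, axis=0)
        theta_all = np.concatenate(theta_chains, axis=0)
        assert par_all.shape[0] == self.chains * n_keep

        self.dataset_ = d
        self.dataset_digest_ = _dataset_digest(d)
        self.selected_structure_ = self.variance_structure
        self.draws_ = pd.DataFrame(par_all, columns=PARAMS)
        self.latent_ = theta_all if self.keep_latent else None
        self.n_draws_ = int(par_all.shape[0])
        self.summaries_ = pd.DataFrame(
            [summarize(self.draws_[p]) for p in PARAMS],
            index=PARAMS, columns=["median", "lower", "upper"])
        self.rhat_ = self._compute_rhat(par_chains)
        finite_rhats = [v for v in self.rhat_.values() if np.isfinite(v)]
        self.converged_ = bool(all(v < RHAT_THRESHOLD for v in finite_rhats))
        if not self.converged_:
            warnings.warn(
                f"convergence flag raised: max split R-hat = "
                f"{max(finite_rhats):.3f} >= {RHAT_THRESHOLD}", UserWarning)
        self.dic_, self.pd_ = self._dic_from_draws(x, n, obs, theta_all)
        return self

    def _fit_auto(self, d: MetaDataset):
        sub_seeds = np.random.SeedSequence(int(self.seed)).generate_state(4)
        cands = {}
        for structure, s in (("equal", sub_seeds[2]), ("unequal", sub_seeds[3])):
            m = self._clone_with(variance_structure=structure,
                                 seed=int(s % (2 ** 31)))
            cands[structure] = m.fit(d)
        chosen = select_model(cands["equal"], cands["unequal"],
                              threshold=self.dic_threshold)
        best = cands[chosen]
        for attr in ("dataset_", "dataset_digest_", "draws_", "latent_",
                     "n_draws_", "summaries_", "rhat_", "converged_",
                     "dic_", "pd_"):
            setattr(self, attr, getattr(best, attr))
        self.selected_structure_ = chosen
        self.candidates_ = cands
        return self

    def _clone_with(self, **overrides):
        params = self.get_params()
        params.update(overrides)
        return BGLMM(**params)

    @staticmethod
    def _compute_rhat(par_chains) -> dict:
        if len(par_chains) < 2:
            return {p: float("nan") for p in PARAMS}
        import arviz as az
        stack = np.stack(par_chains)  # (chain, draw, param)
        out = {}
        for j, p in enumerate(PARAMS):
            col = stack[:, :, j]
            if np.allclose(col, col.flat[0]):   # fixed rho, equal sigmas
                out[p] = 1.0
            else:
                out[p] = float(az.rhat(col))
        return out

    def _dic_from_draws(self, x, n, obs, theta_all):
        dev = _deviance(x, n, obs, theta_all)
        dbar = float(dev.mean())
        theta_bar = theta_all.mean(axis=0)
        dhat = float(_deviance(x, n, obs, theta_bar))
        p_d = dbar - dhat
        return dbar + p_d, p_d

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "model": "arm-based bivariate GLMM (logit link)",
            "params": self.get_params(),
            "selected_structure": self.selected_structure_,
            "n_draws": self.n_draws_,
            "summaries": {p: dict(zip(("median", "lower", "upper"),
                                      map(float, self.summaries_.loc[p])))
                          for p in PARAMS},
            "dic": self.dic_,
            "pd": self.pd_,
            "rhat": self.rhat_,
            "converged": self.converged_,
            "dataset_digest": self.dataset_digest_,
        }
        return json.dumps(payload, indent=1)

    def draws_to_csv(self, path_or_buf=None):
        """Export retained draws, one column per parameter."""
        return self.draws_.to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit(d: MetaDataset, model: ModelConfig | None = None,
        prior: PriorConfig | None = None,
        mcmc: McmcConfig | None = None) -> BGLMM:
    """Fit the BGLMM; convenience wrapper over the estimator class."""
    return BGLMM.from_configs(model, prior, mcmc).fit(d)


def compute_dic(fitted: BGLMM, d: MetaDataset | None = None) -> tuple[float, float]:
    """Recompute (DIC, pD) from a fitted model's retained latent draws.

    DIC = Dbar + pD with the conditional (latent-focused) deviance
    D(theta) = -2 sum log Binomial(x_ik; n_ik, expit(theta_ik)) over
    observed arms; pD = Dbar - D(posterior mean of the latents).
    """
    if getattr(fitted, "latent_", None) is None:
        raise ValueError("latent draws were not retained; refit with "
                         "keep_latent=True to compute the DIC")
    data = d if d is not None else fitted.dataset_
    if d is not None and _dataset_digest(d) != fitted.dataset_digest_:
        raise ValueError("dataset does not match the one the model was fitted on")
    x, n, obs = data.arm_arrays()
    return fitted._dic_from_draws(x, n, obs, fitted.latent_)


def select_model(fit_equal: BGLMM, fit_unequal: BGLMM,
                 threshold: float = 3.0) -> str:
    """DIC model selection with the absolute-difference rule.

    Keeps the simpler equal-SD model unless its DIC exceeds the unequal-SD
    model's by more than ``threshold`` (default 3).
    """
    if isinstance(fit_equal, BGLMM):
        if fit_equal.dataset_digest_ != fit_unequal.dataset_digest_:
            raise ValueError("fits were obtained on different datasets")
        dic_e, dic_u = fit_equal.dic_, fit_unequal.dic_
    else:  # allow raw DIC numbers for decision-logic checks
        dic_e, dic_u = float(fit_equal), float(fit_unequal)
    return "equal" if dic_e - dic_u <= threshold else "unequal"
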