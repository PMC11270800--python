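"""Adaptive Metropolis-within-Gibbs sampler for the bivariate GLMM.

Parameter block layout, per iteration:
  1. study-level latents theta[i, k] = logit(pi_ik): scalar random-walk
     Metropolis against binomial likelihood x conditional normal prior;
  2. (mu0, mu1): exact conjugate bivariate-normal draw given latents and
     Sigma (normal prior N(0, mu_sd^2) per component);
  3. sigma(s): scalar random walk within (0, sigma_upper);
  4. rho: scalar random walk within (rho_lower, rho_upper), skipped when
     rho is fixed.

Step sizes are tuned toward 0.44 acceptance during a dedicated adaptation
phase only; the retained draws come from a fixed-kernel chain.
"""

import numpy as np
from numba import njit

# parameter columns in the output array
PAR_COLS = ("mu0", "mu1", "sigma0", "sigma1", "rho")

_SIGMA_FLOOR = 1e-6
_RHO_CAP = 0.9999


@njit(cache=True)
def _softplus(t):
    if t > 35.0:
        return t
    if t < -35.0:
        return np.exp(t)
    return np.log1p(np.exp(t))


@njit(cache=True)
def _arm_loglik(x, n, t):
    # binomial log-likelihood in the logit parameter, up to the constant
    return x * t - n * _softplus(t)


@njit(cache=True)
def _bvn_loglik(theta, mu0, mu1, s0, s1, r):
    om = 1.0 - r * r
    c = -np.log(s0) - np.log(s1) - 0.5 * np.log(om)
    tot = 0.0
    for i in range(theta.shape[0]):
        z0 = (theta[i, 0] - mu0) / s0
        z1 = (theta[i, 1] - mu1) / s1
        tot += c - 0.5 * (z0 * z0 - 2.0 * r * z0 * z1 + z1 * z1) / om
    return tot


@njit(cache=True)
def run_chain(x, n, obs, mu_sd, sigma_upper, rho_lower, rho_upper,
              equal_sd, rho_fixed, rho_value,
              n_adapt, n_iter, n_burn, thin, seed,
              theta_init, mu_init, sigma_init, rho_init):
    np.random.seed(seed)
    N = x.shape[0]
    theta = theta_init.copy()
    mu0 = mu_init[0]
    mu1 = mu_init[1]
    s0 = sigma_init[0]
    s1 = sigma_init[1] if not equal_sd else sigma_init[0]
    rho = rho_value if rho_fixed else rho_init

    step_t = np.full((N, 2), 1.0)
    step_s0 = 0.5
    step_s1 = 0.5
    step_r = 0.3

    n_keep = (n_iter - n_burn) // thin
    out_par = np.empty((n_keep, 5))
    out_theta = np.empty((n_keep, N, 2))
    kept = 0

    total = n_adapt + n_iter
    for it in range(total):
        adapting = it < n_adapt
        gam = 0.0
        if adapting:
            gam = 5.0 / np.sqrt(it + 10.0)
            if gam > 0.25:
                gam = 0.25

        # --- latents ---------------------------------------------------
        for i in range(N):
            for k in range(2):
                j = 1 - k
                sk = s0 if k == 0 else s1
                sj = s0 if j == 0 else s1
                muk = mu0 if k == 0 else mu1
                muj = mu0 if j == 0 else mu1
                cmean = muk + rho * sk / sj * (theta[i, j] - muj)
                cvar = sk * sk * (1.0 - rho * rho)
                t_cur = theta[i, k]
                t_prop = t_cur + step_t[i, k] * np.random.normal()
                lr = (-0.5 * (t_prop - cmean) ** 2 + 0.5 * (t_cur - cmean) ** 2) / cvar
                if obs[i, k]:
                    lr += (_arm_loglik(x[i, k], n[i, k], t_prop)
                           - _arm_loglik(x[i, k], n[i, k], t_cur))
                acc = 0.0
                if np.log(np.random.random()) < lr:
                    theta[i, k] = t_prop
                    acc = 1.0
                if adapting:
                    step_t[i, k] *= np.exp(gam * (acc - 0.44))

        # --- mu: conjugate bivariate normal ------------------------------
        om = 1.0 - rho * rho
        a = 1.0 / (s0 * s0 * om)
        b = -rho / (s0 * s1 * om)
        c = 1.0 / (s1 * s1 * om)
        prior_prec = 1.0 / (mu_sd * mu_sd)
        p00 = N * a + prior_prec
        p01 = N * b
        p11 = N * c + prior_prec
        st0 = 0.0
        st1 = 0.0
        for i in range(N):
            st0 += theta[i, 0]
            st1 += theta[i, 1]
        b0 = a * st0 + b * st1
        b1 = b * st0 + c * st1
        det = p00 * p11 - p01 * p01
        m0 = (p11 * b0 - p01 * b1) / det
        m1 = (p00 * b1 - p01 * b0) / det
        # Cholesky of the 2x2 posterior covariance P^-1
        c00 = p11 / det
        c01 = -p01 / det
        c11 = p00 / det
        L00 = np.sqrt(c00)
        L10 = c01 / L00
        L11 = np.sqrt(c11 - L10 * L10)
        z0 = np.random.normal()
        z1 = np.random.normal()
        mu0 = m0 + L00 * z0
        mu1 = m1 + L10 * z0 + L11 * z1

        # --- sigma(s) ----------------------------------------------------
        if equal_sd:
            sp = s0 + step_s0 * np.random.normal()
            acc = 0.0
            if _SIGMA_FLOOR < sp < sigma_upper:
                lr = (_bvn_loglik(theta, mu0, mu1, sp, sp, rho)
                      - _bvn_loglik(theta, mu0, mu1, s0, s1, rho))
                if np.log(np.random.random()) < lr:
                    s0 = sp
                    s1 = sp
                    acc = 1.0
            if adapting:
                step_s0 *= np.exp(gam * (acc - 0.44))
        else:
            sp = s0 + step_s0 * np.random.normal()
            acc = 0.0
            if _SIGMA_FLOOR < sp < sigma_upper:
                lr = (_bvn_loglik(theta, mu0, mu1, sp, s1, rho)
                      - _bvn_loglik(theta, mu0, mu1, s0, s1, rho))
                if np.log(np.random.random()) < lr:
                    s0 = sp
                    acc = 1.0
            if adapting:
                step_s0 *= np.exp(gam * (acc - 0.44))
            sp = s1 + step_s1 * np.random.normal()
            acc = 0.0
            if _SIGMA_FLOOR < sp < sigma_upper:
                lr = (_bvn_loglik(theta, mu0, mu1, s0, sp, rho)
                      - _bvn_loglik(theta, mu0, mu1, s0, s1, rho))
                if np.log(np.random.random()) < lr:
                    s1 = sp
                    acc = 1.0
            if adapting:
                step_s1 *= np.exp(gam * (acc - 0.44))

        # --- rho -----------------------------------------------------------
        if not rho_fixed:
            rp = rho + step_r * np.random.normal()
            acc = 0.0
            if rho_lower < rp < rho_upper and -_RHO_CAP < rp < _RHO_CAP:
                lr = (_bvn_loglik(theta, mu0, mu1, s0, s1, rp)
                      - _bvn_loglik(theta, mu0, mu1, s0, s1, rho))
                if np.log(np.random.random()) < lr:
                    rho = rp
                    acc = 1.0
            if adapting:
                step_r *= np.exp(gam * (acc - 0.44))

        # --- retain --------------------------------------------------------
        if it >= n_adapt + n_burn:
            rel = it - n_adapt - n_burn
            if rel % thin == 0 and kept < n_keep:
                out_par[kept, 0] = mu0
                out_par[kept, 1] = mu1
                out_par[kept, 2] = s0
                out_par[kept, 3] = s1
                out_par[kept, 4] = rho
                for i in range(N):
                    out_theta[kept, i, 0] = theta[i, 0]
                    out_theta[kept, i, 1] = theta[i, 1]
                kept += 1

    return out_par, out_theta
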