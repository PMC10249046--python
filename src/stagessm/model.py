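"""Process and observation densities of the life-cycle state-space model.

Process model, on transformed scales (cohorts t = 1..T):

* recruitment   log rho_t     ~ Normal(w_R,t beta_R, sigma_p_R^2)
* survival      logit phi_i,t ~ Normal(w_i,t beta_Si, sigma_p_Si^2)

Abundance recursion within a cohort, initialised at N_{n,0}:

* N_{1,t} = rho_t N_{n,t-1};  N_{i,t} = phi_{i-1,t} N_{i-1,t} for 1 < i <= n.

Observation model for the survey index of stage i in cohort t:

* log Y_{i,t} ~ Normal(log(psi_i N_{i,t}) - sigma_o^2/2, sigma_o^2)

so that E[Y_{i,t}] = psi_i N_{i,t} on the natural scale.  All latent
variables are stored and integrated on the log/logit scale; the process
densities are plain normals on that scale (no Jacobian terms), which makes
the latent block Gaussian up to the observation nonlinearity and is the
standard parameterisation for Laplace-approximated random effects.

Because log-abundance is log N_{n,0} plus a cumulative sum of log vital
rates, analytic gradients and Hessians of the joint negative log-likelihood
with respect to the latent block are available and are used by the inner
Newton optimiser and the samplers.

A ``survival_link="log"`` variant (survival latent = log phi, normal on the
log scale) makes the whole model linear-Gaussian; it exists so the Laplace
approximation can be checked against the exact closed-form marginal.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.special import expit, log_expit

from .types import CovariateSet, Dataset, LatentStates, LifeCycleParams

__all__ = [
    "build_abundances",
    "process_logpdf",
    "observation_logpdf",
    "joint_nll",
    "rescale",
]

_LN2PI = float(np.log(2.0 * np.pi))


def _log_phi_terms(
    logit_phi: np.ndarray, survival_link: str
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log survival and its first two derivatives w.r.t. the latent scale."""
    if survival_link == "logit":
        L = log_expit(logit_phi)            # log phi = -softplus(-x)
        d1 = expit(-logit_phi)              # 1 - phi
        d2 = -expit(logit_phi) * d1         # -phi (1 - phi)
        return L, d1, d2
    if survival_link == "log":
        L = logit_phi
        return L, np.ones_like(L), np.zeros_like(L)
    raise ValueError(f"unknown survival_link {survival_link!r}")


def _log_phi_d3(logit_phi: np.ndarray, survival_link: str) -> np.ndarray:
    """Third derivative of log survival w.r.t. the latent scale."""
    if survival_link == "logit":
        p = expit(logit_phi)
        return -p * (1.0 - p) * (1.0 - 2.0 * p)
    if survival_link == "log":
        return np.zeros_like(logit_phi)
    raise ValueError(f"unknown survival_link {survival_link!r}")


def log_abundances(
    log_N_init: float, latent: LatentStates, survival_link: str = "logit"
) -> np.ndarray:
    """Log abundances log N_{i,t}, shape (n, T), from the cohort recursion.

    Equivalent to cumulative products of vital rates applied to N_{n,0}:
    log N_{i,t} = log N_{n,0} + sum of the log vital rates a cohort passes
    through up to stage i of cohort t.
    """
    lr = latent.log_rho
    L, _, _ = _log_phi_terms(latent.logit_phi, survival_link)
    T = lr.shape[0]
    g = lr + L.sum(axis=0)                     # per-cohort total log growth
    G_prev = np.cumsum(g) - g                  # sum over cohorts before t
    partial = np.vstack([np.zeros(T), np.cumsum(L, axis=0)])  # within-cohort
    return log_N_init + G_prev[None, :] + lr[None, :] + partial


def build_abundances(
    log_N_init: float,
    latent: LatentStates,
    n: Optional[int] = None,
    T: Optional[int] = None,
    survival_link: str = "logit",
) -> np.ndarray:
    """Abundance matrix N (n x T) implied by the latent vital rates.

    ``n`` and ``T``, if given, are checked against the latent dimensions.
    """
    if n is not None and latent.n_stages != n:
        raise ValueError(f"latent states imply n={latent.n_stages}, not {n}")
    if T is not None and latent.T != T:
        raise ValueError(f"latent states imply T={latent.T}, not {T}")
    return np.exp(log_abundances(log_N_init, latent, survival_link))


def _check_dims(params: LifeCycleParams, latent: LatentStates,
                cov: CovariateSet) -> None:
    if latent.n_stages != params.n_stages or cov.n_stages != params.n_stages:
        raise ValueError("n_stages mismatch between params, latent and covariates")
    if latent.T != cov.T:
        raise ValueError("cohort count mismatch between latent states and covariates")
    if params.beta_R.shape[0] != cov.w_R.shape[1]:
        raise ValueError("beta_R length does not match w_R columns")
    for i, (b, w) in enumerate(zip(params.beta_S, cov.w_S)):
        if b.shape[0] != w.shape[1]:
            raise ValueError(f"beta_S[{i}] length does not match w_S[{i}] columns")


def process_means(params: LifeCycleParams, cov: CovariateSet) -> Tuple[np.ndarray, np.ndarray]:
    """Covariate-driven means of log rho (T,) and logit phi (n-1, T)."""
    m_R = cov.w_R @ params.beta_R
    m_S = np.vstack([w @ b for w, b in zip(cov.w_S, params.beta_S)])
    return m_R, m_S


def process_logpdf(
    params: LifeCycleParams,
    latent: LatentStates,
    cov: CovariateSet,
    survival_link: str = "logit",
) -> float:
    """Log density of the latent vital rates on their transformed scales."""
    _check_dims(params, latent, cov)
    m_R, m_S = process_means(params, cov)
    s_R = params.sigma_p_R
    s_S = params.sigma_p_S[:, None]
    zr = (latent.log_rho - m_R) / s_R
    zs = (latent.logit_phi - m_S) / s_S
    T = latent.T
    n1 = params.n_stages - 1
    return float(
        -0.5 * (zr @ zr) - T * np.log(s_R) - 0.5 * T * _LN2PI
        - 0.5 * np.sum(zs * zs) - T * np.sum(np.log(params.sigma_p_S))
        - 0.5 * n1 * T * _LN2PI
    )


def _obs_structure(data: Dataset):
    """Flattened observation bookkeeping, cached on the dataset.

    Returns arrays over the observed (stage, cohort) cells plus, where
    needed, indicator matrices giving which latent variables each
    observation's log-abundance depends on.
    """
    cache = getattr(data, "_obs_cache", None)
    if cache is not None:
        return cache
    n, T = data.Y.shape
    ii, tt = np.nonzero(data.mask)
    ly = np.log(data.Y[ii, tt])
    so = data.sigma_o[ii, tt]
    surveys = data.surveys
    survey_idx = np.array(
        [surveys.index(data.survey_of_stage[i]) for i in ii], dtype=int
    )
    # A_lr[o, j] = 1 if log rho_{j+1} enters log N_{i_o, t_o}
    A_lr = (np.arange(T)[None, :] <= tt[:, None]).astype(float)
    # A_L[o, k*T + j] = 1 if log phi_{k+1, j+1} enters log N_{i_o, t_o}
    kk = np.arange(n - 1)
    jj = np.arange(T)
    before = jj[None, :] < tt[:, None]                       # (n_obs, T)
    same = jj[None, :] == tt[:, None]
    A_L = (
        before[:, None, :]
        | (same[:, None, :] & (kk[None, :, None] < ii[:, None, None]))
    ).astype(float).reshape(ii.shape[0], (n - 1) * T)
    cache = dict(
        ii=ii, tt=tt, ly=ly, so=so, w=1.0 / so**2, survey_idx=survey_idx,
        A_lr=A_lr, A_L=A_L, surveys=surveys,
    )
    data._obs_cache = cache
    return cache


def _log_psi_per_obs(params: LifeCycleParams, data: Dataset,
                     cache) -> np.ndarray:
    log_psi = np.log([params.psi[s] for s in cache["surveys"]])
    return log_psi[cache["survey_idx"]]


def observation_logpdf(
    params: LifeCycleParams, N: np.ndarray, data: Dataset
) -> float:
    """Log density of the observed indices given abundances.

    Missing entries contribute exactly zero.  ``Y_init``, if present, is an
    observation of N_{n,0} through the stage-n survey's bias parameter (the
    abundance N_{n,0} is inferred from ``params.log_N_init``).
    """
    N = np.asarray(N, dtype=float)
    if N.shape != data.Y.shape:
        raise ValueError("N must match Y in shape")
    cache = _obs_structure(data)
    ii, tt = cache["ii"], cache["tt"]
    if np.any(N[ii, tt] <= 0):
        raise ValueError("N must be positive wherever Y is observed")
    so = cache["so"]
    mu = _log_psi_per_obs(params, data, cache) + np.log(N[ii, tt]) - so**2 / 2.0
    z = (cache["ly"] - mu) / so
    out = float(-0.5 * (z @ z) - np.sum(np.log(so)) - 0.5 * so.size * _LN2PI)
    if data.Y_init is not None:
        s0 = data.sigma_o_init
        psi_n = params.psi[data.survey_of_stage[-1]]
        mu0 = np.log(psi_n) + params.log_N_init - s0**2 / 2.0
        z0 = (np.log(data.Y_init) - mu0) / s0
        out += float(-0.5 * z0 * z0 - np.log(s0) - 0.5 * _LN2PI)
    return out


def joint_nll(
    params: LifeCycleParams,
    latent: LatentStates,
    data: Dataset,
    survival_link: str = "logit",
) -> float:
    """Negative joint log-likelihood -(process + observation)."""
    _check_dims(params, latent, data.covariates)
    N = build_abundances(params.log_N_init, latent, survival_link=survival_link)
    return -(
        process_logpdf(params, latent, data.covariates, survival_link)
        + observation_logpdf(params, N, data)
    )


def rescale(params: LifeCycleParams, c: float) -> LifeCycleParams:
    """Map theta to the likelihood-equivalent theta' with N_{n,0} scaled by c.

    Returns a copy with ``log_N_init + log c`` and every psi divided by c,
    leaving all products N_{n,0} psi_i unchanged — the direction along which
    the likelihood is exactly flat when no bias parameter is fixed.
    """
    if c <= 0:
        raise ValueError("rescaling constant c must be positive")
    out = params.copy()
    out.log_N_init = params.log_N_init + np.log(c)
    out.psi = {s: v / c for s, v in params.psi.items()}
    out.psi_fixed = {s: v / c for s, v in params.psi_fixed.items()}
    return out


# ---------------------------------------------------------------------------
# latent-block derivatives (used by the Laplace inner optimiser and samplers)
# ---------------------------------------------------------------------------

class LatentWorkspace:
    """Precomputed joint-nll machinery for fixed (theta, data).

    The inner Laplace optimisation evaluates the joint nll and its latent
    derivatives many times at the same theta; this workspace hoists
    everything that does not depend on the latent vector (process means and
    precisions, observation bookkeeping, additive constants).
    """

    def __init__(
        self,
        params: LifeCycleParams,
        data: Dataset,
        survival_link: str = "logit",
    ):
        _check_dims(
            params,
            LatentStates(np.zeros(data.T),
                         np.zeros((params.n_stages - 1, data.T))),
            data.covariates,
        )
        self.params = params
        self.data = data
        self.survival_link = survival_link
        self.n, self.T = data.n_stages, data.T
        self.m_R, self.m_S = process_means(params, data.covariates)
        self.s_R, self.s_S = params.sigma_p_R, params.sigma_p_S
        cache = _obs_structure(data)
        self.cache = cache
        self.ii, self.tt = cache["ii"], cache["tt"]
        self.ly, self.so, self.w = cache["ly"], cache["so"], cache["w"]
        self.A_lr, self.A_L = cache["A_lr"], cache["A_L"]
        # per-observation mean offset excluding log-abundance
        self.mu0 = _log_psi_per_obs(params, data, cache) - self.so**2 / 2.0
        n, T = self.n, self.T
        self.prior_prec = np.concatenate(
            [np.full(T, 1.0 / self.s_R**2),
             np.broadcast_to((1.0 / self.s_S**2)[:, None], (n - 1, T)).ravel()]
        )
        const = (
            T * np.log(self.s_R) + T * np.sum(np.log(self.s_S))
            + np.sum(np.log(self.so)) + 0.5 * (n * T + self.ly.size) * _LN2PI
        )
        if data.Y_init is not None:
            s0 = data.sigma_o_init
            psi_n = params.psi[data.survey_of_stage[-1]]
            z0 = (np.log(data.Y_init)
                  - (np.log(psi_n) + params.log_N_init - s0**2 / 2.0)) / s0
            const += 0.5 * z0 * z0 + np.log(s0) + 0.5 * _LN2PI
        self.const = float(const)

    def _residuals(self, u: np.ndarray):
        n, T = self.n, self.T
        lr = u[:T]
        x = u[T:].reshape(n - 1, T)
        L, d1, d2 = _log_phi_terms(x, self.survival_link)
        g = lr + L.sum(axis=0)
        G_prev = np.cumsum(g) - g
        base = self.params.log_N_init + G_prev + lr
        loga = np.empty((n, T))
        loga[0] = base
        np.cumsum(L, axis=0, out=loga[1:])
        loga[1:] += base
        r = self.mu0 + loga[self.ii, self.tt] - self.ly
        zr = (lr - self.m_R) / self.s_R
        zs = (x - self.m_S) / self.s_S[:, None]
        return lr, x, L, d1, d2, r, zr, zs

    def nll(self, u: np.ndarray) -> float:
        _, _, _, _, _, r, zr, zs = self._residuals(u)
        return float(
            0.5 * (zr @ zr) + 0.5 * np.sum(zs * zs)
            + 0.5 * np.sum(self.w * r * r) + self.const
        )

    def parts(self, u: np.ndarray, order: int = 2,
              return_curvature: bool = False):
        lr, x, L, d1, d2, r, zr, zs = self._residuals(u)
        nll = float(
            0.5 * (zr @ zr) + 0.5 * np.sum(zs * zs)
            + 0.5 * np.sum(self.w * r * r) + self.const
        )
        if order < 1:
            return (nll, None, None, None) if return_curvature else (nll, None, None)
        wr = self.w * r
        e_lr = self.A_lr.T @ wr
        e_L = self.A_L.T @ wr
        d1f = d1.ravel()
        grad = np.concatenate(
            [zr / self.s_R + e_lr,
             (zs / self.s_S[:, None]).ravel() + e_L * d1f]
        )
        if order < 2:
            return (nll, grad, None, None) if return_curvature else (nll, grad, None)
        J = np.concatenate([self.A_lr, self.A_L * d1f[None, :]], axis=1)
        H = (J * self.w[:, None]).T @ J
        curv = np.concatenate([np.zeros(self.T), e_L * d2.ravel()])
        H[np.diag_indices_from(H)] += self.prior_prec + curv
        if return_curvature:
            return nll, grad, H, curv
        return nll, grad, H


def latent_nll_parts(
    params: LifeCycleParams,
    u: np.ndarray,
    data: Dataset,
    survival_link: str = "logit",
    order: int = 2,
    return_curvature: bool = False,
):
    """Joint nll and its derivatives w.r.t. the stacked latent vector.

    ``u`` stacks log_rho (T) then logit_phi (row-major (n-1, T)).  Returns
    ``(nll, grad, hess)``; ``grad``/``hess`` are None when ``order`` < 1/2.
    With ``return_curvature`` a fourth element is appended: the diagonal
    residual-curvature contribution already included in ``hess`` (zero on
    the log_rho block); subtracting it yields the always-positive-definite
    Gauss-Newton Hessian.
    """
    ws = LatentWorkspace(params, data, survival_link)
    return ws.parts(np.asarray(u, dtype=float), order, return_curvature)
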