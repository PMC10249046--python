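"""Bayesian inference by a seeded Metropolis-within-Gibbs sampler.

The posterior is over the full parameter vector theta and the latent vital
rates u jointly.  The sampler exploits the model's conditional structure:

* regression coefficients beta (recruitment and survival) and the latent
  log-recruitment vector are conditionally Gaussian and are updated by exact
  Gibbs draws;
* the initial log-abundance has a Gaussian likelihood and a uniform prior,
  giving a truncated-normal Gibbs draw;
* logit-survival latents (per-cohort blocks), process SDs and free bias
  parameters are updated by adaptive random-walk Metropolis on unconstrained
  scales, with proposal scales tuned during burn-in only (so the
  post-burn-in kernel is a fixed, valid MCMC kernel).

Default priors follow the simulation-study table: log N_{n,0} ~ U(9,15),
recruitment coefficients ~ N(0, tau=1), survival coefficients ~ N(0, tau =
3(m+1)/pi^2) with m covariates, process SDs and biases ~ Exp(1).

Convergence is summarised by split-chain Gelman-Rubin statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, ndtr, ndtri
from sklearn.base import BaseEstimator

from .model import LatentWorkspace, _obs_structure
from .types import CovariateSet, Dataset, LatentStates, LifeCycleParams

__all__ = [
    "PriorSpec",
    "ChainSet",
    "MetropolisGibbs",
    "table1_priors",
    "log_prior",
    "sample_posterior",
    "gelman_rubin",
    "joint_posterior_summary",
]

_PI2 = np.pi**2


@dataclass
class PriorSpec:
    """Prior families and hyperparameters.

    ``log_N_init_bounds`` are uniform bounds on the log scale.  Normal priors
    are parameterised by mean zero and *precision* tau.  ``sigma_rate`` and
    ``psi_rate`` are exponential rates for the process SDs and biases.
    """

    log_N_init_bounds: Tuple[float, float] = (9.0, 15.0)
    beta_R_tau: float = 1.0
    beta_S_tau: Sequence[float] = (0.61,)
    sigma_rate: float = 1.0
    psi_rate: float = 1.0

    def beta_S_tau_for(self, i: int) -> float:
        taus = list(self.beta_S_tau)
        return taus[i] if i < len(taus) else taus[-1]


def table1_priors(cov: CovariateSet) -> PriorSpec:
    """Default priors; survival-coefficient precision is 3(m+1)/pi^2.

    With one covariate per survival rate this evaluates to 0.6079 (printed
    as 0.61 in the simulation table).
    """
    taus = [3.0 * w.shape[1] / _PI2 for w in cov.w_S]
    return PriorSpec(beta_S_tau=tuple(taus))


def log_prior(theta: LifeCycleParams, priors: PriorSpec) -> float:
    """Sum of log prior densities over the free parameters of theta.

    Fixed bias parameters contribute nothing.  Returns -inf outside the
    support.
    """
    lo, hi = priors.log_N_init_bounds
    if not (lo <= theta.log_N_init <= hi):
        return -np.inf
    if theta.sigma_p_R <= 0 or np.any(theta.sigma_p_S <= 0):
        return -np.inf
    out = -np.log(hi - lo)

    def normal_lp(x, tau):
        return 0.5 * np.log(tau) - 0.5 * np.log(2 * np.pi) - 0.5 * tau * x**2

    out += float(np.sum(normal_lp(theta.beta_R, priors.beta_R_tau)))
    for i, b in enumerate(theta.beta_S):
        out += float(np.sum(normal_lp(b, priors.beta_S_tau_for(i))))
    r = priors.sigma_rate
    out += float(np.log(r) - r * theta.sigma_p_R)
    out += float(np.sum(np.log(r) - r * theta.sigma_p_S))
    for s, v in theta.psi.items():
        if s in theta.psi_fixed:
            continue
        if v <= 0:
            return -np.inf
        out += float(np.log(priors.psi_rate) - priors.psi_rate * v)
    return out


@dataclass
class ChainSet:
    """Posterior draws: ``draws[name]`` has shape (n_chains, n_kept)."""

    draws: Dict[str, np.ndarray]
    n_chains: int
    n_iter: int
    burn_in: int
    seed: int
    acceptance: Dict[str, float] = field(default_factory=dict)

    @property
    def names(self) -> List[str]:
        return list(self.draws)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (iteration, chain, parameter, value)."""
        rows = []
        for name, arr in self.draws.items():
            nc, ni = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "iteration": np.tile(np.arange(ni), nc),
                        "chain": np.repeat(np.arange(nc), ni),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def gelman_rubin(chains: ChainSet | Dict[str, np.ndarray]) -> Dict[str, float]:
    """Split-chain potential scale reduction factor per parameter.

    Each chain is split in half; R-hat compares between- and within-half
    variances.  Raises on chains too short to split.
    """
    draws = chains.draws if isinstance(chains, ChainSet) else chains
    out = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        nc, ni = arr.shape
        if ni < 4:
            raise ValueError(
                f"chain for {name!r} has {ni} draws; need >= 4 to split"
            )
        half = ni // 2
        segs = np.concatenate(
            [arr[:, :half], arr[:, half: 2 * half]], axis=0
        )  # (2 nc, half)
        m, l = segs.shape
        W = float(np.mean(np.var(segs, axis=1, ddof=1)))
        B = float(l * np.var(np.mean(segs, axis=1), ddof=1))
        if W == 0.0:
            out[name] = np.inf if B > 0 else 1.0
            continue
        var_plus = (l - 1) / l * W + B / l
        out[name] = float(np.sqrt(var_plus / W))
    return out


def joint_posterior_summary(
    chains: ChainSet,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    density_grid: int = 40,
):
    """Marginal summaries plus pairwise correlations and density contours.

    Returns ``(marginals, pairwise)``: a DataFrame of means/SDs/quantiles and
    a dict keyed by parameter pair with the Pearson correlation and a 2-D
    Gaussian-KDE evaluation for contour plotting.
    """
    from scipy.stats import gaussian_kde, pearsonr

    flat = {k: v.ravel() for k, v in chains.draws.items()}
    marginals = pd.DataFrame(
        {
            "parameter": list(flat),
            "mean": [np.mean(v) for v in flat.values()],
            "sd": [np.std(v, ddof=1) for v in flat.values()],
            "q2.5": [np.percentile(v, 2.5) for v in flat.values()],
            "q50": [np.percentile(v, 50) for v in flat.values()],
            "q97.5": [np.percentile(v, 97.5) for v in flat.values()],
        }
    )
    pairwise = {}
    for a, b in pairs or []:
        xa, xb = flat[a], flat[b]
        r = float(pearsonr(xa, xb)[0])
        sub = slice(None, None, max(1, xa.size // 2000))
        gx = np.linspace(xa.min(), xa.max(), density_grid)
        gy = np.linspace(xb.min(), xb.max(), density_grid)
        try:
            kde = gaussian_kde(np.vstack([xa[sub], xb[sub]]))
            gxx, gyy = np.meshgrid(gx, gy)
            dens = kde(np.vstack([gxx.ravel(), gyy.ravel()])).reshape(
                gxx.shape
            )
        except np.linalg.LinAlgError:
            dens = None  # perfectly collinear draws have no 2-D density
        pairwise[(a, b)] = {"correlation": r, "x": gx, "y": gy,
                            "density": dens}
    return marginals, pairwise


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class MetropolisGibbs(BaseEstimator):
    """Metropolis-within-Gibbs sampler over (theta, latent vital rates).

    Parameters
    ----------
    fix_psi : survey label -> fixed bias value; as with the ML fit, at least
        one psi should be fixed for an identifiable posterior (can be
        overridden with ``allow_redundant=True`` to study redundancy).
    priors : PriorSpec; defaults to the simulation-table priors.
    n_chains, n_iter : chains and iterations per chain; the first
        ``burn_in`` iterations (default half) are discarded and used for
        proposal adaptation.
    use_likelihood : switch the observation likelihood off to sample the
        prior-plus-process hierarchy only (validation runs).
    seed : master seed; chains use independently spawned substreams.

    Attributes (after ``fit``)
    --------------------------
    chains_ : ChainSet of post-burn-in parameter draws.
    rhat_ : split-chain Gelman-Rubin statistic per free parameter.
    """

    def __init__(
        self,
        fix_psi: Optional[Dict[str, float]] = None,
        priors: Optional[PriorSpec] = None,
        n_chains: int = 4,
        n_iter: int = 20_000,
        burn_in: Optional[int] = None,
        seed: int = 0,
        use_likelihood: bool = True,
        allow_redundant: bool = False,
        init: Optional[LifeCycleParams] = None,
    ):
        self.fix_psi = fix_psi
        self.priors = priors
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.seed = seed
        self.use_likelihood = use_likelihood
        self.allow_redundant = allow_redundant
        self.init = init

    def fit(self, X: Dataset, y=None) -> "MetropolisGibbs":
        data = X
        fix_psi = dict(self.fix_psi or {})
        if not fix_psi and not self.allow_redundant:
            raise ValueError(
                "no bias parameter fixed: the posterior is parameter "
                "redundant along N_init*psi; pass allow_redundant=True to "
                "sample it anyway"
            )
        priors = self.priors or table1_priors(data.covariates)
        burn = self.burn_in if self.burn_in is not None else self.n_iter // 2
        if not 0 < burn < self.n_iter:
            raise ValueError("burn_in must lie strictly inside (0, n_iter)")

        names = self._param_names(data, fix_psi)
        ss = np.random.SeedSequence(self.seed)
        kept = self.n_iter - burn
        draws = {nm: np.empty((self.n_chains, kept)) for nm in names}
        acc_tot: Dict[str, list] = {}
        for c, child in enumerate(ss.spawn(self.n_chains)):
            rng = np.random.default_rng(child)
            chain_draws, acc = _run_chain(
                data, priors, fix_psi, names, self.n_iter, burn, rng,
                self.use_likelihood, self.init,
            )
            for nm in names:
                draws[nm][c] = chain_draws[nm]
            for k, v in acc.items():
                acc_tot.setdefault(k, []).append(v)
        self.chains_ = ChainSet(
            draws=draws,
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            burn_in=burn,
            seed=self.seed,
            acceptance={k: float(np.mean(v)) for k, v in acc_tot.items()},
        )
        self.rhat_ = gelman_rubin(self.chains_)
        return self

    @staticmethod
    def _param_names(data: Dataset, fix_psi: Dict[str, float]) -> List[str]:
        cov = data.covariates
        names = ["log_N_init"]
        names += [f"beta_R_{j}" for j in range(cov.w_R.shape[1])]
        names.append("sigma_p_R")
        for i, w in enumerate(cov.w_S, start=1):
            names += [f"beta_S{i}_{j}" for j in range(w.shape[1])]
            names.append(f"sigma_p_S{i}")
        names += [f"psi_{s}" for s in data.surveys if s not in fix_psi]
        return names


_MAP_CACHE: Dict[int, LifeCycleParams] = {}
_MARG_DEBUG = None  # set to a list to trace marginal-move acceptance terms


def _map_start(
    data: Dataset, fix_psi: Dict[str, float], use_likelihood: bool
) -> LifeCycleParams:
    """Mode-finding initialisation, cached per dataset object."""
    from .laplace import LaplaceMLE, default_start

    psi_init = {s: fix_psi.get(s, 1.0) for s in data.surveys}
    if not use_likelihood or not fix_psi:
        return default_start(data, psi_init)
    key = id(data)
    if key in _MAP_CACHE:
        return _MAP_CACHE[key]
    try:
        est = LaplaceMLE(fix_psi=fix_psi, compute_vcov=False, maxiter=200)
        theta = est.fit(data).theta_
    except Exception:
        theta = default_start(data, psi_init)
    _MAP_CACHE[key] = theta
    if len(_MAP_CACHE) > 32:
        _MAP_CACHE.pop(next(iter(_MAP_CACHE)))
    return theta


def _run_chain(
    data: Dataset,
    priors: PriorSpec,
    fix_psi: Dict[str, float],
    names: List[str],
    n_iter: int,
    burn: int,
    rng: np.random.Generator,
    use_likelihood: bool,
    init: Optional[LifeCycleParams],
):
    n, T = data.n_stages, data.T
    cov = data.covariates
    cache = _obs_structure(data)
    ii, tt, ly, so, w = (cache[k] for k in ("ii", "tt", "ly", "so", "w"))
    A_lr, A_L = cache["A_lr"], cache["A_L"]
    surveys = data.surveys
    survey_idx = cache["survey_idx"]
    free_psi = [s for s in surveys if s not in fix_psi]
    stage_survey = list(data.survey_of_stage)
    adult_survey = stage_survey[-1]
    lo0, hi0 = priors.log_N_init_bounds

    if not use_likelihood:
        w = np.zeros_like(w)

    # Y_init handled as one extra pseudo-observation of log N_init
    has_init = data.Y_init is not None
    if has_init:
        w0 = (1.0 / data.sigma_o_init**2) if use_likelihood else 0.0
        ly0 = np.log(data.Y_init)
        s0sq = data.sigma_o_init**2

    # ---- state initialisation -------------------------------------------
    # Chains start from a jittered posterior-mode estimate (quick Laplace
    # fit); purely data-driven heuristics can land in a secondary basin of
    # the ridged posterior that random-walk moves escape only very slowly.
    if init is not None:
        theta0 = init
    else:
        theta0 = _map_start(data, fix_psi, use_likelihood)
    logN0 = float(np.clip(theta0.log_N_init + 0.3 * rng.standard_normal(),
                          lo0 + 1e-3, hi0 - 1e-3))
    beta_R = theta0.beta_R + 0.2 * rng.standard_normal(theta0.beta_R.shape)
    beta_S = [b + 0.2 * rng.standard_normal(b.shape) for b in theta0.beta_S]
    sig_R = float(theta0.sigma_p_R * np.exp(0.3 * rng.standard_normal()))
    sig_S = theta0.sigma_p_S * np.exp(0.3 * rng.standard_normal(n - 1))
    log_psi = {s: float(np.log(fix_psi.get(s, 1.0))
                        + (0.0 if s in fix_psi else 0.3 * rng.standard_normal()))
               for s in surveys}
    m_R = cov.w_R @ beta_R
    m_S = np.vstack([wS @ b for wS, b in zip(cov.w_S, beta_S)])
    lr = m_R + sig_R * rng.standard_normal(T)
    x = m_S + sig_S[:, None] * rng.standard_normal((n - 1, T))

    # per-observation residual r = mu - ly, maintained incrementally
    log_psi_obs = np.array([log_psi[s] for s in surveys])[survey_idx]

    def full_residual():
        L = log_expit(x)
        return (log_psi_obs + logN0 + A_lr @ lr + A_L @ L.ravel()
                - so**2 / 2.0 - ly)

    r = full_residual()

    # adaptive proposal scales
    scale_x = np.full(T, 0.3)
    scale_sig = np.full(n, 0.3)          # R then S1..S(n-1)
    scale_psi = {s: 0.3 for s in free_psi}
    acc_x = np.zeros(T)
    try_x = np.zeros(T)
    acc_sig = np.zeros(n)
    try_sig = np.zeros(n)
    acc_psi = {s: 0 for s in free_psi}
    try_psi = {s: 0 for s in free_psi}

    kept = n_iter - burn
    out = {nm: np.empty(kept) for nm in names}

    AtW_lr = None  # A_lr' W A_lr, cached; rebuilt never (w fixed)
    W_Alr = A_lr * w[:, None]
    Q_obs_lr = A_lr.T @ W_Alr
    sum_w = float(np.sum(w)) + (w0 if has_init else 0.0)

    WtW_R = cov.w_R.T @ cov.w_R
    WtW_S = [wS.T @ wS for wS in cov.w_S]

    adapt_batch = 50

    # ---- Laplace marginal-augmentation move -----------------------------
    # every few iterations theta is proposed jointly (adaptive covariance)
    # together with a fresh latent field drawn from its Laplace-Gaussian
    # conditional at the proposed theta; the joint-posterior acceptance
    # ratio keeps the kernel exact while moving theta and the latent states
    # coherently across the intercept/bias likelihood ridge.
    marg_every = 4
    p_names: List[Tuple[str, object]] = [("logN0", None)]
    p_names += [("beta_R", j) for j in range(cov.w_R.shape[1])]
    p_names += [("log_sig_R", None)]
    for i, wS in enumerate(cov.w_S):
        p_names += [("beta_S", (i, j)) for j in range(wS.shape[1])]
        p_names += [("log_sig_S", i)]
    p_names += [("log_psi", s) for s in free_psi]
    p_dim = len(p_names)
    th_hist = np.empty((burn, p_dim))
    th_chol = np.eye(p_dim) * 0.05
    th_scale = 1.0
    marg_acc = 0
    marg_try = 0
    use_marginal = use_likelihood

    def pack_state() -> np.ndarray:
        out_v = np.empty(p_dim)
        for idx_p, (kind, key) in enumerate(p_names):
            if kind == "logN0":
                out_v[idx_p] = logN0
            elif kind == "beta_R":
                out_v[idx_p] = beta_R[key]
            elif kind == "log_sig_R":
                out_v[idx_p] = np.log(sig_R)
            elif kind == "beta_S":
                out_v[idx_p] = beta_S[key[0]][key[1]]
            elif kind == "log_sig_S":
                out_v[idx_p] = np.log(sig_S[key])
            else:
                out_v[idx_p] = log_psi[key]
        return out_v

    def theta_from_vector(v: np.ndarray) -> Optional[LifeCycleParams]:
        d = {kind_key: v[idx_p] for idx_p, kind_key in enumerate(p_names)}
        ln0 = v[p_names.index(("logN0", None))]
        if not (lo0 <= ln0 <= hi0):
            return None
        bR = np.array([d[("beta_R", j)] for j in range(cov.w_R.shape[1])])
        bS = [
            np.array([d[("beta_S", (i, j))] for j in range(wS.shape[1])])
            for i, wS in enumerate(cov.w_S)
        ]
        sR = float(np.exp(d[("log_sig_R", None)]))
        sS = np.array([np.exp(d[("log_sig_S", i)]) for i in range(n - 1)])
        psi = {s: float(np.exp(d[("log_psi", s)])) if s in free_psi
               else fix_psi[s] for s in surveys}
        return LifeCycleParams(
            n_stages=n, log_N_init=float(ln0), beta_R=bR, beta_S=bS,
            sigma_p_R=sR, sigma_p_S=sS, psi=psi, psi_fixed=dict(fix_psi),
        )

    def log_prior_v(v: np.ndarray) -> float:
        lp = 0.0
        for idx_p, (kind, key) in enumerate(p_names):
            val = v[idx_p]
            if kind == "logN0":
                if not (lo0 <= val <= hi0):
                    return -np.inf
            elif kind == "beta_R":
                lp += -0.5 * priors.beta_R_tau * val**2
            elif kind == "beta_S":
                lp += -0.5 * priors.beta_S_tau_for(key[0]) * val**2
            elif kind in ("log_sig_R", "log_sig_S"):
                lp += -priors.sigma_rate * np.exp(val) + val
            else:  # log_psi, Exp prior with log-scale Jacobian
                lp += -priors.psi_rate * np.exp(val) + val
        return lp

    # ---- adaptive joint block over the confounded direction -------------
    # free log-psi, vital-rate intercepts and log N_init sit on a likelihood
    # ridge; an adaptive-covariance Metropolis block (Haario-style, frozen
    # after burn-in) learns its orientation and traverses it quickly.
    ridge_names = (
        [("psi", s) for s in free_psi]
        + [("beta_R0", None)]
        + [("beta_S0", i) for i in range(n - 1)]
        + [("logN0", None)]
    )
    nridge = len(ridge_names)
    ridge_hist = np.empty((burn, nridge))
    ridge_chol = np.eye(nridge) * 0.02
    ridge_acc = 0
    ridge_try = 0
    ridge_scale = 1.0

    def ridge_vector():
        v = [log_psi[s] for s in free_psi]
        v.append(beta_R[0])
        v += [beta_S[i][0] for i in range(n - 1)]
        v.append(logN0)
        return np.array(v)

    for it in range(n_iter):
        adapting = it < burn

        # ---- beta_R | lr (conjugate Gibbs) ------------------------------
        beta_R = _draw_conjugate_coefficients(
            rng, WtW_R, cov.w_R.T @ lr, sig_R, priors.beta_R_tau
        )
        m_R = cov.w_R @ beta_R

        # ---- beta_S | x --------------------------------------------------
        for i in range(n - 1):
            beta_S[i] = _draw_conjugate_coefficients(
                rng, WtW_S[i], cov.w_S[i].T @ x[i], sig_S[i],
                priors.beta_S_tau_for(i),
            )
            m_S[i] = cov.w_S[i] @ beta_S[i]

        # ---- lr | rest (conjugate Gibbs; obs linear in lr) ---------------
        Q = Q_obs_lr + np.eye(T) / sig_R**2
        resid_wo_lr = r - A_lr @ lr
        b = m_R / sig_R**2 - A_lr.T @ (w * resid_wo_lr)
        cQ = np.linalg.cholesky(Q)
        mean = np.linalg.solve(cQ.T, np.linalg.solve(cQ, b))
        lr_new = mean + np.linalg.solve(cQ.T, rng.standard_normal(T))
        r = r + A_lr @ (lr_new - lr)
        lr = lr_new

        # ---- logN0 | rest (truncated-normal Gibbs) -----------------------
        resid_wo_n0 = r - logN0
        prec = sum_w
        if prec > 0:
            num = -float(np.sum(w * resid_wo_n0))
            if has_init:
                mu_wo = log_psi[adult_survey] - s0sq / 2.0
                num += w0 * (ly0 - mu_wo)
            mean0 = num / prec
            sd0 = 1.0 / np.sqrt(prec)
            a = ndtr((lo0 - mean0) / sd0)
            bq = ndtr((hi0 - mean0) / sd0)
            uq = rng.uniform(a, bq)
            uq = min(max(uq, 1e-15), 1 - 1e-15)
            logN0_new = mean0 + sd0 * ndtri(uq)
        else:
            logN0_new = rng.uniform(lo0, hi0)
        r = r + (logN0_new - logN0)
        logN0 = logN0_new

        # ---- x blocks (per-cohort random-walk Metropolis) ----------------
        L = log_expit(x)
        for j in range(T):
            xj = x[:, j]
            prop = xj + scale_x[j] * rng.standard_normal(n - 1)
            Lp = log_expit(prop)
            dL = Lp - L[:, j]
            # column indices in A_L for sites (k, j): k*T + j
            idx = np.arange(n - 1) * T + j
            dr = A_L[:, idx] @ dL
            r_prop = r + dr
            d_obs = 0.5 * float(np.sum(w * (r_prop**2 - r**2)))
            d_proc = 0.5 * float(
                np.sum(((prop - m_S[:, j]) / sig_S) ** 2)
                - np.sum(((xj - m_S[:, j]) / sig_S) ** 2)
            )
            try_x[j] += 1
            if np.log(rng.uniform()) < -(d_obs + d_proc):
                x[:, j] = prop
                L[:, j] = Lp
                r = r_prop
                acc_x[j] += 1

        # ---- process SDs (random-walk on log sigma) ----------------------
        z = lr - m_R
        ssq = float(z @ z)
        sig_R = _update_sigma(sig_R, ssq, T, priors.sigma_rate, scale_sig,
                              0, rng, acc_sig, try_sig)
        for i in range(n - 1):
            zi = x[i] - m_S[i]
            sig_S[i] = _update_sigma(
                sig_S[i], float(zi @ zi), T, priors.sigma_rate, scale_sig,
                1 + i, rng, acc_sig, try_sig,
            )

        # ---- interweaved non-centered sigma updates ----------------------
        # in the non-centered parameterisation z = (latent - mean)/sigma the
        # latent row rescales with sigma, which removes the funnel that traps
        # centered samplers when a process SD drifts toward zero
        v = np.log(sig_R)
        vp = v + scale_sig[0] * rng.standard_normal()
        lr_p = m_R + np.exp(vp - v) * (lr - m_R)
        dr_nc = A_lr @ (lr_p - lr)
        r_p = r + dr_nc
        d = 0.5 * float(np.sum(w * (r_p**2 - r**2)))
        d += priors.sigma_rate * (np.exp(vp) - np.exp(v)) - (vp - v)
        if np.log(rng.uniform()) < -d:
            sig_R = float(np.exp(vp))
            lr = lr_p
            r = r_p
        for i in range(n - 1):
            v = np.log(sig_S[i])
            vp = v + scale_sig[1 + i] * rng.standard_normal()
            xi_p = m_S[i] + np.exp(vp - v) * (x[i] - m_S[i])
            idx_row = np.arange(i * T, (i + 1) * T)
            dLrow = log_expit(xi_p) - log_expit(x[i])
            r_p = r + A_L[:, idx_row] @ dLrow
            d = 0.5 * float(np.sum(w * (r_p**2 - r**2)))
            d += priors.sigma_rate * (np.exp(vp) - np.exp(v)) - (vp - v)
            if np.log(rng.uniform()) < -d:
                sig_S[i] = float(np.exp(vp))
                x[i] = xi_p
                r = r_p

        # ---- free psi (random-walk on log psi) ---------------------------
        for s in free_psi:
            sel = survey_idx == surveys.index(s)
            cur = log_psi[s]
            prop = cur + scale_psi[s] * rng.standard_normal()
            dr = prop - cur
            rp = r[sel] + dr
            d_obs = 0.5 * float(np.sum(w[sel] * (rp**2 - r[sel] ** 2)))
            if has_init and s == adult_survey:
                mu_cur = cur + logN0 - s0sq / 2.0
                mu_p = prop + logN0 - s0sq / 2.0
                d_obs += 0.5 * w0 * ((mu_p - ly0) ** 2 - (mu_cur - ly0) ** 2)
            # Exp(1) prior on psi with log-scale proposal (Jacobian e^v)
            d_prior = (priors.psi_rate * (np.exp(prop) - np.exp(cur))
                       - (prop - cur))
            try_psi[s] += 1
            if np.log(rng.uniform()) < -(d_obs + d_prior):
                log_psi[s] = prop
                r[sel] = rp
                log_psi_obs[sel] = prop
                acc_psi[s] += 1

        # ---- Laplace marginal-augmentation move --------------------------
        v_cur = pack_state()
        if adapting:
            th_hist[it] = v_cur
        if use_marginal and (it + 1) % marg_every == 0:
            from .laplace import inner_mode as _inner_mode

            marg_try += 1
            accepted_marg = False
            theta_cur = theta_from_vector(v_cur)
            try:
                ws_cur = LatentWorkspace(theta_cur, data)
                u_cur = np.concatenate([lr, x.ravel()])
                inner_cur = _inner_mode(
                    theta_cur, data, LatentStates(lr, x.copy()),
                    tol=1e-5, max_iter=40, workspace=ws_cur,
                )
                if inner_cur.grad_norm <= 1e-4:
                    v_prop = v_cur + th_scale * (
                        th_chol @ rng.standard_normal(p_dim)
                    )
                    lp_prop = log_prior_v(v_prop)
                    theta_prop = (
                        theta_from_vector(v_prop)
                        if np.isfinite(lp_prop) else None
                    )
                    if theta_prop is not None:
                        ws_prop = LatentWorkspace(theta_prop, data)
                        inner_prop = _inner_mode(
                            theta_prop, data, inner_cur.u_hat,
                            tol=1e-5, max_iter=40, workspace=ws_prop,
                        )
                        if inner_prop.grad_norm <= 1e-4:
                            # deterministic transport: carry the whitened
                            # latent deviation from the old conditional to
                            # the new one; for a Gaussian conditional the
                            # acceptance reduces to the marginal-likelihood
                            # ratio, so the move mixes theta efficiently
                            # regardless of the latent dimension
                            Lc = np.linalg.cholesky(inner_cur.hessian)
                            Lp_ = np.linalg.cholesky(inner_prop.hessian)
                            u_hat_c = inner_cur.u_hat.to_vector()
                            u_hat_p = inner_prop.u_hat.to_vector()
                            z_w = Lc.T @ (u_cur - u_hat_c)
                            u_prop = u_hat_p + np.linalg.solve(Lp_.T, z_w)
                            jd_c = ws_cur.nll(u_cur)
                            jd_p = ws_prop.nll(u_prop)
                            logjac = float(
                                np.sum(np.log(np.diag(Lc)))
                                - np.sum(np.log(np.diag(Lp_)))
                            )
                            la = (-(jd_p - jd_c)
                                  + (lp_prop - log_prior_v(v_cur))
                                  + logjac)
                            if _MARG_DEBUG is not None:
                                _MARG_DEBUG.append(
                                    (la, jd_p - jd_c, logjac, 0.0, 0.0)
                                )
                            if np.log(rng.uniform()) < la:
                                accepted_marg = True
            except np.linalg.LinAlgError:
                accepted_marg = False
            if accepted_marg:
                marg_acc += 1
                logN0 = float(theta_prop.log_N_init)
                beta_R = theta_prop.beta_R.copy()
                beta_S = [b.copy() for b in theta_prop.beta_S]
                sig_R = float(theta_prop.sigma_p_R)
                sig_S = theta_prop.sigma_p_S.copy()
                for s in free_psi:
                    log_psi[s] = float(np.log(theta_prop.psi[s]))
                lr = u_prop[:T].copy()
                x = u_prop[T:].reshape(n - 1, T).copy()
                m_R = cov.w_R @ beta_R
                m_S = np.vstack(
                    [wS @ b for wS, b in zip(cov.w_S, beta_S)]
                )
                log_psi_obs = np.array(
                    [log_psi[s] for s in surveys]
                )[survey_idx]
                r = full_residual()

        # ---- joint ridge move (adaptive-covariance Metropolis) -----------
        cur = ridge_vector()
        if adapting:
            ridge_hist[it] = cur
        if nridge > 0:
            prop = cur + ridge_scale * (
                ridge_chol @ rng.standard_normal(nridge)
            )
            d_all = 0.0
            ok = True
            dpsi = {}
            db_R0 = 0.0
            db_S0 = np.zeros(n - 1)
            dN0 = 0.0
            for val_new, val_old, (kind, key) in zip(prop, cur, ridge_names):
                dv = val_new - val_old
                if kind == "psi":
                    dpsi[key] = dv
                    d_all += (priors.psi_rate
                              * (np.exp(val_new) - np.exp(val_old)) - dv)
                elif kind == "beta_R0":
                    db_R0 = dv
                    d_all += 0.5 * priors.beta_R_tau * (
                        val_new**2 - val_old**2
                    )
                elif kind == "beta_S0":
                    db_S0[key] = dv
                    d_all += 0.5 * priors.beta_S_tau_for(key) * (
                        val_new**2 - val_old**2
                    )
                else:  # logN0
                    dN0 = dv
                    if not (lo0 <= val_new <= hi0):
                        ok = False
            if ok:
                # observation change: psi shifts on survey rows, N0 on all
                dr_obs = np.full(r.shape, dN0)
                for s, dv in dpsi.items():
                    dr_obs[survey_idx == surveys.index(s)] += dv
                r_prop = r + dr_obs
                d_all += 0.5 * float(np.sum(w * (r_prop**2 - r**2)))
                if has_init:
                    dmu0 = dN0 + dpsi.get(adult_survey, 0.0)
                    mu_cur = (log_psi[adult_survey] + logN0 - s0sq / 2.0)
                    d_all += 0.5 * w0 * (
                        (mu_cur + dmu0 - ly0) ** 2 - (mu_cur - ly0) ** 2
                    )
                # process change from shifted means
                zr_c = lr - m_R
                d_all += 0.5 * float(
                    np.sum((zr_c - db_R0) ** 2 - zr_c**2)
                ) / sig_R**2
                for i in range(n - 1):
                    zi = x[i] - m_S[i]
                    d_all += 0.5 * float(
                        np.sum((zi - db_S0[i]) ** 2 - zi**2)
                    ) / sig_S[i] ** 2
                ridge_try += 1
                if np.log(rng.uniform()) < -d_all:
                    ridge_acc += 1
                    for s, dv in dpsi.items():
                        log_psi[s] += dv
                        log_psi_obs[survey_idx == surveys.index(s)] += dv
                    beta_R[0] += db_R0
                    m_R += db_R0
                    for i in range(n - 1):
                        beta_S[i][0] += db_S0[i]
                        m_S[i] += db_S0[i]
                    logN0 += dN0
                    r = r_prop

        # ---- adaptation during burn-in -----------------------------------
        if adapting and (it + 1) % adapt_batch == 0:
            step = 1.0 / np.sqrt((it + 1) / adapt_batch)
            rate = np.divide(acc_x, np.maximum(try_x, 1))
            scale_x *= np.exp(step * (rate - 0.3))
            acc_x[:] = 0
            try_x[:] = 0
            rate = np.divide(acc_sig, np.maximum(try_sig, 1))
            scale_sig *= np.exp(step * (rate - 0.44))
            acc_sig[:] = 0
            try_sig[:] = 0
            for s in free_psi:
                rate = acc_psi[s] / max(try_psi[s], 1)
                scale_psi[s] *= float(np.exp(step * (rate - 0.44)))
                acc_psi[s] = 0
                try_psi[s] = 0
            if ridge_try > 0:
                rate = ridge_acc / ridge_try
                ridge_scale *= float(np.exp(step * (rate - 0.25)))
                ridge_acc = 0
                ridge_try = 0
            if marg_try > 0:
                rate = marg_acc / marg_try
                th_scale *= float(np.exp(2 * step * (rate - 0.25)))
                marg_acc = 0
                marg_try = 0
            if (it + 1) % 200 == 0 and it + 1 >= 400:
                seg = ridge_hist[max(0, it - 1999): it + 1]
                cov_r = np.cov(seg.T)
                cov_r = (2.38**2 / nridge) * cov_r
                cov_r[np.diag_indices_from(cov_r)] += 1e-8
                try:
                    ridge_chol = np.linalg.cholesky(cov_r)
                except np.linalg.LinAlgError:
                    pass
                seg_t = th_hist[max(0, it - 7999): it + 1]
                cov_t = (2.38**2 / p_dim) * np.cov(seg_t.T)
                cov_t[np.diag_indices_from(cov_t)] += 1e-8
                try:
                    th_chol = np.linalg.cholesky(cov_t)
                except np.linalg.LinAlgError:
                    pass

        if (it + 1) % 1000 == 0:
            r = full_residual()  # guard against incremental drift

        if it >= burn:
            k = it - burn
            out["log_N_init"][k] = logN0
            for jj, bb in enumerate(beta_R):
                out[f"beta_R_{jj}"][k] = bb
            out["sigma_p_R"][k] = sig_R
            for i in range(n - 1):
                for jj, bb in enumerate(beta_S[i]):
                    out[f"beta_S{i+1}_{jj}"][k] = bb
                out[f"sigma_p_S{i+1}"][k] = sig_S[i]
            for s in free_psi:
                out[f"psi_{s}"][k] = np.exp(log_psi[s])

    acc = {
        "x_blocks": float(np.sum(acc_x) / max(np.sum(try_x), 1)),
        "sigma": float(np.sum(acc_sig) / max(np.sum(try_sig), 1)),
        "ridge": float(ridge_acc / max(ridge_try, 1)),
        "marginal": float(marg_acc / max(marg_try, 1)),
    }
    if free_psi:
        acc["psi"] = float(
            np.mean([acc_psi[s] / max(try_psi[s], 1) for s in free_psi])
        )
    return out, acc


def _draw_conjugate_coefficients(
    rng: np.random.Generator,
    WtW: np.ndarray,
    Wty: np.ndarray,
    sigma: float,
    tau: float,
) -> np.ndarray:
    """Exact Gibbs draw of regression coefficients.

    Model: y ~ N(W beta, sigma^2 I) with prior beta ~ N(0, tau^-1 I);
    the posterior is N(A^-1 b, A^-1) with A = W'W/sigma^2 + tau I and
    b = W'y/sigma^2.
    """
    A = WtW / sigma**2 + tau * np.eye(WtW.shape[0])
    b = Wty / sigma**2
    cA = np.linalg.cholesky(A)
    mean = np.linalg.solve(cA.T, np.linalg.solve(cA, b))
    return mean + np.linalg.solve(cA.T, rng.standard_normal(b.shape))


def _update_sigma(sig, ssq, T, rate, scales, idx, rng, acc, tries):
    """One random-walk Metropolis update of a process SD on the log scale."""
    v = np.log(sig)
    vp = v + scales[idx] * rng.standard_normal()
    sp = np.exp(vp)
    # process nll + Exp(rate) prior, with log-scale Jacobian
    d = (ssq / 2.0) * (1.0 / sp**2 - 1.0 / sig**2) + T * (vp - v)
    d += rate * (sp - sig) - (vp - v)
    tries[idx] += 1
    if np.log(rng.uniform()) < -d:
        acc[idx] += 1
        return float(sp)
    return float(sig)


def sample_posterior(
    data: Dataset,
    priors: Optional[PriorSpec] = None,
    fix_spec: Optional[Dict[str, float]] = None,
    n_chains: int = 4,
    n_iter: int = 20_000,
    seed: int = 0,
    **kwargs,
) -> ChainSet:
    """Thin functional wrapper over :class:`MetropolisGibbs`."""
    est = MetropolisGibbs(
        fix_psi=fix_spec, priors=priors, n_chains=n_chains, n_iter=n_iter,
        seed=seed, **kwargs,
    )
    return est.fit(data).chains_
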