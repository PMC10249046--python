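"""Domain containers: parameters, covariates, latent states, observed data.

Conventions
-----------
* Stages are indexed ``1..n`` in user-facing labels but stored 0-based.
* Cohorts run ``t = 1..T``; the adult abundance ``N_{n,0}`` initialises the
  recursion and is a fixed-effect parameter (stored on the log scale).
* Missing observations are NaN entries in ``Dataset.Y``.
* Each stage is observed by one survey; two stages may share a survey label,
  in which case they share a single bias parameter psi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = ["LifeCycleParams", "CovariateSet", "LatentStates", "Dataset"]


def default_survey_labels(n_stages: int) -> List[str]:
    return [f"S{i + 1}" for i in range(n_stages)]


@dataclass
class CovariateSet:
    """Design matrices for the vital-rate regressions.

    ``w_R`` is the T x (m_R + 1) recruitment design matrix and ``w_S[i]`` the
    design matrix for survival out of stage ``i+1``; the first column of each
    must be an intercept column of ones.
    """

    w_R: np.ndarray
    w_S: List[np.ndarray]

    def __post_init__(self) -> None:
        self.w_R = np.asarray(self.w_R, dtype=float)
        self.w_S = [np.asarray(w, dtype=float) for w in self.w_S]
        if self.w_R.ndim != 2:
            raise ValueError("w_R must be a 2-D design matrix")
        T = self.w_R.shape[0]
        for i, w in enumerate(self.w_S):
            if w.ndim != 2 or w.shape[0] != T:
                raise ValueError(
                    f"w_S[{i}] must have {T} rows to match w_R, got {w.shape}"
                )
        for name, w in [("w_R", self.w_R)] + [
            (f"w_S[{i}]", w) for i, w in enumerate(self.w_S)
        ]:
            if not np.allclose(w[:, 0], 1.0):
                raise ValueError(f"first column of {name} must be all ones")

    @property
    def T(self) -> int:
        return self.w_R.shape[0]

    @property
    def n_stages(self) -> int:
        return len(self.w_S) + 1


@dataclass
class LifeCycleParams:
    """Full parameter vector theta of the life-cycle state-space model.

    Parameters
    ----------
    n_stages : number of sequential life stages (>= 2).
    log_N_init : log initial adult abundance log N_{n,0}.
    beta_R : recruitment regression coefficients (length m_R + 1).
    beta_S : survival regression coefficients, one vector per stage 1..n-1.
    sigma_p_R : log-scale recruitment process SD.
    sigma_p_S : logit-scale survival process SDs, length n-1.
    psi : survey label -> multiplicative observation bias (catchability).
    psi_fixed : subset of ``psi`` held fixed during fitting, with the value
        each is fixed at.  Identifiability requires at least one psi (or
        log_N_init) to be fixed when fitting.
    """

    n_stages: int
    log_N_init: float
    beta_R: np.ndarray
    beta_S: List[np.ndarray]
    sigma_p_R: float
    sigma_p_S: np.ndarray
    psi: Dict[str, float]
    psi_fixed: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        self.beta_R = np.asarray(self.beta_R, dtype=float)
        self.beta_S = [np.asarray(b, dtype=float) for b in self.beta_S]
        self.sigma_p_S = np.atleast_1d(np.asarray(self.sigma_p_S, dtype=float))
        if len(self.beta_S) != self.n_stages - 1:
            raise ValueError("need one beta_S vector per stage 1..n-1")
        if self.sigma_p_S.shape != (self.n_stages - 1,):
            raise ValueError("sigma_p_S must have length n_stages-1")
        if self.sigma_p_R <= 0 or np.any(self.sigma_p_S <= 0):
            raise ValueError("process SDs must be strictly positive")
        if any(v <= 0 for v in self.psi.values()):
            raise ValueError("all psi must be strictly positive")
        for label, value in self.psi_fixed.items():
            if label not in self.psi:
                raise ValueError(f"psi_fixed refers to unknown survey {label!r}")
            if value <= 0:
                raise ValueError("fixed psi values must be strictly positive")

    def copy(self) -> "LifeCycleParams":
        return LifeCycleParams(
            n_stages=self.n_stages,
            log_N_init=float(self.log_N_init),
            beta_R=self.beta_R.copy(),
            beta_S=[b.copy() for b in self.beta_S],
            sigma_p_R=float(self.sigma_p_R),
            sigma_p_S=self.sigma_p_S.copy(),
            psi=dict(self.psi),
            psi_fixed=dict(self.psi_fixed),
        )

    @property
    def free_psi(self) -> List[str]:
        """Survey labels whose bias parameter is estimated."""
        return [s for s in self.psi if s not in self.psi_fixed]


@dataclass
class LatentStates:
    """Latent vital rates on their transformed scales.

    ``log_rho`` holds log recruitment rates (length T) and ``logit_phi`` the
    logit survival probabilities, shape (n-1, T).  Abundances are a
    deterministic function of these plus ``log_N_init``; see
    :func:`stagessm.model.build_abundances`.  (The all-log-normal test variant
    of the model reinterprets ``logit_phi`` as log survival.)
    """

    log_rho: np.ndarray
    logit_phi: np.ndarray

    def __post_init__(self) -> None:
        self.log_rho = np.asarray(self.log_rho, dtype=float)
        self.logit_phi = np.atleast_2d(np.asarray(self.logit_phi, dtype=float))
        if self.logit_phi.shape[1] != self.log_rho.shape[0]:
            raise ValueError(
                "logit_phi must have one column per cohort in log_rho"
            )

    @property
    def T(self) -> int:
        return self.log_rho.shape[0]

    @property
    def n_stages(self) -> int:
        return self.logit_phi.shape[0] + 1

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.log_rho, self.logit_phi.ravel()])

    @classmethod
    def from_vector(cls, u: np.ndarray, n_stages: int, T: int) -> "LatentStates":
        u = np.asarray(u, dtype=float)
        if u.shape != (n_stages * T,):
            raise ValueError(f"latent vector must have length {n_stages * T}")
        return cls(u[:T], u[T:].reshape(n_stages - 1, T))

    def copy(self) -> "LatentStates":
        return LatentStates(self.log_rho.copy(), self.logit_phi.copy())


@dataclass(eq=False)
class Dataset:
    """Observed abundance indices with known log-scale observation SDs.

    ``Y`` is n x T with NaN marking missing surveys; ``sigma_o`` holds the
    known observation SDs (log scale) for the observed cells.  ``Y_init`` is
    an optional index of the initial adult abundance N_{n,0}, observed through
    the stage-n survey's bias parameter.
    """

    Y: np.ndarray
    sigma_o: np.ndarray
    covariates: CovariateSet
    Y_init: Optional[float] = None
    sigma_o_init: Optional[float] = None
    survey_of_stage: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.sigma_o = np.asarray(self.sigma_o, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D (stages x cohorts)")
        if self.sigma_o.shape != self.Y.shape:
            raise ValueError("sigma_o must match Y in shape")
        n, T = self.Y.shape
        if self.covariates.T != T or self.covariates.n_stages != n:
            raise ValueError("covariates inconsistent with Y dimensions")
        if self.survey_of_stage is None:
            self.survey_of_stage = default_survey_labels(n)
        self.survey_of_stage = list(self.survey_of_stage)
        if len(self.survey_of_stage) != n:
            raise ValueError("survey_of_stage must name one survey per stage")
        mask = self.mask
        if np.any(self.Y[mask] <= 0):
            raise ValueError("observed index values must be strictly positive")
        so = self.sigma_o[mask]
        if np.any(~np.isfinite(so)) or np.any(so <= 0):
            raise ValueError("observation SDs must be finite and positive "
                             "wherever Y is observed")
        if self.Y_init is not None:
            if self.Y_init <= 0:
                raise ValueError("Y_init must be strictly positive")
            if self.sigma_o_init is None or self.sigma_o_init <= 0:
                raise ValueError("Y_init requires a positive sigma_o_init")
        self._obs_cache = None

    @property
    def mask(self) -> np.ndarray:
        """Boolean n x T array, True where Y is observed."""
        return np.isfinite(self.Y)

    @property
    def n_stages(self) -> int:
        return self.Y.shape[0]

    @property
    def T(self) -> int:
        return self.Y.shape[1]

    @property
    def n_obs(self) -> int:
        """Number of non-missing index observations, including Y_init."""
        return int(self.mask.sum()) + (self.Y_init is not None)

    @property
    def surveys(self) -> List[str]:
        """Unique survey labels in stage order."""
        seen: List[str] = []
        for s in self.survey_of_stage:
            if s not in seen:
                seen.append(s)
        return seen
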