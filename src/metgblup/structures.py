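"""Genetic-by-environment covariance structures.

The additive covariance of breeding values across the ``n_E``
location-by-season environments, ``G_AxE``, is parameterised as one of:

* ``uniform`` — a single additive variance shared by every environment with
  perfect cross-environment correlation: ``sigma2_A * J`` (J = all ones).
* ``cs`` — compound symmetry / main-effect-plus-interaction (A + AxE):
  off-diagonals ``sigma2_A``, diagonals ``sigma2_A + sigma2_AxE``.
* ``fa1`` — first-order factor analytic: ``Lambda Lambda^T + diag(Psi)``
  with one loading and one specific variance per environment.

Each structure exposes the covariance matrix, its derivatives with respect
to the parameter vector (for average-information REML), feasibility bounds
and default starting values.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EnvCovStructure",
    "Uniform",
    "CompoundSymmetry",
    "FactorAnalytic1",
    "get_structure",
    "env_cov_matrix",
    "implied_env_correlations",
]


class StructureError(ValueError):
    pass


class EnvCovStructure:
    """Base class: a parameterisation of the n_E x n_E matrix G_AxE."""

    kind: str = "base"

    def __init__(self, n_env: int):
        if n_env < 1:
            raise StructureError("need at least one environment")
        self.n_env = n_env

    @property
    def n_params(self) -> int:
        raise NotImplementedError

    @property
    def param_names(self) -> list:
        raise NotImplementedError

    def cov(self, params: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dcov(self, params: np.ndarray) -> np.ndarray:
        """(n_params, n_E, n_E) array of dSigma/dtheta_i."""
        raise NotImplementedError

    def lower_bounds(self) -> np.ndarray:
        raise NotImplementedError

    def start(self, per_env_var: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def finalize(self, params: np.ndarray) -> np.ndarray:
        """Apply identifiability conventions (e.g. FA sign fix)."""
        return params

    def validate(self, params: np.ndarray) -> None:
        params = np.asarray(params, float)
        if params.shape != (self.n_params,):
            raise StructureError(
                f"{self.kind} expects {self.n_params} parameters, got {params.shape}"
            )
        lb = self.lower_bounds()
        if np.any(params < lb - 1e-12):
            raise StructureError(f"{self.kind} parameters below bounds: {params}")


class Uniform(EnvCovStructure):
    """Homogeneous additive variance, cross-environment correlation 1."""

    kind = "uniform"

    @property
    def n_params(self) -> int:
        return 1

    @property
    def param_names(self) -> list:
        return ["sigma2_A"]

    def cov(self, params):
        self.validate(params)
        return params[0] * np.ones((self.n_env, self.n_env))

    def dcov(self, params):
        return np.ones((1, self.n_env, self.n_env))

    def lower_bounds(self):
        return np.zeros(1)

    def start(self, per_env_var):
        return np.array([0.5 * float(np.mean(per_env_var))])


class CompoundSymmetry(EnvCovStructure):
    """Main effect + homogeneous interaction (A + AxE)."""

    kind = "cs"

    @property
    def n_params(self) -> int:
        return 2

    @property
    def param_names(self) -> list:
        return ["sigma2_A", "sigma2_AxE"]

    def cov(self, params):
        self.validate(params)
        s2a, s2axe = params
        return s2a * np.ones((self.n_env, self.n_env)) + s2axe * np.eye(self.n_env)

    def dcov(self, params):
        d = np.empty((2, self.n_env, self.n_env))
        d[0] = 1.0
        d[1] = np.eye(self.n_env)
        return d

    def lower_bounds(self):
        return np.zeros(2)

    def start(self, per_env_var):
        v = float(np.mean(per_env_var))
        return np.array([0.4 * v, 0.1 * v])


class FactorAnalytic1(EnvCovStructure):
    """Order-1 factor analytic: Lambda Lambda^T + diag(Psi).

    Parameters are the n_E loadings followed by the n_E specific variances.
    The sign of the factor is fixed by requiring the first loading to be
    non-negative (applied by :meth:`finalize`; no rotation exists at order 1).
    """

    kind = "fa1"

    @property
    def n_params(self) -> int:
        return 2 * self.n_env

    @property
    def param_names(self) -> list:
        return [f"lambda_{e}" for e in range(self.n_env)] + [
            f"psi_{e}" for e in range(self.n_env)
        ]

    def split(self, params):
        params = np.asarray(params, float)
        return params[: self.n_env], params[self.n_env :]

    def cov(self, params):
        self.validate(params)
        lam, psi = self.split(params)
        return np.outer(lam, lam) + np.diag(psi)

    def dcov(self, params):
        lam, _ = self.split(params)
        nE = self.n_env
        d = np.zeros((2 * nE, nE, nE))
        for e in range(nE):
            d[e, e, :] += lam
            d[e, :, e] += lam
            d[nE + e, e, e] = 1.0
        return d

    def lower_bounds(self):
        return np.concatenate([np.full(self.n_env, -np.inf), np.zeros(self.n_env)])

    def start(self, per_env_var):
        v = np.asarray(per_env_var, float)
        return np.concatenate([np.sqrt(0.5 * v), 0.1 * v])

    def finalize(self, params):
        lam, psi = self.split(np.asarray(params, float).copy())
        if lam[0] < 0:
            lam = -lam
        return np.concatenate([lam, psi])


_STRUCTURES = {
    "uniform": Uniform,
    "cs": CompoundSymmetry,
    "fa1": FactorAnalytic1,
}


def get_structure(kind: str, n_env: int) -> EnvCovStructure:
    try:
        cls = _STRUCTURES[kind]
    except KeyError:
        raise StructureError(
            f"unknown structure {kind!r}; choose from {sorted(_STRUCTURES)}"
        ) from None
    return cls(n_env)


def env_cov_matrix(kind: str, params, n_env: int) -> np.ndarray:
    """Convenience: the G_AxE matrix for a structure kind and parameters."""
    return get_structure(kind, n_env).cov(np.asarray(params, float))


def implied_env_correlations(cov: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by a covariance matrix; diagonal exactly 1."""
    cov = np.asarray(cov, float)
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise StructureError("zero diagonal variance: correlation undefined")
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr
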