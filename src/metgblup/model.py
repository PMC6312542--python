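"""Multivariate genomic mixed model for multi-environment trials.

The model is ``y = X b + Z u + r`` where

* ``b`` holds the fixed effects: the mean of each location-by-season
  environment, plus planting year at the one location where it applies;
* ``u`` are the genomic breeding values of every genotyped individual in
  every environment, with ``var(u) = G_AxE (x) G_A`` — the Kronecker product
  of the environment covariance structure (uniform, compound symmetry or
  factor analytic, see :mod:`metgblup.structures`) with the genomic
  relationship matrix. ``u`` is laid out in environment-major blocks, each
  block ordered by individual, so that the Kronecker factors appear in that
  order;
* ``r`` are residuals, independent between experimental units; observations
  of the same experimental unit across seasons at a location may share a
  season covariance when ``resid_cov`` is enabled (the default is
  independent, heterogeneous per-environment residual variances).

Variance parameters are estimated by restricted maximum likelihood with
average-information (AI) updates, step halving, a gradient fallback and an
active set pinning variance parameters at the zero boundary. BLUE/BLUP
solutions come from Henderson's mixed model equations at the REML estimates.

Follows the statsmodels convention: :class:`GxEModel` is built from data and
``fit()`` returns a :class:`GxEResults` carrying estimates, their
uncertainty, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .relatedness import RelationshipMatrix, bend
from .structures import EnvCovStructure, get_structure, implied_env_correlations

__all__ = ["GxEModel", "GxEResults", "LRTResult", "lrt"]

_LOG2PI = float(np.log(2.0 * np.pi))


class ModelError(ValueError):
    pass


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of two nested REML fits."""

    statistic: float
    df: int
    pvalue: float
    warning: str | None = None


def lrt(nested, full, df: int) -> LRTResult:
    """Likelihood-ratio test: ``2 (logL_full - logL_nested)`` on df chi-square.

    Accepts fitted results or raw restricted log-likelihoods. A negative
    statistic beyond tolerance signals a convergence problem of the full
    model; it is clipped to 0 with p = 1 and a warning recorded.
    """
    ll_n = getattr(nested, "llf", nested)
    ll_f = getattr(full, "llf", full)
    stat = 2.0 * (ll_f - ll_n)
    warning = None
    if stat < -1e-6:
        warning = f"full model log-likelihood below nested ({stat:.4g}); check convergence"
        stat = 0.0
    stat = max(stat, 0.0)
    return LRTResult(stat, df, float(stats.chi2.sf(stat, df)), warning)


class GxEModel:
    """Genomic G x E mixed model bound to one phenotype table and GRM.

    Parameters
    ----------
    pheno : pandas.DataFrame
        Long-format phenotype table; one row per observation. Records with
        missing ``y`` are dropped from fitting.
    grm : RelationshipMatrix
        Additive genomic relationship matrix covering every individual with
        a record (individuals without records are still predicted).
    location_col, season_col, id_col, y_col, unit_col : str
        Column names; environments are (location, season) pairs.
    planting_year_col, planting_year_location : str, optional
        When given, a planting-year fixed factor is added for records at
        the designated location only.
    resid_cov : bool
        Estimate a residual covariance between seasons within a location
        for repeated observations of the same experimental unit. Off by
        default (independent heterogeneous residual variances).
    """

    def __init__(
        self,
        pheno: pd.DataFrame,
        grm: RelationshipMatrix,
        location_col: str = "Location",
        season_col: str = "Year",
        id_col: str = "REF_ID",
        y_col: str = "y",
        unit_col: str = "Experimental unit",
        planting_year_col: str | None = None,
        planting_year_location: str | None = None,
        resid_cov: bool = False,
        grm_bend: float = 1e-6,
    ):
        df = pheno.copy()
        df = df[pd.to_numeric(df[y_col], errors="coerce").notna()].reset_index(drop=True)
        if len(df) == 0:
            raise ModelError("no records with non-missing phenotype")
        unknown = set(df[id_col].astype(str)) - set(map(str, grm.labels))
        if unknown:
            raise ModelError(
                f"records reference individuals absent from the GRM: {sorted(unknown)[:5]}"
            )
        self.grm = grm
        self.grm_bend = grm_bend
        self.resid_cov = resid_cov
        self.id_col = id_col
        self.y_col = y_col
        self.y = df[y_col].astype(float).to_numpy()
        self.nobs = len(self.y)

        loc = df[location_col].astype(str).to_numpy()
        sea = df[season_col].astype(str).to_numpy()
        self.env_keys = sorted(set(zip(loc, sea)))
        self.n_env = len(self.env_keys)
        env_ix = {k: e for e, k in enumerate(self.env_keys)}
        self.env_idx = np.array([env_ix[k] for k in zip(loc, sea)])
        self.locations = sorted(set(loc))
        self.env_location = np.array([self.locations.index(k[0]) for k in self.env_keys])

        lab_ix = {str(lab): i for i, lab in enumerate(grm.labels)}
        self.ind_idx = np.array([lab_ix[s] for s in df[id_col].astype(str)])
        self.n_ind = grm.n

        if unit_col in df.columns and df[unit_col].astype(str).str.len().gt(0).any():
            units = df[unit_col].astype(str).to_numpy()
        else:
            units = np.array([f"{i}|{l}" for i, l in zip(df[id_col].astype(str), loc)])
        self.unit_codes, self.unit_idx = np.unique(units, return_inverse=True)
        self.location_of_record = loc
        self.season_of_record = sea

        # fixed-effect design: intercept + env dummies (first env reference)
        # + planting-year dummies for records at the designated location
        cols = [np.ones(self.nobs)]
        names = ["intercept"]
        for e in range(1, self.n_env):
            cols.append((self.env_idx == e).astype(float))
            names.append(f"env[{self.env_keys[e][0]}:{self.env_keys[e][1]}]")
        self.py_levels: list = []
        self.py_location = planting_year_location
        if planting_year_col is not None and planting_year_location is not None:
            at_loc = loc == str(planting_year_location)
            py = df[planting_year_col].astype(str).to_numpy()
            levels = sorted(set(py[at_loc]))
            self.py_levels = levels
            for lv in levels[1:]:
                cols.append((at_loc & (py == lv)).astype(float))
                names.append(f"planting_year[{lv}]")
        X = np.column_stack(cols)
        # guard against empty environments creating rank deficiency
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ModelError("fixed-effect design is rank deficient")
        self.exog = X
        self.exog_names = names
        self.df = df

        self._GA_rec = grm.values[np.ix_(self.ind_idx, self.ind_idx)]
        self._GA_bent = bend(grm.values, grm_bend)

        # residual-covariance bookkeeping: record pairs of the same unit at
        # the same location in different environments
        self._same_unit = None
        if resid_cov:
            su = (self.unit_idx[:, None] == self.unit_idx[None, :]) & (
                self.env_idx[:, None] != self.env_idx[None, :]
            )
            self._same_unit = su

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, pheno: pd.DataFrame, grm: RelationshipMatrix, **kw) -> "GxEModel":
        return cls(pheno, grm, **kw)

    # ------------------------------------------------------------------
    def _n_resid_params(self) -> int:
        n = self.n_env
        if self.resid_cov:
            # one covariance per location with >= 2 seasons observed
            n += sum(
                1
                for li in range(len(self.locations))
                if (self.env_location == li).sum() >= 2
            )
        return n

    def _resid_cov_locs(self) -> list:
        return [
            li
            for li in range(len(self.locations))
            if (self.env_location == li).sum() >= 2
        ]

    def _build_R(self, resid: np.ndarray) -> np.ndarray:
        """Dense residual covariance from per-env variances (+ covariances)."""
        R = np.diag(resid[: self.n_env][self.env_idx])
        if self.resid_cov and self._same_unit is not None:
            covs = resid[self.n_env :]
            loc_of_rec = np.array(
                [self.locations.index(l) for l in self.location_of_record]
            )
            for k, li in enumerate(self._resid_cov_locs()):
                mask = self._same_unit & (
                    (loc_of_rec[:, None] == li) & (loc_of_rec[None, :] == li)
                )
                R[mask] = covs[k]
        return R

    def _build_V(self, Sigma: np.ndarray, resid: np.ndarray) -> np.ndarray:
        V = Sigma[np.ix_(self.env_idx, self.env_idx)] * self._GA_rec
        V += self._build_R(resid)
        return V

    # ------------------------------------------------------------------
    def reml_loglik(self, Sigma: np.ndarray, resid: np.ndarray, _parts: bool = False):
        """Restricted log-likelihood at a given G_AxE matrix and residuals.

        ``l_R = -1/2 [(N - p) ln 2pi + ln|V| + ln|X'V^-1 X| + y' P y]`` with
        ``P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1``.
        """
        V = self._build_V(Sigma, np.asarray(resid, float))
        X, y = self.exog, self.y
        n, p = X.shape
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            raise ModelError(
                "V is not positive definite; bend G_A or raise residual floor"
            ) from None
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vinv = linalg.cho_solve(cf, np.eye(n))
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        sign, logdetXtVX = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            raise ModelError("X'V^-1X singular; confounded fixed effects")
        beta = np.linalg.solve(XtVinvX, VinvX.T @ y)
        Py = Vinv @ y - VinvX @ beta
        quad = float(y @ Py)
        ll = -0.5 * ((n - p) * _LOG2PI + logdetV + logdetXtVX + quad)
        if _parts:
            P = Vinv - VinvX @ np.linalg.solve(XtVinvX, VinvX.T)
            return ll, P, Py, beta, XtVinvX
        return ll

    # ------------------------------------------------------------------
    def _split_params(self, theta: np.ndarray, struct: EnvCovStructure):
        q = struct.n_params
        return np.asarray(theta[:q], float), np.asarray(theta[q:], float)

    def _loglik_theta(self, theta, struct):
        g, r = self._split_params(theta, struct)
        return self.reml_loglik(struct.cov(g), r)

    def _start_values(self, struct: EnvCovStructure) -> np.ndarray:
        per_env_var = np.array([
            self.y[self.env_idx == e].var() if (self.env_idx == e).sum() > 1 else self.y.var()
            for e in range(self.n_env)
        ])
        per_env_var = np.where(per_env_var > 0, per_env_var, max(self.y.var(), 1.0))
        resid0 = 0.5 * per_env_var
        start = np.concatenate([struct.start(per_env_var), resid0])
        if self.resid_cov:
            start = np.concatenate([start, np.zeros(len(self._resid_cov_locs()))])
        return start

    def _bounds(self, struct: EnvCovStructure) -> np.ndarray:
        floor = 1e-8 * max(float(self.y.var()), 1.0)
        lb = np.concatenate([struct.lower_bounds(), np.full(self.n_env, floor)])
        if self.resid_cov:
            lb = np.concatenate([lb, np.full(len(self._resid_cov_locs()), -np.inf)])
        return lb

    def _dV_genetic(self, dSig: np.ndarray) -> np.ndarray:
        return dSig[np.ix_(self.env_idx, self.env_idx)] * self._GA_rec

    # ------------------------------------------------------------------
    def fit(
        self,
        structure: str = "fa1",
        start: np.ndarray | None = None,
        max_iter: int = 200,
        tol_logl: float = 1e-6,
        tol_par: float = 1e-4,
        verbose: bool = False,
    ) -> "GxEResults":
        """Estimate variance parameters by AI-REML and solve the MME.

        Returns a :class:`GxEResults`. Non-convergence within ``max_iter``
        returns the last iterate flagged ``converged=False``.
        """
        if structure in ("cs", "fa1") and self.n_env < 2:
            raise ModelError(f"structure {structure!r} needs >= 2 environments")
        struct = get_structure(structure, self.n_env)
        theta = np.asarray(start, float) if start is not None else self._start_values(struct)
        nq = struct.n_params + self._n_resid_params()
        if theta.shape != (nq,):
            raise ModelError(f"expected {nq} parameters, got {theta.shape}")
        lb = self._bounds(struct)
        theta = np.maximum(theta, lb)
        scale = max(float(self.y.var()), 1.0)

        trace = []
        converged = False
        ll = self._loglik_theta(theta, struct)
        n_iter = 0
        for it in range(1, max_iter + 1):
            n_iter = it
            score, AI = self._score_ai(theta, struct)
            # active set: parameters pinned at their lower bound with an
            # outward-pointing score stay fixed this iteration
            at_lb = theta <= lb + 1e-12 * scale
            pinned = at_lb & (score < 0)
            free = ~pinned
            delta = np.zeros_like(theta)
            if free.any():
                A = AI[np.ix_(free, free)]
                A = A + 1e-8 * max(np.trace(A) / max(free.sum(), 1), 1e-12) * np.eye(free.sum())
                try:
                    delta[free] = np.linalg.solve(A, score[free])
                except np.linalg.LinAlgError:
                    delta[free] = score[free] / np.maximum(np.abs(np.diag(A)), 1e-12)

            new_theta, new_ll, accepted = self._line_search(theta, delta, ll, lb, struct)
            if not accepted:
                # gradient fallback, scaled to a modest parameter move
                gnorm = np.linalg.norm(score[free]) if free.any() else 0.0
                if gnorm > 0:
                    gdelta = np.zeros_like(theta)
                    gdelta[free] = score[free] * (0.1 * scale / gnorm)
                    new_theta, new_ll, accepted = self._line_search(
                        theta, gdelta, ll, lb, struct
                    )
            trace.append({"iteration": it, "llf": ll, "params": theta.copy()})
            if not accepted:
                # no direction improves the likelihood: at a (local) optimum
                converged = True
                break
            dll = new_ll - ll
            dpar = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), scale * 1e-3))
            theta, ll = new_theta, new_ll
            if verbose:
                print(f"iter {it:3d} llf {ll:.6f} dll {dll:.3g} dpar {dpar:.3g}")
            if abs(dll) < tol_logl and dpar < tol_par:
                converged = True
                break
        trace.append({"iteration": n_iter + 1, "llf": ll, "params": theta.copy()})

        theta = np.concatenate([
            struct.finalize(theta[: struct.n_params]),
            theta[struct.n_params :],
        ])
        g, r = self._split_params(theta, struct)
        return GxEResults(
            model=self,
            structure=struct,
            params=theta,
            llf=float(ll),
            converged=converged,
            n_iter=n_iter,
            trace=trace,
            genetic_params=g,
            resid_params=r,
        )

    def _line_search(self, theta, delta, ll, lb, struct, max_halvings: int = 10):
        step = 1.0
        for _ in range(max_halvings):
            cand = np.maximum(theta + step * delta, lb)
            cand = self._enforce_resid_corr(cand, struct)
            try:
                cand_ll = self._loglik_theta(cand, struct)
            except ModelError:
                cand_ll = -np.inf
            if np.isfinite(cand_ll) and cand_ll > ll - 1e-12:
                return cand, cand_ll, not np.allclose(cand, theta)
            step *= 0.5
        return theta, ll, False

    def _enforce_resid_corr(self, theta, struct):
        """Keep |residual season correlation| < 1 when resid_cov is on."""
        if not self.resid_cov:
            return theta
        theta = theta.copy()
        nE, q = self.n_env, struct.n_params
        var = theta[q : q + nE]
        covs = theta[q + nE :]
        for k, li in enumerate(self._resid_cov_locs()):
            envs = np.nonzero(self.env_location == li)[0]
            vmin = np.sqrt(np.prod(var[envs[:2]]))
            limit = 0.98 * vmin
            covs[k] = np.clip(covs[k], -limit, limit)
        theta[q + nE :] = covs
        return theta

    # ------------------------------------------------------------------
    def _score_ai(self, theta, struct):
        """REML score vector and average-information matrix at theta."""
        g, r = self._split_params(theta, struct)
        Sigma = struct.cov(g)
        ll, P, Py, beta, XtVinvX = self.reml_loglik(Sigma, r, _parts=True)
        n = self.nobs
        q = struct.n_params + self._n_resid_params()
        score = np.empty(q)
        W = np.empty((n, q))

        dSigs = struct.dcov(g)
        k = 0
        for i in range(struct.n_params):
            dV = self._dV_genetic(dSigs[i])
            score[k] = -0.5 * (np.sum(P * dV) - Py @ dV @ Py)
            W[:, k] = dV @ Py
            k += 1
        diagP = np.diag(P)
        for e in range(self.n_env):
            mask = self.env_idx == e
            score[k] = -0.5 * (diagP[mask].sum() - Py[mask] @ Py[mask])
            w = np.zeros(n)
            w[mask] = Py[mask]
            W[:, k] = w
            k += 1
        if self.resid_cov:
            loc_of_rec = np.array(
                [self.locations.index(l) for l in self.location_of_record]
            )
            for li in self._resid_cov_locs():
                mask2 = self._same_unit & (
                    (loc_of_rec[:, None] == li) & (loc_of_rec[None, :] == li)
                )
                dV = mask2.astype(float)
                score[k] = -0.5 * (np.sum(P * dV) - Py @ dV @ Py)
                W[:, k] = dV @ Py
                k += 1
        PW = P @ W
        AI = 0.5 * (W.T @ PW)
        return score, AI

    # ------------------------------------------------------------------
    def solve_mme(self, Sigma: np.ndarray, resid: np.ndarray, pev: bool = False):
        """Mixed-model BLUE/BLUP solution at given (co)variances.

        Solves Henderson's mixed model equations in their equivalent
        variance form, ``b = (X'V^-1 X)^-1 X'V^-1 y`` and
        ``u = G Z' V^-1 (y - X b)`` with ``V = Z G Z' + R``: identical to
        the MME solution but requiring no inverse of ``G``, so boundary
        estimates (rank-deficient G_AxE, duplicate genotypes) stay exact.

        Returns ``(blues, cov_blues, blups, pev_diag)``; ``blups`` covers
        all n_individuals x n_env cells (environment-major), including cells
        with no record. ``pev_diag`` is None unless ``pev=True``.
        """
        Sigma = np.asarray(Sigma, float)
        X, y = self.exog, self.y
        n, p = X.shape
        nE, nG = self.n_env, self.n_ind
        V = self._build_V(Sigma, np.asarray(resid, float))
        cf = linalg.cho_factor(V, lower=True)
        VinvX = linalg.cho_solve(cf, X)
        XtVinvX = X.T @ VinvX
        cov_blues = np.linalg.inv(XtVinvX)
        blues = cov_blues @ (VinvX.T @ y)
        e = y - X @ blues
        W = linalg.cho_solve(cf, e)  # V^-1 (y - X b-hat)

        GA = self.grm.values
        GA_cols = GA[:, self.ind_idx]  # (nG, N)
        u = np.empty((nE, nG))
        for env in range(nE):
            weights = Sigma[env, self.env_idx] * W
            u[env] = GA_cols @ weights

        pev_diag = None
        if pev:
            # PEV = diag(G) - diag(G Z' P Z G), P the REML projection
            Vinv = linalg.cho_solve(cf, np.eye(n))
            P = Vinv - VinvX @ cov_blues @ VinvX.T
            pev = np.empty((nE, nG))
            for env in range(nE):
                Ge = GA_cols * Sigma[env, self.env_idx]  # (nG, N)
                M = Ge @ P
                pev[env] = Sigma[env, env] * np.diag(GA) - np.sum(M * Ge, axis=1)
            pev_diag = pev.ravel()

        blups = pd.DataFrame(
            u.T,
            index=list(self.grm.labels),
            columns=[f"{l}:{s}" for l, s in self.env_keys],
        )
        return blues, cov_blues, blups, pev_diag


@dataclass
class GxEResults:
    """REML estimates, BLUE/BLUPs and diagnostics for one structure fit."""

    model: GxEModel
    structure: EnvCovStructure
    params: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    trace: list
    genetic_params: np.ndarray
    resid_params: np.ndarray
    _mme: tuple | None = field(default=None, repr=False)

    # ------------------------------------------------------------------
    @property
    def env_cov(self) -> np.ndarray:
        """Estimated G_AxE matrix."""
        return self.structure.cov(self.genetic_params)

    @property
    def env_corr(self) -> np.ndarray:
        """Implied additive genomic correlations among environments."""
        return implied_env_correlations(self.env_cov)

    @property
    def resid_variances(self) -> np.ndarray:
        return self.resid_params[: self.model.n_env]

    def heritabilities(self) -> pd.DataFrame:
        """Per-environment narrow-sense genomic h2 = vG / (vG + vR)."""
        vG = np.diag(self.env_cov)
        vR = self.resid_variances
        return pd.DataFrame({
            "location": [k[0] for k in self.model.env_keys],
            "season": [k[1] for k in self.model.env_keys],
            "vG": vG,
            "vR": vR,
            "vP": vG + vR,
            "h2": vG / (vG + vR),
        })

    def avg_env_correlation(self) -> float:
        """Mean off-diagonal implied correlation (r-bar over environments)."""
        c = self.env_corr
        n = c.shape[0]
        return float(c[np.triu_indices(n, 1)].mean()) if n > 1 else 1.0

    # ------------------------------------------------------------------
    def _solve(self):
        if self._mme is None:
            self._mme = self.model.solve_mme(self.env_cov, self.resid_params)
        return self._mme

    @property
    def blues(self) -> pd.Series:
        b, _, _, _ = self._solve()
        return pd.Series(b, index=self.model.exog_names)

    @property
    def cov_blues(self) -> np.ndarray:
        _, cb, _, _ = self._solve()
        return cb

    @property
    def blups(self) -> pd.DataFrame:
        """Predicted breeding values, individuals x environments."""
        _, _, u, _ = self._solve()
        return u

    def fitted_fixed(self) -> np.ndarray:
        """X b-hat per record (fixed-effect adjustment basis)."""
        return self.model.exog @ self.blues.to_numpy()

    # ------------------------------------------------------------------
    def lsmeans(self, alpha: float = 0.05) -> pd.DataFrame:
        """Adjusted environment means with compact-letter display.

        The mean of environment e is the BLUE cell mean re-expanded from the
        reference coding, averaging over planting-year levels where that
        factor applies. Letters: environments sharing a letter do not differ
        in a pairwise z-test at ``alpha``.
        """
        m = self.model
        p = len(m.exog_names)
        L = np.zeros((m.n_env, p))
        L[:, 0] = 1.0
        for e in range(1, m.n_env):
            L[e, m.exog_names.index(f"env[{m.env_keys[e][0]}:{m.env_keys[e][1]}]")] = 1.0
        if m.py_levels and m.py_location is not None:
            py_cols = [i for i, nm in enumerate(m.exog_names) if nm.startswith("planting_year[")]
            for e in range(m.n_env):
                if m.env_keys[e][0] == str(m.py_location):
                    for c in py_cols:
                        L[e, c] = 1.0 / len(m.py_levels)
        means = L @ self.blues.to_numpy()
        cov = L @ self.cov_blues @ L.T
        se = np.sqrt(np.diag(cov))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        nE = m.n_env
        diff = np.zeros((nE, nE), bool)
        for i in range(nE):
            for j in range(i + 1, nE):
                sd = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
                z = abs(means[i] - means[j]) / sd if sd > 0 else np.inf
                diff[i, j] = diff[j, i] = z > zcrit
        letters = _compact_letters(means, diff)
        return pd.DataFrame({
            "location": [k[0] for k in m.env_keys],
            "season": [k[1] for k in m.env_keys],
            "lsmean": means,
            "se": se,
            "letters": letters,
        })

    # ------------------------------------------------------------------
    def compare_lr(self, nested: "GxEResults", df: int | None = None) -> LRTResult:
        """LRT of this (full) fit against a nested fit."""
        if df is None:
            df = self.structure.n_params - nested.structure.n_params
        return lrt(nested, self, df)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multi-environment genomic mixed model (REML)",
            "=" * 60,
            f"Structure: {self.structure.kind}    environments: {m.n_env}"
            f"    individuals: {m.n_ind}    records: {m.nobs}",
            f"Restricted logL: {self.llf:.4f}    converged: {self.converged}"
            f"    iterations: {self.n_iter}",
            "",
            "Environment variance components:",
            self.heritabilities().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
            "",
            f"Average additive genomic correlation among environments: "
            f"{self.avg_env_correlation():.3f}",
        ]
        if self.structure.kind == "fa1":
            lam = self.genetic_params[: m.n_env]
            psi = self.genetic_params[m.n_env :]
            lines += [
                "",
                "FA(1) loadings:  " + " ".join(f"{v:8.3f}" for v in lam),
                "FA(1) specifics: " + " ".join(f"{v:8.3f}" for v in psi),
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure.kind,
            "llf": self.llf,
            "converged": bool(self.converged),
            "n_iter": self.n_iter,
            "param_names": self.structure.param_names
            + [f"sigma2_R[{l}:{s}]" for l, s in self.model.env_keys]
            + [
                f"resid_cov[{self.model.locations[li]}]"
                for li in (self.model._resid_cov_locs() if self.model.resid_cov else [])
            ],
            "params": [float(v) for v in self.params],
            "heritabilities": self.heritabilities().to_dict(orient="records"),
            "avg_env_correlation": self.avg_env_correlation(),
        }


def _compact_letters(means: np.ndarray, diff: np.ndarray) -> list:
    """Compact letter display from a pairwise significant-difference matrix.

    Environments are swept in mean order; each maximal run of mutually
    non-different items shares one letter. Deterministic and invariant to
    the input ordering (it sorts internally).
    """
    n = len(means)
    order = np.argsort(means, kind="stable")
    # maximal runs (in mean order) of mutually non-different items
    groups: list = []
    for s in range(n):
        e = s
        while e + 1 < n and not any(
            diff[order[a], order[e + 1]] for a in range(s, e + 1)
        ):
            e += 1
        if not any(s0 <= s and e <= e0 for s0, e0 in groups):
            groups.append((s, e))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = [""] * n
    for g, (lo, hi) in enumerate(groups):
        for k in range(lo, hi + 1):
            letters[order[k]] += alphabet[g % len(alphabet)]
    return letters
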