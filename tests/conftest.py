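"""Shared fixtures: a small simulated study and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import null_space

from metgblup import (
    GxEModel,
    Pedigree,
    SimConfig,
    simulate_study,
    vanraden_grm,
)

MODEL_KW = dict(
    planting_year_col="Planting date",
    planting_year_location="Balandran.FR",
)


@pytest.fixture(scope="session")
def small_study():
    """Down-scaled study: 150 individuals, 300 SNPs, 4 locations x 2 seasons."""
    cfg = SimConfig(
        n_founders=80, n_families=14, offspring_per_family=5, m_loci=300
    )
    return simulate_study(cfg, seed=3)


@pytest.fixture(scope="session")
def small_grm(small_study):
    return vanraden_grm(small_study.genotypes)


@pytest.fixture(scope="session")
def small_model(small_study, small_grm):
    return GxEModel(small_study.phenotypes, small_grm, **MODEL_KW)


@pytest.fixture(scope="session")
def fits(small_model):
    """Converged REML fits of all three structures on the small study."""
    return {k: small_model.fit(structure=k) for k in ("uniform", "cs", "fa1")}


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def reml_loglik_error_contrast(y, X, V):
    """Restricted log-likelihood via error contrasts K'y with K'X = 0.

    Uses an orthonormal null-space basis; the ln|X'X| term aligns the
    constant with the profiled-fixed-effects form of the restricted
    likelihood.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    K = null_space(X.T)
    KVK = K.T @ V @ K
    _, logdet = np.linalg.slogdet(KVK)
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    Ky = K.T @ y
    quad = Ky @ np.linalg.solve(KVK, Ky)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + quad + logdet_xx)


def gene_drop_A(records, n_rep=100_000, seed=0):
    """Monte-Carlo numerator relationships by dropping founder alleles.

    Each founder receives two unique alleles; offspring inherit one random
    allele per parent. A[i, j] is twice the coancestry estimated over
    ``n_rep`` independent drops.
    """
    order = Pedigree(records).topological_order()
    parents = {r[0]: (r[1], r[2]) for r in records}
    rng = np.random.default_rng(seed)
    alleles = {}
    counter = 0
    for ind in order:
        pair = []
        for p in parents[ind]:
            if p is None:
                pair.append(np.full(n_rep, counter))
                counter += 1
            else:
                pick = rng.integers(2, size=n_rep).astype(bool)
                pair.append(np.where(pick, alleles[p][0], alleles[p][1]))
        alleles[ind] = pair
    n = len(order)
    A = np.zeros((n, n))
    for i in range(n):
        ai = alleles[order[i]]
        A[i, i] = 1.0 + np.mean(ai[0] == ai[1])
        for j in range(i + 1, n):
            aj = alleles[order[j]]
            s = sum(
                np.mean(ai[a] == aj[b]) for a in range(2) for b in range(2)
            )
            A[i, j] = A[j, i] = s / 2.0
    return order, A


def anova_reml_oneway(y_groups):
    """Closed-form REML for the balanced one-way random-effects model.

    For balanced data the REML estimates equal the ANOVA estimators:
    ``vR = MS_within`` and ``vA = (MS_between - MS_within) / r``.
    """
    y = np.asarray(y_groups, float)
    n, r = y.shape
    gm = y.mean()
    means = y.mean(axis=1)
    ms_between = r * np.sum((means - gm) ** 2) / (n - 1)
    ms_within = np.sum((y - means[:, None]) ** 2) / (n * (r - 1))
    return max((ms_between - ms_within) / r, 0.0), ms_within
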