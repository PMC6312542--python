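"""Genomic and pedigree relatedness, ordination, and linkage disequilibrium.

The additive genomic relationship matrix (GRM) follows VanRaden's first
method: dosages are centred by twice the allele frequency and the
cross-product is scaled by ``2 * sum_j p_j (1 - p_j)``. The pedigree
numerator relationship matrix uses the tabular method. LD is summarised as
the squared Pearson correlation of dosage vectors (composite LD on unphased
genotypes) against physical distance, binned in ranked groups of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "Pedigree",
    "LDResult",
    "OrdinationResult",
    "allele_frequencies",
    "vanraden_grm",
    "pedigree_A",
    "relationship_summary",
    "individual_by_location_grm",
    "eigen_ordination",
    "ld_pairs",
    "bin_ld",
    "bp_to_cM",
    "bend",
]


class RelatednessError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    """Labelled symmetric relationship matrix.

    ``kind`` is one of ``"genomic"`` (G_A from SNPs), ``"pedigree"`` (A) or
    ``"individual_by_location"`` (C = M G_A M^T).
    """

    labels: list
    values: np.ndarray
    kind: str = "genomic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise RelatednessError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise RelatednessError("relationship matrix must be symmetric")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Pedigree:
    """Trio records (individual, parent1, parent2); None = unknown parent."""

    records: list  # [(ind, p1 | None, p2 | None), ...]

    def topological_order(self) -> list:
        parents = {r[0]: (r[1], r[2]) for r in self.records}
        order, state = [], {}

        def visit(node, stack):
            if node is None or node not in parents:
                return
            if state.get(node) == 2:
                return
            if state.get(node) == 1:
                raise RelatednessError(
                    f"pedigree cycle involving {node!r}: {' -> '.join(stack + [node])}"
                )
            state[node] = 1
            for p in parents[node]:
                visit(p, stack + [node])
            state[node] = 2
            order.append(node)

        for r in self.records:
            visit(r[0], [])
        return order


@dataclass
class LDResult:
    """Same-chromosome locus pairs with rho^2, plus ranked-distance bins."""

    pairs: pd.DataFrame  # locus_i, locus_j, distance_bp, rho2
    bins: pd.DataFrame | None = None  # mean_distance_bp, mean_rho2, n_pairs
    skipped_loci: list = field(default_factory=list)


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    vectors: np.ndarray  # (n, k)
    fraction_explained: np.ndarray


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus allele frequency ``p_j = sum_i dosage_ij / (2 n)``.

    Requires a complete (imputed) matrix.
    """
    if G.n_individuals == 0 or G.n_loci == 0:
        raise RelatednessError("empty genotype matrix")
    if np.isnan(G.dosages).any():
        raise RelatednessError("allele frequencies require a complete matrix")
    return G.dosages.sum(axis=0) / (2.0 * G.n_individuals)


def vanraden_grm(G: GenotypeMatrix, p: np.ndarray | None = None) -> RelationshipMatrix:
    """Additive GRM, VanRaden method 1: ``Z Z^T / (2 sum p(1-p))``.

    ``Z`` is the dosage matrix with column ``j`` centred by ``2 p_j``. With
    observed frequencies every row of the result sums to ~0. Monomorphic
    loci (p of 0 or 1) must be removed upstream.
    """
    if p is None:
        p = allele_frequencies(G)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise RelatednessError("monomorphic loci present; filter before the GRM")
    denom = 2.0 * np.sum(p * (1 - p))
    if denom <= 0:
        raise RelatednessError("degenerate panel: sum p(1-p) is zero")
    Z = G.dosages - 2.0 * p
    GA = Z @ Z.T / denom
    return RelationshipMatrix(list(G.individuals), GA, kind="genomic")


def pedigree_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders (unknown parents) are treated as unrelated and non-inbred
    (diagonal 1); the diagonal of a non-founder is ``1 + A[p1, p2] / 2``.
    """
    order = ped.topological_order()
    parents = {r[0]: (r[1], r[2]) for r in ped.records}
    ix = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for ind in order:
        i = ix[ind]
        p1, p2 = parents.get(ind, (None, None))
        i1 = ix.get(p1) if p1 is not None else None
        i2 = ix.get(p2) if p2 is not None else None
        for other in order[: order.index(ind)]:
            j = ix[other]
            a = 0.0
            if i1 is not None:
                a += 0.5 * A[j, i1]
            if i2 is not None:
                a += 0.5 * A[j, i2]
            A[i, j] = A[j, i] = a
        f = 0.5 * A[i1, i2] if (i1 is not None and i2 is not None) else 0.0
        A[i, i] = 1.0 + f
    return RelationshipMatrix(order, A, kind="pedigree")


def relationship_summary(R: RelationshipMatrix) -> dict:
    """Variance and mode of diagonal and off-diagonal elements.

    Variances use the population convention (divide by the element count).
    The mode is the midpoint of the fullest histogram bin (51 bins).
    """
    if R.n < 2:
        raise RelatednessError("need at least two individuals")
    diag = np.diag(R.values)
    off = R.values[np.triu_indices(R.n, k=1)]

    def mode(x):
        hist, edges = np.histogram(x, bins=51)
        k = int(np.argmax(hist))
        return float((edges[k] + edges[k + 1]) / 2)

    return {
        "diag_variance": float(np.var(diag)),
        "offdiag_variance": float(np.var(off)),
        "diag_mode": mode(diag),
        "offdiag_mode": mode(off),
        "diag_max": float(diag.max()),
        "offdiag_max": float(off.max()),
        "diag_mean": float(diag.mean()),
        "offdiag_mean": float(off.mean()),
    }


def individual_by_location_grm(GA: RelationshipMatrix, assignments) -> RelationshipMatrix:
    """Individual-by-location GRM ``C = M G_A M^T``.

    ``assignments`` maps individual -> iterable of locations; each
    (individual, location) realisation becomes one row of the incidence
    matrix M picking that individual's row of G_A.
    """
    ix = {lab: i for i, lab in enumerate(GA.labels)}
    realisations, rows = [], []
    for ind in GA.labels:
        if ind not in assignments:
            continue
        for loc in assignments[ind]:
            realisations.append(f"{ind}@{loc}")
            rows.append(ix[ind])
    unknown = set(assignments) - set(GA.labels)
    if unknown:
        raise RelatednessError(f"assignments reference unknown individuals: {sorted(unknown)[:5]}")
    if not rows:
        raise RelatednessError("no individual-by-location realisations")
    rows = np.asarray(rows)
    C = GA.values[np.ix_(rows, rows)]
    return RelationshipMatrix(realisations, C, kind="individual_by_location")


def bend(values: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Add ``epsilon * I`` until the matrix is numerically positive definite."""
    out = np.asarray(values, float).copy()
    eps = epsilon
    for _ in range(40):
        try:
            np.linalg.cholesky(out)
            return out
        except np.linalg.LinAlgError:
            out[np.diag_indices_from(out)] += eps
            eps *= 10
    raise RelatednessError("matrix could not be bent to positive definite")


def eigen_ordination(
    R: RelationshipMatrix, k: int = 2, denominator: str = "positive"
) -> OrdinationResult:
    """Top-k eigen decomposition of a relationship matrix.

    ``fraction_explained[i]`` is eigenvalue i over the sum of positive
    eigenvalues (``denominator="positive"``, default) or over ``trace(R)``
    (``denominator="trace"``).
    """
    if k > R.n:
        raise RelatednessError("k exceeds matrix dimension")
    vals, vecs = np.linalg.eigh(R.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if denominator == "positive":
        denom = vals[vals > 0].sum()
    elif denominator == "trace":
        denom = np.trace(R.values)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    frac = vals[:k] / denom
    return OrdinationResult(vals[:k], vecs[:, :k], frac)


def ld_pairs(G: GenotypeMatrix, max_distance_bp: float | None = None) -> LDResult:
    """All same-chromosome pairwise dosage rho^2 against physical distance.

    Zero-variance loci are skipped (their correlation is undefined) and
    logged. ``max_distance_bp`` optionally restricts pair distance.
    """
    if G.n_individuals < 2:
        raise RelatednessError("need at least two individuals for LD")
    d = G.dosages
    var = d.var(axis=0)
    skipped = [G.loci["name"].iloc[j] for j in np.nonzero(var == 0)[0]]
    rows = []
    for chrom, idx in G.loci.groupby("chrom", sort=False).groups.items():
        idx = np.asarray([j for j in idx if var[j] > 0])
        if len(idx) < 2:
            continue
        sub = d[:, idx]
        corr = np.corrcoef(sub.T)
        pos = G.loci["pos"].to_numpy()[idx]
        names = G.loci["name"].to_numpy()[idx]
        iu, ju = np.triu_indices(len(idx), k=1)
        dist = np.abs(pos[iu] - pos[ju]).astype(float)
        rho2 = corr[iu, ju] ** 2
        keep = np.ones(len(dist), bool)
        if max_distance_bp is not None:
            keep = dist <= max_distance_bp
        rows.append(pd.DataFrame({
            "locus_i": names[iu][keep],
            "locus_j": names[ju][keep],
            "distance_bp": dist[keep],
            "rho2": rho2[keep],
        }))
    pairs = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["locus_i", "locus_j", "distance_bp", "rho2"])
    )
    return LDResult(pairs=pairs, skipped_loci=skipped)


def bin_ld(ld: LDResult, bin_size: int = 1000) -> LDResult:
    """Average rho^2 in consecutive groups of ``bin_size`` distance-ranked pairs.

    Pairs are sorted by distance and grouped; the last bin may be smaller.
    """
    if len(ld.pairs) == 0:
        raise RelatednessError("no LD pairs to bin")
    pairs = ld.pairs.sort_values("distance_bp", kind="stable").reset_index(drop=True)
    group = np.arange(len(pairs)) // bin_size
    bins = (
        pairs.assign(_g=group)
        .groupby("_g")
        .agg(mean_distance_bp=("distance_bp", "mean"),
             mean_rho2=("rho2", "mean"),
             n_pairs=("rho2", "size"))
        .reset_index(drop=True)
    )
    return LDResult(pairs=ld.pairs, bins=bins, skipped_loci=ld.skipped_loci)


def bp_to_cM(distance_bp: float, kb_per_cM: float = 465.0) -> float:
    """Convert physical distance to genetic distance at ``kb_per_cM`` kb/cM."""
    if kb_per_cM <= 0:
        raise ValueError("kb_per_cM must be positive")
    if distance_bp < 0:
        raise ValueError("distance must be non-negative")
    return (distance_bp / 1000.0) / kb_per_cM
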