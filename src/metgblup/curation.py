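"""Germplasm, SNP and phenotype curation.

Combining genotypic and phenotypic datasets contributed by several breeding
programs requires a common identifier space for individuals (cultivar names
are typed inconsistently across sources), a merged SNP matrix with conflicts
resolved, quality filters on loci, collapsing of duplicate DNA profiles
(clonal material distributed under several names) and imputation of the
remaining missing genotype calls.

Dosage matrices are ``numpy`` float arrays over ``{0, 1, 2, nan}`` where
``nan`` marks a missing call.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "NameRecord",
    "GenotypeMatrix",
    "RawGenotypeSet",
    "CurationReport",
    "format_name",
    "match_names",
    "merge_genotype_sources",
    "filter_snps",
    "find_duplicate_profiles",
    "impute_missing",
    "standardize_phenotypes",
    "PHENOTYPE_FIELDS",
]

#: Standardised field vocabulary for long-format phenotype tables.
PHENOTYPE_FIELDS = [
    "Location",
    "Trial",
    "Section",
    "Row",
    "Position",
    "Block",
    "Plot",
    "Plant",
    "Planting date",
    "REF_ID",
    "Experimental unit",
    "Year",
    "Observation unit",
    "y",
]

#: Mandatory fields a source-to-standard field map must cover.
MANDATORY_FIELDS = ("REF_ID", "Location", "Year", "y")


class CurationError(ValueError):
    """Raised on invalid curation inputs (bad names, schema violations...)."""


@dataclass
class NameRecord:
    """Link between a free-text germplasm name and its canonical keys.

    ``original`` is the name as received, ``formatted`` its canonical
    lowercase token and ``final`` the linkage key shared by records that
    refer to the same individual across sources.
    """

    original: str
    formatted: str
    final: str


@dataclass
class GenotypeMatrix:
    """Individuals-by-loci dosage matrix with a locus map.

    Attributes
    ----------
    individuals : list of str
        Ordered individual labels (rows).
    loci : pandas.DataFrame
        One row per locus with columns ``name``, ``chrom``, ``pos`` (bp,
        1-based) and optionally ``cm``.
    dosages : numpy.ndarray
        ``(n_individuals, n_loci)`` float array over {0, 1, 2, nan}.
    """

    individuals: list
    loci: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.loci)):
            raise CurationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if "pos" in self.loci.columns and (self.loci["pos"] < 0).any():
            raise CurationError("locus positions must be non-negative")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(self.dosages[~ok])
            raise CurationError(f"dosages outside {{0,1,2,missing}}: {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individuals), self.loci.copy(), self.dosages.copy()
        )


@dataclass
class RawGenotypeSet:
    """One source's genotype calls, locus names already standardised."""

    source: str
    individuals: list
    locus_names: list
    calls: np.ndarray  # (n, m) over {0,1,2,nan}

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if len(set(self.locus_names)) != len(self.locus_names):
            raise CurationError(f"duplicate locus names in source {self.source!r}")


@dataclass
class CurationReport:
    """Bookkeeping of what each curation step removed, merged or imputed."""

    n_loci_input: int = 0
    n_loci_removed_missing: int = 0
    n_loci_removed_maf: int = 0
    n_loci_retained: int = 0
    n_conflicts: int = 0
    duplicate_groups: list = field(default_factory=list)
    n_individuals_removed_duplicates: int = 0
    n_imputed_cells: int = 0
    imputed_fraction: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Name standardisation and matching
# ---------------------------------------------------------------------------

def format_name(original: str) -> str:
    """Canonicalise a germplasm name.

    Rules: decompose diacritics to their ASCII base letter, lowercase,
    replace whitespace runs by a single underscore, and delete every other
    non-alphanumeric character (apostrophes, periods, quotes...) without
    inserting a separator.

    >>> format_name("0900 Ziraat")
    '0900_ziraat'
    >>> format_name("Precoce d'Isigny")
    'precoce_disigny'
    """
    if not isinstance(original, str) or not original.strip():
        raise CurationError("empty germplasm name")
    s = unicodedata.normalize("NFKD", original)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = s.lower().strip()
    s = re.sub(r"\s+", "_", s)
    s = re.sub(r"[^a-z0-9_]", "", s)
    if not s.strip("_"):
        raise CurationError(f"name {original!r} has no alphanumeric content")
    return s.strip("_")


def _edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (iterative DP; names are short)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@dataclass
class MatchReport:
    """Outcome of dictionary lookup for one formatted name."""

    query: str
    kind: str  # 'exact' | 'partial' | 'none'
    final: str | None = None
    candidates: list = field(default_factory=list)  # [(formatted, score)]


def match_names(formatted: str, dictionary: dict, max_distance: float = 0.2) -> MatchReport:
    """Match a formatted name against an existing name dictionary.

    ``dictionary`` maps formatted name -> final (linkage) name. An exact hit
    returns the final name; otherwise candidates are collected by substring
    containment or by normalised Levenshtein distance (distance divided by
    the longer length) at most ``max_distance``, ranked best first.
    """
    if formatted in dictionary:
        return MatchReport(formatted, "exact", final=dictionary[formatted])
    candidates = []
    for key in dictionary:
        if formatted in key or key in formatted:
            # substring containment scored by length mismatch
            score = 1.0 - min(len(formatted), len(key)) / max(len(formatted), len(key))
            candidates.append((key, score))
            continue
        dist = _edit_distance(formatted, key) / max(len(formatted), len(key))
        if dist <= max_distance:
            candidates.append((key, dist))
    candidates.sort(key=lambda t: (t[1], t[0]))
    if candidates:
        return MatchReport(formatted, "partial", candidates=candidates)
    return MatchReport(formatted, "none")


# ---------------------------------------------------------------------------
# SNP merging and filters
# ---------------------------------------------------------------------------

def merge_genotype_sources(sets, loci: pd.DataFrame | None = None):
    """Merge genotype calls from several sources into one matrix.

    Individuals are linked by their (final) names, loci by standardised
    identifiers. Agreeing calls are retained; a cell where two sources
    disagree is set to missing and logged as a conflict; a call present in
    exactly one source fills the cell.

    Returns ``(GenotypeMatrix, conflict_log)`` where ``conflict_log`` is a
    list of ``(individual, locus)`` tuples, plus a merge report appended to
    the log is left to the caller. Union of individuals and loci is used.
    """
    sets = list(sets)
    if not sets:
        raise CurationError("need at least one genotype source")
    if len(sets) > 1:
        shared = set(sets[0].locus_names)
        for s in sets[1:]:
            shared &= set(s.locus_names)
        if not shared:
            raise CurationError("sources share no locus identifiers")

    # deterministic union orders: first-seen across sources sorted by name
    all_inds = sorted({i for s in sets for i in s.individuals})
    all_loci = sorted({l for s in sets for l in s.locus_names})
    ind_ix = {v: k for k, v in enumerate(all_inds)}
    loc_ix = {v: k for k, v in enumerate(all_loci)}

    merged = np.full((len(all_inds), len(all_loci)), np.nan)
    conflict = np.zeros_like(merged, dtype=bool)
    for s in sets:
        rows = np.fromiter((ind_ix[i] for i in s.individuals), int, len(s.individuals))
        cols = np.fromiter((loc_ix[l] for l in s.locus_names), int, len(s.locus_names))
        sub = merged[np.ix_(rows, cols)]
        new = s.calls
        disagree = ~np.isnan(sub) & ~np.isnan(new) & (sub != new)
        fill = np.isnan(sub) & ~np.isnan(new)
        sub[fill] = new[fill]
        sub[disagree] = np.nan
        merged[np.ix_(rows, cols)] = sub
        cf = conflict[np.ix_(rows, cols)]
        cf |= disagree
        conflict[np.ix_(rows, cols)] = cf
    # a conflicted cell stays missing even if a third source agrees with one side
    merged[conflict] = np.nan

    conflicts = [
        (all_inds[i], all_loci[j]) for i, j in zip(*np.nonzero(conflict))
    ]
    if loci is None:
        loci = pd.DataFrame({
            "name": all_loci,
            "chrom": ["0"] * len(all_loci),
            "pos": np.arange(1, len(all_loci) + 1),
        })
    else:
        loci = loci.set_index("name").loc[all_loci].reset_index()
    gm = GenotypeMatrix(all_inds, loci, merged)
    return gm, conflicts


def filter_snps(G: GenotypeMatrix, max_missing: float = 0.30, min_maf: float = 0.05):
    """Drop loci with too much missing data or too low minor allele frequency.

    A locus is retained when its missing fraction is <= ``max_missing`` and
    its minor allele frequency, computed on non-missing calls, is
    >= ``min_maf``. Returns ``(filtered GenotypeMatrix, CurationReport)``.
    """
    d = G.dosages
    n = G.n_individuals
    n_miss = np.isnan(d).sum(axis=0)
    miss_frac = n_miss / n
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * (n - n_miss).clip(min=1))
    maf = np.minimum(p, 1 - p)
    maf[n_miss == n] = 0.0

    fail_missing = miss_frac > max_missing
    fail_maf = (maf < min_maf) & ~fail_missing
    keep = ~(fail_missing | fail_maf)

    report = CurationReport(
        n_loci_input=G.n_loci,
        n_loci_removed_missing=int(fail_missing.sum()),
        n_loci_removed_maf=int(fail_maf.sum()),
        n_loci_retained=int(keep.sum()),
    )
    out = GenotypeMatrix(
        list(G.individuals),
        G.loci.loc[keep].reset_index(drop=True),
        d[:, keep].copy(),
    )
    return out, report


def find_duplicate_profiles(
    G: GenotypeMatrix, min_overlap: int = 100, concordance: float = 0.99
):
    """Group individuals with (near-)identical genome-wide DNA profiles.

    Two individuals are linked when their dosage concordance over jointly
    non-missing loci is >= ``concordance`` with at least ``min_overlap``
    such loci; groups are the transitive closure of the links. Returns
    ``(groups, skipped_pairs)`` where groups are lists of individual labels
    (only groups of size >= 2) and skipped pairs had insufficient overlap.
    """
    if G.n_individuals < 2:
        raise CurationError("need at least two individuals")
    d = G.dosages
    n = G.n_individuals
    obs = ~np.isnan(d)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    skipped = []
    filled = np.where(obs, d, -9.0)
    for i in range(n - 1):
        both = obs[i] & obs[i + 1 :]
        overlap = both.sum(axis=1)
        same = ((filled[i] == filled[i + 1 :]) & both).sum(axis=1)
        for k in range(n - 1 - i):
            j = i + 1 + k
            if overlap[k] < min_overlap:
                skipped.append((G.individuals[i], G.individuals[j]))
                continue
            if same[k] / overlap[k] >= concordance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(G.individuals[i])
    dup_groups = [g for g in groups.values() if len(g) > 1]
    return dup_groups, skipped


def deduplicate(G: GenotypeMatrix, groups):
    """Keep the first member of each duplicate group, drop the rest."""
    drop = {m for g in groups for m in g[1:]}
    keep = [i for i, ind in enumerate(G.individuals) if ind not in drop]
    return GenotypeMatrix(
        [G.individuals[i] for i in keep],
        G.loci.copy(),
        G.dosages[keep].copy(),
    )


def impute_missing(G: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Fill missing genotype calls from flanking-marker information.

    For each missing cell the nearest non-missing flanking loci (same
    chromosome, left and right of the target) of that individual define a
    local dosage context; the imputed value is the modal dosage at the
    target locus among individuals sharing that flanking context. When no
    individual shares the context (or no flank exists) the value is drawn
    from the locus' Hardy-Weinberg dosage distribution at its observed
    allele frequency, using a generator seeded by ``seed``.

    Non-missing entries are never changed; the result is deterministic
    given ``seed``.
    """
    d = G.dosages.copy()
    if not np.isnan(d).any():
        return G.copy()
    rng = np.random.default_rng(seed)
    miss = np.isnan(d)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        name = G.loci["name"].iloc[int(np.argmax(all_missing))]
        raise CurationError(f"locus {name!r} has no non-missing call; cannot impute")

    chrom = G.loci["chrom"].to_numpy()
    n_obs = (~miss).sum(axis=0)
    p = np.nansum(d, axis=0) / (2.0 * n_obs)
    hw = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)  # (m, 3)

    orig = G.dosages  # reference for flanking contexts (pre-imputation)
    for j in np.nonzero(miss.any(axis=0))[0]:
        # nearest observed flanks on the same chromosome
        left = next(
            (k for k in range(j - 1, -1, -1) if chrom[k] == chrom[j]), None
        )
        right = next(
            (k for k in range(j + 1, G.n_loci) if chrom[k] == chrom[j]), None
        )
        rows = np.nonzero(miss[:, j])[0]
        for i in rows:
            context_cols = [k for k in (left, right) if k is not None and not np.isnan(orig[i, k])]
            val = np.nan
            if context_cols:
                match = ~np.isnan(orig[:, j])
                for k in context_cols:
                    match &= orig[:, k] == orig[i, k]
                if match.any():
                    counts = np.bincount(orig[match, j].astype(int), minlength=3)
                    val = float(np.argmax(counts))
            if np.isnan(val):
                val = float(rng.choice(3, p=hw[j]))
            d[i, j] = val
    return GenotypeMatrix(list(G.individuals), G.loci.copy(), d)


# ---------------------------------------------------------------------------
# Phenotype standardisation
# ---------------------------------------------------------------------------

def standardize_phenotypes(
    records: pd.DataFrame,
    field_map: dict,
    season_columns: list | None = None,
    repeat_field: str | None = None,
) -> pd.DataFrame:
    """Reshape a source phenotype table into the standardised long format.

    ``field_map`` maps source column names to the standardised vocabulary
    (must cover REF_ID, Location, Year and y unless ``season_columns`` is
    given, in which case the wide season columns are melted into Year/y
    pairs). The ``Experimental unit`` is synthesised from the design units
    and the genetic treatment, and the ``Observation unit`` from the
    experimental unit and the repeat factor. Unmapped columns pass through
    verbatim.
    """
    df = records.rename(columns=field_map).copy()
    if season_columns:
        id_cols = [c for c in df.columns if c not in season_columns]
        df = df.melt(
            id_vars=id_cols, value_vars=season_columns,
            var_name="Year", value_name="y",
        )
    missing = [f for f in MANDATORY_FIELDS if f not in df.columns]
    if missing:
        raise CurationError(f"field map does not cover mandatory fields: {missing}")

    for f in PHENOTYPE_FIELDS:
        if f not in df.columns:
            df[f] = ""
    design_units = ["Location", "Trial", "Section", "Block", "Plot", "Plant"]
    if (df["Experimental unit"] == "").all():
        df["Experimental unit"] = (
            df[design_units].astype(str).agg(":".join, axis=1)
            + ":" + df["REF_ID"].astype(str)
        )
    if (df["Observation unit"] == "").all():
        rep = df[repeat_field].astype(str) if repeat_field else df["Year"].astype(str)
        df["Observation unit"] = df["Experimental unit"].astype(str) + ":" + rep

    dup = df.duplicated(subset=["Experimental unit", "Year"], keep=False)
    if dup.any():
        ex = df.loc[dup, ["Experimental unit", "Year"]].iloc[0].tolist()
        raise CurationError(f"duplicate observation for (Experimental unit, Year)={ex}")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    ordered = PHENOTYPE_FIELDS + [c for c in df.columns if c not in PHENOTYPE_FIELDS]
    return df[ordered]
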