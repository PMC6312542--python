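"""Heritability, adjusted phenotypes, cross-validation and accuracy metrics.

Predictive ability (PA) is the correlation between predicted breeding
values and adjusted phenotypes in a validation set; prediction accuracy
(PACC) divides PA by the square root of the narrow-sense genomic
heritability of the target environment (from the full-data fit, since
independent heritability estimates are unavailable), and its standard
error is ``1 / sqrt(n)`` for a validation group of n individuals.

Two validation schemes mirror the two deployment questions: five-fold
masking of individuals within a location (predicting untested individuals
in a characterised environment) and leaving an entire location out
(predicting into an environment with no phenotypes at all).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import (
    GenotypeMatrix,
    filter_snps,
    find_duplicate_profiles,
    deduplicate,
    impute_missing,
)
from .model import GxEModel, GxEResults, lrt
from .relatedness import (
    allele_frequencies,
    vanraden_grm,
    pedigree_A,
    relationship_summary,
    individual_by_location_grm,
    eigen_ordination,
    ld_pairs,
    bin_ld,
    bp_to_cM,
    RelationshipMatrix,
)

__all__ = [
    "heritability",
    "avg_env_correlation",
    "prediction_accuracy",
    "se_pacc",
    "adjust_phenotypes",
    "within_location_cv",
    "leave_location_out_cv",
    "run_full_analysis",
]


class EvaluationError(ValueError):
    pass


def heritability(vG: float, vR: float) -> float:
    """Narrow-sense genomic heritability ``h2 = vG / (vG + vR)``."""
    if vG < 0 or vR < 0:
        raise EvaluationError("variance components must be non-negative")
    if vG + vR == 0:
        raise EvaluationError("h2 undefined: vG + vR = 0")
    return vG / (vG + vR)


def avg_env_correlation(sigma2_A: float, sigma2_AxE: float) -> float:
    """Average additive genomic correlation among environments.

    ``r_bar = sigma2_A / (sigma2_A + sigma2_AxE)`` — the common correlation
    implied by a compound-symmetry (A + AxE) structure.
    """
    if sigma2_A < 0 or sigma2_AxE < 0:
        raise EvaluationError("variance components must be non-negative")
    if sigma2_A + sigma2_AxE == 0:
        raise EvaluationError("r_bar undefined: both components zero")
    return sigma2_A / (sigma2_A + sigma2_AxE)


def prediction_accuracy(pa: float, h2: float) -> float:
    """``PACC = PA / sqrt(h2)``; may exceed 1 with sampling noise."""
    if not 0 < h2 <= 1:
        raise EvaluationError("h2 must be in (0, 1]")
    return pa / np.sqrt(h2)


def se_pacc(n: int) -> float:
    """Standard error of PACC for a validation group of n individuals."""
    if n < 1:
        raise EvaluationError("validation group must have at least one individual")
    return 1.0 / np.sqrt(n)


def adjust_phenotypes(fit: GxEResults) -> pd.DataFrame:
    """Phenotypes minus all fitted fixed effects (no shrinkage).

    ``y_adj = y - x' b_hat`` per record, removing the location-by-season
    means and the planting-year effect where it applies.
    """
    m = fit.model
    y_adj = m.y - fit.fitted_fixed()
    return pd.DataFrame({
        "REF_ID": m.df[m.id_col].astype(str).to_numpy(),
        "Location": m.location_of_record,
        "Year": m.season_of_record,
        "y": m.y,
        "y_adj": y_adj,
    })


def _h2_by_env(fit: GxEResults) -> dict:
    h = fit.heritabilities()
    return {
        (r.location, r.season): float(r.h2) for r in h.itertuples(index=False)
    }


def _refit(training: pd.DataFrame, grm, model_kw, structure, full_fit, max_iter=100):
    """Fit on a training subset, warm-started from the full-data estimates.

    Falls back to the full-data variance parameters when the training fit
    does not converge (logged in the returned flag)."""
    m = GxEModel(training, grm, **model_kw)
    start = full_fit.params if m.n_env == full_fit.model.n_env else None
    try:
        res = m.fit(structure=structure, start=start, max_iter=max_iter)
    except Exception:
        res = None
    if res is None or not res.converged:
        if start is not None:
            Sigma = full_fit.env_cov
            resid = full_fit.resid_params
        elif res is not None:
            Sigma = res.env_cov
            resid = res.resid_params
        else:
            raise EvaluationError("training fit failed and no fallback available")
        _, _, blups, _ = m.solve_mme(Sigma, resid)
        return m, blups, False
    return m, res.blups, res.converged


def within_location_cv(
    pheno: pd.DataFrame,
    grm: RelationshipMatrix,
    k: int = 5,
    seed: int = 0,
    structure: str = "fa1",
    full_fit: GxEResults | None = None,
    model_kw: dict | None = None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Five-fold within-location cross-validation.

    Individuals at each location are randomly assigned to ``k`` sets;
    for each location-by-set the validation individuals' records at that
    location are masked, the G x E model refitted on the remainder, and
    their breeding values in the masked environments predicted. PA is
    computed per location-by-set-by-season against adjusted phenotypes from
    the full-data fit, then averaged over sets for the season-level report.
    ``se.PACC = 1 / sqrt(n)`` uses the season-level validation count.
    """
    if k < 2:
        raise EvaluationError("k-fold CV needs k >= 2")
    model_kw = model_kw or {}
    model = GxEModel(pheno, grm, **model_kw)
    if full_fit is None:
        full_fit = model.fit(structure=structure)
    y_adj = model.y - full_fit.fitted_fixed()
    h2 = _h2_by_env(full_fit)
    rng = np.random.default_rng(seed)

    ids = np.array([str(model.grm.labels[i]) for i in model.ind_idx])
    rows = []
    for loc in model.locations:
        at_loc = model.location_of_record == loc
        inds = np.array(sorted(set(ids[at_loc])))
        fold = rng.permuted(np.arange(len(inds)) % k)
        for s in range(k):
            val_inds = set(inds[fold == s])
            mask = at_loc & np.isin(ids, list(val_inds))
            if not mask.any():
                continue
            training = model.df[~mask]
            _, blups, conv = _refit(training, grm, model_kw, structure, full_fit)
            for season in sorted(set(model.season_of_record[at_loc])):
                env_col = f"{loc}:{season}"
                vmask = mask & (model.season_of_record == season)
                n_val = int(vmask.sum())
                if n_val < min_group or env_col not in blups.columns:
                    rows.append({
                        "location": loc, "season": season, "set": s,
                        "n": n_val, "n_set_inds": len(val_inds),
                        "PA": np.nan, "flag": "too_few", "converged": conv,
                    })
                    continue
                pred = blups.loc[ids[vmask], env_col].to_numpy()
                pa = float(np.corrcoef(pred, y_adj[vmask])[0, 1])
                rows.append({
                    "location": loc, "season": season, "set": s,
                    "n": n_val, "n_set_inds": len(val_inds),
                    "PA": pa, "flag": "", "converged": conv,
                })
    per_set = pd.DataFrame(rows)

    agg_rows = []
    for (loc, season), grp in per_set.groupby(["location", "season"]):
        ok = grp[grp["PA"].notna()]
        if len(ok) == 0:
            continue
        pa = float(ok["PA"].mean())
        n_season = float(ok["n"].mean())
        h2_env = h2[(loc, season)]
        agg_rows.append({
            "location": loc, "season": season, "scheme": "within_location",
            "n_GxL": float(grp["n_set_inds"].mean()),
            "n_GxLS": n_season,
            "PA": pa,
            "PACC": prediction_accuracy(pa, h2_env),
            "se.PACC": se_pacc(max(int(round(n_season)), 1)),
            "n_sets": len(ok),
        })
    result = pd.DataFrame(agg_rows)
    result.attrs["per_set"] = per_set
    result.attrs["seed"] = seed
    return result


def leave_location_out_cv(
    pheno: pd.DataFrame,
    grm: RelationshipMatrix,
    seed: int = 0,
    structure: str = "fa1",
    full_fit: GxEResults | None = None,
    model_kw: dict | None = None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Leave-one-location-out cross-validation.

    For each location all its records are dropped, the model is refitted on
    the remaining locations, and each dropped individual's predicted
    breeding values are averaged across the preserved environments. PA is
    the per-season correlation of that average with the dropped location's
    adjusted phenotypes; PACC uses the dropped environments' full-data h2.
    """
    model_kw = model_kw or {}
    model = GxEModel(pheno, grm, **model_kw)
    if model.n_env < 2 or len(model.locations) < 2:
        raise EvaluationError("leave-location-out CV needs >= 2 locations")
    if full_fit is None:
        full_fit = model.fit(structure=structure)
    y_adj = model.y - full_fit.fitted_fixed()
    h2 = _h2_by_env(full_fit)
    ids = np.array([str(model.grm.labels[i]) for i in model.ind_idx])

    rows = []
    for loc in model.locations:
        at_loc = model.location_of_record == loc
        training = model.df[~at_loc]
        m2, blups, conv = _refit(training, grm, model_kw, structure, full_fit)
        preserved = [c for c in blups.columns if not c.startswith(f"{loc}:")]
        pred_mean = blups[preserved].mean(axis=1)
        for season in sorted(set(model.season_of_record[at_loc])):
            vmask = at_loc & (model.season_of_record == season)
            n_val = int(vmask.sum())
            if n_val < min_group:
                rows.append({
                    "location": loc, "season": season, "scheme": "across_location",
                    "n_GxL": len(set(ids[at_loc])), "n_GxLS": n_val,
                    "PA": np.nan, "PACC": np.nan,
                    "se.PACC": np.nan, "flag": "too_few", "converged": conv,
                })
                continue
            pred = pred_mean.loc[ids[vmask]].to_numpy()
            pa = float(np.corrcoef(pred, y_adj[vmask])[0, 1])
            rows.append({
                "location": loc, "season": season, "scheme": "across_location",
                "n_GxL": len(set(ids[at_loc])), "n_GxLS": n_val,
                "PA": pa,
                "PACC": prediction_accuracy(pa, h2[(loc, season)]),
                "se.PACC": se_pacc(n_val),
                "flag": "", "converged": conv,
            })
    result = pd.DataFrame(rows)
    result.attrs["seed"] = seed
    return result


# ---------------------------------------------------------------------------
# End-to-end orchestration
# ---------------------------------------------------------------------------

def run_full_analysis(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    pedigree=None,
    structures: tuple = ("uniform", "cs", "fa1"),
    max_missing: float = 0.30,
    min_maf: float = 0.05,
    cv_k: int = 5,
    run_cv: bool = True,
    seed: int = 0,
    ld_bin_size: int = 1000,
    kb_per_cm: float = 465.0,
    model_kw: dict | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the complete analysis sequence on curated or raw inputs.

    Curation (SNP filters, duplicate collapse, imputation) -> GRM, LD decay
    and eigen-ordination -> REML fits of the requested structures with LRT
    comparisons -> heritabilities, average correlation, least-square means
    and implied correlations -> both cross-validation schemes. Returns a
    results bundle (dict of plain types and DataFrames); when ``outdir`` is
    given the bundle is also written as JSON + CSV files. Deterministic for
    fixed inputs and seed.
    """
    model_kw = model_kw or {}
    bundle: dict = {"seed": seed, "thresholds": {
        "max_missing": max_missing, "min_maf": min_maf,
        "cv_k": cv_k, "ld_bin_size": ld_bin_size, "kb_per_cm": kb_per_cm,
    }}
    stage = "curation"
    try:
        G, report = filter_snps(genotypes, max_missing=max_missing, min_maf=min_maf)
        if G.n_individuals >= 2 and G.n_loci > 0:
            groups, _ = find_duplicate_profiles(G)
            report.duplicate_groups = groups
            report.n_individuals_removed_duplicates = sum(len(g) - 1 for g in groups)
            if groups:
                G = deduplicate(G, groups)
        n_missing = int(np.isnan(G.dosages).sum())
        if n_missing:
            G = impute_missing(G, seed=seed)
        report.n_imputed_cells = n_missing
        report.imputed_fraction = n_missing / max(G.dosages.size, 1)
        bundle["curation"] = report.to_dict()

        stage = "relatedness"
        p = allele_frequencies(G)
        poly = (p > 0) & (p < 1)
        if not poly.all():
            G = GenotypeMatrix(
                list(G.individuals), G.loci.loc[poly].reset_index(drop=True),
                G.dosages[:, poly],
            )
            p = p[poly]
        grm = vanraden_grm(G, p)
        bundle["grm_summary"] = relationship_summary(grm)
        if pedigree is not None:
            A = pedigree_A(pedigree)
            bundle["pedigree_summary"] = relationship_summary(A)

        ld = bin_ld(ld_pairs(G), bin_size=ld_bin_size)
        bundle["ld_bins"] = ld.bins
        below = ld.bins[ld.bins["mean_rho2"] < 0.2]
        bundle["ld_summary"] = {
            "mean_rho2_within_100kb": float(
                ld.pairs.loc[ld.pairs["distance_bp"] <= 1e5, "rho2"].mean()
            ),
            "distance_rho2_below_0.2_kb": float(below["mean_distance_bp"].iloc[0] / 1000)
            if len(below)
            else None,
            "distance_rho2_below_0.2_cM": bp_to_cM(
                float(below["mean_distance_bp"].iloc[0]), kb_per_cm
            )
            if len(below)
            else None,
        }

        loc_col = model_kw.get("location_col", "Location")
        id_col = model_kw.get("id_col", "REF_ID")
        assignments: dict = {}
        for ind, loc in zip(phenotypes[id_col].astype(str), phenotypes[loc_col].astype(str)):
            assignments.setdefault(ind, set()).add(loc)
        assignments = {
            k: sorted(v) for k, v in assignments.items() if k in set(map(str, grm.labels))
        }
        C = individual_by_location_grm(grm, assignments)
        ordn = eigen_ordination(C, k=2)
        bundle["ordination"] = {
            "eigenvalues": ordn.eigenvalues.tolist(),
            "fraction_explained": ordn.fraction_explained.tolist(),
            "fraction_first_two": float(ordn.fraction_explained.sum()),
        }

        stage = "model_fit"
        pheno_known = phenotypes[
            phenotypes[id_col].astype(str).isin(set(map(str, grm.labels)))
        ]
        model = GxEModel(pheno_known, grm, **model_kw)
        fits: dict = {}
        for kind in structures:
            fits[kind] = model.fit(structure=kind)
        bundle["fits"] = {k: f.to_dict() for k, f in fits.items()}
        lrts = {}
        if "uniform" in fits and "cs" in fits:
            lrts["cs_vs_uniform"] = lrt(fits["uniform"], fits["cs"], df=1)
        if "cs" in fits and "fa1" in fits:
            lrts["fa1_vs_cs"] = lrt(
                fits["cs"], fits["fa1"], df=2 * model.n_env - 2
            )
        bundle["lrt"] = {
            k: {"statistic": v.statistic, "df": v.df, "pvalue": v.pvalue}
            for k, v in lrts.items()
        }
        if "cs" in fits:
            s2a, s2axe = fits["cs"].genetic_params
            bundle["r_bar_AxE"] = avg_env_correlation(s2a, s2axe)
        best = fits.get("fa1") or fits.get("cs") or next(iter(fits.values()))
        bundle["heritabilities"] = best.heritabilities()
        bundle["env_correlations"] = pd.DataFrame(
            best.env_corr,
            index=[f"{l}:{s}" for l, s in model.env_keys],
            columns=[f"{l}:{s}" for l, s in model.env_keys],
        )
        bundle["lsmeans"] = best.lsmeans()
        bundle["blups"] = best.blups
        bundle["best_structure"] = best.structure.kind

        if run_cv:
            stage = "cross_validation"
            bundle["cv_within"] = within_location_cv(
                pheno_known, grm, k=cv_k, seed=seed,
                structure=best.structure.kind, full_fit=best, model_kw=model_kw,
            )
            if len(model.locations) >= 2:
                bundle["cv_across"] = leave_location_out_cv(
                    pheno_known, grm, seed=seed,
                    structure=best.structure.kind, full_fit=best, model_kw=model_kw,
                )
    except Exception as err:
        if outdir is not None:
            _write_bundle(bundle, outdir)
        raise EvaluationError(f"analysis failed at stage {stage!r}: {err}") from err

    if outdir is not None:
        _write_bundle(bundle, outdir)
    return bundle


def _write_bundle(bundle: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scalars = {}
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(outdir / f"{key}.csv", index=key in ("blups", "env_correlations"))
        else:
            scalars[key] = val
    with open(outdir / "results.json", "w") as fh:
        json.dump(scalars, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    return str(obj)
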