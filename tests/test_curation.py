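"""Name standardisation, SNP merging/filtering, duplicates and imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metgblup.curation import (
    CurationError,
    GenotypeMatrix,
    RawGenotypeSet,
    filter_snps,
    find_duplicate_profiles,
    format_name,
    impute_missing,
    match_names,
    merge_genotype_sources,
    standardize_phenotypes,
)


def gm(dosages, chrom=None, pos=None, individuals=None):
    d = np.asarray(dosages, float)
    n, m = d.shape
    loci = pd.DataFrame({
        "name": [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
    })
    inds = individuals if individuals is not None else [f"i{k}" for k in range(n)]
    return GenotypeMatrix(inds, loci, d)


class TestFormatName:
    @pytest.mark.parametrize("raw,expected", [
        ("Bing", "bing"),
        ("0900 Ziraat", "0900_ziraat"),
        ("Precoce d'Isigny", "precoce_disigny"),
        ("Noire de Meched", "noire_de_meched"),
        ("Ambrunés", "ambrunes"),
        ("  Emperor  Francis ", "emperor_francis"),
    ])
    def test_examples(self, raw, expected):
        assert format_name(raw) == expected

    @pytest.mark.parametrize("bad", ["", "   ", "''!!"])
    def test_invalid_names(self, bad):
        with pytest.raises(CurationError):
            format_name(bad)

    @settings(max_examples=200, deadline=None)
    @given(st.text(min_size=1, max_size=40))
    def test_idempotent_and_canonical(self, raw):
        try:
            once = format_name(raw)
        except CurationError:
            return
        assert format_name(once) == once
        assert all(c.islower() or c.isdigit() or c == "_" for c in once)


class TestMatchNames:
    DICT = {"bing": "bing", "burlat": "burlat", "sumtare": "sweetheart"}

    def test_exact_returns_final(self):
        rep = match_names("sumtare", self.DICT)
        assert rep.kind == "exact" and rep.final == "sweetheart"

    def test_substring_partial(self):
        rep = match_names("bing_cherry", self.DICT)
        assert rep.kind == "partial"
        assert rep.candidates[0][0] == "bing"

    def test_edit_distance_partial_ranked(self):
        rep = match_names("burlet", self.DICT)  # 1 edit from burlat
        assert rep.kind == "partial"
        assert rep.candidates[0][0] == "burlat"

    def test_unmatched_is_none(self):
        assert match_names("zzz_unknown", self.DICT).kind == "none"


class TestMerge:
    def _sets(self):
        a = RawGenotypeSet("A", ["x", "y"], ["s0", "s1"],
                           np.array([[0.0, np.nan], [1.0, 2.0]]))
        b = RawGenotypeSet("B", ["x", "y"], ["s0", "s1"],
                           np.array([[0.0, 2.0], [1.0, 0.0]]))
        return a, b

    def test_agreement_fill_and_conflict(self):
        a, b = self._sets()
        merged, conflicts = merge_genotype_sources([a, b])
        df = pd.DataFrame(merged.dosages, index=merged.individuals,
                          columns=merged.loci["name"])
        assert df.loc["x", "s0"] == 0          # agreement kept
        assert df.loc["x", "s1"] == 2          # single-source call fills
        assert np.isnan(df.loc["y", "s1"])     # disagreement -> missing
        assert conflicts == [("y", "s1")]

    def test_order_insensitive(self):
        a, b = self._sets()
        m1, c1 = merge_genotype_sources([a, b])
        m2, c2 = merge_genotype_sources([b, a])
        assert np.array_equal(m1.dosages, m2.dosages, equal_nan=True)
        assert len(c1) == len(c2)

    def test_no_shared_loci_errors(self):
        a = RawGenotypeSet("A", ["x"], ["s0"], np.array([[0.0]]))
        b = RawGenotypeSet("B", ["x"], ["s9"], np.array([[2.0]]))
        with pytest.raises(CurationError, match="share no locus"):
            merge_genotype_sources([a, b])


class TestFilterSnps:
    def test_monomorphic_removed(self):
        G = gm([[0, 0], [0, 1], [0, 2], [0, 1]])
        out, rep = filter_snps(G)
        assert list(out.loci["name"]) == ["s1"]
        assert rep.n_loci_removed_maf == 1

    def test_missing_fraction_threshold(self):
        col = [np.nan] * 4 + [1.0] * 6  # 40% missing > 30%
        keep = [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]
        G = gm(np.column_stack([col, keep]))
        out, rep = filter_snps(G)
        assert list(out.loci["name"]) == ["s1"]
        assert rep.n_loci_removed_missing == 1

    def test_counts_reconcile_and_values_untouched(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 30)).astype(float)
        d[rng.random(d.shape) < 0.2] = np.nan
        G = gm(d)
        out, rep = filter_snps(G)
        assert rep.n_loci_input == 30
        assert rep.n_loci_retained + rep.n_loci_removed_missing + rep.n_loci_removed_maf == 30
        kept = [j for j, nm in enumerate(G.loci["name"]) if nm in set(out.loci["name"])]
        assert np.array_equal(out.dosages, d[:, kept], equal_nan=True)
        assert out.individuals == G.individuals


class TestDuplicates:
    def test_identical_rows_grouped(self):
        row = np.array([0, 1, 2, 1, 0] * 40, float)
        G = gm(np.vstack([row, row, 1 - (row == 0)]))
        groups, _ = find_duplicate_profiles(G, min_overlap=50)
        assert groups == [["i0", "i1"]]

    def test_concordance_threshold(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, 1000).astype(float)
        near = base.copy()
        near[0] = (near[0] + 1) % 3            # 999/1000 = 0.999 >= 0.99
        far = base.copy()
        idx = rng.choice(1000, 100, replace=False)
        far[idx] = (far[idx] + 1) % 3          # 0.90 < 0.99
        G = gm(np.vstack([base, near, far]))
        groups, _ = find_duplicate_profiles(G)
        assert groups == [["i0", "i1"]]

    def test_transitive_grouping(self):
        base = np.tile([0.0, 1.0, 2.0, 1.0], 75)  # 300 loci
        a, b, c = base.copy(), base.copy(), base.copy()
        b[0] = 0.0   # a~b differ at 1
        c[1] = 2.0   # b~c differ at 2 from a, 2 from b -> all within 0.99
        G = gm(np.vstack([a, b, c]))
        groups, _ = find_duplicate_profiles(G, min_overlap=100)
        assert len(groups) == 1 and sorted(groups[0]) == ["i0", "i1", "i2"]

    def test_insufficient_overlap_skipped(self):
        d = np.full((2, 120), np.nan)
        d[:, :50] = 1.0
        G = gm(d)
        groups, skipped = find_duplicate_profiles(G, min_overlap=100)
        assert groups == [] and skipped == [("i0", "i1")]


class TestImpute:
    def test_complete_matrix_unchanged(self):
        G = gm([[0, 1], [2, 1]])
        out = impute_missing(G, seed=1)
        assert np.array_equal(out.dosages, G.dosages)

    def test_flanking_conditional_mode(self):
        # 10 complete individuals share flank (0, 2) and all carry dosage 2
        # at the middle locus; the individual with the missing middle call
        # and the same flanks must be imputed 2
        rows = [[0.0, 2.0, 2.0]] * 10 + [[0.0, np.nan, 2.0]]
        out = impute_missing(gm(np.array(rows)), seed=0)
        assert out.dosages[10, 1] == 2.0

    def test_all_missing_locus_errors(self):
        d = np.array([[0.0, np.nan], [1.0, np.nan]])
        with pytest.raises(CurationError, match="s1"):
            impute_missing(gm(d), seed=0)

    def test_deterministic_and_touches_only_missing(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(30, 20)).astype(float)
        miss = rng.random(d.shape) < 0.15
        d[miss] = np.nan
        G = gm(d)
        a = impute_missing(G, seed=5)
        b = impute_missing(G, seed=5)
        c = impute_missing(G, seed=6)
        assert np.array_equal(a.dosages, b.dosages)
        assert not np.isnan(a.dosages).any()
        # different seeds may differ only at originally-missing cells
        assert np.array_equal(a.dosages[~miss], c.dosages[~miss])
        assert np.array_equal(a.dosages[~miss], d[~miss])


class TestStandardizePhenotypes:
    def test_wide_seasons_melt_to_long(self):
        wide = pd.DataFrame({
            "cultivar": ["bing", "burlat"],
            "site": ["X", "X"],
            "1997": [150.0, 140.0],
            "1998": [152.0, 141.0],
        })
        out = standardize_phenotypes(
            wide, {"cultivar": "REF_ID", "site": "Location"},
            season_columns=["1997", "1998"],
        )
        assert len(out) == 4
        assert set(out["Year"]) == {"1997", "1998"}
        assert (out.loc[out["REF_ID"] == "bing"].sort_values("Year")["y"]
                .tolist() == [150.0, 152.0])

    def test_optional_design_fields_empty_but_present(self):
        df = pd.DataFrame({
            "id": ["a"], "loc": ["X"], "yr": ["2014"], "val": [100.0],
        })
        out = standardize_phenotypes(
            df, {"id": "REF_ID", "loc": "Location", "yr": "Year", "val": "y"}
        )
        assert out["Block"].iloc[0] == "" and out["Plot"].iloc[0] == ""

    def test_duplicate_observation_errors(self):
        df = pd.DataFrame({
            "id": ["a", "a"], "loc": ["X", "X"], "yr": ["2014", "2014"],
            "val": [1.0, 2.0],
        })
        with pytest.raises(CurationError, match="duplicate"):
            standardize_phenotypes(
                df, {"id": "REF_ID", "loc": "Location", "yr": "Year", "val": "y"}
            )

    def test_missing_mandatory_field_errors(self):
        df = pd.DataFrame({"id": ["a"], "val": [1.0]})
        with pytest.raises(CurationError, match="mandatory"):
            standardize_phenotypes(df, {"id": "REF_ID", "val": "y"})

    def test_unmapped_columns_pass_through(self):
        df = pd.DataFrame({
            "id": ["a"], "loc": ["X"], "yr": ["2014"], "val": [1.0],
            "rootstock": ["colt"],
        })
        out = standardize_phenotypes(
            df, {"id": "REF_ID", "loc": "Location", "yr": "Year", "val": "y"}
        )
        assert out["rootstock"].iloc[0] == "colt"
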