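"""Readers and writers for the package's plain-text interchange formats.

Genotypes travel as dosage CSV (rows = individuals, columns = loci, cells
0/1/2 or empty/NA for missing) or as a PLINK-style ped/map text pair where
the .map file gives chromosome, locus name, cM and bp and columns 7+ of the
.ped file are allele pairs recoded to dosage of the non-reference allele.
Relationship matrices are labelled square CSVs or 3-column sparse text;
pedigrees are 3-column CSVs with empty cells for unknown parents.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .curation import GenotypeMatrix, CurationError
from .relatedness import Pedigree, RelationshipMatrix

__all__ = [
    "read_genotype_csv",
    "write_genotype_csv",
    "read_plink",
    "write_plink",
    "read_phenotypes",
    "write_phenotypes",
    "read_grm_csv",
    "write_grm_csv",
    "write_grm_sparse",
    "read_pedigree_csv",
    "write_pedigree_csv",
]


def read_genotype_csv(path, map_path=None) -> GenotypeMatrix:
    """Dosage CSV (first column = individual label) with optional locus map.

    The map CSV needs columns ``name, chrom, pos`` (and optionally ``cm``);
    without a map, loci are placed consecutively on one pseudo-chromosome.
    """
    df = pd.read_csv(path, index_col=0, dtype={0: str})
    dosages = df.to_numpy(dtype=float)
    names = [str(c) for c in df.columns]
    if map_path is not None:
        loci = pd.read_csv(map_path, dtype={"name": str, "chrom": str})
        loci = loci.set_index("name").loc[names].reset_index()
    else:
        loci = pd.DataFrame({"name": names, "chrom": "0", "pos": np.arange(1, len(names) + 1)})
    return GenotypeMatrix([str(i) for i in df.index], loci, dosages)


def write_genotype_csv(G: GenotypeMatrix, path, map_path=None) -> None:
    df = pd.DataFrame(G.dosages, index=G.individuals, columns=G.loci["name"])
    df.to_csv(path, index_label="individual")
    if map_path is not None:
        G.loci.to_csv(map_path, index=False)


def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """PLINK text ped/map dialect recoded to dosages.

    map: whitespace-separated ``chrom name cM bp``. ped: ``family id father
    mother sex phenotype`` then two allele columns per locus; '0' marks a
    missing allele call. Dosage counts the lexicographically larger allele
    at each locus (deterministic orientation).
    """
    loci = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "name", "cm", "pos"],
        dtype={"chrom": str, "name": str},
    )
    m = len(loci)
    individuals, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise CurationError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            individuals.append(parts[1])
            alleles = np.array(parts[6:]).reshape(m, 2)
            rows.append(alleles)
    if not rows:
        raise CurationError("empty ped file")
    allele_arr = np.stack(rows)  # (n, m, 2)
    dosages = np.full((len(individuals), m), np.nan)
    for j in range(m):
        a = allele_arr[:, j, :]
        missing = (a == "0").any(axis=1)
        observed = np.unique(a[~missing])
        if len(observed) == 0:
            continue
        counted = max(observed)  # lexicographically larger allele
        dosages[:, j] = (a == counted).sum(axis=1).astype(float)
        dosages[missing, j] = np.nan
    loci = loci[["name", "chrom", "pos", "cm"]]
    return GenotypeMatrix(individuals, loci.reset_index(drop=True), dosages)


def write_plink(G: GenotypeMatrix, ped_path, map_path, alleles=("A", "B")) -> None:
    a0, a1 = alleles
    cm = G.loci["cm"] if "cm" in G.loci.columns else np.zeros(G.n_loci)
    with open(map_path, "w") as fh:
        for (_, row), c in zip(G.loci.iterrows(), cm):
            fh.write(f"{row['chrom']}\t{row['name']}\t{c}\t{int(row['pos'])}\n")
    code = {0.0: (a0, a0), 1.0: (a0, a1), 2.0: (a1, a1)}
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(G.individuals):
            fields = [str(ind), str(ind), "0", "0", "0", "-9"]
            for d in G.dosages[i]:
                pair = ("0", "0") if np.isnan(d) else code[float(d)]
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str).assign(
        y=lambda d: pd.to_numeric(d["y"], errors="coerce")
    )


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_grm_csv(path, kind: str = "genomic") -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix([str(i) for i in df.index], df.to_numpy(float), kind=kind)


def write_grm_csv(R: RelationshipMatrix, path) -> None:
    R.to_frame().to_csv(path, index_label="")


def write_grm_sparse(R: RelationshipMatrix, path) -> None:
    with open(path, "w") as fh:
        for i in range(R.n):
            for j in range(i, R.n):
                fh.write(f"{R.labels[i]}\t{R.labels[j]}\t{R.values[i, j]:.10g}\n")


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = list(df.columns[:3])
    records = [
        (r[cols[0]], r[cols[1]] or None, r[cols[2]] or None)
        for _, r in df.iterrows()
    ]
    return Pedigree(records)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    pd.DataFrame(
        [(i, p1 or "", p2 or "") for i, p1, p2 in ped.records],
        columns=["individual", "parent1", "parent2"],
    ).to_csv(path, index=False)
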