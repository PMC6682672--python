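"""Genotype and phenotype containers, file formats, marker summaries, kinship.

Genotypes are biallelic SNP calls on recombinant inbred lines (RILs), coded
-1 and 1 for the two homozygous classes and 0 for heterozygotes, with a
genetic map (chromosome, position in cM) aligned to the SNP columns.
Missing calls use the sentinel :data:`MISSING`.

Two plain-text formats are supported:

* ``hapmap`` — tab-separated, one row per SNP with columns
  ``rs``, ``chrom``, ``pos_cM`` followed by one column per RIL.
* ``csv-matrix`` — RIL x SNP matrix of codes with RIL ids as the index;
  the marker map travels in a ``<path>.map.csv`` sidecar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-9)
_VALID_CODES = frozenset((-1, 0, 1, int(MISSING)))


@dataclass
class GenotypeMatrix:
    """RIL x SNP genotype codes plus an aligned genetic map.

    Parameters
    ----------
    codes
        int8 array of shape (n_rils, n_snps) with entries in {-1, 0, 1}
        (or :data:`MISSING`).
    snp_ids, ril_ids
        Unique identifiers for columns and rows.
    chrom
        Chromosome label per SNP.
    pos_cm
        Genetic position per SNP in centimorgans.
    """

    codes: np.ndarray
    snp_ids: np.ndarray
    ril_ids: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.ril_ids = np.asarray(self.ril_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        n, m = self.codes.shape
        if len(self.ril_ids) != n:
            raise ValueError("ril_ids length does not match codes rows")
        for name, arr in (("snp_ids", self.snp_ids), ("chrom", self.chrom),
                          ("pos_cm", self.pos_cm)):
            if len(arr) != m:
                raise ValueError(f"{name} length does not match codes columns")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicated SNP ids")
        if len(set(self.ril_ids)) != n:
            raise ValueError("duplicated RIL ids")
        bad = ~np.isin(self.codes, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {int(self.codes[i, j])} at "
                f"RIL {self.ril_ids[i]!r} / SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_rils(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos_cm": self.pos_cm}
        )

    def map_is_sorted(self) -> bool:
        """True if positions are non-decreasing within every chromosome."""
        for c in pd.unique(self.chrom):
            p = self.pos_cm[self.chrom == c]
            if np.any(np.diff(p) < 0):
                return False
        return True

    def float_codes(self, impute: bool = False) -> np.ndarray:
        """Codes as float64 with missing as NaN, or per-SNP mean-imputed."""
        x = self.codes.astype(np.float64)
        x[self.codes == MISSING] = np.nan
        if impute and np.isnan(x).any():
            mu = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
            mu = np.where(np.isnan(mu), 0.0, mu)
            idx = np.where(np.isnan(x))
            x[idx] = mu[idx[1]]
        return x

    def subset(self, rils=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by integer or boolean index arrays."""
        r = slice(None) if rils is None else np.asarray(rils)
        s = slice(None) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            codes=self.codes[r][:, s].copy(),
            snp_ids=self.snp_ids[s].copy(),
            ril_ids=self.ril_ids[r].copy(),
            chrom=self.chrom[s].copy(),
            pos_cm=self.pos_cm[s].copy(),
        )


@dataclass
class KinshipMatrix:
    """Square RIL x RIL genomic relationship matrix."""

    values: np.ndarray
    ril_ids: np.ndarray
    method: str = "vanraden"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


@dataclass
class PhenotypeTable:
    """Tidy phenotypes: one row per (RIL, trait, environment).

    ``genetic_values`` optionally carries the simulator's true genetic values
    (ril_id, environment, genetic_value) for oracle checks.
    """

    data: pd.DataFrame
    genetic_values: pd.DataFrame | None = None

    _REQUIRED = ("ril_id", "trait", "environment", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")

    @property
    def environments(self) -> list:
        return list(pd.unique(self.data["environment"]))

    @property
    def traits(self) -> list:
        return list(pd.unique(self.data["trait"]))

    def values_for(self, ril_ids, trait=None, environment=None) -> np.ndarray:
        """Phenotype vector aligned to ``ril_ids`` (NaN where absent)."""
        d = self.data
        if trait is not None:
            d = d[d["trait"] == trait]
        if environment is not None:
            d = d[d["environment"] == environment]
        s = d.set_index("ril_id")["value"]
        if s.index.has_duplicates:
            raise ValueError(
                "trait/environment selection does not identify a unique "
                "value per RIL"
            )
        return s.reindex(list(ril_ids)).to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(data=pd.read_csv(path))


# ---------------------------------------------------------------------------
# genotype file formats


def write_genotypes(geno: GenotypeMatrix, path, format: str = "hapmap") -> None:
    if format == "hapmap":
        df = pd.DataFrame(
            geno.codes.T, index=pd.Index(geno.snp_ids, name="rs"),
            columns=list(geno.ril_ids),
        ).astype(object)
        df[df == int(MISSING)] = "NA"
        df.insert(0, "chrom", geno.chrom)
        df.insert(1, "pos_cM", geno.pos_cm)
        df.to_csv(path, sep="\t")
    elif format == "csv-matrix":
        df = pd.DataFrame(
            geno.codes, index=pd.Index(geno.ril_ids, name="ril_id"),
            columns=list(geno.snp_ids),
        ).astype(object)
        df[df == int(MISSING)] = "NA"
        df.to_csv(path)
        geno.map.to_csv(f"{path}.map.csv", index=False)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _parse_codes(raw: pd.DataFrame, ril_ids, snp_ids) -> np.ndarray:
    """Parse a RIL x SNP frame of code symbols, naming the offending cell."""
    vals = raw.to_numpy()
    out = np.empty(vals.shape, dtype=np.int8)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        for i, v in enumerate(col):
            if isinstance(v, str):
                v = v.strip()
            if v in ("NA", "", None) or (isinstance(v, float) and np.isnan(v)):
                out[i, j] = MISSING
                continue
            try:
                code = int(v)
            except (TypeError, ValueError):
                code = None
            if code not in (-1, 0, 1):
                raise ValueError(
                    f"invalid genotype code {v!r} at RIL {ril_ids[i]!r} / "
                    f"SNP {snp_ids[j]!r}"
                )
            out[i, j] = code
    return out


def read_genotypes(path, format: str = "hapmap") -> GenotypeMatrix:
    if format == "hapmap":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
        if not {"chrom", "pos_cM"} <= set(df.columns):
            raise ValueError("hapmap file must have 'chrom' and 'pos_cM' columns")
        snp_ids = df.index.to_numpy(dtype=object)
        ril_cols = [c for c in df.columns if c not in ("chrom", "pos_cM")]
        codes = _parse_codes(df[ril_cols].T.reset_index(drop=True),
                             ril_cols, snp_ids)
        geno = GenotypeMatrix(
            codes=codes, snp_ids=snp_ids, ril_ids=np.array(ril_cols, dtype=object),
            chrom=df["chrom"].to_numpy(dtype=object),
            pos_cm=df["pos_cM"].to_numpy(dtype=float),
        )
    elif format == "csv-matrix":
        df = pd.read_csv(path, index_col=0, dtype=object)
        mp = pd.read_csv(f"{path}.map.csv")
        snp_ids = np.array(df.columns, dtype=object)
        if not np.array_equal(snp_ids, mp["snp_id"].to_numpy(dtype=object)):
            raise ValueError("map sidecar does not match matrix columns")
        ril_ids = df.index.to_numpy(dtype=object)
        codes = _parse_codes(df.reset_index(drop=True), ril_ids, snp_ids)
        geno = GenotypeMatrix(
            codes=codes, snp_ids=snp_ids, ril_ids=ril_ids,
            chrom=mp["chrom"].to_numpy(dtype=object),
            pos_cm=mp["pos_cm"].to_numpy(dtype=float),
        )
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if not geno.map_is_sorted():
        warnings.warn("genetic map positions are not sorted within chromosomes",
                      stacklevel=2)
    return geno


# ---------------------------------------------------------------------------
# marker summaries and relationship matrix


def minor_allele_freq(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency in [0, 0.5].

    MAF = min(p, 1-p) with p = (2 n_hom(+1) + n_het) / (2 n_nonmissing);
    the het code 0 contributes one copy of each allele.
    """
    c = geno.codes
    nonmiss = (c != MISSING).sum(axis=0)
    if np.any(nonmiss == 0):
        j = int(np.argmin(nonmiss))
        raise ValueError(f"SNP {geno.snp_ids[j]!r} has no non-missing calls")
    n_plus = (c == 1).sum(axis=0)
    n_het = (c == 0).sum(axis=0)
    p = (2.0 * n_plus + n_het) / (2.0 * nonmiss)
    return np.minimum(p, 1.0 - p)


def kinship(geno: GenotypeMatrix, method: str = "vanraden") -> KinshipMatrix:
    """VanRaden genomic relationship matrix K = W W' / (2 sum p(1-p)).

    W are genotype codes centred by 2p-1 (the population mean of the -1/0/1
    coding at allele frequency p); missing calls are mean-imputed per SNP.
    """
    if method != "vanraden":
        raise ValueError(f"unknown kinship method {method!r}")
    if geno.n_rils < 2 or geno.n_snps < 2:
        raise ValueError("kinship needs at least 2 RILs and 2 SNPs")
    x = geno.float_codes(impute=True)
    # frequency of the +1 allele (unfolded, unlike minor_allele_freq)
    c = geno.codes
    nonmiss = (c != MISSING).sum(axis=0)
    p_plus = (2.0 * (c == 1).sum(axis=0) + (c == 0).sum(axis=0)) / (2.0 * nonmiss)
    denom = 2.0 * np.sum(p_plus * (1.0 - p_plus))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: kinship denominator is zero")
    w = x - (2.0 * p_plus - 1.0)
    k = (w @ w.T) / denom
    k = (k + k.T) / 2.0
    return KinshipMatrix(values=k, ril_ids=geno.ril_ids, method=method)


def write_kinship(k: KinshipMatrix, path) -> None:
    pd.DataFrame(k.values, index=list(k.ril_ids),
                 columns=list(k.ril_ids)).to_csv(path)


def read_kinship(path, method: str = "vanraden") -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return KinshipMatrix(values=df.to_numpy(dtype=float),
                         ril_ids=df.index.to_numpy(dtype=object), method=method)
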