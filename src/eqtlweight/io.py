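"""Tabular input/output and the shared domain types.

All coordinates are 1-based inclusive (PLINK/VCF convention).  Association
tables are whitespace- or tab-delimited with a configurable column mapping
(header names or 0-based positional indices), because the upstream sources
(PLINK ``.assoc`` output, meta-analysis p-value lists, SNAP proxy exports)
do not share a schema.  Floats are written in scientific notation with six
significant digits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpKey",
    "ColumnMap",
    "AssocTable",
    "EqtlTable",
    "GenotypeMatrix",
    "LdTable",
    "read_assoc_table",
    "write_assoc_table",
    "read_eqtl_table",
    "read_genotypes",
    "write_genotype_matrix",
    "read_ld_table",
    "write_table",
]

FLOAT_FMT = "%.6e"
MISSING_TOKENS = {"NA", "na", "nan", ".", ""}


@dataclass(frozen=True)
class SnpKey:
    """Identifier of a SNP: rs-style (or arbitrary) id plus optional 1-based position."""

    snp_id: str
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos} for {self.snp_id}")


@dataclass
class ColumnMap:
    """Mapping from logical columns to file columns (header names or 0-based indices)."""

    snp_id: str | int = "SNP"
    p: str | int = "P"
    chrom: str | int | None = "CHR"
    pos: str | int | None = "BP"

    @property
    def positional(self) -> bool:
        return isinstance(self.snp_id, int)


def _select(df: pd.DataFrame, col: str | int, what: str) -> pd.Series:
    if isinstance(col, int):
        if col >= df.shape[1]:
            raise ValueError(f"column index {col} for {what} out of range ({df.shape[1]} columns)")
        return df.iloc[:, col]
    if col not in df.columns:
        raise ValueError(f"column {col!r} for {what} not found; available: {list(df.columns)}")
    return df[col]


def _read_delimited(path: str | Path, dialect: str, header: bool) -> pd.DataFrame:
    sep = "\t" if dialect == "tsv" else r"\s+"
    return pd.read_csv(path, sep=sep, header=0 if header else None, dtype=str, comment="#")


class AssocTable:
    """Per-SNP association results: the ordered p-values :math:`P_1, \\dots, P_m`.

    Wraps a DataFrame with columns ``snp_id, chrom, pos, p`` (plus any extras,
    e.g. effect sizes from a scan).  ``snp_id`` is unique; p-values lie in
    (0, 1].  A scan may record a missing p for a non-converged fit, flagged in
    a ``converged`` column; such rows are excluded from validation only when
    the flag marks them.
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        required = {"snp_id", "p"}
        if not required.issubset(df.columns):
            raise ValueError(f"AssocTable requires columns {sorted(required)}")
        df = df.reset_index(drop=True).copy()
        if "chrom" not in df.columns:
            df["chrom"] = None
        if "pos" not in df.columns:
            df["pos"] = np.nan
        self.df = df
        if validate:
            self._validate()

    def _validate(self) -> None:
        if len(self.df) < 1:
            raise ValueError("AssocTable must have at least one row")
        dup = self.df["snp_id"][self.df["snp_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate snp_id in association table: {dup.iloc[0]!r}")
        p = self.df["p"].to_numpy(dtype=float)
        flagged_ok = (
            ~self.df["converged"].to_numpy(dtype=bool)
            if "converged" in self.df.columns
            else np.zeros(len(p), dtype=bool)
        )
        bad = ~((p > 0) & (p <= 1)) & ~flagged_ok
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"p-value out of (0, 1] at row {row + 1} "
                f"(snp {self.df['snp_id'].iloc[row]!r}): {p[row]!r}"
            )

    @property
    def m(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def p(self) -> np.ndarray:
        return self.df["p"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(
        cls,
        snp_ids: Sequence[str],
        p: Sequence[float],
        chrom: Sequence[str] | None = None,
        pos: Sequence[int] | None = None,
        **extra: Sequence,
    ) -> "AssocTable":
        data: dict = {"snp_id": list(snp_ids), "p": np.asarray(p, dtype=float)}
        if chrom is not None:
            data["chrom"] = list(chrom)
        if pos is not None:
            data["pos"] = list(pos)
        data.update(extra)
        return cls(pd.DataFrame(data), validate="converged" not in extra)

    def __len__(self) -> int:
        return self.m

    def __repr__(self) -> str:
        return f"AssocTable(m={self.m})"


def read_assoc_table(
    path: str | Path,
    dialect: str = "whitespace",
    columns: ColumnMap | None = None,
    header: bool | None = None,
) -> AssocTable:
    """Read an association table (PLINK ``.assoc``-shaped or any delimited list).

    Parameters
    ----------
    dialect
        ``"tsv"`` (hard tabs) or ``"whitespace"`` (any run of blanks).
    columns
        Logical-to-physical column mapping; positional (integer) mappings
        imply a headerless file unless ``header`` is set explicitly.
    """
    columns = columns or ColumnMap()
    if header is None:
        header = not columns.positional
    raw = _read_delimited(path, dialect, header)
    if raw.empty:
        raise ValueError(f"empty association table: {path}")
    out = pd.DataFrame({"snp_id": _select(raw, columns.snp_id, "snp_id").astype(str)})
    for name, col in (("chrom", columns.chrom), ("pos", columns.pos)):
        if col is not None:
            try:
                s = _select(raw, col, name)
            except ValueError:
                continue
            out[name] = pd.to_numeric(s, errors="coerce") if name == "pos" else s.astype(str)
    p_raw = _select(raw, columns.p, "p")
    p = pd.to_numeric(p_raw, errors="coerce")
    if p.isna().any():
        row = int(p.index[p.isna()][0])
        raise ValueError(f"unparseable p-value at row {row + 1}: {p_raw.iloc[row]!r}")
    out["p"] = p.to_numpy(dtype=float)
    return AssocTable(out)


def write_assoc_table(table: AssocTable, path: str | Path) -> None:
    cols = ["snp_id", "chrom", "pos", "p"] + [
        c for c in table.df.columns if c not in ("snp_id", "chrom", "pos", "p")
    ]
    table.df[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


class EqtlTable:
    """Best *cis* eQTL evidence per SNP: p-value, LOD score and target gene.

    A SNP regulating several expression probes appears once, carrying the
    minimum probe-level p-value (and that row's LOD/gene).
    """

    def __init__(self, df: pd.DataFrame, *, collapsed: bool = False):
        required = {"snp_id", "p_eqtl"}
        if not required.issubset(df.columns):
            raise ValueError(f"EqtlTable requires columns {sorted(required)}")
        df = df.reset_index(drop=True).copy()
        if "lod" not in df.columns:
            df["lod"] = np.nan
        if "gene" not in df.columns:
            df["gene"] = None
        p = df["p_eqtl"].to_numpy(dtype=float)
        if not ((p > 0) & (p < 1)).all():
            bad = int(np.flatnonzero(~((p > 0) & (p < 1)))[0])
            raise ValueError(
                f"eQTL p-value out of (0, 1) at row {bad + 1} "
                f"(snp {df['snp_id'].iloc[bad]!r}): {p[bad]!r}"
            )
        self.df = df
        if not collapsed:
            self.df = self._collapse(df)

    @staticmethod
    def _collapse(df: pd.DataFrame) -> pd.DataFrame:
        # keep first-appearance order, minimum p_eqtl per SNP (that row's lod/gene)
        order = df["snp_id"].drop_duplicates()
        idx = df.groupby("snp_id", sort=False)["p_eqtl"].idxmin()
        out = df.loc[idx.loc[order].to_numpy()].reset_index(drop=True)
        return out

    def collapse(self) -> "EqtlTable":
        """Idempotent per-SNP minimum-p collapse."""
        return EqtlTable(self.df, collapsed=False)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    def p_eqtl_map(self) -> dict[str, float]:
        return dict(zip(self.df["snp_id"], self.df["p_eqtl"].astype(float)))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"EqtlTable(n_snps={len(self)})"


def read_eqtl_table(
    path: str | Path,
    dialect: str = "tsv",
    columns: Mapping[str, str | int] | None = None,
) -> EqtlTable:
    """Read an eQTL reference table and collapse multiple probe rows per SNP."""
    cmap = {"snp_id": "SNP", "p_eqtl": "P", "lod": "LOD", "gene": "GENE"}
    if columns:
        cmap.update(columns)
    header = not isinstance(cmap["snp_id"], int)
    raw = _read_delimited(path, dialect, header)
    if raw.empty:
        raise ValueError(f"empty eQTL table: {path}")
    out = pd.DataFrame({"snp_id": _select(raw, cmap["snp_id"], "snp_id").astype(str)})
    out["p_eqtl"] = pd.to_numeric(_select(raw, cmap["p_eqtl"], "p_eqtl")).to_numpy(dtype=float)
    for name in ("lod", "gene"):
        try:
            s = _select(raw, cmap[name], name)
        except ValueError:
            continue
        out[name] = pd.to_numeric(s, errors="coerce") if name == "lod" else s.astype(str)
    return EqtlTable(out)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosages in {0, 1, 2}, ``nan`` for missing.

    Optionally carries a binary phenotype and real-valued covariate columns
    aligned to individuals.
    """

    dosages: np.ndarray
    snps: list[SnpKey]
    phenotype: np.ndarray | None = None
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError(
                f"{self.dosages.shape[1]} genotype columns but {len(self.snps)} SnpKeys"
            )
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype entry outside {{0,1,2,NA}} at individual {i}, snp "
                f"{self.snps[j].snp_id!r}: {self.dosages[i, j]!r}"
            )
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=float)
            if self.phenotype.shape != (self.n_individuals,):
                raise ValueError("phenotype length must match individuals")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.n_individuals:
                raise ValueError("covariate rows must match individuals")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return np.array([s.snp_id for s in self.snps])

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (dosage) allele per SNP."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.dosages[:, keep],
            [self.snps[i] for i in keep],
            phenotype=self.phenotype,
            covariates=self.covariates,
        )


def _read_matrix_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    snps = [SnpKey(c) for c in df.columns]
    vals = df.to_numpy()
    out = np.empty(vals.shape, dtype=float)
    for (i, j), tok in np.ndenumerate(vals):
        tok = "" if tok is None or (isinstance(tok, float) and np.isnan(tok)) else str(tok).strip()
        if tok in MISSING_TOKENS:
            out[i, j] = np.nan
        elif tok in ("0", "1", "2"):
            out[i, j] = float(tok)
        else:
            raise ValueError(
                f"genotype entry outside {{0,1,2,NA}} at row {i + 1}, column "
                f"{snps[j].snp_id!r}: {tok!r}"
            )
    return GenotypeMatrix(out, snps)


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cols: list[np.ndarray] = []
    snps: list[SnpKey] = []
    for var in vcf:
        gts = var.genotypes  # [[a0, a1, phased], ...]
        dos = np.empty(len(gts), dtype=float)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype (ploidy {len(alleles)}) at "
                    f"{var.CHROM}:{var.POS} for sample index {i}"
                )
            if any(a < 0 for a in alleles):
                dos[i] = np.nan
            else:
                dos[i] = float(sum(1 for a in alleles if a > 0))
        snps.append(SnpKey(var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), int(var.POS)))
        cols.append(dos)
    if not cols:
        raise ValueError(f"no variant records in VCF: {path}")
    return GenotypeMatrix(np.column_stack(cols), snps)


def read_genotypes(path: str | Path, format: str = "matrix_tsv") -> GenotypeMatrix:
    """Read genotypes from a matrix TSV (SNP per column, individual per row,
    entries 0/1/2/NA) or from a diploid VCF (GT fields -> alt-dosage counts,
    ``./.`` -> missing)."""
    if format == "matrix_tsv":
        return _read_matrix_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotype_matrix(G: GenotypeMatrix, path: str | Path) -> None:
    def tok(v: float) -> str:
        return "NA" if np.isnan(v) else str(int(v))

    with open(path, "w") as fh:
        fh.write("\t".join(s.snp_id for s in G.snps) + "\n")
        for row in G.dosages:
            fh.write("\t".join(tok(v) for v in row) + "\n")


class LdTable:
    """Symmetric pairwise LD lookup: (snp_a, snp_b) -> (r2, D').

    Missing pairs are distinct from r2 = 0: ``lookup`` returns ``None`` when
    no LD information is available for a pair.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"snp_a", "snp_b", "r2"}
        if not required.issubset(df.columns):
            raise ValueError(f"LdTable requires columns {sorted(required)}")
        df = df.reset_index(drop=True).copy()
        if "dprime" not in df.columns:
            df["dprime"] = np.nan
        if "distance" not in df.columns:
            df["distance"] = np.nan
        r2 = df["r2"].to_numpy(dtype=float)
        if ((r2 < 0) | (r2 > 1)).any():
            raise ValueError("r2 must lie in [0, 1]")
        dp = df["dprime"].to_numpy(dtype=float)
        if np.nanmax(dp, initial=0.0) > 1.0 or np.nanmin(dp, initial=0.0) < 0.0:
            raise ValueError("D' must lie in [0, 1]")
        self.df = df
        self._index: dict[frozenset, tuple[float, float, float]] = {}
        for a, b, r, d, dist in zip(df["snp_a"], df["snp_b"], r2, dp, df["distance"]):
            key = frozenset((str(a), str(b)))
            prev = self._index.get(key)
            if prev is None or r > prev[0]:
                self._index[key] = (float(r), float(d), float(dist))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "LdTable":
        """Build from (snp_a, snp_b, r2[, dprime[, distance]]) tuples."""
        rows = []
        for tup in pairs:
            a, b, r2 = tup[0], tup[1], tup[2]
            dp = tup[3] if len(tup) > 3 else np.nan
            dist = tup[4] if len(tup) > 4 else np.nan
            rows.append((a, b, r2, dp, dist))
        return cls(pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2", "dprime", "distance"]))

    def lookup(self, a: str, b: str) -> tuple[float, float] | None:
        hit = self._index.get(frozenset((a, b)))
        return None if hit is None else (hit[0], hit[1])

    def partners(self, a: str) -> dict[str, tuple[float, float, float]]:
        """All SNPs with a recorded pair against ``a`` -> (r2, D', distance)."""
        out: dict[str, tuple[float, float, float]] = {}
        for key, val in self._index.items():
            ids = tuple(key)
            if a in ids:
                other = ids[0] if ids[0] != a else (ids[1] if len(ids) > 1 else a)
                out[other] = val
        return out

    def __len__(self) -> int:
        return len(self._index)


def read_ld_table(
    path: str | Path,
    dialect: str = "tsv",
    columns: Mapping[str, str | int] | None = None,
) -> LdTable:
    """Read a pairwise LD table (SNAP-shaped: SNP, Proxy, Distance, RSquared, DPrime)."""
    cmap: dict[str, str | int | None] = {
        "snp_a": "SNP",
        "snp_b": "Proxy",
        "r2": "RSquared",
        "dprime": "DPrime",
        "distance": "Distance",
    }
    if columns:
        cmap.update(columns)
    header = not isinstance(cmap["snp_a"], int)
    raw = _read_delimited(path, dialect, header)
    out = pd.DataFrame(
        {
            "snp_a": _select(raw, cmap["snp_a"], "snp_a").astype(str),
            "snp_b": _select(raw, cmap["snp_b"], "snp_b").astype(str),
            "r2": pd.to_numeric(_select(raw, cmap["r2"], "r2")).to_numpy(dtype=float),
        }
    )
    for name in ("dprime", "distance"):
        col = cmap.get(name)
        if col is None:
            continue
        try:
            out[name] = pd.to_numeric(_select(raw, col, name), errors="coerce")
        except ValueError:
            continue
    return LdTable(out)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV with a stable column order and scientific floats."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
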