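"""Data containers and file formats.

The package works on two aligned tables: a genotype matrix of additive
minor-allele counts (0/1/2, with a sentinel for missing calls) plus per-SNP
annotation, and a covariate table holding the case/control label and the
environmental covariates used for adjustment (gender, smoking status in four
categories, geographical region in five, and age in years).

Primary interchange format is plain TSV; PLINK text (.ped/.map) is supported
read-only, recoded to minor-allele counts at load time.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

SMOKING_LEVELS = ("never", "occasional", "former", "current")
REGION_LEVELS = ("Barcelona", "Valles/Bages", "Elche", "Asturias", "Tenerife")
GENDER_LEVELS = ("female", "male")

SNP_ANNOTATION_COLUMNS = ["rs", "gene", "chrom", "pos", "allele_a", "allele_b", "func"]


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclasses.dataclass
class GenotypeMatrix:
    """n individuals x p SNPs of additive genotype codes.

    ``codes`` is int8 with values in {0, 1, 2} and :data:`MISSING` (-1) for
    missing calls; code c counts copies of the minor allele, so 0 = common
    homozygote AA, 1 = heterozygote Aa, 2 = rare homozygote aa.
    """

    codes: np.ndarray
    snps: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-d array")
        bad = ~np.isin(self.codes, [-1, 0, 1, 2])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"invalid genotype code at row {i}, column {j}")
        if len(self.snps) != self.codes.shape[1]:
            raise ValueError("annotation length != number of SNP columns")
        if len(self.sample_ids) != self.codes.shape[0]:
            raise ValueError("sample_ids length != number of rows")
        rs = self.snps["rs"]
        if rs.duplicated().any():
            dup = rs[rs.duplicated()].iloc[0]
            raise ValueError(f"duplicated rs ID: {dup}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(self.codes[:, keep], self.snps.iloc[keep], list(self.sample_ids))

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(self.codes[keep], self.snps, [self.sample_ids[i] for i in keep])

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency over non-missing calls.

        Computed as the frequency of the allele the codes count; a value above
        0.5 indicates the stored orientation is no longer minor (e.g. after
        subsetting) and is reported as-is.
        """
        obs = self.codes != MISSING
        counts = np.where(obs, self.codes, 0).sum(axis=0).astype(float)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)


@dataclasses.dataclass
class CovariateTable:
    """Per-individual outcome and environmental covariates.

    Wraps a DataFrame with columns ``label`` (1 = case), ``gender``,
    ``smoking`` (four levels; missing allowed and kept as NA), ``region`` and
    ``age`` in years.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        required = {"label", "gender", "smoking", "region", "age"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValueError(f"covariate table missing columns: {sorted(missing_cols)}")
        if not df["label"].isin([0, 1]).all():
            raise ValueError("label must be binary 0/1")
        if not df["gender"].isin(GENDER_LEVELS).all():
            raise ValueError("gender outside vocabulary")
        ok_smoking = df["smoking"].isna() | df["smoking"].isin(SMOKING_LEVELS)
        if not ok_smoking.all():
            raise ValueError("smoking status outside vocabulary")
        if (df["age"] <= 0).any():
            raise ValueError("ages must be positive")
        self.data = df

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"].to_numpy(dtype=np.int8)

    def subset(self, keep: np.ndarray) -> "CovariateTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CovariateTable(self.data.iloc[keep])

    def nonsmokers(self) -> np.ndarray:
        """Boolean mask of never smokers."""
        return (self.data["smoking"] == "never").to_numpy()

    def design_matrix(self, standardize_age: bool = True) -> tuple[np.ndarray, list[str]]:
        """Dummy-coded design with reference levels female / never / first region.

        Returns (W, names); first column is the intercept.  Age is standardized
        (mean 0, sd 1) by default so the sampler mixes on a common scale; the
        un-standardized variant is available for reporting.  Rows with missing
        smoking status fall into the reference (never) category.
        """
        df = self.data
        cols = [np.ones(len(df))]
        names = ["intercept"]
        cols.append((df["gender"] == "male").to_numpy(float))
        names.append("gender_male")
        for lev in SMOKING_LEVELS[1:]:
            cols.append((df["smoking"] == lev).to_numpy(float))
            names.append(f"smoking_{lev}")
        regions = [r for r in REGION_LEVELS if r in set(df["region"])]
        if not regions:
            regions = sorted(set(df["region"]))
        for lev in regions[1:]:
            cols.append((df["region"] == lev).to_numpy(float))
            names.append(f"region_{lev}")
        age = df["age"].to_numpy(float)
        if standardize_age:
            sd = age.std()
            age = (age - age.mean()) / sd if sd > 0 else age - age.mean()
        cols.append(age)
        names.append("age")
        return np.column_stack(cols), names


def prune_collinear(W: np.ndarray) -> list[int]:
    """Indices of a maximal linearly independent column subset (keeps column 0).

    Used to drop empty factor levels and aliased dummies before model fits.
    """
    keep = [0]
    for c in range(1, W.shape[1]):
        if np.linalg.matrix_rank(W[:, keep + [c]]) == len(keep) + 1:
            keep.append(c)
    return keep


# ---------------------------------------------------------------------------
# genotype readers / writers

def read_genotypes(path: str | Path, dialect: str = "tsv",
                   annotation: str | Path | None = None) -> GenotypeMatrix:
    """Read a genotype matrix.

    dialect="tsv": header row of rs IDs, one row per individual (first column
    sample ID), cells 0/1/2/NA.  Optional ``annotation`` TSV supplies the SNP
    records; otherwise a minimal annotation is built from the header.

    dialect="plink_text": ``path`` is the .ped file; the .map file with the
    same stem must sit next to it.  Allele pairs are recoded to minor-allele
    counts (minor = less frequent allele in the file, ties broken
    alphabetically); "0 0" is missing.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path, annotation)
    if dialect == "plink_text":
        return _read_plink_text(path)
    raise ValueError(f"unsupported dialect: {dialect!r}")


def _read_tsv(path: Path, annotation: str | Path | None) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    rs_ids = header[1:]
    if len(set(rs_ids)) != len(rs_ids):
        dup = [r for r, c in Counter(rs_ids).items() if c > 1][0]
        raise FormatError(f"duplicated rs ID in header: {dup}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_ids = df.iloc[:, 0].tolist()
    geno = df.iloc[:, 1:]
    geno.columns = rs_ids
    codes = np.empty(geno.shape, dtype=np.int8)
    valid = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
    for j, col in enumerate(geno.columns):
        for i, tok in enumerate(geno[col]):
            tok = "NA" if pd.isna(tok) else str(tok).strip()
            if tok not in valid:
                raise FormatError(
                    f"invalid genotype token {tok!r} at row {i + 1}, column {col}")
            codes[i, j] = valid[tok]
    if annotation is not None:
        snps = read_snp_annotation(annotation)
        if list(snps["rs"]) != rs_ids:
            snps = snps.set_index("rs").loc[rs_ids].reset_index()
    else:
        snps = _minimal_annotation(rs_ids)
    return GenotypeMatrix(codes, snps, sample_ids)


def _minimal_annotation(rs_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame({
        "rs": rs_ids, "gene": "", "chrom": "", "pos": 0,
        "allele_a": "", "allele_b": "", "func": "",
    })


def read_snp_annotation(path: str | Path) -> pd.DataFrame:
    snps = pd.read_csv(path, sep="\t", dtype={"rs": str, "chrom": str})
    missing = set(SNP_ANNOTATION_COLUMNS) - set(snps.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    return snps[SNP_ANNOTATION_COLUMNS]


def _read_plink_text(ped_path: Path) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise FormatError(f"missing companion .map file: {map_path}")
    snp_rows = []
    for line in map_path.read_text().splitlines():
        if not line.strip():
            continue
        chrom, rs, _cm, pos = line.split()[:4]
        snp_rows.append((chrom, rs, int(pos)))
    p = len(snp_rows)
    sample_ids: list[str] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(ped_path.read_text().splitlines()):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) != 6 + 2 * p:
            raise FormatError(f".ped row {ln + 1}: expected {6 + 2 * p} fields, got {len(tok)}")
        sample_ids.append(tok[1])
        allele_pairs.append([(tok[6 + 2 * j], tok[7 + 2 * j]) for j in range(p)])
    n = len(sample_ids)
    codes = np.full((n, p), MISSING, dtype=np.int8)
    alleles = []
    for j in range(p):
        counts: Counter[str] = Counter()
        for i in range(n):
            for a in allele_pairs[i][j]:
                if a != "0":
                    counts[a] += 1
        obs = sorted(counts)  # alphabetical for deterministic ties
        if len(obs) > 2:
            raise FormatError(f"SNP {snp_rows[j][1]}: more than two alleles {obs}")
        if not obs:
            minor, major = "", ""
        elif len(obs) == 1:
            minor, major = obs[0], obs[0]
        else:
            # minor = less frequent; tie -> alphabetically first
            a, b = obs
            minor, major = (a, b) if counts[a] <= counts[b] else (b, a)
        alleles.append((minor, major))
        for i in range(n):
            pair = allele_pairs[i][j]
            if "0" in pair:
                continue
            codes[i, j] = sum(1 for a in pair if a == minor)
    chrom = [r[0] for r in snp_rows]
    snps = pd.DataFrame({
        "rs": [r[1] for r in snp_rows], "gene": "", "chrom": chrom,
        "pos": [r[2] for r in snp_rows],
        "allele_a": [a[1] for a in alleles], "allele_b": [a[0] for a in alleles],
        "func": "",
    })
    if snps["rs"].duplicated().any():
        dup = snps["rs"][snps["rs"].duplicated()].iloc[0]
        raise FormatError(f"duplicated rs ID: {dup}")
    return GenotypeMatrix(codes, snps, sample_ids)


def write_genotypes(G: GenotypeMatrix, path: str | Path,
                    annotation_path: str | Path | None = None) -> None:
    """Write the TSV dialect (and, optionally, the annotation TSV)."""
    path = Path(path)
    cells = np.where(G.codes == MISSING, "NA", G.codes.astype(str))
    df = pd.DataFrame(cells, columns=list(G.snps["rs"]))
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep="\t", index=False)
    if annotation_path is not None:
        G.snps.to_csv(annotation_path, sep="\t", index=False)


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path)
    return CovariateTable(df)


def write_covariates(C: CovariateTable, path: str | Path) -> None:
    C.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results writers

BTL_COLUMNS = ["rs", "gene", "post_prob", "direction",
               "or_mean", "or_median", "or_q025", "or_q975"]
AUCRF_PATH_COLUMNS = ["step", "size", "oob_auc"]
AUCRF_IMPORTANCE_COLUMNS = ["variable", "mdg", "relative_importance"]
LOGISTIC_COLUMNS = ["rs", "or_aa_aa", "p_trend", "p_bonferroni", "converged"]


def _fmt(df: pd.DataFrame, prob_cols: list[str], or_cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in prob_cols:
        if c in out:
            out[c] = out[c].map(lambda v: f"{v:.4f}" if pd.notna(v) else "NA")
    for c in or_cols:
        if c in out:
            out[c] = out[c].map(lambda v: f"{v:.2f}" if pd.notna(v) else "NA")
    return out


def write_results(tables: dict[str, pd.DataFrame], out_prefix: str | Path) -> list[Path]:
    """Write result tables as TSVs with fixed headers and numeric formatting.

    Recognized keys: "btl", "aucrf_path", "aucrf_importance", "logistic",
    "selection".  Probabilities are printed to 4 decimals, odds ratios to 2.
    Unknown keys are written as-is.  Returns the written paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    schema = {
        "btl": (BTL_COLUMNS, ["post_prob"], ["or_mean", "or_median", "or_q025", "or_q975"]),
        "aucrf_path": (AUCRF_PATH_COLUMNS, ["oob_auc"], []),
        "aucrf_importance": (AUCRF_IMPORTANCE_COLUMNS, ["relative_importance"], []),
        "logistic": (LOGISTIC_COLUMNS, ["p_trend", "p_bonferroni"], ["or_aa_aa"]),
    }
    for key, df in tables.items():
        path = out_prefix.parent / f"{out_prefix.name}.{key}.tsv"
        if key in schema:
            cols, probs, ors = schema[key]
            if df.empty:
                df = pd.DataFrame(columns=cols)
            else:
                df = df[cols]
            df = _fmt(df, probs, ors)
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
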