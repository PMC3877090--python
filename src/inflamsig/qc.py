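"""Genotype quality control.

The chain transforms raw genotype calls into the analysis-ready matrix in a
fixed order: sample call-rate filter -> per-SNP missingness filter -> MAF
filter with Fisher-test rescue -> kNN imputation -> X-chromosome exclusion ->
LD pruning.  Every stage returns a :class:`QCReport` entry whose removed and
retained counts reconcile exactly with its input.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import CovariateTable, GenotypeMatrix, MISSING


class QCError(RuntimeError):
    pass


@dataclasses.dataclass
class QCStage:
    name: str
    n_in: int
    n_removed: int
    axis: str  # "samples" or "snps"
    details: pd.DataFrame | None = None

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclasses.dataclass
class QCReport:
    stages: list[QCStage] = dataclasses.field(default_factory=list)

    def add(self, stage: QCStage) -> None:
        self.stages.append(stage)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"stage": s.name, "axis": s.axis, "in": s.n_in,
             "removed": s.n_removed, "out": s.n_out}
            for s in self.stages
        ])


def sample_call_rate_filter(G: GenotypeMatrix, min_rate: float = 0.95
                            ) -> tuple[GenotypeMatrix, QCStage]:
    """Drop individuals whose fraction of successfully typed SNPs is <= min_rate.

    Retention requires a call rate strictly above the threshold (an individual
    typed at exactly 95% of SNPs is removed).
    """
    call_rate = 1.0 - G.missing_mask.mean(axis=1)
    keep = call_rate > min_rate
    if not keep.any():
        raise QCError("call-rate filter removed every individual")
    details = pd.DataFrame({"sample_id": G.sample_ids, "call_rate": call_rate,
                            "kept": keep})
    return (G.subset_samples(keep),
            QCStage("sample_call_rate", G.n, int((~keep).sum()), "samples", details))


def snp_missingness_filter(G: GenotypeMatrix, max_missing: float = 0.05
                           ) -> tuple[GenotypeMatrix, QCStage]:
    """Drop SNPs with a missing fraction strictly above max_missing."""
    miss = G.missing_mask.mean(axis=0)
    keep = miss <= max_missing
    if not keep.any():
        raise QCError("missingness filter removed every SNP")
    details = pd.DataFrame({"rs": G.snps["rs"], "missing_frac": miss, "kept": keep})
    return (G.subset_snps(keep),
            QCStage("snp_missingness", G.p, int((~keep).sum()), "snps", details))


def maf_filter_with_rescue(G: GenotypeMatrix, labels: np.ndarray,
                           maf_min: float = 0.05, alpha: float = 0.05,
                           genotypic: bool = False
                           ) -> tuple[GenotypeMatrix, QCStage]:
    """Keep a SNP iff MAF >= maf_min, or it shows a case-control association.

    Rare SNPs (MAF < maf_min) are rescued when a Fisher exact test of the
    2x2 allele-count table (cases vs controls) rejects at ``alpha``; the
    genotypic 2x3 variant (Fisher-Freeman-Halton via chi-square Monte Carlo is
    avoided -- exact 2x3 through scipy's network algorithm is not available, so
    the genotypic flag uses a chi-square test) is available behind ``genotypic``.
    Monomorphic SNPs are always removed with reason "monomorphic".
    """
    labels = np.asarray(labels)
    if len(labels) != G.n:
        raise ValueError("labels not aligned to genotype rows")
    maf = G.maf()
    maf = np.minimum(maf, 1.0 - maf)
    keep = np.zeros(G.p, dtype=bool)
    reasons = []
    case = labels == 1
    for j in range(G.p):
        col = G.codes[:, j]
        obs = col != MISSING
        if maf[j] == 0 or np.isnan(maf[j]):
            reasons.append("monomorphic")
            continue
        if maf[j] >= maf_min:
            keep[j] = True
            reasons.append("common")
            continue
        p = _assoc_p(col, obs, case, genotypic)
        if p < alpha:
            keep[j] = True
            reasons.append("rescued")
        else:
            reasons.append("rare_no_assoc")
    if not keep.any():
        raise QCError("MAF filter removed every SNP")
    details = pd.DataFrame({"rs": G.snps["rs"], "maf": maf, "reason": reasons,
                            "kept": keep})
    return (G.subset_snps(keep),
            QCStage("maf_fisher_rescue", G.p, int((~keep).sum()), "snps", details))


def _assoc_p(col: np.ndarray, obs: np.ndarray, case: np.ndarray,
             genotypic: bool) -> float:
    if genotypic:
        table = np.array([[np.sum((col == c) & obs & case) for c in (0, 1, 2)],
                          [np.sum((col == c) & obs & ~case) for c in (0, 1, 2)]])
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            return 1.0
        return float(stats.chi2_contingency(table)[1])
    a = int(col[obs & case].sum())
    b = int(2 * (obs & case).sum() - a)
    c = int(col[obs & ~case].sum())
    d = int(2 * (obs & ~case).sum() - c)
    return float(stats.fisher_exact([[a, b], [c, d]])[1])


def pairwise_matching_distance(codes: np.ndarray) -> np.ndarray:
    """n x n distance = 1 - simple-matching proportion over mutually observed SNPs.

    Pairs sharing no observed SNP get distance NaN.
    """
    obs = (codes != MISSING).astype(np.float64)
    mutual = obs @ obs.T
    matches = np.zeros_like(mutual)
    for c in (0, 1, 2):
        ind = ((codes == c) & (codes != MISSING)).astype(np.float64)
        matches += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - matches / mutual
    dist[mutual == 0] = np.nan
    return dist


def knn_impute(G: GenotypeMatrix, k: int = 3) -> GenotypeMatrix:
    """Fill missing calls with the modal genotype of the k nearest individuals.

    Distance is 1 - simple-matching proportion over mutually observed SNPs
    (computed once on the original missingness pattern).  For a missing cell
    the k nearest individuals *observed at that SNP* vote; modal ties break
    toward the smaller code, distance ties break by sample order.  Fails if no
    SNP is observed for some pair needed (an individual sharing no observed
    SNP with anyone) or if a SNP is missing in everyone.
    """
    codes = G.codes.copy()
    miss_rows, miss_cols = np.nonzero(codes == MISSING)
    if len(miss_rows) == 0:
        return GenotypeMatrix(codes, G.snps, list(G.sample_ids))
    if (codes == MISSING).all(axis=0).any():
        raise QCError("a SNP is missing in every individual; cannot impute")
    dist = pairwise_matching_distance(codes)
    np.fill_diagonal(dist, np.inf)
    for i in np.unique(miss_rows):
        if np.all(np.isnan(np.delete(dist[i], i))):
            raise QCError(f"individual {G.sample_ids[i]} shares no observed SNP "
                          "with any other individual")
    out = codes.copy()
    for i, j in zip(miss_rows, miss_cols):
        candidates = np.flatnonzero(codes[:, j] != MISSING)
        d = dist[i, candidates]
        ok = ~np.isnan(d)
        candidates, d = candidates[ok], d[ok]
        if len(candidates) == 0:
            raise QCError(f"no observed donor for sample {i}, SNP {j}")
        # stable sort on distance -> distance ties resolved by sample order
        order = np.argsort(d, kind="stable")[:k]
        votes = codes[candidates[order], j]
        counts = np.bincount(votes, minlength=3)
        out[i, j] = int(np.argmax(counts))  # argmax takes the smaller code on ties
    return GenotypeMatrix(out, G.snps, list(G.sample_ids))


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of additive codes (composite LD).

    Constant columns have undefined correlation and are treated as r^2 = 0.
    """
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_prune(G: GenotypeMatrix, r2_max: float = 0.8
             ) -> tuple[GenotypeMatrix, QCStage]:
    """Greedy LD pruning in annotation order.

    Scanning SNPs left to right, a SNP is dropped when its genotype-code r^2
    with any already-kept SNP exceeds ``r2_max``; the earlier member of each
    offending pair survives.  Requires an imputed matrix.  The surviving set
    has all pairwise r^2 <= r2_max, so the operation is idempotent.
    """
    if (G.codes == MISSING).any():
        raise QCError("ld_prune requires an imputed (complete) matrix")
    X = G.codes.astype(np.float64)
    kept: list[int] = []
    dropped, partner, r2_at_drop = [], [], []
    sd = X.std(axis=0)
    for j in range(G.p):
        drop_against = -1
        r2_obs = 0.0
        if sd[j] > 0:
            for i in kept:
                if sd[i] == 0:
                    continue
                r2 = genotype_r2(X[:, i], X[:, j])
                if r2 > r2_max:
                    drop_against, r2_obs = i, r2
                    break
        if drop_against >= 0:
            dropped.append(j)
            partner.append(G.snps["rs"].iloc[drop_against])
            r2_at_drop.append(r2_obs)
        else:
            kept.append(j)
    details = pd.DataFrame({
        "rs": G.snps["rs"].iloc[dropped].to_numpy() if dropped else [],
        "partner_rs": partner, "r2": r2_at_drop,
    })
    return (G.subset_snps(np.array(kept, dtype=int)),
            QCStage("ld_prune", G.p, len(dropped), "snps", details))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditions on the allele counts and enumerates every possible heterozygote
    count with the same parity; the p-value sums the probabilities of all
    configurations no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("zero individuals")
    n_a = n_Aa + 2 * n_aa  # minor-allele count (orientation irrelevant)
    n_A = 2 * n - n_a
    rare = min(n_a, n_A)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het | allele counts) up to a constant
    from scipy.special import gammaln
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1) - gammaln(n_rare_hom + 1) - gammaln(n_common_hom + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_Aa][0]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


def hwe_control_report(G: GenotypeMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Per-SNP exact HWE p-values in the control stratum (reporting use)."""
    ctrl = np.asarray(labels) == 0
    rows = []
    for j in range(G.p):
        col = G.codes[ctrl, j]
        col = col[col != MISSING]
        counts = np.bincount(col, minlength=3)
        rows.append({"rs": G.snps["rs"].iloc[j],
                     "p_hwe": hwe_exact_test(*counts) if counts.sum() else np.nan})
    return pd.DataFrame(rows)


def pca_check(G: GenotypeMatrix, n_components: int = 2) -> np.ndarray:
    """Scores on the first components of the column-standardized genotypes.

    Emitted for visual stratification checks; no automatic exclusion is made.
    """
    if G.p < n_components:
        raise QCError(f"need at least {n_components} SNPs for PCA")
    if (G.codes == MISSING).any():
        raise QCError("pca_check requires an imputed matrix")
    from sklearn.decomposition import PCA
    X = G.codes.astype(np.float64)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    return PCA(n_components=n_components, svd_solver="full").fit_transform(X)


def exclude_x_chromosome(G: GenotypeMatrix) -> tuple[GenotypeMatrix, QCStage]:
    """Drop SNPs annotated to the X chromosome."""
    chrom = G.snps["chrom"].astype(str).str.upper()
    keep = ~chrom.isin(["X", "23", "CHRX"])
    return (G.subset_snps(keep.to_numpy()),
            QCStage("exclude_x", G.p, int((~keep).sum()), "snps", None))


def run_qc(G: GenotypeMatrix, C: CovariateTable, *, min_call_rate: float = 0.95,
           max_missing: float = 0.05, maf_min: float = 0.05, fisher_alpha: float = 0.05,
           k: int = 3, r2_max: float = 0.8,
           hwe_filter_alpha: float | None = None
           ) -> tuple[GenotypeMatrix, CovariateTable, QCReport]:
    """Full chain in the fixed order; returns filtered data plus the report.

    ``hwe_filter_alpha`` enables a replication-style HWE exclusion in controls
    (e.g. 1e-4); by default HWE is reported, not filtered on.
    """
    report = QCReport()
    call_rate = 1.0 - G.missing_mask.mean(axis=1)
    keep_samples = call_rate > min_call_rate
    G, stage = sample_call_rate_filter(G, min_call_rate)
    C = C.subset(keep_samples)
    report.add(stage)
    G, stage = snp_missingness_filter(G, max_missing)
    report.add(stage)
    G, stage = maf_filter_with_rescue(G, C.labels, maf_min, fisher_alpha)
    report.add(stage)
    G = knn_impute(G, k=k)
    if hwe_filter_alpha is not None:
        hwe = hwe_control_report(G, C.labels)
        keep = (hwe["p_hwe"] >= hwe_filter_alpha).to_numpy()
        stage = QCStage("hwe_controls", G.p, int((~keep).sum()), "snps", hwe)
        G = G.subset_snps(keep)
        report.add(stage)
    G, stage = exclude_x_chromosome(G)
    report.add(stage)
    G, stage = ld_prune(G, r2_max)
    report.add(stage)
    return G, C, report
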