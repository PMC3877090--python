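"""Synthetic case-control cohorts under the liability-threshold model.

The generator mirrors the structure the analysis assumes: a latent liability
l_i = w_i'beta + sum_j x_ij g_j + e_i with e_i ~ N(0,1) and threshold 0, sparse
SNP effects g, LD blocks induced by a Gaussian copula, categorical covariates
with liability-scale effects, and genotypes missing completely at random.
Individuals are accepted by rejection sampling until the case and control
quotas are filled, matching a case-control (not cohort) design.

Genotypes are drawn per LD block: a latent equicorrelated normal vector is
thresholded at the Hardy-Weinberg quantiles of each SNP's minor-allele
frequency, so marginal genotype frequencies are exactly HW while the
between-SNP genotype correlation is controlled only stochastically through the
latent correlation ``ld_rho``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import (REGION_LEVELS, SMOKING_LEVELS, CovariateTable, GenotypeMatrix,
                 MISSING)


class RejectionBudgetError(RuntimeError):
    """Raised when the case/control quotas cannot be filled within budget."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of the generative model.

    Defaults emulate the study scale: ~1,000 cases and ~1,000 controls typed
    at ~900 SNPs with a handful of causal variants of modest liability-scale
    effect (|g| = 0.35 per allele copy, i.e. observed-scale OR_aa/AA near the
    1.1-1.2 range the analysis reports), LD blocks of 4 with latent
    correlation 0.5, a current-smoking effect of 0.95 on the liability scale
    (probit equivalent of an odds ratio near 5), and 2% missing calls.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    p_snps: int = 900
    n_causal: int = 5
    effect_size: float | tuple[float, ...] = 0.35
    maf_range: tuple[float, float] = (0.1, 0.4)
    ld_block_size: int = 4
    ld_rho: float = 0.5
    covariate_effects: dict[str, float] = dataclasses.field(default_factory=lambda: {
        "gender_male": 0.2,
        "smoking_occasional": 0.2,
        "smoking_former": 0.5,
        "smoking_current": 0.95,
        "age": 0.1,  # per standardized unit
    })
    missing_rate: float = 0.02
    seed: int = 0
    max_batches: int = 2000

    def __post_init__(self) -> None:
        if self.n_causal > self.p_snps:
            raise ValueError("n_causal must be <= p_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")


@dataclasses.dataclass
class TrueEffects:
    """Ground truth of a simulated cohort; non-causal SNPs have g exactly 0."""

    causal_indices: np.ndarray
    g_true: np.ndarray
    beta_true: dict[str, float]

    def g_full(self, p: int) -> np.ndarray:
        g = np.zeros(p)
        g[self.causal_indices] = self.g_true
        return g


def inject_ld(block_assignments: np.ndarray, rho: float) -> np.ndarray:
    """Block-diagonal equicorrelation matrix (ones on the diagonal)."""
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    blocks = np.asarray(block_assignments)
    same = blocks[:, None] == blocks[None, :]
    R = np.where(same, rho, 0.0)
    np.fill_diagonal(R, 1.0)
    return R


def _draw_genotypes(rng: np.random.Generator, n: int, mafs: np.ndarray,
                    blocks: np.ndarray, rho: float) -> np.ndarray:
    """Copula draw: equicorrelated latent normals thresholded at HW quantiles."""
    p = len(mafs)
    z = np.empty((n, p))
    sq_rho, sq_rem = np.sqrt(rho), np.sqrt(1.0 - rho)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        shared = rng.standard_normal((n, 1))
        z[:, idx] = sq_rho * shared + sq_rem * rng.standard_normal((n, len(idx)))
    q = mafs
    # P(code 0) = (1-q)^2, P(code <= 1) = (1-q)^2 + 2q(1-q) = 1 - q^2
    t0 = stats.norm.ppf((1 - q) ** 2)
    t1 = stats.norm.ppf(1 - q ** 2)
    return ((z > t0).astype(np.int8) + (z > t1).astype(np.int8))


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "gender": rng.choice(GENDERS, size=n, p=[0.3, 0.7]),
        "smoking": rng.choice(SMOKING_LEVELS, size=n, p=[0.25, 0.06, 0.37, 0.32]),
        "region": rng.choice(REGION_LEVELS, size=n, p=[0.18, 0.16, 0.08, 0.16, 0.42]),
        "age": rng.uniform(40.0, 80.0, size=n),
    })


GENDERS = ("female", "male")


def _covariate_liability(df: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    eta = np.zeros(len(df))
    for key, coef in effects.items():
        if key == "age":
            eta += coef * (df["age"].to_numpy() - 60.0) / 11.5  # ~sd of U(40,80)
        elif key == "gender_male":
            eta += coef * (df["gender"] == "male").to_numpy(float)
        elif key.startswith("smoking_"):
            eta += coef * (df["smoking"] == key.removeprefix("smoking_")).to_numpy(float)
        elif key.startswith("region_"):
            eta += coef * (df["region"] == key.removeprefix("region_")).to_numpy(float)
        else:
            raise ValueError(f"unknown covariate effect key: {key}")
    return eta


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, CovariateTable, TrueEffects]:
    """Draw a case-control cohort under the liability-threshold model.

    Rejection-samples batches of individuals, keeping cases (liability > 0)
    and controls (liability <= 0) until both quotas are exactly filled.  Raises
    :class:`RejectionBudgetError` with the offending quota if ``max_batches``
    batches do not suffice (extreme covariate/genetic effects can make one
    class vanishingly rare).
    """
    rng = np.random.default_rng(config.seed)
    p = config.p_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    blocks = np.arange(p) // config.ld_block_size
    causal = np.sort(rng.choice(p, size=config.n_causal, replace=False))
    if np.isscalar(config.effect_size):
        signs = rng.choice([-1.0, 1.0], size=config.n_causal)
        g_true = float(config.effect_size) * signs
    else:
        g_true = np.asarray(config.effect_size, float)  # signed, graded effects
        if len(g_true) != config.n_causal:
            raise ValueError("effect_size sequence length must equal n_causal")
    truth = TrueEffects(causal, g_true, dict(config.covariate_effects))
    g_full = truth.g_full(p)

    batch = max(256, config.n_cases + config.n_controls)
    codes_parts, covar_parts = [], []
    n_case = n_ctrl = 0
    for _ in range(config.max_batches):
        X = _draw_genotypes(rng, batch, mafs, blocks, config.ld_rho)
        W = _draw_covariates(rng, batch)
        eta = _covariate_liability(W, config.covariate_effects) + X @ g_full
        liab = eta + rng.standard_normal(batch)
        is_case = liab > 0.0
        take = np.zeros(batch, dtype=bool)
        need_case = config.n_cases - n_case
        need_ctrl = config.n_controls - n_ctrl
        case_idx = np.flatnonzero(is_case)[:need_case]
        ctrl_idx = np.flatnonzero(~is_case)[:need_ctrl]
        take[case_idx] = True
        take[ctrl_idx] = True
        n_case += len(case_idx)
        n_ctrl += len(ctrl_idx)
        W = W.iloc[np.flatnonzero(take)].copy()
        W["label"] = is_case[take].astype(int)
        codes_parts.append(X[take])
        covar_parts.append(W)
        if n_case >= config.n_cases and n_ctrl >= config.n_controls:
            break
    else:
        short = "cases" if n_case < config.n_cases else "controls"
        raise RejectionBudgetError(
            f"rejection budget exhausted after {config.max_batches} batches: "
            f"only {n_case}/{config.n_cases} cases and {n_ctrl}/{config.n_controls} "
            f"controls drawn ({short} quota unmet)")

    codes = np.concatenate(codes_parts)
    covar = pd.concat(covar_parts, ignore_index=True)
    # deterministic ordering: cases first, preserving draw order
    order = np.argsort(-covar["label"].to_numpy(), kind="stable")
    codes = codes[order]
    covar = covar.iloc[order].reset_index(drop=True)

    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes = np.where(mask, MISSING, codes).astype(np.int8)

    snps = pd.DataFrame({
        "rs": [f"rs{900000 + j}" for j in range(p)],
        "gene": [f"GENE{b}" for b in blocks],
        "chrom": [str(1 + b % 22) for b in blocks],
        "pos": 1000 * (np.arange(p) + 1),
        "allele_a": "A", "allele_b": "B",
        "func": "simulated",
    })
    sample_ids = [f"ind{i:05d}" for i in range(len(covar))]
    G = GenotypeMatrix(codes, snps, sample_ids)
    C = CovariateTable(covar[["label", "gender", "smoking", "region", "age"]])
    return G, C, truth


# ---------------------------------------------------------------------------
# fixed reference population

_PROFILE = {
    # stratum -> (total, male, never/occ/former/current smoking, region counts,
    #             never-smoker male, never-smoker region counts)
    "case": (1047, 915, (147, 44, 400, 450), (182, 171, 77, 180, 437),
             52, (22, 21, 15, 26, 63)),
    "control": (988, 873, (277, 79, 361, 267), (196, 157, 79, 146, 410),
                180, (45, 38, 27, 35, 132)),
}


def reference_cohort_covariates() -> CovariateTable:
    """Covariate table reproducing the characteristic profile of the Spanish
    bladder-cancer case-control study population (1,047 cases / 988 controls).

    All printed margins are exact: gender, four-level smoking status and
    five-level region per stratum, plus the gender and region breakdowns of
    the never-smoker subset (147 cases / 277 controls).  Smoking categories do
    not sum to the stratum totals in the source profile; the remainder (6
    cases, 4 controls) carries missing smoking status.  The joint structure
    beyond these margins is arbitrary but deterministic.  Ages are a
    deterministic spread over 40-80 years.
    """
    frames = []
    for stratum, (total, male, smoking, region, ns_male, ns_region) in _PROFILE.items():
        n_never = smoking[0]
        smoking_col = (["never"] * n_never + ["occasional"] * smoking[1]
                       + ["former"] * smoking[2] + ["current"] * smoking[3])
        smoking_col += [None] * (total - len(smoking_col))
        # gender: honor the never-smoker male count, fill the rest to the margin
        gender_col = (["male"] * ns_male + ["female"] * (n_never - ns_male)
                      + ["male"] * (male - ns_male)
                      + ["female"] * (total - male - (n_never - ns_male)))
        # region: never-smoker panel first, remainder fills the overall margin
        region_col: list[str] = []
        for lev, cnt in zip(REGION_LEVELS, ns_region):
            region_col += [lev] * cnt
        for lev, cnt, ns_cnt in zip(REGION_LEVELS, region, ns_region):
            region_col += [lev] * (cnt - ns_cnt)
        age_col = np.linspace(40.0, 80.0, total)
        frames.append(pd.DataFrame({
            "label": 1 if stratum == "case" else 0,
            "gender": gender_col,
            "smoking": pd.array(smoking_col, dtype="object"),
            "region": region_col,
            "age": age_col,
        }))
    return CovariateTable(pd.concat(frames, ignore_index=True))
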