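"""AUC-optimized random-forest backward elimination (AUC-RF).

A forest of classification trees (bootstrap samples, Gini splits, mtry
candidate variables per split) ranks variables once by mean decrease Gini
(MDG); backward elimination then repeatedly drops the bottom fraction of the
*initial* ranking, refitting a forest at each step and scoring it by the
out-of-bag AUC.  The optimal subset is the step with maximal OOB AUC (ties go
to the smaller subset).  Relative importance is MDG divided by the largest
MDG.  Environmental covariates (gender, smoking, region, age categorized in
three groups) enter as ordinal-coded features alongside the SNPs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .io import CovariateTable, GenotypeMatrix, MISSING, SMOKING_LEVELS

AGE_LEVELS = ("<60", "60-70", ">=70")


@dataclasses.dataclass
class AUCRFConfig:
    """Forest and elimination settings (500 trees, drop 20%, stop at 10)."""

    ntree: int = 500
    drop_fraction: float = 0.2
    k_min: int = 10
    mtry: int | None = None  # default floor(sqrt(m)) per forest
    seed: int = 0
    rerank: bool = False  # re-rank at each step instead of the fixed initial ranking

    def __post_init__(self) -> None:
        if not (0.0 < self.drop_fraction < 1.0):
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")


@dataclasses.dataclass
class AUCRFResult:
    initial_ranking: list[str]        # variables ordered by full-model MDG, best first
    path: pd.DataFrame                # step, size, oob_auc, variables
    optimal_subset: list[str]
    importances: pd.DataFrame         # variable, mdg, relative_importance

    @property
    def optimal_auc(self) -> float:
        sizes = self.path["size"].to_numpy()
        mask = sizes == len(self.optimal_subset)
        return float(self.path.loc[mask, "oob_auc"].iloc[0])


def categorize_age(age: np.ndarray | float) -> np.ndarray:
    """Three age groups: <60, 60-70, >=70 (boundaries 60 and 70 go upward)."""
    age = np.asarray(age, float)
    out = np.where(age < 60.0, AGE_LEVELS[0],
                   np.where(age < 70.0, AGE_LEVELS[1], AGE_LEVELS[2]))
    return out if out.ndim else out[()]


def feature_table(G: GenotypeMatrix, C: CovariateTable) -> pd.DataFrame:
    """SNP codes plus ordinal-coded covariates (age in 3 categories)."""
    if (G.codes == MISSING).any():
        raise ValueError("feature table requires an imputed genotype matrix")
    df = pd.DataFrame(G.codes, columns=list(G.snps["rs"]))
    cv = C.data
    df["gender"] = (cv["gender"] == "male").astype(int).to_numpy()
    smoking = cv["smoking"].map({s: i for i, s in enumerate(SMOKING_LEVELS)})
    df["smoking"] = smoking.fillna(0).astype(int).to_numpy()
    regions = {r: i for i, r in enumerate(pd.unique(cv["region"]))}
    df["region"] = cv["region"].map(regions).to_numpy()
    age_cat = categorize_age(cv["age"].to_numpy())
    df["age_group"] = pd.Categorical(age_cat, categories=AGE_LEVELS).codes
    return df


def fit_forest(X: pd.DataFrame | np.ndarray, y: np.ndarray, config: AUCRFConfig,
               seed: int | None = None) -> tuple[pd.Series, np.ndarray]:
    """Fit one forest; return per-variable MDG and per-individual OOB case score.

    MDG is the (impurity-decrease) Gini importance; the OOB score of
    individual i aggregates the votes of the trees whose bootstrap sample
    excluded i.  Individuals never out of bag (vanishingly rare at 500 trees)
    score NaN and are dropped from AUC computation downstream.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    m = X.shape[1]
    mtry = config.mtry if config.mtry is not None else max(1, int(math.isqrt(m)))
    rf = RandomForestClassifier(
        n_estimators=config.ntree, criterion="gini",
        max_features=min(mtry, m), bootstrap=True, oob_score=True,
        random_state=(config.seed if seed is None else seed) % (2**31 - 1),
        n_jobs=1,
    )
    rf.fit(X.to_numpy(), y)
    mdg = pd.Series(rf.feature_importances_, index=X.columns, name="mdg")
    scores = rf.oob_decision_function_[:, list(rf.classes_).index(1)]
    return mdg, scores


def oob_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC (ties counted 1/2) of OOB scores against labels."""
    scores = np.asarray(scores, float)
    y = np.asarray(y)
    ok = np.isfinite(scores)
    scores, y = scores[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined with one class absent")
    return float(roc_auc_score(y, scores))


def backward_eliminate(X: pd.DataFrame, y: np.ndarray,
                       config: AUCRFConfig) -> AUCRFResult:
    """Backward elimination over forests scored by OOB AUC.

    The full-model forest fixes the variable ranking (and the reported
    importances); each step records (subset, OOB AUC) and removes the
    worst-ranked floor(drop_fraction * size) variables (at least one), until
    the subset size is <= k_min -- the final subset is recorded too.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    m = X.shape[1]
    if m < config.k_min:
        raise ValueError(f"need at least k_min={config.k_min} variables, got {m}")
    rng = np.random.default_rng(config.seed)
    mdg_full, scores = fit_forest(X, y, config, seed=int(rng.integers(2**31 - 1)))
    order = mdg_full.sort_values(ascending=False, kind="stable")
    ranking = list(order.index)
    current = list(ranking)
    steps = []
    auc0 = oob_auc(scores, y)
    step = 0
    while True:
        if step == 0:
            auc = auc0
        else:
            if config.rerank:
                mdg_cur, sc = fit_forest(X[current], y, config,
                                         seed=int(rng.integers(2**31 - 1)))
                current = list(mdg_cur.sort_values(ascending=False, kind="stable").index)
            else:
                _, sc = fit_forest(X[current], y, config,
                                   seed=int(rng.integers(2**31 - 1)))
            auc = oob_auc(sc, y)
        steps.append({"step": step, "size": len(current), "oob_auc": auc,
                      "variables": tuple(current)})
        if len(current) <= config.k_min:
            break
        n_drop = max(1, int(config.drop_fraction * len(current)))
        current = current[: len(current) - n_drop]
        step += 1
    path = pd.DataFrame(steps)
    # optimal: max AUC, ties -> smaller subset
    best = path.sort_values(["oob_auc", "size"], ascending=[False, True],
                            kind="stable").iloc[0]
    importances = pd.DataFrame({
        "variable": ranking,
        "mdg": order.to_numpy(),
        "relative_importance": order.to_numpy() / order.iloc[0],
    })
    return AUCRFResult(
        initial_ranking=ranking,
        path=path,
        optimal_subset=list(best["variables"]),
        importances=importances,
    )


def elimination_path_sizes(m: int, drop_fraction: float = 0.2, k_min: int = 10) -> list[int]:
    """Subset sizes the elimination will visit (arithmetic only, no fitting)."""
    sizes = [m]
    while sizes[-1] > k_min:
        sizes.append(sizes[-1] - max(1, int(drop_fraction * sizes[-1])))
    return sizes
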