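"""Cross-method synthesis: descriptive tables, selection overlaps, OR ranges,
rank correlations, and total vs non-smoker comparisons.

This module consumes the outputs of the other modules and recomputes nothing
statistical beyond ranks and set intersections.  Published per-SNP summaries
from the Spanish bladder-cancer inflammatory-gene study (total population, 37
SNPs selected at the 0.8 posterior-probability cutoff; non-smoker subset, 9
SNPs at 0.75) ship as package data for worked examples.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io import REGION_LEVELS, SMOKING_LEVELS, CovariateTable


def published_snp_summary(population: str = "total") -> pd.DataFrame:
    """Published per-SNP results table ("total" or "nonsmoker").

    Columns: rs, gene, func, position, alleles, or_btl (posterior-mean
    OR_aa/AA from the threshold-LASSO fit), post_prob (posterior probability
    of association, in percent), or_logistic, p_trend, aucrf_selected (1 if
    the SNP was also in the AUC-RF optimal subset).
    """
    names = {"total": "total_population_snp_summary.tsv",
             "nonsmoker": "nonsmoker_snp_summary.tsv"}
    if population not in names:
        raise ValueError(f"population must be one of {sorted(names)}")
    with resources.files("inflamsig.data").joinpath(names[population]).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def descriptive_table(C: CovariateTable) -> pd.DataFrame:
    """Counts and integer percentages per case/control stratum.

    Rows cover gender, the four smoking-status levels, and region; percentages
    are computed within the stratum column (half-up rounding).  Empty strata
    yield zero counts with blank percentages.
    """
    rows = []
    df = C.data
    strata = {"case": df[df["label"] == 1], "control": df[df["label"] == 0]}
    variables = [("gender", ["male", "female"], "gender"),
                 ("smoking", list(SMOKING_LEVELS), "smoking"),
                 ("region", [r for r in REGION_LEVELS if r in set(df["region"])]
                  or sorted(set(df["region"])), "region")]
    for var, levels, colname in variables:
        for lev in levels:
            row = {"variable": var, "level": lev}
            for name, sub in strata.items():
                cnt = int((sub[colname] == lev).sum())
                row[f"{name}_n"] = cnt
                row[f"{name}_pct"] = (_round_half_up(100.0 * cnt / len(sub))
                                      if len(sub) else "")
            rows.append(row)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SelectionReport:
    """Per-method selected SNP sets with intersections and comparisons."""

    btl_set: set[str]
    aucrf_set: set[str]
    logistic_set: set[str]
    btl_cutoff: float
    venn: dict[str, int]
    spearman_rho: float | None = None
    or_range_protective: tuple[float, float] | None = None
    or_range_risk: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "btl_cutoff": self.btl_cutoff,
            "n_btl": len(self.btl_set),
            "n_aucrf": len(self.aucrf_set),
            "n_logistic": len(self.logistic_set),
            "venn": self.venn,
            "spearman_rho": self.spearman_rho,
            "or_range_protective": self.or_range_protective,
            "or_range_risk": self.or_range_risk,
        }


def intersect_selections(sets: dict[str, set[str]]) -> dict[str, int]:
    """Exact Venn region counts for two or three named sets.

    Keys are '&'-joined sorted name combinations for the exclusive regions
    plus pairwise 'name1&name2_total' intersection counts.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("need 2 or 3 sets")
    universe = set().union(*sets.values())
    out: dict[str, int] = {}
    # exclusive regions
    import itertools
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            out["&".join(combo) + "_only"] = len(inside - outside)
    for a, b in itertools.combinations(names, 2):
        out[f"{a}&{b}"] = len(sets[a] & sets[b])
    if len(names) == 3:
        out["&".join(names)] = len(set.intersection(*sets.values()))
    out["union"] = len(universe)
    return out


def or_range(or_values: pd.Series | np.ndarray, direction: str) -> tuple[float, float]:
    """(min, max) of posterior-mean ORs restricted to one direction.

    direction="protective" keeps OR < 1, "risk" keeps OR > 1; both rounded to
    two decimals.  Fails if no OR lies in the requested direction.
    """
    vals = np.asarray(or_values, float)
    if direction == "protective":
        vals = vals[vals < 1.0]
    elif direction == "risk":
        vals = vals[vals > 1.0]
    else:
        raise ValueError("direction must be 'protective' or 'risk'")
    if len(vals) == 0:
        raise ValueError(f"no ORs in direction {direction!r}")
    return (round(float(vals.min()), 2), round(float(vals.max()), 2))


def rank_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties.

    Used to compare the threshold-LASSO posterior probabilities with the
    logistic-regression evidence (pass -log10 p as the second vector so both
    order from weak to strong).  A constant vector makes rho undefined (NaN).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def stratified_rerun_report(total_sets: dict[float, set[str]],
                            nonsmoker_sets: dict[float, set[str]]) -> pd.DataFrame:
    """Overlap between total-population and non-smoker selections per cutoff.

    Both arguments map a posterior-probability cutoff (e.g. 0.8, 0.75) -- or
    any method label -- to the selected rs-ID set at that cutoff.
    """
    rows = []
    for cutoff in sorted(set(total_sets) & set(nonsmoker_sets), reverse=True):
        a, b = total_sets[cutoff], nonsmoker_sets[cutoff]
        rows.append({"cutoff": cutoff, "n_total": len(a), "n_nonsmoker": len(b),
                     "n_overlap": len(a & b),
                     "overlap": tuple(sorted(a & b))})
    return pd.DataFrame(rows)


def build_selection_report(btl_table: pd.DataFrame, aucrf_selected: set[str],
                           logistic_table: pd.DataFrame,
                           btl_cutoff: float = 0.8,
                           alpha: float = 0.05) -> SelectionReport:
    """Assemble the cross-method report from the per-method output tables.

    ``btl_table`` needs columns rs, post_prob, or_mean (per-SNP summaries over
    all SNPs); ``logistic_table`` needs rs, p_trend, p_bonferroni.
    """
    sel = btl_table[btl_table["post_prob"] > btl_cutoff]
    btl_set = set(sel["rs"])
    logi_sig = set(logistic_table.loc[logistic_table["p_bonferroni"] < alpha, "rs"])
    venn = intersect_selections({"btl": btl_set, "aucrf": set(aucrf_selected),
                                 "logistic": logi_sig})
    merged = btl_table.merge(logistic_table, on="rs")
    ok = merged["p_trend"].notna()
    rho = rank_correlation(merged.loc[ok, "post_prob"].to_numpy(),
                           -np.log10(np.maximum(merged.loc[ok, "p_trend"].to_numpy(),
                                                1e-300))) if ok.sum() >= 3 else None
    ors = sel["or_mean"].to_numpy()
    return SelectionReport(
        btl_set=btl_set, aucrf_set=set(aucrf_selected), logistic_set=logi_sig,
        btl_cutoff=btl_cutoff, venn=venn, spearman_rho=rho,
        or_range_protective=or_range(ors, "protective") if (ors < 1).any() else None,
        or_range_risk=or_range(ors, "risk") if (ors > 1).any() else None,
    )
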