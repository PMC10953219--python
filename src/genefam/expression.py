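"""qPCR relative expression (comparative Ct) and physiology indices.

Relative expression uses the Livak 2^-ddCt method with an assumed
amplification efficiency of 2: Ct values are replicate-averaged, dCt
normalises the target to the reference gene, ddCt compares each
treatment level to the flagged control level, and the fold change is
2^-ddCt. Significance marks come from Welch's two-sample t-test on the
per-replicate dCt values (the standard qPCR practice when the original
analysis names only "a 5% level"); a Benjamini-Hochberg column is
emitted alongside but the marks deliberately stay per-cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

CT_COLUMNS = ("gene", "cultivar", "tissue", "stress", "level",
              "is_control", "replicate", "ct")


def read_ct_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"level": str})  # levels are labels, not numbers
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def _group_key(df: pd.DataFrame) -> list[str]:
    return ["cultivar", "tissue", "stress"]


def delta_delta_ct(ct_table: pd.DataFrame, ref_gene: str) -> pd.DataFrame:
    """Fold changes per gene x condition by the comparative Ct method.

    Within each (cultivar, tissue, stress) group the level flagged
    ``is_control`` anchors ddCt. Returns one row per (gene, cultivar,
    tissue, stress, level) with delta_ct, delta_delta_ct, fold_change,
    direction, p_value, significance mark and a BH-adjusted column.
    """
    df = ct_table.copy()
    results = []
    for (cultivar, tissue, stress), grp in df.groupby(_group_key(df), sort=False):
        controls = grp.loc[grp["is_control"].astype(bool), "level"].unique()
        if len(controls) != 1:
            raise ValueError(
                f"({cultivar}, {tissue}, {stress}): need exactly one control "
                f"level, found {list(controls)}")
        control_level = controls[0]
        ref = grp[grp["gene"] == ref_gene]
        if ref.empty:
            raise ValueError(
                f"reference gene {ref_gene} missing for ({cultivar}, {tissue}, {stress})")
        ref_mean = ref.groupby("level")["ct"].mean()
        for gene, gene_grp in grp[grp["gene"] != ref_gene].groupby("gene", sort=False):
            target_mean = gene_grp.groupby("level")["ct"].mean()
            missing_ref = set(target_mean.index) - set(ref_mean.index)
            if missing_ref:
                raise ValueError(
                    f"reference gene {ref_gene} missing for conditions "
                    f"{sorted(missing_ref)}")
            if control_level not in target_mean.index:
                raise ValueError(f"{gene}: no control-level measurement")
            dct = target_mean - ref_mean.loc[target_mean.index]
            dct_control = dct.loc[control_level]
            for level in target_mean.index:
                ddct = dct.loc[level] - dct_control
                fc = 2.0 ** (-ddct)
                direction = "up" if fc > 1 else ("down" if fc < 1 else "unchanged")
                p = ddct_significance(grp, gene, level, control_level, ref_gene)
                results.append({
                    "gene": gene, "cultivar": cultivar, "tissue": tissue,
                    "stress": stress, "level": level,
                    "is_control": level == control_level,
                    "delta_ct": dct.loc[level], "delta_delta_ct": ddct,
                    "fold_change": fc, "direction": direction, "p_value": p,
                })
    out = pd.DataFrame(results)
    out["mark"] = out["p_value"].map(significance_mark)
    out["p_bh"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _replicate_dct(grp: pd.DataFrame, gene: str, level: str, ref_gene: str) -> np.ndarray:
    tgt = grp[(grp["gene"] == gene) & (grp["level"] == level)]
    ref = grp[(grp["gene"] == ref_gene) & (grp["level"] == level)]
    merged = tgt.merge(ref, on="replicate", suffixes=("_t", "_r"))
    return (merged["ct_t"] - merged["ct_r"]).to_numpy()


def ddct_significance(ct_group: pd.DataFrame, gene: str, level: str,
                      control_level: str, ref_gene: str) -> float:
    """Welch two-sided t-test on per-replicate dCt, treatment vs control.

    Returns NaN (not assessable) with fewer than 2 replicates per group;
    identical groups give p = 1.
    """
    treat = _replicate_dct(ct_group, gene, level, ref_gene)
    control = _replicate_dct(ct_group, gene, control_level, ref_gene)
    if len(treat) < 2 or len(control) < 2:
        return float("nan")
    if np.var(treat) == 0 and np.var(control) == 0:
        # degenerate (noise-free) groups: identical means are certainly
        # null, distinct means certainly not
        return 1.0 if treat.mean() == control.mean() else 0.0
    res = stats.ttest_ind(treat, control, equal_var=False)
    return float(res.pvalue) if np.isfinite(res.pvalue) else 1.0


def significance_mark(p: float) -> str:
    if not np.isfinite(p):
        return "na"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH adjusted p-values; NaNs pass through."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    pm = p[mask]
    m = pm.size
    if m:
        order = np.argsort(pm)
        ranked = pm[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[mask] = res
    return out


@dataclass
class RwcSample:
    WF: float  # fresh weight
    WD: float  # dry weight
    WS: float  # turgid (saturated) weight

    def __post_init__(self) -> None:
        if not (self.WS >= self.WF >= self.WD > 0):
            raise ValueError("require WS >= WF >= WD > 0")


def rwc(WF: float, WD: float, WS: float) -> float:
    """Relative water content, %: 100 * (WF - WD) / (WS - WD)."""
    sample = RwcSample(WF=WF, WD=WD, WS=WS)
    if sample.WS == sample.WD:
        raise ValueError("WS == WD: relative water content undefined")
    return 100.0 * (sample.WF - sample.WD) / (sample.WS - sample.WD)


def na_k_ratio(na_conc: float, k_conc: float) -> float:
    """Sodium-to-potassium concentration ratio, a salinity-stress index."""
    if na_conc <= 0 or k_conc <= 0:
        raise ValueError("concentrations must be positive")
    return na_conc / k_conc


def heat_matrix(expression_results: pd.DataFrame,
                k_groups: int = 4) -> tuple[pd.DataFrame, pd.Series]:
    """log2 fold-change matrix (genes x conditions) with hierarchical
    gene grouping (Euclidean distance, average linkage, tree cut at
    ``k_groups``)."""
    if k_groups < 1:
        raise ValueError("k_groups must be >= 1")
    df = expression_results.copy()
    if (df["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive")
    df["condition"] = (df["cultivar"].astype(str) + "/" + df["tissue"].astype(str)
                       + "/" + df["stress"].astype(str) + "/" + df["level"].astype(str))
    mat = df.pivot_table(index="gene", columns="condition", values="fold_change",
                         sort=False)
    if mat.isna().any().any():
        raise ValueError("incomplete gene x condition table")
    logmat = np.log2(mat)
    if len(logmat) == 1:
        groups = pd.Series([1], index=logmat.index, name="group")
        return logmat, groups
    Z = linkage(logmat.to_numpy(), method="average", metric="euclidean")
    labels = fcluster(Z, t=min(k_groups, len(logmat)), criterion="maxclust")
    groups = pd.Series(labels, index=logmat.index, name="group")
    return logmat, groups
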