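"""Voxel-wise and VOI-level group/outcome statistics.

Voxel-wise: two-sample pooled-variance t maps, Benjamini-Hochberg FDR over
in-mask voxels, signed z maps thresholded at corrected P = 0.05, Cohen's d
effect-size maps with the moderate / large / very large partition at 0.80
and 1.20. VOI-level: per-subject regional mean BP tables, two-way ANOVA
(group x VOI, genotype as additive covariate, type-II sums of squares),
Tukey-HSD post hocs on the studentized range, Spearman outcome correlations
(exact permutation p at small n), and the descriptive Shapiro-Wilk /
chi-square / Kruskal-Wallis battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

D_CLASS_CODES = {"none": 0, "moderate": 1, "large": 2, "very_large": 3}


@dataclass(frozen=True)
class VoxelStatMaps:
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    z: np.ndarray
    d: np.ndarray
    d_class: np.ndarray  # integer-coded per D_CLASS_CODES
    brain_mask: np.ndarray


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    _, q, _, _ = multipletests(flat, method="fdr_bh")
    return q.reshape(p.shape)


def classify_d(d: np.ndarray) -> np.ndarray:
    """Effect-size classes: |d| < 0.80 moderate, 0.80 <= |d| <= 1.20 large,
    |d| > 1.20 very large."""
    a = np.abs(np.asarray(d, dtype=float))
    out = np.full(a.shape, D_CLASS_CODES["moderate"], dtype=np.int8)
    out[(a >= 0.80) & (a <= 1.20)] = D_CLASS_CODES["large"]
    out[a > 1.20] = D_CLASS_CODES["very_large"]
    return out


def voxelwise_ttest(
    bp_maps_a: list[np.ndarray],
    bp_maps_b: list[np.ndarray],
    brain_mask: np.ndarray,
    alpha: float = 0.05,
    welch: bool = False,
) -> VoxelStatMaps:
    """Per-voxel two-sample two-tailed t-test (pooled variance by default,
    Welch behind a flag), BH-FDR across in-mask voxels, signed z and Cohen's
    d maps. Positive t/z/d means group A > group B."""
    if len(bp_maps_a) < 2 or len(bp_maps_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    A = np.stack([np.asarray(m)[brain_mask] for m in bp_maps_a])
    B = np.stack([np.asarray(m)[brain_mask] for m in bp_maps_b])
    na, nb = len(A), len(B)
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if welch:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = float(na + nb - 2)
    zero_var = se2 == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} voxels have zero pooled variance; p set to 1"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        d = (ma - mb) / np.sqrt(sp2)
    t = np.where(zero_var, 0.0, t)
    d = np.where(sp2 == 0, 0.0, d)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(zero_var, 1.0, p)
    q = bh_fdr(p)
    z = sps.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0) * np.sign(t)
    z = np.where(q <= alpha, z, 0.0)

    def to_map(v, fill=np.nan, dtype=float):
        m = np.full(brain_mask.shape, fill, dtype=dtype)
        m[brain_mask] = v
        return m

    return VoxelStatMaps(
        t=to_map(t), p=to_map(p, fill=1.0), q=to_map(q, fill=1.0),
        z=to_map(z, fill=0.0), d=to_map(d),
        d_class=to_map(classify_d(d), fill=D_CLASS_CODES["none"], dtype=np.int8),
        brain_mask=brain_mask,
    )


# ---------------------------------------------------------------------------
# VOI tables
# ---------------------------------------------------------------------------

def voi_table(
    bp_maps: dict[str, np.ndarray],
    label_map,
    voi_list: list[str],
    subjects: pd.DataFrame,
    lesion_masks: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """One row per subject x VOI with the regional mean BP and subject
    metadata. Rows whose VOI intersects that subject's lesion mask are
    flagged (``lesioned``), not dropped, so exclusions stay auditable."""
    lesion_masks = lesion_masks or {}
    subjects = subjects.set_index("id", drop=False)
    voi_masks = {v: label_map.mask(v) for v in voi_list}  # raises on missing VOI
    rows = []
    for sid, bp in bp_maps.items():
        meta = subjects.loc[sid]
        lesion = lesion_masks.get(sid)
        for voi, mask in voi_masks.items():
            vals = np.asarray(bp)[mask]
            rows.append(
                {
                    "id": sid,
                    "voi": voi,
                    "bp": float(np.nanmean(vals)),
                    "group": meta["group"],
                    "genotype": meta["genotype"],
                    "outcome": meta.get("outcome", ""),
                    "crs_r": meta.get("crs_r", np.nan),
                    "lesioned": bool((mask & lesion).any()) if lesion is not None else False,
                }
            )
    return pd.DataFrame(rows)


def two_way_anova(
    table: pd.DataFrame,
    response: str = "bp",
    factors: tuple[str, str] = ("group", "voi"),
    covariate: str | None = "genotype",
    interaction: bool = True,
) -> pd.DataFrame:
    """Two-way ANOVA with type-II sums of squares and an additive categorical
    covariate. Returns a table with (factor, F, df, p)."""
    fa, fb = factors
    for f in (fa, fb):
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    y = table[response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        terms = [f"C({fa})", f"C({fb})"]
        if interaction:
            terms.append(f"C({fa}):C({fb})")
        if covariate is not None and table[covariate].nunique() > 1:
            terms.append(f"C({covariate})")
        return pd.DataFrame(
            {"factor": terms, "F": 0.0, "df": np.nan, "p": 1.0}
        )
    formula = f"{response} ~ C({fa}) + C({fb})"
    if interaction:
        formula += f" + C({fa}):C({fb})"
    if covariate is not None and table[covariate].nunique() > 1:
        formula += f" + C({covariate})"
    model = smf.ols(formula, data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.drop(index="Residual", errors="ignore")
    return pd.DataFrame(
        {
            "factor": aov.index,
            "F": aov["F"].to_numpy(),
            "df": aov["df"].to_numpy(),
            "p": aov["PR(>F)"].to_numpy(),
        }
    ).reset_index(drop=True)


def tukey_hsd(
    table: pd.DataFrame, factor: str, response: str = "bp"
) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise comparisons using the
    studentized range distribution (one-way layout over ``factor``)."""
    levels = list(pd.unique(table[factor]))
    if len(levels) < 2:
        raise ValueError("Tukey HSD needs at least 2 levels")
    groups = {g: table.loc[table[factor] == g, response].to_numpy(float) for g in levels}
    ns = {g: len(v) for g, v in groups.items()}
    k = len(levels)
    df_err = sum(ns.values()) - k
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_err
    rows = []
    for g1, g2 in combinations(levels, 2):
        diff = groups[g1].mean() - groups[g2].mean()
        if mse == 0:
            q_stat, p = 0.0, 1.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
            q_stat = abs(diff) / se
            p = float(sps.studentized_range.sf(q_stat, k, df_err))
        rows.append(
            {"level_1": g1, "level_2": g2, "mean_diff": diff,
             "q": q_stat, "p_adj": min(p, 1.0)}
        )
    return pd.DataFrame(rows)


def groupwise_tukey_by_voi(
    table: pd.DataFrame,
    factor: str = "group",
    voi_col: str = "voi",
    response: str = "bp",
) -> pd.DataFrame:
    """Per-VOI pairwise group comparisons drawn from one Tukey family over
    all group-by-VOI cells (the post hoc of the two-way ANOVA): the
    studentized-range critical level accounts for every cell pair, and only
    the within-VOI group pairs are reported."""
    y = table[response].to_numpy(float)
    cells = list(zip(table[factor].astype(str), table[voi_col].astype(str)))
    uniq = list(dict.fromkeys(cells))
    if len(uniq) < 2:
        raise ValueError("need at least 2 group-by-VOI cells")
    stats = {}
    ss_err = 0.0
    for cell in uniq:
        v = y[[c == cell for c in cells]]
        stats[cell] = (v.mean(), len(v))
        ss_err += ((v - v.mean()) ** 2).sum()
    k = len(uniq)
    df_err = len(y) - k
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = ss_err / df_err
    levels = list(dict.fromkeys(g for g, _ in uniq))
    vois = list(dict.fromkeys(v for _, v in uniq))
    rows, qs = [], []
    for voi in vois:
        for g1, g2 in combinations(levels, 2):
            if (g1, voi) not in stats or (g2, voi) not in stats:
                continue
            m1, n1 = stats[(g1, voi)]
            m2, n2 = stats[(g2, voi)]
            if mse == 0:
                q_stat = 0.0
            else:
                q_stat = abs(m1 - m2) / np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
            rows.append(
                {"voi": voi, "level_1": g1, "level_2": g2,
                 "mean_diff": m1 - m2, "q": q_stat}
            )
            qs.append(q_stat)
    p = (
        np.minimum(sps.studentized_range.sf(np.array(qs), k, df_err), 1.0)
        if mse > 0
        else np.ones(len(qs))
    )
    out = pd.DataFrame(rows)
    out["p_adj"] = p
    return out


# ---------------------------------------------------------------------------
# Rank correlation and descriptive battery
# ---------------------------------------------------------------------------

def spearman(x, y, exact_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; two-sided p by full
    permutation enumeration for n <= ``exact_n``, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation is undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def _rho(rm):
        rxc = rx - rx.mean()
        rmc = rm - rm.mean(axis=-1, keepdims=True)
        num = (rxc * rmc).sum(axis=-1)
        den = np.sqrt((rxc**2).sum() * (rmc**2).sum(axis=-1))
        return num / den

    rho = float(_rho(ry))
    if n <= exact_n:
        perms = np.array(list(permutations(ry)))
        null = _rho(perms)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        tstat = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2.0 * sps.t.sf(abs(tstat), n - 2))
    return rho, min(p, 1.0)


def descriptive_tests(
    cohort: pd.DataFrame,
    group_col: str = "group",
    numeric_cols: list[str] | None = None,
    categorical_cols: list[str] | None = None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Between-group descriptive battery: Shapiro-Wilk normality per group for
    numeric columns, then Kruskal-Wallis (the non-normal route) across
    groups; chi-square (no continuity correction) for categorical columns.
    The routing decision is recorded per variable."""
    numeric_cols = numeric_cols or []
    categorical_cols = categorical_cols or []
    col = cohort[group_col]
    declared = (
        list(col.cat.categories) if isinstance(col.dtype, pd.CategoricalDtype)
        else list(pd.unique(col))
    )
    for g in declared:
        if (col == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")
    groups = declared
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for col in numeric_cols:
        samples = [cohort.loc[cohort[group_col] == g, col].dropna().to_numpy(float) for g in groups]
        sw_ps = []
        for s in samples:
            if len(s) >= 3 and np.ptp(s) > 0:
                sw_ps.append(float(sps.shapiro(s).pvalue))
            else:
                sw_ps.append(np.nan)
        normal = all(p > normality_alpha for p in sw_ps if np.isfinite(p))
        if normal:
            stat, p = sps.f_oneway(*samples)
            test = "anova"
        else:
            stat, p = sps.kruskal(*samples)
            test = "kruskal"
        rows.append(
            {"variable": col, "test": test, "statistic": float(stat),
             "p": float(p), "shapiro_min_p": float(np.nanmin(sw_ps))}
        )
    for col in categorical_cols:
        ct = pd.crosstab(cohort[group_col], cohort[col])
        chi2, p, dof, _ = sps.chi2_contingency(ct.to_numpy(), correction=False)
        rows.append(
            {"variable": col, "test": "chi2", "statistic": float(chi2),
             "p": float(p), "shapiro_min_p": np.nan}
        )
    return pd.DataFrame(rows)
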