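"""Per-ecotype differential abundance and cross-ecotype core-responsive calls.

The rank-sum test is exact (full enumeration, tie-aware) whenever the pooled
sample is small enough, which covers the 4-vs-4 replicate design; larger
samples fall back to the tie-corrected normal approximation with continuity
correction. Core calling requires both significance and the fold threshold
in the same ecotype.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust
from .io_model import CountTable, RelativeAbundanceTable, StudyDesign, to_relative_abundance

EXACT_LIMIT = 12  # pooled n up to which the exact enumeration is used


@lru_cache(maxsize=None)
def _combination_index(n: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p-value.

    Exact enumeration of all C(n, n1) group assignments (valid with ties)
    when n1 + n2 <= 12; otherwise the tie-corrected normal approximation
    with a 0.5 continuity correction. Two-sided extremeness is measured as
    deviation of the rank sum from its null mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n1, n = x.size, pooled.size
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = ranks.sum() * n1 / n
    if n <= EXACT_LIMIT:
        combos = _combination_index(n, n1)
        sums = ranks[combos].sum(axis=1)
        p = float(np.mean(np.abs(sums - mu) >= abs(w - mu) - 1e-9))
        return min(p, 1.0)
    n2 = n - n1
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / np.sqrt(sigma2)
    return float(min(2.0 * stats.norm.sf(z), 1.0))


def welch_t_test(x, y) -> float:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def fold_change(mean_a: float, mean_b: float, eps: float = 1e-6) -> float:
    """(mean_a + eps) / (mean_b + eps); a is drought, b is control."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("group means must be non-negative")
    return (mean_a + eps) / (mean_b + eps)


def per_ecotype_da(
    table,
    design: StudyDesign,
    ecotype: str,
    abundance_min: float = 0.001,
    alpha: float = 0.05,
    test: str = "wilcoxon",
    adjust: bool = False,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Drought-vs-control test per taxon within one ecotype.

    Taxa enter only when their mean relative abundance across the ecotype's
    samples exceeds ``abundance_min``. No multiplicity adjustment by default
    (``adjust=True`` switches on BH and tests against adjusted p).
    """
    if isinstance(table, CountTable):
        table = to_relative_abundance(table)
    if not isinstance(table, RelativeAbundanceTable):
        raise TypeError("expected a CountTable or RelativeAbundanceTable")
    drought = design.samples_for(ecotype=ecotype, treatment="drought")
    control = design.samples_for(ecotype=ecotype, treatment="control")
    if len(drought) < 2 or len(control) < 2:
        raise ValueError(
            f"ecotype {ecotype!r} needs >= 2 replicates in both treatments "
            f"(drought={len(drought)}, control={len(control)})"
        )
    rows_d = [table.sample_ids.index(s) for s in drought]
    rows_c = [table.sample_ids.index(s) for s in control]
    values = table.values
    mean_all = values[rows_d + rows_c].mean(axis=0)
    eligible = np.nonzero(mean_all > abundance_min)[0]

    test_fn = {"wilcoxon": wilcoxon_rank_sum, "welch": welch_t_test}[test]
    records = []
    for j in eligible:
        xd = values[rows_d, j]
        xc = values[rows_c, j]
        p = test_fn(xd, xc)
        fold = fold_change(xd.mean(), xc.mean(), eps=eps)
        records.append(
            {
                "ecotype": ecotype,
                "taxon": table.taxon_ids[j],
                "mean_drought": xd.mean(),
                "mean_control": xc.mean(),
                "p": p,
                "fold": fold,
                "direction": "enriched" if fold >= 1.0 else "depleted",
            }
        )
    out = pd.DataFrame(
        records,
        columns=["ecotype", "taxon", "mean_drought", "mean_control", "p", "fold", "direction"],
    )
    if len(out) == 0:
        out["significant"] = pd.Series(dtype=bool)
        return out
    if adjust:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def da_all_ecotypes(table, design: StudyDesign, include_bulk: bool = False, **kwargs) -> pd.DataFrame:
    frames = [
        per_ecotype_da(table, design, eco, **kwargs)
        for eco in design.ecotypes(include_bulk=include_bulk)
    ]
    return pd.concat(frames, ignore_index=True)


def fold_matrix(da: pd.DataFrame) -> pd.DataFrame:
    """Taxa x ecotypes matrix of drought/control folds (NaN where untested)."""
    return da.pivot(index="taxon", columns="ecotype", values="fold")


def call_core_responsive(
    da: pd.DataFrame, k_core: int = 5, f_min: float = 1.2
) -> pd.DataFrame:
    """Cross-ecotype consensus call.

    core_enriched: DA-significant, direction enriched, and fold >= f_min in
    at least ``k_core`` ecotypes; core_depleted symmetric with
    fold <= 1/f_min. If both directions reach k_core the taxon is flagged
    ``ambiguous``. The cluster direction is the majority DA direction.
    """
    ecotypes = list(pd.unique(da["ecotype"]))
    if len(ecotypes) < k_core:
        raise ValueError(f"need >= {k_core} ecotypes, have {len(ecotypes)}")
    rows = []
    for taxon, sub in da.groupby("taxon", sort=True):
        sig = sub[sub["significant"]]
        n_enr = int(((sig["direction"] == "enriched") & (sig["fold"] >= f_min)).sum())
        n_dep = int(((sig["direction"] == "depleted") & (sig["fold"] <= 1.0 / f_min)).sum())
        if n_enr >= k_core and n_dep >= k_core:
            status = "ambiguous"
        elif n_enr >= k_core:
            status = "core_enriched"
        elif n_dep >= k_core:
            status = "core_depleted"
        else:
            status = "none"
        n_sig_enr = int((sig["direction"] == "enriched").sum())
        n_sig_dep = int((sig["direction"] == "depleted").sum())
        cluster = "cluster1" if n_sig_enr >= n_sig_dep else "cluster2"
        rows.append(
            {
                "taxon": taxon,
                "n_ecotypes_tested": len(sub),
                "n_ecotypes_enriched": n_enr,
                "n_ecotypes_depleted": n_dep,
                "status": status,
                "cluster": cluster,
            }
        )
    return pd.DataFrame(rows)


def group_fold_contrast(
    core: pd.DataFrame, folds: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Tolerant-vs-sensitive mean fold per core taxon, ranked for follow-up.

    ``folds`` is the taxa x ecotypes fold matrix; ecotype class comes from
    the design. Ties are labeled ``equal`` rather than forced to a side.
    """
    tolerant = [e for e in folds.columns if design.tolerance_of(e) == "tolerant"]
    sensitive = [e for e in folds.columns if design.tolerance_of(e) == "sensitive"]
    if not tolerant or not sensitive:
        raise ValueError("both tolerance classes must be present")
    out = core[core["status"].isin(["core_enriched", "core_depleted"])].copy()
    mean_tol, mean_sen, labels = [], [], []
    for taxon in out["taxon"]:
        ft = folds.loc[taxon, tolerant].astype(float).dropna()
        fs = folds.loc[taxon, sensitive].astype(float).dropna()
        mt = float(ft.mean()) if len(ft) else np.nan
        ms = float(fs.mean()) if len(fs) else np.nan
        mean_tol.append(mt)
        mean_sen.append(ms)
        if np.isnan(mt) or np.isnan(ms) or mt == ms:
            labels.append("equal")
        else:
            labels.append("higher_in_tolerant" if mt > ms else "lower_in_tolerant")
    out["mean_fold_tolerant"] = mean_tol
    out["mean_fold_sensitive"] = mean_sen
    out["group_contrast"] = labels
    out["contrast_ratio"] = out["mean_fold_tolerant"] / out["mean_fold_sensitive"]
    return out.sort_values("contrast_ratio", ascending=False, kind="stable").reset_index(drop=True)
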