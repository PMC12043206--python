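"""Alpha diversity, Bray-Curtis distances, PCoA, and permutation PERMANOVA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._util import bh_adjust
from .io_model import CountTable, RelativeAbundanceTable


@dataclass
class DistanceMatrix:
    sample_ids: list
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if m.shape != (n, n):
            raise ValueError("distance matrix must be square and match sample ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < -1e-12):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def select(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.matrix[np.ix_(idx, idx)])


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    pseudo_f: float
    p: float
    n_perm: int

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("R2 must lie in [0, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample Shannon entropy (natural log) and observed richness."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("samples with zero totals have undefined diversity")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -terms.sum(axis=1)
    richness = (counts > 0).sum(axis=1)
    return pd.DataFrame(
        {"shannon": shannon, "richness": richness.astype(int)}, index=table.sample_ids
    )


def bray_curtis(table: RelativeAbundanceTable) -> DistanceMatrix:
    d = squareform(pdist(table.values, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # positive axes / positive inertia


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical scaling of the Gower-centered matrix.

    Negative eigenvalues are reported as-is (no correction); axis signs are
    canonicalized so the largest-magnitude loading on each axis is positive.
    """
    n = len(dm.sample_ids)
    if n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    d2 = dm.matrix**2
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh((gower + gower.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    positive = eigval > tol
    axes = eigvec[:, positive] * np.sqrt(eigval[positive])
    for j in range(axes.shape[1]):
        k = np.argmax(np.abs(axes[:, j]))
        if axes[k, j] < 0:
            axes[:, j] = -axes[:, j]
    pos_inertia = eigval[positive].sum()
    proportion = eigval[positive] / pos_inertia if pos_inertia > 0 else eigval[positive]
    coords = pd.DataFrame(
        axes, index=dm.sample_ids, columns=[f"PCo{j + 1}" for j in range(axes.shape[1])]
    )
    return PCoAResult(coordinates=coords, eigenvalues=eigval, proportion_explained=proportion)


def _group_onehots(labels: np.ndarray):
    groups = pd.unique(labels)
    masks = [(labels == g) for g in groups]
    sizes = np.array([m.sum() for m in masks])
    return groups, masks, sizes


def _ss_stats(d2: np.ndarray, labels: np.ndarray):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    _, masks, sizes = _group_onehots(labels)
    ss_within = 0.0
    for mask, size in zip(masks, sizes):
        x = mask.astype(float)
        ss_within += x @ d2 @ x / (2.0 * size)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    labels,
    factor: str = "factor",
    n_perm: int = 999,
    seed=None,
) -> PermanovaResult:
    """One-factor PERMANOVA with free (unrestricted) label permutation.

    pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)); the permutation
    p-value uses the (1 + more-extreme) / (1 + n_perm) estimator so it is
    never zero.
    """
    labels = np.asarray(list(labels))
    n = dm.matrix.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must match the distance matrix samples")
    groups, _, sizes = _group_onehots(labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if np.any(sizes < 2):
        small = [g for g, s in zip(groups, sizes) if s < 2]
        raise ValueError(f"groups with a single sample: {small}")
    g = len(groups)
    d2 = dm.matrix**2
    ss_total, ss_within = _ss_stats(d2, labels)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_between / (g - 1)) / (ss_within / (n - g))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    ss_within_perm = np.zeros(n_perm)
    for grp, size in zip(groups, sizes):
        member = (labels == grp).astype(float)
        x = member[perms]  # n_perm x n one-hot rows under each permutation
        ss_within_perm += np.einsum("pi,ij,pj->p", x, d2, x) / (2.0 * size)
    ss_between_perm = ss_total - ss_within_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_between_perm / (g - 1)) / (ss_within_perm / (n - g))
    p = (1 + int(np.sum(f_perm >= f_obs - 1e-12))) / (1 + n_perm)
    return PermanovaResult(
        factor=factor, r2=float(np.clip(r2, 0, 1)), pseudo_f=float(f_obs), p=float(p), n_perm=n_perm
    )


def permanova_pairwise(dm: DistanceMatrix, labels, n_perm: int = 999, seed=None) -> pd.DataFrame:
    """All group pairs with BH-adjusted p-values."""
    labels = np.asarray(list(labels))
    groups = list(pd.unique(labels))
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            keep = np.isin(labels, [groups[i], groups[j]])
            sub = DistanceMatrix(
                [s for s, k in zip(dm.sample_ids, keep) if k],
                dm.matrix[np.ix_(keep, keep)],
            )
            res = permanova(
                sub,
                labels[keep],
                factor=f"{groups[i]} vs {groups[j]}",
                n_perm=n_perm,
                seed=rng.integers(2**32),
            )
            rows.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "r2": res.r2,
                    "pseudo_f": res.pseudo_f,
                    "p": res.p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def permanova_sequential(
    dm: DistanceMatrix, design_frame: pd.DataFrame, factors, n_perm: int = 999, seed=None
) -> pd.DataFrame:
    """Sequential (terms-in-order) multi-factor partitioning a la adonis.

    Each term's SS is the increment in tr(H G) when its dummy-coded columns
    are appended to the model; F uses the residual of the full model and p
    comes from free permutation of samples.
    """
    factors = list(factors)
    n = dm.matrix.shape[0]
    labels = {f: np.asarray(design_frame[f].astype(str)) for f in factors}
    d2 = dm.matrix**2
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ d2 @ centering
    ss_total = np.trace(gower)

    def hat(cols):
        x = np.column_stack([np.ones(n)] + cols)
        q, r = np.linalg.qr(x)
        rank = np.sum(np.abs(np.diag(r)) > 1e-10)
        q = q[:, :rank]
        return q @ q.T, rank

    hats, dfs = [], []
    cols: list = []
    prev_rank = 1
    for f in factors:
        groups = pd.unique(labels[f])
        cols.extend([(labels[f] == g).astype(float) for g in groups[1:]])
        h, rank = hat(cols)
        hats.append(h)
        dfs.append(rank - prev_rank)
        prev_rank = rank
    h_full = hats[-1]
    df_res = n - prev_rank

    def term_ss(g):
        prev = 0.0
        out = []
        for h in hats:
            tr = float(np.sum(h * g))
            out.append(tr - prev)
            prev = tr
        return np.array(out), float(ss_total_of(g) - np.sum(h_full * g))

    def ss_total_of(g):
        return np.trace(g)

    ss_terms, ss_res = term_ss(gower)
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factors))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = gower[np.ix_(perm, perm)]
        ss_t, ss_r = term_ss(gp)
        f_p = (ss_t / np.array(dfs)) / (ss_r / df_res)
        exceed += f_p >= f_obs - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    return pd.DataFrame(
        {
            "factor": factors,
            "df": dfs,
            "ss": ss_terms,
            "r2": ss_terms / ss_total,
            "pseudo_f": f_obs,
            "p": p,
            "mode": "sequential",
        }
    )


def cumulative_abundance(table: RelativeAbundanceTable, taxa, samples=None) -> float:
    """Mean over samples of the summed relative abundance of a taxon set."""
    taxa = list(taxa)
    if not taxa:
        warnings.warn("cumulative_abundance of an empty taxon set is 0", stacklevel=2)
        return 0.0
    missing = [t for t in taxa if t not in table.taxon_ids]
    if missing:
        raise ValueError(f"taxa not in table: {missing}")
    cols = [table.taxon_ids.index(t) for t in taxa]
    rows = (
        slice(None)
        if samples is None
        else [table.sample_ids.index(s) for s in samples]
    )
    return float(table.values[rows][:, cols].sum(axis=1).mean())
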