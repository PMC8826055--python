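"""Rarefaction, alpha/beta diversity, ordination, and nonparametric group tests.

Standard computations are delegated to established implementations
(scikit-bio for Faith's PD, PCoA, and ANOSIM; scipy and statsmodels for rank
tests, correlations, and Benjamini–Hochberg correction); this module fixes the
conventions used throughout the toolkit (rarefaction without replacement,
positive-eigenvalue PCoA, the +1 permutation p-value correction) and exposes a
generic nonparametric differential-abundance screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix, TreeNode
from skbio.stats import ordination as skbio_ordination
from skbio.stats.distance import anosim as skbio_anosim
from statsmodels.stats.multitest import multipletests

from .io_core import OtuTable

__all__ = [
    "OrdinationResult",
    "AnosimResult",
    "GroupTestResult",
    "rarefy_counts",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "anosim",
    "group_tests",
    "correlation",
    "bh_adjust",
    "differential_abundance",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling ordination restricted to positive eigenvalues.

    ``coordinates`` is samples × axes; axes are ordered by decreasing
    eigenvalue and ``proportion_explained`` is computed over the positive
    eigenvalues only.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p: float
    n_permutations: int


@dataclass(frozen=True)
class GroupTestResult:
    method: str  # "kruskal-wallis" or "mann-whitney"
    statistic: float
    p: float


# ---------------------------------------------------------------------------
# Rarefaction and alpha diversity
# ---------------------------------------------------------------------------

def rarefy_counts(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning
    (a single recorded draw, multivariate hypergeometric).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    keep_rows, keep_ids = [], []
    dropped = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = int(row.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            keep_rows.append(row.copy())
        else:
            keep_rows.append(rng.multivariate_hypergeometric(row, depth))
        keep_ids.append(sid)
    if dropped:
        warnings.warn(
            f"rarefy_counts: dropped {len(dropped)} sample(s) below depth "
            f"{depth}: {dropped}",
            stacklevel=2,
        )
    if not keep_rows:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    return OtuTable(np.array(keep_rows), tuple(keep_ids), table.otu_ids)


def _faith_pd(tree: TreeNode, present_tips: set) -> float:
    """Total branch length of the subtree spanning ``present_tips`` and the
    root.  Computed directly on the tree (handles multifurcating roots)."""
    spanning: set[int] = set()
    total = 0.0
    for tip in tree.tips():
        if tip.name not in present_tips:
            continue
        node = tip
        while node.parent is not None and id(node) not in spanning:
            spanning.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def alpha_diversity(table: OtuTable, tree: TreeNode) -> pd.DataFrame:
    """Per-sample OTU richness and Faith's phylogenetic diversity.

    PD is the total branch length of the subtree spanning the present tips
    and the root.  All-zero samples get richness 0 and PD 0 with a warning.
    """
    rows = []
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        richness = int((counts > 0).sum())
        if richness == 0:
            warnings.warn(f"sample {sid!r} has zero total count; PD set to 0",
                          stacklevel=2)
            pd_val = 0.0
        else:
            present = {o for o, c in zip(table.otu_ids, counts) if c > 0}
            pd_val = _faith_pd(tree, present)
        rows.append({"sample_id": sid, "richness": richness, "faith_pd": pd_val})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Beta diversity and ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity: Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    zero = table.sample_sums() == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValueError(
            f"Bray–Curtis undefined between all-zero samples: {bad}"
        )
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, ids=list(table.sample_ids))


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis (classical scaling).

    Negative eigenvalues (non-Euclidean input) are dropped; the proportion
    explained is computed over the positive eigenvalues only.  A fully
    degenerate matrix (all distances 0) yields a single all-zero axis.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = skbio_ordination.pcoa(d, method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig > max(1e-12, 1e-10 * abs(eig).max() if eig.size else 0)
    if not pos.any():
        coords = pd.DataFrame(
            np.zeros((len(d.ids), 1)), index=list(d.ids), columns=["PC1"]
        )
        return OrdinationResult(coords, np.zeros(1), np.zeros(1))
    eig_pos = eig[pos]
    order = np.argsort(eig_pos)[::-1]
    eig_pos = eig_pos[order]
    coords = res.samples.to_numpy()[:, pos][:, order]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        pd.DataFrame(coords, index=list(d.ids), columns=cols),
        eig_pos,
        eig_pos / eig_pos.sum(),
    )


def anosim(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    ``r = (mean between-group rank − mean within-group rank) / (M/2)`` with
    ``M = n(n−1)/2``; the p-value uses the +1 permutation correction, so its
    floor is ``1/(n_permutations+1)``.
    """
    labels = pd.Series(list(groups), index=list(d.ids))
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"ANOSIM groups need >= 2 members; too small: {small}")
    res = skbio_anosim(d, labels.to_numpy(), permutations=n_permutations,
                       seed=seed)
    return AnosimResult(
        r=float(res["test statistic"]),
        p=float(res["p-value"]),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Rank tests, correlation, multiple testing
# ---------------------------------------------------------------------------

def group_tests(values, groups) -> GroupTestResult:
    """Nonparametric difference test across groups.

    Two groups → two-sided Mann–Whitney U (exact enumeration for total n ≤ 10
    without ties); more → Kruskal–Wallis H with tie correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    uniq = pd.unique(labels)
    split = [values[labels == g] for g in uniq]
    if any(len(s) == 0 for s in split):
        raise ValueError("empty group")
    if len(split) < 2:
        raise ValueError("need at least 2 groups")
    if len(split) == 2:
        x, y = split
        method = "auto"
        if len(values) <= 10 and len(np.unique(values)) == len(values):
            method = "exact"
        stat, p = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method
        )
        return GroupTestResult("mann-whitney", float(stat), float(p))
    if all(np.all(s == values[0]) for s in split):
        return GroupTestResult("kruskal-wallis", 0.0, 1.0)
    stat, p = scipy.stats.kruskal(*split)
    return GroupTestResult("kruskal-wallis", float(stat), float(p))


def correlation(
    x, y, method: str = "pearson", n_permutations: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Pearson or Spearman correlation with p-value.

    For n < 10 the p-value comes from a permutation test instead of the
    t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        func = scipy.stats.pearsonr
    elif method == "spearman":
        func = scipy.stats.spearmanr
    else:
        raise ValueError(f"unknown method {method!r}")
    if len(x) < 10:
        perm = scipy.stats.PermutationMethod(
            n_resamples=n_permutations, rng=np.random.default_rng(seed)
        )
        res = func(x, y, method=perm)
    else:
        res = func(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(
    table: OtuTable,
    groups,
    min_prevalence: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Nonparametric differential-abundance screen on relative abundances.

    For every OTU present in at least ``min_prevalence`` of samples, a
    Kruskal–Wallis test across groups is computed on relative abundances,
    BH-adjusted over OTUs; ``enriched`` is the group with the highest median
    relative abundance, reported for OTUs with adjusted p < ``alpha``.
    """
    labels = np.asarray(list(groups))
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    rel = table.relative_abundance()
    prevalence = (table.counts > 0).mean(axis=0)
    keep = np.nonzero(prevalence >= min_prevalence)[0]
    rows = []
    for j in keep:
        per_group = [rel[labels == g, j] for g in uniq]
        flat = rel[:, j]
        if np.all(flat == flat[0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = scipy.stats.kruskal(*per_group)
        medians = {g: float(np.median(v)) for g, v in zip(uniq, per_group)}
        rows.append(
            {
                "otu_id": table.otu_ids[j],
                "statistic": float(stat),
                "p": float(p),
                "median_top_group": max(medians, key=medians.get),
                "prevalence": float(prevalence[j]),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
        out["enriched"] = np.where(
            out["p_adjusted"] < alpha, out["median_top_group"], ""
        )
        out = out.drop(columns="median_top_group")
    return out
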