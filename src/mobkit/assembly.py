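"""Phylogenetic null models and the five-way community assembly partition.

The machinery follows the standard two-stage null-model framework for
partitioning community assembly processes:

1. βNTI — the z-score of the observed between-sample mean nearest taxon
   distance (βMNTD) against a tip-label–shuffling null.  |βNTI| > 2 indicates
   deterministic selection: variable selection (VS) when > +2 (communities
   more phylogenetically divergent than expected), homogeneous selection (HS)
   when < −2.
2. RC_bray — a Raup–Crick metric on Bray–Curtis dissimilarity, rescaled to
   [−1, 1], for the pairs selection does not explain.  RC > +0.95 indicates
   dispersal limitation (DL), RC < −0.95 homogenizing dispersal (HD), and
   anything else is undominated (UD, ecological drift plus weak/ mixed
   processes).

ses-MPD (the within-sample analogue) classifies individual communities as
phylogenetically clustered (z < −2), overdispersed (z > 2), or stochastic.

All null randomizations shuffle tip labels on the cophenetic matrix (for the
phylogenetic metrics) or assemble richness- and abundance-constrained random
communities (for RC_bray); both are vectorized over samples so the default
999 randomizations stay cheap at the 36-sample scale this toolkit targets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .io_core import OtuTable

__all__ = [
    "PROCESSES",
    "cophenetic_distances",
    "ses_mpd",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "classify_assembly_processes",
    "process_fractions",
    "assembly_vs_function",
]

#: the five assembly processes, in reporting order
PROCESSES = ("VS", "HS", "DL", "HD", "UD")

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Patristic (branch-length path) distances between all pairs of tips."""
    return tree.tip_tip_distances()


def _aligned_distance_array(table: OtuTable, tree: TreeNode) -> np.ndarray:
    dm = cophenetic_distances(tree)
    missing = set(table.otu_ids) - set(dm.ids)
    if missing:
        raise ValueError(
            f"table and tree are not aligned; missing tips: {sorted(missing)[:5]}"
        )
    idx = [dm.index(o) for o in table.otu_ids]
    return dm.data[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# ses-MPD
# ---------------------------------------------------------------------------

def _mpd_all_samples(
    rel: np.ndarray, present: np.ndarray, d: np.ndarray, weighted: bool
) -> np.ndarray:
    """MPD for every sample under one distance matrix.

    Weighted: Σ_{i≠j} d_ij w_i w_j / (1 − Σ w_i²) with w the within-sample
    relative abundances.  Unweighted: mean off-diagonal distance among
    present OTUs.
    """
    n = rel.shape[0]
    out = np.full(n, np.nan)
    for s in range(n):
        idx = np.nonzero(present[s])[0]
        if len(idx) < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        if weighted:
            w = rel[s, idx]
            w = w / w.sum()
            denom = 1.0 - np.sum(w**2)
            out[s] = w @ sub @ w / denom
        else:
            k = len(idx)
            out[s] = sub.sum() / (k * (k - 1))
    return out


def ses_mpd(
    table: OtuTable,
    tree: TreeNode,
    n_null: int = 999,
    abundance_weighted: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Standardized effect size of mean pairwise phylogenetic distance.

    The null shuffles tip labels of the cophenetic matrix ``n_null`` times.
    Samples with fewer than 2 present OTUs get NaN and ``defined=False``.
    Classification bands: z < −2 clustered, z > 2 overdispersed, else
    stochastic.
    """
    d = _aligned_distance_array(table, tree)
    rel = table.relative_abundance()
    present = table.presence()
    rng = np.random.default_rng(seed)
    obs = _mpd_all_samples(rel, present, d, abundance_weighted)
    p = d.shape[0]
    nulls = np.empty((n_null, table.n_samples))
    for r in range(n_null):
        perm = rng.permutation(p)
        nulls[r] = _mpd_all_samples(
            rel, present, d[np.ix_(perm, perm)], abundance_weighted
        )
    null_mean = np.nanmean(nulls, axis=0)
    null_sd = np.nanstd(nulls, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - null_mean) / null_sd
    rows = []
    for i, sid in enumerate(table.sample_ids):
        defined = np.isfinite(obs[i]) and np.isfinite(z[i])
        if defined:
            band = (
                "clustered" if z[i] < -2 else
                "overdispersed" if z[i] > 2 else "stochastic"
            )
        else:
            band = "undefined"
        rows.append(
            {
                "sample_id": sid,
                "mpd_obs": obs[i],
                "null_mean": null_mean[i],
                "null_sd": null_sd[i],
                "z": z[i],
                "classification": band,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# βMNTD / βNTI
# ---------------------------------------------------------------------------

def _beta_mntd_matrix(
    rel: np.ndarray,
    present: np.ndarray,
    d: np.ndarray,
    weighted: bool,
) -> np.ndarray:
    """βMNTD between all sample pairs under one distance matrix.

    βMNTD(a,b) = ½ [Σᵢ fᵢᵃ · min_{j∈b} d(i,j) + Σⱼ fⱼᵇ · min_{i∈a} d(j,i)];
    a shared OTU's nearest taxon in the other sample is itself (distance 0).
    """
    n, p = rel.shape
    # nearest[i, b] = distance from OTU i to its nearest taxon present in b
    nearest = np.empty((p, n))
    for b in range(n):
        idx = np.nonzero(present[b])[0]
        if len(idx) == 0:
            raise ValueError(f"sample index {b} has no present OTUs")
        nearest[:, b] = d[:, idx].min(axis=1)
    if weighted:
        f = rel / rel.sum(axis=1, keepdims=True)
    else:
        f = present / present.sum(axis=1, keepdims=True)
    half = f @ nearest  # half[a, b] = Σ_i f_i^a nearest(i, b)
    return 0.5 * (half + half.T)


def beta_mntd(
    table: OtuTable,
    tree: TreeNode,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """Between-sample mean nearest taxon distance (observed)."""
    d = _aligned_distance_array(table, tree)
    mat = _beta_mntd_matrix(
        table.relative_abundance(), table.presence(), d, abundance_weighted
    )
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, ids=list(table.sample_ids))


def beta_nti(
    table: OtuTable,
    tree: TreeNode,
    n_null: int = 999,
    abundance_weighted: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """βNTI for every sample pair.

    The null shuffles tip labels of the cophenetic matrix (equivalently,
    permutes rows/columns) ``n_null`` times and recomputes βMNTD;
    βNTI = (obs − null mean) / null sd.  Pairs with a zero null sd are
    flagged ``defined=False``.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    d = _aligned_distance_array(table, tree)
    rel = table.relative_abundance()
    present = table.presence()
    rng = np.random.default_rng(seed)
    obs = _beta_mntd_matrix(rel, present, d, abundance_weighted)
    n = table.n_samples
    p = d.shape[0]
    nulls = np.empty((n_null, n, n))
    for r in range(n_null):
        perm = rng.permutation(p)
        nulls[r] = _beta_mntd_matrix(
            rel, present, d[np.ix_(perm, perm)], abundance_weighted
        )
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    rows = []
    for a, b in itertools.combinations(range(n), 2):
        sd = null_sd[a, b]
        if sd > 0:
            z = (obs[a, b] - null_mean[a, b]) / sd
            defined = True
        else:
            z = np.nan
            defined = False
        rows.append(
            {
                "sample_a": table.sample_ids[a],
                "sample_b": table.sample_ids[b],
                "beta_mntd_obs": obs[a, b],
                "null_mean": null_mean[a, b],
                "null_sd": sd,
                "beta_nti": z,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

def _null_community(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occ_prob: np.ndarray,
    abund_prob: np.ndarray,
) -> np.ndarray:
    """One Raup–Crick null community.

    Occupancy: draw the observed richness of distinct OTUs with probability
    proportional to occurrence frequency across samples.  Abundance: give
    each chosen OTU one individual, then distribute the remaining reads
    multinomially with probability proportional to pool-wide relative
    abundance among the chosen OTUs.
    """
    p = len(occ_prob)
    chosen = rng.choice(p, size=richness, replace=False, p=occ_prob)
    counts = np.zeros(p, dtype=np.int64)
    counts[chosen] = 1
    remaining = total - richness
    if remaining > 0:
        w = abund_prob[chosen]
        w = w / w.sum()
        counts[chosen] += rng.multinomial(remaining, w)
    return counts


def raup_crick_bray(
    table: OtuTable, n_null: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Bray–Curtis-based Raup–Crick metric for every sample pair.

    For each randomization, a null community is assembled for every sample
    (conditioning on its observed richness and total reads, with
    occupancy-proportional species draws and abundance filled proportionally
    to pool-wide relative abundance), and Bray–Curtis is computed among the
    null communities.  RC = (#{null < obs} + ½·#{null = obs}) / n_null,
    rescaled to [−1, 1] via ×2 − 1.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    present = table.presence()
    occ = present.sum(axis=0).astype(float)
    if (occ > 0).sum() < 2:
        raise ValueError("degenerate pool: fewer than 2 occurring OTUs")
    occ_prob = occ / occ.sum()
    pool = table.counts.sum(axis=0).astype(float)
    abund_prob = pool / pool.sum()
    richness = present.sum(axis=1)
    totals = table.sample_sums()
    n = table.n_samples
    rng = np.random.default_rng(seed)

    obs = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    less = np.zeros((n, n))
    equal = np.zeros((n, n))
    for _ in range(n_null):
        nulls = np.array(
            [
                _null_community(rng, int(richness[s]), int(totals[s]),
                                occ_prob, abund_prob)
                for s in range(n)
            ],
            dtype=float,
        )
        null_bc = squareform(pdist(nulls, metric="braycurtis"))
        less += null_bc < obs
        equal += null_bc == obs
    rc = 2.0 * (less + 0.5 * equal) / n_null - 1.0
    rows = []
    for a, b in itertools.combinations(range(n), 2):
        rows.append(
            {
                "sample_a": table.sample_ids[a],
                "sample_b": table.sample_ids[b],
                "bray_curtis_obs": obs[a, b],
                "rc_bray": rc[a, b],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------

def classify_assembly_processes(pairs: pd.DataFrame) -> pd.DataFrame:
    """Assign each sample pair to one of the five assembly processes.

    Decision table (βNTI first, RC_bray only when selection is rejected):
    HS if βNTI < −2; VS if βNTI > +2; else DL if RC > 0.95; HD if RC < −0.95;
    UD otherwise.  Pairs with undefined inputs get ``undefined``.
    """
    needed = {"beta_nti", "rc_bray"}
    missing = needed - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs frame missing columns: {sorted(missing)}")
    out = pairs.copy()

    def classify(row) -> str:
        b, rc = row["beta_nti"], row["rc_bray"]
        if not (np.isfinite(b) and np.isfinite(rc)):
            return "undefined"
        if b < -BNTI_THRESHOLD:
            return "HS"
        if b > BNTI_THRESHOLD:
            return "VS"
        if rc > RC_THRESHOLD:
            return "DL"
        if rc < -RC_THRESHOLD:
            return "HD"
        return "UD"

    out["process"] = out.apply(classify, axis=1)
    return out


def process_fractions(
    classified: pd.DataFrame, sample_groups: pd.Series
) -> pd.DataFrame:
    """Percentage of within-group pairs assigned to each process.

    ``sample_groups`` maps sample id → group label (site or wetland type);
    only pairs whose two members share a group contribute to that group's
    fractions.  Percentages sum to 100 per group.
    """
    groups = sample_groups.to_dict()
    ga = classified["sample_a"].map(groups)
    gb = classified["sample_b"].map(groups)
    within = classified[(ga == gb) & ga.notna()].copy()
    within["group"] = ga[within.index]
    if within.empty:
        raise ValueError("no within-group pairs for the given grouping")
    rows = []
    for group, sub in within.groupby("group", sort=True):
        sub = sub[sub["process"] != "undefined"]
        total = len(sub)
        if total == 0:
            raise ValueError(f"group {group!r} has no classified pairs")
        frac = {
            proc: 100.0 * (sub["process"] == proc).sum() / total
            for proc in PROCESSES
        }
        rows.append({"group": group, "n_pairs": total, **frac})
    return pd.DataFrame(rows).set_index("group")


def assembly_vs_function(
    classified: pd.DataFrame, mop: pd.Series
) -> pd.DataFrame:
    """Regress βNTI and RC_bray on the pairwise |MOP difference| (OLS).

    Pairs missing a MOP value on either side are dropped.  Returns one row
    per metric with slope, intercept, r², and p.
    """
    mop = mop.dropna()
    sub = classified[
        classified["sample_a"].isin(mop.index)
        & classified["sample_b"].isin(mop.index)
    ].copy()
    if len(sub) < 3:
        raise ValueError("need at least 3 pairs with MOP on both sides")
    dmop = np.abs(
        mop[sub["sample_a"]].to_numpy() - mop[sub["sample_b"]].to_numpy()
    )
    if np.std(dmop) == 0:
        raise ValueError("zero variance in pairwise MOP differences")
    rows = []
    for metric in ("beta_nti", "rc_bray"):
        y = sub[metric].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.std(y[ok]) == 0:
            raise ValueError(f"degenerate {metric} values for regression")
        fit = scipy.stats.linregress(dmop[ok], y[ok])
        rows.append(
            {
                "metric": metric,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.rvalue**2,
                "p": fit.pvalue,
                "n_pairs": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
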