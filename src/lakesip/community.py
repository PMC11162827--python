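"""Community statistics: rarefaction, dissimilarity, PERMANOVA, SIMPER, screen.

Genus-level 16S count tables (genera x bottles) are rarefied to a common
depth, filtered to genera above 0.5% of all reads, and expressed as
percent contributions per bottle.  Community structure is compared on
Bray–Curtis dissimilarities of square-root-transformed contributions with
one-way PERMANOVA (permutation p-values with the (#{F* >= F} + 1)/(n + 1)
small-sample correction) and decomposed into per-taxon contributions with
SIMPER.  Putative decomposer genera are those whose relative abundance
correlates with the substrate decomposition rate (Spearman rho > 0.6)
while contributing more than 2% in at least one lake; a Pearson R² below
0.3 flags a genus as an unlikely decomposer without removing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "rarefy",
    "filter_abundance",
    "braycurtis_matrix",
    "PermanovaResult",
    "permanova",
    "simper",
    "decomposer_screen",
    "nmds_ordination",
]

GLOBAL_ABUNDANCE_THRESHOLD_PCT = 0.5
SCREEN_RHO_THRESHOLD = 0.6
SCREEN_ABUNDANCE_THRESHOLD_PCT = 2.0
SCREEN_R2_THRESHOLD = 0.3


def rarefy(otu: pd.DataFrame, depth: int = 4000, seed: int | None = None) -> pd.DataFrame:
    """Subsample every bottle without replacement to exactly ``depth`` reads.

    ``otu`` is a genera x bottles integer count table.  Bottles with fewer
    than ``depth`` reads are dropped with a warning.  Deterministic given
    ``seed`` (multivariate hypergeometric sampling).
    """
    rng = np.random.default_rng(seed)
    counts = otu.to_numpy()
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("OTU table must hold non-negative integer counts")
    keep, columns = [], []
    for j, bottle in enumerate(otu.columns):
        total = int(counts[:, j].sum())
        if total < depth:
            warnings.warn(f"bottle {bottle!r} has {total} < {depth} reads; dropped", stacklevel=2)
            continue
        if total == depth:
            keep.append(counts[:, j])
        else:
            keep.append(rng.multivariate_hypergeometric(counts[:, j], depth))
        columns.append(bottle)
    if not columns:
        raise ValueError("no bottle reaches the rarefaction depth")
    return pd.DataFrame(np.column_stack(keep), index=otu.index, columns=columns)


def filter_abundance(
    otu: pd.DataFrame, global_threshold_pct: float = GLOBAL_ABUNDANCE_THRESHOLD_PCT
) -> pd.DataFrame:
    """Drop rare genera and express the rest as percent per bottle.

    A genus is retained when its reads exceed ``global_threshold_pct`` of
    all reads in the table.  Percentages are of each bottle's total reads
    (before the filter), so dropped tail reads do not inflate the rest.
    """
    totals = otu.sum(axis=0)
    global_pct = otu.sum(axis=1) / otu.to_numpy().sum() * 100.0
    kept = otu.loc[global_pct > global_threshold_pct]
    if kept.empty:
        raise ValueError("abundance filter removed every genus")
    return kept / totals * 100.0


def braycurtis_matrix(table: pd.DataFrame, sqrt_transform: bool = True) -> pd.DataFrame:
    """Bray–Curtis dissimilarity between bottles of a genera x bottles table.

    The square-root transform (applied before the distance when flagged)
    damps the influence of dominant genera, as is conventional for
    community ordination.  Returns a symmetric bottle x bottle frame with
    zero diagonal and values in [0, 1].
    """
    x = table.to_numpy(dtype=float).T  # bottles as rows
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    if (x.sum(axis=1) == 0).any():
        empty = table.columns[x.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero bottle(s): {empty}")
    if sqrt_transform:
        x = np.sqrt(x)
    dm = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.columns, columns=table.columns)


@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA result."""

    statistic: float  # pseudo-F
    p_value: float
    n_permutations: int
    df_among: int
    df_within: int
    n: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = codes.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        members = codes == g
        ng = int(members.sum())
        ss_within += d2[np.ix_(members, members)].sum() / (2.0 * ng)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    dm,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with permutation p-value.

    The pseudo-F compares among-group to within-group sums of squared
    dissimilarities (Anderson's one-way form); on Euclidean distances of a
    single variable it equals the classical one-way ANOVA F.  The p-value
    is ``(#{F_perm >= F_obs} + 1) / (n_perm + 1)``.
    """
    d = np.asarray(dm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    codes, groups = pd.factorize(np.asarray(grouping))
    k = len(groups)
    n = codes.size
    if n != d.shape[0]:
        raise ValueError("grouping length must match the distance matrix")
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every group needs at least two members")
    d2 = d**2
    f_obs = _pseudo_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(codes), k) >= f_obs:
            hits += 1
    return PermanovaResult(
        statistic=float(f_obs),
        p_value=(hits + 1) / (n_perm + 1),
        n_permutations=n_perm,
        df_among=k - 1,
        df_within=n - k,
        n=n,
    )


def _simper_pair(table: pd.DataFrame, a: list, b: list) -> pd.DataFrame:
    x = table[a].to_numpy(dtype=float)
    y = table[b].to_numpy(dtype=float)
    contrib = np.zeros(table.shape[0])
    n_pairs = 0
    for i in range(x.shape[1]):
        for j in range(y.shape[1]):
            denom = (x[:, i] + y[:, j]).sum()
            if denom == 0:
                raise ValueError("cannot compare two all-zero bottles")
            contrib += np.abs(x[:, i] - y[:, j]) / denom
            n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    out = pd.DataFrame(
        {
            "taxon": table.index,
            "contribution": contrib,
            "contribution_pct": contrib / total * 100.0 if total > 0 else 0.0,
            "mean_abundance_a": x.mean(axis=1),
            "mean_abundance_b": y.mean(axis=1),
        }
    ).sort_values("contribution", ascending=False, ignore_index=True)
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    out.attrs["mean_dissimilarity"] = float(total)
    return out


def simper(table: pd.DataFrame, grouping) -> pd.DataFrame | dict:
    """SIMPER: per-taxon contribution to between-group Bray–Curtis.

    For each pair of bottles from different groups a taxon contributes
    ``|x_i - y_i| / sum_t (x_t + y_t)``; contributions are averaged over
    all between-group pairs, so they sum exactly to the mean between-group
    dissimilarity (stored in ``.attrs['mean_dissimilarity']``).  With more
    than two groups a dict of pairwise tables is returned.
    """
    groups = pd.Series(list(grouping), index=table.columns)
    levels = groups.unique().tolist()
    if len(levels) < 2:
        raise ValueError("SIMPER needs at least two groups")
    if len(levels) == 2:
        a = groups.index[groups == levels[0]].tolist()
        b = groups.index[groups == levels[1]].tolist()
        return _simper_pair(table, a, b)
    out = {}
    for i, ga in enumerate(levels):
        for gb in levels[i + 1 :]:
            a = groups.index[groups == ga].tolist()
            b = groups.index[groups == gb].tolist()
            out[(ga, gb)] = _simper_pair(table, a, b)
    return out


def decomposer_screen(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    rates: pd.DataFrame,
    substrate: str = "PS",
    rho_threshold: float = SCREEN_RHO_THRESHOLD,
    abundance_threshold_pct: float = SCREEN_ABUNDANCE_THRESHOLD_PCT,
    r2_threshold: float = SCREEN_R2_THRESHOLD,
    target: pd.Series | None = None,
) -> pd.DataFrame:
    """Identify genera whose abundance tracks the decomposition rate.

    Per season, the Spearman rho of each genus's percent abundance (from
    the already rarefied + filtered ``table``) against the per-lake mean
    decomposition rate of ``substrate`` bottles is computed (ties by
    average ranks); a genus passes when rho exceeds ``rho_threshold`` and
    its mean abundance exceeds ``abundance_threshold_pct`` in at least one
    lake.  Pearson r and R² against the per-bottle rate are the exclusion
    statistic: R² below ``r2_threshold`` marks the genus ``unlikely``
    without removing it.  ``target`` optionally replaces the per-lake mean
    rate with an external per-bottle score (e.g. an ordination axis).

    ``rates`` is the per-bottle output of :func:`lakesip.fate.bottle_rates`.
    """
    meta = metadata.set_index("bottle")
    r = rates.set_index("bottle")["decomposition"]
    out = []
    for season in meta["season"].unique():
        bottles = [
            b
            for b in table.columns
            if meta.loc[b, "season"] == season and meta.loc[b, "substrate"] == substrate
        ]
        bottles = [b for b in bottles if b in r.index]
        if len(bottles) < 3:
            continue
        lakes = meta.loc[bottles, "lake"]
        per_bottle_rate = r.loc[bottles]
        lake_mean = per_bottle_rate.groupby(lakes).mean()
        y = (
            target.loc[bottles].to_numpy()
            if target is not None
            else lakes.map(lake_mean).to_numpy()
        )
        for genus in table.index:
            x = table.loc[genus, bottles].to_numpy(dtype=float)
            if np.ptp(x) == 0.0:
                warnings.warn(
                    f"genus {genus!r} has constant abundance in {season}; skipped", stacklevel=2
                )
                continue
            rho = stats.spearmanr(x, y).statistic
            pearson = stats.pearsonr(x, per_bottle_rate.to_numpy()).statistic
            lake_abund = pd.Series(x, index=bottles).groupby(lakes).mean()
            max_lake = float(lake_abund.max())
            out.append(
                {
                    "genus": genus,
                    "season": season,
                    "spearman_rho": float(rho),
                    "pearson_r": float(pearson),
                    "r_squared": float(pearson**2),
                    "mean_abundance_pct": float(x.mean()),
                    "max_lake_abundance_pct": max_lake,
                    "passes": bool(rho > rho_threshold and max_lake > abundance_threshold_pct),
                    "unlikely": bool(pearson**2 < r2_threshold),
                }
            )
    return pd.DataFrame(out)


def nmds_ordination(dm: pd.DataFrame, n_components: int = 2, seed: int = 0) -> pd.DataFrame:
    """Non-metric MDS embedding of a distance matrix (plotting plumbing)."""
    from sklearn.manifold import MDS

    mds = MDS(
        n_components=n_components,
        metric=False,
        dissimilarity="precomputed",
        random_state=seed,
        normalized_stress="auto",
        n_init=4,
    )
    coords = mds.fit_transform(np.asarray(dm, dtype=float))
    cols = [f"nmds{i + 1}" for i in range(n_components)]
    out = pd.DataFrame(coords, index=dm.index, columns=cols)
    out.attrs["stress"] = float(mds.stress_)
    return out
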