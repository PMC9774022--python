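"""Community-level statistics: diversity, ordination, group tests, effect sizes.

Conventions: Shannon entropy in nats; Simpson reported on the Gini-Simpson
scale (1 - sum p^2, higher = more diverse); Chao1 in its bias-corrected
form. Group-difference tests run on total-sum-scaled relative abundances.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import FeatureTable, PhyloTree
from .pls import pls_components

# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: FeatureTable, richness_estimators: bool = True) -> pd.DataFrame:
    """Per-sample observed richness, Chao1, ACE, Shannon (nats), Gini-Simpson.

    Chao1 and ACE are undefined on non-integer data; pass
    ``richness_estimators=False`` to compute only Shannon/Simpson on
    relative abundances.
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any():
        raise ValidationError("all-zero sample: diversity undefined")
    if richness_estimators and not table.is_integer():
        raise ValidationError(
            "richness estimators need integer counts; "
            "set richness_estimators=False for relative abundances"
        )
    from skbio.diversity.alpha import ace as _ace
    from skbio.diversity.alpha import chao1 as _chao1

    rows = {}
    for j, sid in enumerate(table.sample_ids):
        c = counts[:, j]
        p = c / c.sum()
        nz = p[p > 0]
        row = {
            "observed_features": int((c > 0).sum()),
            "shannon": float(-(nz * np.log(nz)).sum()),
            "simpson": float(1.0 - (nz ** 2).sum()),
        }
        if richness_estimators:
            ci = c.astype(int)
            row["chao1"] = float(_chao1(ci, bias_corrected=True))
            try:
                row["ace"] = float(_ace(ci))
            except Exception:  # no rare features: estimator degenerates to S_obs
                row["ace"] = float(row["observed_features"])
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarities."""

    sample_ids: list[str]
    data: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if (self.data < -1e-12).any():
            raise ValidationError("negative distances")

    def to_skbio(self) -> skbio.DistanceMatrix:
        d = (self.data + self.data.T) / 2
        np.fill_diagonal(d, 0.0)
        return skbio.DistanceMatrix(np.maximum(d, 0.0), ids=self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


def unifrac(table: FeatureTable, tree: PhyloTree, weighted: bool = False) -> DistanceMatrix:
    """Phylogenetic dissimilarity between all sample pairs.

    Unweighted: fraction of branch length unique to one sample out of the
    branch length covered by either. Weighted: Lozupone-normalized
    abundance-weighted variant.
    """
    missing = set(table.feature_ids) - set(tree.leaf_names)
    if missing:
        raise ValidationError(f"features missing from tree: {sorted(missing)[:5]}")
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("zero-total sample: UniFrac undefined")
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": True} if weighted else {}
    dm = skbio.diversity.beta_diversity(
        metric, table.counts.T, ids=table.sample_ids,
        taxa=table.feature_ids, tree=tree.tree, **kwargs,
    )
    return DistanceMatrix(table.sample_ids,
                          dm.data,
                          "weighted_unifrac" if weighted else "unweighted_unifrac")


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Ordination:
    method: str
    coordinates: pd.DataFrame          # samples x axes
    eigenvalues: np.ndarray | None = None
    explained: np.ndarray | None = None  # nonnegative fractions, sum <= 1


def pcoa(dist: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical multidimensional scaling of a distance matrix.

    Negative eigenvalues are reported as-is in ``eigenvalues``; explained
    fractions are computed over the positive spectrum only.
    """
    n = len(dist.sample_ids)
    if k > n:
        raise ValidationError(f"cannot request {k} axes for {n} samples")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = skbio.stats.ordination.pcoa(dist.to_skbio(), method="eigh",
                                          number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = np.maximum(eig, 0.0)
    explained = (pos / pos.sum())[:k] if pos.sum() > 0 else np.zeros(k)
    coords = res.samples.iloc[:, :k]
    coords.index = dist.sample_ids
    coords.columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return Ordination("PCoA", coords, eig, explained)


def plsda(table: FeatureTable, labels: Mapping[str, str] | pd.Series,
          k: int = 2) -> Ordination:
    """Supervised ordination: PLS against a centered one-hot group response."""
    labels = pd.Series(labels).reindex(table.sample_ids)
    if labels.isna().any():
        raise ValidationError("labels missing for some samples")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("PLS-DA needs >= 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs >= 2 samples")
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = table.relative_abundance().counts.T
    X = X - X.mean(axis=0)
    Y = pd.get_dummies(labels).to_numpy(float)
    Y = Y - Y.mean(axis=0)
    T, _, _, _ = pls_components(X, Y, k)
    coords = pd.DataFrame(T, index=table.sample_ids,
                          columns=[f"PLS{i + 1}" for i in range(k)])
    # explained X-variance per component via loadings reconstruction
    tot = (X ** 2).sum()
    expl = []
    Xd = X.copy()
    for a in range(k):
        t = T[:, a]
        p = Xd.T @ t / (t @ t)
        expl.append(float((np.outer(t, p) ** 2).sum() / tot) if tot > 0 else 0.0)
        Xd = Xd - np.outer(t, p)
    return Ordination("PLSDA", coords, None, np.array(expl))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(dist: DistanceMatrix, labels: Mapping[str, str] | pd.Series,
           n_permutations: int = 999, seed: int = 0) -> AnosimResult:
    """Analysis of similarities: rank-based between- vs within-group contrast.

    R near 1 means between-group dissimilarities dominate; the p-value uses
    the (count + 1)/(permutations + 1) convention and can never be zero.
    """
    labels = pd.Series(labels).reindex(dist.sample_ids)
    if labels.isna().any():
        raise ValidationError("labels missing for some samples")
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValidationError("ANOSIM needs >= 2 groups with >= 2 samples each")
    n = len(dist.sample_ids)
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dist.data[iu])
    grp = labels.to_numpy()
    within = grp[iu[0]] == grp[iu[1]]
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(grp)
        w = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, w) >= r_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AnosimResult(r_obs, p, n_permutations)


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def _rank_test(groups: list[np.ndarray]) -> tuple[str, float, float]:
    """Wilcoxon rank-sum for 2 groups, Kruskal-Wallis for >= 3."""
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        test = "wilcoxon" if len(groups) == 2 else "kruskal_wallis"
        return test, np.nan, 1.0
    if len(groups) == 2:
        a, b = groups
        no_ties = len(np.unique(allv)) == allv.size
        method = "exact" if (max(len(a), len(b)) <= 25 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return "wilcoxon", float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return "kruskal_wallis", float(res.statistic), float(res.pvalue)


def diff_abundance(table: FeatureTable, labels: Mapping[str, str] | pd.Series,
                   relative: bool = True) -> pd.DataFrame:
    """Per-feature nonparametric group test with BH-adjusted q-values.

    Two groups use the Wilcoxon rank-sum test (exact null for n <= 25
    without ties), three or more the Kruskal-Wallis test. Constant
    features get p = 1 and a ``degenerate`` flag.
    """
    labels = pd.Series(labels).reindex(table.sample_ids)
    if labels.isna().any():
        raise ValidationError("labels missing for some samples")
    data = table.relative_abundance().counts if relative else table.counts
    group_names = sorted(labels.unique())
    masks = [(labels == g).to_numpy() for g in group_names]
    rows = []
    for i, fid in enumerate(table.feature_ids):
        vals = data[i]
        groups = [vals[m] for m in masks]
        test, statistic, p = _rank_test(groups)
        row = {"feature_id": fid, "test": test, "statistic": statistic, "p": p,
               "degenerate": bool(np.isnan(statistic))}
        for g, gv in zip(group_names, groups):
            row[f"median_{g}"] = float(np.median(gv))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature_id")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# LEfSe-style LDA effect sizes
# ---------------------------------------------------------------------------

def lda_effect_size(table: FeatureTable, labels: Mapping[str, str] | pd.Series,
                    alpha: float = 0.05, cutoff: float = 3.0,
                    n_boot: int = 30, subsample_fraction: float = 2 / 3,
                    seed: int = 0) -> pd.DataFrame:
    """Group-enriched features scored by a log10 linear-discriminant effect.

    Features passing a Kruskal-Wallis screen at ``alpha`` are scaled to a
    per-sample total of 1e6, then repeatedly subsampled (balanced, a
    ``subsample_fraction`` of each group per round); each round fits a
    one-dimensional LDA and the effect is the average of the
    discriminant-projected class difference and the raw class-mean
    difference, reported as log10(1 + effect). Only features with score
    >= ``cutoff`` are returned.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    labels = pd.Series(labels).reindex(table.sample_ids)
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValidationError("pairwise comparison required (2 groups)")
    screen = diff_abundance(table, labels)
    survivors = screen.index[(screen["p"] < alpha) & ~screen["degenerate"]].tolist()
    cols = ["feature_id", "enriched_group", "lda_score", "p_screen"]
    if not survivors:
        return pd.DataFrame(columns=cols).set_index("feature_id")
    rel = table.relative_abundance().select_features(survivors)
    X_all = rel.counts.T * 1e6  # LEfSe per-sample scaling
    y_all = (labels == names[1]).to_numpy().astype(int)
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(y_all == 0)
    idx1 = np.flatnonzero(y_all == 1)
    take0 = max(2, int(round(subsample_fraction * idx0.size)))
    take1 = max(2, int(round(subsample_fraction * idx1.size)))
    eff_sum = np.zeros(len(survivors))
    rounds = 0
    for _ in range(n_boot):
        sub = np.concatenate([rng.choice(idx0, take0, replace=False),
                              rng.choice(idx1, take1, replace=False)])
        X = X_all[sub].copy()
        y = y_all[sub]
        # jitter avoids singular within-class scatter on sparse features
        X += rng.normal(0.0, 1e-5 * max(X.mean(), 1.0), size=X.shape)
        clf = LinearDiscriminantAnalysis(solver="svd")
        try:
            clf.fit(X, y)
        except Exception:
            continue
        w = clf.scalings_[:, 0]
        nrm = np.linalg.norm(w)
        if nrm == 0:
            continue
        w = w / nrm
        ld = X @ w
        proj_gap = abs(ld[y == 1].mean() - ld[y == 0].mean())
        coeff = np.abs(w) * proj_gap
        mean_gap = np.abs(X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0))
        eff_sum += (coeff + mean_gap) / 2.0
        rounds += 1
    if rounds == 0:
        return pd.DataFrame(columns=cols).set_index("feature_id")
    scores = np.log10(1.0 + eff_sum / rounds)
    mean_by_grp = [X_all[y_all == g].mean(axis=0) for g in (0, 1)]
    enriched = np.where(mean_by_grp[1] > mean_by_grp[0], names[1], names[0])
    out = pd.DataFrame({
        "feature_id": survivors,
        "enriched_group": enriched,
        "lda_score": scores,
        "p_screen": screen.loc[survivors, "p"].to_numpy(),
    }).set_index("feature_id")
    return out[out["lda_score"] >= cutoff].sort_values("lda_score", ascending=False)


# ---------------------------------------------------------------------------
# Venn partition of feature presence
# ---------------------------------------------------------------------------

def shared_features(table: FeatureTable, labels: Mapping[str, str] | pd.Series
                    ) -> dict[tuple[str, ...], int]:
    """Counts of every region of the 2- or 3-set presence Venn partition.

    A feature is present in a group when it has a nonzero count in at
    least one of the group's samples. Keys are sorted tuples of the group
    names owning the region exclusively.
    """
    labels = pd.Series(labels).reindex(table.sample_ids)
    names = sorted(labels.unique())
    presence: dict[str, set[str]] = {}
    for g in names:
        m = (labels == g).to_numpy()
        if not m.any():
            raise ValidationError(f"group {g} has no samples")
        mask = (table.counts[:, m] > 0).any(axis=1)
        presence[g] = {f for f, keep in zip(table.feature_ids, mask) if keep}
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(presence[g] for g in combo))
            outside = set.union(*(presence[g] for g in names if g not in combo)) \
                if len(combo) < len(names) else set()
            regions[tuple(combo)] = len(inside - outside)
    return regions
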