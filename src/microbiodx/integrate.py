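"""Cross-omic integration: Spearman correlation networks, cohort baseline
tables, and the end-to-end study orchestration."""

from __future__ import annotations

import dataclasses
import functools
import itertools
import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import (CLINICAL_VARS, CohortMetadata, FeatureTable, MetaboliteBatch,
                 PhyloTree, RunConfig)

# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def _exact_rho_distribution(n: int) -> np.ndarray:
    """All Spearman rho values over permutations of n untied ranks."""
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(base)))
    d2 = ((perms - base) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n ** 2 - 1))


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with average-rank ties; exact two-sided p for n <= 9
    without ties, t-approximation otherwise."""
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    no_ties = (len(np.unique(x)) == n) and (len(np.unique(y)) == n)
    if n <= 9 and no_ties:
        null = _exact_rho_distribution(n)
        p = float((np.abs(null) >= abs(rho) - 1e-12).mean())
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def spearman_matrix(a: pd.DataFrame, b: pd.DataFrame,
                    type_a: str = "taxon", type_b: str = "phenotype",
                    min_samples: int = 5) -> pd.DataFrame:
    """All-pairs Spearman correlations between two named value tables.

    Both tables are samples x variables and are aligned on their index.
    Missing values are removed pairwise; pairs with fewer than
    ``min_samples`` complete observations or a constant vector are reported
    with a ``skipped`` reason instead of a rho. BH q-values span all
    computed pairs.
    """
    common = a.index.intersection(b.index)
    if len(common) < min_samples:
        raise ValidationError(f"fewer than {min_samples} shared samples")
    a, b = a.loc[common], b.loc[common]
    rows = []
    for va in a.columns:
        for vb in b.columns:
            pair = pd.concat([a[va], b[vb]], axis=1).dropna()
            row = {"var_a": va, "var_b": vb, "type_a": type_a, "type_b": type_b,
                   "n": len(pair), "rho": np.nan, "p": np.nan, "skipped": ""}
            if len(pair) < min_samples:
                row["skipped"] = "too few complete observations"
            elif pair.iloc[:, 0].nunique() == 1 or pair.iloc[:, 1].nunique() == 1:
                row["skipped"] = "constant vector"
            else:
                x = pair.iloc[:, 0].to_numpy(float)
                y = pair.iloc[:, 1].to_numpy(float)
                row["rho"], row["p"] = spearman_with_p(x, y)
            rows.append(row)
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"].to_numpy(),
                                         method="fdr_bh")[1]
    out["sign"] = np.sign(out["rho"]).fillna(0).astype(int)
    out["stars"] = [(_stars(p) if np.isfinite(p) else "") for p in out["p"]]
    return out


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CorrelationNetwork:
    graph: nx.Graph
    rule: str

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            [{"node": n, **d} for n, d in self.graph.nodes(data=True)])
        edges = pd.DataFrame(
            [{"source": u, "target": v, **d}
             for u, v, d in self.graph.edges(data=True)])
        return nodes, edges


def build_network(edges: pd.DataFrame, p_max: float = 0.05,
                  use_q: bool = False, min_abs_rho: float = 0.0
                  ) -> CorrelationNetwork:
    """Thresholded correlation network; isolated nodes are dropped.

    An empty result is legitimate (flagged via ``n_edges == 0``), not an
    error.
    """
    col = "q" if use_q else "p"
    keep = edges[(edges[col] < p_max)
                 & (edges["rho"].abs() >= min_abs_rho)
                 & (edges["skipped"] == "")
                 & (edges["var_a"] != edges["var_b"])]
    g = nx.Graph()
    for _, e in keep.iterrows():
        g.add_node(e["var_a"], node_type=e["type_a"])
        g.add_node(e["var_b"], node_type=e["type_b"])
        g.add_edge(e["var_a"], e["var_b"], rho=float(e["rho"]),
                   p=float(e["p"]), q=float(e["q"]), sign=int(e["sign"]))
    rule = f"{col}<{p_max}" + (f", |rho|>={min_abs_rho}" if min_abs_rho else "")
    return CorrelationNetwork(g, rule)


# ---------------------------------------------------------------------------
# cohort baseline tables
# ---------------------------------------------------------------------------

def percentage(count: int, total: int) -> float:
    """Percentage rounded to one decimal, as printed in cohort tables."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return round(100.0 * count / total, 1)


def _describe_normal(v: pd.Series) -> str:
    return f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"


def _describe_skewed(v: pd.Series) -> str:
    q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
    return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"


def cohort_table(metadata: CohortMetadata, groups: Sequence[str] | None = None,
                 continuous: Sequence[str] | None = None,
                 categorical: Sequence[str] = ("sex",),
                 shapiro_alpha: float = 0.05) -> pd.DataFrame:
    """Baseline characteristics table with per-variable test selection.

    Continuous variables are reported mean ± SD with a t-test (ANOVA for
    three or more groups) when every group passes Shapiro-Wilk normality at
    ``shapiro_alpha``, and median [IQR] with a rank test otherwise.
    Categorical variables get counts (percent to one decimal) with a
    chi-square test, or Fisher's exact test when any expected cell is
    below 5 in a 2x2 layout.
    """
    df = metadata.frame
    if groups is not None:
        df = df[df["group"].isin(groups)]
    names = sorted(df["group"].unique())
    if len(names) < 2:
        raise ValidationError("cohort table needs >= 2 groups")
    if continuous is None:
        continuous = ["age"] + [v for v in CLINICAL_VARS if v in df.columns]
    rows = []
    for var in continuous:
        if var not in df.columns:
            continue
        per_group = {g: df.loc[df["group"] == g, var].dropna() for g in names}
        if any(len(v) == 0 for v in per_group.values()):
            rows.append({"variable": var, "descriptor": "missing",
                         **{g: "missing" for g in names},
                         "test": "none", "p": np.nan})
            continue
        normal = all(
            len(v) >= 3 and stats.shapiro(v).pvalue > shapiro_alpha
            for v in per_group.values()
        )
        vals = [per_group[g].to_numpy(float) for g in names]
        if normal:
            if len(names) == 2:
                test, p = "t-test", stats.ttest_ind(*vals).pvalue
            else:
                test, p = "anova", stats.f_oneway(*vals).pvalue
            desc = {g: _describe_normal(per_group[g]) for g in names}
            form = "mean ± SD"
        else:
            if len(names) == 2:
                test, p = "wilcoxon", stats.mannwhitneyu(
                    *vals, alternative="two-sided").pvalue
            else:
                test, p = "kruskal_wallis", stats.kruskal(*vals).pvalue
            desc = {g: _describe_skewed(per_group[g]) for g in names}
            form = "median [IQR]"
        rows.append({"variable": var, "descriptor": form, **desc,
                     "test": test, "p": float(p)})
    for var in categorical:
        if var not in df.columns:
            continue
        ct = pd.crosstab(df[var], df["group"])
        ct = ct.reindex(columns=names, fill_value=0)
        expected = stats.contingency.expected_freq(ct.to_numpy())
        if ct.shape == (2, 2) and (expected < 5).any():
            test, p = "fisher", stats.fisher_exact(ct.to_numpy())[1]
        else:
            test, p = "chi-square", stats.chi2_contingency(ct.to_numpy())[1]
        for level, row in ct.iterrows():
            rows.append({
                "variable": f"{var}={level}", "descriptor": "n (%)",
                **{g: f"{row[g]} ({percentage(int(row[g]), int(ct[g].sum()))})"
                   for g in names},
                "test": test, "p": float(p),
            })
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# full-study orchestration
# ---------------------------------------------------------------------------

def run_full_study(table: FeatureTable, metadata: CohortMetadata,
                   tree: PhyloTree | None = None,
                   batch: MetaboliteBatch | None = None,
                   config: RunConfig | None = None,
                   outdir: str | Path | None = None) -> dict:
    """Execute every pipeline stage and return (and optionally persist) a
    machine-readable report.

    Stages: cohort summary; alpha diversity; UniFrac + PCoA + ANOSIM (when
    a tree is given); shared-OTU Venn partition; differential abundance and
    LDA effect sizes; diagnostic model (HC vs IgAN); differential model
    (IgAN vs n_IgAN, when present); metabolomics arm (when a batch is
    given); taxon-phenotype and metabolite correlation networks.
    """
    from . import community, markers, metabolomics

    cfg = config or RunConfig()
    report: dict = {"schema_version": 1, "seed": cfg.seed, "stages": {}}
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def persist(name: str, df: pd.DataFrame) -> None:
        if out is not None:
            df.to_csv(out / f"{name}.tsv", sep="\t")

    def stage(name):
        def deco(fn):
            try:
                report["stages"][name] = fn()
            except Exception as exc:  # keep partial results, label the stage
                report["stages"][name] = {"error": f"{type(exc).__name__}: {exc}"}
            return None
        return deco

    groups_present = sorted(metadata.group.unique())

    @stage("cohort_summary")
    def _():
        summ = cohort_table(metadata)
        persist("cohort_summary", summ)
        return {"n_variables": len(summ)}

    @stage("alpha_diversity")
    def _():
        alpha = community.alpha_diversity(table)
        persist("alpha_diversity", alpha)
        return {"mean_shannon": float(alpha["shannon"].mean())}

    @stage("venn")
    def _():
        regions = community.shared_features(table, metadata.group)
        return {"+".join(k): v for k, v in regions.items()}

    @stage("beta_diversity")
    def _():
        if tree is None:
            return {"skipped": "no tree supplied"}
        res = {}
        for weighted in (False, True):
            dm = community.unifrac(table, tree, weighted=weighted)
            persist(dm.metric, dm.to_dataframe())
            ano = community.anosim(dm, metadata.group,
                                   n_permutations=cfg.n_permutations, seed=cfg.seed)
            ord_ = community.pcoa(dm, k=2)
            persist(f"pcoa_{dm.metric}", ord_.coordinates)
            res[dm.metric] = {"anosim_R": ano.r, "anosim_p": ano.p_value}
        return res

    @stage("diff_abundance")
    def _():
        da = community.diff_abundance(table, metadata.group)
        persist("diff_abundance", da)
        return {"n_significant_raw": int((da["p"] < cfg.screen_alpha).sum())}

    pair_models = [("HC", "IgAN"), ("IgAN", "n_IgAN")]
    for ctrl, dis in pair_models:
        if ctrl not in groups_present or dis not in groups_present:
            continue
        name = f"model_{ctrl}_vs_{dis}"

        @stage(name)
        def _(ctrl=ctrl, dis=dis):
            res = markers.MicrobiomeDiagnostic(
                table, metadata, groups=(ctrl, dis), config=cfg).fit(seed=cfg.seed)
            if out is not None:
                res.error_curve.to_dataframe().to_csv(
                    out / f"{ctrl}_vs_{dis}_error_curve.tsv", sep="\t", index=False)
                for phase, pod in res.pod.items():
                    pod.to_series().to_csv(
                        out / f"{ctrl}_vs_{dis}_pod_{phase}.tsv", sep="\t")
            return res.to_report()

    @stage("metabolomics")
    def _():
        if batch is None:
            return {"skipped": "metabolomics disabled (no batch supplied)"}
        corrected, uncorrectable = metabolomics.qc_rlsc(batch, span=cfg.loess_span)
        filtered, removed = metabolomics.rsd_filter(corrected, cfg.rsd_threshold)
        X, labels = filtered.study_labels()
        fit = metabolomics.OPLSDA.from_batch(filtered, seed=cfg.seed).fit()
        perm = fit.permutation_test(n_perm=max(cfg.oplsda_permutations, 20),
                                    seed=cfg.seed)
        diff = metabolomics.differential_metabolites(
            X, labels, fit.vip(), p_cut=cfg.screen_alpha, vip_cut=cfg.vip_cutoff)
        persist("differential_metabolites", diff)
        sig = diff[diff["significant"]]
        return {
            "n_uncorrectable": len(uncorrectable), "n_removed_rsd": len(removed),
            "r2x": fit.r2x, "r2y": fit.r2y, "q2": fit.q2,
            "permutation_pass": bool(perm.passed),
            "n_significant": int(len(sig)),
            "n_up": int((sig["direction"] == "up").sum()),
            "n_down": int((sig["direction"] == "down").sum()),
        }

    @stage("integration")
    def _():
        rel = table.relative_abundance()
        taxa = rel.to_dataframe().T
        # limit to the most abundant taxa to keep the network readable
        top = taxa.mean().sort_values(ascending=False).index[:30]
        edges = spearman_matrix(taxa[top], metadata.clinical(),
                                type_a="taxon", type_b="phenotype")
        net = build_network(edges, p_max=cfg.screen_alpha)
        if out is not None:
            nodes_df, edges_df = net.to_tables()
            nodes_df.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
            edges_df.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        return {"n_edges": net.n_edges, "n_nodes": net.graph.number_of_nodes()}

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
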