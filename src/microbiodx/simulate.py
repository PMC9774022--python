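"""Synthetic cohorts with recorded ground truth.

The microbiome generator draws per-group log-normal mean abundance vectors,
plants multiplicative group effects on chosen marker OTUs, and samples reads
multinomially at a fixed depth, so every column of the count table sums to
the configured depth exactly. Clinical phenotypes are tied to chosen taxa
through a Gaussian copula so that target Spearman correlations are induced
without distorting either marginal.

The metabolome generator produces positive intensities as
baseline x group fold change x smooth injection-order drift x log-normal
noise, with pooled-QC injections interleaved through the run.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import (CLINICAL_VARS, CohortMetadata, FeatureTable, MetaboliteBatch,
                 PhyloTree, read_tree_string)

# baseline clinical marginals (mean, sd) on adult reference scales
_CLINICAL_MARGINALS: dict[str, tuple[float, float]] = {
    "HB": (130.0, 20.0), "BUN": (5.5, 2.0), "Scr": (80.0, 30.0),
    "UA": (330.0, 80.0), "ALB": (45.0, 5.0), "T-CHO": (4.5, 1.0),
    "TG": (1.5, 0.8), "HDL": (1.2, 0.3), "LDL": (2.7, 0.8),
    "eGFR": (100.0, 25.0), "24hTP": (0.8, 0.6),
}
# additive group shifts reproducing the direction of renal-disease chemistry
_GROUP_SHIFTS: dict[str, dict[str, float]] = {
    "IgAN": {"Scr": 40.0, "ALB": -7.0, "eGFR": -25.0, "24hTP": 1.0},
    "n_IgAN": {"Scr": 35.0, "ALB": -9.0, "eGFR": -22.0, "24hTP": 2.0},
}
_SUBTYPE_PROBS = {"MN": 0.65, "MCD": 0.29, "FSGS": 0.04, "MPGN": 0.02}


@dataclasses.dataclass
class CohortTruth:
    """Ground truth planted by the generators."""

    planted_marker_ids: list[str] = dataclasses.field(default_factory=list)
    effect_sizes: dict[str, dict[str, float]] = dataclasses.field(default_factory=dict)
    phenotype_links: list[tuple[str, str, float]] = dataclasses.field(default_factory=list)
    metabolite_truth: dict[str, float] = dataclasses.field(default_factory=dict)
    drift_model: dict[str, list[float]] = dataclasses.field(default_factory=dict)
    noise_cv: float = 0.0
    seed: int = 0


def _random_bifurcating_newick(names: Sequence[str], rng: np.random.Generator) -> str:
    """Random topology by sequential pair joins; exponential branch lengths."""
    nodes = [f"{n}:{rng.exponential(1.0):.6f}" for n in names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.exponential(1.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    # strip the root's branch length: the tree is rooted at the final join
    root = nodes[0]
    root = root[: root.rfind(":")]
    return root + ";"


def simulate_cohort(
    n_per_group: Mapping[str, int],
    n_features: int = 500,
    effect_size: float = 4.0,
    n_planted: int = 8,
    effect_groups: Sequence[str] | None = None,
    phenotype_links: Sequence[tuple[int, str, float]] = (),
    depth: int = 20000,
    sigma: float = 0.8,
    mu_sd: float = 1.5,
    seed: int = 0,
) -> tuple[FeatureTable, CohortMetadata, PhyloTree, CohortTruth]:
    """Simulate an OTU table, metadata, tree and truth record.

    Parameters
    ----------
    n_per_group
        Samples per group label, e.g. ``{"HC": 60, "IgAN": 60}``.
    effect_size
        Multiplicative abundance shift applied to planted OTUs in each
        group of ``effect_groups`` (default: every non-HC group). 1.0
        plants nothing.
    phenotype_links
        ``(planted_marker_index, clinical_variable, target_spearman_rho)``
        triples realised by a Gaussian copula against the marker's
        relative abundance.
    depth
        Multinomial sequencing depth per sample; column sums equal it exactly.
    sigma
        Per-sample log-normal overdispersion of relative abundances.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    for g, n in n_per_group.items():
        if n < 2:
            raise ValidationError(f"need >= 2 samples per group (got {n} for {g})")
    if n_planted > n_features:
        raise ValidationError("more planted markers than features")
    if len(phenotype_links) > n_features:
        raise ValidationError("more phenotype links than features")
    rng = np.random.default_rng(seed)

    feature_ids = [f"OTU{i + 1}" for i in range(n_features)]
    groups = list(n_per_group)
    if effect_groups is None:
        effect_groups = [g for g in groups if g != "HC"] or groups[1:]

    planted_idx = np.sort(rng.choice(n_features, size=n_planted, replace=False))
    mu = rng.normal(0.0, mu_sd, size=n_features)

    sample_ids: list[str] = []
    group_col: list[str] = []
    counts_cols: list[np.ndarray] = []
    for g in groups:
        shift = np.zeros(n_features)
        if g in effect_groups and effect_size != 1.0 and n_planted:
            shift[planted_idx] = np.log(effect_size)
        for k in range(n_per_group[g]):
            sample_ids.append(f"{g}_{k + 1}")
            group_col.append(g)
            lam = np.exp(mu + shift + rng.normal(0.0, sigma, size=n_features))
            counts_cols.append(rng.multinomial(depth, lam / lam.sum()))
    counts = np.column_stack(counts_cols).astype(float)

    phyla = ["Firmicutes", "Bacteroidota", "Proteobacteria", "Actinobacteriota"]
    genera = ["Blautia", "Bacteroides", "Escherichia-Shigella", "Faecalibacterium",
              "Prevotella", "Subdoligranulum", "Roseburia", "Bifidobacterium"]
    lineages = [
        "k__Bacteria;p__{};c__;o__;f__;g__{}".format(
            phyla[i % len(phyla)], genera[i % len(genera)])
        for i in range(n_features)
    ]
    table = FeatureTable(feature_ids, sample_ids, counts, lineages)

    tree = read_tree_string(_random_bifurcating_newick(feature_ids, rng))

    # ---- metadata with copula-linked phenotypes -----------------------
    n_total = len(sample_ids)
    group_arr = np.array(group_col)
    meta = pd.DataFrame({"sample_id": sample_ids, "group": group_col})
    meta["sex"] = rng.choice(["M", "F"], size=n_total)
    meta["age"] = np.clip(rng.normal(40, 12, size=n_total), 18, 70).round(0)
    meta["subtype"] = "none"
    n_mask = group_arr == "n_IgAN"
    if n_mask.any():
        meta.loc[n_mask, "subtype"] = rng.choice(
            list(_SUBTYPE_PROBS), size=int(n_mask.sum()), p=list(_SUBTYPE_PROBS.values())
        )

    rel = counts / counts.sum(axis=0)
    linked_vars = {}
    truth_links: list[tuple[str, str, float]] = []
    for marker_rank, var, rho_s in phenotype_links:
        if var not in _CLINICAL_MARGINALS:
            raise ValidationError(f"unknown clinical variable {var!r}")
        if abs(rho_s) > 1:
            raise ValidationError("target Spearman rho must be in [-1, 1]")
        fi = planted_idx[marker_rank] if n_planted else marker_rank
        x = rel[fi]
        # normal scores of the abundance ranks; Pearson rho that induces
        # the target Spearman under a bivariate Gaussian copula
        z_x = stats.norm.ppf((stats.rankdata(x) - 0.5) / n_total)
        rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
        z_v = rho_p * z_x + np.sqrt(1 - rho_p ** 2) * rng.normal(size=n_total)
        m, s = _CLINICAL_MARGINALS[var]
        linked_vars[var] = np.maximum(m + s * z_v, 0.01 * m)
        truth_links.append((feature_ids[fi], var, float(rho_s)))

    for var, (m, s) in _CLINICAL_MARGINALS.items():
        if var in linked_vars:
            vals = linked_vars[var]
        else:
            vals = np.maximum(m + s * rng.normal(size=n_total), 0.01 * m)
            for g, shifts in _GROUP_SHIFTS.items():
                if var in shifts:
                    vals = np.where(group_arr == g,
                                    np.maximum(vals + shifts[var], 0.01 * m), vals)
        meta[var] = np.round(vals, 2)

    metadata = CohortMetadata(meta)
    truth = CohortTruth(
        planted_marker_ids=[feature_ids[i] for i in planted_idx],
        effect_sizes={g: {feature_ids[i]: float(effect_size) for i in planted_idx}
                      for g in effect_groups},
        phenotype_links=truth_links,
        seed=seed,
    )
    return table, metadata, tree, truth


def simulate_metabolome(
    n_per_group: Mapping[str, int],
    n_qc: int = 10,
    n_metabolites: int = 50,
    n_up: int = 5,
    n_down: int = 5,
    fold_up: float = 2.0,
    fold_down: float = 0.5,
    drift_amplitude: float = 0.2,
    noise_cv: float = 0.10,
    qc_every: int = 5,
    disease_group: str = "IgAN",
    seed: int = 0,
) -> tuple[MetaboliteBatch, CohortTruth]:
    """Simulate an LC-MS batch with injection-order drift and pooled QCs.

    The QC schedule is ``3`` leading QC injections followed by one QC after
    every ``qc_every`` study injections, until ``n_qc`` QCs are placed.
    Setting ``drift_amplitude=0`` leaves only the log-normal noise, whose
    coefficient of variation is ``noise_cv`` by construction.
    """
    if n_qc < 3:
        raise ValidationError("n_qc must be >= 3")
    if n_up + n_down > n_metabolites:
        raise ValidationError("more planted metabolites than metabolites")
    rng = np.random.default_rng(seed)

    met_ids = [f"M{i + 1}" for i in range(n_metabolites)]
    baseline = np.exp(rng.normal(10.0, 1.0, size=n_metabolites))
    fold = np.ones(n_metabolites)
    up_idx = np.arange(n_up)
    down_idx = np.arange(n_up, n_up + n_down)
    fold[up_idx] = fold_up
    fold[down_idx] = fold_down

    # smooth multiplicative drift: linear + sinusoidal term per metabolite
    lin = rng.normal(0.0, 1.0, size=n_metabolites)
    amp = rng.uniform(0.5, 1.0, size=n_metabolites)
    phase = rng.uniform(0, 2 * np.pi, size=n_metabolites)

    study_ids, study_groups = [], []
    for g, n in n_per_group.items():
        study_ids += [f"{g}_s{k + 1}" for k in range(n)]
        study_groups += [g] * n
    order = rng.permutation(len(study_ids))
    study_ids = [study_ids[i] for i in order]
    study_groups = [study_groups[i] for i in order]

    # interleave QCs: 3 leading, then one after every qc_every study samples
    seq: list[tuple[str, str]] = [("QC", f"QC_{i + 1}") for i in range(min(3, n_qc))]
    qc_used = len(seq)
    since = 0
    for sid, g in zip(study_ids, study_groups):
        seq.append(("study", sid))
        since += 1
        if since == qc_every and qc_used < n_qc:
            qc_used += 1
            seq.append(("QC", f"QC_{qc_used}"))
            since = 0
    while qc_used < n_qc:  # trailing QCs if the schedule did not place them all
        qc_used += 1
        seq.append(("QC", f"QC_{qc_used}"))

    n_inj = len(seq)
    t = np.arange(1, n_inj + 1)
    tn = (t - 1) / max(n_inj - 1, 1)
    drift = np.empty((n_inj, n_metabolites))
    for j in range(n_metabolites):
        f = lin[j] * (2 * tn - 1) + np.sin(2 * np.pi * tn + phase[j])
        drift[:, j] = np.exp(drift_amplitude * amp[j] * f / 2.0)

    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    group_of = dict(zip(study_ids, study_groups))
    inten = np.empty((n_inj, n_metabolites))
    stypes, groups_col, ids = [], [], []
    for i, (stype, sid) in enumerate(seq):
        base = baseline.copy()
        if stype == "study" and group_of[sid] == disease_group:
            base = base * fold
        noise = np.exp(rng.normal(0.0, sigma, size=n_metabolites) - sigma ** 2 / 2)
        inten[i] = base * drift[i] * noise
        stypes.append(stype)
        groups_col.append("" if stype == "QC" else group_of[sid])
        ids.append(sid)

    batch = MetaboliteBatch(ids, met_ids, inten, t, np.array(stypes, object),
                            np.array(groups_col, object))
    truth = CohortTruth(
        metabolite_truth={met_ids[i]: float(fold[i])
                          for i in np.concatenate([up_idx, down_idx])},
        drift_model={met_ids[j]: [float(drift_amplitude), float(amp[j]),
                                  float(lin[j]), float(phase[j])]
                     for j in range(n_metabolites)},
        noise_cv=float(noise_cv),
        seed=seed,
    )
    return batch, truth
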