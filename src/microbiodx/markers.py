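"""Random-forest marker selection and the probability-of-disease (POD) index.

Workflow (all selection steps see training samples only):

1. stratified 2:1 cohort split,
2. Wilcoxon rank-sum screen of features at p < alpha,
3. candidates ranked by forest importance; nested subsets of increasing
   size scored by stratified k-fold cross-validated misclassification;
   the optimal size is the smallest whose error falls below
   (minimum error + SD of the fold errors at the minimum),
4. a random forest on the selected markers; POD = fraction of trees voting
   the disease class, evaluated by ROC/AUC on each phase.

POD is the positive-vote fraction rather than a ratio of disease to
control votes: the ratio is undefined when no tree votes control, and any
strictly monotone transform of the votes leaves the ROC curve and AUC
unchanged.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .io import CohortMetadata, FeatureTable, RunConfig

# ---------------------------------------------------------------------------
# cohort splitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Partition:
    train_ids: list[str]
    test_ids: list[str]
    per_group_train: dict[str, int]
    per_group_test: dict[str, int]
    ratio: str
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValidationError("train and test sets overlap")


def split_cohort(metadata: CohortMetadata, ratio: str = "2:1", seed: int = 0,
                 groups: Sequence[str] | None = None) -> Partition:
    """Stratified random train/test split at the given ratio.

    Per group, the training size is ceil(r1/(r1+r2) * n); e.g. 150:117 at
    2:1 gives 100+78 training and 50+39 test samples.
    """
    cfg = RunConfig(split_ratio=ratio)
    r1, r2 = cfg.ratio_parts()
    frac = r1 / (r1 + r2)
    df = metadata.frame
    if groups is not None:
        df = df[df["group"].isin(groups)]
    rng = np.random.default_rng(seed)
    train, test = [], []
    per_train, per_test = {}, {}
    for g, sub in df.groupby("group", sort=True):
        ids = sub["sample_id"].tolist()
        if len(ids) < 2:
            raise ValidationError(f"group {g} has fewer than 2 samples")
        n_train = math.ceil(frac * len(ids))
        perm = rng.permutation(len(ids))
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
        per_train[g] = n_train
        per_test[g] = len(ids) - n_train
    return Partition(train, test, per_train, per_test, ratio, seed)


# ---------------------------------------------------------------------------
# screening and selection
# ---------------------------------------------------------------------------

def wilcoxon_screen(table: FeatureTable, labels: Mapping[str, str] | pd.Series,
                    alpha: float = 0.05) -> list[str]:
    """Features with two-sided rank-sum p < alpha, ordered by p.

    An empty return is the documented flag that selection cannot proceed.
    """
    from .community import diff_abundance

    labels = pd.Series(labels).reindex(table.sample_ids)
    if labels.nunique() != 2:
        raise ValidationError("screen requires exactly 2 groups")
    res = diff_abundance(table, labels)
    passed = res[(res["p"] < alpha) & ~res["degenerate"]].sort_values("p")
    return passed.index.tolist()


@dataclasses.dataclass
class ErrorCurve:
    sizes: list[int]
    errors: list[float]
    sds: list[float]
    cutoff: float
    chosen_size: int

    def __post_init__(self) -> None:
        argmin = int(np.argmin(self.errors))
        expect = self.errors[argmin] + self.sds[argmin]
        if not np.isclose(self.cutoff, expect):
            raise ValidationError("cutoff must equal min(error) + SD at argmin")
        below = [s for s, e in zip(self.sizes, self.errors) if e <= self.cutoff]
        if not below or self.chosen_size != min(below):
            raise ValidationError("chosen size must be the smallest below cutoff")
        if self.chosen_size > self.sizes[argmin]:
            raise ValidationError("chosen size exceeds argmin size")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "cv_error": self.errors,
                             "sd": self.sds})


def apply_error_rule(sizes: Sequence[int], errors: Sequence[float],
                     sds: Sequence[float]) -> ErrorCurve:
    """Minimum-error-plus-SD rule: pick the smallest subset whose CV error
    does not exceed the minimum error plus its fold-SD."""
    errors = list(map(float, errors))
    sds = list(map(float, sds))
    argmin = int(np.argmin(errors))
    cutoff = errors[argmin] + sds[argmin]
    chosen = min(s for s, e in zip(sizes, errors) if e <= cutoff)
    return ErrorCurve(list(sizes), errors, sds, cutoff, chosen)


def _candidate_sizes(n: int, dense_to: int = 30, step: float = 1.3) -> list[int]:
    sizes = list(range(1, min(dense_to, n) + 1))
    s = float(sizes[-1])
    while sizes[-1] < n:
        s *= step
        sizes.append(min(int(math.ceil(s)), n))
    return sorted(set(sizes))


def rank_candidates(table: FeatureTable, y: np.ndarray, candidates: list[str],
                    seed: int, n_refits: int = 5, n_trees: int = 200) -> list[str]:
    """Candidates ordered by mean-decrease-impurity importance, averaged
    over several forest refits to stabilize the ordering."""
    X = table.select_features(candidates).counts.T
    imp = np.zeros(len(candidates))
    for r in range(n_refits):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + r,
                                    n_jobs=1)
        rf.fit(X, y)
        imp += rf.feature_importances_
    order = np.argsort(-imp, kind="stable")
    return [candidates[i] for i in order]


def select_markers(table: FeatureTable, labels: Mapping[str, str] | pd.Series,
                   candidates: list[str], folds: int = 5, seed: int = 0,
                   n_trees: int = 200) -> tuple[ErrorCurve, list[str]]:
    """Cross-validated nested-subset selection over ranked candidates."""
    if not candidates:
        raise ValidationError("empty candidate set: screening flagged no features")
    labels = pd.Series(labels).reindex(table.sample_ids)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if len(table.sample_ids) < folds:
        raise ValidationError("fewer samples than folds")
    classes = sorted(labels.unique())
    y = (labels == classes[-1]).to_numpy().astype(int)
    ranked = rank_candidates(table, y, candidates, seed, n_trees=n_trees)
    sizes = _candidate_sizes(len(ranked))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    X_full = table.select_features(ranked).counts.T
    errors, sds = [], []
    for size in sizes:
        X = X_full[:, :size]
        fold_err = []
        for f, (tr, te) in enumerate(splits):
            rf = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=seed + 1000 + f, n_jobs=1)
            rf.fit(X[tr], y[tr])
            fold_err.append(float((rf.predict(X[te]) != y[te]).mean()))
        errors.append(float(np.mean(fold_err)))
        sds.append(float(np.std(fold_err, ddof=1)))
    curve = apply_error_rule(sizes, errors, sds)
    return curve, ranked[: curve.chosen_size]


# ---------------------------------------------------------------------------
# classifier, POD, ROC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MarkerModel:
    markers: list[str]
    forest: RandomForestClassifier
    positive_class: str
    classes: list[str]
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)


def fit_classifier(table: FeatureTable, labels: Mapping[str, str] | pd.Series,
                   markers: list[str], seed: int = 0, positive_class: str | None = None,
                   n_trees: int = 500) -> MarkerModel:
    """Random forest restricted to the selected marker features."""
    if not markers:
        raise ValidationError("marker set is empty")
    labels = pd.Series(labels).reindex(table.sample_ids)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValidationError("binary classifier requires exactly 2 classes")
    if positive_class is None:
        positive_class = classes[-1]
    if positive_class not in classes:
        raise ValidationError(f"positive class {positive_class!r} not in labels")
    X = table.select_features(markers).counts.T
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                oob_score=True, n_jobs=1)
    rf.fit(X, (labels == positive_class).to_numpy().astype(int))
    return MarkerModel(markers, rf, positive_class, classes, seed)


@dataclasses.dataclass
class PodResult:
    sample_ids: list[str]
    pod: np.ndarray
    positive_class: str
    n_trees: int

    def __post_init__(self) -> None:
        self.pod = np.asarray(self.pod, dtype=float)
        if ((self.pod < 0) | (self.pod > 1)).any():
            raise ValidationError("POD values must lie in [0, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.pod, index=self.sample_ids, name="POD")


def pod_index(model: MarkerModel, table: FeatureTable) -> PodResult:
    """Probability-of-disease: fraction of forest trees voting the disease
    class for each sample."""
    X = table.select_features(model.markers).counts.T
    votes = np.zeros(X.shape[0])
    for est in model.forest.estimators_:
        votes += est.predict(X)
    pod = votes / model.n_trees
    return PodResult(list(table.sample_ids), pod, model.positive_class,
                     model.n_trees)


@dataclasses.dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError("AUC out of [0, 1]")


def auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via the U identity with half-credit ties: U / (n1 * n2)."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def roc_auc(scores: np.ndarray | PodResult, labels: Mapping[str, str] | pd.Series,
            positive_class: str | None = None, n_boot: int = 1000,
            seed: int = 0) -> RocResult:
    """Empirical ROC with trapezoid AUC, percentile-bootstrap CI, and a
    two-sided Mann-Whitney p-value against AUC = 0.5."""
    if isinstance(scores, PodResult):
        if positive_class is None:
            positive_class = scores.positive_class
        s = pd.Series(scores.pod, index=scores.sample_ids)
    else:
        s = pd.Series(np.asarray(scores, float))
        if not isinstance(labels, pd.Series):
            labels = pd.Series(list(labels))
        labels = labels.reset_index(drop=True) if len(labels) == len(s) else labels
    lab = pd.Series(labels)
    if isinstance(scores, PodResult):
        lab = lab.reindex(scores.sample_ids)
    if lab.nunique() != 2:
        raise ValidationError("ROC requires both classes present")
    if positive_class is None:
        positive_class = sorted(lab.unique())[-1]
    y = (lab.to_numpy() == positive_class).astype(int)
    x = s.to_numpy(float)
    fpr, tpr, thr = roc_curve(y, x)
    auc = float(np.trapezoid(tpr, fpr))
    pos, neg = x[y == 1], x[y == 0]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, len(pos), replace=True)
        bn = rng.choice(neg, len(neg), replace=True)
        boots[b] = auc_mann_whitney(bp, bn)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    return RocResult(fpr, tpr, thr, auc, float(min(ci_low, auc)),
                     float(max(ci_high, auc)), p, n_boot)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DiagnosticResults:
    """Fitted diagnostic pipeline: selected markers, POD and ROC per phase."""

    partition: Partition
    candidates: list[str]
    error_curve: ErrorCurve
    markers: list[str]
    model: MarkerModel
    pod: dict[str, PodResult]
    roc: dict[str, RocResult]
    positive_class: str

    def summary(self) -> str:
        lines = [
            "Microbiome diagnostic model",
            "=" * 40,
            f"positive class:      {self.positive_class}",
            f"screen survivors:    {len(self.candidates)}",
            f"selected markers:    {len(self.markers)} "
            f"(cutoff {self.error_curve.cutoff:.4f})",
            f"  {', '.join(self.markers)}",
        ]
        for phase, roc in self.roc.items():
            lines.append(
                f"{phase:12s} AUC = {roc.auc:.4f} "
                f"[{roc.ci_low:.4f}, {roc.ci_high:.4f}]  p = {roc.p_value:.3g}"
            )
        return "\n".join(lines)

    def to_report(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "n_candidates": len(self.candidates),
            "markers": list(self.markers),
            "error_curve": {
                "sizes": self.error_curve.sizes,
                "errors": self.error_curve.errors,
                "sds": self.error_curve.sds,
                "cutoff": self.error_curve.cutoff,
                "chosen_size": self.error_curve.chosen_size,
            },
            "auc": {phase: {"auc": r.auc, "ci": [r.ci_low, r.ci_high],
                            "p_value": r.p_value}
                    for phase, r in self.roc.items()},
            "partition": {"train": self.partition.per_group_train,
                          "test": self.partition.per_group_test},
        }


class MicrobiomeDiagnostic:
    """Random-forest diagnostic model over an OTU table and cohort labels.

    Parameters
    ----------
    table, metadata
        Cohort-wide feature table and metadata; samples of the two
        ``groups`` are used, others ignored.
    groups
        (control, disease) labels; the second is the POD-positive class.
    config
        Pipeline constants; ``screen_alpha``, ``cv_folds``, ``split_ratio``,
        ``n_trees`` and ``cv_trees`` are honoured here.
    """

    def __init__(self, table: FeatureTable, metadata: CohortMetadata,
                 groups: tuple[str, str] = ("HC", "IgAN"),
                 config: RunConfig | None = None, relative: bool = True):
        self.config = config or RunConfig()
        self.groups = groups
        keep = metadata.samples_in(*groups)
        if not keep:
            raise ValidationError(f"no samples in groups {groups}")
        self.table = table.select_samples(keep)
        if relative:
            self.table = self.table.relative_abundance()
        self.labels = metadata.group.loc[keep]
        self.metadata = metadata

    def fit(self, seed: int | None = None,
            independent: tuple[FeatureTable, pd.Series] | None = None
            ) -> DiagnosticResults:
        """Split, screen, select, fit, and evaluate POD/ROC per phase."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        part = split_cohort(self.metadata, cfg.split_ratio, seed, groups=self.groups)
        train_tab = self.table.select_samples(part.train_ids)
        train_lab = self.labels.loc[part.train_ids]
        candidates = wilcoxon_screen(train_tab, train_lab, cfg.screen_alpha)
        if not candidates:
            raise ValidationError("screen returned no candidates; cannot select markers")
        curve, markers = select_markers(train_tab, train_lab, candidates,
                                        folds=cfg.cv_folds, seed=seed,
                                        n_trees=cfg.cv_trees)
        model = fit_classifier(train_tab, train_lab, markers, seed=seed,
                               positive_class=self.groups[1], n_trees=cfg.n_trees)
        phases: dict[str, tuple[FeatureTable, pd.Series]] = {
            "train": (train_tab, train_lab),
            "test": (self.table.select_samples(part.test_ids),
                     self.labels.loc[part.test_ids]),
        }
        if independent is not None:
            ind_tab, ind_lab = independent
            phases["independent"] = (ind_tab.relative_abundance()
                                     if not np.allclose(ind_tab.counts.sum(0), 1)
                                     else ind_tab, pd.Series(ind_lab))
        pod, roc = {}, {}
        for phase, (tab, lab) in phases.items():
            p = pod_index(model, tab)
            pod[phase] = p
            roc[phase] = roc_auc(p, lab, positive_class=self.groups[1], seed=seed)
        return DiagnosticResults(part, candidates, curve, markers, model,
                                 pod, roc, self.groups[1])


def run_diagnostic_pipeline(table: FeatureTable, metadata: CohortMetadata,
                            config: RunConfig | None = None,
                            groups: tuple[str, str] = ("HC", "IgAN"),
                            seed: int | None = None,
                            independent: tuple[FeatureTable, pd.Series] | None = None
                            ) -> DiagnosticResults:
    """Functional wrapper over :class:`MicrobiomeDiagnostic`."""
    return MicrobiomeDiagnostic(table, metadata, groups, config).fit(
        seed=seed, independent=independent)
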