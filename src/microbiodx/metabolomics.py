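"""Untargeted-metabolomics processing: QC-RLSC drift correction, RSD
filtering, scaling, PCA, OPLS-DA with VIP and permutation validation, and
differential-metabolite calls.

OPLS-DA follows the single-response orthogonal-projection scheme: response-
orthogonal variation is removed from X by ``n_orthogonal`` filtering
components before one predictive component is fitted, so the predictive
score carries all class-correlated variance and the orthogonal scores are
exactly uncorrelated with the response. Model quality is summarised by
R2X/R2Y (fitted variance) and Q2 (k-fold cross-validated prediction of the
class response).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .community import Ordination, _rank_test
from .errors import StateError, ValidationError
from .io import MetaboliteBatch

# ---------------------------------------------------------------------------
# QC-RLSC and RSD filtering
# ---------------------------------------------------------------------------

def qc_rlsc(batch: MetaboliteBatch, span: float = 0.75,
            robust_iters: int = 3) -> tuple[MetaboliteBatch, list[str]]:
    """QC-based robust LOESS signal correction.

    Per metabolite, a degree-1 LOESS curve (tricube weights, ``span``
    fraction of QC points, ``robust_iters`` robustifying iterations) is fit
    to the QC intensities against injection order; every injection is
    divided by the curve value at its own order (linearly interpolated,
    clamped at the QC boundary) and rescaled by the QC median. Metabolites
    whose curve dips to <= 0 are left uncorrected and reported.
    """
    qc = batch.qc_mask
    if qc.sum() < 3:
        raise ValidationError("QC-RLSC requires >= 3 QC injections")
    order = batch.injection_order.astype(float)
    qc_order = order[qc]
    corrected = batch.intensities.copy()
    uncorrectable: list[str] = []
    for j, mid in enumerate(batch.metabolite_ids):
        qc_y = batch.intensities[qc, j]
        fit = lowess(qc_y, qc_order, frac=span, it=robust_iters,
                     return_sorted=True)
        curve = np.interp(order, fit[:, 0], fit[:, 1])
        if (curve <= 0).any():
            uncorrectable.append(mid)
            continue
        corrected[:, j] = batch.intensities[:, j] / curve * np.median(qc_y)
    return batch.replace(intensities=corrected), uncorrectable


def qc_rsd(batch: MetaboliteBatch) -> pd.Series:
    """Relative standard deviation (percent) of each metabolite over QCs."""
    qc = batch.qc_mask
    if not qc.any():
        raise ValidationError("no QC injections present")
    q = batch.intensities[qc]
    return pd.Series(100.0 * q.std(axis=0, ddof=1) / q.mean(axis=0),
                     index=batch.metabolite_ids, name="rsd_percent")


def rsd_filter(batch: MetaboliteBatch, threshold: float = 30.0
               ) -> tuple[MetaboliteBatch, list[str]]:
    """Drop metabolites whose QC RSD is >= ``threshold`` percent."""
    rsd = qc_rsd(batch)
    keep = rsd[rsd < threshold].index.tolist()
    removed = rsd[rsd >= threshold].index.tolist()
    idx = [batch.metabolite_ids.index(m) for m in keep]
    return batch.replace(metabolite_ids=keep,
                         intensities=batch.intensities[:, idx]), removed


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

class Scaler:
    """Column-wise centering / unit-variance / Pareto scaling with inverse.

    Zero-variance columns under variance-based modes are centered only and
    listed in ``flagged``.
    """

    MODES = ("center", "unit", "pareto")

    def __init__(self, mode: str = "unit"):
        if mode not in self.MODES:
            raise ValidationError(f"mode must be one of {self.MODES}")
        self.mode = mode
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self.flagged: list[int] = []

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.flagged = np.flatnonzero(sd == 0).tolist()
        if self.mode == "center":
            self.scale_ = np.ones_like(sd)
        else:
            s = sd if self.mode == "unit" else np.sqrt(sd)
            s = np.where(s == 0, 1.0, s)
            self.scale_ = s
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise StateError("Scaler not fitted")
        return (np.asarray(X, float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise StateError("Scaler not fitted")
        return np.asarray(Z, float) * self.scale_ + self.mean_


def scale_features(X: np.ndarray, mode: str = "unit") -> tuple[np.ndarray, Scaler]:
    scaler = Scaler(mode)
    return scaler.fit_transform(X), scaler


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(X: np.ndarray, k: int = 2,
            sample_ids: Sequence[str] | None = None) -> Ordination:
    """Centered SVD principal components with explained-variance fractions."""
    X = np.asarray(X, float)
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > min(X.shape):
        raise ValidationError(f"k={k} exceeds min dimension of {X.shape}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    tot = (s ** 2).sum()
    explained = (s[:k] ** 2) / tot if tot > 0 else np.zeros(k)
    idx = list(sample_ids) if sample_ids is not None else list(range(X.shape[0]))
    coords = pd.DataFrame(scores, index=idx,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return Ordination("PCA", coords, s ** 2, explained)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def _opls_fit_core(X: np.ndarray, y: np.ndarray, n_orth: int):
    """Orthogonal filtering + one predictive component on centered data.

    Returns (t, w, p_load, q, T_orth, W_orth, P_orth, X_filtered).
    """
    Xd = X.copy()
    w = Xd.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValidationError("response carries no signal in X")
    w = w / nw
    T_o, W_o, P_o = [], [], []
    for _ in range(n_orth):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o /= n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        T_o.append(t_o)
        W_o.append(w_o)
        P_o.append(p_o)
    t = Xd @ w
    p_load = Xd.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    return t, w, p_load, q, T_o, W_o, P_o, Xd


@dataclasses.dataclass
class OPLSDAResults:
    """Fitted OPLS-DA model with quality statistics and VIP access."""

    r2x: float
    r2y: float
    q2: float
    scores: np.ndarray            # predictive component, one per sample
    orthogonal_scores: np.ndarray  # samples x n_orth (may be empty)
    weights: np.ndarray           # unit-norm predictive weights
    loadings: np.ndarray
    q_loading: float
    y_mean: float
    classes: list[str]
    scaler: Scaler
    orth_weights: np.ndarray
    orth_loadings: np.ndarray
    n_orthogonal: int
    cv_folds: int
    seed: int
    model: "OPLSDA"

    def vip(self) -> pd.Series:
        """Variable importance on projection for the predictive component.

        Normalized so that the mean squared VIP is exactly 1.
        """
        p = len(self.weights)
        v = np.sqrt(p * self.weights ** 2 / (self.weights ** 2).sum())
        ids = self.model.metabolite_ids
        return pd.Series(v, index=ids, name="VIP")

    def predict_scores(self, X_raw: np.ndarray) -> np.ndarray:
        """Predictive scores for new samples (same correction applied)."""
        Z = self.scaler.transform(X_raw)
        for k in range(self.orth_weights.shape[1]):
            t_o = Z @ self.orth_weights[:, k]
            Z = Z - np.outer(t_o, self.orth_loadings[:, k])
        return Z @ self.weights

    def predict_response(self, X_raw: np.ndarray) -> np.ndarray:
        return self.predict_scores(X_raw) * self.q_loading + self.y_mean

    def permutation_test(self, n_perm: int = 200, seed: int = 0
                         ) -> "PermutationResult":
        return permutation_test(self.model.X_raw, self.model.labels, self,
                                n_perm=n_perm, seed=seed)

    def summary(self) -> str:
        return "\n".join([
            "OPLS-DA",
            "=" * 40,
            f"classes:       {self.classes[0]} vs {self.classes[1]}",
            f"components:    1 predictive + {self.orthogonal_scores.shape[1]} orthogonal",
            f"R2X(cum) = {self.r2x:.4f}   R2Y(cum) = {self.r2y:.4f}   "
            f"Q2(cum) = {self.q2:.4f}",
        ])


class OPLSDA:
    """Orthogonal PLS discriminant model for a two-class metabolite matrix.

    Parameters
    ----------
    X
        samples x metabolites intensity matrix (corrected, unscaled).
    labels
        Two class labels, one per sample; the lexicographically larger
        label is coded 1.
    n_orthogonal
        Number of response-orthogonal filtering components (default 1).
    scale
        ``unit`` (default), ``center`` or ``pareto`` column scaling.
    cv_folds
        Folds for the cross-validated Q2 (default 7).
    """

    def __init__(self, X: np.ndarray, labels: Sequence[str],
                 n_orthogonal: int = 1, scale: str = "unit",
                 cv_folds: int = 7, seed: int = 0,
                 metabolite_ids: Sequence[str] | None = None):
        X = np.asarray(X, float)
        labels = np.asarray(labels, object)
        classes = sorted(set(labels))
        if len(classes) != 2:
            raise ValidationError("OPLS-DA requires exactly 2 classes")
        counts = [(labels == c).sum() for c in classes]
        if min(counts) < 3:
            raise ValidationError("each class needs >= 3 samples")
        self.X_raw = X
        self.labels = labels
        self.classes = classes
        self.n_orthogonal = int(n_orthogonal)
        self.scale_mode = scale
        self.cv_folds = int(cv_folds)
        self.seed = int(seed)
        self.metabolite_ids = (list(metabolite_ids) if metabolite_ids is not None
                               else [f"var{i + 1}" for i in range(X.shape[1])])

    @classmethod
    def from_batch(cls, batch: MetaboliteBatch, **kw) -> "OPLSDA":
        X, groups = batch.study_labels()
        return cls(X, groups, metabolite_ids=batch.metabolite_ids, **kw)

    def fit(self) -> OPLSDAResults:
        scaler = Scaler(self.scale_mode)
        Z = scaler.fit_transform(self.X_raw)
        y01 = (self.labels == self.classes[1]).astype(float)
        y = y01 - y01.mean()
        ss_x = (Z ** 2).sum()
        ss_y = (y ** 2).sum()
        t, w, p_load, q, T_o, W_o, P_o, _ = _opls_fit_core(Z, y, self.n_orthogonal)
        modelled = np.outer(t, p_load)
        for t_o, p_o in zip(T_o, P_o):
            modelled += np.outer(t_o, p_o)
        r2x = float((modelled ** 2).sum() / ss_x) if ss_x > 0 else 0.0
        r2y = float(1.0 - ((y - t * q) ** 2).sum() / ss_y)
        q2 = self._q2(Z, y, ss_y)
        T_orth = (np.column_stack(T_o) if T_o else np.zeros((len(y), 0)))
        W_orth = (np.column_stack(W_o) if W_o else np.zeros((Z.shape[1], 0)))
        P_orth = (np.column_stack(P_o) if P_o else np.zeros((Z.shape[1], 0)))
        return OPLSDAResults(
            r2x=r2x, r2y=r2y, q2=q2, scores=t, orthogonal_scores=T_orth,
            weights=w, loadings=p_load, q_loading=q, y_mean=float(y01.mean()),
            classes=self.classes, scaler=scaler, orth_weights=W_orth,
            orth_loadings=P_orth, n_orthogonal=self.n_orthogonal,
            cv_folds=self.cv_folds, seed=self.seed, model=self,
        )

    def _q2(self, Z: np.ndarray, y: np.ndarray, ss_y: float) -> float:
        """k-fold cross-validated predictive ability of the class response."""
        n = len(y)
        folds = min(self.cv_folds, n)
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(n)
        assignments = np.array_split(order, folds)
        press = 0.0
        for test_idx in assignments:
            mask = np.ones(n, bool)
            mask[test_idx] = False
            Zt, yt = Z[mask], y[mask]
            yt_c = yt - yt.mean()
            try:
                t, w, p_load, q, T_o, W_o, P_o, _ = _opls_fit_core(
                    Zt - Zt.mean(axis=0), yt_c, self.n_orthogonal)
            except ValidationError:
                press += (y[test_idx] ** 2).sum()
                continue
            Znew = Z[test_idx] - Zt.mean(axis=0)
            for k in range(len(W_o)):
                t_o = Znew @ W_o[k]
                Znew = Znew - np.outer(t_o, P_o[k])
            y_hat = (Znew @ w) * q + yt.mean()
            press += ((y[test_idx] - y_hat) ** 2).sum()
        return float(1.0 - press / ss_y)


def fit_oplsda(X: np.ndarray, labels: Sequence[str], n_orthogonal: int = 1,
               cv_folds: int = 7, seed: int = 0, scale: str = "unit",
               metabolite_ids: Sequence[str] | None = None) -> OPLSDAResults:
    """Functional wrapper over :class:`OPLSDA`."""
    return OPLSDA(X, labels, n_orthogonal=n_orthogonal, scale=scale,
                  cv_folds=cv_folds, seed=seed,
                  metabolite_ids=metabolite_ids).fit()


def vip(results: OPLSDAResults) -> pd.Series:
    if not isinstance(results, OPLSDAResults):
        raise StateError("vip() requires a fitted OPLS-DA model")
    return results.vip()


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PermutationResult:
    n_permutations: int
    permuted_r2: np.ndarray
    permuted_q2: np.ndarray
    label_correlations: np.ndarray
    r2_intercept: float
    q2_intercept: float
    observed_r2: float
    observed_q2: float
    passed: bool


def permutation_test(X: np.ndarray, labels: Sequence[str],
                     results: OPLSDAResults, n_perm: int = 200,
                     seed: int = 0) -> PermutationResult:
    """Label-permutation overfitting check for an OPLS-DA model.

    Labels are permuted ``n_perm`` times (permutations identical to the
    original are discarded), the model refit, and lines are regressed
    through (|label correlation|, R2) and (|label correlation|, Q2)
    including the unpermuted point at correlation 1. The model passes when
    both y-axis intercepts fall below both the unpermuted R2 and Q2; since
    Q2 <= R2Y on any fit, this means both intercepts must undercut the
    cross-validated Q2, which is what rules out overfitted models whose
    permuted fits retain high apparent R2.
    """
    if n_perm < 20:
        raise ValidationError("n_perm must be >= 20")
    labels = np.asarray(labels, object)
    y01 = (labels == results.classes[1]).astype(float)
    rng = np.random.default_rng(seed)
    r2s, q2s, cors = [], [], []
    attempts = 0
    while len(r2s) < n_perm and attempts < 20 * n_perm:
        attempts += 1
        perm = rng.permutation(len(labels))
        if np.array_equal(labels[perm], labels):
            continue  # degenerate permutation: excluded from the null set
        lab_p = labels[perm]
        try:
            res_p = OPLSDA(X, lab_p, n_orthogonal=results.n_orthogonal,
                           scale=results.scaler.mode, cv_folds=results.cv_folds,
                           seed=seed).fit()
        except ValidationError:
            continue
        yp = (lab_p == results.classes[1]).astype(float)
        c = abs(np.corrcoef(y01, yp)[0, 1]) if y01.std() > 0 else 0.0
        r2s.append(res_p.r2y)
        q2s.append(res_p.q2)
        cors.append(c)
    r2s, q2s, cors = map(np.asarray, (r2s, q2s, cors))
    # include the unpermuted model at correlation 1 (standard validation plot)
    cx = np.append(cors, 1.0)
    r2_fit = np.polyfit(cx, np.append(r2s, results.r2y), 1)
    q2_fit = np.polyfit(cx, np.append(q2s, results.q2), 1)
    r2_int, q2_int = float(r2_fit[1]), float(q2_fit[1])
    floor = min(results.r2y, results.q2)
    passed = (r2_int < floor) and (q2_int < floor)
    return PermutationResult(len(r2s), r2s, q2s, cors, r2_int, q2_int,
                             results.r2y, results.q2, passed)


# ---------------------------------------------------------------------------
# differential metabolites
# ---------------------------------------------------------------------------

def differential_metabolites(X: np.ndarray, labels: Sequence[str],
                             vip_scores: pd.Series,
                             disease_class: str | None = None,
                             p_cut: float = 0.05, vip_cut: float = 1.0,
                             metabolite_ids: Sequence[str] | None = None
                             ) -> pd.DataFrame:
    """Per-metabolite rank-test p, fold change and VIP with the combined
    significance call.

    Fold change = disease mean / control mean on corrected, unscaled
    intensities. The full table is returned (for volcano plotting); the
    ``significant`` column marks p < ``p_cut`` and VIP > ``vip_cut``.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels, object)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValidationError("two classes required")
    if disease_class is None:
        disease_class = classes[1]
    ids = (list(metabolite_ids) if metabolite_ids is not None
           else list(vip_scores.index))
    dis = labels == disease_class
    rows = []
    for j, mid in enumerate(ids):
        vals = X[:, j]
        _, _, p = _rank_test([vals[~dis], vals[dis]])
        mc, md = vals[~dis].mean(), vals[dis].mean()
        fc = md / mc if mc > 0 else np.inf
        rows.append({
            "metabolite_id": mid, "p": p,
            "fold_change": fc,
            "log2_fc": np.log2(fc) if np.isfinite(fc) and fc > 0 else np.nan,
            "vip": float(vip_scores.get(mid, np.nan)),
        })
    out = pd.DataFrame(rows).set_index("metabolite_id")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["direction"] = np.where(out["log2_fc"] > 0, "up",
                                np.where(out["log2_fc"] < 0, "down", "none"))
    out["significant"] = (out["p"] < p_cut) & (out["vip"] > vip_cut) \
        & np.isfinite(out["fold_change"])
    return out
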