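"""Core data model and file I/O for the diagnostic pipeline.

All tabular containers keep an explicit orientation: feature tables are
features x samples both on disk and in memory; metabolite batches are
samples x metabolites (one CSV row per injection). Identifier matching
across containers is strict set equality with a diff in the error message.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
import yaml

from .errors import FormatError, ValidationError

GROUPS = ("HC", "IgAN", "n_IgAN")
SUBTYPES = ("MN", "MCD", "FSGS", "MPGN", "none")
CLINICAL_VARS = (
    "HB", "BUN", "Scr", "UA", "ALB", "T-CHO", "TG", "HDL", "LDL", "eGFR", "24hTP",
)
#: canonical rank order used for positional lineage parsing
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = {"k": 0, "d": 0, "p": 1, "c": 2, "o": 3, "f": 4, "g": 5, "s": 6}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dupes[:5]}")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a Silva/QIIME-style lineage string into rank -> label.

    Fragments may carry rank prefixes (``g__Blautia``, ``D_5__Blautia``);
    unprefixed fragments are assigned positionally kingdom -> species.
    """
    out: dict[str, str] = {}
    pos = 0
    for frag in str(lineage).split(";"):
        frag = frag.strip()
        if not frag:
            pos += 1
            continue
        idx = None
        if "__" in frag:
            prefix, _, label = frag.partition("__")
            prefix = prefix.strip().lower()
            if prefix.startswith("d_") and prefix[2:].isdigit():
                idx = int(prefix[2:])
            elif prefix[:1] in _RANK_PREFIXES:
                idx = _RANK_PREFIXES[prefix[:1]]
            frag = label.strip()
        if idx is None:
            idx = pos
        if idx < len(RANKS) and frag:
            out[RANKS[idx]] = frag
        pos = idx + 1
    return out


@dataclasses.dataclass
class FeatureTable:
    """Counts (or abundances) of taxonomic features per sample.

    ``counts`` is features x samples, nonnegative. ``lineages`` is required
    when ``rank_level == "OTU"``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lineages: list[str] | None = None
    rank_level: str = "OTU"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")
        if self.rank_level == "OTU" and self.lineages is not None:
            if len(self.lineages) != len(self.feature_ids):
                raise ValidationError("one lineage required per feature")

    # -- convenience ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def is_integer(self) -> bool:
        return bool(np.all(self.counts == np.round(self.counts)))

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(
            self.feature_ids, list(sample_ids), self.counts[:, idx],
            self.lineages, self.rank_level,
        )

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise ValidationError(f"features not in table: {missing[:5]}")
        idx = [pos[f] for f in feature_ids]
        lin = [self.lineages[i] for i in idx] if self.lineages is not None else None
        return FeatureTable(list(feature_ids), self.sample_ids, self.counts[idx],
                            lin, self.rank_level)

    def relative_abundance(self) -> "FeatureTable":
        """Total-sum scaling: each sample column sums to 1."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValidationError(f"all-zero samples cannot be normalized: {bad[:5]}")
        return FeatureTable(self.feature_ids, self.sample_ids, self.counts / totals,
                            self.lineages, self.rank_level)


@dataclasses.dataclass
class CohortMetadata:
    """Per-sample group labels, demographics and clinical chemistry.

    Clinical values may be missing (NaN); they are never imputed and are
    excluded pairwise by downstream correlation code.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("sample_id", "group"):
            if col not in df.columns:
                raise FormatError(f"metadata requires a '{col}' column")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"].tolist(), "sample")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        if "subtype" not in df.columns:
            df["subtype"] = "none"
        df["subtype"] = df["subtype"].fillna("none")
        bad = set(df["subtype"]) - set(SUBTYPES)
        if bad:
            raise ValidationError(f"unknown subtype labels: {sorted(bad)}")
        mism = df[(df["subtype"] != "none") & (df["group"] != "n_IgAN")]
        if len(mism):
            raise ValidationError(
                f"subtype set for non-n_IgAN samples: {mism['sample_id'].tolist()[:5]}"
            )
        nonneg = [v for v in CLINICAL_VARS if v in df.columns]
        for v in nonneg:
            df[v] = pd.to_numeric(df[v], errors="coerce")
            if (df[v].dropna() < 0).any():
                raise ValidationError(f"clinical variable {v} has negative values")
        df = df.set_index("sample_id", drop=False)
        object.__setattr__(self, "frame", df)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def group(self) -> pd.Series:
        return self.frame["group"]

    def samples_in(self, *groups: str) -> list[str]:
        return self.frame.loc[self.frame["group"].isin(groups), "sample_id"].tolist()

    def clinical(self) -> pd.DataFrame:
        cols = [v for v in CLINICAL_VARS if v in self.frame.columns]
        return self.frame[cols]


class PhyloTree:
    """Rooted tree over OTU feature ids with nonnegative branch lengths."""

    def __init__(self, tree: skbio.TreeNode):
        tips = list(tree.tips())
        names = [t.name for t in tips]
        if not names:
            raise FormatError("tree has no leaves")
        if any(n is None for n in names):
            raise ValidationError("tree has unnamed leaves")
        _check_unique(names, "leaf")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise ValidationError("negative branch length")
        self.tree = tree
        self.leaf_names = names

    def total_branch_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self.tree.traverse(include_self=False)))

    def write(self, path: str | Path) -> None:
        self.tree.write(str(path), format="newick")


@dataclasses.dataclass
class MetaboliteBatch:
    """LC-MS intensity matrix with injection order and QC annotations.

    ``intensities`` is samples x metabolites, strictly positive; rows follow
    ``sample_ids``. ``sample_type`` distinguishes pooled QC injections from
    study samples; ``group`` is defined for study samples only.
    """

    sample_ids: list[str]
    metabolite_ids: list[str]
    intensities: np.ndarray
    injection_order: np.ndarray
    sample_type: np.ndarray  # "study" | "QC"
    group: np.ndarray        # "HC" | "IgAN" | "" for QC

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.injection_order = np.asarray(self.injection_order, dtype=int)
        self.sample_type = np.asarray(self.sample_type, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.metabolite_ids, "metabolite")
        n = len(self.sample_ids)
        if self.intensities.shape != (n, len(self.metabolite_ids)):
            raise ValidationError("intensity matrix shape mismatch")
        if (self.intensities <= 0).any():
            raise ValidationError("intensities must be strictly positive")
        if len(np.unique(self.injection_order)) != n:
            raise ValidationError("injection_order values must be unique")
        if self.n_qc < 3:
            raise ValidationError("at least 3 QC injections are required")
        bad = set(self.sample_type) - {"study", "QC"}
        if bad:
            raise ValidationError(f"unknown sample_type: {sorted(bad)}")

    @property
    def qc_mask(self) -> np.ndarray:
        return self.sample_type == "QC"

    @property
    def n_qc(self) -> int:
        return int((self.sample_type == "QC").sum())

    def study_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(intensities, group) restricted to study samples, injection order."""
        m = ~self.qc_mask
        return self.intensities[m], self.group[m]

    def replace(self, **kw) -> "MetaboliteBatch":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class RunConfig:
    """All tunable constants of the pipeline in one place."""

    seed: int = 0
    cv_folds: int = 5
    screen_alpha: float = 0.05
    lda_cutoff: float = 3.0
    vip_cutoff: float = 1.0
    rsd_threshold: float = 30.0       # percent
    n_permutations: int = 999
    oplsda_permutations: int = 200
    split_ratio: str = "2:1"
    loess_span: float = 0.75
    n_trees: int = 500
    cv_trees: int = 100
    table_path: str = ""
    metadata_path: str = ""
    tree_path: str = ""
    metabolite_path: str = ""

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        for name in ("screen_alpha", "lda_cutoff", "vip_cutoff", "rsd_threshold",
                     "loess_span"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        self.ratio_parts()

    def ratio_parts(self) -> tuple[int, int]:
        try:
            a, b = (int(x) for x in str(self.split_ratio).split(":"))
        except ValueError as exc:
            raise ValidationError(f"unparseable split ratio {self.split_ratio!r}") from exc
        if a <= 0 or b <= 0:
            raise ValidationError("split ratio parts must be positive")
        return a, b

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a QIIME-classic TSV: '#OTU_ID', sample columns, optional 'taxonomy'."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse feature table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError("feature table needs an id column and >= 1 sample column")
    first = df.columns[0]
    if first.lstrip("#").strip().upper() not in {"OTU_ID", "OTU ID", "FEATURE_ID", "ID"}:
        raise FormatError(f"unexpected first header cell {first!r} (want '#OTU_ID')")
    lineages = None
    if df.columns[-1].lower() == "taxonomy":
        lineages = df.iloc[:, -1].tolist()
        df = df.iloc[:, :-1]
    feature_ids = df.iloc[:, 0].tolist()
    sample_ids = list(df.columns[1:])
    try:
        counts = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from exc
    return FeatureTable(feature_ids, sample_ids, counts, lineages)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.insert(0, "#OTU_ID", table.feature_ids)
    if table.lineages is not None:
        df["taxonomy"] = table.lineages
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> CohortMetadata:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:
        raise FormatError(f"cannot parse metadata {path}: {exc}") from exc
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def read_tree(path_or_handle) -> PhyloTree:
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = skbio.TreeNode.read(
                str(path_or_handle) if isinstance(path_or_handle, (str, Path))
                else path_or_handle,
                format="newick",
            )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick: {exc}") from exc
    return PhyloTree(tree)


def read_tree_string(newick: str) -> PhyloTree:
    return read_tree(_stdio.StringIO(newick))


def read_metabolites(path: str | Path) -> MetaboliteBatch:
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except Exception as exc:
        raise FormatError(f"cannot parse metabolite CSV {path}: {exc}") from exc
    required = {"sample_id", "sample_type", "injection_order", "group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metabolite CSV missing columns: {sorted(missing)}")
    met_cols = [c for c in df.columns if c not in required]
    if not met_cols:
        raise FormatError("metabolite CSV has no metabolite columns")
    return MetaboliteBatch(
        sample_ids=df["sample_id"].tolist(),
        metabolite_ids=met_cols,
        intensities=df[met_cols].to_numpy(float),
        injection_order=df["injection_order"].to_numpy(int),
        sample_type=df["sample_type"].to_numpy(object),
        group=df["group"].fillna("").to_numpy(object),
    )


def write_metabolites(batch: MetaboliteBatch, path: str | Path) -> None:
    df = pd.DataFrame(batch.intensities, columns=batch.metabolite_ids)
    df.insert(0, "group", batch.group)
    df.insert(0, "injection_order", batch.injection_order)
    df.insert(0, "sample_type", batch.sample_type)
    df.insert(0, "sample_id", batch.sample_ids)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# taxonomy aggregation
# ---------------------------------------------------------------------------

def aggregate_taxa(table: FeatureTable, rank: str) -> FeatureTable:
    """Collapse an OTU table to a coarser rank by summing counts.

    Features whose lineage lacks the requested rank are pooled under
    ``unclassified_<parent label>`` where the parent is the deepest rank
    the lineage does resolve.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; choose from {RANKS}")
    if table.lineages is None:
        raise ValidationError("table has no lineages to aggregate on")
    rank_idx = RANKS.index(rank)
    labels = []
    any_resolved = False
    for lin in table.lineages:
        parsed = parse_lineage(lin)
        if rank in parsed:
            labels.append(parsed[rank])
            any_resolved = True
        else:
            parent = ""
            for r in RANKS[:rank_idx][::-1]:
                if r in parsed:
                    parent = parsed[r]
                    break
            labels.append(f"unclassified_{parent}" if parent else "unclassified")
    if not any_resolved:
        raise ValidationError(f"rank {rank!r} absent from every lineage")
    df = table.to_dataframe()
    df.index = labels
    agg = df.groupby(level=0, sort=True).sum()
    return FeatureTable(agg.index.tolist(), table.sample_ids, agg.to_numpy(),
                        lineages=None, rank_level=rank)


def check_ids_match(table: FeatureTable, meta: CohortMetadata,
                    tree: PhyloTree | None = None) -> None:
    """Strict identifier agreement across containers, with a diff message."""
    ts, ms = set(table.sample_ids), set(meta.sample_ids)
    if ts != ms:
        raise ValidationError(
            f"sample ids differ: table-only={sorted(ts - ms)[:5]} "
            f"metadata-only={sorted(ms - ts)[:5]}"
        )
    if tree is not None:
        tf, lf = set(table.feature_ids), set(tree.leaf_names)
        if not tf <= lf:
            raise ValidationError(f"features missing from tree: {sorted(tf - lf)[:5]}")
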