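"""Reading, writing and validating the pipeline's on-disk formats.

The package works with three kinds of input per study:

* per-subject ROI time series — a TSV/CSV table, header row = ROI names,
  one row per acquired volume (time point);
* a sub-network partition — a JSON object mapping sub-network names to
  lists of ROI names (or 0-based indices);
* a subject label table — TSV with columns ``subject_id`` and ``label``
  (``ASD``/``NC``, coded internally as +1/−1).

A canonical six-network division of the 116-region AAL atlas (sensorimotor,
visual, execution/attention, default-mode, subcortical, cerebellar) ships
with the package, and a data-driven alternative based on k-means clustering
of ROI time series is provided.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import (
    FormatError,
    OverlapError,
    ParseError,
    PartitionError,
    UncoveredRoiError,
    UnknownRoiError,
    ValidationError,
)

log = logging.getLogger(__name__)

_LABEL_CODES = {"ASD": 1, "NC": -1, "+1": 1, "-1": -1, "1": 1}


@dataclass
class RoiTimeSeries:
    """One subject's signal matrix, time points × ROIs."""

    subject_id: str
    values: np.ndarray  # shape (n_time, n_roi), float
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"{self.subject_id}: expected a 2-D time×ROI matrix, "
                f"got ndim={self.values.ndim}"
            )
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValidationError(
                f"{self.subject_id}: need at least 2 time points and 2 ROIs, "
                f"got {m}×{n}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.subject_id}: non-finite values in time series")
        if len(self.roi_names) != n:
            raise ValidationError(
                f"{self.subject_id}: {len(self.roi_names)} ROI names for {n} columns"
            )
        if len(set(self.roi_names)) != n:
            raise ValidationError(f"{self.subject_id}: duplicate ROI names")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    @property
    def n_roi(self) -> int:
        return self.values.shape[1]


@dataclass
class SubNetworkPartition:
    """Named, disjoint groups of ROI indices covering all ROIs.

    ``networks`` preserves insertion order; all downstream feature layouts
    follow that order.
    """

    networks: dict[str, list[int]]

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(idx) for name, idx in self.networks.items()}

    @property
    def n_roi(self) -> int:
        return sum(len(idx) for idx in self.networks.values())

    def validate(self, n_roi: int) -> None:
        seen: dict[int, str] = {}
        for name, idx in self.networks.items():
            if len(idx) < 2:
                raise PartitionError(
                    f"sub-network {name!r} has {len(idx)} ROI(s); need at least 2"
                )
            for i in idx:
                if not 0 <= i < n_roi:
                    raise PartitionError(
                        f"sub-network {name!r}: ROI index {i} out of range 0..{n_roi - 1}"
                    )
                if i in seen:
                    raise OverlapError(
                        f"ROI index {i} claimed by both {seen[i]!r} and {name!r}"
                    )
                seen[i] = name
        missing = sorted(set(range(n_roi)) - set(seen))
        if missing:
            raise UncoveredRoiError(f"ROI indices not covered by any sub-network: {missing}")


@dataclass
class LabelTable:
    """subject_id → class label, +1 = patient (ASD), −1 = control (NC)."""

    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: v for s, v in self.labels.items() if v not in (1, -1)}
        if bad:
            raise ValidationError(f"labels must be +1/-1, got {bad}")

    def vector_for(self, subject_ids: list[str]) -> np.ndarray:
        missing = [s for s in subject_ids if s not in self.labels]
        if missing:
            raise ValidationError(f"subjects without labels: {missing}")
        return np.array([self.labels[s] for s in subject_ids], dtype=int)


# ---------------------------------------------------------------------------
# time-series tables


def read_timeseries(path: str | Path, dialect: str = "tsv") -> RoiTimeSeries:
    """Read one subject's time×ROI table; subject id = file stem."""
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: malformed table: {exc}") from exc
    roi_names = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = df[col].to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.nonzero(bad.isna().to_numpy())[0][0])
            raise ParseError(
                f"{path}: non-numeric cell at row {row + 1}, column {roi_names[j]!r}"
            ) from None
    ts = RoiTimeSeries(subject_id=path.stem, values=values, roi_names=roi_names)
    zero = [n for n, v in zip(roi_names, values.T) if np.all(v == 0)]
    if zero:
        log.warning("%s: constant-zero ROI columns: %s", path.stem, zero)
    return ts


def write_timeseries(ts: RoiTimeSeries, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.DataFrame(ts.values, columns=ts.roi_names)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# partitions


def load_partition(path: str | Path, roi_names: list[str]) -> SubNetworkPartition:
    """Load a JSON partition and resolve it against ``roi_names``.

    The JSON is an object mapping sub-network name → list of ROI names
    (matched case-sensitively) or 0-based integer indices.  A top-level
    ``networks`` key wrapping that object is also accepted (the bundled
    asset's layout).
    """
    with open(path) as fh:
        raw = json.load(fh)
    if "networks" in raw and isinstance(raw["networks"], dict):
        raw = raw["networks"]
    return resolve_partition(raw, roi_names)


def resolve_partition(
    mapping: dict[str, list], roi_names: list[str]
) -> SubNetworkPartition:
    index_of = {name: i for i, name in enumerate(roi_names)}
    networks: dict[str, list[int]] = {}
    for net, members in mapping.items():
        idx: list[int] = []
        for m in members:
            if isinstance(m, int) and not isinstance(m, bool):
                idx.append(m)
            elif isinstance(m, str):
                if m not in index_of:
                    raise UnknownRoiError(f"sub-network {net!r}: unknown ROI name {m!r}")
                idx.append(index_of[m])
            else:
                raise PartitionError(f"sub-network {net!r}: bad member {m!r}")
        networks[net] = idx
    part = SubNetworkPartition(networks=networks)
    part.validate(len(roi_names))
    return part


def write_partition(
    part: SubNetworkPartition, roi_names: list[str], path: str | Path
) -> None:
    out = {net: [roi_names[i] for i in idx] for net, idx in part.networks.items()}
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


def aal116_roi_names() -> list[str]:
    """The 116 AAL atlas region names in atlas order."""
    with resources.files("hierfc.data").joinpath("aal116_six_networks.json").open() as fh:
        return json.load(fh)["roi_names"]


def aal116_partition() -> SubNetworkPartition:
    """Bundled six-network division of the AAL-116 atlas.

    Sub-network sizes: SMN 18, Visual 14, EAN 17, DMN 22, SBC 19,
    Cerebel 26.  The region membership is the package's reconstruction of
    the standard functional grouping of the AAL regions consistent with
    those sizes (the odd group sizes force the superior temporal pole pair
    to be split between SBC and EAN).
    """
    ref = resources.files("hierfc.data").joinpath("aal116_six_networks.json")
    with ref.open() as fh:
        raw = json.load(fh)
    return resolve_partition(raw["networks"], raw["roi_names"])


def partition_by_kmeans(
    subjects: list[RoiTimeSeries],
    k: int,
    seed: int,
    max_retries: int = 5,
) -> SubNetworkPartition:
    """Data-driven partition: k-means clustering of ROI time series.

    Each ROI is represented by its z-scored time series averaged across
    subjects (order-invariant), clustered with Euclidean k-means++.
    Clusters are re-seeded up to ``max_retries`` times if any cluster ends
    up smaller than the 2-ROI minimum a sub-network requires.
    """
    if k < 2:
        raise ValidationError(f"k must be ≥ 2, got {k}")
    names = subjects[0].roi_names
    for s in subjects[1:]:
        if s.roi_names != names:
            raise ValidationError(f"subject {s.subject_id}: ROI names differ across subjects")
    feats = np.zeros((len(names), subjects[0].n_time))
    for s in subjects:
        v = s.values
        sd = v.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        feats += ((v - v.mean(axis=0)) / sd).T
    feats /= len(subjects)

    last_sizes = None
    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(feats)
        counts = np.bincount(labels, minlength=k)
        last_sizes = counts.tolist()
        if counts.min() >= 2:
            width = len(str(k - 1))
            networks = {
                f"cluster_{c:0{width}d}": np.nonzero(labels == c)[0].tolist()
                for c in range(k)
            }
            part = SubNetworkPartition(networks=networks)
            part.validate(len(names))
            return part
    raise PartitionError(
        f"k-means produced a cluster smaller than 2 ROIs after {max_retries} "
        f"re-seeds (last sizes {last_sizes})"
    )


# ---------------------------------------------------------------------------
# labels


def read_labels(path: str | Path) -> LabelTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"subject_id", "label"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: label table needs columns {sorted(need)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"{path}: duplicate subject ids {dups}")
    labels: dict[str, int] = {}
    for _, row in df.iterrows():
        raw = str(row["label"]).strip()
        if raw not in _LABEL_CODES:
            raise ParseError(
                f"{path}: unknown label {raw!r} for subject {row['subject_id']!r} "
                f"(expected ASD/NC or +1/-1)"
            )
        labels[str(row["subject_id"])] = _LABEL_CODES[raw]
    return LabelTable(labels=labels)


def write_labels(table: LabelTable, path: str | Path) -> None:
    rows = [
        {"subject_id": s, "label": "ASD" if v == 1 else "NC"}
        for s, v in table.labels.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
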