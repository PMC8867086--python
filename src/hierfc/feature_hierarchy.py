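"""Hierarchical connectivity features: intra/inter sub-network × low/high order.

Per subject, four tagged blocks are produced:

* ``intra_high`` (f1): per sub-network, the lower triangle *including* the
  diagonal of the fitted Kronecker factor Ĉ (the diagonal carries variance
  information);
* ``intra_low``  (f2): per sub-network, the strict lower triangle of the
  fitted mean matrix M̂ (the diagonal is identically 1);
* ``inter_high`` (f3) and ``inter_low`` (f4): the same two vectorizations
  of the fit to the network of sub-network *mean time series*.

Triangles are traversed row-major over (i > j) resp. (i ≥ j) pairs, so
feature indices are stable.  Fusion concatenates the blocks in the order
(intra_high, intra_low, inter_high, inter_low).  Two conventional
baselines are also provided: the static full-series correlation vector and
its windowed-mean (dynamic) counterpart.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import RoiTimeSeries, SubNetworkPartition
from .mvnd_fit import FitConfig, fit_factor, fit_mean
from .window_fcn import WindowSpec, fcn_sequence, static_correlation

FUSE_ORDER = ("intra_high", "intra_low", "inter_high", "inter_low")


@dataclass
class FeatureBlock:
    """A tagged feature vector with per-entry provenance.

    Each ``index_map`` entry is a dict describing where the feature came
    from: ``{"block": tag, "network": ..., "i": ..., "j": ..., "role": ...}``
    for intra blocks (ROI indices), or ``{"block": tag, "network_i": ...,
    "network_j": ..., "role": ...}`` for inter blocks.  ``role`` is
    ``"mean"`` (low order) or ``"factor"`` (high order).
    """

    tag: str
    values: np.ndarray
    index_map: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.index_map) != self.values.size:
            raise ValidationError(
                f"block {self.tag!r}: {self.values.size} values but "
                f"{len(self.index_map)} provenance entries"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FeatureTable:
    """Subjects × fused features, with column provenance and block spans."""

    subject_ids: list[str]
    values: np.ndarray  # (n_subjects, n_features)
    provenance: list[dict]
    block_slices: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.subject_ids):
            raise ValidationError("row count does not match subject ids")
        if self.values.shape[1] != len(self.provenance):
            raise ValidationError("column count does not match provenance length")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def columns_for_tags(self, tags: list[str]) -> np.ndarray:
        cols: list[int] = []
        for tag in tags:
            if tag not in self.block_slices:
                raise ValidationError(
                    f"no block {tag!r} in table; have {sorted(self.block_slices)}"
                )
            a, b = self.block_slices[tag]
            cols.extend(range(a, b))
        return np.asarray(cols, dtype=int)

    def restrict(self, tags: list[str]) -> "FeatureTable":
        cols = self.columns_for_tags(tags)
        slices: dict[str, tuple[int, int]] = {}
        pos = 0
        for tag in tags:
            a, b = self.block_slices[tag]
            slices[tag] = (pos, pos + (b - a))
            pos += b - a
        return FeatureTable(
            subject_ids=list(self.subject_ids),
            values=self.values[:, cols],
            provenance=[self.provenance[c] for c in cols],
            block_slices=slices,
        )


# ---------------------------------------------------------------------------
# vectorization helpers


def lower_triangle_pairs(n: int, include_diagonal: bool) -> list[tuple[int, int]]:
    """Row-major (i, j) pairs with i > j (or i ≥ j when the diagonal is kept)."""
    extra = 1 if include_diagonal else 0
    return [(i, j) for i in range(n) for j in range(i + extra)]


def vec_lower(mat: np.ndarray, include_diagonal: bool) -> np.ndarray:
    pairs = lower_triangle_pairs(mat.shape[0], include_diagonal)
    return np.array([mat[i, j] for i, j in pairs], dtype=float)


def unvec_lower(values: np.ndarray, n: int, include_diagonal: bool,
                diagonal_fill: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from its triangle vectorization."""
    mat = np.full((n, n), np.nan)
    pairs = lower_triangle_pairs(n, include_diagonal)
    if len(values) != len(pairs):
        raise ValidationError(f"expected {len(pairs)} values, got {len(values)}")
    for (i, j), v in zip(pairs, values):
        mat[i, j] = v
        mat[j, i] = v
    if not include_diagonal:
        np.fill_diagonal(mat, diagonal_fill)
    return mat


# ---------------------------------------------------------------------------
# extraction


def mean_series(ts: RoiTimeSeries, partition: SubNetworkPartition) -> RoiTimeSeries:
    """Per-sub-network average time series; one column per sub-network."""
    partition.validate(ts.n_roi)
    cols = [ts.values[:, idx].mean(axis=1) for idx in partition.networks.values()]
    return RoiTimeSeries(
        subject_id=ts.subject_id,
        values=np.column_stack(cols),
        roi_names=list(partition.networks.keys()),
    )


def extract_intra(
    ts: RoiTimeSeries,
    partition: SubNetworkPartition,
    spec: WindowSpec,
    fit_cfg: FitConfig | None = None,
) -> tuple[FeatureBlock, FeatureBlock]:
    """Within-network features: one matrix-normal fit per sub-network."""
    cfg = fit_cfg or FitConfig()
    partition.validate(ts.n_roi)
    low_vals: list[np.ndarray] = []
    low_map: list[dict] = []
    high_vals: list[np.ndarray] = []
    high_map: list[dict] = []
    for net, idx in partition.networks.items():
        seq = fcn_sequence(ts, idx, spec)
        m_hat = fit_mean(seq)
        fit = fit_factor(seq, m_hat, tol=cfg.tol, max_iter=cfg.max_iter, ridge=cfg.ridge)
        low_vals.append(vec_lower(m_hat, include_diagonal=False))
        low_map.extend(
            {"block": "intra_low", "network": net, "i": idx[i], "j": idx[j], "role": "mean"}
            for i, j in lower_triangle_pairs(len(idx), include_diagonal=False)
        )
        high_vals.append(vec_lower(fit.factor, include_diagonal=True))
        high_map.extend(
            {"block": "intra_high", "network": net, "i": idx[i], "j": idx[j], "role": "factor"}
            for i, j in lower_triangle_pairs(len(idx), include_diagonal=True)
        )
    return (
        FeatureBlock(tag="intra_low", values=np.concatenate(low_vals), index_map=low_map),
        FeatureBlock(tag="intra_high", values=np.concatenate(high_vals), index_map=high_map),
    )


def extract_inter(
    ts: RoiTimeSeries,
    partition: SubNetworkPartition,
    spec: WindowSpec,
    fit_cfg: FitConfig | None = None,
) -> tuple[FeatureBlock, FeatureBlock]:
    """Across-network features: one fit to the network of mean series."""
    cfg = fit_cfg or FitConfig()
    ms = mean_series(ts, partition)
    seq = fcn_sequence(ms, list(range(ms.n_roi)), spec)
    m_hat = fit_mean(seq)
    fit = fit_factor(seq, m_hat, tol=cfg.tol, max_iter=cfg.max_iter, ridge=cfg.ridge)
    names = ms.roi_names
    low_map = [
        {"block": "inter_low", "network_i": names[i], "network_j": names[j], "role": "mean"}
        for i, j in lower_triangle_pairs(len(names), include_diagonal=False)
    ]
    high_map = [
        {"block": "inter_high", "network_i": names[i], "network_j": names[j], "role": "factor"}
        for i, j in lower_triangle_pairs(len(names), include_diagonal=True)
    ]
    return (
        FeatureBlock(tag="inter_low",
                     values=vec_lower(m_hat, include_diagonal=False), index_map=low_map),
        FeatureBlock(tag="inter_high",
                     values=vec_lower(fit.factor, include_diagonal=True), index_map=high_map),
    )


def minmax_normalize(block: FeatureBlock) -> FeatureBlock:
    """(v − min)/(max − min) over the block's own entries.

    A constant block maps to all zeros with a warning.
    """
    if len(block) == 0:
        raise ValidationError(f"block {block.tag!r} is empty")
    lo, hi = float(block.values.min()), float(block.values.max())
    if hi == lo:
        warnings.warn(f"block {block.tag!r} is constant; normalized to zeros")
        vals = np.zeros_like(block.values)
    else:
        vals = (block.values - lo) / (hi - lo)
    return FeatureBlock(tag=block.tag, values=vals, index_map=list(block.index_map))


def fuse(blocks: list[FeatureBlock]) -> FeatureBlock:
    """Concatenate blocks in canonical tag order into one fused vector."""
    if not blocks:
        raise ValidationError("no blocks to fuse")
    by_tag: dict[str, FeatureBlock] = {}
    for b in blocks:
        if b.tag in by_tag:
            raise ValidationError(f"duplicated block tag {b.tag!r}")
        by_tag[b.tag] = b
    ordered = [by_tag.pop(t) for t in FUSE_ORDER if t in by_tag]
    ordered += list(by_tag.values())  # any extra tags (baselines) keep input order
    return FeatureBlock(
        tag="fused",
        values=np.concatenate([b.values for b in ordered]),
        index_map=[e for b in ordered for e in b.index_map],
    )


def baseline_static(ts: RoiTimeSeries, roi_subset: list[int] | None = None) -> FeatureBlock:
    """Conventional static connectivity: strict lower triangle of the
    full-series correlation matrix."""
    subset = list(range(ts.n_roi)) if roi_subset is None else list(roi_subset)
    corr = static_correlation(ts, subset)
    index_map = [
        {"block": "static_baseline", "i": subset[i], "j": subset[j], "role": "mean"}
        for i, j in lower_triangle_pairs(len(subset), include_diagonal=False)
    ]
    return FeatureBlock(tag="static_baseline",
                        values=vec_lower(corr, include_diagonal=False), index_map=index_map)


def baseline_dynamic(
    ts: RoiTimeSeries, roi_subset: list[int] | None, spec: WindowSpec
) -> FeatureBlock:
    """Conventional dynamic connectivity: strict lower triangle of the
    windowed-sequence mean (equals the static baseline when K = 1)."""
    subset = list(range(ts.n_roi)) if roi_subset is None else list(roi_subset)
    seq = fcn_sequence(ts, subset, spec)
    mean = fit_mean(seq)
    index_map = [
        {"block": "dynamic_baseline", "i": subset[i], "j": subset[j], "role": "mean"}
        for i, j in lower_triangle_pairs(len(subset), include_diagonal=False)
    ]
    return FeatureBlock(tag="dynamic_baseline",
                        values=vec_lower(mean, include_diagonal=False), index_map=index_map)


def extract_subject(
    ts: RoiTimeSeries,
    partition: SubNetworkPartition,
    spec: WindowSpec,
    fit_cfg: FitConfig | None = None,
    baselines: bool = False,
) -> FeatureBlock:
    """Full fused (un-normalized) feature vector for one subject."""
    low_i, high_i = extract_intra(ts, partition, spec, fit_cfg)
    low_e, high_e = extract_inter(ts, partition, spec, fit_cfg)
    blocks = [high_i, low_i, high_e, low_e]
    if baselines:
        blocks.append(baseline_static(ts))
        blocks.append(baseline_dynamic(ts, None, spec))
    return fuse(blocks)


def build_feature_table(
    subjects: list[RoiTimeSeries],
    partition: SubNetworkPartition,
    spec: WindowSpec,
    fit_cfg: FitConfig | None = None,
    baselines: bool = False,
) -> FeatureTable:
    """Stack fused per-subject vectors into a subjects × features table."""
    if not subjects:
        raise ValidationError("no subjects")
    fused = [extract_subject(ts, partition, spec, fit_cfg, baselines) for ts in subjects]
    widths = {f.values.size for f in fused}
    if len(widths) != 1:
        raise ValidationError(f"inconsistent fused widths across subjects: {widths}")
    prov = fused[0].index_map
    slices: dict[str, tuple[int, int]] = {}
    for pos, entry in enumerate(prov):
        tag = entry["block"]
        if tag not in slices:
            slices[tag] = (pos, pos + 1)
        else:
            slices[tag] = (slices[tag][0], pos + 1)
    return FeatureTable(
        subject_ids=[s.subject_id for s in subjects],
        values=np.vstack([f.values for f in fused]),
        provenance=prov,
        block_slices=slices,
    )


def dimension_report(partition: SubNetworkPartition, m_time: int,
                     n_roi: int | None = None) -> dict:
    """Dimension diagnostics for the matrix-normal sample-size problem.

    Per sub-network: the dimension of one windowed connectivity matrix
    (N_u²), its ratio to the number of time points, and its percentage of
    the full-network dimension N².  The full network's own figures are
    reported under ``"full_network"``.
    """
    n = partition.n_roi if n_roi is None else n_roi
    report: dict = {"m_time": m_time, "n_roi": n, "sub_networks": {}}
    for net, idx in partition.networks.items():
        nu = len(idx)
        report["sub_networks"][net] = {
            "n_roi": nu,
            "dimension": nu * nu,
            "ratio_to_time": nu * nu / m_time,
            "pct_of_full": nu * nu / (n * n) * 100.0,
        }
    report["full_network"] = {
        "n_roi": n,
        "dimension": n * n,
        "ratio_to_time": n * n / m_time,
    }
    return report


# ---------------------------------------------------------------------------
# serialization


def save_feature_table(table: FeatureTable, tsv_path: str | Path) -> None:
    tsv_path = Path(tsv_path)
    df = pd.DataFrame(table.values, index=table.subject_ids)
    df.index.name = "subject_id"
    df.columns = [f"f{j:05d}" for j in range(table.n_features)]
    df.to_csv(tsv_path, sep="\t", float_format="%.17g")
    sidecar = {
        "block_slices": {k: list(v) for k, v in table.block_slices.items()},
        "provenance": table.provenance,
    }
    tsv_path.with_suffix(".provenance.json").write_text(json.dumps(sidecar))


def load_feature_table(tsv_path: str | Path) -> FeatureTable:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", index_col="subject_id")
    sidecar = json.loads(tsv_path.with_suffix(".provenance.json").read_text())
    return FeatureTable(
        subject_ids=[str(s) for s in df.index],
        values=df.to_numpy(dtype=float),
        provenance=sidecar["provenance"],
        block_slices={k: (v[0], v[1]) for k, v in sidecar["block_slices"].items()},
    )
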