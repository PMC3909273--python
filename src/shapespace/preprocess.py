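"""Feature-table transformation and dimensionality reduction.

Raw morphology features are strictly positive, heavy-tailed measurements
(areas, intensities, protrusion counts ...) on very different scales.  The
pipeline first maps every feature onto a common range, compresses its dynamic
range with a log transform, and then projects cells into a low-dimensional
principal-component space in which all downstream clustering and distance
computations happen.

The transformation is: per-feature min-max rescale to [0, 1], add a small
offset (default 0.01) so no value is zero, take the natural log.  PCA is then
run on the covariance of the transformed table and the top components
(default 3) are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "ScaleLogTransform",
    "PCEmbedding",
    "scale_and_log",
    "pca_reduce",
]


@dataclass
class FeatureTable:
    """Cells x features matrix with per-cell condition labels.

    Parameters
    ----------
    cell_ids : array of str, one per row.
    tc_ids : array of str, treatment-condition label per cell.
    values : (n_cells, n_features) float array, all finite.
    feature_names : list of str, one per column.
    """

    cell_ids: np.ndarray
    tc_ids: np.ndarray
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.tc_ids = np.asarray(self.tc_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x features matrix")
        n_cells, n_features = self.values.shape
        if n_cells < 2:
            raise ValueError("a feature table needs at least 2 cells")
        if len(self.cell_ids) != n_cells or len(self.tc_ids) != n_cells:
            raise ValueError("cell_ids/tc_ids length must match number of rows")
        if len(self.feature_names) != n_features:
            raise ValueError("feature_names length must match number of columns")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value for cell {self.cell_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "tc_id", self.tc_ids)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        feature_names = [c for c in df.columns if c not in ("cell_id", "tc_id")]
        return cls(
            cell_ids=df["cell_id"].to_numpy(dtype=object),
            tc_ids=df["tc_id"].to_numpy(dtype=object),
            values=df[feature_names].to_numpy(dtype=float),
            feature_names=list(feature_names),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class ScaleLogTransform:
    """Recorded per-feature scaling constants so held-out cells can be
    transformed identically to the table the constants were fit on."""

    mins: np.ndarray
    ranges: np.ndarray
    offset: float
    feature_names: list[str]
    constant_features: list[str] = field(default_factory=list)

    def apply(self, table: FeatureTable) -> FeatureTable:
        if table.feature_names != self.feature_names:
            raise ValueError("feature names do not match recorded transform")
        scaled = np.zeros_like(table.values)
        nonconst = self.ranges > 0
        scaled[:, nonconst] = (
            table.values[:, nonconst] - self.mins[nonconst]
        ) / self.ranges[nonconst]
        # constant features map to 0 before offset+log
        transformed = np.log(scaled + self.offset)
        return FeatureTable(
            cell_ids=table.cell_ids,
            tc_ids=table.tc_ids,
            values=transformed,
            feature_names=list(table.feature_names),
        )

    def to_dict(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "ranges": self.ranges.tolist(),
            "offset": self.offset,
            "feature_names": self.feature_names,
            "constant_features": self.constant_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleLogTransform":
        return cls(
            mins=np.asarray(d["mins"], dtype=float),
            ranges=np.asarray(d["ranges"], dtype=float),
            offset=float(d["offset"]),
            feature_names=list(d["feature_names"]),
            constant_features=list(d.get("constant_features", [])),
        )


def scale_and_log(
    table: FeatureTable, offset: float = 0.01
) -> tuple[FeatureTable, ScaleLogTransform]:
    """Min-max rescale each feature to [0, 1], add ``offset``, take natural log.

    Constant (zero-range) features cannot be min-max scaled; all their values
    are mapped to 0 before the offset and log, and the event is logged.

    Returns the transformed table and the recorded :class:`ScaleLogTransform`
    (applying the transform to the training table reproduces the output).
    """
    if offset <= 0:
        raise ValueError("offset must be positive so the log is defined")
    mins = table.values.min(axis=0)
    maxs = table.values.max(axis=0)
    ranges = maxs - mins
    constant = [
        name for name, r in zip(table.feature_names, ranges) if r == 0
    ]
    if constant:
        logger.info(
            "scale_and_log: %d constant feature(s) mapped to log(offset): %s",
            len(constant),
            ", ".join(constant[:10]),
        )
    transform = ScaleLogTransform(
        mins=mins,
        ranges=ranges,
        offset=float(offset),
        feature_names=list(table.feature_names),
        constant_features=constant,
    )
    return transform.apply(table), transform


@dataclass
class PCEmbedding:
    """Per-cell coordinates in the retained principal components.

    ``loadings`` columns are the orthonormal component directions in feature
    space; ``variance_fractions`` are the retained components' shares of total
    variance and ``full_variance_fractions`` covers the complete spectrum
    (sums to 1).  ``transform`` records the scaling constants applied before
    PCA, if any.
    """

    coords: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    full_variance_fractions: np.ndarray
    mean: np.ndarray
    cell_ids: np.ndarray
    tc_ids: np.ndarray
    transform: ScaleLogTransform | None = None

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            self.coords,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        df.insert(0, "tc_id", self.tc_ids)
        df.insert(0, "cell_id", self.cell_ids)
        df.to_csv(out / "coords.tsv", sep="\t", index=False)
        meta = {
            "loadings": self.loadings.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "full_variance_fractions": self.full_variance_fractions.tolist(),
            "mean": self.mean.tolist(),
            "transform": self.transform.to_dict() if self.transform else None,
        }
        (out / "metadata.json").write_text(json.dumps(meta))

    @classmethod
    def read(cls, in_dir: str | Path) -> "PCEmbedding":
        src = Path(in_dir)
        df = pd.read_csv(src / "coords.tsv", sep="\t")
        meta = json.loads((src / "metadata.json").read_text())
        pc_cols = [c for c in df.columns if c.startswith("PC")]
        return cls(
            coords=df[pc_cols].to_numpy(dtype=float),
            loadings=np.asarray(meta["loadings"], dtype=float),
            variance_fractions=np.asarray(meta["variance_fractions"], dtype=float),
            full_variance_fractions=np.asarray(
                meta["full_variance_fractions"], dtype=float
            ),
            mean=np.asarray(meta["mean"], dtype=float),
            cell_ids=df["cell_id"].to_numpy(dtype=object),
            tc_ids=df["tc_id"].to_numpy(dtype=object),
            transform=(
                ScaleLogTransform.from_dict(meta["transform"])
                if meta.get("transform")
                else None
            ),
        )


def pca_reduce(
    table: FeatureTable,
    n_components: int = 3,
    transform: ScaleLogTransform | None = None,
    variance_threshold: float | None = None,
) -> PCEmbedding:
    """Mean-centred covariance PCA of an (already transformed) feature table.

    Component signs are fixed by making the largest-magnitude loading of each
    component positive, so results are deterministic across runs and BLAS
    implementations.  If ``variance_threshold`` is given, components with a
    variance fraction at or above the threshold are retained instead of a
    fixed ``n_components`` (off by default).
    """
    X = table.values
    n_cells, n_features = X.shape
    if n_components > n_features:
        raise ValueError("n_components cannot exceed the number of features")
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: Xc = U S Vt, eigenvalues of covariance are S^2/(n-1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / max(n_cells - 1, 1)
    total = eigvals.sum()
    if total == 0:
        raise ValueError("data has zero variance; PCA undefined")
    fractions = eigvals / total
    rank = int(np.sum(S > S[0] * max(n_cells, n_features) * np.finfo(float).eps))
    if variance_threshold is not None:
        n_components = max(int(np.sum(fractions >= variance_threshold)), 1)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds data rank {rank}"
        )
    loadings = Vt[:n_components].T.copy()  # n_features x d, orthonormal cols
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(n_components):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    coords = Xc @ loadings
    return PCEmbedding(
        coords=coords,
        loadings=loadings,
        variance_fractions=fractions[:n_components].copy(),
        full_variance_fractions=fractions.copy(),
        mean=mean,
        cell_ids=table.cell_ids,
        tc_ids=table.tc_ids,
        transform=transform,
    )
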