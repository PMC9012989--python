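"""Attribute granulation: deterministic 1-D K-means plus the two-threshold
rule turning each ROI into binary high/low-temperature attributes.

Each ROI's temperature multiset is clustered into low / medium / high
temperature groups (plus a background group when the ROI contains filtered
zeros). Randomness is removed entirely: K is fixed by the presence of
background (K=4 with zeros, else K=3) and the initial centers are fixed
order statistics of the data, so the same field always granulates to the
same bits — the design goal being reproducible clustering rather than
globally optimal clustering.

Writing T_roi for the set of nonzero-cluster mean temperatures of one ROI,
and T̄_min / T̄_max for the whole-body averages of the smallest / largest
nonzero-cluster means over all 18 ROIs:

    ROI-L = 1  iff  min(T_roi) <= T̄_min       (low-temperature attribute)
    ROI-H = 1  iff  max(T_roi) >= T̄_max       (high-temperature attribute)

with inclusive boundaries. Over a cohort this yields an N x 36 binary
formal context with columns ROI1-H, ROI1-L, ..., ROI18-H, ROI18-L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateROIError, ParameterError, ThermoAposError
from .roi_segmentation import ROI_TABLE, ROISet

__all__ = [
    "ATTRIBUTE_NAMES",
    "ClusterSpec",
    "ClusterOutcome",
    "GlobalThresholds",
    "AttributePair",
    "FormalContext",
    "select_k",
    "init_centers",
    "kmeans_1d",
    "cluster_roi",
    "global_thresholds",
    "granulate_roi",
    "granulate_roiset",
    "build_formal_context",
]

ROI_LABELS = tuple(ROI_TABLE)

#: Column order of the formal context: ROI1-H, ROI1-L, ... ROI18-H, ROI18-L.
ATTRIBUTE_NAMES = tuple(
    f"{label}-{suffix}" for label in ROI_LABELS for suffix in ("H", "L")
)


@dataclass(frozen=True)
class ClusterSpec:
    """Deterministic clustering recipe for one ROI."""

    k: int
    initial_centers: tuple[float, ...]
    max_iter: int = 300
    tol: float = 1e-6  # °C

    def __post_init__(self) -> None:
        if self.k != len(self.initial_centers):
            raise ParameterError("K must match the number of initial centers")


@dataclass
class ClusterOutcome:
    """Converged clustering of one ROI's temperatures."""

    centers: np.ndarray          # final centers, °C, index-aligned with init
    cluster_means: np.ndarray    # mean temperature of each nonempty cluster's members
    sizes: np.ndarray            # member count per cluster (sums to ROI pixel count)
    labels: np.ndarray           # cluster index of each input value
    has_background: bool         # True when cluster 0 is the zero cluster

    @property
    def nonzero_cluster_means(self) -> np.ndarray:
        """T_roi: mean temperatures of the nonempty non-background clusters."""
        start = 1 if self.has_background else 0
        means = [
            float(self.cluster_means[i])
            for i in range(start, len(self.sizes))
            if self.sizes[i] > 0
        ]
        return np.array(sorted(means))


@dataclass(frozen=True)
class GlobalThresholds:
    """Whole-body attribute thresholds, °C.

    ``tbar_min`` — average over the 18 ROIs of each ROI's smallest
    nonzero-cluster mean; ``tbar_max`` — same for the largest.
    """

    tbar_min: float
    tbar_max: float

    def __post_init__(self) -> None:
        if self.tbar_min > self.tbar_max + 1e-12:
            raise ParameterError("tbar_min cannot exceed tbar_max")


@dataclass(frozen=True)
class AttributePair:
    """One ROI's binary granulation."""

    roi_low: int
    roi_high: int


def select_k(values: np.ndarray) -> int:
    """K=4 when the ROI contains background zeros, else K=3."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise DegenerateROIError("empty ROI")
    return 4 if np.any(values == 0.0) else 3


def init_centers(values: np.ndarray, k: int) -> tuple[float, ...]:
    """Fixed initial centers from the data's order statistics.

    K=4: 0, nonzero minimum, nonzero mean, nonzero maximum.
    K=3: minimum, mean, maximum.
    """
    values = np.asarray(values, dtype=np.float64)
    if k == 4:
        nz = values[values != 0.0]
        if nz.size == 0:
            raise DegenerateROIError("ROI contains only background zeros")
        return (0.0, float(nz.min()), float(nz.mean()), float(nz.max()))
    if k == 3:
        return (float(values.min()), float(values.mean()), float(values.max()))
    raise ParameterError(f"K must be 3 or 4, got {k}")


def kmeans_1d(values: np.ndarray, spec: ClusterSpec) -> ClusterOutcome:
    """Lloyd's algorithm on a 1-D multiset from fixed centers.

    Assignment ties go to the lower-index center; an emptied cluster keeps
    its previous center. Iteration stops when the largest center shift drops
    below ``tol`` or after ``max_iter`` sweeps. Identical inputs always give
    bitwise-identical outcomes.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise DegenerateROIError("cannot cluster an empty ROI")
    if not np.all(np.isfinite(values)):
        raise ParameterError("non-finite temperature passed to kmeans_1d")
    centers = np.array(spec.initial_centers, dtype=np.float64)
    labels = np.zeros(values.size, dtype=np.intp)
    for _ in range(spec.max_iter):
        # argmin returns the first (lowest-index) minimizer: the tie rule
        labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new_centers = centers.copy()
        for j in range(spec.k):
            members = values[labels == j]
            if members.size:
                new_centers[j] = members.mean()
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < spec.tol:
            break
    labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    sizes = np.bincount(labels, minlength=spec.k)
    cluster_means = np.array(
        [values[labels == j].mean() if sizes[j] else np.nan for j in range(spec.k)]
    )
    return ClusterOutcome(
        centers=centers,
        cluster_means=cluster_means,
        sizes=sizes,
        labels=labels,
        has_background=(spec.k == 4),
    )


def cluster_roi(values: np.ndarray, max_iter: int = 300, tol: float = 1e-6) -> ClusterOutcome:
    """Select K, fix the centers, run deterministic K-means: one ROI end to end."""
    k = select_k(values)
    spec = ClusterSpec(k=k, initial_centers=init_centers(values, k), max_iter=max_iter, tol=tol)
    outcome = kmeans_1d(np.asarray(values, dtype=np.float64), spec)
    if outcome.nonzero_cluster_means.size == 0:
        raise DegenerateROIError("ROI has no nonzero cluster after clustering")
    return outcome


def global_thresholds(outcomes: dict[str, ClusterOutcome]) -> GlobalThresholds:
    """Whole-body T̄_min / T̄_max over all 18 ROI outcomes."""
    missing = sorted(set(ROI_LABELS) - set(outcomes))
    if missing:
        raise ThermoAposError(f"outcomes missing for {missing}")
    mins, maxs = [], []
    for label in ROI_LABELS:
        t_roi = outcomes[label].nonzero_cluster_means
        if t_roi.size == 0:
            raise DegenerateROIError(f"{label}: no nonzero cluster; cannot form thresholds")
        mins.append(t_roi[0])
        maxs.append(t_roi[-1])
    return GlobalThresholds(tbar_min=float(np.mean(mins)), tbar_max=float(np.mean(maxs)))


def granulate_roi(outcome: ClusterOutcome, thresholds: GlobalThresholds) -> AttributePair:
    """Apply the inclusive two-threshold rule to one ROI's cluster means."""
    t_roi = outcome.nonzero_cluster_means
    if t_roi.size == 0:
        raise DegenerateROIError("no nonzero cluster to granulate")
    return AttributePair(
        roi_low=int(t_roi[0] <= thresholds.tbar_min),
        roi_high=int(t_roi[-1] >= thresholds.tbar_max),
    )


def granulate_roiset(roiset: ROISet) -> dict[str, AttributePair]:
    """Granulate one subject: cluster all 18 ROIs, derive whole-body
    thresholds, then binarize each ROI against them."""
    outcomes = {label: cluster_roi(roiset[label]) for label in ROI_LABELS}
    thresholds = global_thresholds(outcomes)
    return {label: granulate_roi(outcomes[label], thresholds) for label in ROI_LABELS}


class FormalContext:
    """Binary objects x attributes incidence table (the "formal background").

    Rows are objects in input order. :func:`build_formal_context` always
    produces the pipeline's 36-column layout (ROI1-H, ROI1-L, ...,
    ROI18-L); the class itself accepts any binary table so small contexts
    can be constructed directly.
    """

    def __init__(self, table: pd.DataFrame):
        if len(set(table.columns)) != len(table.columns):
            raise ParameterError("context attribute names must be unique")
        if len(set(table.index)) != len(table.index):
            raise ParameterError("context object ids must be unique")
        if not table.isin([0, 1]).all().all():
            raise ParameterError("context entries must be binary")
        self.table = table.astype(int)

    @property
    def objects(self) -> tuple:
        return tuple(self.table.index)

    @property
    def attributes(self) -> tuple:
        return tuple(self.table.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.table.shape

    def intent(self, obj) -> tuple[str, ...]:
        """Attribute set of one object."""
        row = self.table.loc[obj]
        return tuple(a for a in self.attributes if row[a] == 1)

    def extent(self, attribute: str) -> tuple:
        """Objects possessing one attribute."""
        col = self.table[attribute]
        return tuple(col.index[col == 1])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="object")

    @classmethod
    def from_csv(cls, path) -> "FormalContext":
        table = pd.read_csv(path, index_col="object")
        table.index.name = None
        return cls(table)

    def to_burmeister(self, path) -> None:
        """Serialize in the Burmeister ``.cxt`` plain-text FCA format."""
        n, m = self.shape
        lines = ["B", "", str(n), str(m), ""]
        lines += [str(o) for o in self.objects]
        lines += list(self.attributes)
        for _, row in self.table.iterrows():
            lines.append("".join("X" if v else "." for v in row))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def build_formal_context(
    granulations: list[tuple[object, dict[str, AttributePair]]],
) -> FormalContext:
    """Assemble per-subject granulations into the N x 36 context.

    ``granulations`` is an ordered list of ``(object_id, {label: pair})``;
    row order follows input order.
    """
    rows, index = [], []
    for obj, pairs in granulations:
        missing = sorted(set(ROI_LABELS) - set(pairs))
        if missing:
            raise ThermoAposError(f"object {obj!r} missing granulation for {missing}")
        row = []
        for label in ROI_LABELS:
            row.extend((pairs[label].roi_high, pairs[label].roi_low))
        rows.append(row)
        index.append(obj)
    table = pd.DataFrame(rows, index=index, columns=list(ATTRIBUTE_NAMES))
    return FormalContext(table)
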