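"""Colony-forming-unit quantification from binary segmentation masks.

A colony count is the number of connected foreground components of a mask
(8-connectivity by default: a colony touching another diagonally is still one
colony).  Counts are compared by mean absolute error and by binning accuracy:
the food-safety convention of three intervals [0,40), [40,300), [300,inf),
plus a fine-grained equal-width scheme (20 bins by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def count_components(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of maximal connected foreground components of a binary mask."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary (values in {0,1})")
    _, n = ndimage.label(m, structure=_STRUCTURES[connectivity])
    return int(n)


@dataclass(frozen=True)
class BinScheme:
    """Half-open count intervals [e_0, e_1), ..., [e_{n-1}, inf) with e_0 = 0."""

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if not edges or edges[0] != 0.0:
            raise ValueError("edges must start at 0")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    def assign(self, count) -> np.ndarray | int:
        """Bin index of a count (or array of counts)."""
        idx = np.searchsorted(self.edges, np.asarray(count, dtype=float),
                              side="right") - 1
        return idx if idx.ndim else int(idx)


#: the three food-safety intervals [0,40), [40,300), [300,inf)
BIN3_SCHEME = BinScheme(edges=(0.0, 40.0, 300.0))


def bin3(count: int) -> int:
    """Three-interval food-safety bin of a colony count."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    return int(BIN3_SCHEME.assign(count))


def make_equal_bins(max_count: int, n_bins: int = 20) -> BinScheme:
    """Equal-width scheme: n_bins intervals spanning [0, max_count), the last
    extended to infinity."""
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    if max_count < n_bins:
        raise ValueError("max_count must be at least n_bins")
    edges = np.linspace(0.0, float(max_count), n_bins + 1)[:-1]
    return BinScheme(edges=tuple(edges))


@dataclass(frozen=True)
class CfuRecord:
    """Per-image colony counts and their bin assignments."""

    image_id: str
    predicted_count: int
    true_count: int
    predicted_bin3: int
    true_bin3: int
    predicted_bin_fine: int
    true_bin_fine: int


def make_records(image_ids: Sequence[str], predicted: Sequence[int],
                 true: Sequence[int],
                 fine_scheme: BinScheme | None = None) -> list[CfuRecord]:
    """Assemble records; the fine scheme defaults to 20 equal-width bins over
    the observed maximum true count."""
    predicted = [int(c) for c in predicted]
    true = [int(c) for c in true]
    if not (len(image_ids) == len(predicted) == len(true)):
        raise ValueError("inputs must have equal length")
    if fine_scheme is None:
        fine_scheme = make_equal_bins(max(max(true), 20), 20)
    return [
        CfuRecord(image_id=str(i), predicted_count=p, true_count=t,
                  predicted_bin3=bin3(p), true_bin3=bin3(t),
                  predicted_bin_fine=int(fine_scheme.assign(p)),
                  true_bin_fine=int(fine_scheme.assign(t)))
        for i, p, t in zip(image_ids, predicted, true)]


def count_mae(records: Iterable[CfuRecord]) -> float:
    """Mean absolute error of the predicted colony counts."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    return float(np.mean([abs(r.predicted_count - r.true_count)
                          for r in records]))


@dataclass(frozen=True)
class BinnedAccuracy:
    """Overall bin-agreement accuracy plus per-true-bin breakdown."""

    overall: float
    per_bin: dict[int, float | None]   # None for bins with no records
    support: dict[int, int]


def binned_accuracy(records: Iterable[CfuRecord],
                    scheme: BinScheme) -> BinnedAccuracy:
    """Fraction of images whose predicted bin equals the true bin, overall
    and grouped by the TRUE bin (empty bins reported as undefined)."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    pred = scheme.assign(np.array([r.predicted_count for r in records]))
    true = scheme.assign(np.array([r.true_count for r in records]))
    hit = pred == true
    per_bin: dict[int, float | None] = {}
    support: dict[int, int] = {}
    for b in range(scheme.n_bins):
        sel = true == b
        support[b] = int(sel.sum())
        per_bin[b] = float(hit[sel].mean()) if sel.any() else None
    return BinnedAccuracy(overall=float(hit.mean()), per_bin=per_bin,
                          support=support)


def records_to_frame(records: Sequence[CfuRecord]) -> pd.DataFrame:
    """Tabular report of per-image counts and bins."""
    return pd.DataFrame([r.__dict__ for r in records])
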