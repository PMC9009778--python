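"""Per-ROI aggregation of fitted vertices into mean body-part response fields.

The central exchange format is the *vertex table*: one row per surface
vertex with its coordinates, ROI label, vertex area, fitted distances
dx_1..dx_18, derived center/size, fit statistics and FDR selection flag.
Aggregation averages the normalized response fields of all selected vertices
sharing a pRF center, per ROI, yielding the 18 x 18 mean response field that
feeds the body-part graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import normalized_proximity
from .task_design import BODY_PART_LABELS

__all__ = [
    "ROI_LABELS",
    "MeanResponseField",
    "normalized_proximity",
    "dx_columns",
    "mean_body_part_prf",
    "mean_over_subjects",
    "surface_area_by_center",
    "equalize_representation",
]

#: Cortical areas of the analysis: primary motor (M1) and somatosensory (S1)
#: cortex, supplementary motor area, dorsal/ventral premotor cortex, insular
#: cortex and inferior/superior parietal cortex.
ROI_LABELS: tuple[str, ...] = ("M1", "S1", "SMA", "PMd", "PMv", "Insula", "iPC", "sPC")


@dataclass(frozen=True)
class MeanResponseField:
    """Mean normalized response field per center body part, one ROI.

    ``mu[i - 1]`` is the average normalized-proximity 18-vector over selected
    vertices whose pRF center is body part ``i`` (1 = closest to the field
    center, 0 = at ``dx_max``); its diagonal entry is by construction the row
    maximum.  ``counts`` records how many vertices entered each row.
    """

    roi: str
    mu: np.ndarray  # (n_parts, n_parts)
    counts: np.ndarray  # (n_parts,)

    @property
    def n_parts(self) -> int:
        return self.mu.shape[0]

    def to_long(self, subject: str | int = "pooled") -> pd.DataFrame:
        """Long-format table (roi, center_part, part, mean_proximity, ...)."""
        rows = []
        for i in range(self.n_parts):
            for j in range(self.n_parts):
                rows.append(
                    {
                        "roi": self.roi,
                        "center_part": BODY_PART_LABELS[i],
                        "part": BODY_PART_LABELS[j],
                        "mean_proximity": self.mu[i, j],
                        "n_vertices": int(self.counts[i]),
                        "subject": subject,
                    }
                )
        return pd.DataFrame(rows)


def dx_columns(n_parts: int = 18) -> list[str]:
    return [f"dx_{i}" for i in range(1, n_parts + 1)]


def _selected_in_roi(table: pd.DataFrame, roi: str) -> pd.DataFrame:
    sub = table[table["roi"] == roi]
    if "selected" in sub.columns:
        sub = sub[sub["selected"].astype(bool)]
    return sub


def mean_body_part_prf(
    table: pd.DataFrame,
    roi: str,
    dx_max: float = 10.0,
    n_parts: int = 18,
) -> MeanResponseField:
    """Average normalized response fields per center body part in one ROI.

    Row i is the mean untruncated normalized proximity over selected
    vertices with ``center == i``; distant body parts therefore keep graded
    nonzero values rather than being zeroed at the HWHM window.  Every
    center must be represented by at least one vertex.
    """
    sub = _selected_in_roi(table, roi)
    cols = dx_columns(n_parts)
    mu = np.empty((n_parts, n_parts))
    counts = np.empty(n_parts, dtype=int)
    for i in range(1, n_parts + 1):
        rows = sub[sub["center"] == i]
        if len(rows) == 0:
            raise ValueError(
                f"ROI {roi!r}: no selected vertex has its pRF center at "
                f"body part {i} ({BODY_PART_LABELS[i - 1]})"
            )
        prox = normalized_proximity(rows[cols].to_numpy(dtype=float), dx_max)
        mu[i - 1] = prox.mean(axis=0)
        counts[i - 1] = len(rows)
    return MeanResponseField(roi=roi, mu=mu, counts=counts)


def mean_over_subjects(fields: list[MeanResponseField]) -> MeanResponseField:
    """Equal-weight average of per-subject mean response fields (one ROI)."""
    if not fields:
        raise ValueError("no fields to average")
    rois = {f.roi for f in fields}
    if len(rois) != 1:
        raise ValueError(f"fields span several ROIs: {sorted(rois)}")
    mu = np.mean([f.mu for f in fields], axis=0)
    counts = np.sum([f.counts for f in fields], axis=0)
    return MeanResponseField(roi=fields[0].roi, mu=mu, counts=counts)


def surface_area_by_center(
    table: pd.DataFrame, roi: str, n_parts: int = 18
) -> np.ndarray:
    """Fraction of the ROI's surface area preferring each body part.

    Vertex areas are summed per pRF center and normalized by the ROI's total
    selected surface area; the fractions sum to 1.
    """
    sub = _selected_in_roi(table, roi)
    if len(sub) == 0:
        raise ValueError(f"ROI {roi!r} contains no selected vertices")
    areas = sub["area"].to_numpy(dtype=float)
    if np.any(areas <= 0):
        raise ValueError("vertex areas must be positive")
    total = areas.sum()
    frac = np.zeros(n_parts)
    for i in range(1, n_parts + 1):
        frac[i - 1] = areas[(sub["center"] == i).to_numpy()].sum() / total
    return frac


def equalize_representation(
    table: pd.DataFrame, roi: str, seed: int = 0, n_parts: int = 18
) -> pd.DataFrame:
    """Subsample one ROI so every pRF center has the same vertex count.

    Each center's selected vertices are subsampled without replacement down
    to the minimum per-center count (seeded, reproducible); used to check
    that graph metrics are not driven by unequal body-part representation.
    Rows of other ROIs are dropped.
    """
    sub = _selected_in_roi(table, roi)
    counts = [int((sub["center"] == i).sum()) for i in range(1, n_parts + 1)]
    if min(counts) == 0:
        missing = counts.index(0) + 1
        raise ValueError(
            f"ROI {roi!r}: no selected vertex has its pRF center at "
            f"body part {missing} ({BODY_PART_LABELS[missing - 1]})"
        )
    target = min(counts)
    rng = np.random.default_rng(seed)
    kept = []
    for i in range(1, n_parts + 1):
        idx = sub.index[sub["center"] == i].to_numpy()
        kept.append(rng.choice(idx, size=target, replace=False))
    return sub.loc[np.sort(np.concatenate(kept))]
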