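"""File I/O, timeseries preparation and run configuration.

Plain tab-separated tables are the canonical on-disk format for every
artifact (events, vertex tables, mean response fields, edge lists, metric
tables); timeseries travel as dense vertices x volumes matrices.  NIfTI and
GIFTI readers are thin optional adapters so the core pipeline stays
format-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "prepare_timeseries",
    "dct_highpass_basis",
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
    "read_timeseries_nifti",
]


@dataclass
class RunConfig:
    """Validated pipeline configuration (key-value YAML on disk)."""

    tr: float = 2.1
    dx_max: float = 10.0
    boxcar: float = 3.0
    highpass_hz: float = 0.01
    drop_fraction: float = 0.05
    fdr_q: float = 0.05
    seed: int = 0  # randomness of simulation/subsampling
    schedule_seed: int = 0  # pseudo-randomization of the task schedule
    repetitions: int = 9
    base_iti: float = 10.0
    long_iti: float = 14.7
    volumes_per_run: tuple[int, ...] = (237, 191, 237, 191)
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    rois: tuple[str, ...] = ("M1", "S1", "SMA", "PMd", "PMv", "Insula", "iPC", "sPC")

    def __post_init__(self) -> None:
        if self.tr <= 0 or self.dx_max <= 0 or self.boxcar <= 0:
            raise ValueError("tr, dx_max and boxcar must be positive")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("volumes_per_run", "rois"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def dct_highpass_basis(n_volumes: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift basis below the cutoff frequency (plus mean).

    Returns an (n_volumes, K+1) column-orthonormal matrix whose first column
    is the constant and whose cosine columns span fluctuations slower than
    ``cutoff_hz``; regressing it out is the standard fMRI high-pass filter.
    """
    duration = n_volumes * tr
    K = int(np.floor(2.0 * duration * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [np.ones(n_volumes) / np.sqrt(n_volumes)]
    for k in range(1, K + 1):
        c = np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_volumes))
        cols.append(c / np.linalg.norm(c))
    return np.column_stack(cols)


def prepare_timeseries(
    raw_runs: list[np.ndarray], tr: float, cutoff_hz: float = 0.01
) -> np.ndarray:
    """Concatenate runs after high-pass filtering and percent-change scaling.

    Per run, slow drifts below ``cutoff_hz`` (and the mean) are removed by
    discrete-cosine regression, then the residual is scaled to percent
    signal change relative to the run's raw vertex mean; runs are
    concatenated in the given (protocol) order.
    """
    if not raw_runs:
        raise ValueError("no runs supplied")
    n_vertices = raw_runs[0].shape[0]
    out = []
    for r, run in enumerate(raw_runs):
        run = np.asarray(run, dtype=float)
        if run.shape[0] != n_vertices:
            raise ValueError(
                f"run {r + 1} has {run.shape[0]} vertices; expected {n_vertices}"
            )
        mean = run.mean(axis=1)
        if np.any(np.abs(mean) < 1e-12):
            raise ValueError(
                f"run {r + 1} contains zero-mean vertices; cannot scale to "
                "percent signal change"
            )
        X = dct_highpass_basis(run.shape[1], tr, cutoff_hz)
        filtered = run - (run @ X) @ X.T
        out.append(100.0 * filtered / mean[:, None])
    return np.concatenate(out, axis=1)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any artifact table as TSV at full float precision."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=["NA"])
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed table {path}: {err}") from err


def write_matrix(
    matrix: np.ndarray, path: str | Path, labels: list[str] | None = None
) -> None:
    """Dense matrix as TSV, optionally with a header row of labels."""
    df = pd.DataFrame(np.asarray(matrix))
    if labels is not None:
        df.columns = labels
    df.to_csv(path, sep="\t", index=False, header=labels is not None,
              float_format="%.17g")


def read_matrix(path: str | Path, header: bool = False) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", header=0 if header else None)
    return df.to_numpy(dtype=float)


def write_edge_list(graph, path: str | Path) -> None:
    """Body graph as a (part_a, part_b, weight) TSV of retained edges."""
    rows = [
        {"part_a": graph.labels[i], "part_b": graph.labels[j], "weight": w}
        for i, j, w in graph.edge_list()
    ]
    write_table(pd.DataFrame(rows, columns=["part_a", "part_b", "weight"]), path)


def read_edge_list(path: str | Path, labels: tuple[str, ...]):
    """Rebuild a body graph from an edge-list TSV over the given node set."""
    from .bodygraph import BodyGraph

    df = read_table(path)
    index = {lab: k for k, lab in enumerate(labels)}
    W = np.zeros((len(labels), len(labels)))
    for row in df.itertuples():
        try:
            i, j = index[row.part_a], index[row.part_b]
        except KeyError as err:
            raise ValueError(f"unknown body part in {path}: {err}") from err
        W[i, j] = W[j, i] = row.weight
    return BodyGraph(weights=W, labels=tuple(labels))


def read_timeseries_nifti(path: str | Path) -> np.ndarray:
    """Read a NIfTI/GIFTI timeseries into a vertices x volumes matrix."""
    try:
        import nibabel as nib
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "reading NIfTI/GIFTI requires the optional 'neuro' extra (nibabel)"
        ) from err
    img = nib.load(str(path))
    if hasattr(img, "darrays"):  # GIFTI: one darray per volume
        return np.column_stack([d.data for d in img.darrays])
    data = np.asarray(img.dataobj)
    return data.reshape(-1, data.shape[-1])
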