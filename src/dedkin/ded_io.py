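"""ASCII I/O: the ROI table dialect and the four run-output text files.

The region-of-interest (ROI) table is a tab-separated text file.  The first
column holds the voxel index of each ROI grid point in the parent map; the
remaining ``P`` columns hold the difference-electron-density value of that
voxel at each acquisition time, in chronological order.  Acquisition times
are *not* stored in the table; they travel in the run configuration.

A training run additionally emits four text files: the per-checkpoint
intermediate maps, the per-checkpoint rate coefficients, the per-iteration
loss, and the final concentration profiles on a dense time grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = ["DEDMapSeries", "RunOutputs", "read_roi_table", "write_roi_table", "write_run_outputs", "read_params_file"]


@dataclass
class DEDMapSeries:
    """An N-voxel x P-time-point matrix of DED values plus voxel indices.

    Attributes
    ----------
    voxel_index : int array, shape (N,)
        Position of each row in the parent map grid; unique.
    values : float array, shape (N, P)
        DED values, electrons/A^3.
    times : float array, shape (P,) or None
        Acquisition times, seconds, strictly increasing.  Optional because
        the ROI file format does not carry them.
    """

    voxel_index: np.ndarray
    values: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (N x P) array")
        n, p = self.values.shape
        if n < 1 or p < 2:
            raise ValueError(f"need N >= 1 voxels and P >= 2 time points, got N={n}, P={p}")
        if self.voxel_index.shape != (n,):
            raise ValueError("voxel_index length must equal the number of rows")
        if len(np.unique(self.voxel_index)) != n:
            raise ValueError("voxel_index entries must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (p,):
                raise ValueError("times length must equal the number of value columns")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass
class RunOutputs:
    """Text-file contract of a training run.

    ``intermediates_trace`` holds one N x M map block per kept checkpoint,
    ``rates_trace`` one length-R rate vector per kept checkpoint (s^-1),
    ``loss_trace`` one value per iteration, and ``concentrations_out`` the
    final (M + 1)-state profiles on a dense time grid.
    """

    intermediates_trace: list[np.ndarray]
    rates_trace: np.ndarray
    loss_trace: np.ndarray
    concentrations_out: np.ndarray
    concentration_times: np.ndarray
    checkpoint_iterations: np.ndarray
    rate_labels: tuple[str, ...] = ()


class ROIFormatError(ValueError):
    """Raised for structurally invalid ROI tables (named offending line)."""


def read_roi_table(path: str | os.PathLike) -> DEDMapSeries:
    """Read a tab-separated ROI table.

    The number of time points P is inferred from the column count; every row
    must carry ``1 + P`` numeric fields.
    """
    indices: list[int] = []
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if width is None:
                width = len(fields)
                if width < 3:
                    raise ROIFormatError(
                        f"{path}: line {lineno}: need at least 3 columns (index + >=2 time points), found {width}"
                    )
            elif len(fields) != width:
                raise ROIFormatError(f"{path}: line {lineno}: expected {width} fields, found {len(fields)}")
            try:
                idx = int(float(fields[0]))
                vals = [float(f) for f in fields[1:]]
            except ValueError as exc:
                raise ROIFormatError(f"{path}: line {lineno}: non-numeric field ({exc})") from None
            indices.append(idx)
            rows.append(vals)
    if not rows:
        raise ROIFormatError(f"{path}: empty ROI table")
    return DEDMapSeries(voxel_index=np.array(indices), values=np.array(rows))


def write_roi_table(series: DEDMapSeries, path: str | os.PathLike) -> None:
    """Write a DEDMapSeries as a tab-separated table at full double precision."""
    with open(path, "w") as fh:
        for idx, row in zip(series.voxel_index, series.values):
            fh.write(str(int(idx)) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_run_outputs(run: RunOutputs, out_dir: str | os.PathLike, checkpoint_stride: int = 1000) -> dict[str, str]:
    """Write the four run-output text files into ``out_dir``.

    intermediates.txt : N lines, M x (number of kept checkpoints) columns
    rates.txt         : one line per kept checkpoint, R columns (s^-1)
    loss.txt          : one line per iteration, single column
    concentrations.txt: one line per dense-grid time, time + M + 1 columns

    The intermediate/rate traces are subsampled every ``checkpoint_stride``
    iterations (recorded in a header comment); the loss is per-iteration.
    """
    if checkpoint_stride < 1:
        raise ValueError("checkpoint_stride must be a positive integer")
    if len(run.intermediates_trace) == 0 or len(run.rates_trace) == 0 or len(run.loss_trace) == 0:
        raise ValueError("run traces are empty")
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, name + ".txt") for name in ("intermediates", "rates", "loss", "concentrations")}

    keep = [i for i, it in enumerate(run.checkpoint_iterations) if it % checkpoint_stride == 0]
    if not keep:
        keep = [len(run.checkpoint_iterations) - 1]
    # always keep the final checkpoint
    if keep[-1] != len(run.checkpoint_iterations) - 1:
        keep.append(len(run.checkpoint_iterations) - 1)

    header = f"# checkpoint_stride = {checkpoint_stride}; iterations: " + " ".join(
        str(int(run.checkpoint_iterations[i])) for i in keep
    )
    blocks = np.hstack([run.intermediates_trace[i] for i in keep])
    np.savetxt(paths["intermediates"], blocks, delimiter="\t", header=header, comments="")

    rate_header = header
    if run.rate_labels:
        rate_header += "\n# " + "\t".join(run.rate_labels)
    np.savetxt(paths["rates"], np.asarray(run.rates_trace)[keep], delimiter="\t", header=rate_header, comments="")

    np.savetxt(paths["loss"], np.asarray(run.loss_trace).reshape(-1, 1), delimiter="\t")

    conc = np.column_stack([run.concentration_times, run.concentrations_out.T])
    np.savetxt(
        paths["concentrations"], conc, delimiter="\t",
        header="# time_s\t" + "\t".join(f"state_{i}" for i in range(run.concentrations_out.shape[0])), comments="",
    )
    return paths


def read_params_file(path: str | os.PathLike) -> dict[str, str]:
    """Parse a plain ``key = value`` parameter file; '#' starts a comment."""
    params: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            params[key.strip()] = value.strip()
    return params
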