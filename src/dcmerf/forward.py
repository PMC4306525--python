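"""Sensor-space forward model: lead fields, spatial modes, ERF containers.

Source pyramidal depolarisation maps linearly to sensors through a lead field
whose columns are smooth synthetic topographies (the electromagnetic head
model itself is out of scope).  Sensor data are reduced to a small number of
orthonormal spatial modes — the left singular vectors of the grand-average
data — which are shared across subjects and models so that model evidences
remain comparable.

The on-disk evoked-response container is a directory holding one CSV matrix
(channels x time) per condition plus a JSON metadata sidecar; a single-file
HDF5 mirror with the same schema is available by giving the path an ``.h5``
suffix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .nmm import SourceTrajectory

__all__ = [
    "LeadField",
    "SpatialModes",
    "ERFDataset",
    "ERFParseError",
    "project_to_sensors",
    "compute_spatial_modes",
    "retained_variance",
    "mode_reduce",
    "baseline_correct",
    "crop_erf",
    "read_erf",
    "write_erf",
    "synthesize_lead_field",
]


@dataclass
class LeadField:
    """Linear map from source pyramidal output to sensors.

    ``matrix`` is sensors x sources; ``log_output_gain`` holds one log-scale
    output gain per source (a free parameter of the inversion).
    """

    matrix: np.ndarray
    source_names: list[str]
    log_output_gain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead field must be finite")
        if self.matrix.shape[1] != len(self.source_names):
            raise ValueError("lead field columns must match source names")
        if self.log_output_gain is None:
            self.log_output_gain = np.zeros(self.matrix.shape[1])
        self.log_output_gain = np.asarray(self.log_output_gain, float)

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    def reordered(self, names: list[str]) -> "LeadField":
        """Columns permuted to a new source order (same source set)."""
        if set(names) != set(self.source_names):
            raise ValueError("reordering requires the same source set")
        perm = [self.source_names.index(n) for n in names]
        return LeadField(matrix=self.matrix[:, perm], source_names=list(names),
                         log_output_gain=self.log_output_gain[perm])


@dataclass
class SpatialModes:
    """Orthonormal spatial projection (modes x sensors)."""

    projection: np.ndarray

    def __post_init__(self) -> None:
        self.projection = np.asarray(self.projection, float)
        g = self.projection @ self.projection.T
        if not np.allclose(g, np.eye(len(g)), atol=1e-8):
            raise ValueError("mode rows must be orthonormal")

    @property
    def n_modes(self) -> int:
        return self.projection.shape[0]

    def apply(self, sensor_data: np.ndarray) -> np.ndarray:
        """Project channels x ... data into mode space."""
        return np.tensordot(self.projection, sensor_data, axes=(1, 0))


@dataclass
class ERFDataset:
    """Evoked responses of one subject: conditions x channels x time.

    ``time_ms`` is relative to stimulus onset; ``baseline_ms`` is the
    (start, end) window used for baseline correction.
    """

    data: np.ndarray
    conditions: list[str]
    fs_hz: float
    time_ms: np.ndarray
    baseline_ms: tuple[float, float] | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.time_ms = np.asarray(self.time_ms, float)
        if self.data.ndim != 3:
            raise ValueError("data must be conditions x channels x time")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("first axis must match condition labels")
        if self.data.shape[2] != len(self.time_ms):
            raise ValueError("last axis must match time axis")
        dt = np.diff(self.time_ms)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("time axis must be uniform")
        if not self.channel_names:
            self.channel_names = [f"ch{i:03d}" for i in range(self.data.shape[1])]
        if self.baseline_ms is not None:
            b0, b1 = self.baseline_ms
            if b1 <= b0:
                raise ValueError("baseline window must have positive width")
            if b1 < self.time_ms[0] or b0 > self.time_ms[-1]:
                raise ValueError("baseline window lies outside the epoch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


class ERFParseError(ValueError):
    pass


def project_to_sensors(traj: SourceTrajectory | np.ndarray, lf: LeadField,
                       source_names: list[str] | None = None) -> np.ndarray:
    """Map pyramidal output (sources x time) to sensors x time.

    Per-source output gains ``exp(log_output_gain)`` scale the columns; the
    map is exactly linear in the source activity.
    """
    if isinstance(traj, SourceTrajectory):
        pyr = traj.pyramidal_output
        names = traj.source_names
    else:
        pyr = np.asarray(traj, float)
        names = source_names
    if names is not None and list(names) != list(lf.source_names):
        raise ValueError(
            f"source order mismatch: trajectory {names} vs lead field {lf.source_names}"
        )
    gains = np.exp(lf.log_output_gain)
    return lf.matrix @ (gains[:, None] * pyr)


def compute_spatial_modes(data: ERFDataset | list[ERFDataset] | np.ndarray,
                          n_modes: int) -> SpatialModes:
    """Top left singular vectors of the channels x (time x conditions) data.

    Accepts one dataset, a list of datasets (concatenated along time), or a
    raw channels x anything matrix.  Deterministic up to sign; signs are fixed
    so each mode's largest-magnitude entry is positive.
    """
    if isinstance(data, ERFDataset):
        mats = [data.data.transpose(1, 0, 2).reshape(data.n_channels, -1)]
    elif isinstance(data, list):
        mats = [d.data.transpose(1, 0, 2).reshape(d.n_channels, -1) for d in data]
    else:
        mats = [np.asarray(data, float)]
    X = np.concatenate(mats, axis=1)
    if n_modes > X.shape[0]:
        raise ValueError(f"n_modes={n_modes} exceeds {X.shape[0]} channels")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    U = U[:, :n_modes]
    for j in range(U.shape[1]):
        k = np.argmax(np.abs(U[:, j]))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
    return SpatialModes(projection=U.T)


def retained_variance(data: ERFDataset | np.ndarray, modes: SpatialModes) -> float:
    """Fraction of total data variance captured by the mode projection."""
    X = data.data.transpose(1, 0, 2).reshape(data.n_channels, -1) if isinstance(
        data, ERFDataset) else np.asarray(data, float)
    total = float(np.sum(X ** 2))
    if total == 0:
        return 1.0
    return float(np.sum((modes.projection @ X) ** 2) / total)


def mode_reduce(data: ERFDataset, modes: SpatialModes, t0: float, t1: float) -> np.ndarray:
    """Baseline-correct, crop to the modelling window, project to mode space.

    Returns a modes x time x conditions array ready for inversion.
    """
    d = baseline_correct(data) if data.baseline_ms is not None else data
    d = crop_erf(d, t0, t1)
    return modes.apply(d.data.transpose(1, 2, 0))


def baseline_correct(data: ERFDataset) -> ERFDataset:
    """Subtract the per-channel mean over the baseline window; idempotent."""
    if data.baseline_ms is None:
        raise ValueError("dataset has no baseline window")
    b0, b1 = data.baseline_ms
    sel = (data.time_ms >= b0) & (data.time_ms <= b1)
    if not np.any(sel):
        raise ValueError("baseline window contains no samples")
    corrected = data.data - data.data[:, :, sel].mean(axis=2, keepdims=True)
    return replace(data, data=corrected)


def crop_erf(data: ERFDataset, t0: float, t1: float) -> ERFDataset:
    """Restrict the epoch to time points in [t0, t1] ms."""
    sel = (data.time_ms >= t0 - 1e-9) & (data.time_ms <= t1 + 1e-9)
    if not np.any(sel):
        raise ValueError("crop window contains no samples")
    b = data.baseline_ms
    if b is not None and (b[1] < data.time_ms[sel][0] or b[0] > data.time_ms[sel][-1]):
        b = None  # baseline window no longer inside the epoch
    return replace(data, data=data.data[:, :, sel], time_ms=data.time_ms[sel],
                   baseline_ms=b)


# ---------------------------------------------------------------------------
# on-disk container
# ---------------------------------------------------------------------------

_META_FIELDS = ("fs_hz", "time_ms", "conditions", "channel_names")


def write_erf(data: ERFDataset, path: str | Path) -> Path:
    """Write an ERF container (CSV directory, or single HDF5 if path ends .h5)."""
    path = Path(path)
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=data.data)
            f.create_dataset("time_ms", data=data.time_ms)
            f.attrs["fs_hz"] = data.fs_hz
            f.attrs["conditions"] = json.dumps(data.conditions)
            f.attrs["channel_names"] = json.dumps(data.channel_names)
            if data.baseline_ms is not None:
                f.attrs["baseline_ms"] = list(data.baseline_ms)
        return path
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs_hz": data.fs_hz,
        "time_ms": data.time_ms.tolist(),
        "conditions": data.conditions,
        "channel_names": data.channel_names,
        "baseline_ms": list(data.baseline_ms) if data.baseline_ms is not None else None,
    }
    (path / "erf.json").write_text(json.dumps(meta, indent=1))
    for c, label in enumerate(data.conditions):
        np.savetxt(path / f"condition_{label}.csv", data.data[c], delimiter=",",
                   fmt="%.17g")
    return path


def read_erf(path: str | Path) -> ERFDataset:
    """Read an ERF container written by :func:`write_erf` (lossless round trip)."""
    path = Path(path)
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "r") as f:
            for k in ("fs_hz", "conditions"):
                if k not in f.attrs:
                    raise ERFParseError(f"missing field {k!r} in {path}")
            baseline = tuple(f.attrs["baseline_ms"]) if "baseline_ms" in f.attrs else None
            return ERFDataset(
                data=f["data"][...],
                conditions=json.loads(f.attrs["conditions"]),
                fs_hz=float(f.attrs["fs_hz"]),
                time_ms=f["time_ms"][...],
                baseline_ms=baseline,
                channel_names=json.loads(f.attrs["channel_names"]),
            )
    sidecar = path / "erf.json"
    if not sidecar.exists():
        raise ERFParseError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for k in _META_FIELDS:
        if k not in meta:
            raise ERFParseError(f"missing field {k!r} in {sidecar}")
    mats = []
    for label in meta["conditions"]:
        f = path / f"condition_{label}.csv"
        if not f.exists():
            raise ERFParseError(f"missing condition matrix {f}")
        mats.append(np.atleast_2d(np.loadtxt(f, delimiter=",")))
    baseline = tuple(meta["baseline_ms"]) if meta.get("baseline_ms") else None
    return ERFDataset(
        data=np.stack(mats), conditions=meta["conditions"], fs_hz=meta["fs_hz"],
        time_ms=np.asarray(meta["time_ms"], float), baseline_ms=baseline,
        channel_names=meta["channel_names"],
    )


def synthesize_lead_field(
    n_sensors: int,
    source_names: list[str],
    seed: int,
    smooth_sd: float | None = None,
) -> LeadField:
    """Smooth synthetic topographies on a virtual sensor ring.

    Each source column is a seeded Gaussian random vector circularly smoothed
    with a Gaussian kernel (sd ``smooth_sd`` sensors, default ring/16), then
    normalised to unit norm.  Columns are linearly independent with
    overwhelming probability; rank is verified.
    """
    rng = np.random.default_rng(seed)
    S = len(source_names)
    if smooth_sd is None:
        smooth_sd = max(1.0, n_sensors / 16.0)
    pos = np.arange(n_sensors)
    d = np.minimum(pos[:, None] - pos[None, :], 0) + np.abs(pos[:, None] - pos[None, :])
    d = np.minimum(d, n_sensors - d)  # circular distance
    K = np.exp(-0.5 * (d / smooth_sd) ** 2)
    cols = K @ rng.standard_normal((n_sensors, S))
    cols /= np.linalg.norm(cols, axis=0, keepdims=True)
    if np.linalg.matrix_rank(cols) < S:
        raise RuntimeError("synthetic lead field is rank deficient; change seed")
    return LeadField(matrix=cols, source_names=list(source_names))
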