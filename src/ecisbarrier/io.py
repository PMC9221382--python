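"""Data model and tidy-CSV readers/writers for impedance spectra and surrogate traces.

Two on-disk formats are supported, both long (tidy) CSV:

* spectrum table: ``node_id,obs_axis,obs_index,frequency_hz,z_real_ohm,z_imag_ohm``
* trace table:    ``node_id,n_cycles,r1k_ohm,c64k_nf``

Impedance is stored as real/imaginary pairs (node-level ohms); the observation
axis is tagged explicitly as either culture hours or cumulative RD cycles so
the two time bases used in culture monitoring versus damage experiments can
never be mixed in one series.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Acquisition frequency grid: successive doubling from 62.5 Hz to 64 kHz (11 points).
DEFAULT_FREQUENCIES: np.ndarray = 62.5 * 2.0 ** np.arange(11)

#: Electrode geometry of the 8-node flow array.
ELECTRODES_PER_NODE = 10
ELECTRODE_DIAMETER_UM = 250.0

SPECTRUM_COLUMNS = [
    "node_id",
    "obs_axis",
    "obs_index",
    "frequency_hz",
    "z_real_ohm",
    "z_imag_ohm",
]
TRACE_COLUMNS = ["node_id", "n_cycles", "r1k_ohm", "c64k_nf"]

VALID_AXES = ("culture_hours", "cumulative_rd_cycles")


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class IntegrityError(ValueError):
    """Duplicate keys or inconsistent metadata."""


def node_area_cm2(
    n_electrodes: int = ELECTRODES_PER_NODE,
    diameter_um: float = ELECTRODE_DIAMETER_UM,
) -> float:
    """Total working-electrode area of one node in cm^2."""
    radius_cm = diameter_um * 1e-4 / 2.0
    return n_electrodes * np.pi * radius_cm**2


@dataclass
class SpectrumSeries:
    """Complex impedance spectra grouped by (node_id, obs_index).

    Parameters
    ----------
    data : DataFrame with the spectrum-table columns, sorted by
        (node_id, obs_index, frequency_hz).
    obs_axis : 'culture_hours' or 'cumulative_rd_cycles'; a single series never
        mixes the two time bases.
    """

    data: pd.DataFrame
    obs_axis: str = "cumulative_rd_cycles"
    electrode_count_per_node: int = ELECTRODES_PER_NODE
    electrode_diameter_um: float = ELECTRODE_DIAMETER_UM

    def __post_init__(self) -> None:
        if self.obs_axis not in VALID_AXES:
            raise SchemaError(f"obs_axis must be one of {VALID_AXES}, got {self.obs_axis!r}")
        missing = [c for c in SPECTRUM_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"spectrum data missing columns: {missing}")
        axes = set(self.data["obs_axis"].unique())
        if axes and axes != {self.obs_axis}:
            raise IntegrityError(f"mixed or mismatched obs_axis values: {sorted(axes)}")
        self.data = self.data.sort_values(
            ["node_id", "obs_index", "frequency_hz"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def total_electrode_area_cm2(self) -> float:
        return node_area_cm2(self.electrode_count_per_node, self.electrode_diameter_um)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.data["node_id"].unique())

    def obs_indices(self, node_id: int) -> np.ndarray:
        sub = self.data[self.data["node_id"] == node_id]
        return np.sort(sub["obs_index"].unique())

    def spectrum(self, node_id: int, obs_index: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (frequencies_hz, complex Z) for one (node, observation)."""
        sub = self.data[
            (self.data["node_id"] == node_id) & (self.data["obs_index"] == obs_index)
        ]
        if sub.empty:
            raise KeyError(f"no spectrum for node {node_id} at obs_index {obs_index}")
        f = sub["frequency_hz"].to_numpy(float)
        z = sub["z_real_ohm"].to_numpy(float) + 1j * sub["z_imag_ohm"].to_numpy(float)
        return f, z

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[int, float, float, complex]],
        obs_axis: str = "cumulative_rd_cycles",
        **meta,
    ) -> "SpectrumSeries":
        """Build from (node_id, obs_index, frequency_hz, Z) tuples."""
        rows = [
            {
                "node_id": int(n),
                "obs_axis": obs_axis,
                "obs_index": float(o),
                "frequency_hz": float(f),
                "z_real_ohm": float(np.real(z)),
                "z_imag_ohm": float(np.imag(z)),
            }
            for n, o, f, z in records
        ]
        return cls(pd.DataFrame(rows, columns=SPECTRUM_COLUMNS), obs_axis=obs_axis, **meta)


@dataclass
class SurrogateTrace:
    """Per-node real-time monitoring signals vs cumulative RD cycle count.

    r1k is the series resistance at 1 kHz (ohm), tracking tight-junction
    integrity; c64k is the series capacitance at 64 kHz (nF), tracking
    electrode coverage.
    """

    node_id: int
    n: np.ndarray
    r1k: np.ndarray
    c64k: np.ndarray
    epoch_size: int = 10

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.r1k = np.asarray(self.r1k, dtype=float)
        self.c64k = np.asarray(self.c64k, dtype=float)
        if not (len(self.n) == len(self.r1k) == len(self.c64k)):
            raise SchemaError("n, r1k and c64k must have equal length")
        if np.any(np.diff(self.n) < 0):
            raise IntegrityError("cycle counts must be non-decreasing")
        if np.any(self.r1k <= 0) or np.any(self.c64k <= 0):
            raise IntegrityError("r1k and c64k must be strictly positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurrogateTrace):
            return NotImplemented
        return (
            self.node_id == other.node_id
            and np.array_equal(self.n, other.n)
            and np.array_equal(self.r1k, other.r1k)
            and np.array_equal(self.c64k, other.c64k)
        )


def read_spectrum_table(path: str | Path, obs_axis: str | None = None) -> SpectrumSeries:
    """Read a long-format spectrum CSV into a validated :class:`SpectrumSeries`.

    Raises :class:`SchemaError` on missing columns, :class:`ParseError` on
    non-numeric cells (with the offending row number), and
    :class:`IntegrityError` on duplicate (node, obs_index, frequency) keys.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header") from exc
    missing = [c for c in SPECTRUM_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    numeric = {}
    for col in ["node_id", "obs_index", "frequency_hz", "z_real_ohm", "z_imag_ohm"]:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +2: header line and 1-based numbering
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
        numeric[col] = parsed
    df = pd.DataFrame(numeric)
    df["node_id"] = df["node_id"].astype(int)
    df["obs_axis"] = raw["obs_axis"]
    df = df[SPECTRUM_COLUMNS]
    dup = df.duplicated(subset=["node_id", "obs_index", "frequency_hz"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["node_id", "obs_index", "frequency_hz"]].tolist()
        raise IntegrityError(f"{path}: duplicate (node, obs, frequency) key {key}")
    axes = df["obs_axis"].unique().tolist()
    if len(axes) != 1:
        raise IntegrityError(f"{path}: mixed obs_axis values {axes}")
    if obs_axis is not None and axes[0] != obs_axis:
        raise IntegrityError(f"{path}: obs_axis {axes[0]!r} does not match requested {obs_axis!r}")
    return SpectrumSeries(df, obs_axis=axes[0])


def write_spectrum_table(series: SpectrumSeries, path: str | Path) -> Path:
    path = Path(path)
    series.data.to_csv(path, index=False)
    return path


def write_trace_table(traces: Sequence[SurrogateTrace], path: str | Path) -> Path:
    """Write surrogate traces to the trace CSV; the round trip through
    :func:`read_trace_table` is lossless (full float precision)."""
    path = Path(path)
    if len(traces) == 0:
        warnings.warn("writing an empty trace collection (header-only file)")
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "node_id": np.full(len(t.n), t.node_id, dtype=int),
                    "n_cycles": t.n,
                    "r1k_ohm": t.r1k,
                    "c64k_nf": t.c64k,
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    # 17 significant digits round-trip any float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trace_table(path: str | Path, epoch_size: int = 10) -> list[SurrogateTrace]:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    traces = []
    for node_id, sub in df.groupby("node_id", sort=True):
        traces.append(
            SurrogateTrace(
                node_id=int(node_id),
                n=sub["n_cycles"].to_numpy(float),
                r1k=sub["r1k_ohm"].to_numpy(float),
                c64k=sub["c64k_nf"].to_numpy(float),
                epoch_size=epoch_size,
            )
        )
    return traces


@dataclass
class ValidationIssue:
    kind: str  # 'completeness' | 'monotonicity' | 'physicality'
    node_id: int
    obs_index: float | None
    message: str


def validate_series(
    series: SpectrumSeries, grid: np.ndarray | None = None
) -> list[ValidationIssue]:
    """Report (without raising) completeness, monotonicity and physicality issues.

    Completeness is checked against the default 11-frequency doubling grid
    unless another grid is supplied. The operation is read-only and idempotent.
    """
    grid = DEFAULT_FREQUENCIES if grid is None else np.asarray(grid, float)
    issues: list[ValidationIssue] = []
    for node in series.nodes:
        obs = series.obs_indices(node)
        if np.any(np.diff(obs) <= 0):
            issues.append(
                ValidationIssue("monotonicity", node, None, "obs_index not strictly increasing")
            )
        for o in obs:
            f, z = series.spectrum(node, o)
            missing = sorted(set(np.round(grid, 6)) - set(np.round(f, 6)))
            if missing:
                issues.append(
                    ValidationIssue(
                        "completeness",
                        node,
                        float(o),
                        f"node {node} obs {o}: missing frequencies {missing}",
                    )
                )
            neg = np.flatnonzero(np.real(z) < 0)
            for i in neg:
                issues.append(
                    ValidationIssue(
                        "physicality",
                        node,
                        float(o),
                        f"node {node} obs {o}: negative resistance at {f[i]} Hz",
                    )
                )
    return issues


@dataclass
class FitReport:
    """Aggregated per-node fit results with provenance, serialized as JSON."""

    schema_version: str = "1"
    provenance: dict = field(default_factory=dict)
    nodes: dict = field(default_factory=dict)
    cases: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": self.schema_version,
                "provenance": self.provenance,
                "nodes": self.nodes,
                "cases": self.cases,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config for provenance fields."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
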