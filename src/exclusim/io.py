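"""Plain-text readers and writers for snapshots, trajectories and patterns.

Formats (all delimited text with ``#`` header comment lines):

* snapshot: ``# L=<int>``, ``# D=<d11,d12,d22>``, ``# seed=<int>``,
  ``# step=<int>`` then rows ``row,col,type`` (types 1/2 only, empties
  implicit).  The reader validates ranges and admissibility.
* trajectory: ``step,density1,density2,ratio`` CSV with parameter headers.
* point pattern: ``# field_um=<float> seed=<int>`` then ``x_um,y_um,type``.
* growth table: ``time,value[,sd]`` CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .initial import PointPattern
from .lattice import ExclusionRule, LatticeConfig, is_admissible

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_trajectory",
    "read_trajectory",
    "write_point_pattern",
    "read_point_pattern",
    "read_growth_table",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file does not conform to its documented format."""


def _parse_headers(path: PathLike) -> tuple[dict[str, str], int]:
    """Collect ``# key=value`` headers; return them and the header line count."""
    headers: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            for tok in line[1:].strip().split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    headers[k] = v
    return headers, n


def write_snapshot(
    path: PathLike,
    config: LatticeConfig,
    rule: ExclusionRule,
    seed: Optional[int] = None,
    step: Optional[int] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# L={config.L}\n")
        fh.write(f"# D={rule.d11},{rule.d12},{rule.d22}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if step is not None:
            fh.write(f"# step={step}\n")
        fh.write("row,col,type\n")
        for r, c in config.occupied_sites():
            fh.write(f"{r},{c},{config.state[r, c]}\n")


def read_snapshot(path: PathLike) -> tuple[LatticeConfig, ExclusionRule, dict[str, str]]:
    """Load a snapshot, validating site ranges and admissibility."""
    headers, n_header = _parse_headers(path)
    if "L" not in headers or "D" not in headers:
        raise FormatError(f"{path}: snapshot header must declare L and D")
    L = int(headers["L"])
    try:
        d11, d12, d22 = (int(v) for v in headers["D"].split(","))
    except ValueError as err:
        raise FormatError(f"{path}: malformed D header {headers['D']!r}") from err
    rule = ExclusionRule(d11=d11, d12=d12, d22=d22)
    config = LatticeConfig.empty(L)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= n_header or not line.strip():
                continue
            if line.startswith("row"):
                continue
            parts = line.strip().split(",")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected row,col,type")
            try:
                r, c, t = (int(p) for p in parts)
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: non-integer field") from err
            if not (0 <= r < L and 0 <= c < L):
                raise FormatError(f"{path}:{lineno}: site ({r},{c}) outside L={L}")
            if t not in (1, 2):
                raise FormatError(f"{path}:{lineno}: cell type must be 1 or 2, got {t}")
            if config.state[r, c] != 0:
                raise FormatError(f"{path}:{lineno}: duplicate site ({r},{c})")
            config.state[r, c] = t
    if not is_admissible(config, rule):
        raise FormatError(f"{path}: configuration is not admissible under D={headers['D']}")
    return config, rule, headers


def write_trajectory(path: PathLike, traj: Trajectory, metadata: Optional[dict] = None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("step,density1,density2,ratio\n")
        for s, d1, d2, q in zip(traj.steps, traj.density1, traj.density2, traj.ratio):
            fh.write(f"{s},{d1:.10g},{d2:.10g},{q:.10g}\n")


def read_trajectory(path: PathLike) -> tuple[Trajectory, dict[str, str]]:
    headers, _ = _parse_headers(path)
    df = pd.read_csv(path, comment="#")
    for col in ("step", "density1", "density2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    traj = Trajectory(
        steps=df["step"].to_numpy(dtype=np.int64),
        density1=df["density1"].to_numpy(dtype=float),
        density2=df["density2"].to_numpy(dtype=float),
    )
    return traj, headers


def write_point_pattern(path: PathLike, pattern: PointPattern, seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        seed_part = f" seed={seed}" if seed is not None else ""
        fh.write(f"# field_um={pattern.field_um:g}{seed_part}\n")
        fh.write("x_um,y_um,type\n")
        for x, y, t in zip(pattern.x, pattern.y, pattern.cell_type):
            fh.write(f"{x:.10g},{y:.10g},{t}\n")


def read_point_pattern(path: PathLike) -> PointPattern:
    headers, _ = _parse_headers(path)
    if "field_um" not in headers:
        raise FormatError(f"{path}: point pattern header must declare field_um")
    df = pd.read_csv(path, comment="#")
    for col in ("x_um", "y_um", "type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    try:
        return PointPattern(
            x=df["x_um"].to_numpy(float),
            y=df["y_um"].to_numpy(float),
            cell_type=df["type"].to_numpy(int),
            field_um=float(headers["field_um"]),
        )
    except ValueError as err:
        raise FormatError(f"{path}: {err}") from err


def read_growth_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in ("time", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df
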