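"""Tabular text I/O, analysis configuration and packaged sequence fixtures.

All interchange formats are plain text: a long-format trace table
(molecule_id, frame, time_s, donor, acceptor), two-column spectrum /
kinetic / melting / titration tables with a one-line header, and
key-value report files. Writers are atomic (temp file + rename) so a
failed run never leaves a partial artifact.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .traces import IntensityTrajectory

__all__ = [
    "AnalysisConfig",
    "SequenceFixture",
    "load_sequences",
    "read_trace_table",
    "write_trace_table",
    "read_two_column",
    "write_two_column",
    "write_report",
    "atomic_write",
]

TRACE_COLUMNS = ["molecule_id", "frame", "time_s", "donor", "acceptor"]


class AnalysisConfig(BaseModel):
    """All pipeline tunables in one validated, hashable record.

    Unknown keys are rejected so a typo in a config file fails loudly
    instead of silently using a default. The config hash is embedded in
    every report for provenance.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    # trace processing
    first_frames: int = 15
    bin_width: float = 0.02
    hist_range: tuple[float, float] = (-0.1, 1.1)
    min_total_frac: float = 0.1  # of ensemble-median total intensity
    bleach_step_sigma: float = 5.0
    # population fitting
    components: str = "auto"  # auto | 1 | 2
    f_test_alpha: float = 0.01
    # kinetics
    median_filter: bool = True
    dwell_bin_frames: int = 2
    min_dwells: int = 30
    rate_method: str = "occupancy"  # headline estimator; histogram/mle also computed
    temperature_K: float = 293.15
    # spectroscopy
    sg_window: int = 11
    sg_order: int = 3

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SequenceFixture:
    """A named DNA sequence shipped with the package (5'->3')."""

    name: str
    sequence: str
    role: str

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.name}: non-ACGT characters in sequence")


_ROLES = {
    "G4_IX": "G4 motif",
    "G4_IXmut": "mutant",
    "FRET_G4_strand": "FRET strand (Cy3, G4-containing)",
    "FRET_biotin_strand": "FRET strand (Cy5-biotin anchor)",
}


def load_sequences() -> dict[str, SequenceFixture]:
    """Load the packaged oligonucleotide fixtures from FASTA."""
    text = resources.files("g4fold").joinpath("data/sequences.fasta").read_text()
    out: dict[str, SequenceFixture] = {}
    name, chunks = None, []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                out[name] = SequenceFixture(name, "".join(chunks), _ROLES.get(name, "other"))
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line)
    if name is not None:
        out[name] = SequenceFixture(name, "".join(chunks), _ROLES.get(name, "other"))
    return out


def atomic_write(path: str | Path, text: str) -> None:
    """Write text via a temp file and atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_trace_table(
    trajectories: Iterable[IntensityTrajectory], path: str | Path
) -> None:
    """Write trajectories as one long-format tab-separated table."""
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": traj.molecule_id,
                    "frame": np.arange(traj.n_frames),
                    "time_s": traj.time,
                    "donor": traj.donor,
                    "acceptor": traj.acceptor,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    atomic_write(path, df.to_csv(sep="\t", index=False, float_format="%.6f"))


def read_trace_table(path: str | Path) -> list[IntensityTrajectory]:
    """Read a long-format trace table back into trajectories.

    Malformed numeric cells are reported with their 1-based data row
    number; an empty file yields an empty list.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        import logging

        logging.getLogger(__name__).warning("%s is empty", path)
        return []
    df = pd.read_csv(path, sep="\t", dtype={"molecule_id": str})
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("frame", "time_s", "donor", "acceptor"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if bad.size:
            raise ValueError(f"{path}: non-numeric value in column '{col}' at data row {bad[0] + 1}")
        df[col] = coerced
    out = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame")
        t = grp["time_s"].to_numpy()
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        out.append(
            IntensityTrajectory(
                molecule_id=str(mol),
                time=t,
                donor=grp["donor"].to_numpy(),
                acceptor=grp["acceptor"].to_numpy(),
                frame_interval=dt,
            )
        )
    return out


def read_two_column(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a two-column table with a one-line header and optional
    ``# key: value`` metadata lines; returns (x, y, metadata)."""
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    header_seen = False
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    k, v = line[1:].split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.replace(",", "\t").split()
            if not header_seen:
                header_seen = True
                meta["columns"] = "\t".join(parts)
                continue
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed data at line {i}") from exc
    xy = np.array(rows, dtype=float)
    if xy.size == 0:
        raise ValueError(f"{path}: no data rows")
    return xy[:, 0], xy[:, 1], meta


def write_two_column(
    path: str | Path,
    x: np.ndarray,
    y: np.ndarray,
    x_name: str,
    y_name: str,
    metadata: dict | None = None,
) -> None:
    lines = []
    for k, v in (metadata or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append(f"{x_name}\t{y_name}")
    for xi, yi in zip(x, y):
        lines.append(f"{xi:.6g}\t{yi:.6g}")
    atomic_write(path, "\n".join(lines) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path: str | Path, report: dict, config: AnalysisConfig) -> None:
    """Write a structured report as JSON with a provenance block."""
    payload = {
        "provenance": {
            "package": "g4fold",
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        **_jsonable(report),
    }
    atomic_write(path, json.dumps(payload, indent=2, default=str) + "\n")
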