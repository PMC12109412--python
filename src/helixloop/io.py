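"""File I/O, run configuration and trajectory bookkeeping.

Plain-text interchange formats only: single- or multi-model PDB for
atomic snapshots, CSV for frame tables, histograms and parameter tables,
JSON for fit reports, YAML for run configuration.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser

from .helix_build import Atom, AtomicModel, BpFrame, DuplexPath

__all__ = [
    "PdbFormatError",
    "write_pdb",
    "read_multimodel_pdb",
    "write_frame_table",
    "read_frame_table",
    "write_histogram_series",
    "read_histogram_series",
    "trajectory_bookkeeping",
    "RunConfig",
    "load_config",
]


class PdbFormatError(ValueError):
    """Malformed PDB input; the message names the offending line."""


# ---------------------------------------------------------------------------
# PDB

_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s} {resname:>3s} {chain:1s}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def _format_atom_name(name: str) -> str:
    # standard PDB convention: one/two-letter element names start in col 14
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(models: list[AtomicModel] | AtomicModel, path: str | Path) -> None:
    """Write one or more atomic models; multiple models get MODEL/ENDMDL
    records (a trajectory), a single model is written bare."""
    if isinstance(models, AtomicModel):
        models = [models]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for m_idx, model in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {m_idx:>4d}\n")
            serial = 0
            prev_chain = None
            for atom in model.atoms:
                if prev_chain is not None and atom.chain != prev_chain:
                    fh.write("TER\n")
                prev_chain = atom.chain
                serial += 1
                fh.write(
                    _ATOM_FMT.format(
                        serial=serial,
                        name=_format_atom_name(atom.name),
                        resname=atom.resname,
                        chain=atom.chain,
                        resseq=atom.resseq,
                        x=atom.xyz[0],
                        y=atom.xyz[1],
                        z=atom.xyz[2],
                        occ=1.0,
                        b=0.0,
                        element=atom.element,
                    )
                )
            fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _validate_model_records(path: str | Path) -> None:
    """Cheap structural pre-scan: MODEL/ENDMDL pairing, with line numbers."""
    open_model_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if open_model_line is not None:
                    raise PdbFormatError(
                        f"line {lineno}: MODEL record opened while the MODEL "
                        f"from line {open_model_line} is still open"
                    )
                open_model_line = lineno
            elif rec == "ENDMDL":
                if open_model_line is None:
                    raise PdbFormatError(f"line {lineno}: ENDMDL without MODEL")
                open_model_line = None
            elif rec == "ATOM":
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError as exc:
                    raise PdbFormatError(
                        f"line {lineno}: malformed ATOM coordinates"
                    ) from exc
    if open_model_line is not None:
        raise PdbFormatError(
            f"MODEL record at line {open_model_line} is never closed (truncated file)"
        )


def read_multimodel_pdb(path: str | Path) -> list[AtomicModel]:
    """Read an ordered trajectory of atomic models from a (multi-model)
    PDB file, preserving chain/residue/atom identity."""
    _validate_model_records(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    models = []
    for model in structure:
        atoms = []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    atoms.append(
                        Atom(
                            name=atom.get_name(),
                            element=(atom.element or atom.get_name()[0]).strip(),
                            xyz=np.array(atom.get_coord(), dtype=float),
                            resname=residue.get_resname().strip(),
                            resseq=residue.get_id()[1],
                            chain=chain.get_id(),
                        )
                    )
        models.append(AtomicModel(atoms=tuple(atoms)))
    if not models:
        raise PdbFormatError("no models found in PDB file")
    return models


# ---------------------------------------------------------------------------
# Frame tables (CSV)

_FRAME_COLUMNS = [
    "snapshot", "bp_id", "identity", "closed",
    "ox", "oy", "oz",
    "xx", "xy", "xz", "yx", "yy", "yz", "zx", "zy", "zz",
]


def write_frame_table(paths: list[DuplexPath] | DuplexPath, out: str | Path) -> None:
    """Write one or more duplex paths as a tidy CSV of bp frames (origin
    plus triad columns, one row per bp per snapshot)."""
    if isinstance(paths, DuplexPath):
        paths = [paths]
    rows = []
    for s_idx, p in enumerate(paths):
        for f in p.frames:
            rows.append(
                [s_idx, f.bp_id, f.identity, p.closed, *f.origin,
                 *f.triad[:, 0], *f.triad[:, 1], *f.triad[:, 2]]
            )
    pd.DataFrame(rows, columns=_FRAME_COLUMNS).to_csv(out, index=False)


def read_frame_table(path: str | Path) -> list[DuplexPath]:
    df = pd.read_csv(path)
    missing = set(_FRAME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"frame table missing columns: {sorted(missing)}")
    paths = []
    for _, group in df.groupby("snapshot", sort=True):
        frames = []
        for _, row in group.iterrows():
            triad = np.column_stack(
                [
                    row[["xx", "xy", "xz"]].to_numpy(dtype=float),
                    row[["yx", "yy", "yz"]].to_numpy(dtype=float),
                    row[["zx", "zy", "zz"]].to_numpy(dtype=float),
                ]
            )
            frames.append(
                BpFrame(
                    origin=row[["ox", "oy", "oz"]].to_numpy(dtype=float),
                    triad=triad,
                    bp_id=int(row["bp_id"]),
                    identity=str(row["identity"]),
                )
            )
        paths.append(
            DuplexPath(frames=tuple(frames), closed=bool(group["closed"].iloc[0]))
        )
    return paths


# ---------------------------------------------------------------------------
# Histogram CSV (columns: time_min, bin_left, bin_right, count)

def write_histogram_series(series, out: str | Path) -> None:
    rows = []
    for t, counts in zip(series.timepoints, series.counts):
        for b, c in enumerate(counts):
            rows.append(
                [t, series.bin_edges[b], series.bin_edges[b + 1], int(c)]
            )
    pd.DataFrame(
        rows, columns=["time_min", "bin_left", "bin_right", "count"]
    ).to_csv(out, index=False)


def read_histogram_series(path: str | Path):
    from .synth_fret import HistogramSeries

    df = pd.read_csv(path)
    required = {"time_min", "bin_left", "bin_right", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"histogram CSV must have columns {sorted(required)}")
    times = np.sort(df["time_min"].unique())
    first = df[df["time_min"] == times[0]].sort_values("bin_left")
    edges = np.append(first["bin_left"].to_numpy(), first["bin_right"].iloc[-1])
    counts = np.array(
        [
            df[df["time_min"] == t].sort_values("bin_left")["count"].to_numpy()
            for t in times
        ]
    )
    return HistogramSeries(
        timepoints=times,
        bin_edges=edges,
        counts=counts,
        looped_counts=np.zeros(len(times), dtype=int),
    )


# ---------------------------------------------------------------------------
# Trajectory bookkeeping

def trajectory_bookkeeping(
    duration_ns: float, save_interval_ps: float, discard_ns: float
) -> tuple[int, int]:
    """Snapshot counts for a saved trajectory.

    Returns ``(n_saved, n_analyzed)`` with floor behavior for
    non-divisible intervals: e.g. a 300 ns run saved every 10 ps gives
    30,000 snapshots, and discarding the first 100 ns leaves 20,000 for
    analysis.
    """
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    interval_ns = save_interval_ps / 1000.0
    if not 0 < interval_ns <= duration_ns:
        raise ValueError("save interval must be in (0, duration]")
    if not 0 <= discard_ns < duration_ns:
        raise ValueError("discard must be in [0, duration)")
    n_saved = int(np.floor(duration_ns / interval_ns + 1e-9))
    n_analyzed = int(np.floor((duration_ns - discard_ns) / interval_ns + 1e-9))
    return n_saved, n_analyzed


# ---------------------------------------------------------------------------
# Run configuration

_KNOWN_SECTIONS = {"seed", "outdir", "log_level", "simulate", "kinetics", "build",
                   "analyze", "circle"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; unknown top-level keys are rejected."""

    seed: int = 0
    outdir: str = "."
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    build: dict = field(default_factory=dict)
    analyze: dict = field(default_factory=dict)
    circle: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
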