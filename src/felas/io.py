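"""Plain-text I/O: LAMMPS-style dump, extended XYZ, stress tables, patterns.

All trajectory output carries unwrapped coordinates (``xu yu zu``) plus the
box, which is what every analysis routine needs; wrapped copies are
recomputed on demand.  FASTA input goes through Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .engine import StressSeries, Topology, Trajectory
from .landscape import StickerPattern
from .phase import CoexistencePoint, CriticalFit

__all__ = [
    "read_fasta",
    "write_lammps_dump",
    "read_lammps_dump",
    "write_xyz",
    "read_xyz",
    "write_stress",
    "read_stress",
    "write_pattern_json",
    "read_pattern_json",
    "write_pattern_table",
    "write_binodal_csv",
    "read_binodal_csv",
    "write_critical_fit_json",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines fine) as {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_lammps_dump(trajectory: Trajectory, path: str | Path) -> None:
    """Text dump with `id type xu yu zu` columns and orthogonal box bounds."""
    topo = trajectory.topology
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{trajectory.times[f]:.10g}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{topo.n_beads}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write(f"0.0 {trajectory.box[d]:.10g}\n")
            fh.write("ITEM: ATOMS id type xu yu zu\n")
            pos = trajectory.positions[f]
            for i in range(topo.n_beads):
                fh.write(
                    f"{i + 1} {topo.bead_type[i] + 1} "
                    f"{pos[i, 0]:.10g} {pos[i, 1]:.10g} {pos[i, 2]:.10g}\n"
                )


def read_lammps_dump(
    path: str | Path, n_chains: int | None = None, chain_length: int | None = None
) -> Trajectory:
    """Read back the dump format written by :func:`write_lammps_dump`."""
    times, frames = [], []
    box = np.zeros(3)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        assert lines[i].startswith("ITEM: TIMESTEP")
        times.append(float(lines[i + 1]))
        n = int(lines[i + 3])
        for d in range(3):
            lo, hi = map(float, lines[i + 5 + d].split())
            box[d] = hi - lo
        start = i + 9
        rows = np.array(
            [list(map(float, lines[start + k].split())) for k in range(n)]
        )
        order = np.argsort(rows[:, 0])
        rows = rows[order]
        frames.append(rows[:, 2:5])
        i = start + n
    pos = np.stack(frames)
    n_atoms = pos.shape[1]
    if chain_length is None:
        chain_length = n_atoms if n_chains is None else n_atoms // n_chains
    if n_chains is None:
        n_chains = n_atoms // chain_length
    topo = Topology.linear(n_chains, chain_length)
    return Trajectory(
        times=np.asarray(times), positions=pos, box=box.copy(), topology=topo
    )


def write_xyz(trajectory: Trajectory, path: str | Path) -> None:
    """Extended XYZ with a Lattice record and unwrapped coordinates."""
    topo = trajectory.topology
    b = trajectory.box
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{topo.n_beads}\n")
            fh.write(
                f'Lattice="{b[0]} 0 0 0 {b[1]} 0 0 0 {b[2]}" '
                f"Properties=species:S:1:pos:R:3 Time={trajectory.times[f]}\n"
            )
            pos = trajectory.positions[f]
            for i in range(topo.n_beads):
                fh.write(
                    f"T{topo.bead_type[i]} "
                    f"{pos[i, 0]:.10g} {pos[i, 1]:.10g} {pos[i, 2]:.10g}\n"
                )


def read_xyz(
    path: str | Path, n_chains: int | None = None, chain_length: int | None = None
) -> Trajectory:
    times, frames = [], []
    box = np.ones(3)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        header = lines[i + 1]
        if "Lattice=" in header:
            lat = header.split('Lattice="')[1].split('"')[0].split()
            box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
        t = 0.0
        for tok in header.split():
            if tok.startswith("Time="):
                t = float(tok[5:])
        times.append(t)
        rows = np.array(
            [lines[i + 2 + k].split()[1:4] for k in range(n)], dtype=float
        )
        frames.append(rows)
        i += 2 + n
    pos = np.stack(frames)
    n_atoms = pos.shape[1]
    if chain_length is None:
        chain_length = n_atoms if n_chains is None else n_atoms // n_chains
    if n_chains is None:
        n_chains = n_atoms // chain_length
    topo = Topology.linear(n_chains, chain_length)
    return Trajectory(
        times=np.asarray(times), positions=pos, box=box, topology=topo
    )


def write_stress(series: StressSeries, path: str | Path) -> None:
    df = pd.DataFrame(series.data, columns=list(StressSeries.COLUMNS))
    df.insert(0, "time", series.times)
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# volume={series.volume} temperature={series.temperature}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_stress(path: str | Path) -> StressSeries:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            tok.split("=") for tok in header.lstrip("#").split() if "=" in tok
        )
        df = pd.read_csv(fh, sep="\t")
    return StressSeries(
        times=df["time"].to_numpy(),
        data=df[list(StressSeries.COLUMNS)].to_numpy(),
        volume=float(meta.get("volume", np.nan)),
        temperature=float(meta.get("temperature", np.nan)),
    )


def write_pattern_json(pattern: StickerPattern, path: str | Path) -> None:
    Path(path).write_text(pattern.to_json())


def read_pattern_json(path: str | Path) -> StickerPattern:
    return StickerPattern.from_json(Path(path).read_text())


def write_pattern_table(pattern: StickerPattern, path: str | Path) -> None:
    """Delimited text: index, well_depth, is_sticker."""
    df = pd.DataFrame(
        {
            "index": np.arange(pattern.n_residues),
            "well_depth": pattern.well_depth,
            "is_sticker": pattern.is_sticker.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_binodal_csv(points: list[CoexistencePoint], path: str | Path) -> None:
    pd.DataFrame(
        {
            "T": [p.T for p in points],
            "rho_liquid": [p.rho_liquid for p in points],
            "rho_vapor": [p.rho_vapor for p in points],
        }
    ).to_csv(path, index=False)


def read_binodal_csv(path: str | Path) -> list[CoexistencePoint]:
    df = pd.read_csv(path)
    return [
        CoexistencePoint(T=r.T, rho_liquid=r.rho_liquid, rho_vapor=r.rho_vapor)
        for r in df.itertuples()
    ]


def write_critical_fit_json(fit: CriticalFit, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "Tc": fit.Tc,
                "rho_c": fit.rho_c,
                "A": fit.A,
                "delta_rho0": fit.delta_rho0,
                "beta": fit.beta,
                "stderr": fit.stderr,
            },
            indent=2,
        )
    )
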