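"""File formats: PLUMED-dialect COLVAR/HILLS text, PDB/GRO structures,
CSV frame sequences, and JSON reports with provenance.

COLVAR/HILLS files use the whitespace table format with a ``#! FIELDS ...``
header so that third-party reweighting tools can consume them. Structures
are written as standard-column PDB (species tag in the residue name, leaflet
tag in the chain ID) or fixed-width GRO in nm; charges and radii are
re-derived from the species tables on read, coordinates round-trip to the
format precision (0.001 nm).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Sequence

import numpy as np

from .constants import SPECIES_CHARGE, SPECIES_RADIUS
from .cv import CVSample
from .engine import BiasState
from .structures import ToyStructure

COLVAR_FIELDS = ("time", "z", "theta", "phi", "min_zr")
HILLS_FIELDS = ("time", "center", "sigma", "height")


# -- PLUMED-dialect tables --------------------------------------------------

def write_plumed_table(path, fields: Sequence[str], rows: np.ndarray) -> None:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for row in rows:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_plumed_table(path):
    """Parse a ``#! FIELDS`` whitespace table; malformed lines are reported
    with their line number."""
    fields = None
    data: List[List[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line.split()
                if len(parts) >= 2 and parts[1] == "FIELDS":
                    fields = parts[2:]
                continue
            if line.startswith("#"):
                continue
            vals = line.split()
            if fields is None:
                raise ValueError(f"{path}: data before a #! FIELDS header "
                                 f"(line {ln})")
            if len(vals) != len(fields):
                raise ValueError(f"{path}: line {ln} has {len(vals)} columns, "
                                 f"expected {len(fields)} ({' '.join(fields)})")
            try:
                data.append([float(v) for v in vals])
            except ValueError:
                raise ValueError(f"{path}: line {ln} is not numeric: {line!r}"
                                 ) from None
    if fields is None:
        raise ValueError(f"{path}: no #! FIELDS header found")
    return fields, np.asarray(data, dtype=float).reshape(-1, len(fields))


def write_colvar(path, samples: Sequence[CVSample]) -> None:
    rows = [[s.time, s.z_abs, s.theta, s.phi, s.min_zr] for s in samples]
    write_plumed_table(path, COLVAR_FIELDS, np.asarray(rows))


def read_colvar(path) -> List[CVSample]:
    fields, data = read_plumed_table(path)
    unknown = set(fields) - set(COLVAR_FIELDS)
    if unknown:
        raise ValueError(f"{path}: unknown COLVAR fields {sorted(unknown)}; "
                         f"expected a subset of {list(COLVAR_FIELDS)}")
    col = {f: i for i, f in enumerate(fields)}
    out = []
    for row in data:
        out.append(CVSample(
            time=row[col["time"]],
            z_abs=row[col["z"]] if "z" in col else 0.0,
            theta=row[col["theta"]] if "theta" in col else 0.0,
            phi=row[col["phi"]] if "phi" in col else 0.0,
            min_zr=row[col["min_zr"]] if "min_zr" in col else 0.0,
        ))
    return out


def write_hills(path, bias: BiasState) -> None:
    rows = np.stack([bias.times, bias.centers,
                     np.full(bias.n_hills, bias.sigma), bias.heights], axis=-1) \
        if bias.n_hills else np.empty((0, 4))
    write_plumed_table(path, HILLS_FIELDS, rows)


def read_hills(path, w0: float = 1.0, gamma: float = 10.0,
               stride: int = 500) -> BiasState:
    fields, data = read_plumed_table(path)
    if list(fields) != list(HILLS_FIELDS):
        raise ValueError(f"{path}: HILLS fields {fields} do not match "
                         f"{list(HILLS_FIELDS)}")
    sigma = float(data[0, 2]) if len(data) else 1.0
    return BiasState(sigma=sigma, w0=w0, gamma=gamma, stride=stride,
                     times=data[:, 0], centers=data[:, 1], heights=data[:, 3])


# -- structures -------------------------------------------------------------

def write_pdb(struct: ToyStructure, path) -> None:
    """Standard-column PDB; coordinates converted to Angstrom. The species
    tag rides in the residue name, the leaflet tag in the chain ID."""
    with open(path, "w") as fh:
        b = struct.box * 10.0
        fh.write(f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                 f"  90.00  90.00  90.00 P 1           1\n")
        for i in range(struct.n_atoms):
            x, y, z = struct.xyz[i] * 10.0
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:<4s}{chain:1s}{resid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}\n".format(
                    serial=(i + 1) % 100000, name=struct.names[i][:4],
                    res=struct.resnames[i][:4], chain=struct.leaflet[i],
                    resid=int(struct.resids[i]) % 10000,
                    x=x, y=y, z=z, occ=1.0, b=0.0))
        fh.write("END\n")


def read_pdb(path) -> ToyStructure:
    names, resids, resnames, xyz, leaflet = [], [], [], [], []
    box = np.array([10.0, 10.0, 10.0])
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])]) / 10.0
            elif line.startswith(("ATOM", "HETATM")):
                names.append(line[12:16].strip())
                resnames.append(line[17:21].strip())
                leaflet.append(line[21] if line[21] != " " else "N")
                resids.append(int(line[22:26]))
                xyz.append([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
    return _structure_from_records(names, resids, resnames, xyz, box, leaflet,
                                   scale=0.1)


def write_gro(struct: ToyStructure, path, title: str = "memfes toy") -> None:
    with open(path, "w") as fh:
        fh.write(f"{title}\n{struct.n_atoms:>5d}\n")
        for i in range(struct.n_atoms):
            x, y, z = struct.xyz[i]
            fh.write(f"{int(struct.resids[i]) % 100000:>5d}"
                     f"{struct.resnames[i]:<5s}{struct.names[i]:>5s}"
                     f"{(i + 1) % 100000:>5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
        fh.write(f"{struct.box[0]:10.5f}{struct.box[1]:10.5f}"
                 f"{struct.box[2]:10.5f}\n")


def read_gro(path) -> ToyStructure:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[1])
    names, resids, resnames, xyz = [], [], [], []
    for line in lines[2:2 + n]:
        resids.append(int(line[0:5]))
        resnames.append(line[5:10].strip())
        names.append(line[10:15].strip())
        xyz.append([float(line[20:28]), float(line[28:36]), float(line[36:44])])
    box = np.array([float(v) for v in lines[2 + n].split()[:3]])
    return _structure_from_records(names, resids, resnames, xyz, box,
                                   leaflet=None, scale=1.0)


def _structure_from_records(names, resids, resnames, xyz, box, leaflet,
                            scale: float) -> ToyStructure:
    n = len(names)
    resnames = np.array(resnames, dtype="U4")
    species = np.where(np.isin(resnames, list(SPECIES_RADIUS)), resnames,
                       "PROT")
    species = np.where(resnames == "SLB", "SLAB", species)
    names_a = np.array(names, dtype="U4")
    charges = np.array([
        SPECIES_CHARGE.get(sp, 0.0) if nm == "P" else 0.0
        for sp, nm in zip(species, names_a)])
    radii = np.array([
        0.20 if nm == "P" else SPECIES_RADIUS.get(sp, 0.19)
        for sp, nm in zip(species, names_a)])
    return ToyStructure(
        names=names_a, resids=np.array(resids),
        resnames=resnames, species=np.array(species, dtype="U4"),
        xyz=np.asarray(xyz, dtype=float) * scale,
        charges=charges, radii=radii, box=np.asarray(box, dtype=float),
        leaflet=(np.array(leaflet, dtype="U1") if leaflet is not None
                 else None),
    )


# -- frame sequences --------------------------------------------------------

def write_frames_csv(path, frames: np.ndarray) -> None:
    """Frame sequence as CSV: frame, atom, x, y, z (nm)."""
    n_frames, n_atoms, _ = frames.shape
    with open(path, "w") as fh:
        fh.write("frame,atom,x,y,z\n")
        for f in range(n_frames):
            for a in range(n_atoms):
                x, y, z = frames[f, a]
                fh.write(f"{f},{a},{x:.6f},{y:.6f},{z:.6f}\n")


def read_frames_csv(path) -> np.ndarray:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    n_frames = int(data[:, 0].max()) + 1
    n_atoms = int(data[:, 1].max()) + 1
    out = np.full((n_frames, n_atoms, 3), np.nan)
    out[data[:, 0].astype(int), data[:, 1].astype(int)] = data[:, 2:5]
    return out


# -- reports with provenance ------------------------------------------------

def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(path, payload: dict, config: dict = None,
                 seeds: dict = None) -> None:
    """JSON report with a provenance block (config hash, seeds, version)."""
    from . import __version__
    doc = dict(payload)
    doc["provenance"] = {
        "package": "memfes",
        "version": __version__,
        "config_hash": config_hash(config or {}),
        "config": config or {},
        "seeds": seeds or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)
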