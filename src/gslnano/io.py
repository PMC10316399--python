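"""File formats: decay curves, coordinate files, topology tables, configs.

Internal unit conventions: nm for every length (PDB is the only Å surface,
converted at the boundary), ns for time.  Decay curves are two-column
delimited text with a ``#`` comment header carrying the photophysical
metadata; coordinates are GRO (native, multi-frame accepted) or PDB (via
MDAnalysis); tables are comma-separated UTF-8 CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fret import DecayCurve
from .hbond import MoietyMap, Topology
from .membrane import DomainConfiguration, ProbeConfiguration

__all__ = [
    "read_decay",
    "write_decay",
    "read_structure",
    "write_gro",
    "write_pdb",
    "read_topology",
    "write_topology",
    "read_moieties",
    "write_moieties",
    "write_domain_snapshot",
    "read_domain_snapshot",
    "write_probe_snapshot",
    "read_probe_snapshot",
    "write_resolved_config",
    "read_resolved_config",
]


class ParseError(ValueError):
    """File parsing failure, pointing at the offending line."""


# ---------------------------------------------------------------------------
# decay curves
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("tau_d_ns", "r0_nm", "channel_width_ns")


def write_decay(path, curve: DecayCurve, kind: str | None = None) -> None:
    """Two-column text: time_ns and counts (ints) or intensity (floats)."""
    if kind is None:
        kind = "counts" if curve.counts is not None else "intensity"
    values = curve.counts if kind == "counts" else curve.intensity
    if values is None:
        raise ValueError(f"curve has no {kind} to write")
    lines = ["# gslnano decay", f"# kind = {kind}"]
    meta = dict(curve.metadata)
    meta.setdefault("channel_width_ns", curve.channel_width_ns)
    for key in _HEADER_KEYS:
        if key in meta and meta[key] is not None:
            lines.append(f"# {key} = {meta[key]}")
    lines.append("# columns: time_ns value")
    fmt = "%d" if kind == "counts" else "%.10e"
    for t, v in zip(curve.time_ns, values):
        lines.append(f"{t:.9f}\t{fmt % v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_decay(path) -> DecayCurve:
    """Parse a decay file; validates the grid and count signs line by line."""
    meta: dict = {}
    kind = None
    times: list[float] = []
    values: list[float] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                val = val.strip()
                if key == "kind":
                    kind = val
                else:
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = val
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected two columns")
        try:
            t, v = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        if times and t <= times[-1]:
            raise ParseError(
                f"{path}: line {lineno}: time grid not strictly increasing "
                f"({t} after {times[-1]})"
            )
        if v < 0:
            raise ParseError(f"{path}: line {lineno}: negative value {v}")
        times.append(t)
        values.append(v)
    if len(times) < 2:
        raise ParseError(f"{path}: fewer than two data rows")
    t_arr = np.array(times)
    v_arr = np.array(values)
    if kind is None:
        kind = "counts" if np.allclose(v_arr, np.round(v_arr)) else "intensity"
    if kind == "counts":
        return DecayCurve(time_ns=t_arr, counts=v_arr.astype(np.int64), metadata=meta)
    return DecayCurve(time_ns=t_arr, intensity=v_arr, metadata=meta)


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def read_structure(path, dialect: str | None = None, multi_frame: bool = True):
    """Read coordinates in nm plus the box, from GRO or PDB.

    Returns ``(coords, box)`` with coords of shape (n_frames, n_atoms, 3).
    PDB coordinates (Å) are converted to nm; GRO is already nm.  Frames with
    differing atom counts raise an error.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").upper()
    dialect = dialect.upper()
    if dialect == "GRO":
        return _read_gro(path, multi_frame)
    if dialect == "PDB":
        return _read_pdb(path, multi_frame)
    raise ValueError(f"unsupported structure dialect {dialect!r}")


def _read_gro(path: Path, multi_frame: bool):
    lines = path.read_text().splitlines()
    frames = []
    box = None
    i = 0
    n_expected = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if i + 1 >= len(lines):
            raise ParseError(f"{path}: truncated GRO frame at line {i + 1}")
        try:
            natoms = int(lines[i + 1].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: line {i + 2}: bad atom count") from exc
        if n_expected is None:
            n_expected = natoms
        elif natoms != n_expected:
            raise ParseError(
                f"{path}: line {i + 2}: atom count {natoms} differs from "
                f"first frame ({n_expected})"
            )
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise ParseError(f"{path}: truncated frame (expected {natoms} atoms)")
        coords = np.empty((natoms, 3))
        for k, al in enumerate(atom_lines):
            try:
                coords[k] = (float(al[20:28]), float(al[28:36]), float(al[36:44]))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {i + 3 + k}: bad GRO atom line") from exc
        box_parts = lines[i + 2 + natoms].split()
        box = np.array([float(x) for x in box_parts[:3]])
        frames.append(coords)
        i += natoms + 3
        if not multi_frame:
            break
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return np.array(frames), box


def _read_pdb(path: Path, multi_frame: bool):
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = []
        box = None
        for _ts in u.trajectory:
            frames.append(u.atoms.positions.copy() / 10.0)  # Å -> nm
            if u.dimensions is not None:
                box = np.array(u.dimensions[:3]) / 10.0
            if not multi_frame:
                break
    counts = {f.shape[0] for f in frames}
    if len(counts) != 1:  # pragma: no cover - MDAnalysis enforces this
        raise ParseError(f"{path}: atom count varies across frames")
    return np.array(frames), box


def write_gro(path, coords: np.ndarray, box: np.ndarray,
              topology: Topology | None = None, title: str = "gslnano frame") -> None:
    """Write (multi-frame) GRO; atom/residue names from the topology if given."""
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    if topology is not None:
        resids = topology.atoms["mol_id"].to_numpy() + 1
        resnames = topology.atoms["species"].astype(str).str[:5].to_numpy()
        names = [
            f"{e}{i % 1000}" for i, e in enumerate(topology.atoms["element"])
        ]
    else:
        resids = np.ones(n_atoms, dtype=int)
        resnames = np.full(n_atoms, "MOL")
        names = [f"X{i % 1000}" for i in range(n_atoms)]
    box = np.asarray(box, float)
    out = []
    for frame in coords:
        out.append(title)
        out.append(f"{n_atoms:5d}")
        for k in range(n_atoms):
            out.append(
                f"{resids[k] % 100000:5d}{resnames[k]:<5s}{names[k]:>5s}"
                f"{(k + 1) % 100000:5d}"
                f"{frame[k, 0]:8.3f}{frame[k, 1]:8.3f}{frame[k, 2]:8.3f}"
            )
        out.append(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}")
    Path(path).write_text("\n".join(out) + "\n")


def write_pdb(path, coords: np.ndarray, box: np.ndarray,
              topology: Topology | None = None) -> None:
    """Write a (multi-frame) PDB with coordinates converted nm -> Å."""
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = coords.shape[1]
    if topology is not None:
        elements = topology.atoms["element"].to_numpy()
        resids = topology.atoms["mol_id"].to_numpy() + 1
        resnames = topology.atoms["species"].astype(str).str[:3].to_numpy()
    else:
        elements = np.full(n_atoms, "C")
        resids = np.ones(n_atoms, dtype=int)
        resnames = np.full(n_atoms, "MOL")
    box = np.asarray(box, float) * 10.0
    lines = [
        f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    ]
    for f, frame in enumerate(coords):
        lines.append(f"MODEL     {f + 1:4d}")
        for k in range(n_atoms):
            x, y, z = frame[k] * 10.0
            name = f"{elements[k]}{k % 100}"[:4]
            lines.append(
                f"ATOM  {k + 1 if k < 99999 else 99999:5d} {name:<4s}"
                f"{resnames[k]:>4s} {resids[k] % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elements[k]:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# topology / moiety tables
# ---------------------------------------------------------------------------

def write_topology(topology: Topology, atoms_csv, bonds_csv) -> None:
    df = topology.atoms.copy()
    df.insert(0, "atom_id", np.arange(len(df)))
    df.to_csv(atoms_csv, index=False)
    pd.DataFrame(topology.bonds, columns=["atom_i", "atom_j"]).to_csv(
        bonds_csv, index=False
    )


def read_topology(atoms_csv, bonds_csv) -> Topology:
    atoms = pd.read_csv(atoms_csv)
    if "atom_id" in atoms.columns:
        atoms = atoms.sort_values("atom_id").drop(columns=["atom_id"])
    bonds = pd.read_csv(bonds_csv)[["atom_i", "atom_j"]].to_numpy()
    return Topology(atoms=atoms.reset_index(drop=True), bonds=bonds)


def write_moieties(moiety_map: MoietyMap, path) -> None:
    pd.DataFrame(
        {"atom_id": np.arange(len(moiety_map.labels)), "moiety": moiety_map.labels}
    ).to_csv(path, index=False)


def read_moieties(path) -> MoietyMap:
    df = pd.read_csv(path).sort_values("atom_id")
    return MoietyMap(labels=df["moiety"].reset_index(drop=True))


def write_domain_snapshot(config: DomainConfiguration, path) -> None:
    """One record per disc: center_x_nm, center_y_nm (radius/box in header)."""
    df = pd.DataFrame(config.centers, columns=["center_x_nm", "center_y_nm"])
    with open(path, "w") as fh:
        fh.write(f"# radius_nm = {config.radius_nm!r}\n")
        fh.write(f"# box_length_nm = {config.box_length_nm!r}\n")
        df.to_csv(fh, index=False)


def read_domain_snapshot(path) -> DomainConfiguration:
    meta = _read_hash_header(path)
    df = pd.read_csv(path, comment="#")
    return DomainConfiguration(
        centers=df[["center_x_nm", "center_y_nm"]].to_numpy(),
        radius_nm=float(meta["radius_nm"]),
        box_length_nm=float(meta["box_length_nm"]),
    )


def write_probe_snapshot(probes: ProbeConfiguration, path) -> None:
    """One record per probe: kind, x_nm, y_nm, leaflet, in_domain."""
    rows = []
    for kind, xy, leaf, inside in (
        ("donor", probes.donor_xy, probes.donor_leaflet, probes.donor_in_domain),
        ("acceptor", probes.acceptor_xy, probes.acceptor_leaflet,
         probes.acceptor_in_domain),
    ):
        for k in range(len(xy)):
            rows.append(
                {"kind": kind, "x_nm": xy[k, 0], "y_nm": xy[k, 1],
                 "leaflet": int(leaf[k]), "in_domain": bool(inside[k])}
            )
    with open(path, "w") as fh:
        fh.write(f"# box_length_nm = {probes.box_length_nm!r}\n")
        fh.write(f"# bilayer_separation_nm = {probes.bilayer_separation_nm!r}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_probe_snapshot(path) -> ProbeConfiguration:
    meta = _read_hash_header(path)
    df = pd.read_csv(path, comment="#")
    d = df[df["kind"] == "donor"]
    a = df[df["kind"] == "acceptor"]
    return ProbeConfiguration(
        donor_xy=d[["x_nm", "y_nm"]].to_numpy(),
        donor_leaflet=d["leaflet"].to_numpy(),
        donor_in_domain=d["in_domain"].to_numpy(dtype=bool),
        acceptor_xy=a[["x_nm", "y_nm"]].to_numpy(),
        acceptor_leaflet=a["leaflet"].to_numpy(),
        acceptor_in_domain=a["in_domain"].to_numpy(dtype=bool),
        box_length_nm=float(meta["box_length_nm"]),
        bilayer_separation_nm=float(meta["bilayer_separation_nm"]),
    )


def _read_hash_header(path) -> dict:
    meta = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("#"):
            break
        key, _, val = line.lstrip("#").partition("=")
        meta[key.strip()] = val.strip()
    return meta


def write_resolved_config(path, config: dict) -> None:
    """Persist the fully resolved run configuration next to its outputs."""
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def read_resolved_config(path) -> dict:
    """Reload a logged configuration (lossless JSON round trip)."""
    return json.loads(Path(path).read_text())
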