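"""File formats: extended XYZ, LAMMPS data (atomic style), and the
self-contained model archive.

The model archive is a zip container holding one JSON metadata document
plus named parameter arrays as raw little-endian float64 buffers (shapes
recorded in the metadata) — parameters and declared architecture only,
no serialized code, so the format stays language-neutral. Length/energy
units are declared in the metadata and converted at the I/O boundary;
internally everything is Å and eV.
"""

from __future__ import annotations

import json
import zipfile

import numpy as np

from .potentials import LennardJones, SemilocalPotential, ToyMPGNN
from .system import ParticleSystem, UnitsSpec

__all__ = [
    "write_extxyz",
    "write_extxyz_frame",
    "read_extxyz",
    "write_lammps_data",
    "read_lammps_data",
    "save_model",
    "load_model",
    "ARCHIVE_FORMAT_VERSION",
]

ARCHIVE_FORMAT_VERSION = 1


# ---------------------------------------------------------------- extxyz


def _symbols(system: ParticleSystem) -> list[str]:
    names = system.species_names
    if names is None:
        names = [f"X{c}" for c in range(int(system.species.max()) + 1)]
    return [names[c] for c in system.species]


def write_extxyz_frame(fh, system: ParticleSystem) -> None:
    lat = system.box
    pbc = " ".join("T" if p else "F" for p in system.periodic)
    names = system.species_names or [
        f"X{c}" for c in range(int(system.species.max()) + 1)
    ]
    fh.write(f"{system.n_atoms}\n")
    fh.write(
        f'Lattice="{lat[0]:.10g} 0 0 0 {lat[1]:.10g} 0 0 0 {lat[2]:.10g}" '
        f'Properties=species:S:1:pos:R:3 pbc="{pbc}" '
        f'species_names="{" ".join(names)}"\n'
    )
    syms = _symbols(system)
    for s, (x, y, z) in zip(syms, system.positions):
        fh.write(f"{s} {x:.12g} {y:.12g} {z:.12g}\n")


def write_extxyz(path, system: ParticleSystem) -> None:
    with open(path, "w") as fh:
        write_extxyz_frame(fh, system)


def _parse_kv(comment: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    i = 0
    n = len(comment)
    while i < n:
        while i < n and comment[i].isspace():
            i += 1
        if i >= n:
            break
        eq = comment.find("=", i)
        if eq < 0:
            raise ValueError(f"line {lineno}: malformed key-value pair in header")
        key = comment[i:eq].strip()
        j = eq + 1
        if j < n and comment[j] == '"':
            end = comment.find('"', j + 1)
            if end < 0:
                raise ValueError(f"line {lineno}: unterminated quote in header")
            out[key] = comment[j + 1 : end]
            i = end + 1
        else:
            end = j
            while end < n and not comment[end].isspace():
                end += 1
            out[key] = comment[j:end]
            i = end
    return out


def read_extxyz(path) -> ParticleSystem:
    """Read the first frame of an extended-XYZ file."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError("line 1: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError("line 1: expected an atom count") from None
    if len(lines) < n + 2:
        raise ValueError(f"line {len(lines)}: file truncated; expected {n} atom lines")
    kv = _parse_kv(lines[1].strip(), 2)
    if "Lattice" not in kv:
        raise ValueError("line 2: missing Lattice key")
    cell = np.fromstring(kv["Lattice"], sep=" ")
    if cell.size != 9:
        raise ValueError("line 2: Lattice must contain 9 numbers")
    cell = cell.reshape(3, 3)
    if np.any(np.abs(cell - np.diag(np.diag(cell))) > 1e-12):
        raise ValueError("line 2: only orthorhombic lattices are supported")
    box = np.diag(cell)
    pbc_str = kv.get("pbc", "T T T").replace('"', "").split()
    periodic = np.array([tok.upper().startswith("T") for tok in pbc_str])
    names = kv.get("species_names", "").split() or None
    symbols, positions = [], []
    for k in range(n):
        parts = lines[2 + k].split()
        if len(parts) < 4:
            raise ValueError(f"line {3 + k}: expected 'symbol x y z'")
        symbols.append(parts[0])
        positions.append([float(v) for v in parts[1:4]])
    if names is None:
        names = list(dict.fromkeys(symbols))
    lookup = {s: i for i, s in enumerate(names)}
    try:
        species = np.array([lookup[s] for s in symbols], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown species symbol {exc}") from None
    return ParticleSystem(
        positions=np.asarray(positions),
        species=species,
        box=box,
        periodic=periodic,
        species_names=names,
    )


# ------------------------------------------------------------ LAMMPS data


def write_lammps_data(path, system: ParticleSystem) -> None:
    """Atomic-style LAMMPS data file; atom and type ids are 1-based."""
    n_types = int(system.species.max()) + 1
    with open(path, "w") as fh:
        fh.write("LAMMPS data file (atomic style)\n\n")
        fh.write(f"{system.n_atoms} atoms\n{n_types} atom types\n\n")
        for k, ax in enumerate("xyz"):
            fh.write(f"0.0 {system.box[k]:.12g} {ax}lo {ax}hi\n")
        fh.write("\nAtoms # atomic\n\n")
        for i in range(system.n_atoms):
            x, y, z = system.positions[i]
            fh.write(
                f"{system.global_ids[i] + 1} {system.species[i] + 1} "
                f"{x:.12g} {y:.12g} {z:.12g}\n"
            )


def read_lammps_data(path) -> ParticleSystem:
    with open(path) as fh:
        lines = fh.readlines()
    n_atoms = None
    bounds = {}
    atoms_at = None
    for i, raw in enumerate(lines):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "xy xz yz" in line:
            raise ValueError("triclinic tilt factors are not supported (atomic style, orthorhombic only)")
        if line.endswith("atoms"):
            n_atoms = int(line.split()[0])
        for ax in "xyz":
            if line.endswith(f"{ax}lo {ax}hi"):
                lo, hi = map(float, line.split()[:2])
                bounds[ax] = (lo, hi)
        if line.startswith("Atoms"):
            atoms_at = i
            break
    if n_atoms is None or atoms_at is None or len(bounds) != 3:
        raise ValueError("malformed LAMMPS data file: missing counts, bounds or Atoms section")
    rows = []
    for raw in lines[atoms_at + 1 :]:
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 8):
            raise ValueError("Atoms line must be 'id type x y z [ix iy iz]'")
        rows.append((int(parts[0]), int(parts[1]), *map(float, parts[2:5])))
        if len(rows) == n_atoms:
            break
    if len(rows) != n_atoms:
        raise ValueError(f"expected {n_atoms} atom lines, found {len(rows)}")
    rows.sort()
    ids = np.array([r[0] for r in rows], dtype=np.int64)
    lo = np.array([bounds[ax][0] for ax in "xyz"])
    hi = np.array([bounds[ax][1] for ax in "xyz"])
    return ParticleSystem(
        positions=np.array([r[2:5] for r in rows]) - lo,
        species=np.array([r[1] for r in rows], dtype=np.int64) - 1,
        box=hi - lo,
        periodic=np.array([True, True, True]),
        global_ids=ids - 1,
    )


# ------------------------------------------------------------ model archive

_KINDS = {"lennard_jones": LennardJones, "toy_mpgnn": ToyMPGNN}
# which named arrays / metadata entries carry units (for conversion)
_LENGTH_ARRAYS = {"lennard_jones": ("sigma",), "toy_mpgnn": ()}
_ENERGY_ARRAYS = {"lennard_jones": ("epsilon",), "toy_mpgnn": ("w_out", "b_out")}


def save_model(
    potential: SemilocalPotential, path, units: UnitsSpec = UnitsSpec()
) -> None:
    """Write a self-contained archive; values are stored in the declared
    units (converted from the internal Å/eV on write)."""
    meta = potential.metadata()
    arrays = potential.parameter_arrays()
    kind = meta["kind"]
    meta["cutoff"] = meta["cutoff"] / units.length_to_angstrom
    arrays = dict(arrays)
    for name in _LENGTH_ARRAYS[kind]:
        arrays[name] = arrays[name] / units.length_to_angstrom
    for name in _ENERGY_ARRAYS[kind]:
        arrays[name] = arrays[name] / units.energy_to_ev
    document = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "model": meta,
        "units": {
            "length_unit": units.length_unit,
            "length_to_angstrom": units.length_to_angstrom,
            "energy_unit": units.energy_unit,
            "energy_to_ev": units.energy_to_ev,
        },
        "arrays": {
            name: {"shape": list(np.shape(a)), "dtype": "<f8"}
            for name, a in arrays.items()
        },
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("metadata.json", json.dumps(document, indent=1, sort_keys=True))
        for name, a in arrays.items():
            zf.writestr(
                f"params/{name}.bin",
                np.ascontiguousarray(a, dtype="<f8").tobytes(),
            )


def load_model(path) -> SemilocalPotential:
    """Load an archive, converting declared units to internal Å/eV.

    Round trip ``load(save(m))`` reproduces evaluations bit-for-bit for
    Å/eV archives (float64 is stored exactly).
    """
    with zipfile.ZipFile(path) as zf:
        document = json.loads(zf.read("metadata.json"))
        version = document.get("format_version")
        if version != ARCHIVE_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model archive format version {version!r}; "
                f"this reader supports version {ARCHIVE_FORMAT_VERSION}"
            )
        meta = document["model"]
        kind = meta["kind"]
        if kind not in _KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        units = document["units"]
        arrays = {}
        for name, spec in document["arrays"].items():
            buf = np.frombuffer(zf.read(f"params/{name}.bin"), dtype="<f8")
            arrays[name] = buf.reshape(spec["shape"]).copy()
    meta["cutoff"] = meta["cutoff"] * units["length_to_angstrom"]
    for name in _LENGTH_ARRAYS[kind]:
        arrays[name] = arrays[name] * units["length_to_angstrom"]
    for name in _ENERGY_ARRAYS[kind]:
        arrays[name] = arrays[name] * units["energy_to_ev"]
    return _KINDS[kind].from_arrays(meta, arrays)
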