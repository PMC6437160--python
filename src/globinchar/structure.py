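"""Static-structure solvent-accessible surface area.

Fixed-width PDB parsing (ATOM/HETATM, altloc resolution by occupancy) and a
Shrake-Rupley SASA with a deterministic golden-spiral point set.  The heme
observable sums SASA over HEM/HEC residues and reports nm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: Atomic radii (Angstrom); standard values.
ATOM_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "FE": 2.00,
    "H": 1.10, "P": 1.80,
}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    res_name: str
    chain: str
    res_seq: int
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    radius: float = DEFAULT_RADIUS
    element_known: bool = True


@dataclass(frozen=True)
class Structure:
    atoms: tuple[Atom, ...]

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    def select_residue(self, *res_names: str) -> list[int]:
        names = {r.upper() for r in res_names}
        return [i for i, a in enumerate(self.atoms) if a.res_name.upper() in names]


def _infer_element(record: str, name_field: str) -> str:
    el = record[76:78].strip().upper() if len(record) >= 78 else ""
    if el:
        return el
    name = name_field.strip()
    # fall back on the atom-name convention: columns 13-14 hold the element
    two = name_field[:2].strip().upper()
    if two in ATOM_RADII and not two.isdigit():
        return two
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def parse_structure(pdb_text: str) -> Structure:
    """Parse ATOM/HETATM records from PDB text.

    Element comes from columns 77-78 with an atom-name fallback; for altloc
    groups the highest-occupancy conformer is kept (ties break to 'A').
    Malformed fixed-width records are rejected with their line number.
    """
    raw: list[Atom] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ValueError(f"line {lineno}: truncated ATOM/HETATM record")
        try:
            serial = int(line[6:11])
            name = line[12:16]
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain = line[21].strip()
            res_seq = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed fixed-width record ({exc})") from None
        element = _infer_element(line, name)
        known = element in ATOM_RADII
        raw.append(Atom(
            serial=serial, name=name.strip(), res_name=res_name, chain=chain,
            res_seq=res_seq, element=element, xyz=(x, y, z), occupancy=occ,
            altloc=altloc, radius=ATOM_RADII.get(element, DEFAULT_RADIUS),
            element_known=known,
        ))
    if not raw:
        return Structure(atoms=())
    # altloc resolution: highest occupancy per (chain, res_seq, res_name, name)
    best: dict[tuple, Atom] = {}
    for a in raw:
        key = (a.chain, a.res_seq, a.res_name, a.name)
        if key not in best:
            best[key] = a
            continue
        b = best[key]
        if a.occupancy > b.occupancy or (
            a.occupancy == b.occupancy and a.altloc == "A" and b.altloc != "A"
        ):
            best[key] = a
    atoms = tuple(sorted(best.values(), key=lambda a: a.serial))
    return Structure(atoms=atoms)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)
    ])


@dataclass(frozen=True)
class SasaResult:
    per_atom: np.ndarray          # Angstrom^2
    total: float                  # Angstrom^2
    by_residue: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def group_total(self, indices) -> float:
        return float(self.per_atom[list(indices)].sum())


def sasa(structure: Structure, probe: float = PROBE_RADIUS, n_points: int = 960) -> SasaResult:
    """Shrake-Rupley SASA with a fixed golden-spiral point set.

    For each atom, ``n_points`` test points on its probe-extended sphere are
    checked against the probe-extended spheres of neighboring atoms; the
    accessible fraction times the extended-sphere area is that atom's SASA.
    """
    if len(structure.atoms) == 0:
        raise ValueError("structure has no atoms")
    xyz = structure.coordinates()
    ext = structure.radii() + probe
    unit = sphere_points(n_points)
    tree = cKDTree(xyz)
    max_ext = ext.max()
    per_atom = np.empty(len(structure.atoms))
    for i in range(len(structure.atoms)):
        pts = xyz[i] + ext[i] * unit
        neighbors = [j for j in tree.query_ball_point(xyz[i], ext[i] + max_ext)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * ext[i] ** 2
    by_res: dict[tuple[str, int, str], float] = {}
    for a, area in zip(structure.atoms, per_atom):
        key = (a.chain, a.res_seq, a.res_name)
        by_res[key] = by_res.get(key, 0.0) + float(area)
    return SasaResult(per_atom=per_atom, total=float(per_atom.sum()), by_residue=by_res)


HEME_RESIDUES = ("HEM", "HEC")


def heme_sasa(
    structure: Structure, probe: float = PROBE_RADIUS, n_points: int = 960
) -> float:
    """SASA summed over heme residues, in nm^2 (Angstrom^2 / 100)."""
    idx = structure.select_residue(*HEME_RESIDUES)
    if not idx:
        raise ValueError("structure contains no HEM/HEC residue")
    result = sasa(structure, probe=probe, n_points=n_points)
    return result.group_total(idx) / 100.0
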