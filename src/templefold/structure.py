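"""Complex structures, native contact maps and hydrophobic SASA.

Internal coordinate unit is nm throughout (PDB I/O converts from/to
Angstrom).  A "heavy side-chain atom" is any non-hydrogen atom outside the
backbone set {N, CA, C, O, OXT}; glycine contributes its CA as a side-chain
proxy so it can still form contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Heavy side-chain atom names per standard residue, ordered from CB outward.
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "PRO": ("CB", "CG", "CD"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "MET": ("CB", "CG", "SD", "CE"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "CYS": ("CB", "SG"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Bondi van der Waals radii in nm, keyed by element symbol.
BONDI_RADII_NM = {"C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180, "H": 0.120, "P": 0.180}
DEFAULT_RADIUS_NM = 0.170

ANGSTROM_PER_NM = 10.0


class MissingChainError(KeyError):
    """Requested chain absent from a structure."""


class UnsupportedMutationError(ValueError):
    """Mutation would require building atoms not present in the template."""


@dataclass
class ComplexStructure:
    """Two-chain complex with per-atom records, coordinates in nm.

    ``chain_id``, ``res_index``, ``res_name``, ``atom_name`` and ``element``
    are parallel arrays over atoms; ``coords`` is (n_atoms, 3).  Exactly two
    chain roles exist: ``receptor_chain`` and ``ligand_chain``.
    """

    chain_id: np.ndarray
    res_index: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    receptor_chain: str
    ligand_chain: str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        present = set(np.unique(self.chain_id))
        for c in (self.receptor_chain, self.ligand_chain):
            if c not in present:
                raise MissingChainError(
                    f"chain {c!r} not in structure (available: {sorted(present)})"
                )
        if self.receptor_chain == self.ligand_chain:
            raise ValueError("receptor and ligand chains must differ")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residues(self) -> list[tuple[str, int]]:
        """Unique (chain, residue index) pairs in file order."""
        seen: dict[tuple[str, int], None] = {}
        for c, i in zip(self.chain_id, self.res_index):
            seen.setdefault((str(c), int(i)), None)
        return list(seen)

    def residue_name(self, chain: str, index: int) -> str:
        mask = (self.chain_id == chain) & (self.res_index == index)
        if not mask.any():
            raise KeyError((chain, index))
        return str(self.res_name[mask][0])

    def sidechain_mask(self) -> np.ndarray:
        """Boolean mask of heavy side-chain atoms (Gly: its CA)."""
        is_heavy = self.element != "H"
        is_side = ~np.isin(self.atom_name, sorted(BACKBONE_ATOMS))
        gly_ca = (self.res_name == "GLY") & (self.atom_name == "CA")
        return is_heavy & (is_side | gly_ca)

    def atom_mask(self, chain: str, index: int) -> np.ndarray:
        return (self.chain_id == chain) & (self.res_index == index)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Return a rigidly moved copy (coords @ R.T + t)."""
        return replace(self, coords=self.coords @ np.asarray(rotation).T + translation)

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            self.chain_id.copy(), self.res_index.copy(), self.res_name.copy(),
            self.atom_name.copy(), self.element.copy(), self.coords.copy(),
            self.receptor_chain, self.ligand_chain,
        )


@dataclass(frozen=True)
class NativeContactMap:
    """Native heavy side-chain atom-pair counts per residue pair.

    Keys are ordered pairs ``((chain_i, res_i), (chain_j, res_j))`` with the
    smaller (chain, index) first; lookups through :meth:`get` are symmetric.
    Same-chain nearest neighbours (|i - j| <= 1) are never present.
    """

    counts: dict[tuple[tuple[str, int], tuple[str, int]], int]
    cutoff: float = 0.65

    @staticmethod
    def _key(a: tuple[str, int], b: tuple[str, int]):
        return (a, b) if a <= b else (b, a)

    def get(self, a: tuple[str, int], b: tuple[str, int]) -> int:
        return self.counts.get(self._key(a, b), 0)

    def pairs_of(self, res: tuple[str, int]):
        """All (partner, count) entries involving ``res``."""
        out = []
        for (a, b), n in self.counts.items():
            if a == res:
                out.append((b, n))
            elif b == res:
                out.append((a, n))
        return out

    def residue_count(self, res: tuple[str, int]) -> int:
        """Total native atom-pair count of one residue."""
        return sum(n for _, n in self.pairs_of(res))

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class BindingSiteDefinition:
    """Residues making up the hydrophobic binding site."""

    residues: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("binding site must be non-empty")

    def validate(self, s: ComplexStructure) -> None:
        have = set(s.residues())
        missing = [r for r in self.residues if tuple(r) not in have]
        if missing:
            raise KeyError(f"site residues not in structure: {missing}")


# ---------------------------------------------------------------------------
# PDB I/O


def read_pdb(path, receptor_chain: str, ligand_chain: str) -> ComplexStructure:
    """Read a two-chain complex from a PDB file.

    Uses the first MODEL of multi-model (NMR) files, drops hydrogens,
    resolves alternate locations to the highest occupancy, and converts
    coordinates from Angstrom to nm.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDBConstructionWarning on odd files
        model = PDBParser(QUIET=True).get_structure("complex", str(path))[0]

    available = [c.id for c in model]
    for c in (receptor_chain, ligand_chain):
        if c not in available:
            raise MissingChainError(f"chain {c!r} not found; available chains: {available}")

    rows = []
    for chain in model:
        if chain.id not in (receptor_chain, ligand_chain):
            continue
        for residue in chain:
            if residue.id[0] != " ":  # skip het/water
                continue
            atoms = {}
            for atom in residue.get_atoms():
                elem = (atom.element or atom.get_name()[0]).upper()
                if elem == "H" or atom.get_name().startswith("H"):
                    continue
                name = atom.get_name()
                prev = atoms.get(name)
                if prev is None or (atom.get_occupancy() or 1.0) > prev[0]:
                    atoms[name] = (atom.get_occupancy() or 1.0, atom.coord, elem)
            if not atoms:
                continue
            if len(atoms) == 1 and "CA" in atoms:
                warnings.warn(
                    f"residue {chain.id}{residue.id[1]} has no side-chain heavy atoms; "
                    "kept with CA only",
                    stacklevel=2,
                )
            for name, (_, xyz, elem) in atoms.items():
                rows.append((chain.id, residue.id[1], residue.get_resname(), name, elem, xyz))

    chain_id = np.array([r[0] for r in rows], dtype=object)
    res_index = np.array([r[1] for r in rows], dtype=int)
    res_name = np.array([r[2] for r in rows], dtype=object)
    atom_name = np.array([r[3] for r in rows], dtype=object)
    element = np.array([r[4] for r in rows], dtype=object)
    coords = np.array([r[5] for r in rows], dtype=float) / ANGSTROM_PER_NM
    return ComplexStructure(
        chain_id, res_index, res_name, atom_name, element, coords,
        receptor_chain, ligand_chain,
    )


def write_pdb(s: ComplexStructure, path, coords_list=None) -> None:
    """Write a structure (or several coordinate frames as MODELs) to PDB."""
    frames = [s.coords] if coords_list is None else list(coords_list)
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for m, coords in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            serial = 1
            for i in range(s.n_atoms):
                x, y, z = np.asarray(coords[i]) * ANGSTROM_PER_NM
                name = str(s.atom_name[i])
                pad = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d} {pad:<4s} {str(s.res_name[i]):<3s} "
                    f"{str(s.chain_id[i])}{int(s.res_index[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {str(s.element[i]):>2s}\n"
                )
                serial += 1
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Native contacts


def native_contacts(s: ComplexStructure, cutoff: float = 0.65) -> NativeContactMap:
    """Count heavy side-chain atom pairs within ``cutoff`` (nm, strict <).

    Residue pairs that are nearest neighbours on the same chain
    (|i - j| <= 1) are excluded; pairs with zero count are omitted.
    """
    mask = s.sidechain_mask()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return NativeContactMap({}, cutoff)
    coords = s.coords[idx]
    chains = s.chain_id[idx]
    resids = s.res_index[idx]

    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    close = d2 < cutoff * cutoff

    counts: dict = {}
    n = len(idx)
    ii, jj = np.nonzero(np.triu(close, k=1))
    for a, b in zip(ii, jj):
        ca, cb = str(chains[a]), str(chains[b])
        ra, rb = int(resids[a]), int(resids[b])
        if (ca, ra) == (cb, rb):
            continue
        if ca == cb and abs(ra - rb) <= 1:
            continue
        key = NativeContactMap._key((ca, ra), (cb, rb))
        counts[key] = counts.get(key, 0) + 1
    return NativeContactMap(counts, cutoff)


# ---------------------------------------------------------------------------
# Mutation


def mutate_residue(s: ComplexStructure, chain: str, index: int, new_type: str) -> ComplexStructure:
    """Coarse deletion-only substitution: truncate the side chain to the
    atoms shared with ``new_type`` and retype the residue.

    Growth mutations (target side chain needs atoms the template lacks,
    e.g. A->W) are unsupported; supply a pre-built structure instead.
    """
    new_type = new_type.upper()
    if new_type not in SIDECHAIN_ATOMS:
        raise ValueError(f"unknown residue type {new_type!r}")
    res_mask = s.atom_mask(chain, index)
    if not res_mask.any():
        raise KeyError(f"residue {chain}{index} not in structure")

    target_atoms = set(SIDECHAIN_ATOMS[new_type])
    present_side = {
        str(a) for a in s.atom_name[res_mask] if str(a) not in BACKBONE_ATOMS
    }
    missing = target_atoms - present_side
    if missing:
        raise UnsupportedMutationError(
            f"mutation to {new_type} needs atoms {sorted(missing)} absent from the "
            f"template residue; deletion-only modelling cannot build them"
        )

    keep = np.ones(s.n_atoms, dtype=bool)
    drop = res_mask & ~np.isin(s.atom_name, sorted(BACKBONE_ATOMS | target_atoms))
    keep &= ~drop
    out = ComplexStructure(
        s.chain_id[keep].copy(), s.res_index[keep].copy(), s.res_name[keep].copy(),
        s.atom_name[keep].copy(), s.element[keep].copy(), s.coords[keep].copy(),
        s.receptor_chain, s.ligand_chain,
    )
    out.res_name[out.atom_mask(chain, index)] = new_type
    return out


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Approximately uniform points on the unit sphere (Fibonacci spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 0.14,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (nm^2).

    Standard Shrake-Rupley: each atom's extended sphere (radius + probe) is
    covered with ``n_points`` test points; points inside any neighbour's
    extended sphere are buried.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    unit = _sphere_points(n_points)
    ext = radii + probe
    areas = np.empty(n)
    # neighbour lists via full distance matrix (desk-scale systems)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        nbr = np.flatnonzero((d[i] < ext[i] + ext) & (np.arange(n) != i))
        if nbr.size:
            dp = np.linalg.norm(pts[:, None, :] - coords[nbr][None, :, :], axis=-1)
            exposed = np.all(dp >= ext[nbr][None, :], axis=1)
        else:
            exposed = np.ones(n_points, dtype=bool)
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * exposed.mean()
    return areas


def atom_radii(s: ComplexStructure) -> np.ndarray:
    return np.array(
        [BONDI_RADII_NM.get(str(e), DEFAULT_RADIUS_NM) for e in s.element]
    )


def hydrophobic_sasa(
    s: ComplexStructure,
    site: BindingSiteDefinition,
    probe: float = 0.14,
    n_points: int = 960,
) -> float:
    """Hydrophobic binding-site SASA: Shrake-Rupley on the full complex,
    summed over heavy side-chain atoms of the site residues (nm^2)."""
    site.validate(s)
    areas = shrake_rupley(s.coords, atom_radii(s), probe=probe, n_points=n_points)
    side = s.sidechain_mask()
    total = 0.0
    for chain, index in site.residues:
        total += float(areas[s.atom_mask(chain, index) & side].sum())
    return total
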