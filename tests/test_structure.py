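import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import brute_force_contacts
from templefold.structure import (
    BindingSiteDefinition,
    ComplexStructure,
    MissingChainError,
    UnsupportedMutationError,
    atom_radii,
    hydrophobic_sasa,
    mutate_residue,
    native_contacts,
    read_pdb,
    shrake_rupley,
    write_pdb,
)

SEED = np.random.default_rng(123)


def build_structure(residues, receptor_chain="A", ligand_chain="B"):
    """residues: list of (chain, index, resname, [(atom, element, xyz), ...])."""
    rows = []
    for chain, idx, resname, atoms in residues:
        for name, elem, xyz in atoms:
            rows.append((chain, idx, resname, name, elem, xyz))
    return ComplexStructure(
        chain_id=np.array([r[0] for r in rows], dtype=object),
        res_index=np.array([r[1] for r in rows], dtype=int),
        res_name=np.array([r[2] for r in rows], dtype=object),
        atom_name=np.array([r[3] for r in rows], dtype=object),
        element=np.array([r[4] for r in rows], dtype=object),
        coords=np.array([r[5] for r in rows], dtype=float),
        receptor_chain=receptor_chain,
        ligand_chain=ligand_chain,
    )


def simple_residue(chain, idx, resname, origin, sc_atoms=None):
    """Backbone + side-chain atoms around an origin."""
    o = np.asarray(origin, dtype=float)
    atoms = [
        ("N", "N", o + [0.0, 0.12, 0]),
        ("CA", "C", o),
        ("C", "C", o + [0.12, -0.05, 0]),
        ("O", "O", o + [0.12, -0.17, 0]),
    ]
    for k, (name, elem) in enumerate(sc_atoms or []):
        atoms.append((name, elem, o + [0.0, -0.10 - 0.12 * k, 0.05]))
    return (chain, idx, resname, atoms)


class TestReadWritePdb:
    def test_round_trip(self, toy, tmp_path):
        path = tmp_path / "toy.pdb"
        write_pdb(toy, path)
        back = read_pdb(path, "A", "B")
        assert back.n_atoms == toy.n_atoms
        assert np.allclose(back.coords, toy.coords, atol=1e-3)
        assert list(back.res_name) == list(toy.res_name)

    def test_first_model_of_multimodel(self, toy, tmp_path):
        path = tmp_path / "multi.pdb"
        frames = [toy.coords, toy.coords + 0.5, toy.coords + 1.0]
        write_pdb(toy, path, coords_list=frames)
        back = read_pdb(path, "A", "B")
        assert back.n_atoms == toy.n_atoms
        assert np.allclose(back.coords, toy.coords, atol=1e-3)

    def test_missing_chain_lists_available(self, toy, tmp_path):
        path = tmp_path / "toy.pdb"
        write_pdb(toy, path)
        with pytest.raises(MissingChainError, match="available"):
            read_pdb(path, "A", "Z")


class TestNativeContacts:
    def test_beyond_cutoff_no_entry(self):
        s = build_structure([
            simple_residue("A", 1, "ALA", [0, 0, 0], [("CB", "C")]),
            simple_residue("B", 1, "ALA", [2, 0, 0], [("CB", "C")]),
        ])
        assert len(native_contacts(s)) == 0

    def test_nearest_neighbours_excluded(self):
        s = build_structure([
            simple_residue("A", 1, "ALA", [0, 0, 0], [("CB", "C")]),
            simple_residue("A", 2, "ALA", [0.1, 0, 0], [("CB", "C")]),
            simple_residue("B", 1, "ALA", [5, 0, 0], [("CB", "C")]),
        ])
        cm = native_contacts(s)
        assert cm.get(("A", 1), ("A", 2)) == 0

    def test_strict_inequality_at_cutoff(self):
        s = build_structure([
            ("A", 1, "ALA", [("CA", "C", [0, 0, 0]), ("CB", "C", [0, 0, 0])]),
            ("A", 3, "ALA", [("CA", "C", [0.65, 0, 0]), ("CB", "C", [0.65, 0, 0])]),
            ("B", 1, "ALA", [("CA", "C", [5, 0, 0]), ("CB", "C", [5, 0, 0])]),
        ])
        cm = native_contacts(s)
        assert cm.get(("A", 1), ("A", 3)) == 0  # exactly at cutoff: excluded

    def test_glycine_uses_ca_proxy(self):
        s = build_structure([
            ("A", 1, "GLY", [("N", "N", [0, 0.12, 0]), ("CA", "C", [0, 0, 0])]),
            ("A", 3, "ALA", [("CA", "C", [0.3, 0, 0]), ("CB", "C", [0.3, 0.1, 0])]),
            ("B", 1, "ALA", [("CA", "C", [5, 0, 0]), ("CB", "C", [5, 0, 0])]),
        ])
        cm = native_contacts(s)
        assert cm.get(("A", 1), ("A", 3)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_oracle_random_structures(self, seed):
        rng = np.random.default_rng(seed)
        residues = []
        names = ["ALA", "VAL", "LEU", "SER", "GLY"]
        for chain, offset in (("A", 0), ("B", 5)):
            for i in range(1, 6):
                o = rng.uniform(0, 1.2, 3)
                resname = names[(i + offset) % len(names)]
                sc = [] if resname == "GLY" else [("CB", "C"), ("CG", "C")]
                residues.append(simple_residue(chain, i, resname, o, sc))
        s = build_structure(residues)
        cm = native_contacts(s)
        assert cm.counts == brute_force_contacts(s)

    def test_symmetry_and_rigid_invariance(self, toy, cmap):
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = toy.transformed(rot, np.array([1.0, -2.0, 0.5]))
        cm2 = native_contacts(moved)
        assert cm2.counts == cmap.counts
        for (a, b), n in cmap.counts.items():
            assert cmap.get(b, a) == n  # symmetric lookup


class TestMutateResidue:
    def _ile_structure(self):
        return build_structure([
            simple_residue("A", 72, "ILE", [0, 0, 0],
                           [("CB", "C"), ("CG1", "C"), ("CG2", "C"), ("CD1", "C")]),
            simple_residue("A", 43, "LEU", [1, 0, 0],
                           [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")]),
            simple_residue("B", 1, "ALA", [0.5, 0.3, 0], [("CB", "C")]),
        ])

    def test_ile_to_val_drops_one_atom(self):
        s = self._ile_structure()
        m = mutate_residue(s, "A", 72, "VAL")
        assert m.n_atoms == s.n_atoms - 1
        assert m.residue_name("A", 72) == "VAL"
        assert "CD1" not in set(m.atom_name[m.atom_mask("A", 72)])

    def test_leu_to_ala_keeps_cb_only(self):
        s = self._ile_structure()
        m = mutate_residue(s, "A", 43, "ALA")
        side = [a for a in m.atom_name[m.atom_mask("A", 43)] if a not in "N CA C O".split()]
        assert side == ["CB"]

    def test_growth_mutation_unsupported(self):
        s = self._ile_structure()
        with pytest.raises(UnsupportedMutationError, match="deletion-only"):
            mutate_residue(s, "B", 1, "TRP")

    def test_mutation_never_creates_contacts(self):
        s = self._ile_structure()
        wt = native_contacts(s)
        m = mutate_residue(s, "A", 72, "VAL")
        mut = native_contacts(m)
        assert mut.counts == brute_force_contacts(m)
        for pair, n in mut.counts.items():
            assert n <= wt.get(*pair)

    def test_unknown_residue(self):
        with pytest.raises(ValueError, match="unknown residue"):
            mutate_residue(self._ile_structure(), "A", 72, "XXX")


class TestShrakeRupley:
    def test_single_sphere_analytic(self):
        r = 0.17
        areas = shrake_rupley(np.zeros((1, 3)), np.array([r]), probe=0.14)
        exact = 4 * np.pi * (r + 0.14) ** 2
        assert abs(areas[0] - exact) / exact < 0.01

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        radii = np.array([0.17, 0.152])
        areas = shrake_rupley(coords, radii)
        singles = [
            shrake_rupley(np.zeros((1, 3)), np.array([r]))[0] for r in radii
        ]
        assert np.allclose(areas, singles, rtol=1e-12)

    def test_two_sphere_closed_form(self):
        # equal extended radii R at distance d < 2R: per-sphere exposed area
        # is 4 pi R^2 - 2 pi R h with cap height h = R - d/2
        r, probe, d = 0.17, 0.14, 0.35
        R = r + probe
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = shrake_rupley(coords, np.array([r, r]), probe=probe, n_points=2000)
        h = R - d / 2
        exact = 4 * np.pi * R**2 - 2 * np.pi * R * h
        assert abs(areas[0] - exact) / exact < 0.02
        assert abs(areas[1] - exact) / exact < 0.02

    def test_rotation_invariance(self, toy):
        radii = atom_radii(toy)
        a = shrake_rupley(toy.coords, radii, n_points=240)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
        b = shrake_rupley(toy.coords @ rot.T + 3.0, radii, n_points=240)
        assert np.allclose(a.sum(), b.sum(), rtol=0.02)

    def test_adding_atoms_never_increases(self, toy):
        radii = atom_radii(toy)
        full = shrake_rupley(toy.coords, radii, n_points=240)
        sub = shrake_rupley(toy.coords[:50], radii[:50], n_points=240)
        assert np.all(full[:50] <= sub + 1e-9)


class TestHydrophobicSasa:
    def test_site_must_exist(self, toy):
        site = BindingSiteDefinition((("A", 999),))
        with pytest.raises(KeyError):
            hydrophobic_sasa(toy, site)

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            BindingSiteDefinition(())

    def test_ligand_binding_buries_site(self, toy, cmap):
        # receptor residues with inter-chain contacts lose exposure on binding
        site = BindingSiteDefinition(tuple(sorted({
            a if a[0] == "A" else b
            for a, b in cmap.counts if a[0] != b[0]
        })))
        bound = hydrophobic_sasa(toy, site, n_points=240)
        apart = toy.copy()
        apart.coords[apart.chain_id == "B"] += np.array([0.0, 0.0, 10.0])
        free = hydrophobic_sasa(apart, site, n_points=240)
        assert bound < free


def test_structure_invariants(toy):
    assert set(np.unique(toy.chain_id)) == {"A", "B"}
    assert np.all(np.isfinite(toy.coords))
    # residue indices unique per chain
    for chain in ("A", "B"):
        idx = toy.res_index[toy.chain_id == chain]
        names = toy.atom_name[toy.chain_id == chain]
        per_res = {}
        for i, nm in zip(idx, names):
            per_res.setdefault(i, []).append(nm)
        for i, atoms in per_res.items():
            assert len(atoms) == len(set(atoms))
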