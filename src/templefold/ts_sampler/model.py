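"""Two-site-per-residue Go-type coarse-grained model.

Each residue contributes a CA site plus a side-chain centroid site
(glycine: CA only).  The potential has four parts:

- bonded harmonics on CA(i)-CA(i+1), CA(i)-CA(i+2), CA(i)-CA(i+3) and
  CA-SC distances, restraining chain geometry at its native values;
- an elastic network over receptor site pairs within a cutoff, holding the
  folded template near its native shape without breaking frame invariance;
- attractive Gaussian wells centred at the native side-chain centroid
  separation for every native-contact residue pair, with depth proportional
  to the atomistic heavy-atom pair count;
- a soft r^-12 repulsion between all non-excluded site pairs.

A contact is "formed" when the centroid distance is below 1.2x its native
value, so the native conformation scores Phi_sim = 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..structure import ComplexStructure, NativeContactMap

# Force-field constants (kcal/mol, nm); exposed via build_cg_model kwargs.
K_BOND = 100.0
K_ANGLE = 20.0   # CA(i)-CA(i+2)
K_DIHED = 5.0    # CA(i)-CA(i+3)
K_NETWORK = 20.0
NETWORK_CUTOFF = 1.0
EPS_CONTACT = 2.2      # per native heavy-atom pair
EPS_CONTACT_MAX = 6.6  # cap on a single well depth
WELL_WIDTH = 0.10
SIGMA_REP = 0.30
EPS_REP = 1.0
FORMED_FACTOR = 1.2


@dataclass
class CGModel:
    """Flat-array coarse-grained model ready for the MC kernel."""

    # sites
    x0: np.ndarray            # (n_sites, 3) native coordinates, nm
    site_chain: np.ndarray    # 0 receptor, 1 ligand
    site_kind: np.ndarray     # 0 CA, 1 side-chain centroid
    site_residue: np.ndarray  # residue index per site
    # residues
    residues: list            # [(chain_label, res_index), ...]
    residue_chain: np.ndarray
    contact_site: np.ndarray  # per residue: its SC site (CA for Gly)
    # bonded terms
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    # native contact wells
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_r0: np.ndarray
    pair_eps: np.ndarray
    pair_cut: np.ndarray      # formed threshold per pair
    pair_res_a: np.ndarray    # residue indices per pair
    pair_res_b: np.ndarray
    pair_weight: np.ndarray   # atomistic heavy-atom pair count
    res_weight: np.ndarray    # per-residue total native weight
    # nonbonded
    excl: np.ndarray          # (n_sites, n_sites) bool, skip repulsion
    # constants
    well_width: float = WELL_WIDTH
    sigma_rep: float = SIGMA_REP
    eps_rep: float = EPS_REP
    contact_map: NativeContactMap | None = field(default=None, repr=False)

    @property
    def n_sites(self) -> int:
        return len(self.x0)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def ligand_sites(self) -> np.ndarray:
        return np.flatnonzero(self.site_chain == 1)

    def residue_index(self, res: tuple[str, int]) -> int:
        return self.residues.index((str(res[0]), int(res[1])))

    def phi_arrays(self, restraints=None) -> tuple[np.ndarray, float]:
        """(phi_exp per residue with NaN for unrestrained, k_phi)."""
        phi_exp = np.full(self.n_residues, np.nan)
        if restraints is None:
            return phi_exp, 0.0
        for res, phi in restraints.entries.items():
            phi_exp[self.residue_index(res)] = phi
        return phi_exp, restraints.k_phi


def _sidechain_centroids(s: ComplexStructure):
    """Per residue: (CA coord, side-chain centroid or None)."""
    out = []
    side = s.sidechain_mask()
    for chain, idx in s.residues():
        m = s.atom_mask(chain, idx)
        ca = m & (s.atom_name == "CA")
        ca_xyz = s.coords[ca][0] if ca.any() else s.coords[m].mean(axis=0)
        sc = m & side & ~(s.atom_name == "CA")
        sc_xyz = s.coords[sc].mean(axis=0) if sc.any() else None
        out.append(((chain, idx), ca_xyz, sc_xyz))
    return out


def build_cg_model(
    s: ComplexStructure,
    contact_map: NativeContactMap | None = None,
    eps_contact: float = EPS_CONTACT,
    k_network: float = K_NETWORK,
    network_cutoff: float = NETWORK_CUTOFF,
) -> CGModel:
    """Build the Go model from a native complex structure.

    ``contact_map`` defaults to :func:`templefold.structure.native_contacts`
    on ``s``; its atomistic heavy-atom pair counts set the well depths and
    the Phi weights.
    """
    from ..structure import native_contacts

    if contact_map is None:
        contact_map = native_contacts(s)

    info = _sidechain_centroids(s)
    residues = [(str(c), int(i)) for (c, i), _, _ in info]
    residue_chain = np.array(
        [0 if c == s.receptor_chain else 1 for c, _ in residues], dtype=np.int8
    )

    coords, chain_arr, kind_arr, resid_arr = [], [], [], []
    ca_site = np.empty(len(residues), dtype=np.int64)
    contact_site = np.empty(len(residues), dtype=np.int64)
    for r, (_, ca_xyz, sc_xyz) in enumerate(info):
        ca_site[r] = len(coords)
        coords.append(ca_xyz)
        chain_arr.append(residue_chain[r])
        kind_arr.append(0)
        resid_arr.append(r)
        if sc_xyz is not None:
            contact_site[r] = len(coords)
            coords.append(sc_xyz)
            chain_arr.append(residue_chain[r])
            kind_arr.append(1)
            resid_arr.append(r)
        else:  # glycine-like: CA is the contact proxy
            contact_site[r] = ca_site[r]

    x0 = np.asarray(coords, dtype=float)
    site_chain = np.asarray(chain_arr, dtype=np.int8)
    site_kind = np.asarray(kind_arr, dtype=np.int8)
    site_residue = np.asarray(resid_arr, dtype=np.int64)
    n = len(x0)

    # bonded terms along each chain, plus CA-SC struts
    bi, bj, br, bk = [], [], [], []

    def add_bond(i, j, k):
        bi.append(i)
        bj.append(j)
        br.append(float(np.linalg.norm(x0[i] - x0[j])))
        bk.append(k)

    for r in range(len(residues)):
        if contact_site[r] != ca_site[r]:
            add_bond(ca_site[r], contact_site[r], K_BOND)
        for sep, kk in ((1, K_BOND), (2, K_ANGLE), (3, K_DIHED)):
            q = r + sep
            if q < len(residues) and residues[q][0] == residues[r][0]:
                add_bond(ca_site[r], ca_site[q], kk)

    # receptor elastic network (frame-invariant stand-in for a native tether)
    rec_sites = np.flatnonzero(site_chain == 0)
    for a_pos, a in enumerate(rec_sites):
        for b in rec_sites[a_pos + 1:]:
            if site_residue[a] == site_residue[b]:
                continue
            d = float(np.linalg.norm(x0[a] - x0[b]))
            if d < network_cutoff:
                add_bond(a, b, k_network)

    bond_i = np.asarray(bi, dtype=np.int64)
    bond_j = np.asarray(bj, dtype=np.int64)
    bond_r0 = np.asarray(br, dtype=float)
    bond_k = np.asarray(bk, dtype=float)

    # native contact wells between side-chain centroid sites
    res_lookup = {res: r for r, res in enumerate(residues)}
    pi, pj, pr, pe, pc, pa, pb, pw = [], [], [], [], [], [], [], []
    for (ra, rb), count in sorted(contact_map.counts.items()):
        if ra not in res_lookup or rb not in res_lookup:
            continue
        a, b = res_lookup[ra], res_lookup[rb]
        i, j = contact_site[a], contact_site[b]
        r0 = float(np.linalg.norm(x0[i] - x0[j]))
        pi.append(i)
        pj.append(j)
        pr.append(r0)
        pe.append(min(eps_contact * count, EPS_CONTACT_MAX))
        pc.append(FORMED_FACTOR * r0)
        pa.append(a)
        pb.append(b)
        pw.append(float(count))
    pair_i = np.asarray(pi, dtype=np.int64)
    pair_j = np.asarray(pj, dtype=np.int64)
    pair_res_a = np.asarray(pa, dtype=np.int64)
    pair_res_b = np.asarray(pb, dtype=np.int64)
    pair_weight = np.asarray(pw, dtype=float)
    res_weight = np.zeros(len(residues))
    for a, b, w in zip(pair_res_a, pair_res_b, pair_weight):
        res_weight[a] += w
        res_weight[b] += w

    # repulsion exclusions: bonded pairs plus same-chain residue neighbours
    # (|i - j| <= 1, mirroring the nearest-neighbour rule of the contact map)
    excl = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(excl, True)
    res_of = np.array([residues[r][1] for r in site_residue])
    chain_of = np.array([residues[r][0] for r in site_residue], dtype=object)
    same_chain = chain_of[:, None] == chain_of[None, :]
    excl |= same_chain & (np.abs(res_of[:, None] - res_of[None, :]) <= 1)
    for i, j in zip(bond_i, bond_j):
        excl[i, j] = excl[j, i] = True

    return CGModel(
        x0=x0, site_chain=site_chain, site_kind=site_kind, site_residue=site_residue,
        residues=residues, residue_chain=residue_chain, contact_site=contact_site,
        bond_i=bond_i, bond_j=bond_j, bond_r0=bond_r0, bond_k=bond_k,
        pair_i=pair_i, pair_j=pair_j,
        pair_r0=np.asarray(pr, dtype=float),
        pair_eps=np.asarray(pe, dtype=float),
        pair_cut=np.asarray(pc, dtype=float),
        pair_res_a=pair_res_a, pair_res_b=pair_res_b,
        pair_weight=pair_weight, res_weight=res_weight,
        excl=excl, contact_map=contact_map,
    )
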