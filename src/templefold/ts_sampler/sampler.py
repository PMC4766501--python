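"""Annealing driver, native reference sampling and Phi_sim evaluation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .model import CGModel
from .restraints import AnnealingSchedule, PhiRestraintSet

logger = logging.getLogger(__name__)

ENGINE_NOTE = (
    "coarse-grained Go model + Metropolis MC (substitute for the published "
    "explicit-solvent atomistic MD engine)"
)


@dataclass
class TSEnsemble:
    """Conformational ensemble from restrained (or free) sampling.

    ``coords`` is (n_conformations, n_sites, 3) in nm; ``phi_sim_matrix``
    holds per-conformation Phi_sim per residue under the smooth switching
    criterion the sampler restrains (NaN where a residue has no native
    contacts); provenance records seed, schedule and engine.
    """

    model: CGModel
    coords: np.ndarray
    energy_go: np.ndarray
    energy_phi: np.ndarray
    phi_sim_matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_conformations(self) -> int:
        return len(self.coords)

    def mean_phi_sim(self, res: tuple[str, int]) -> float:
        return float(np.nanmean(self.phi_sim_matrix[:, self.model.residue_index(res)]))

    def mean_native_contact_fraction(self) -> float:
        """Ensemble mean of the weighted fraction of native contacts formed."""
        m = self.model
        total = m.pair_weight.sum()
        fracs = np.empty(self.n_conformations)
        for c in range(self.n_conformations):
            formed = _kernel.contact_flags(
                self.coords[c], m.pair_i, m.pair_j, m.pair_cut
            )
            fracs[c] = m.pair_weight[formed].sum() / total
        return float(fracs.mean())


def _csr(n_sites: int, a: np.ndarray, b: np.ndarray):
    """CSR adjacency (start offsets + item indices) for per-site lookups."""
    per_site: list[list[int]] = [[] for _ in range(n_sites)]
    for idx, (i, j) in enumerate(zip(a, b)):
        per_site[int(i)].append(idx)
        per_site[int(j)].append(idx)
    start = np.zeros(n_sites + 1, dtype=np.int64)
    flat: list[int] = []
    for s in range(n_sites):
        flat.extend(per_site[s])
        start[s + 1] = len(flat)
    return start, np.asarray(flat, dtype=np.int64)


def _kernel_args(model: CGModel, phi_exp: np.ndarray, k_phi: float) -> dict:
    sb_start, sb_bond = _csr(model.n_sites, model.bond_i, model.bond_j)
    sp_start, sp_pair = _csr(model.n_sites, model.pair_i, model.pair_j)
    return dict(
        ligand_sites=model.ligand_sites.astype(np.int64),
        sb_start=sb_start, sb_bond=sb_bond,
        bond_i=model.bond_i, bond_j=model.bond_j,
        bond_r0=model.bond_r0, bond_k=model.bond_k,
        sp_start=sp_start, sp_pair=sp_pair,
        pair_i=model.pair_i, pair_j=model.pair_j,
        pair_r0=model.pair_r0, pair_eps=model.pair_eps,
        pair_cut=model.pair_cut,
        pair_res_a=model.pair_res_a, pair_res_b=model.pair_res_b,
        pair_weight=model.pair_weight,
        excl=model.excl, sigma_rep=model.sigma_rep, eps_rep=model.eps_rep,
        well_w=model.well_width,
        res_weight=model.res_weight, phi_exp=phi_exp, k_phi=k_phi,
    )


def go_energy(model: CGModel, coords: np.ndarray) -> float:
    """Go energy (bonds + repulsion + native wells) of one conformation."""
    return float(_kernel.go_energy(
        np.ascontiguousarray(coords, dtype=float),
        model.bond_i, model.bond_j, model.bond_r0, model.bond_k,
        model.pair_i, model.pair_j, model.pair_r0, model.pair_eps,
        model.excl, model.sigma_rep, model.eps_rep, model.well_width,
    ))


def _discrete_wform(coords: np.ndarray, model: CGModel) -> np.ndarray:
    formed = _kernel.contact_flags(
        np.ascontiguousarray(coords, dtype=float),
        model.pair_i, model.pair_j, model.pair_cut,
    )
    wform = np.zeros(model.n_residues)
    for p in np.flatnonzero(formed):
        wform[model.pair_res_a[p]] += model.pair_weight[p]
        wform[model.pair_res_b[p]] += model.pair_weight[p]
    return wform


def phi_sim(coords: np.ndarray, model: CGModel, res: tuple[str, int]) -> float:
    """Fraction of a residue's native contacts formed in one conformation.

    Contacts are weighted by their atomistic heavy-atom pair counts; a pair
    counts as formed when the centroid distance is below 1.2x its native
    value (the smooth switching variant of this criterion drives the
    sampler's restraint gradient).
    """
    r = model.residue_index(res)
    if model.res_weight[r] == 0:
        raise ValueError(f"residue {res} has no native contacts: Phi_sim undefined")
    wform = _discrete_wform(coords, model)
    return float(wform[r] / model.res_weight[r])


def phi_sim_all(coords: np.ndarray, model: CGModel) -> np.ndarray:
    """Discrete Phi_sim for every residue (NaN where undefined)."""
    wform = _discrete_wform(coords, model)
    out = np.full(model.n_residues, np.nan)
    ok = model.res_weight > 0
    out[ok] = wform[ok] / model.res_weight[ok]
    return out


def restraint_energy(
    coords: np.ndarray, restraints: PhiRestraintSet, model: CGModel
) -> float:
    """E_phi = k_phi * sum over restrained residues of (Phi_exp - Phi_sim)^2."""
    if model.contact_map is not None:
        restraints.validate(model.contact_map)
    phi_exp, k_phi = model.phi_arrays(restraints)
    wform = _discrete_wform(coords, model)
    return float(_kernel.phi_energy(wform, model.res_weight, phi_exp, k_phi))


def randomized_ligand_pose(model: CGModel, rng: np.random.Generator) -> np.ndarray:
    """Native coords with the ligand rigidly rotated and displaced within
    3 nm of the binding site."""
    x = model.x0.copy()
    lig = model.ligand_sites
    if lig.size == 0:
        return x
    centre = x[lig].mean(axis=0)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.standard_normal(3)
    shift *= rng.uniform(0.5, 3.0) / max(np.linalg.norm(shift), 1e-9)
    x[lig] = (x[lig] - centre) @ q.T + centre + shift
    return x


def _run(
    model: CGModel,
    restraints: PhiRestraintSet | None,
    temps_per_cycle: np.ndarray,
    n_cycles: int,
    seed: int,
    start: str,
    step_site: float = 0.03,
    step_trans: float = 0.08,
    step_rot: float = 0.2,
    provenance: dict | None = None,
) -> TSEnsemble:
    """Shared driver: ``start`` is "native" (each cycle independently from
    the native pose), "random" (each cycle from a randomised ligand pose)
    or "chain" (each cycle from the previous cycle's endpoint)."""
    phi_exp, k_phi = model.phi_arrays(restraints)
    args = _kernel_args(model, phi_exp, k_phi)
    ss = np.random.SeedSequence([seed, 0x7E11])
    cycle_seeds = ss.generate_state(n_cycles)
    pose_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11EA1]))

    x = model.x0.copy()
    fval, wform = _kernel.phi_state(
        x, model.pair_i, model.pair_j, model.pair_cut,
        model.pair_res_a, model.pair_res_b, model.pair_weight, model.n_residues,
    )
    coords = np.empty((n_cycles, model.n_sites, 3))
    e_go = np.empty(n_cycles)
    e_phi = np.empty(n_cycles)
    phis = np.empty((n_cycles, model.n_residues))
    for c in range(n_cycles):
        if start != "chain" and c > 0 or start == "random" and c == 0:
            x = (model.x0.copy() if start == "native"
                 else randomized_ligand_pose(model, pose_rng))
            fval, wform = _kernel.phi_state(
                x, model.pair_i, model.pair_j, model.pair_cut,
                model.pair_res_a, model.pair_res_b, model.pair_weight,
                model.n_residues,
            )
        acc_s, att_s, acc_r, att_r = _kernel.run_sweeps(
            x, temps_per_cycle, int(cycle_seeds[c] % (2**31 - 1)),
            step_site, step_trans, step_rot,
            fval=fval, wform=wform, **args,
        )
        rate = acc_s / max(att_s, 1)
        if rate < 0.01:
            step_site *= 0.5
            step_trans *= 0.5
            logger.warning(
                "cycle %d acceptance %.2f%% < 1%%: step sizes halved to %.4g nm",
                c, 100 * rate, step_site,
            )
        coords[c] = x
        e_go[c] = go_energy(model, x)
        e_phi[c] = float(_kernel.phi_energy(wform, model.res_weight, phi_exp, k_phi))
        with np.errstate(invalid="ignore"):
            ok = model.res_weight > 0
            phis[c] = np.where(ok, wform / np.where(ok, model.res_weight, 1.0), np.nan)
        logger.debug(
            "cycle %d: T %.0f->%.0f K acc(site) %.1f%% acc(rigid) %.1f%% "
            "E_go %.2f E_phi %.2f",
            c, temps_per_cycle[0], temps_per_cycle[-1],
            100 * rate, 100 * acc_r / max(att_r, 1), e_go[c], e_phi[c],
        )
    prov = {"seed": seed, "engine": ENGINE_NOTE, "start": start}
    if provenance:
        prov.update(provenance)
    return TSEnsemble(model, coords, e_go, e_phi, phis, prov)


def anneal(
    model: CGModel,
    restraints: PhiRestraintSet | None,
    schedule: AnnealingSchedule,
    seed: int,
    start: str = "native",
    **step_kwargs,
) -> TSEnsemble:
    """Phi-restrained simulated annealing.

    Each cycle ramps the temperature linearly from ``schedule.t_high`` to
    ``schedule.t_low`` and contributes its final conformation to the
    ensemble.  By default every cycle starts independently from the native
    pose and the annealing melts it down to the restrained target; ``start``
    may instead be "random" (randomised ligand pose per cycle) or "chain"
    (continue from the previous endpoint) — both explore worse in practice
    because misdocked poses are kinetic traps at these temperatures.
    Bit-reproducible for a given seed.
    """
    if restraints is not None and model.contact_map is not None:
        restraints.validate(model.contact_map)
    prov = {
        "kind": "ts_anneal",
        "schedule": {
            "n_cycles": schedule.n_cycles,
            "sweeps_per_cycle": schedule.sweeps_per_cycle,
            "t_high": schedule.t_high,
            "t_low": schedule.t_low,
        },
        "restraints": None if restraints is None else {
            "n": len(restraints), "k_phi": restraints.k_phi,
        },
    }
    return _run(
        model, restraints, schedule.cycle_temperatures(), schedule.n_cycles,
        seed, start, provenance=prov, **step_kwargs,
    )


def native_reference(
    model: CGModel,
    temperature: float = 283.0,
    sweeps: int = 20000,
    seed: int = 0,
    n_frames: int = 100,
    **step_kwargs,
) -> TSEnsemble:
    """Unrestrained constant-temperature sampling from the native state.

    Provides the native baseline for fluctuation comparisons and the
    ensemble over which hydrophobic SASA is averaged.  Frames are collected
    along one continuous trajectory.
    """
    sweeps_per_frame = max(sweeps // n_frames, 1)
    temps = np.full(sweeps_per_frame, float(temperature))
    prov = {"kind": "native_reference", "temperature": temperature, "sweeps": sweeps}
    return _run(
        model, None, temps, n_frames, seed, "chain",
        provenance=prov, **step_kwargs,
    )


def subset_restraint_control(
    model: CGModel,
    restraints: PhiRestraintSet,
    residue_subset,
    schedule: AnnealingSchedule,
    seed: int,
    full_ensemble: TSEnsemble | None = None,
) -> tuple[TSEnsemble, dict]:
    """Anneal with only a subset of the restraints (robustness control).

    Returns the subset ensemble and a comparison report; when
    ``full_ensemble`` is given the report includes the mean absolute
    difference of native-contact formation frequencies between the two
    ensembles and both mean native-contact fractions.
    """
    sub = restraints.subset(residue_subset)
    ens = anneal(model, sub, schedule, seed)
    ens.provenance["kind"] = "subset_restraint_control"
    ens.provenance["subset"] = sorted(str(r) for r in sub.entries)
    report: dict = {"n_subset": len(sub), "n_full": len(restraints)}
    report["subset_native_fraction"] = ens.mean_native_contact_fraction()
    if full_ensemble is not None:
        f_sub = _pair_frequencies(ens)
        f_full = _pair_frequencies(full_ensemble)
        report["mean_abs_frequency_diff"] = float(np.abs(f_sub - f_full).mean())
        report["full_native_fraction"] = full_ensemble.mean_native_contact_fraction()
    return ens, report


def _pair_frequencies(e: TSEnsemble) -> np.ndarray:
    m = e.model
    freq = np.zeros(len(m.pair_i))
    for c in range(e.n_conformations):
        freq += _kernel.contact_flags(e.coords[c], m.pair_i, m.pair_j, m.pair_cut)
    return freq / e.n_conformations
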