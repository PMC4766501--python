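import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from templefold.structure import native_contacts
from templefold.synthetic_data import gen_phi_set, gen_toy_complex
from templefold.ts_sampler import (
    AnnealingSchedule,
    PhiRestraintSet,
    anneal,
    build_cg_model,
    native_reference,
    phi_sim,
    restraint_energy,
    subset_restraint_control,
)
from templefold.ts_sampler import _kernel
from templefold.ts_sampler.model import CGModel
from templefold.ts_sampler.restraints import NonClassicalPhiWarning
from templefold.ts_sampler.sampler import go_energy, phi_sim_all


class TestBuildCgModel:
    def test_site_count_bookkeeping(self, toy, model):
        n_res = len(toy.residues())
        n_gly = sum(1 for c, i in toy.residues() if toy.residue_name(c, i) == "GLY")
        assert model.n_sites == 2 * n_res - n_gly

    def test_glycine_contributes_ca_site(self):
        s = gen_toy_complex(8, 4, seed=1)
        s.res_name[s.atom_mask("A", 2)] = "GLY"
        keep = ~(s.atom_mask("A", 2) & (s.atom_name == "CB"))
        import templefold.structure as ts

        s2 = ts.ComplexStructure(
            s.chain_id[keep], s.res_index[keep], s.res_name[keep],
            s.atom_name[keep], s.element[keep], s.coords[keep], "A", "B",
        )
        m = build_cg_model(s2)
        r = m.residue_index(("A", 2))
        assert m.contact_site[r] == np.flatnonzero(
            (m.site_residue == r) & (m.site_kind == 0))[0]

    def test_native_is_lowest_among_test_conformations(self, model):
        e_native = go_energy(model, model.x0)
        lig = model.ligand_sites
        displaced = model.x0.copy()
        displaced[lig] += np.array([0.0, 0.0, 5.0])
        rng = np.random.default_rng(0)
        scrambled = model.x0.copy()
        scrambled[lig] = rng.uniform(-1, 1, size=(len(lig), 3)) + scrambled[lig].mean(0)
        assert e_native < go_energy(model, displaced)
        assert e_native < go_energy(model, scrambled)

    def test_energy_frame_invariance(self, model):
        rot = Rotation.from_rotvec([0.5, -0.2, 1.1]).as_matrix()
        moved = model.x0 @ rot.T + np.array([2.0, -1.0, 0.3])
        assert go_energy(model, moved) == pytest.approx(
            go_energy(model, model.x0), rel=1e-9, abs=1e-9
        )


class TestPhiSim:
    def test_native_is_one(self, model, cmap):
        for res, _ in sorted(cmap.counts):
            if model.res_weight[model.residue_index(res)] > 0:
                assert phi_sim(model.x0, model, res) == pytest.approx(1.0)

    def test_displaced_ligand_zeroes_interchain(self, model, cmap):
        x = model.x0.copy()
        x[model.ligand_sites] += np.array([0.0, 0.0, 5.0])
        # a ligand residue whose contacts are all inter-chain reads zero
        for res in {r for pair in cmap.counts for r in pair if r[0] == "B"}:
            partners = cmap.pairs_of(res)
            if all(p[0][0] == "A" for p in partners):
                assert phi_sim(x, model, res) == pytest.approx(0.0)

    def test_brute_force_oracle(self, model):
        rng = np.random.default_rng(5)
        x = model.x0 + rng.normal(0, 0.15, size=model.x0.shape)
        sims = phi_sim_all(x, model)
        for r in range(model.n_residues):
            if model.res_weight[r] == 0:
                continue
            formed_w = 0.0
            for p in range(len(model.pair_i)):
                if model.pair_res_a[p] != r and model.pair_res_b[p] != r:
                    continue
                d = np.linalg.norm(x[model.pair_i[p]] - x[model.pair_j[p]])
                if d < model.pair_cut[p]:
                    formed_w += model.pair_weight[p]
            assert sims[r] == pytest.approx(formed_w / model.res_weight[r])

    def test_residue_without_contacts_undefined(self, toy, cmap, model):
        contacted = {r for pair in cmap.counts for r in pair}
        lonely = [r for r in toy.residues() if r not in contacted]
        if not lonely:
            pytest.skip("every residue has contacts in this toy")
        with pytest.raises(ValueError, match="undefined"):
            phi_sim(model.x0, model, lonely[0])


class TestRestraintEnergy:
    def test_exact_match_is_zero(self, model, cmap):
        entries = {
            res: 1.0
            for res in {r for pair in cmap.counts for r in pair if r[0] == "B"}
        }
        restr = PhiRestraintSet(entries, k_phi=3.0)
        assert restraint_energy(model.x0, restr, model) == pytest.approx(0.0)

    def test_half_mismatch_quarter(self, model, cmap):
        res = next(r for pair in cmap.counts for r in pair if r[0] == "B")
        restr = PhiRestraintSet({res: 0.5}, k_phi=1.0)
        # native Phi_sim = 1.0, target 0.5 -> (0.5)^2 * 1.0
        assert restraint_energy(model.x0, restr, model) == pytest.approx(0.25)

    def test_nonnegative_for_random_conformations(self, model, cmap):
        restr = gen_phi_set(cmap, "B", 0.5, 0.2, seed=3)
        rng = np.random.default_rng(11)
        for _ in range(10):
            x = model.x0 + rng.normal(0, 0.3, size=model.x0.shape)
            assert restraint_energy(x, restr, model) >= 0.0

    def test_requires_native_contacts(self, model):
        restr = PhiRestraintSet({("B", 9999): 0.5})
        with pytest.raises(ValueError, match="native contacts"):
            restraint_energy(model.x0, restr, model)

    def test_nonclassical_phi_warns(self):
        with pytest.warns(NonClassicalPhiWarning):
            PhiRestraintSet({("B", 1): 1.4})


class TestAnneal:
    def test_determinism(self, model, cmap):
        restr = gen_phi_set(cmap, "B", 0.6, 0.1, seed=2)
        sched = AnnealingSchedule(n_cycles=3, sweeps_per_cycle=150)
        a = anneal(model, restr, sched, seed=5)
        b = anneal(model, restr, sched, seed=5)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.phi_sim_matrix, b.phi_sim_matrix, equal_nan=True)

    def test_conformation_count_matches_cycles(self, model, short_schedule):
        ens = anneal(model, None, short_schedule, seed=1)
        assert ens.n_conformations == short_schedule.n_cycles

    def test_unrestrained_low_t_relaxes_to_native(self, model):
        sched = AnnealingSchedule(n_cycles=6, sweeps_per_cycle=300,
                                  t_high=300.0, t_low=283.0)
        ens = anneal(model, None, sched, seed=3)
        assert ens.mean_native_contact_fraction() > 0.8

    def test_full_restraints_dominate(self, model, cmap):
        entries = {
            res: 1.0
            for res in {r for pair in cmap.counts for r in pair if r[0] == "B"}
        }
        restr = PhiRestraintSet(entries, k_phi=60.0)
        ens = anneal(model, restr, AnnealingSchedule(8, 400), seed=4)
        mean_phi = np.nanmean([ens.mean_phi_sim(r) for r in entries])
        assert mean_phi >= 0.9

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            AnnealingSchedule(t_high=283.0, t_low=383.0)
        with pytest.raises(ValueError):
            AnnealingSchedule(n_cycles=0)


class TestNativeReference:
    def test_mean_phi_near_one(self, model, cmap):
        ref = native_reference(model, sweeps=3000, seed=2, n_frames=15)
        phis = [
            ref.mean_phi_sim(res)
            for res in {r for pair in cmap.counts for r in pair}
            if model.res_weight[model.residue_index(res)] > 0
        ]
        assert np.nanmean(phis) == pytest.approx(1.0, abs=0.1)

    def test_energy_stationary(self, model):
        ref = native_reference(model, sweeps=6000, seed=2, n_frames=30)
        e = ref.energy_go
        half = len(e) // 2
        drift = abs(e[half:].mean() - e[:half].mean())
        assert drift < 2 * e.std(ddof=1)

    def test_native_less_fluctuating_than_restrained(self, model, cmap):
        from templefold.ensemble_analysis import ensemble_fluctuation

        ref = native_reference(model, sweeps=3000, seed=6, n_frames=15)
        restr = gen_phi_set(cmap, "B", 0.5, 0.1, seed=2, upper=1.0)
        ens = anneal(model, restr, AnnealingSchedule(15, 400), seed=6)
        assert ensemble_fluctuation(ref) < ensemble_fluctuation(ens)


class TestSubsetControl:
    def test_full_subset_is_identity(self, model, cmap, short_schedule):
        restr = gen_phi_set(cmap, "B", 0.8, 0.1, seed=2, upper=1.0)
        full = anneal(model, restr, short_schedule, seed=9)
        sub, report = subset_restraint_control(
            model, restr, list(restr.entries), short_schedule, seed=9,
            full_ensemble=full,
        )
        assert np.array_equal(sub.coords, full.coords)
        assert report["mean_abs_frequency_diff"] == pytest.approx(0.0)

    def test_empty_subset_rejected(self, model, cmap, short_schedule):
        restr = gen_phi_set(cmap, "B", 0.8, 0.1, seed=2)
        with pytest.raises(ValueError, match="empty"):
            subset_restraint_control(model, restr, [], short_schedule, seed=1)

    def test_subset_recovery_and_more_native(self, model, cmap):
        # targets below the native equilibrium: the subset run tracks its
        # targets and ends at least as native-like as the full-restraint
        # ensemble (fewer below-native restraints -> more native)
        restr = gen_phi_set(cmap, "B", 0.8, 0.05, seed=8, upper=1.0)
        sched = AnnealingSchedule(20, 600)
        full = anneal(model, restr, sched, seed=13)
        subset = sorted(restr.entries)[:4]
        sub, report = subset_restraint_control(
            model, restr, subset, sched, seed=13, full_ensemble=full,
        )
        for res in subset:
            assert abs(sub.mean_phi_sim(res) - restr.entries[res]) < 0.15
        assert report["subset_native_fraction"] >= report["full_native_fraction"] - 0.02


class TestMetropolisKernel:
    def test_detailed_balance_two_site_boltzmann(self):
        # single harmonic bond E = k (r - r0)^2: sampled bond lengths must
        # follow p(r) ~ r^2 exp(-E/kT) (chi-squared GOF, p > 0.01)
        k_bond, r0, temp = 50.0, 0.5, 300.0
        kt = 1.98720425e-3 * temp
        x0 = np.array([[0.0, 0, 0], [r0, 0, 0]])
        n = 2
        model = CGModel(
            x0=x0.copy(),
            site_chain=np.zeros(n, dtype=np.int8),
            site_kind=np.zeros(n, dtype=np.int8),
            site_residue=np.array([0, 1]),
            residues=[("A", 1), ("A", 5)],
            residue_chain=np.zeros(2, dtype=np.int8),
            contact_site=np.array([0, 1]),
            bond_i=np.array([0]), bond_j=np.array([1]),
            bond_r0=np.array([r0]), bond_k=np.array([k_bond]),
            pair_i=np.array([], dtype=np.int64), pair_j=np.array([], dtype=np.int64),
            pair_r0=np.array([]), pair_eps=np.array([]), pair_cut=np.array([]),
            pair_res_a=np.array([], dtype=np.int64),
            pair_res_b=np.array([], dtype=np.int64),
            pair_weight=np.array([]), res_weight=np.zeros(2),
            excl=np.ones((2, 2), dtype=bool),
        )
        from templefold.ts_sampler.sampler import _kernel_args

        args = _kernel_args(model, np.full(2, np.nan), 0.0)
        x = x0.copy()
        fval, wform = _kernel.phi_state(
            x, model.pair_i, model.pair_j, model.pair_cut,
            model.pair_res_a, model.pair_res_b, model.pair_weight, 2,
        )
        temps = np.full(10, temp)
        samples = []
        for chunk in range(3000):
            _kernel.run_sweeps(
                x, temps, 1000 + chunk, 0.05, 0.0, 0.0,
                fval=fval, wform=wform, **args,
            )
            samples.append(np.linalg.norm(x[0] - x[1]))
        samples = np.asarray(samples[100:])

        sigma = np.sqrt(kt / (2 * k_bond))
        edges = np.linspace(r0 - 3 * sigma, r0 + 3 * sigma, 11)
        grid = np.linspace(edges[0], edges[-1], 4001)
        pdf = grid**2 * np.exp(-k_bond * (grid - r0) ** 2 / kt)
        cdf = np.concatenate(([0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2)))
        cdf /= cdf[-1]
        probs = np.diff(np.interp(edges, grid, cdf))
        inside = (samples >= edges[0]) & (samples <= edges[-1])
        counts, _ = np.histogram(samples[inside], bins=edges)
        probs = probs / probs.sum()
        chi2 = ((counts - inside.sum() * probs) ** 2 / (inside.sum() * probs)).sum()
        p = 1 - stats.chi2.cdf(chi2, df=len(counts) - 1)
        assert p > 0.01

    def test_phi_bookkeeping_stays_consistent(self, model, cmap):
        from templefold.ts_sampler.sampler import _kernel_args

        restr = gen_phi_set(cmap, "B", 0.5, 0.1, seed=1)
        phi_exp, k_phi = model.phi_arrays(restr)
        args = _kernel_args(model, phi_exp, k_phi)
        x = np.ascontiguousarray(model.x0.copy())
        fval, wform = _kernel.phi_state(
            x, model.pair_i, model.pair_j, model.pair_cut,
            model.pair_res_a, model.pair_res_b, model.pair_weight,
            model.n_residues,
        )
        temps = np.linspace(383, 283, 50)
        _kernel.run_sweeps(x, temps, 77, 0.03, 0.08, 0.2,
                           fval=fval, wform=wform, **args)
        f2, w2 = _kernel.phi_state(
            x, model.pair_i, model.pair_j, model.pair_cut,
            model.pair_res_a, model.pair_res_b, model.pair_weight,
            model.n_residues,
        )
        assert np.allclose(fval, f2, atol=1e-9)
        assert np.allclose(wform, w2, atol=1e-9)
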