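# templefold

From stopped-flow binding kinetics to Φ-value-restrained transition-state
ensembles for coupled folding-and-binding reactions.

The package implements a complete, reusable pipeline:

1. **kinetics** — single-exponential fits of pseudo-first-order binding
   traces and linear regression `k_obs = k_on·[L] + k_off` (slope = k_on,
   intercept = k_off, weighted or unweighted, with standard errors).
2. **energetics** — mutational free-energy changes
   (`ΔΔG_eq = RT·ln(K_D,mut/K_D,wt)`, `ΔΔG‡ = RT·ln(k_on,wt/k_on,mut)`),
   Φ values with the customary 0.4 kcal/mol exclusion rule, and
   linear free-energy-relationship (Brønsted α) fits with case-resampling
   bootstrap uncertainties.
3. **structure** — PDB I/O (nm units internally), native contact maps
   (heavy side-chain atom pairs within 0.65 nm, nearest neighbours
   excluded), deletion-only coarse mutations, and Shrake–Rupley SASA for
   hydrophobic binding-site exposure.
4. **ts_sampler** — transition-state ensembles by simulated annealing of a
   two-site-per-residue Gō model under a pseudo-energy
   `E_Φ = k_Φ·Σ(Φ_exp − Φ_sim)²`, where Φ_sim is the fraction of a
   residue's native contacts formed. Sampling is Metropolis Monte Carlo
   (site moves + rigid-body ligand moves), fully reproducible by seed.
5. **ensemble_analysis** — fluctuation about the iteratively superposed
   mean structure, native/non-native contact-frequency maps, and
   cross-correlations (fluctuation vs. log k_on, fluctuation vs. α).
6. **synthetic_data** — seeded generators for every input: noisy kinetic
   traces, a toy helix-in-groove complex, Beta-distributed Φ restraint
   sets, and LFER datasets with known ground truth.
7. **pipeline/CLI** — end-to-end orchestration with per-stage seeds fanned
   out from one master seed.

**Engine note.** The original analysis sampled restrained ensembles with
explicit-solvent atomistic molecular dynamics. Here that engine is
deliberately replaced by a desk-scale coarse-grained structure-based model;
the Φ restraint, contact definitions and ensemble statistics are
implemented exactly, and every ensemble records the substitution in its
provenance. Absolute fluctuation magnitudes are therefore not comparable
to atomistic values — cross-variant orderings and correlations are.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (kinetic parameter
recovery, LFER recovery/coverage, Φ-restraint recovery within 0.10,
templated-folding fluctuation ordering, oracle equivalences, and the Φ
exclusion rule). The whole suite runs in a couple of minutes on one CPU.

## CLI

```sh
templefold simulate --scenario paper_like --out data/ --seed 1
templefold fit-kinetics --manifest data/manifest.yaml --out rates.csv
templefold lfer --rates rates.csv --wt-ligand WT --bootstrap 1000 --seed 1
templefold sample-ts --pdb data/complex.pdb --restraints data/phi_WT.csv \
    --cycles 300 --seed 11 --out-prefix ts_WT
templefold analyze --ensemble ts_WT.pdb --ref data/complex.pdb --out stats.json
templefold config --show
templefold run --config run.yaml        # full pipeline, or defaults:
templefold run --seed 1 --out run/
```

A full `templefold run` writes `rates.csv`, `energetics.csv`,
`lfer_<variant>.json`, `ensembles/`, `stats.json`, `correlations.json`,
a machine-readable `summary.json` (byte-identical on rerun with the same
seed) and a human-readable `report.txt`.

## File formats

- traces: CSV `time_s,signal` + YAML manifest (file → concentration, variant)
- rate constants: CSV `receptor_variant,ligand_variant,kon_uM_s,kon_sd,koff_s,koff_sd,temperature_K`
- Φ restraints: CSV `chain,residue,phi,phi_sd`
- contact maps: CSV `chain_i,res_i,chain_j,res_j,n_atom_pairs[,frequency]`
- ensembles: multi-MODEL PDB of the coarse-grained sites + per-conformation CSV
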