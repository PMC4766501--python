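"""File formats exchanged between pipeline stages.

- traces: CSV with header ``time_s,signal``, one file per concentration,
  listed in a YAML manifest;
- rate constants: CSV ``receptor_variant,ligand_variant,kon_uM_s,kon_sd,
  koff_s,koff_sd,temperature_K`` (the canonical kinetics -> energetics
  exchange format);
- Phi restraints: CSV ``chain,residue,phi,phi_sd``;
- ensembles: multi-MODEL PDB of the coarse-grained sites (CA + CB
  pseudo-atoms) plus a per-conformation CSV of energies and Phi_sim.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import BindingTrace, RateConstants
from .structure import ComplexStructure
from .ts_sampler import CGModel, PhiRestraintSet, TSEnsemble, build_cg_model

RATES_COLUMNS = [
    "receptor_variant", "ligand_variant", "kon_uM_s", "kon_sd",
    "koff_s", "koff_sd", "temperature_K",
]


# -- kinetic traces ---------------------------------------------------------

def write_trace_csv(trace: BindingTrace, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "signal"])
        for t, y in zip(trace.time, trace.signal):
            w.writerow([f"{t:.9g}", f"{y:.9g}"])


def read_trace_csv(path, ligand_conc: float, probe_conc: float) -> BindingTrace:
    df = pd.read_csv(path)
    return BindingTrace(
        df["time_s"].to_numpy(), df["signal"].to_numpy(), ligand_conc, probe_conc
    )


def write_manifest(path, series: list[dict]) -> None:
    """``series`` entries: receptor_variant, ligand_variant, temperature_K,
    probe_conc_uM and traces: [{file, ligand_conc_uM}, ...]."""
    with open(path, "w") as fh:
        yaml.safe_dump({"series": series}, fh, sort_keys=False)


def read_manifest(path) -> list[dict]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "series" not in doc:
        raise ValueError(f"manifest {path} lacks a top-level 'series' list")
    return doc["series"]


def load_manifest_traces(manifest_path) -> list[dict]:
    """Resolve a manifest into per-series dicts with BindingTrace objects
    grouped by concentration."""
    base = Path(manifest_path).parent
    out = []
    for entry in read_manifest(manifest_path):
        probe = float(entry.get("probe_conc_uM", 3.0))
        traces: dict[float, list[BindingTrace]] = {}
        for t in entry["traces"]:
            conc = float(t["ligand_conc_uM"])
            traces.setdefault(conc, []).append(
                read_trace_csv(base / t["file"], conc, probe)
            )
        out.append({
            "receptor_variant": entry.get("receptor_variant", "WT"),
            "ligand_variant": entry.get("ligand_variant", "WT"),
            "temperature_K": float(entry.get("temperature_K", 283.15)),
            "traces": traces,
        })
    return out


# -- rate constants ---------------------------------------------------------

def write_rates_csv(rates: list[RateConstants], path) -> None:
    rows = [
        {
            "receptor_variant": r.variant_receptor,
            "ligand_variant": r.variant_ligand,
            "kon_uM_s": r.k_on, "kon_sd": r.k_on_sd,
            "koff_s": r.k_off, "koff_sd": r.k_off_sd,
            "temperature_K": r.temperature,
        }
        for r in rates
    ]
    pd.DataFrame(rows, columns=RATES_COLUMNS).to_csv(path, index=False)


def read_rates_csv(path) -> list[RateConstants]:
    df = pd.read_csv(path)
    missing = set(RATES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rates CSV missing columns: {sorted(missing)}")
    return [
        RateConstants(
            k_on=row.kon_uM_s, k_off=row.koff_s,
            k_on_sd=row.kon_sd, k_off_sd=row.koff_sd,
            temperature=row.temperature_K,
            variant_receptor=row.receptor_variant,
            variant_ligand=row.ligand_variant,
        )
        for row in df.itertuples()
    ]


# -- energetics -------------------------------------------------------------

def write_energetics_csv(records, path) -> None:
    rows = [
        {
            "ligand_variant": r.ligand_variant,
            "ddg_eq_kcal": r.ddg_eq, "ddg_eq_sd": r.ddg_eq_sd,
            "ddg_ts_kcal": r.ddg_ts, "ddg_ts_sd": r.ddg_ts_sd,
            "phi": "" if r.phi is None else r.phi,
            "phi_sd": "" if r.phi_sd is None else r.phi_sd,
            "included_in_phi": r.included_in_phi,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_energetics_csv(path) -> list:
    from .energetics import EnergeticRecord

    df = pd.read_csv(path)
    records = []
    for row in df.itertuples():
        phi = getattr(row, "phi", None)
        phi = None if phi is None or pd.isna(phi) else float(phi)
        phi_sd = getattr(row, "phi_sd", None)
        phi_sd = None if phi_sd is None or pd.isna(phi_sd) else float(phi_sd)
        records.append(EnergeticRecord(
            ligand_variant=str(row.ligand_variant),
            ddg_eq=float(row.ddg_eq_kcal), ddg_ts=float(row.ddg_ts_kcal),
            ddg_eq_sd=float(getattr(row, "ddg_eq_sd", float("nan"))),
            ddg_ts_sd=float(getattr(row, "ddg_ts_sd", float("nan"))),
            phi=phi, phi_sd=phi_sd,
            included_in_phi=bool(getattr(row, "included_in_phi", phi is not None)),
        ))
    return records


def write_lfer_json(result, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "alpha": result.alpha, "alpha_sd": result.alpha_sd,
                "intercept_kcal": result.intercept,
                "intercept_sd": result.intercept_sd,
                "n_points": result.n_points,
                "bootstrap_samples": result.bootstrap_samples,
                "seed": result.seed,
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")


# -- Phi restraints ---------------------------------------------------------

def write_restraints_csv(restraints: PhiRestraintSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["chain", "residue", "phi", "phi_sd"])
        for (chain, res), phi in sorted(restraints.entries.items()):
            sd = restraints.sds.get((chain, res), "")
            w.writerow([chain, res, f"{phi:.6g}", sd])


def read_restraints_csv(path, k_phi: float | None = None) -> PhiRestraintSet:
    df = pd.read_csv(path)
    entries = {}
    sds = {}
    for row in df.itertuples():
        key = (str(row.chain), int(row.residue))
        entries[key] = float(row.phi)
        if hasattr(row, "phi_sd") and pd.notna(row.phi_sd) and row.phi_sd != "":
            sds[key] = float(row.phi_sd)
    kwargs = {} if k_phi is None else {"k_phi": k_phi}
    return PhiRestraintSet(entries, sds, **kwargs)


# -- contact maps -----------------------------------------------------------

def write_contact_map_csv(cmap, path, frequencies: dict | None = None) -> None:
    """Schema: chain_i,res_i,chain_j,res_j,n_atom_pairs[,frequency]."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["chain_i", "res_i", "chain_j", "res_j", "n_atom_pairs"]
        if frequencies is not None:
            header.append("frequency")
        w.writerow(header)
        for (a, b), n in sorted(cmap.counts.items()):
            row = [a[0], a[1], b[0], b[1], n]
            if frequencies is not None:
                row.append(f"{frequencies.get((a, b), 0.0):.4f}")
            w.writerow(row)


# -- CG ensembles -----------------------------------------------------------

def write_ensemble(e: TSEnsemble, pdb_path, csv_path=None) -> None:
    """Multi-MODEL PDB of the CG sites plus per-conformation statistics."""
    m = e.model
    with open(pdb_path, "w") as fh:
        for c in range(e.n_conformations):
            fh.write(f"MODEL     {c + 1:4d}\n")
            for i in range(m.n_sites):
                chain, resi = m.residues[m.site_residue[i]]
                name = "CA" if m.site_kind[i] == 0 else "CB"
                x, y, z = e.coords[c, i] * 10.0
                fh.write(
                    f"ATOM  {i + 1:5d}  {name:<3s} GLY {chain}{resi:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    if csv_path is not None:
        rows = []
        for c in range(e.n_conformations):
            row = {"conformation": c, "energy_go": e.energy_go[c],
                   "energy_phi": e.energy_phi[c]}
            for r, (chain, resi) in enumerate(m.residues):
                if not np.isnan(e.phi_sim_matrix[c, r]):
                    row[f"phi_{chain}{resi}"] = e.phi_sim_matrix[c, r]
            rows.append(row)
        pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_ensemble(pdb_path, reference: ComplexStructure,
                  model: CGModel | None = None) -> TSEnsemble:
    """Rebuild a TSEnsemble from a CG multi-MODEL PDB and its native
    reference structure (used to rebuild the model and contact map)."""
    from .ts_sampler.sampler import phi_sim_all

    if model is None:
        model = build_cg_model(reference)
    frames = []
    current: list[list[float]] = []
    with open(pdb_path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("ATOM"):
                current.append([
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                ])
            elif line.startswith("ENDMDL"):
                frames.append(np.asarray(current) / 10.0)
    if not frames:
        raise ValueError(f"no MODEL frames in {pdb_path}")
    coords = np.stack(frames)
    if coords.shape[1] != model.n_sites:
        raise ValueError(
            f"ensemble has {coords.shape[1]} sites, model expects {model.n_sites}"
        )
    n = len(coords)
    from .ts_sampler.sampler import go_energy
    e_go = np.array([go_energy(model, coords[c]) for c in range(n)])
    phis = np.stack([phi_sim_all(coords[c], model) for c in range(n)])
    return TSEnsemble(
        model, coords, e_go, np.zeros(n), phis,
        {"kind": "loaded", "source": str(pdb_path)},
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
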