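"""End-to-end orchestration: simulate -> kinetics -> energetics ->
sample-ts -> analyze -> correlate.

Stages communicate only through the documented file formats (see
:mod:`templefold.io`); a single master seed fans out deterministically to
per-stage seeds, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .energetics import energetic_record, lfer_fit
from .ensemble_analysis import contact_frequency_map, correlate, ensemble_fluctuation
from .kinetics import fit_trace_series
from .structure import (
    BindingSiteDefinition,
    hydrophobic_sasa,
    native_contacts,
    read_pdb,
    write_pdb,
)
from .synthetic_data import (
    ScenarioSpec,
    gen_lfer_dataset,
    gen_phi_set,
    gen_toy_complex,
    gen_trace_series,
    paper_like_scenario,
)
from .kinetics import RateConstants
from .ts_sampler import AnnealingSchedule, anneal, build_cg_model, native_reference
from .ts_sampler.restraints import DEFAULT_K_PHI

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved run configuration; written beside the outputs of every run."""

    out_dir: str = "run"
    scenario: str = "paper_like"
    master_seed: int = 1
    # kinetics / synthetic design
    concentrations: tuple = (8.0, 16.0, 32.0, 64.0, 80.0)
    probe_conc_uM: float = 3.0
    noise_sd_frac: float = 0.02
    replicates: int = 5
    # energetics
    phi_threshold_kcal: float = 0.4
    bootstrap: int = 1000
    # structure / sampler
    contact_cutoff_nm: float = 0.65
    k_phi: float = DEFAULT_K_PHI
    n_cycles: int = 50
    sweeps_per_cycle: int = 1000
    t_high: float = 383.0
    t_low: float = 283.0
    receptor_len: int = 30
    ligand_len: int = 10
    stages: tuple = (
        "simulate", "kinetics", "energetics", "sample_ts", "analyze", "correlate",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("concentrations", "stages"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["concentrations"] = list(self.concentrations)
        doc["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    def schedule(self) -> AnnealingSchedule:
        return AnnealingSchedule(
            n_cycles=self.n_cycles, sweeps_per_cycle=self.sweeps_per_cycle,
            t_high=self.t_high, t_low=self.t_low,
        )


def _scenario(config: RunConfig) -> ScenarioSpec:
    if config.scenario != "paper_like":
        raise ValueError(f"unknown scenario {config.scenario!r}")
    return paper_like_scenario(config.master_seed)


def simulate_scenario(spec: ScenarioSpec, out_dir, config: RunConfig) -> dict:
    """Write every pipeline input: traces + manifest, toy complex PDB, Phi
    restraint CSVs, LFER datasets and the generating ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = []
    for v, (k_on, k_off) in sorted(spec.rates.items()):
        rc = RateConstants(k_on, k_off, variant_ligand=v)
        traces = gen_trace_series(
            rc, config.concentrations, config.probe_conc_uM,
            config.noise_sd_frac, config.replicates,
            seed=spec.stage_seed(f"traces:{v}"),
        )
        entries = []
        slug = v.replace("/", "-")
        for i, (conc, reps) in enumerate(sorted(traces.items())):
            for j, tr in enumerate(reps):
                fname = f"trace_{slug}_{i}_{j}.csv"
                tio.write_trace_csv(tr, out / fname)
                entries.append({"file": fname, "ligand_conc_uM": conc})
        series.append({
            "receptor_variant": "KIX",
            "ligand_variant": v,
            "temperature_K": 283.15,
            "probe_conc_uM": config.probe_conc_uM,
            "traces": entries,
        })
    tio.write_manifest(out / "manifest.yaml", series)

    toy = gen_toy_complex(
        spec.receptor_len, spec.ligand_len, seed=spec.stage_seed("toy"),
    )
    write_pdb(toy, out / "complex.pdb")
    cmap = native_contacts(toy, config.contact_cutoff_nm)
    tio.write_contact_map_csv(cmap, out / "native_contacts.csv")

    for name, mean in sorted(spec.phi_means.items()):
        restr = gen_phi_set(
            cmap, toy.ligand_chain, mean, spec.phi_spread,
            seed=spec.stage_seed(f"phi:{name}"), k_phi=config.k_phi, upper=1.0,
        )
        tio.write_restraints_csv(restr, out / f"phi_{name}.csv")

    for name, (alpha, intercept) in sorted(spec.lfer_params.items()):
        records = gen_lfer_dataset(
            alpha, intercept, spec.lfer_n, noise_sd=spec.lfer_noise_sd,
            seed=spec.stage_seed(f"lfer:{name}"),
        )
        tio.write_energetics_csv(records, out / f"lfer_input_{name}.csv")

    truth = {
        "rates": {v: list(kk) for v, kk in spec.rates.items()},
        "phi_means": spec.phi_means,
        "lfer_params": {k: list(v) for k, v in spec.lfer_params.items()},
        "master_seed": spec.master_seed,
    }
    tio.write_json(truth, out / "ground_truth.json")
    return truth


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Outputs: ``data/`` (synthetic inputs), ``rates.csv``, ``energetics_*``,
    ``lfer_*.json``, ``ensembles/``, ``stats.json``, ``correlations.json``,
    ``summary.json``, ``report.txt`` and the resolved ``config.yaml``.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    spec = _scenario(config)
    data_dir = run_dir / "data"
    summary: dict = {"scenario": spec.name, "master_seed": config.master_seed}

    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        if name in config.stages:
            current_stage = name
            return True
        return False

    t0 = time.time()
    try:
        if stage("simulate"):
            logger.info("stage simulate -> %s", data_dir)
            simulate_scenario(spec, data_dir, config)

        if stage("kinetics"):
            logger.info("stage kinetics")
            fitted = []
            for entry in tio.load_manifest_traces(data_dir / "manifest.yaml"):
                rc = fit_trace_series(
                    entry["traces"],
                    variant_receptor=entry["receptor_variant"],
                    variant_ligand=entry["ligand_variant"],
                )
                rc.temperature = entry["temperature_K"]
                fitted.append(rc)
            tio.write_rates_csv(fitted, run_dir / "rates.csv")
            summary["rates"] = {
                r.variant_ligand: {"k_on": r.k_on, "k_off": r.k_off}
                for r in fitted
            }

        if stage("energetics"):
            logger.info("stage energetics")
            rates = {r.variant_ligand: r for r in tio.read_rates_csv(run_dir / "rates.csv")}
            wt = rates["WT"]
            records = [
                energetic_record(wt, mut, config.phi_threshold_kcal)
                for v, mut in sorted(rates.items()) if v != "WT"
            ]
            tio.write_energetics_csv(records, run_dir / "energetics.csv")
            summary["alpha"] = {}
            for name in sorted(spec.lfer_params):
                recs = tio.read_energetics_csv(data_dir / f"lfer_input_{name}.csv")
                res = lfer_fit(
                    recs, bootstrap=config.bootstrap,
                    seed=spec.stage_seed(f"lfer_fit:{name}"),
                )
                tio.write_lfer_json(res, run_dir / f"lfer_{name}.json")
                summary["alpha"][name] = {
                    "alpha": res.alpha, "alpha_sd": res.alpha_sd,
                    "intercept": res.intercept,
                }

        if stage("sample_ts"):
            logger.info("stage sample_ts")
            ens_dir = run_dir / "ensembles"
            ens_dir.mkdir(exist_ok=True)
            toy = read_pdb(data_dir / "complex.pdb", "A", "B")
            cmap = native_contacts(toy, config.contact_cutoff_nm)
            model = build_cg_model(toy, cmap)
            sched = config.schedule()
            for name in sorted(spec.phi_means):
                restr = tio.read_restraints_csv(
                    data_dir / f"phi_{name}.csv", k_phi=config.k_phi,
                )
                ens = anneal(model, restr, sched, seed=spec.stage_seed(f"anneal:{name}"))
                tio.write_ensemble(
                    ens, ens_dir / f"ts_{name}.pdb", ens_dir / f"ts_{name}.csv",
                )
            ref = native_reference(
                model, temperature=config.t_low,
                sweeps=config.sweeps_per_cycle * 10,
                seed=spec.stage_seed("native_reference"), n_frames=50,
            )
            tio.write_ensemble(ref, ens_dir / "native_reference.pdb")

        if stage("analyze"):
            logger.info("stage analyze")
            toy = read_pdb(data_dir / "complex.pdb", "A", "B")
            cmap = native_contacts(toy, config.contact_cutoff_nm)
            model = build_cg_model(toy, cmap)
            stats: dict = {"fluctuation_nm": {}, "n_nonnative_pairs": {}}
            for name in sorted(spec.phi_means):
                ens = tio.read_ensemble(
                    run_dir / "ensembles" / f"ts_{name}.pdb", toy, model,
                )
                stats["fluctuation_nm"][name] = ensemble_fluctuation(ens)
                freq = contact_frequency_map(ens)
                stats["n_nonnative_pairs"][name] = len(freq["nonnative"])
            ref = tio.read_ensemble(
                run_dir / "ensembles" / "native_reference.pdb", toy, model,
            )
            stats["native_reference_fluctuation_nm"] = ensemble_fluctuation(ref)
            site = BindingSiteDefinition(tuple(
                sorted({
                    pair[0] if pair[0][0] == toy.receptor_chain else pair[1]
                    for pair in cmap.counts
                    if pair[0][0] != pair[1][0]
                })
            ))
            sasas = [
                hydrophobic_sasa(_cg_frame_structure(toy, model, ref.coords[c]), site)
                for c in range(0, ref.n_conformations, 10)
            ]
            stats["hydrophobic_sasa_nm2"] = {
                "mean": float(np.mean(sasas)), "sd": float(np.std(sasas, ddof=1)),
            }
            tio.write_json(stats, run_dir / "stats.json")
            summary["fluctuation_nm"] = stats["fluctuation_nm"]
            summary["hydrophobic_sasa_nm2"] = stats["hydrophobic_sasa_nm2"]

        if stage("correlate"):
            logger.info("stage correlate")
            names = sorted(spec.phi_means)
            fluct = [summary["fluctuation_nm"][n] for n in names]
            log_kon = [float(np.log10(spec.rates[n][0])) for n in names]
            alphas = [summary["alpha"][n]["alpha"] for n in names]
            reports = {
                "fluctuation_vs_log_kon": correlate(
                    fluct, log_kon, "fluctuation_nm", "log10_kon"),
                "fluctuation_vs_alpha": correlate(
                    fluct, alphas, "fluctuation_nm", "alpha"),
            }
            corr = {
                key: {"r": rep.r, "slope": rep.slope,
                      "intercept": rep.intercept, "n": rep.n}
                for key, rep in reports.items()
            }
            tio.write_json(corr, run_dir / "correlations.json")
            summary["correlations"] = corr
    except Exception as exc:  # noqa: BLE001 - abort with the failing stage
        logger.error("stage %s failed; partial outputs kept in %s",
                     current_stage, run_dir)
        raise StageError(current_stage, exc) from exc

    summary["elapsed_s"] = round(time.time() - t0, 2)
    tio.write_json({k: v for k, v in summary.items() if k != "elapsed_s"},
                   run_dir / "summary.json")
    _write_report(summary, run_dir / "report.txt")
    logger.info("pipeline complete in %.1f s", summary["elapsed_s"])
    return run_dir


def _cg_frame_structure(reference, model, frame_coords):
    """Map CG site coordinates of one frame back onto the reference
    structure's atoms (CA follows the CA site, side-chain atoms follow
    their centroid site) for approximate per-frame SASA."""
    s = reference.copy()
    side = s.sidechain_mask()
    for r, (chain, resi) in enumerate(model.residues):
        res_mask = s.atom_mask(chain, resi)
        ca_site = None
        for i in np.flatnonzero(model.site_residue == r):
            if model.site_kind[i] == 0:
                ca_site = i
        sc_site = model.contact_site[r]
        shift_ca = frame_coords[ca_site] - model.x0[ca_site]
        shift_sc = frame_coords[sc_site] - model.x0[sc_site]
        sc_mask = res_mask & side & (s.atom_name != "CA")
        bb_mask = res_mask & ~sc_mask
        s.coords[bb_mask] += shift_ca
        s.coords[sc_mask] += shift_sc
    return s


def _write_report(summary: dict, path) -> None:
    lines = [
        f"templefold pipeline report — scenario {summary['scenario']}, "
        f"seed {summary['master_seed']}",
        "",
    ]
    if "rates" in summary:
        lines.append("Fitted rate constants (uM^-1 s^-1, s^-1):")
        for v, r in summary["rates"].items():
            lines.append(f"  {v:12s} k_on {r['k_on']:7.3f}  k_off {r['k_off']:7.2f}")
        lines.append("")
    if "alpha" in summary:
        lines.append("LFER alpha per scenario:")
        for n, a in summary["alpha"].items():
            lines.append(
                f"  {n:6s} alpha {a['alpha']:.3f} +/- {a['alpha_sd']:.3f} "
                f"(intercept {a['intercept']:.3f} kcal/mol)"
            )
        lines.append("")
    if "fluctuation_nm" in summary:
        lines.append("Ensemble fluctuation about the mean structure (nm):")
        for n, f in summary["fluctuation_nm"].items():
            lines.append(f"  {n:6s} {f:.3f}")
        lines.append("")
    if "correlations" in summary:
        for key, c in summary["correlations"].items():
            lines.append(f"Correlation {key}: r = {c['r']:+.3f} (n = {c['n']})")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
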