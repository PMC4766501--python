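"""Ensemble statistics: fluctuation about the mean structure, contact
frequency maps and cross-correlations.

The alignment frame is the receptor's CA sites (the folded template);
the fluctuation statistic defaults to the ligand CA sites, since the
conclusions concern the disordered chain folding on the template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ts_sampler import TSEnsemble
from .ts_sampler import _kernel


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation and least-squares line for one variable pair."""

    x_label: str
    y_label: str
    r: float
    slope: float
    intercept: float
    n: int
    p_value: float


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation/translation superposing mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, mc, tc


def _selection_indices(e: TSEnsemble, selection: str) -> np.ndarray:
    m = e.model
    if selection == "ligand_ca":
        idx = np.flatnonzero((m.site_chain == 1) & (m.site_kind == 0))
    elif selection == "receptor_ca":
        idx = np.flatnonzero((m.site_chain == 0) & (m.site_kind == 0))
    elif selection == "all":
        idx = np.arange(m.n_sites)
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} is empty")
    return idx


def superpose_ensemble(e: TSEnsemble, max_iter: int = 10, tol: float = 1e-8) -> np.ndarray:
    """Iteratively superpose all members onto the evolving mean structure.

    Alignment uses the receptor CA sites; returns aligned coordinates of
    shape (n_conformations, n_sites, 3).
    """
    align = _selection_indices(e, "receptor_ca")
    coords = e.coords.copy()
    mean = coords[0].copy()
    for _ in range(max_iter):
        for c in range(len(coords)):
            rot, mc, tc = _kabsch(coords[c][align], mean[align])
            coords[c] = (coords[c] - mc) @ rot.T + tc
        new_mean = coords.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    return coords


def ensemble_fluctuation(e: TSEnsemble, selection: str = "ligand_ca") -> float:
    """Average deviation from the mean structure (nm).

    Members are superposed on the receptor CA sites; the statistic is the
    mean over members of the RMS deviation of the selected sites from the
    coordinate-average structure.
    """
    if e.n_conformations < 2:
        raise ValueError("fluctuation needs >= 2 conformations")
    sel = _selection_indices(e, selection)
    aligned = superpose_ensemble(e)
    mean = aligned.mean(axis=0)
    dev = aligned[:, sel, :] - mean[sel]
    rms_per_member = np.sqrt((dev**2).sum(axis=2).mean(axis=1))
    return float(rms_per_member.mean())


def mean_structure(e: TSEnsemble) -> np.ndarray:
    """Coordinate average after iterative superposition (n_sites, 3)."""
    return superpose_ensemble(e).mean(axis=0)


def contact_frequency_map(
    e: TSEnsemble,
    nonnative_cutoff: float = 0.65,
    nonnative_threshold: float = 0.10,
) -> dict:
    """Per-residue-pair formation frequency over the ensemble.

    Native pairs use the model's per-pair formed criterion (1.2x native
    centroid distance); non-native pairs (no native contact) use a fixed
    centroid cutoff and are reported when formed in at least
    ``nonnative_threshold`` of the members.
    Returns ``{"native": {pair: freq}, "nonnative": {pair: freq}}`` with
    pairs keyed by ((chain, res), (chain, res)).
    """
    if e.n_conformations == 0:
        raise ValueError("empty ensemble")
    m = e.model
    native_freq = np.zeros(len(m.pair_i))
    for c in range(e.n_conformations):
        native_freq += _kernel.contact_flags(
            e.coords[c], m.pair_i, m.pair_j, m.pair_cut
        )
    native_freq /= e.n_conformations
    native = {}
    native_keys = set()
    for p in range(len(m.pair_i)):
        key = (m.residues[m.pair_res_a[p]], m.residues[m.pair_res_b[p]])
        native[key] = float(native_freq[p])
        native_keys.add(key)

    # non-native pairs: centroid sites of residue pairs absent from the map
    cs = m.contact_site
    n_res = m.n_residues
    counts = np.zeros((n_res, n_res))
    for c in range(e.n_conformations):
        xyz = e.coords[c][cs]
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        counts += d < nonnative_cutoff
    counts /= e.n_conformations
    nonnative = {}
    for a in range(n_res):
        for b in range(a + 1, n_res):
            ra, rb = m.residues[a], m.residues[b]
            if ra[0] == rb[0] and abs(ra[1] - rb[1]) <= 1:
                continue
            if (ra, rb) in native_keys:
                continue
            if counts[a, b] >= nonnative_threshold:
                nonnative[(ra, rb)] = float(counts[a, b])
    return {"native": native, "nonnative": nonnative}


def correlate(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationReport:
    """Pearson r and least-squares line between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs equal-length series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance series")
    lr = stats.linregress(x, y)
    return CorrelationReport(
        x_label=x_label, y_label=y_label,
        r=float(lr.rvalue), slope=float(lr.slope),
        intercept=float(lr.intercept), n=len(x), p_value=float(lr.pvalue),
    )
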