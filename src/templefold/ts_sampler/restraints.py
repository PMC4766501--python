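"""Restraint sets and annealing schedules."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL = 1.98720425e-3

#: Default restraint force constant, kcal/mol per squared Phi unit.  A
#: "soft" choice (mismatch 0.5 on one residue ~ 5 k_B T at 283 K, ~11
#: kcal/mol) leaves the Go term biasing ensemble-mean Phi_sim by up to
#: ~0.3; pilot runs on the toy complex showed ~100 kcal/mol is needed to
#: hold attainable targets within 0.10.
DEFAULT_K_PHI = 100.0


class NonClassicalPhiWarning(UserWarning):
    """Phi outside [0, 1] accepted and restrained as-is."""


@dataclass
class PhiRestraintSet:
    """Experimental Phi values keyed by (chain, residue index).

    ``entries`` maps (chain, residue) -> Phi_exp; ``sds`` optionally carries
    per-residue uncertainties.  Values outside [0, 1] are possible
    experimentally and are accepted as-is (flagged with a warning); every
    restrained residue must have at least one native contact in the
    reference map.
    """

    entries: dict[tuple[str, int], float]
    sds: dict[tuple[str, int], float] = field(default_factory=dict)
    k_phi: float = DEFAULT_K_PHI

    def __post_init__(self) -> None:
        for res, phi in self.entries.items():
            if not np.isfinite(phi):
                raise ValueError(f"non-finite Phi for {res}")
            if phi < 0 or phi > 1.2:
                warnings.warn(
                    f"non-classical Phi = {phi:.3g} at {res}; restrained as-is",
                    NonClassicalPhiWarning,
                    stacklevel=2,
                )

    def validate(self, contact_map) -> None:
        missing = [r for r in self.entries if contact_map.residue_count(r) == 0]
        if missing:
            raise ValueError(f"restrained residues without native contacts: {missing}")

    def subset(self, residues) -> "PhiRestraintSet":
        residues = set(residues)
        if not residues:
            raise ValueError("empty restraint subset")
        unknown = residues - set(self.entries)
        if unknown:
            raise ValueError(f"subset residues not restrained: {sorted(unknown)}")
        return PhiRestraintSet(
            {r: v for r, v in self.entries.items() if r in residues},
            {r: v for r, v in self.sds.items() if r in residues},
            self.k_phi,
        )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AnnealingSchedule:
    """Simulated-annealing schedule: ``n_cycles`` cycles, each ramping the
    temperature linearly from ``t_high`` down to ``t_low`` over
    ``sweeps_per_cycle`` Monte Carlo sweeps.

    The published protocol used 300 cycles of 150 ps between 383 K and
    283 K; one 150 ps segment maps here to ``sweeps_per_cycle`` sweeps
    (default 2000).
    """

    n_cycles: int = 300
    sweeps_per_cycle: int = 2000
    t_high: float = 383.0
    t_low: float = 283.0
    ramp: str = "linear"

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles >= 1 required")
        if not (self.t_high > self.t_low > 0):
            raise ValueError("require T_high > T_low > 0")
        if self.ramp != "linear":
            raise ValueError("only linear ramps are supported")

    def cycle_temperatures(self) -> np.ndarray:
        """Per-sweep temperatures within one cycle (T_high -> T_low)."""
        return np.linspace(self.t_high, self.t_low, self.sweeps_per_cycle)
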