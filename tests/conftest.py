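import numpy as np
import pytest

from templefold.structure import native_contacts
from templefold.synthetic_data import gen_toy_complex
from templefold.ts_sampler import AnnealingSchedule, build_cg_model


@pytest.fixture(scope="session")
def toy():
    return gen_toy_complex(30, 10, seed=0)


@pytest.fixture(scope="session")
def cmap(toy):
    return native_contacts(toy)


@pytest.fixture(scope="session")
def model(toy, cmap):
    return build_cg_model(toy, cmap)


@pytest.fixture(scope="session")
def short_schedule():
    return AnnealingSchedule(n_cycles=8, sweeps_per_cycle=400)


def brute_force_contacts(s, cutoff=0.65):
    """O(N^2) all-pairs oracle for the native contact definition, written
    independently of templefold.structure.native_contacts."""
    from templefold.structure import BACKBONE_ATOMS

    counts = {}
    n = s.n_atoms
    for i in range(n):
        name_i = str(s.atom_name[i])
        if str(s.element[i]) == "H":
            continue
        side_i = name_i not in BACKBONE_ATOMS or (
            str(s.res_name[i]) == "GLY" and name_i == "CA"
        )
        if not side_i:
            continue
        for j in range(i + 1, n):
            name_j = str(s.atom_name[j])
            if str(s.element[j]) == "H":
                continue
            side_j = name_j not in BACKBONE_ATOMS or (
                str(s.res_name[j]) == "GLY" and name_j == "CA"
            )
            if not side_j:
                continue
            ra = (str(s.chain_id[i]), int(s.res_index[i]))
            rb = (str(s.chain_id[j]), int(s.res_index[j]))
            if ra == rb:
                continue
            if ra[0] == rb[0] and abs(ra[1] - rb[1]) <= 1:
                continue
            d = np.sqrt(((s.coords[i] - s.coords[j]) ** 2).sum())
            if d < cutoff:
                key = (ra, rb) if ra <= rb else (rb, ra)
                counts[key] = counts.get(key, 0) + 1
    return counts
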