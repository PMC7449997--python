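import numpy as np
import pytest

import pharmvote as pv
from pharmvote.pipeline import RunConfig, build_pharmacophores_for_frame


@pytest.fixture(scope="session")
def tiny_scenario() -> pv.SyntheticScenario:
    """Small, fast scenario for unit-level checks (coarser grid, few frames)."""
    return pv.SyntheticScenario(
        seed=11, n_frames=4, n_actives=6, n_decoys=24, box_side=10.0, spacing=0.5
    )


def pharm_sets_for(sc: pv.SyntheticScenario) -> list[pv.PharmacophoreSet]:
    """Build each frame's pharmacophore set straight from the generator."""
    space = sc.active_spaces()[0]
    cfg = RunConfig(
        frames_dir="", library="", labels="", output_dir="",
        active_spaces=[{"center": [float(v) for v in space.center]}],
    )
    sets = []
    for fr in pv.generate_receptor_ensemble(sc):
        maps = pv.generate_grid_maps(sc, fr.frame_index)
        ps, _ = build_pharmacophores_for_frame(fr, {"space_0": maps}, [space], cfg)
        sets.append(ps)
    return sets


@pytest.fixture(scope="session")
def tiny_pharm_sets(tiny_scenario):
    return pharm_sets_for(tiny_scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_grid_map(rng, n=10, spacing=0.5, center=(0.0, 0.0, 0.0), atom_type="hydrophobic"):
    e = rng.normal(0.0, 1.0, (n + 1, n + 1, n + 1))
    return pv.GridMap(
        atom_type=atom_type,
        center=np.asarray(center, float),
        spacing=spacing,
        n_intervals=(n, n, n),
        energies=e,
    )
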