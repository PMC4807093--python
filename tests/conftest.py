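import numpy as np
import pytest

from mdcna.ensemble_io import CoordinateEnsemble, select
from mdcna import synthetic as syn


def full_selection(ensemble, atom_name="CA"):
    """Select every residue of a single-chain ensemble."""
    numbers = sorted(
        ensemble.atom_table.loc[
            ensemble.atom_table["atom_name"] == atom_name, "residue_number"
        ].unique()
    )
    return select(ensemble, list(numbers), atom_name)


def displacement_ensemble(base_coords, displacements):
    """Ensemble = base + per-frame displacement array, with a generic table."""
    base = np.asarray(base_coords, dtype=float)
    disp = np.asarray(displacements, dtype=float)
    model = syn._chain_model(base)
    return CoordinateEnsemble(base[None, :, :] + disp, model.atom_table)


@pytest.fixture(scope="session")
def two_block_run():
    """One sampled two-block ensemble shared across read-only tests."""
    design = syn.two_block_design()
    ensemble, truth = syn.sample_block_ensemble(design, seed=1)
    return design, ensemble, truth


@pytest.fixture(scope="session")
def hinge_run():
    design = syn.hinge_design()
    ensemble, truth = syn.sample_hinge_ensemble(design, seed=2)
    return design, ensemble, truth
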