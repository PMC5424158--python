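import numpy as np
import pandas as pd
import pytest

from sctumor import cnv, simulate
from sctumor.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def default_experiment():
    """The default synthetic tumour mix (300 carcinoma / 150 immune / 30 stromal)."""
    return simulate.simulate_experiment(simulate.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_profiles(default_experiment):
    """Inferred CNV profiles for the default mix."""
    exp = default_experiment
    ref = cnv.build_reference(exp.normal)
    z = cnv.zscore(exp.matrix, ref)
    return cnv.smooth_chromosomal(z, exp.annotation)


@pytest.fixture(scope="session")
def small_experiment():
    """A quick small synthetic study for property tests."""
    cfg = simulate.SimulationConfig(
        n_genes=900, n_chromosomes=3,
        cells_per_population={"carcinoma": 60, "T": 20, "B": 10, "macrophage": 10, "stromal": 10},
        seed=11,
    )
    return simulate.simulate_experiment(cfg, n_clones=2, segments_per_clone=2, n_normals=10)


def make_matrix(tpm: np.ndarray, genes=None, cells=None, groups=None, **kw) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a raw array with auto ids."""
    tpm = np.asarray(tpm, dtype=float)
    genes = genes or [f"g{i}" for i in range(tpm.shape[0])]
    cells = cells or [f"c{j}" for j in range(tpm.shape[1])]
    df = pd.DataFrame(tpm, index=genes, columns=cells)
    grp = pd.Series(groups if groups is not None else "grp", index=cells)
    return ExpressionMatrix(tpm=df, groups=grp, **kw)


@pytest.fixture
def matrix_factory():
    return make_matrix
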