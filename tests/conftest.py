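import numpy as np
import pandas as pd
import pytest

from splitroot import ExpressionMatrix, SimulationConfig, generate_splitroot_experiment
from splitroot.matrix import make_sample_table


def make_matrix(values: np.ndarray, organ="shoot", conditions=None, n_rep=None,
                times=None, scale="linear") -> ExpressionMatrix:
    """Assemble a small ExpressionMatrix with a regular sample layout."""
    from splitroot.matrix import ROOT_CONDITIONS, SHOOT_CONDITIONS

    conditions = conditions or (
        SHOOT_CONDITIONS if organ == "shoot" else ROOT_CONDITIONS
    )
    n_samples = values.shape[1]
    times = times if times is not None else [0.0]
    n_rep = n_rep or n_samples // (len(conditions) * len(times))
    records = []
    for cond in conditions:
        for t in times:
            for rep in range(1, n_rep + 1):
                pool = (
                    f"split_t{t:g}_r{rep}"
                    if cond in ("Split", "Sp.NO3", "Sp.Cl")
                    else f"{cond}_t{t:g}_r{rep}"
                )
                records.append(
                    dict(
                        sample_id=f"{organ}_{cond}_t{t:g}_r{rep}",
                        organ=organ, condition=cond, time_h=float(t),
                        replicate=rep, plant_pool_id=pool,
                        genotype="Col-0", species="arabidopsis",
                    )
                )
    samples = make_sample_table(records)
    assert len(samples) == n_samples, "layout does not match value columns"
    genes = [f"G{i:05d}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=genes, columns=samples.index)
    return ExpressionMatrix(values=df, samples=samples, scale=scale)


@pytest.fixture(scope="session")
def small_experiment():
    """A compact seeded split-root experiment with planted pairs."""
    cfg = SimulationConfig(n_genes=200, n_planted_pairs=12, seed=7)
    shoot, root, truth = generate_splitroot_experiment(cfg)
    return cfg, shoot, root, truth
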