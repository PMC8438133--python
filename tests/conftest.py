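import numpy as np
import pandas as pd
import pytest

from modnet_germ import synthetic
from modnet_germ.io_formats import CountMatrix, SampleMeta


@pytest.fixture(scope="session")
def mini_design():
    return synthetic.generate_design("mini")


@pytest.fixture(scope="session")
def mini_truth(mini_design):
    return synthetic.plant_truth(
        mini_design,
        n_genes=150,
        n_tfs=10,
        n_modules=4,
        n_edges=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def mini_counts(mini_design, mini_truth):
    cm, _ = synthetic.simulate_counts(mini_design, mini_truth, seed=12)
    return cm


@pytest.fixture(scope="session")
def standard_instance():
    """One simulated dataset under the standard benchmark preset."""
    import modnet_germ.benchmark as bench

    return bench.standard_instance(7)


def toy_matrix(counts, lines=("L1", "L2"), stages=(1,), replicates=1):
    """CountMatrix from a plain array: columns grouped line-major."""
    counts = np.asarray(counts, dtype=np.int64)
    samples = []
    for line in lines:
        for stage in stages:
            for rep in range(1, replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{line}_s{stage}_r{rep}",
                        line=line,
                        subset="Mips",
                        genotype_flags=(line.endswith("lpa"), False, False),
                        phytic_class="lpa" if line.endswith("lpa") else "normal",
                        stage=stage,
                        replicate=rep,
                    )
                )
    genes = [f"g{i}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=genes, columns=[s.sample_id for s in samples])
    return CountMatrix(counts=df, samples=tuple(samples))
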