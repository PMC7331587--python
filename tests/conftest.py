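import numpy as np
import pytest

import coexscreen as cs


@pytest.fixture(scope="session")
def default_run():
    """Default synthetic study (seed 42) with the full pipeline executed."""
    m, design, truth = cs.default_dataset(seed=42)
    result = cs.run_pipeline(cs.PipelineConfig(), m, design)
    return m, design, truth, result


@pytest.fixture()
def tiny_counts():
    """4 samples x 3 proteins toy count matrix."""
    values = np.array(
        [
            [3.0, 0.0, 2.0, 5.0],
            [1.0, 5.0, 0.0, 0.0],
            [2.0, 2.0, 2.0, 2.0],
        ]
    )
    return cs.AbundanceMatrix(["P1", "P2", "P3"], ["S1", "S2", "S3", "S4"], values)


@pytest.fixture()
def three_group_design():
    """10 samples in groups EX19DEL(3) / L858R(4) / NONE(3)."""
    sids = [f"S{i}" for i in range(10)]
    status = ["EX19DEL"] * 3 + ["L858R"] * 4 + ["NONE"] * 3
    return cs.TraitDesign(sids, status)
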