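import numpy as np
import pandas as pd
import pytest

import prsmed as pm
from prsmed.genotypes import GenotypeMatrix
from prsmed.scoring import ScoringFile, REQUIRED_COLUMNS


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-sized simulated cohort shared by read-only tests."""
    params = pm.SimulationParams(n_samples=800, n_variants=200, n_modules=6, seed=42)
    genotypes, scoring, cohort, truth = pm.simulate_cohort(params)
    return {"params": params, "genotypes": genotypes, "scoring": scoring,
            "cohort": cohort, "truth": truth}


@pytest.fixture
def toy_genotypes():
    """Four hand-built variants; sample dosages chosen for hand arithmetic."""
    variants = pd.DataFrame({
        "chrom": ["1", "1", "1", "2"],
        "pos": [100, 200, 300, 400],
        "ref": ["A", "C", "G", "T"],
        "alt": ["G", "T", "A", "C"],
        "af": [0.5, 0.25, 0.1, 0.4],
    })
    dosages = np.array([
        [0.0, 1.0, 2.0, 0.0],
        [1.0, 2.0, 0.0, 1.0],
        [2.0, 0.0, 1.0, 2.0],
    ])
    return GenotypeMatrix(sample_ids=["s1", "s2", "s3"],
                          variants=variants, dosages=dosages)


def make_scoring(rows, score_id="TOY"):
    df = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    return ScoringFile(score_id=score_id, variants=df)


@pytest.fixture
def toy_scoring():
    return make_scoring([
        ("1", 100, "G", "A", 0.5),   # matched, effect = alt
        ("1", 200, "C", "T", -0.1),  # matched, effect = ref (flip)
        ("2", 400, "C", "T", 0.4),   # matched
    ])
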