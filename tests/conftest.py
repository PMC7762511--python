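import numpy as np
import pandas as pd
import pytest

from mathsurv import SyntheticConfig, simulate_maf

TOY_MAF = """\
#version 2.4
Hugo_Symbol\tChromosome\tStart_Position\tVariant_Classification\tTumor_Sample_Barcode\tt_ref_count\tt_alt_count
TP53\t17\t7579472\tMissense_Mutation\tS1\t70\t30
KRAS\t12\t25398284\tMissense_Mutation\tS1\t90\t10
EGFR\t7\t55259515\tSilent\tS1\t50\t50
TP53\t17\t7578406\tNonsense_Mutation\tS2\t60\t40
MUC16\t19\t9057093\tMissense_Mutation\tS2\t80\t20
TTN\t2\t179431347\tSilent\tS2\t55\t45
"""


@pytest.fixture
def toy_maf_path(tmp_path):
    p = tmp_path / "toy.maf"
    p.write_text(TOY_MAF)
    return p


@pytest.fixture(scope="session")
def small_maf():
    """A 60-sample simulated MAF shared across read-only tests."""
    cfg = SyntheticConfig(seed=7, n_samples=60)
    maf, truth = simulate_maf(cfg)
    return maf, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def spawn_seeds(base: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds below 2**31."""
    ss = np.random.SeedSequence(base)
    return [int(s) for s in ss.generate_state(n) % (2**31)]
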