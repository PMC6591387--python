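import numpy as np
import pytest

from rava.types import CTRL, MSFAM, MSS, CohortDesign, Consequence, GenotypeMatrix, VariantRecord


@pytest.fixture
def tiny_records():
    """Four annotated variants spanning the consequence / rarity space."""
    return [
        VariantRecord("1", 100, "A", "G", gene="GENEA", consequence=Consequence.missense,
                      cadd_phred=25.0, ref_af=8e-6, ref_ac=2, call_rate=1.0),
        VariantRecord("1", 200, "C", "T", gene="GENEA", consequence=Consequence.frameshift,
                      cadd_phred=None, ref_af=None, ref_ac=None, call_rate=1.0),
        VariantRecord("2", 300, "G", "A", gene="GENEB", consequence=Consequence.missense,
                      cadd_phred=10.0, ref_af=0.01, ref_ac=2460, call_rate=1.0),
        VariantRecord("2", 400, "T", "C", gene="GENEB", consequence=Consequence.synonymous,
                      cadd_phred=3.0, ref_af=0.002, ref_ac=492, call_rate=1.0),
    ]


@pytest.fixture
def tiny_gm(tiny_records):
    """Six samples (4 cases, 2 controls) at the four tiny variants."""
    dosages = np.array(
        [
            [1, 0, 1, 0],
            [0, 1, 0, 1],
            [1, 0, 0, 0],
            [0, 0, 2, 0],
            [0, 0, 1, 1],
            [0, 0, 0, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(
        [f"S{i}" for i in range(6)], [r.key for r in tiny_records], dosages
    )


@pytest.fixture
def tiny_design():
    return CohortDesign(
        {"S0": MSFAM, "S1": MSFAM, "S2": MSS, "S3": MSS, "S4": CTRL, "S5": CTRL}
    )
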