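import numpy as np
import pytest

from transomic.io_formats import PromoterRecord, PromoterSet, PWMatrix, PROMOTER_LEN


@pytest.fixture
def sharp_matrix() -> PWMatrix:
    """Sharp 6-position matrix with consensus ACGTAC."""
    counts = np.ones((6, 4))
    for i, base in enumerate("ACGTAC"):
        counts[i, "ACGT".index(base)] = 10.0
    return PWMatrix(matrix_id="M_TEST", tf_symbols=("TFX",), counts=counts, cutoff=0.85)


def make_promoter(gene_id: str, label: str, seq: str | None = None, seed: int = 0) -> PromoterRecord:
    if seq is None:
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, PROMOTER_LEN)])
    return PromoterRecord(gene_id=gene_id, sequence=seq, label=label)


@pytest.fixture
def tiny_promoter_set() -> PromoterSet:
    return PromoterSet(
        records=[
            make_promoter("Y1", "yes", seed=1),
            make_promoter("Y2", "yes", seed=2),
            make_promoter("N1", "no", seed=3),
            make_promoter("N2", "no", seed=4),
        ]
    )
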