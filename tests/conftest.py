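import numpy as np
import pytest
from hypothesis import settings

from methylselect.core import DOWN, UP, LabelVector, MethylationMatrix

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def four_sample_fixture():
    """Hand fixture: one probe cleanly splitting two down from two up samples."""
    meth = MethylationMatrix(
        row_ids=["cg1"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array([[0.1, 0.2, 0.8, 0.9]]),
    )
    labels = LabelVector(
        gene_id="G1",
        sample_ids=["s1", "s2", "s3", "s4"],
        labels=np.array([DOWN, DOWN, UP, UP], dtype=object),
    )
    return meth, labels


def random_instance(seed, n_probes=5, n_samples=20):
    """Random beta matrix with balanced random labels (both classes present)."""
    rng = np.random.default_rng(seed)
    values = rng.random((n_probes, n_samples))
    sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    probe_ids = [f"cg{i}" for i in range(n_probes)]
    half = n_samples // 2
    labels = np.array([DOWN] * half + [UP] * (n_samples - half), dtype=object)
    rng.shuffle(labels)
    meth = MethylationMatrix(probe_ids, sample_ids, values)
    lv = LabelVector(gene_id="G1", sample_ids=sample_ids, labels=labels)
    return meth, lv
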