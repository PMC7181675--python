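import numpy as np
import pandas as pd
import pytest

from popgenkit.genotype_io import GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_ledger_dataset(
    n_samples: int = 20,
    n_fail: int = 3_901,
    n_unmapped: int = 832,
    n_sex: int = 15_629,
    n_auto_pass: int = 619_638,
    rng: np.random.Generator | None = None,
) -> GenotypeDataset:
    """Dataset whose QC ledger is exact by construction.

    Passing markers carry a rotated balanced genotype pattern (allele
    frequency 0.5, full call rate) so call-rate/MAF filters never fire on
    them; failing markers are monomorphic.  Optionally shuffles the rotation
    phase with *rng* (ledger counts are invariant to it).
    """
    n = n_samples
    m = n_fail + n_unmapped + n_sex + n_auto_pass
    base = np.array([0] * (n // 4) + [2] * (n // 4) + [1] * (n - 2 * (n // 4)), np.int8)
    if rng is not None:
        base = rng.permutation(base)
    cols = np.stack([np.roll(base, k) for k in range(n)], axis=1)  # n x n phases
    g = cols[:, np.arange(m) % n].astype(np.int8)
    g[:, :n_fail] = 0  # monomorphic -> fails the MAF filter

    chrom = np.full(m, "1", dtype=object)
    chrom[n_fail : n_fail + n_unmapped] = "0"
    chrom[n_fail + n_unmapped : n_fail + n_unmapped + n_sex] = "X"
    pos = np.arange(1, m + 1) * 100
    pos[n_fail : n_fail + n_unmapped] = 0
    markers = pd.DataFrame(
        {
            "marker_id": [f"r{i}" for i in range(m)],
            "chromosome": chrom,
            "position_bp": pos,
            "allele1": "A",
            "allele2": "B",
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "population": "P",
            "sex": "male",
            "birth_year": 2000,
        }
    )
    return GenotypeDataset(g, markers, samples).sort_by_map()
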