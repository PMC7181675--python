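"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["reference_roh_clusters"]


def reference_roh_clusters() -> pd.DataFrame:
    """Published consensus ROH cluster intervals on the BovineHD map.

    Used to exercise the package's interval coordinate/length convention
    (length = end_bp - start_bp, ends inclusive of terminal SNP positions)
    against independently published coordinates.  Columns: chromosome,
    start_snp, start_bp, end_bp, length_bp, n_snps, p_value, population.
    """
    with resources.files("popgenkit.data").joinpath(
        "reference_roh_clusters.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chromosome": str})
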