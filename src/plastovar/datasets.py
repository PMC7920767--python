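"""Bundled example tables.

``sediment_read_counts()`` loads the per-sample, per-genus read-count
table from a Siberian lake sediment core study system (four core depths
from ~60 to ~6,700 calibrated years before present, each sequenced both
by hybridization capture and by shotgun metagenomics, with reads
assigned to the shrub genera Alnus, Betula and Salix).  Counts are
reported post-deduplication with the with-duplicate totals alongside,
plus breadth of coverage and the published relative percentages —
useful as a worked example for the abundance arithmetic.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd


def sediment_read_counts() -> pd.DataFrame:
    with importlib.resources.files("plastovar.data").joinpath("sediment_read_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
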