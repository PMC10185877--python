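"""Small bundled reference tables.

Currently one table: the published head-and-neck squamous cell
carcinoma (HNSCC) lncRNA set from a breast-cancer case study, with the
hit membership of each set member in the original differential-expression
lncRNA list and in its RWR-expanded counterpart.  It exercises the
hit-counting arithmetic on real symbols without any download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_hnscc_case_study() -> pd.DataFrame:
    """HNSCC lncRNA set with per-member hit status in two query lists.

    Columns: ``lncRNA`` (HGNC-style symbol), ``in_original`` and
    ``in_expanded`` (0/1 membership in the original and expanded
    breast-cancer differential-expression lists).
    """
    with resources.files("tlsea.data").joinpath("hnscc_case_study.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["in_original"] = df["in_original"].astype(bool)
    df["in_expanded"] = df["in_expanded"].astype(bool)
    return df
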