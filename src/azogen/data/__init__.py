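"""Packaged reference data: a fixed set of 40 recommended photoswitch
candidates (top 20 by PageRank centrality and top 10 each by QED and SA
score), with the ranking block and generating model of each row.  One
SMILES appears under two models, as recommended twice."""

from importlib import resources

import pandas as pd

__all__ = ["table2"]


def table2() -> pd.DataFrame:
    """The 40 fixture molecules as (smiles, block, model) rows."""
    rows = []
    with resources.files(__package__).joinpath("table2_smiles.smi").open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            block, model = parts[1].split("|")
            rows.append({"smiles": parts[0], "block": block, "model": model})
    return pd.DataFrame(rows)
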