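"""Table and FASTA input/output.

All tables are tab-separated with a single header line. Abundance-like
grids travel in long format (mag_id, month, layer, value) and are pivoted
to a (month, layer) column MultiIndex in memory. FASTA is wrapped at 80
columns; reading goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def grid_to_long(grid: pd.DataFrame, value_name: str) -> pd.DataFrame:
    """(mag x (month, layer)) grid -> long table mag_id/month/layer/value."""
    long = grid.stack(["month", "layer"], future_stack=True) \
               .rename(value_name).reset_index()
    long = long.rename(columns={long.columns[0]: "mag_id"})
    return long


def long_to_grid(long: pd.DataFrame, value_name: str) -> pd.DataFrame:
    """Long table -> grid with a (month, layer) column MultiIndex.

    Month/layer column order follows first appearance in the table, so a
    round-trip preserves the original sample order.
    """
    months = list(dict.fromkeys(long["month"]))
    layers = list(dict.fromkeys(long["layer"]))
    grid = long.pivot_table(index="mag_id", columns=["month", "layer"],
                            values=value_name, fill_value=0.0, sort=False)
    grid = grid.reindex(
        columns=pd.MultiIndex.from_product([months, layers],
                                           names=["month", "layer"]),
        fill_value=0.0)
    return grid
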