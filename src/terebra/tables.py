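"""Species trait and occurrence tables (UTF-8, tab-delimited, header row).

Binary codings follow the study's conventions throughout:
planktotrophic = 0 / nonplanktotrophic = 1; venom gland present = 0 /
absent = 1; shallow = 0 / deep = 1; small = 0 / large = 1.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .tree import PhyloTree, TreeError

TRAIT_COLUMNS = ["species", "vg_state", "larval_state", "size_mm",
                 "depth_min_m", "depth_max_m"]
OCCURRENCE_COLUMNS = ["species", "station", "station_min_depth",
                      "station_max_depth"]

BINARY_STATE_COLUMNS = ("vg_state", "larval_state", "depth_state", "size_state")


def read_trait_table(source) -> pd.DataFrame:
    """Read a species-indexed trait table from a TSV path or file object.

    Requires a ``species`` column; binary state columns may hold 0, 1 or
    empty (missing).  Returns a DataFrame indexed by species.
    """
    df = pd.read_csv(source, sep="\t", dtype={"species": str})
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species rows: {dup}")
    df = df.set_index("species")
    for col in BINARY_STATE_COLUMNS:
        if col in df.columns:
            vals = df[col].dropna().unique()
            bad = [v for v in vals if v not in (0, 1, 0.0, 1.0)]
            if bad:
                raise ValueError(f"column {col} has non-binary values: {bad}")
    return df


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="species")


def read_occurrence_table(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype={"species": str, "station": str})
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    lo = df["station_min_depth"].to_numpy(float)
    hi = df["station_max_depth"].to_numpy(float)
    if np.any(lo < 0) or np.any(lo > hi):
        raise ValueError("station depth intervals must satisfy 0 <= min <= max")
    return df


def write_occurrence_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def align_to_tree(tree: PhyloTree, series: pd.Series, allow_missing: bool = False):
    """Return values of ``series`` ordered like ``tree.tip_ids``.

    Every tree tip must be present in the series (unless *allow_missing*,
    in which case NaN is filled); series entries that are not tips raise.
    """
    tips = tree.tip_labels
    extra = set(series.index) - set(tips)
    if extra:
        raise TreeError(f"species absent from the tree: {sorted(extra)}")
    if not allow_missing:
        absent = [t for t in tips if t not in series.index]
        if absent:
            raise TreeError(f"tree tips without data: {absent}")
    return series.reindex(tips).to_numpy()


def table_from_text(text: str, kind: str = "trait") -> pd.DataFrame:
    """Convenience for tests and examples: parse an inline TSV string."""
    reader = read_trait_table if kind == "trait" else read_occurrence_table
    return reader(io.StringIO(text))
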