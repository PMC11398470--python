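"""Count-matrix assembly, abundance filtering, barcode matching and
per-construct aggregation.

The barcode count matrix has one row per canonical barcode and one column
per sequencing library, i.e. per (sample, channel) pair; column metadata
(condition, replicate, channel) rides along in a MultiIndex.  Barcodes are
filtered on their arithmetic mean across *all* columns — both channels —
with the boundary kept inclusive: a mean exactly equal to the threshold is
retained, only strictly smaller means are discarded.  Matching against the
lookup table annotates each barcode with its construct and channel, and
aggregation sums molecule counts over the member barcodes of each
(construct, channel).

A conservation ledger ties the stages together: for every column,
raw sum = construct sum + unmatched sum + filtered-out sum.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .liblink import LookupTable
from .manifest import CHANNELS

COLUMN_LEVELS = ["sample_id", "condition", "replicate", "channel"]


def make_columns(manifest: pd.DataFrame) -> pd.MultiIndex:
    cols = manifest[COLUMN_LEVELS].drop_duplicates()
    if cols.duplicated(subset=["sample_id", "channel"]).any():
        raise ValueError("duplicate (sample_id, channel) column in manifest")
    return pd.MultiIndex.from_frame(cols)


def column_meta(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column metadata of a count matrix as a plain DataFrame."""
    return matrix.columns.to_frame(index=False)


def tabulate(counts: Mapping[tuple[str, str], Mapping[str, int] | pd.Series],
             manifest: pd.DataFrame) -> pd.DataFrame:
    """Assemble the barcode x library molecule-count matrix.

    ``counts`` maps (sample_id, channel) to a per-library table of
    barcode -> molecule count.  The row set is the union of barcodes across
    libraries; a barcode absent from a library gets 0.  Rows are sorted
    lexicographically so the matrix is deterministic.
    """
    columns = make_columns(manifest)
    series = {}
    for col in columns:
        key = (col[0], col[3])  # (sample_id, channel)
        if key not in counts:
            raise ValueError(f"no counts provided for library {key}")
        s = counts[key]
        if not isinstance(s, pd.Series):
            s = pd.Series(s, dtype="int64")
        series[col] = s.astype("int64")
    extra = set(counts) - {(c[0], c[3]) for c in columns}
    if extra:
        raise ValueError(f"counts provided for libraries absent from manifest: {sorted(extra)}")
    matrix = pd.DataFrame(series).fillna(0).astype("int64")
    matrix.columns = pd.MultiIndex.from_tuples(matrix.columns, names=COLUMN_LEVELS)
    matrix = matrix.sort_index()
    matrix.index.name = "barcode"
    return matrix


def filter_low_abundance(matrix: pd.DataFrame, min_mean: float = 32.0) -> pd.DataFrame:
    """Keep rows whose mean count across all columns is >= ``min_mean``.

    The boundary is inclusive: discarding applies to means strictly below
    the threshold.
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    return matrix.loc[matrix.mean(axis=1) >= min_mean]


def match_to_constructs(matrix: pd.DataFrame, lookup: LookupTable,
                        ntc_prefix: str = "NTC"):
    """Annotate barcode rows with (construct_id, channel) from the lookup.

    Returns (matched matrix, annotations, unmatched report).  Annotations
    carry ``negative_control`` (construct id starts with ``ntc_prefix``)
    and ``channel_conflict`` (the lookup channel disagrees with the library
    channel of every nonzero column — likely index bleed-through or a
    lookup error; such rows are kept but flagged).
    """
    index = lookup.index
    hits = [bc in index for bc in matrix.index]
    matched = matrix.loc[hits]
    unmatched = matrix.loc[[not h for h in hits]]
    unmatched_report = pd.DataFrame({
        "barcode": unmatched.index,
        "total_count": unmatched.sum(axis=1).to_numpy(),
    })

    construct_ids = [index[bc][0] for bc in matched.index]
    channels = [index[bc][1] for bc in matched.index]
    col_channels = matched.columns.get_level_values("channel").to_numpy()
    values = matched.to_numpy()
    conflict = []
    for k, ch in enumerate(channels):
        nonzero = values[k] > 0
        conflict.append(bool(nonzero.any()) and not (col_channels[nonzero] == ch).any())
    annotations = pd.DataFrame({
        "construct_id": construct_ids,
        "channel": channels,
        "negative_control": [c.startswith(ntc_prefix) for c in construct_ids],
        "channel_conflict": conflict,
    }, index=matched.index)
    return matched, annotations, unmatched_report


def aggregate_by_construct(matrix: pd.DataFrame, annotations: pd.DataFrame):
    """Sum counts over member barcodes of each (construct, channel).

    Returns (construct matrix, row info).  The construct matrix keeps all
    library columns; row info records ``barcode_n`` (contributing barcodes)
    and ``single_channel`` (construct observed in only one channel).
    """
    if not matrix.index.equals(annotations.index):
        raise ValueError("annotations must align with the matrix rows")
    keys = pd.MultiIndex.from_frame(
        annotations[["construct_id", "channel"]], names=["construct_id", "channel"])
    grouped = matrix.groupby(keys).sum()
    grouped.index = pd.MultiIndex.from_tuples(grouped.index,
                                              names=["construct_id", "channel"])
    grouped = grouped.sort_index()
    barcode_n = matrix.groupby(keys).size()
    barcode_n.index = grouped.index
    n_channels = grouped.groupby(level="construct_id").size()
    info = pd.DataFrame({
        "barcode_n": barcode_n,
        "negative_control": annotations.groupby(keys)["negative_control"].first().to_numpy(),
        "single_channel": [n_channels[c] < len(CHANNELS)
                           for c in grouped.index.get_level_values("construct_id")],
    }, index=grouped.index)
    return grouped, info


def paired_matrix(construct_matrix: pd.DataFrame) -> pd.DataFrame:
    """Fold a (construct, channel)-rowed matrix into construct rows.

    Entry (construct, column) takes the count of the construct's barcodes
    in the column's own channel, giving one row per construct across both
    channels — the shape needed for channel-ratio testing.  Constructs
    missing a channel get zeros there.
    """
    col_channels = construct_matrix.columns.get_level_values("channel")
    constructs = construct_matrix.index.get_level_values("construct_id").unique()
    out = pd.DataFrame(0, index=constructs, columns=construct_matrix.columns,
                       dtype="int64")
    for ch in CHANNELS:
        try:
            sub = construct_matrix.xs(ch, level="channel")
        except KeyError:
            continue
        cols = construct_matrix.columns[col_channels == ch]
        out.loc[sub.index, cols] = sub[cols].to_numpy()
    out.index.name = "construct_id"
    return out


def pair_counts(matrix: pd.DataFrame, lookup: LookupTable) -> pd.DataFrame:
    """Barcode-pair-level matrix: one row per plasmid barcode pair.

    Entry (pair, column) is the count of the pair's red barcode in red
    columns and of its ir barcode in ir columns.  Pairs whose barcodes were
    both filtered out are dropped.  Row labels are "bc_red|bc_ir".
    """
    col_channels = matrix.columns.get_level_values("channel").to_numpy()
    entries = lookup.entries
    red = matrix.reindex(entries["bc_red"]).fillna(0).to_numpy(dtype="int64")
    ir = matrix.reindex(entries["bc_ir"]).fillna(0).to_numpy(dtype="int64")
    present = (entries["bc_red"].isin(matrix.index)
               | entries["bc_ir"].isin(matrix.index)).to_numpy()
    values = np.where(col_channels[None, :] == "red", red, ir)[present]
    labels = (entries["bc_red"] + "|" + entries["bc_ir"]).to_numpy()[present]
    out = pd.DataFrame(values, index=labels, columns=matrix.columns)
    out.index.name = "barcode_pair"
    return out.sort_index()


def conservation_ledger(raw: pd.DataFrame, filtered: pd.DataFrame,
                        unmatched_report: pd.DataFrame,
                        construct_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column accounting: raw = construct + unmatched + filtered-out."""
    filtered_out = raw.loc[~raw.index.isin(filtered.index)]
    unmatched = filtered.loc[filtered.index.isin(unmatched_report["barcode"])]
    ledger = pd.DataFrame({
        "raw_sum": raw.sum(axis=0),
        "construct_sum": construct_matrix.sum(axis=0),
        "unmatched_sum": unmatched.sum(axis=0),
        "filtered_out_sum": filtered_out.sum(axis=0),
    })
    ledger["balanced"] = (
        ledger["raw_sum"] ==
        ledger["construct_sum"] + ledger["unmatched_sum"] + ledger["filtered_out_sum"])
    return ledger


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix with its column metadata as header rows."""
    matrix.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=list(range(len(COLUMN_LEVELS))),
                     index_col=0)
    df.columns.names = COLUMN_LEVELS
    return df.astype("int64")


def write_matrix_mtx(matrix: pd.DataFrame, prefix: str | Path) -> None:
    """MatrixMarket triplet export with row/column annotation TSVs."""
    from scipy import io as spio
    from scipy import sparse
    prefix = Path(prefix)
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(matrix.to_numpy()))
    pd.Series(matrix.index, name=matrix.index.name or "row").to_csv(
        str(prefix) + ".rows.tsv", sep="\t", index=False)
    column_meta(matrix).to_csv(str(prefix) + ".cols.tsv", sep="\t", index=False)
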