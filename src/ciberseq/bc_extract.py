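"""Extraction of (barcode, UMI) pairs from short amplicon reads.

The UMI occupies a fixed block at the 5' end of the read; the barcode is
located relative to an anchor sequence matched with a bounded number of
substitutions.  Extraction is deterministic and order-preserving, ignores
quality scores, and rejects rather than guesses: reads that are too short,
lack the anchor, or carry an ambiguous base inside the UMI or barcode are
counted in a reject log so that record conservation (reads in = tags out +
rejects) can be checked at any point.

Two code paths produce identical results: a per-record path for FASTQ
streams of arbitrary read length, and a vectorized path over equal-length
read blocks used by the simulator-driven pipeline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import _seqcodes as sc
from .io import iter_fastq
from .layouts import ShortReadLayout

REJECT_REASONS = ("too_short", "anchor_missing", "ambiguous_base")


@dataclass
class RejectLog:
    """Per-library tally of extraction outcomes."""

    total: int = 0
    accepted: int = 0
    reasons: Counter = field(default_factory=Counter)

    @property
    def rejected(self) -> int:
        return self.total - self.accepted

    def merge(self, other: "RejectLog") -> None:
        self.total += other.total
        self.accepted += other.accepted
        self.reasons.update(other.reasons)


def _extract_one(seq: str, layout: ShortReadLayout):
    """Extract (barcode, umi) from one read, or a reject reason string."""
    u, b, a = layout.umi_len, layout.barcode_len, len(layout.anchor)
    if len(seq) < u + b + a:
        return "too_short"
    seq = seq.upper()
    umi = seq[:u]
    anchor = layout.anchor
    if layout.barcode_offset_policy == "anchor_then_barcode":
        expected_off = u
    else:
        expected_off = u + b
    # fast path: anchor at its expected offset
    off = None
    window = seq[expected_off:expected_off + a]
    if len(window) == a and sum(x != y for x, y in zip(window, anchor)) <= layout.max_anchor_mismatch:
        off = expected_off
    else:
        arr = sc.seq_to_bytes(seq)
        hit = None
        windows = np.lib.stride_tricks.sliding_window_view(arr, a)
        mism = (windows != sc.seq_to_bytes(anchor)).sum(axis=1)
        best_off = int(np.argmin(mism))
        if int(mism[best_off]) <= layout.max_anchor_mismatch:
            hit = best_off
        if hit is None:
            return "anchor_missing"
        off = hit
    if layout.barcode_offset_policy == "anchor_then_barcode":
        bc_start = off + a
    else:
        bc_start = off - b
    if bc_start < u or bc_start + b > len(seq):
        return "too_short"
    barcode = seq[bc_start:bc_start + b]
    if set(umi) - set("ACGT") or set(barcode) - set("ACGT"):
        return "ambiguous_base"
    return barcode, umi


def extract_tags(reads: Iterable[tuple[str, str]] | str | Path,
                 layout: ShortReadLayout) -> tuple[pd.DataFrame, RejectLog]:
    """Extract tags from a FASTQ path or an iterable of (name, seq) records.

    Returns a DataFrame with columns (barcode, umi) in input order, plus a
    :class:`RejectLog` accounting for every input record.
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    log = RejectLog()
    barcodes: list[str] = []
    umis: list[str] = []
    for _name, seq in reads:
        log.total += 1
        result = _extract_one(seq, layout)
        if isinstance(result, str):
            log.reasons[result] += 1
        else:
            log.accepted += 1
            barcodes.append(result[0])
            umis.append(result[1])
    return pd.DataFrame({"barcode": barcodes, "umi": umis}), log


def extract_tags_block(block: np.ndarray, layout: ShortReadLayout
                       ) -> tuple[np.ndarray, np.ndarray, RejectLog]:
    """Vectorized extraction over an equal-length ASCII read block (n, L).

    Returns (barcode rows, umi rows, RejectLog); rows are ASCII arrays of
    shape (n_accepted, barcode_len) and (n_accepted, umi_len), in input
    order.  Produces exactly the same accept/reject decisions as the
    per-record path.
    """
    log = RejectLog(total=block.shape[0])
    u, b = layout.umi_len, layout.barcode_len
    anchor = sc.seq_to_bytes(layout.anchor)
    a = len(anchor)
    n, read_len = block.shape if block.size else (0, 0)
    if n == 0:
        return (np.empty((0, b), np.uint8), np.empty((0, u), np.uint8), log)
    if read_len < u + b + a:
        log.reasons["too_short"] = n
        return (np.empty((0, b), np.uint8), np.empty((0, u), np.uint8), log)

    expected_off = u if layout.barcode_offset_policy == "anchor_then_barcode" else u + b
    offsets = np.full(n, expected_off, dtype=np.int64)
    mism = (block[:, expected_off:expected_off + a] != anchor).sum(axis=1)
    need_scan = np.flatnonzero(mism > layout.max_anchor_mismatch)
    anchor_missing = np.zeros(n, dtype=bool)
    if need_scan.size:
        sub = block[need_scan]
        n_off = read_len - a + 1
        best = np.full(need_scan.size, a + 1, dtype=np.int64)
        best_off = np.zeros(need_scan.size, dtype=np.int64)
        for off in range(n_off):
            m = (sub[:, off:off + a] != anchor).sum(axis=1)
            better = m < best  # strict: keeps the leftmost best offset
            best = np.where(better, m, best)
            best_off = np.where(better, off, best_off)
        ok = best <= layout.max_anchor_mismatch
        offsets[need_scan[ok]] = best_off[ok]
        anchor_missing[need_scan[~ok]] = True

    if layout.barcode_offset_policy == "anchor_then_barcode":
        bc_start = offsets + a
    else:
        bc_start = offsets - b
    in_range = (~anchor_missing) & (bc_start >= u) & (bc_start + b <= read_len)
    too_short = (~anchor_missing) & ~in_range

    idx = np.flatnonzero(in_range)
    default_start = expected_off + a if layout.barcode_offset_policy == "anchor_then_barcode" \
        else expected_off - b
    shifted = idx[bc_start[idx] != default_start]
    if shifted.size == 0:
        # common case: every accepted read has the anchor at its expected
        # offset, so the barcode is one contiguous slice
        bc_rows = block[idx, default_start:default_start + b]
    else:
        bc_rows = block[idx, default_start:default_start + b].copy()
        where = np.searchsorted(idx, shifted)
        for k, row in zip(where, shifted):
            s = bc_start[row]
            bc_rows[k] = block[row, s:s + b]
    umi_rows = block[idx, :u]
    clean = sc.is_acgt(bc_rows).all(axis=1) & sc.is_acgt(umi_rows).all(axis=1)

    log.reasons["anchor_missing"] = int(anchor_missing.sum())
    log.reasons["too_short"] = int(too_short.sum())
    log.reasons["ambiguous_base"] = int((~clean).sum())
    log.reasons += Counter()  # drop zero entries
    log.accepted = int(clean.sum())
    return bc_rows[clean], umi_rows[clean], log


def extract_library(fastq_path: str | Path, layout: ShortReadLayout,
                    block: bool = True) -> tuple[np.ndarray, np.ndarray, RejectLog]:
    """Extract one amplicon library from disk into ASCII tag arrays.

    Uses the vectorized block path when all reads share one length, falling
    back to the per-record path otherwise.
    """
    if block:
        from .io import read_fastq_block
        try:
            reads = read_fastq_block(fastq_path)
        except ValueError:  # mixed read lengths: take the per-record path
            reads = None
        if reads is not None:
            return extract_tags_block(reads, layout)
    tags, log = extract_tags(fastq_path, layout)
    return (sc.strs_to_rows(list(tags["barcode"])),
            sc.strs_to_rows(list(tags["umi"])), log)
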