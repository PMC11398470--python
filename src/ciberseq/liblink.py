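"""Barcode-to-sgRNA lookup construction from long reads of the plasmid library.

Every library plasmid carries a dual-sgRNA cassette and two random barcodes,
one embedded in each reporter transcript.  Long reads over the linearized
plasmid see all three elements at once, so grouping reads by their barcode
pair and majority-voting the guide cassette yields the lookup table that
later links expressed-barcode counts back to guide identity.

Error handling is deliberately conservative: barcode grouping is by exact
identity, and read errors are expected to fail the support/purity
thresholds rather than be corrected.  With 25-nt random barcodes the
chance of two library barcodes landing within error distance of each
other is negligible, so dropping is safe and relinking is never attempted.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from . import _seqcodes as sc
from .io import iter_fastq
from .layouts import LongReadLayout

LOOKUP_COLUMNS = ["construct_id", "guide_key", "bc_red", "bc_ir", "support", "purity"]
DISCARD_CATEGORIES = ("low_support", "low_purity", "barcode_collision")
NOPARSE_REASONS = ("anchor_missing", "length_mismatch", "ambiguous_anchor",
                   "ambiguous_base")


@dataclass(frozen=True)
class ParsedConstructRead:
    """Barcodes and guide cassette recovered from one long read."""

    bc_red: str
    bc_ir: str
    guide_key: str
    orientation: str  # "forward" or "reverse-complement"


@dataclass(frozen=True)
class ParseFailure:
    """A long read that could not be interpreted, with the failing step."""

    reason: str

    def __post_init__(self) -> None:
        if self.reason not in NOPARSE_REASONS:
            raise ValueError(f"unknown no-parse reason {self.reason!r}")


def _best_anchor_hit(seq: np.ndarray, anchor: np.ndarray, max_mismatch: int):
    """Leftmost best Hamming match of ``anchor`` in ``seq``.

    Returns (offset, mismatches) or None when the best match exceeds the
    mismatch budget.  Ties at the best distance resolve to the leftmost
    offset, which keeps parsing deterministic.
    """
    la, ls = len(anchor), len(seq)
    if la > ls:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(seq, la)
    mism = (windows != anchor).sum(axis=1)
    off = int(np.argmin(mism))
    best = int(mism[off])
    if best > max_mismatch:
        return None
    return off, best


def _parse_oriented(seq: np.ndarray, layout: LongReadLayout):
    """Try to parse one orientation; returns (result, n_anchors_found)."""
    hits = {}
    found = 0
    for name, anchor in layout.anchors.items():
        hit = _best_anchor_hit(seq, sc.seq_to_bytes(anchor), layout.max_anchor_mismatch)
        if hit is None:
            return ParseFailure("anchor_missing"), found
        hits[name] = (hit[0], hit[0] + len(anchor))
        found += 1

    def region(up: str, down: str) -> np.ndarray | None:
        start = hits[up][1]
        stop = hits[down][0]
        if stop < start:
            return None
        return seq[start:stop]

    bc_red = region("anchor_up_red", "anchor_down_red")
    bc_ir = region("anchor_up_ir", "anchor_down_ir")
    cassette = region("anchor_guide_up", "anchor_guide_down")
    if bc_red is None or bc_ir is None or cassette is None:
        # anchors found but in a conflicting arrangement
        return ParseFailure("ambiguous_anchor"), found
    if len(bc_red) != layout.barcode_len or len(bc_ir) != layout.barcode_len:
        return ParseFailure("length_mismatch"), found
    if len(cassette) != 2 * layout.guide_len:
        return ParseFailure("length_mismatch"), found
    if not (sc.is_acgt(bc_red).all() and sc.is_acgt(bc_ir).all()
            and sc.is_acgt(cassette).all()):
        return ParseFailure("ambiguous_base"), found
    guide_a = sc.bytes_to_str(cassette[: layout.guide_len])
    guide_b = sc.bytes_to_str(cassette[layout.guide_len:])
    return (sc.bytes_to_str(bc_red), sc.bytes_to_str(bc_ir),
            guide_key(guide_a, guide_b)), found


def guide_key(protospacer_a: str, protospacer_b: str) -> str:
    """Canonical identifier of a dual-sgRNA cassette."""
    return f"{protospacer_a.upper()}|{protospacer_b.upper()}"


def parse_long_read(seq: str, layout: LongReadLayout) -> ParsedConstructRead | ParseFailure:
    """Recover (bc_red, bc_ir, guide_key) from one long read.

    Each anchor is located by a leftmost-best Hamming substring scan with at
    most ``layout.max_anchor_mismatch`` substitutions; the forward
    orientation is tried first, then the reverse complement.  Non-nucleotide
    characters other than N raise ``ValueError``; an N inside an extracted
    element yields a no-parse with reason ``ambiguous_base``.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("long read contains characters outside {A,C,G,T,N}")
    fwd = sc.seq_to_bytes(seq)
    attempts = []
    for orientation, oriented in (("forward", fwd),
                                  ("reverse-complement", sc.revcomp_bytes(fwd))):
        result, found = _parse_oriented(oriented, layout)
        if not isinstance(result, ParseFailure):
            bc_red, bc_ir, key = result
            return ParsedConstructRead(bc_red, bc_ir, key, orientation)
        attempts.append((found, result))
    # report the failure of the orientation that got furthest
    attempts.sort(key=lambda t: -t[0])
    return attempts[0][1]


def parse_fastq(path: str | Path, layout: LongReadLayout):
    """Parse every read of a FASTQ file.

    Returns (list of ParsedConstructRead, Counter of no-parse reasons).
    """
    parsed: list[ParsedConstructRead] = []
    failures: Counter[str] = Counter()
    for _name, seq in iter_fastq(path):
        result = parse_long_read(seq, layout)
        if isinstance(result, ParseFailure):
            failures[result.reason] += 1
        else:
            parsed.append(result)
    return parsed, failures


class LookupTable:
    """Barcode -> (construct, channel) mapping with support/purity metadata.

    One row per barcode pair (one physical plasmid); ``construct_id`` groups
    barcode pairs that share the same guide cassette.  Every barcode maps to
    exactly one (construct, channel) and never appears in both channels.
    """

    def __init__(self, entries: pd.DataFrame):
        entries = entries.reset_index(drop=True)
        missing = [c for c in LOOKUP_COLUMNS if c not in entries.columns]
        if missing:
            raise ValueError(f"lookup entries missing columns: {missing}")
        entries = entries[LOOKUP_COLUMNS].copy()
        entries["support"] = entries["support"].astype(int)
        entries["purity"] = entries["purity"].astype(float)
        if len(entries):
            if (entries["support"] < 1).any():
                raise ValueError("lookup support must be >= 1")
            if ((entries["purity"] < 0) | (entries["purity"] > 1)).any():
                raise ValueError("lookup purity must lie in [0, 1]")
            all_bcs = pd.concat([entries["bc_red"], entries["bc_ir"]])
            dup = all_bcs[all_bcs.duplicated()]
            if len(dup):
                raise ValueError(
                    f"barcode {dup.iloc[0]!r} appears in more than one lookup entry")
        self.entries = entries
        self._index: dict[str, tuple[str, str]] | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LookupTable):
            return NotImplemented
        a = self.entries.sort_values(["bc_red", "bc_ir"]).reset_index(drop=True)
        b = other.entries.sort_values(["bc_red", "bc_ir"]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        return bool(
            (a[["construct_id", "guide_key", "bc_red", "bc_ir"]]
             == b[["construct_id", "guide_key", "bc_red", "bc_ir"]]).all().all()
            and (a["support"] == b["support"]).all()
            and np.allclose(a["purity"], b["purity"]))

    @property
    def index(self) -> Mapping[str, tuple[str, str]]:
        """barcode -> (construct_id, channel)."""
        if self._index is None:
            idx: dict[str, tuple[str, str]] = {}
            for row in self.entries.itertuples(index=False):
                idx[row.bc_red] = (row.construct_id, "red")
                idx[row.bc_ir] = (row.construct_id, "ir")
            self._index = idx
        return self._index

    def write(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "LookupTable":
        df = pd.read_csv(path, sep="\t", dtype={"construct_id": str})
        if list(df.columns) != LOOKUP_COLUMNS:
            raise ValueError(
                f"{path}: expected columns {LOOKUP_COLUMNS}, got {list(df.columns)}")
        all_bcs = pd.concat([df["bc_red"], df["bc_ir"]]) if len(df) else pd.Series(dtype=str)
        dup_mask = all_bcs.duplicated(keep=False)
        if dup_mask.any():
            bad = all_bcs[dup_mask].iloc[0]
            line = int(all_bcs[all_bcs == bad].index[0]) + 2  # 1-based incl. header
            raise ValueError(f"{path}:{line}: barcode {bad!r} present in two rows")
        return cls(df)


def build_lookup(parsed: Iterable[ParsedConstructRead],
                 min_support: int = 3,
                 min_purity: float = 0.9,
                 construct_prefix: str = "C"):
    """Assemble the lookup table from parsed long reads.

    Reads are grouped by exact (bc_red, bc_ir) identity; each group is
    assigned its majority guide cassette with ``purity`` = majority fraction
    (ties broken toward the lexicographically smaller guide key).  Groups
    failing ``min_support`` or ``min_purity`` are discarded, and after
    assembly any barcode string occurring in more than one surviving entry
    (collision or chimera) removes every entry containing it.

    Returns (LookupTable, DiscardReport) where the report is a DataFrame
    with columns (bc_red, bc_ir, category, support, purity).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not (0.5 < min_purity <= 1.0):
        raise ValueError("min_purity must lie in (0.5, 1]")

    groups: dict[tuple[str, str], Counter[str]] = defaultdict(Counter)
    for read in parsed:
        groups[(read.bc_red, read.bc_ir)][read.guide_key] += 1

    kept: list[tuple[str, str, str, int, float]] = []
    discard_rows: list[tuple[str, str, str, int, float]] = []
    for (bc_red, bc_ir), votes in groups.items():
        support = sum(votes.values())
        top_n = max(votes.values())
        key = min(k for k, n in votes.items() if n == top_n)
        purity = top_n / support
        if support < min_support:
            discard_rows.append((bc_red, bc_ir, "low_support", support, purity))
        elif purity < min_purity:
            discard_rows.append((bc_red, bc_ir, "low_purity", support, purity))
        else:
            kept.append((key, bc_red, bc_ir, support, purity))

    # collision pass: any barcode string in more than one surviving entry
    bc_count: Counter[str] = Counter()
    for key, bc_red, bc_ir, *_ in kept:
        bc_count[bc_red] += 1
        bc_count[bc_ir] += 1
    final = []
    for key, bc_red, bc_ir, support, purity in kept:
        if bc_count[bc_red] > 1 or bc_count[bc_ir] > 1:
            discard_rows.append((bc_red, bc_ir, "barcode_collision", support, purity))
        else:
            final.append((key, bc_red, bc_ir, support, purity))

    guide_ids = {key: f"{construct_prefix}{i:05d}"
                 for i, key in enumerate(sorted({k for k, *_ in final}), start=1)}
    entries = pd.DataFrame(
        [(guide_ids[k], k, br, bi, s, p) for k, br, bi, s, p in
         sorted(final, key=lambda t: (t[1], t[2]))],
        columns=LOOKUP_COLUMNS)
    report = pd.DataFrame(
        discard_rows, columns=["bc_red", "bc_ir", "category", "support", "purity"])
    return LookupTable(entries), report


def write_lookup(table: LookupTable, path: str | Path) -> None:
    table.write(path)


def read_lookup(path: str | Path) -> LookupTable:
    return LookupTable.read(path)
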