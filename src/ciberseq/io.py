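"""FASTQ input/output helpers.

Reading goes through pysam's FASTX parser (htslib), which handles plain
and gzip-compressed files transparently.  Writing emits minimal four-line
records with a constant quality string, which is sufficient because the
pipeline ignores quality scores.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from . import _seqcodes as sc


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) for every record of a FASTQ(.gz) file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence


def read_fastq_block(path: str | Path) -> np.ndarray:
    """Load an equal-length FASTQ into an ASCII array of shape (n, L).

    Raises ValueError when read lengths differ; use :func:`iter_fastq` for
    variable-length input.
    """
    seqs = [seq for _name, seq in iter_fastq(path)]
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    return sc.strs_to_rows(seqs)


def write_fastq(path: str | Path, seqs: Iterable[str] | np.ndarray,
                name_prefix: str = "read") -> int:
    """Write sequences as a FASTQ(.gz when the suffix says so) file.

    ``seqs`` may be an iterable of strings or a 2-D ASCII array.  Returns
    the number of records written.
    """
    path = Path(path)
    if isinstance(seqs, np.ndarray):
        seqs = sc.rows_to_strs(seqs)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as out:
        chunk: list[str] = []
        for i, seq in enumerate(seqs):
            chunk.append(f"@{name_prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
            if len(chunk) >= 10000:
                out.write("".join(chunk))
                chunk = []
        out.write("".join(chunk))
    return n
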