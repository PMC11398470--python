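"""Directional collapse of sequencing-error barcodes and UMI deduplication.

Amplicon sequencing turns each true barcode into a cloud of low-count
error variants within small Hamming distance.  Both barcodes and UMIs are
cleaned with the *directional* network rule: a directed edge a -> b exists
when Hamming(a, b) <= max_dist and reads(a) >= 2*reads(b) - 1, and every
sequence is absorbed into the root of its highest-count reachable
absorber.  The count criterion stops genuinely distinct, comparably
abundant sequences from merging while sweeping up error progeny, which in
PCR-amplified data carry a small fraction of their parent's reads.

The network contract is defined over all pairs; the implementation finds
candidate neighbor pairs by exact-matching ``max_dist + 1`` sequence
segments (a pair within distance d must agree exactly on at least one of
d + 1 disjoint segments), which scales near-linearly without changing the
result.  Indels are not considered: fixed-length extraction makes
substitutions the dominant error mode.

Public entry points accept plain mappings (barcode -> UMI -> read count);
the array entry point :func:`count_molecules_arrays` is the
high-throughput path used by the pipeline.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from . import _seqcodes as sc

TagCounts = Mapping[str, Mapping[str, int]]


def _candidate_pairs(seqs: np.ndarray, codes: np.ndarray, max_dist: int,
                     groups: np.ndarray | None) -> np.ndarray:
    """All index pairs (i < j) with equal group and Hamming <= max_dist.

    Returned as an (m, 2) int64 array with no duplicates.
    """
    n, length = seqs.shape
    if n < 2:
        return np.empty((0, 2), dtype=np.int64)
    n_seg = max_dist + 1
    bounds = np.linspace(0, length, n_seg + 1).astype(int)
    pair_keys: list[np.ndarray] = []
    for s in range(n_seg):
        lo, hi = bounds[s], bounds[s + 1]
        seg_codes = sc.pack(seqs[:, lo:hi])
        if groups is None:
            sort_keys = (seg_codes,)
        else:
            sort_keys = (seg_codes, groups)
        order = np.lexsort(sort_keys)
        sk = seg_codes[order]
        same = sk[1:] == sk[:-1]
        if groups is not None:
            g = groups[order]
            same &= g[1:] == g[:-1]
        # run ids: increments where the key changes
        run_id = np.concatenate([[0], np.cumsum(~same)])
        run_len = np.bincount(run_id)
        max_run = int(run_len.max()) if run_len.size else 0
        for d in range(1, max_run):
            ok = np.flatnonzero(run_id[:-d] == run_id[d:])
            if ok.size == 0:
                continue
            i = order[ok]
            j = order[ok + d]
            dist = sc.hamming_codes(codes[i], codes[j])
            keep = dist <= max_dist
            if keep.any():
                a = np.minimum(i[keep], j[keep]).astype(np.int64)
                b = np.maximum(i[keep], j[keep]).astype(np.int64)
                pair_keys.append(a * np.int64(n) + b)
    if not pair_keys:
        return np.empty((0, 2), dtype=np.int64)
    keys = np.unique(np.concatenate(pair_keys))
    return np.stack([keys // n, keys % n], axis=1)


def directional_roots(seqs: np.ndarray, counts: np.ndarray, max_dist: int,
                      groups: np.ndarray | None = None) -> np.ndarray:
    """Root index for every sequence under the directional network rule.

    Parameters
    ----------
    seqs
        ASCII array of shape (n, L), equal-length sequences, L <= 32.
    counts
        Read count per sequence (summed over UMIs for barcodes).
    max_dist
        Maximum Hamming distance for an edge; 0 is the identity map.
    groups
        Optional integer group labels; edges never cross groups (used to
        deduplicate UMIs within each barcode in one pass).

    Canonical sequences map to themselves.  Roots are claimed in order of
    (higher count, lexicographically smaller sequence), so a sequence
    reachable from several absorbers goes to the highest-priority one.
    """
    seqs = np.asarray(seqs, dtype=np.uint8)
    counts = np.asarray(counts, dtype=np.int64)
    n = seqs.shape[0]
    if counts.shape != (n,):
        raise ValueError("counts must align with seqs")
    if (counts < 1).any():
        raise ValueError("read counts must be >= 1")
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    root = np.arange(n, dtype=np.int64)
    if n < 2 or max_dist == 0:
        return root

    codes = sc.pack(seqs)
    pairs = _candidate_pairs(seqs, codes, max_dist, groups)
    if len(pairs) == 0:
        return root

    # directed edges by the count criterion, in both directions when it holds
    i, j = pairs[:, 0], pairs[:, 1]
    ci, cj = counts[i], counts[j]
    fwd = ci >= 2 * cj - 1   # i absorbs j
    bwd = cj >= 2 * ci - 1   # j absorbs i
    src = np.concatenate([i[fwd], j[bwd]])
    dst = np.concatenate([j[fwd], i[bwd]])
    if src.size == 0:
        return root

    # CSR adjacency
    order = np.argsort(src, kind="stable")
    src_s, dst_s = src[order], dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src_s + 1, 1)
    indptr = np.cumsum(indptr)

    # claim order: higher count first, then lexicographically smaller sequence;
    # nodes with no incident edge are their own roots and need no traversal
    has_edge = np.zeros(n, dtype=bool)
    has_edge[src] = True
    has_edge[dst] = True
    touched = np.flatnonzero(has_edge)
    priority = touched[np.lexsort((codes[touched], -counts[touched]))]
    assigned = np.zeros(n, dtype=bool)
    for node in priority:
        if assigned[node]:
            continue
        assigned[node] = True
        root[node] = node
        stack = [int(node)]
        while stack:
            u = stack.pop()
            for v in dst_s[indptr[u]:indptr[u + 1]]:
                if not assigned[v]:
                    assigned[v] = True
                    root[v] = node
                    stack.append(int(v))
    return root


def _tagcounts_arrays(counts: TagCounts):
    barcodes = list(counts)
    if not barcodes:
        return [], None, None
    length = len(barcodes[0])
    if any(len(b) != length for b in barcodes):
        raise ValueError("barcodes must have equal length")
    seqs = sc.strs_to_rows(barcodes)
    totals = np.array([sum(counts[b].values()) for b in barcodes], dtype=np.int64)
    return barcodes, seqs, totals


def collapse_barcodes(counts: TagCounts, max_dist: int = 1,
                      method: str = "directional") -> dict[str, str]:
    """Map every raw barcode to its canonical barcode.

    The map is idempotent: canonical barcodes map to themselves, and every
    canonical barcode exists in the input.
    """
    if method != "directional":
        raise ValueError(f"unknown collapse method {method!r}")
    barcodes, seqs, totals = _tagcounts_arrays(counts)
    if not barcodes:
        return {}
    roots = directional_roots(seqs, totals, max_dist)
    return {barcodes[k]: barcodes[roots[k]] for k in range(len(barcodes))}


def dedup_umis(umis: Mapping[str, int], max_dist: int = 1) -> int:
    """Number of distinct molecules given UMI read counts.

    With ``max_dist=0`` this is the number of distinct UMIs; otherwise the
    directional rule merges error UMIs into their parents first.
    """
    if not umis:
        return 0
    seqs = sc.strs_to_rows(list(umis))
    counts = np.array(list(umis.values()), dtype=np.int64)
    roots = directional_roots(seqs, counts, max_dist)
    return int(np.unique(roots).size)


def count_molecules(counts: TagCounts, bc_max_dist: int = 1,
                    umi_max_dist: int = 1) -> dict[str, int]:
    """Molecule count per canonical barcode.

    Applies barcode collapse, merges the UMI tables of absorbed barcodes
    (summing read counts of identical UMIs), then deduplicates UMIs within
    each canonical barcode.
    """
    cmap = collapse_barcodes(counts, bc_max_dist)
    merged: dict[str, dict[str, int]] = {}
    for bc, umi_table in counts.items():
        dest = merged.setdefault(cmap[bc], {})
        for umi, n in umi_table.items():
            if n < 1:
                raise ValueError("read counts must be >= 1")
            dest[umi] = dest.get(umi, 0) + n
    return {bc: dedup_umis(umis, umi_max_dist) for bc, umis in merged.items()}


def count_molecules_arrays(bc_rows: np.ndarray, umi_rows: np.ndarray,
                           bc_max_dist: int = 1, umi_max_dist: int = 1):
    """Array path: one row per read; returns per-canonical-barcode counts.

    Parameters
    ----------
    bc_rows, umi_rows
        ASCII arrays of shape (n_reads, barcode_len) and (n_reads, umi_len).

    Returns
    -------
    (canonical_bc_rows, molecule_counts, read_counts)
        ASCII rows of the canonical barcodes (sorted lexicographically) with
        aligned molecule and read counts.
    """
    n_reads = bc_rows.shape[0]
    if umi_rows.shape[0] != n_reads:
        raise ValueError("barcode and UMI arrays must align")
    bc_len = bc_rows.shape[1] if n_reads else 0
    if n_reads == 0:
        return (np.empty((0, bc_len), np.uint8), np.empty(0, np.int64),
                np.empty(0, np.int64))

    bc_codes = sc.pack(bc_rows)
    umi_codes = sc.pack(umi_rows)

    # aggregate identical (barcode, umi) pairs
    order = np.lexsort((umi_codes, bc_codes))
    bcs, umis = bc_codes[order], umi_codes[order]
    new_pair = np.ones(n_reads, dtype=bool)
    new_pair[1:] = (bcs[1:] != bcs[:-1]) | (umis[1:] != umis[:-1])
    starts = np.flatnonzero(new_pair)
    pair_bc = bcs[starts]
    pair_umi = umis[starts]
    pair_reads = np.diff(np.append(starts, n_reads)).astype(np.int64)

    # unique barcodes with total read counts
    new_bc = np.ones(pair_bc.size, dtype=bool)
    new_bc[1:] = pair_bc[1:] != pair_bc[:-1]
    bc_starts = np.flatnonzero(new_bc)
    uniq_bc_codes = pair_bc[bc_starts]
    bc_group_of_pair = np.cumsum(new_bc) - 1
    bc_reads = np.bincount(bc_group_of_pair, weights=pair_reads).astype(np.int64)

    uniq_bc_rows = sc.unpack(uniq_bc_codes, bc_rows.shape[1])
    roots = directional_roots(uniq_bc_rows, bc_reads, bc_max_dist)

    # remap pairs onto canonical barcodes and re-aggregate identical UMIs
    canon_of_pair = roots[bc_group_of_pair]
    order2 = np.lexsort((pair_umi, canon_of_pair))
    cb, cu, cr = canon_of_pair[order2], pair_umi[order2], pair_reads[order2]
    new2 = np.ones(cb.size, dtype=bool)
    new2[1:] = (cb[1:] != cb[:-1]) | (cu[1:] != cu[:-1])
    starts2 = np.flatnonzero(new2)
    grp_bc = cb[starts2]
    grp_umi = cu[starts2]
    seg_id = np.cumsum(new2) - 1
    grp_reads = np.bincount(seg_id, weights=cr).astype(np.int64)

    # deduplicate UMIs within each canonical barcode in one grouped pass
    umi_seq_rows = sc.unpack(grp_umi, umi_rows.shape[1])
    umi_roots = directional_roots(umi_seq_rows, grp_reads, umi_max_dist,
                                  groups=grp_bc.astype(np.int64))

    # molecules per canonical barcode = distinct (barcode, root UMI) pairs
    mol_keys = np.stack([grp_bc.astype(np.uint64), umi_roots.astype(np.uint64)],
                        axis=1)
    uniq_mol = np.unique(mol_keys, axis=0)
    canon_idx, mol_counts = np.unique(uniq_mol[:, 0].astype(np.int64),
                                      return_counts=True)
    read_totals = np.zeros(canon_idx.size, dtype=np.int64)
    pos = np.searchsorted(canon_idx, grp_bc)
    np.add.at(read_totals, pos, grp_reads)

    # canon_idx indexes the unique-barcode arrays; sorted index order equals
    # sorted code order, so the output stays lexicographic
    canon_rows = uniq_bc_rows[canon_idx]
    return canon_rows, mol_counts.astype(np.int64), read_totals
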