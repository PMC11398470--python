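"""Synthetic dual-barcoded screen generator with known ground truth.

The generator emulates the statistics of a genome-scale dual-barcoded
CRISPRi reporter library: each construct (a dual-sgRNA cassette) carries
several barcode pairs (one 25-nt barcode per reporter channel, on average
8 pairs per construct), a subset of constructs are non-targeting controls,
construct abundances are log-normal, molecule counts per barcode and
library are negative-binomial, and chosen constructs carry planted log2
effects on the red (pathway-reporter) channel in chosen conditions.
Per-barcode-pair baseline biases (sequence-intrinsic red:ir expression
differences) are drawn once per library and applied in every condition,
mirroring the barcode-dependent effects a matched-promoter control screen
reveals.

Simulation is molecule-first: every molecule receives its UMI before PCR
duplication and sequencing errors, so the deduplicated truth is
well-defined — PCR duplicates share their molecule's UMI and acquire
read errors independently.  Truth counts are recorded pre-error.

Determinism: every output is a pure function of the config seed; per-stage
and per-library generators are spawned from it, so regenerating any one
library gives identical reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from . import _seqcodes as sc
from .io import write_fastq
from .layouts import DEFAULT_LONG_LAYOUT, DEFAULT_SHORT_LAYOUT, LongReadLayout, ShortReadLayout
from .liblink import LookupTable, guide_key
from .manifest import CHANNELS, MANIFEST_COLUMNS


@dataclass
class SimConfig:
    """Study conditions of a synthetic screen.

    Scale defaults are a desk-scale reduction of a genome-wide library
    (2,000 constructs standing in for ~21,554; 100 non-targeting controls
    for ~989) with the library's per-construct barcode multiplicity
    (mean 8 pairs) and barcode/UMI geometry (25 nt / 10 nt) kept at full
    size.  Noise defaults: log-normal construct abundance (sigma 0.5),
    NB dispersion 0.05, PCR duplication 0.5 (one extra copy per molecule
    on average), substitution error 0.5% per base.
    """

    seed: int
    n_constructs: int = 2000
    n_nontargeting: int = 100
    barcode_len: int = 25
    umi_len: int = 10
    guide_len: int = 20
    mean_barcodes_per_construct: float = 8.0
    abundance_sigma: float = 0.5
    dispersion: float = 0.05
    depth: int = 2_000_000          # expected molecules per library
    pcr_duplication_rate: float = 0.5
    substitution_error_rate: float = 0.005
    long_read_error_rate: float = 0.01
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_bias_sd: float = 0.0
    read_len: int = 72

    def __post_init__(self) -> None:
        for name in ("pcr_duplication_rate", "substitution_error_rate",
                     "long_read_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_constructs < 1 or self.n_nontargeting < 0:
            raise ValueError("construct counts must be positive")
        if self.n_nontargeting > self.n_constructs:
            raise ValueError("n_nontargeting cannot exceed n_constructs")
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if self.mean_barcodes_per_construct < 1:
            raise ValueError("mean_barcodes_per_construct must be >= 1")
        if self.read_len < DEFAULT_SHORT_LAYOUT.min_read_len:
            raise ValueError("read_len shorter than the amplicon layout")


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator."""

    library: LookupTable
    construct_abundance: pd.Series            # relative weight per construct
    pair_share: pd.Series                     # share within construct, per pair
    effects: pd.DataFrame                     # construct x condition log2 effects
    baseline_bias: pd.Series                  # per-pair log2 red:ir bias
    counts: pd.DataFrame | None = None        # barcode x library molecule truth


def _unique_random_rows(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n globally distinct random sequences (rejection sampling)."""
    if length < 32 and n > 4 ** length // 2:
        raise ValueError("barcode space too small for the requested library")
    rows = sc.random_seq_rows(rng, n, length)
    for _ in range(64):
        codes = sc.pack(rows)
        _, first = np.unique(codes, return_index=True)
        dup = np.setdiff1d(np.arange(n), first)
        if dup.size == 0:
            return rows
        rows[dup] = sc.random_seq_rows(rng, dup.size, length)
    raise RuntimeError("could not draw distinct sequences")


def simulate_library(cfg: SimConfig) -> SimTruth:
    """Draw the construct library: guides, barcode pairs, abundances, biases.

    Per-construct barcode-pair counts are 1 + Poisson(mean - 1), so the
    configured mean holds and every construct keeps at least one pair.
    Barcodes are globally distinct across both channels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    n = cfg.n_constructs
    ids = [f"NTC{i:05d}" if i <= cfg.n_nontargeting else f"C{i:05d}"
           for i in range(1, n + 1)]
    guides = _unique_random_rows(rng, 2 * n, cfg.guide_len)
    keys = [guide_key(sc.bytes_to_str(guides[2 * i]), sc.bytes_to_str(guides[2 * i + 1]))
            for i in range(n)]
    pairs_per = 1 + rng.poisson(cfg.mean_barcodes_per_construct - 1.0, size=n)
    total_pairs = int(pairs_per.sum())
    barcodes = _unique_random_rows(rng, 2 * total_pairs, cfg.barcode_len)
    bc_red = sc.rows_to_strs(barcodes[:total_pairs])
    bc_ir = sc.rows_to_strs(barcodes[total_pairs:])
    construct_of_pair = np.repeat(np.arange(n), pairs_per)
    entries = pd.DataFrame({
        "construct_id": [ids[c] for c in construct_of_pair],
        "guide_key": [keys[c] for c in construct_of_pair],
        "bc_red": bc_red,
        "bc_ir": bc_ir,
        "support": 1,
        "purity": 1.0,
    })
    entries = entries.sort_values(["bc_red", "bc_ir"]).reset_index(drop=True)
    library = LookupTable(entries)

    abundance = pd.Series(
        rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n), index=ids)
    abundance /= abundance.sum()
    share = np.concatenate([
        rng.dirichlet(np.ones(k)) for k in pairs_per])
    pair_ids = entries["bc_red"] + "|" + entries["bc_ir"]
    # entries were re-sorted; rebuild share aligned to the sorted order
    share_series = pd.Series(share, index=(pd.Series(bc_red) + "|" + pd.Series(bc_ir)).to_numpy())
    share_series = share_series.loc[pair_ids.to_numpy()]
    share_series.index = pair_ids.to_numpy()

    bias = pd.Series(
        rng.normal(0.0, cfg.baseline_bias_sd, size=total_pairs) if cfg.baseline_bias_sd > 0
        else np.zeros(total_pairs), index=pair_ids.to_numpy())

    effects = pd.DataFrame(0.0, index=ids, columns=sorted(
        {cond for eff in cfg.effects.values() for cond in eff}))
    for cid, eff in cfg.effects.items():
        if cid not in effects.index:
            raise ValueError(f"planted effect for unknown construct {cid!r}")
        for cond, lfc in eff.items():
            effects.loc[cid, cond] = float(lfc)

    return SimTruth(library=library, construct_abundance=abundance,
                    pair_share=share_series, effects=effects, baseline_bias=bias)


def simulate_long_reads(truth: SimTruth, cfg: SimConfig, reads_per_pair: int = 5,
                        layout: LongReadLayout = DEFAULT_LONG_LAYOUT,
                        error_rate: float | None = None,
                        seed: int | None = None) -> list[str]:
    """Long reads over every library plasmid, random strand, i.i.d. errors.

    Returns the read sequences (write with :func:`ciberseq.io.write_fastq`).
    At zero error rate, parsing inverts the layout exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(cfg.seed if seed is None else seed), 2]))
    rate = cfg.long_read_error_rate if error_rate is None else error_rate
    entries = truth.library.entries
    n_pairs = len(entries)
    n_reads = n_pairs * reads_per_pair

    pad5 = "TGCTAGACCGGTATCAGCTA"
    pad3 = "CATGGTTCAGCCTAGAGTCA"
    parts = []
    for row in entries.itertuples(index=False):
        ga, gb = row.guide_key.split("|")
        parts.append(pad5 + layout.anchor_up_red + row.bc_red + layout.anchor_down_red
                     + layout.anchor_guide_up + ga + gb + layout.anchor_guide_down
                     + layout.anchor_up_ir + row.bc_ir + layout.anchor_down_ir + pad3)
    template = sc.strs_to_rows(parts)
    reads = np.repeat(template, reads_per_pair, axis=0)
    sc.apply_substitutions(rng, reads, rate)
    flip = rng.random(n_reads) < 0.5
    reads[flip] = sc.revcomp_bytes(reads[flip])
    return sc.rows_to_strs(reads)


@dataclass
class SimScreen:
    """A simulated screen: manifest, truth counts, and per-library reads."""

    cfg: SimConfig
    truth: SimTruth
    manifest: pd.DataFrame
    layout: ShortReadLayout

    def library_keys(self) -> list[tuple[str, str]]:
        return [(r.sample_id, r.channel) for r in self.manifest.itertuples(index=False)]

    def reads_for(self, sample_id: str, channel: str) -> np.ndarray:
        """Regenerate the ASCII read block of one library (deterministic)."""
        return _library_reads(self, sample_id, channel)

    def iter_reads(self) -> Iterator[tuple[tuple[str, str], np.ndarray]]:
        for key in self.library_keys():
            yield key, self.reads_for(*key)

    def write_fastqs(self, outdir: str | Path, gzip_out: bool = False) -> pd.DataFrame:
        """Write per-library FASTQs plus manifest and truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        suffix = ".fastq.gz" if gzip_out else ".fastq"
        paths = []
        for key, block in self.iter_reads():
            path = outdir / f"{key[0]}_{key[1]}{suffix}"
            write_fastq(path, block, name_prefix=f"{key[0]}_{key[1]}_")
            paths.append(str(path))
        manifest["fastq_path"] = paths
        manifest[MANIFEST_COLUMNS].to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        self.truth.library.write(outdir / "truth_library.tsv")
        self.truth.counts.to_csv(outdir / "truth_counts.tsv", sep="\t")
        return manifest


def _sample_columns(conditions: list[str], replicates: int) -> pd.DataFrame:
    rows = []
    for cond in conditions:
        for rep in range(1, replicates + 1):
            for ch in CHANNELS:
                rows.append(("", f"{cond}_r{rep}", cond, str(rep), ch))
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def simulate_screen(truth: SimTruth, cfg: SimConfig,
                    conditions: list[str] = ["uninduced", "induced"],
                    replicates: int = 3,
                    layout: ShortReadLayout = DEFAULT_SHORT_LAYOUT) -> SimScreen:
    """Draw truth molecule counts for a conditions x replicates design.

    Expected molecules per barcode and library are
    ``depth * construct_weight * pair_share``, with the red channel
    multiplied by ``2**(planted effect + baseline bias)``; realized counts
    are NB with the configured dispersion (Poisson when it is 0).  Reads
    are generated lazily per library by :meth:`SimScreen.reads_for`.
    """
    if not conditions or replicates < 1:
        raise ValueError("design must be nonempty")
    manifest = _sample_columns(list(conditions), replicates)
    entries = truth.library.entries
    pair_ids = (entries["bc_red"] + "|" + entries["bc_ir"]).to_numpy()
    weight = truth.construct_abundance.loc[entries["construct_id"]].to_numpy() \
        * truth.pair_share.loc[pair_ids].to_numpy()
    bias = truth.baseline_bias.loc[pair_ids].to_numpy()

    counts = {}
    for row in manifest.itertuples(index=False):
        rng = _library_rng(cfg, row.sample_id, row.channel, stage=3)
        mu = cfg.depth * weight
        if row.channel == "red":
            eff = (truth.effects[row.condition].loc[entries["construct_id"]].to_numpy()
                   if row.condition in truth.effects.columns
                   else np.zeros(len(entries)))
            mu = mu * np.exp2(eff + bias)
        if cfg.dispersion > 0:
            lam = rng.gamma(shape=1.0 / cfg.dispersion,
                            scale=cfg.dispersion * mu)
            n_mol = rng.poisson(lam)
        else:
            n_mol = rng.poisson(mu)
        barcode = entries["bc_red"] if row.channel == "red" else entries["bc_ir"]
        counts[(row.sample_id, row.condition, row.replicate, row.channel)] = \
            pd.Series(n_mol, index=barcode.to_numpy())

    truth_counts = pd.DataFrame(counts).fillna(0).astype("int64")
    truth_counts.columns = pd.MultiIndex.from_tuples(
        truth_counts.columns, names=["sample_id", "condition", "replicate", "channel"])
    truth_counts.index.name = "barcode"
    truth_counts = truth_counts.sort_index()
    truth.counts = truth_counts
    return SimScreen(cfg=cfg, truth=truth, manifest=manifest, layout=layout)


def _library_rng(cfg: SimConfig, sample_id: str, channel: str, stage: int):
    key = [int(cfg.seed), stage, CHANNELS.index(channel)] + \
        [ord(c) for c in sample_id]
    return np.random.default_rng(np.random.SeedSequence(key))


def _library_reads(screen: SimScreen, sample_id: str, channel: str) -> np.ndarray:
    """Materialize the sequencing reads of one library from its truth counts."""
    cfg = screen.cfg
    layout = screen.layout
    rng = _library_rng(cfg, sample_id, channel, stage=4)
    col = screen.truth.counts.xs((sample_id, channel),
                                 level=("sample_id", "channel"), axis=1)
    mols = col.iloc[:, 0]
    mols = mols[mols > 0]
    n_mol = int(mols.sum())
    if n_mol == 0:
        return np.empty((0, cfg.read_len), dtype=np.uint8)

    bc_rows = sc.strs_to_rows(list(mols.index))
    mol_bc = np.repeat(np.arange(len(mols)), mols.to_numpy())

    # distinct UMI per molecule within its barcode group
    umis = sc.random_seq_rows(rng, n_mol, cfg.umi_len)
    for _ in range(32):
        keys = sc.pack(umis) | (mol_bc.astype(np.uint64) << np.uint64(2 * cfg.umi_len + 2))
        order = np.argsort(keys, kind="stable")
        dup_sorted = np.zeros(n_mol, dtype=bool)
        dup_sorted[1:] = keys[order][1:] == keys[order][:-1]
        dup = order[dup_sorted]
        if dup.size == 0:
            break
        umis[dup] = sc.random_seq_rows(rng, dup.size, cfg.umi_len)
    else:
        raise RuntimeError("could not assign distinct UMIs")

    # PCR duplicates: extra copies per molecule, geometric tail
    p = cfg.pcr_duplication_rate
    extra = (rng.geometric(1.0 - p, size=n_mol) - 1) if p > 0 \
        else np.zeros(n_mol, dtype=np.int64)
    copies = 1 + extra
    read_mol = np.repeat(np.arange(n_mol), copies)

    u, a = cfg.umi_len, len(layout.anchor)
    b = cfg.barcode_len
    tail_len = cfg.read_len - (u + a + b)
    tail = (sc.seq_to_bytes("AGCTTACGGACCGTTAGCAATCGGATCCTAGGCATCAGTTACGCTAGGTA"
                            * (tail_len // 50 + 1))[:tail_len]
            if tail_len > 0 else np.empty(0, dtype=np.uint8))
    n_reads = int(copies.sum())
    reads = np.empty((n_reads, cfg.read_len), dtype=np.uint8)
    reads[:, :u] = umis[read_mol]
    reads[:, u:u + a] = sc.seq_to_bytes(layout.anchor)
    reads[:, u + a:u + a + b] = bc_rows[mol_bc[read_mol]]
    if tail_len > 0:
        reads[:, u + a + b:] = tail
    sc.apply_substitutions(rng, reads, cfg.substitution_error_rate)
    return reads
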