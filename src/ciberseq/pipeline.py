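"""End-to-end orchestration: extract -> collapse -> tabulate -> filter ->
match -> aggregate -> test -> call hits.

Stage outputs are plain files (TSV) so any stage can be re-run or
inspected independently; a run manifest records package version,
parameters, input checksums and the read/molecule conservation ledger.
Re-running with identical inputs reproduces identical outputs.

The pipeline consumes either a manifest of FASTQ files on disk or an
in-memory :class:`~ciberseq.simulate.SimScreen`, whose per-library read
blocks stream through the identical stages without touching disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import _seqcodes as sc
from . import bc_extract, bc_umi, diffstats, tabulate
from .bc_extract import RejectLog
from .layouts import DEFAULT_SHORT_LAYOUT, ShortReadLayout
from .liblink import LookupTable, read_lookup
from .manifest import read_manifest
from .simulate import SimScreen

log = logging.getLogger("ciberseq")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything one screen analysis needs.

    Either ``manifest_path`` (FASTQs on disk) or an in-memory screen must
    be supplied to :func:`run_all`.  The barcode-level test runs the
    design's contrast per barcode within its own channel; the construct
    table is then tested after aggregation.
    """

    lookup_path: str | None = None
    manifest_path: str | None = None
    outdir: str | None = None
    layout: ShortReadLayout = field(default_factory=lambda: DEFAULT_SHORT_LAYOUT)
    bc_max_dist: int = 1
    umi_max_dist: int = 1
    min_mean: float = 32.0
    alpha: float = 0.01
    lfc_threshold: float = 1.5
    design: diffstats.DesignSpec | None = None
    baseline_path: str | None = None
    test_level: str = "construct"   # "construct", "barcode" or "both"
    ntc_prefix: str = "NTC"


@dataclass
class PipelineResult:
    barcode_matrix: pd.DataFrame
    filtered_matrix: pd.DataFrame
    annotations: pd.DataFrame
    unmatched: pd.DataFrame
    construct_matrix: pd.DataFrame
    construct_info: pd.DataFrame
    extraction: dict
    ledger: pd.DataFrame
    barcode_results: pd.DataFrame | None = None
    construct_results: pd.DataFrame | None = None
    run_manifest: dict | None = None


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def count_library(reads, layout: ShortReadLayout, bc_max_dist: int,
                  umi_max_dist: int) -> tuple[pd.Series, pd.Series, RejectLog]:
    """Extract, collapse and deduplicate one library.

    ``reads`` is a FASTQ path or an ASCII read block.  Returns (molecule
    counts, read counts, reject log), counts indexed by canonical barcode.
    """
    if isinstance(reads, np.ndarray):
        bc_rows, umi_rows, rejlog = bc_extract.extract_tags_block(reads, layout)
    else:
        bc_rows, umi_rows, rejlog = bc_extract.extract_library(reads, layout)
    canon, molecules, read_counts = bc_umi.count_molecules_arrays(
        bc_rows, umi_rows, bc_max_dist=bc_max_dist, umi_max_dist=umi_max_dist)
    labels = sc.rows_to_strs(canon)
    return (pd.Series(molecules, index=labels, name="molecule_count"),
            pd.Series(read_counts, index=labels, name="read_count"), rejlog)


def run_all(cfg: PipelineConfig, screen: SimScreen | None = None,
            lookup: LookupTable | None = None) -> PipelineResult:
    """Run every stage in order and (optionally) write the results bundle."""
    # ---- inputs -----------------------------------------------------------
    if lookup is None:
        if cfg.lookup_path is None:
            raise StageError("inputs", "no_lookup", "no lookup table supplied")
        lookup = read_lookup(cfg.lookup_path)
    checksums = {}
    if screen is not None:
        manifest = screen.manifest
        def _reads_of(row):
            return screen.reads_for(row.sample_id, row.channel)
    elif cfg.manifest_path is not None:
        manifest = read_manifest(cfg.manifest_path, require_paths=True)
        checksums = {row.fastq_path: _sha256(row.fastq_path)
                     for row in manifest.itertuples(index=False)}
        def _reads_of(row):
            return row.fastq_path
    else:
        raise StageError("inputs", "no_reads", "neither a manifest nor a screen supplied")

    # ---- extract / collapse / dedup per library ---------------------------
    counts: dict[tuple[str, str], pd.Series] = {}
    extraction: dict[str, dict] = {}
    try:
        for row in manifest.itertuples(index=False):
            key = (row.sample_id, row.channel)
            mols, read_counts, rejlog = count_library(
                _reads_of(row), cfg.layout, cfg.bc_max_dist, cfg.umi_max_dist)
            counts[key] = mols
            extraction[f"{key[0]}:{key[1]}"] = {
                "reads": rejlog.total, "tags": rejlog.accepted,
                "rejects": dict(rejlog.reasons),
                "molecules": int(mols.sum()), "reads_kept": int(read_counts.sum()),
            }
            log.info("library %s: %d reads -> %d tags -> %d molecules",
                     key, rejlog.total, rejlog.accepted, int(mols.sum()))
            if rejlog.total != rejlog.accepted + rejlog.rejected:
                raise StageError("extract", "conservation",
                                 f"record accounting broken for {key}")
    except (OSError, ValueError) as err:
        raise StageError("extract", "io", str(err)) from err

    # ---- tabulate / filter / match / aggregate ----------------------------
    raw = tabulate.tabulate(counts, manifest)
    filtered = tabulate.filter_low_abundance(raw, cfg.min_mean)
    matched, annotations, unmatched = tabulate.match_to_constructs(
        filtered, lookup, ntc_prefix=cfg.ntc_prefix)
    construct_matrix, construct_info = tabulate.aggregate_by_construct(
        matched, annotations)
    ledger = tabulate.conservation_ledger(raw, filtered, unmatched, construct_matrix)
    if not ledger["balanced"].all():
        raise StageError("tabulate", "conservation", "count ledger does not balance")

    # ---- statistics -------------------------------------------------------
    baseline = None
    if cfg.baseline_path is not None:
        baseline = pd.read_csv(cfg.baseline_path, sep="\t", index_col=0)
    barcode_results = None
    construct_results = None
    if cfg.design is not None:
        if cfg.test_level in ("barcode", "both"):
            barcode_results = test_per_barcode(
                matched, annotations, cfg.design, alpha=cfg.alpha,
                lfc_threshold=cfg.lfc_threshold)
        if cfg.test_level in ("construct", "both"):
            paired = tabulate.paired_matrix(construct_matrix)
            construct_results = test_matrix(
                paired, cfg.design, baseline=baseline, alpha=cfg.alpha,
                lfc_threshold=cfg.lfc_threshold)

    # ---- outputs ----------------------------------------------------------
    run_manifest = {
        "version": __version__,
        "parameters": {
            "bc_max_dist": cfg.bc_max_dist, "umi_max_dist": cfg.umi_max_dist,
            "min_mean": cfg.min_mean, "alpha": cfg.alpha,
            "lfc_threshold": cfg.lfc_threshold, "test_level": cfg.test_level,
        },
        "inputs": checksums,
        "extraction": extraction,
        "ledger": {str(k): {c: int(v) if c != "balanced" else bool(v)
                            for c, v in row.items()}
                   for k, row in ledger.to_dict("index").items()},
    }
    result = PipelineResult(
        barcode_matrix=raw, filtered_matrix=filtered, annotations=annotations,
        unmatched=unmatched, construct_matrix=construct_matrix,
        construct_info=construct_info, extraction=extraction, ledger=ledger,
        barcode_results=barcode_results, construct_results=construct_results,
        run_manifest=run_manifest)
    if cfg.outdir is not None:
        _write_bundle(Path(cfg.outdir), result)
    return result


def test_matrix(matrix: pd.DataFrame, design: diffstats.DesignSpec,
                baseline: pd.DataFrame | None = None, alpha: float = 0.01,
                lfc_threshold: float = 1.5,
                cells: list | None = None) -> pd.DataFrame:
    """Size factors + dispersions + NB Wald + BH + hit calls for one matrix."""
    mask = design.column_mask(matrix.columns.to_frame(index=False))
    sub = matrix.loc[:, mask]
    sf = diffstats.size_factors(sub, pseudo_reference=True)
    meta = sub.columns.to_frame(index=False)
    if cells is None:
        cells = (meta["condition"] + ":" + meta["channel"]).tolist()
    params = diffstats.estimate_dispersions(sub, sf, cells=cells)
    res = diffstats.nb_wald(sub, params, design, baseline=baseline)
    res["padj"] = diffstats.bh_adjust(res["pvalue"].to_numpy())
    return diffstats.call_hits(res, alpha=alpha, lfc_threshold=lfc_threshold)


def test_per_barcode(matrix: pd.DataFrame, annotations: pd.DataFrame,
                     design: diffstats.DesignSpec, alpha: float = 0.01,
                     lfc_threshold: float = 1.5) -> pd.DataFrame:
    """Run the design's condition contrast per barcode within its channel.

    Each barcode is expressed from a single reporter transcript, so its
    counts live in one channel's libraries; the contrast is evaluated on
    that channel's columns, and BH adjustment spans all tested barcodes.
    """
    if design.kind != "condition_effect":
        raise ValueError("per-barcode testing uses a condition_effect design")
    pieces = []
    for channel in ("red", "ir"):
        rows = annotations.index[annotations["channel"] == channel]
        if len(rows) == 0:
            continue
        ch_design = diffstats.DesignSpec(
            kind="condition_effect", condition_test=design.condition_test,
            condition_ref=design.condition_ref, channel=channel)
        mask = ch_design.column_mask(matrix.columns.to_frame(index=False))
        sub = matrix.loc[rows, mask]
        sf = diffstats.size_factors(sub, pseudo_reference=True)
        meta = sub.columns.to_frame(index=False)
        cells = (meta["condition"] + ":" + meta["channel"]).tolist()
        params = diffstats.estimate_dispersions(sub, sf, cells=cells)
        res = diffstats.nb_wald(sub, params, ch_design)
        res["channel"] = channel
        pieces.append(res)
    out = pd.concat(pieces)
    out["padj"] = diffstats.bh_adjust(out["pvalue"].to_numpy())
    return diffstats.call_hits(out, alpha=alpha, lfc_threshold=lfc_threshold)


def _write_bundle(outdir: Path, result: PipelineResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tabulate.write_matrix_tsv(result.barcode_matrix, outdir / "barcode_matrix.tsv")
    tabulate.write_matrix_tsv(result.filtered_matrix, outdir / "filtered_matrix.tsv")
    result.annotations.to_csv(outdir / "barcode_annotations.tsv", sep="\t")
    result.unmatched.to_csv(outdir / "unmatched_barcodes.tsv", sep="\t", index=False)
    tabulate.write_matrix_tsv(result.construct_matrix, outdir / "construct_matrix.tsv")
    tabulate.write_matrix_tsv(tabulate.paired_matrix(result.construct_matrix),
                              outdir / "paired_matrix.tsv")
    result.construct_info.to_csv(outdir / "construct_info.tsv", sep="\t")
    result.ledger.to_csv(outdir / "conservation_ledger.tsv", sep="\t")
    if result.barcode_results is not None:
        result.barcode_results.to_csv(outdir / "barcode_results.tsv", sep="\t")
    if result.construct_results is not None:
        result.construct_results.to_csv(outdir / "construct_results.tsv", sep="\t")
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(result.run_manifest, fh, indent=2, sort_keys=True)
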