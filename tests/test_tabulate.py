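"""Matrix assembly, abundance filtering, matching and aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ciberseq as cs
from ciberseq import tabulate as tb
from ciberseq.manifest import validate_manifest

BC = ["ACGTACGTACGTACGTACGTACGTA", "CCGTACGTACGTACGTACGTACGTC",
      "GGGTACGTACGTACGTACGTACGTG", "TTTTACGTACGTACGTACGTACGTT"]


def mini_manifest(n_cond=1, n_rep=1) -> pd.DataFrame:
    rows = []
    for c in range(n_cond):
        for r in range(n_rep):
            for ch in ("red", "ir"):
                rows.append(("x.fq", f"c{c}_r{r}", f"cond{c}", str(r), ch))
    return validate_manifest(pd.DataFrame(
        rows, columns=["fastq_path", "sample_id", "condition", "replicate", "channel"]))


class TestTabulate:
    def test_single_library_single_cell(self):
        manifest = mini_manifest().iloc[:1]
        m = tb.tabulate({("c0_r0", "red"): {BC[0]: 5}}, manifest)
        assert m.shape == (1, 1) and m.iloc[0, 0] == 5

    def test_union_semantics_zero_fills(self):
        manifest = mini_manifest()
        m = tb.tabulate({("c0_r0", "red"): {BC[0]: 5},
                         ("c0_r0", "ir"): {BC[1]: 3}}, manifest)
        assert m.shape == (2, 2)
        assert m.loc[BC[0]].tolist() == [5, 0]
        assert m.loc[BC[1]].tolist() == [0, 3]

    def test_missing_library_errors(self):
        with pytest.raises(ValueError, match="no counts"):
            tb.tabulate({("c0_r0", "red"): {BC[0]: 5}}, mini_manifest())

    def test_duplicate_column_errors(self):
        manifest = mini_manifest()
        manifest.loc[1, "channel"] = "red"
        with pytest.raises(ValueError, match="duplicate"):
            validate_manifest(manifest)

    def test_matches_independent_recount(self, small_screen):
        """Matrix entries equal a per-library recount done independently."""
        from ciberseq import pipeline
        counts = {}
        for key, block in small_screen.iter_reads():
            mols, _reads, _log = pipeline.count_library(
                block, small_screen.layout, 1, 1)
            counts[key] = mols
        m = tb.tabulate(counts, small_screen.manifest)
        for key, series in counts.items():
            col = m.xs(key, level=("sample_id", "channel"), axis=1).iloc[:, 0]
            assert col.loc[series.index].equals(series.astype("int64"))
            assert col.sum() == series.sum()


class TestFilterLowAbundance:
    def test_boundary_mean_exactly_32_kept(self):
        manifest = mini_manifest(n_rep=2)
        m = pd.DataFrame([[32, 32, 32, 32], [31, 31, 31, 31]],
                         index=BC[:2], columns=tb.make_columns(manifest))
        kept = tb.filter_low_abundance(m, 32)
        assert list(kept.index) == [BC[0]]

    def test_mean_just_below_discarded(self):
        manifest = mini_manifest(n_rep=2)
        m = pd.DataFrame([[32, 32, 32, 31]], index=BC[:1],
                         columns=tb.make_columns(manifest))
        assert len(tb.filter_low_abundance(m, 32)) == 0

    def test_all_zero_row_discarded(self):
        manifest = mini_manifest()
        m = pd.DataFrame([[0, 0]], index=BC[:1], columns=tb.make_columns(manifest))
        assert len(tb.filter_low_abundance(m, 1e-9)) == 0

    def test_random_matrix_against_row_mean_oracle(self, rng):
        manifest = mini_manifest(n_cond=3)
        cols = tb.make_columns(manifest)
        m = pd.DataFrame(rng.integers(0, 100, size=(50, 6)),
                         index=[f"{b}{i:021d}" for i, b in
                                zip(range(50), ["ACGT"] * 50)],
                         columns=cols)
        kept = tb.filter_low_abundance(m, 32)
        expected = [i for i in m.index if sum(m.loc[i]) / 6 >= 32]
        assert list(kept.index) == expected

    def test_idempotent(self, rng):
        manifest = mini_manifest(n_cond=3)
        m = pd.DataFrame(rng.integers(0, 100, size=(30, 6)),
                         index=[f"b{i}" for i in range(30)],
                         columns=tb.make_columns(manifest))
        once = tb.filter_low_abundance(m, 32)
        assert tb.filter_low_abundance(once, 32).equals(once)


class TestMatchAndAggregate:
    @pytest.fixture()
    def lookup(self):
        entries = pd.DataFrame({
            "construct_id": ["C1", "C1", "NTC1"],
            "guide_key": ["AAA|CCC", "AAA|CCC", "GGG|TTT"],
            "bc_red": [BC[0], BC[1], BC[2]],
            "bc_ir": ["A" * 25, "C" * 25, "G" * 25],
            "support": [3, 3, 3], "purity": [1.0, 1.0, 1.0]})
        return cs.LookupTable(entries)

    def test_present_annotated_absent_reported(self, lookup):
        manifest = mini_manifest()
        m = pd.DataFrame([[5, 0], [0, 7], [4, 0]],
                         index=[BC[0], "A" * 25, BC[3]],
                         columns=tb.make_columns(manifest))
        matched, annot, unmatched = tb.match_to_constructs(m, lookup)
        assert set(matched.index) == {BC[0], "A" * 25}
        assert annot.loc[BC[0], "construct_id"] == "C1"
        assert annot.loc[BC[0], "channel"] == "red"
        assert annot.loc["A" * 25, "channel"] == "ir"
        assert unmatched["barcode"].tolist() == [BC[3]]

    def test_negative_control_flag(self, lookup):
        manifest = mini_manifest()
        m = pd.DataFrame([[5, 0]], index=[BC[2]], columns=tb.make_columns(manifest))
        _, annot, _ = tb.match_to_constructs(m, lookup)
        assert bool(annot["negative_control"].iloc[0])

    def test_channel_conflict_flagged(self, lookup):
        manifest = mini_manifest()
        # BC[0] is a red barcode but only the ir library observed it
        m = pd.DataFrame([[0, 9]], index=[BC[0]], columns=tb.make_columns(manifest))
        _, annot, _ = tb.match_to_constructs(m, lookup)
        assert bool(annot["channel_conflict"].iloc[0])

    def test_aggregation_sums_member_barcodes(self, lookup):
        manifest = mini_manifest()
        m = pd.DataFrame([[3, 0], [5, 0]], index=[BC[0], BC[1]],
                         columns=tb.make_columns(manifest))
        matched, annot, _ = tb.match_to_constructs(m, lookup)
        cm, info = tb.aggregate_by_construct(matched, annot)
        assert cm.loc[("C1", "red")].tolist() == [8, 0]
        assert info.loc[("C1", "red"), "barcode_n"] == 2
        assert bool(info.loc[("C1", "red"), "single_channel"])

    def test_fully_filtered_construct_absent(self, lookup):
        manifest = mini_manifest()
        m = pd.DataFrame([[40, 0]], index=[BC[0]], columns=tb.make_columns(manifest))
        matched, annot, _ = tb.match_to_constructs(m, lookup)
        cm, _ = tb.aggregate_by_construct(matched, annot)
        assert "NTC1" not in cm.index.get_level_values("construct_id")

    def test_grouped_sum_matches_brute_force(self, rng, lookup):
        manifest = mini_manifest(n_rep=2)
        idx = [BC[0], BC[1], BC[2], "A" * 25, "C" * 25, "G" * 25]
        m = pd.DataFrame(rng.integers(1, 50, size=(6, 4)), index=idx,
                         columns=tb.make_columns(manifest))
        matched, annot, _ = tb.match_to_constructs(m, lookup)
        cm, info = tb.aggregate_by_construct(matched, annot)
        # brute force: dict accumulation
        expected: dict[tuple[str, str], np.ndarray] = {}
        for bc in idx:
            cid, ch = lookup.index[bc]
            expected.setdefault((cid, ch), np.zeros(4, dtype=int))
            expected[(cid, ch)] += m.loc[bc].to_numpy()
        for key, vals in expected.items():
            assert cm.loc[key].tolist() == vals.tolist()

    def test_conservation_ledger_balances(self, lookup, rng):
        manifest = mini_manifest(n_rep=2)
        idx = [BC[0], BC[1], BC[3], "A" * 25, "TTTTTTTTTTTTTTTTTTTTTTTTT"]
        raw = pd.DataFrame(rng.integers(0, 80, size=(5, 4)), index=idx,
                           columns=tb.make_columns(manifest))
        filtered = tb.filter_low_abundance(raw, 20)
        matched, annot, unmatched = tb.match_to_constructs(filtered, lookup)
        cm, _ = tb.aggregate_by_construct(matched, annot)
        ledger = tb.conservation_ledger(raw, filtered, unmatched, cm)
        assert bool(ledger["balanced"].all())


class TestPairedViews:
    def test_paired_matrix_folds_channels(self, small_screen):
        truth = small_screen.truth
        m = truth.counts
        matched, annot, _ = tb.match_to_constructs(m, truth.library)
        cm, _ = tb.aggregate_by_construct(matched, annot)
        paired = tb.paired_matrix(cm)
        col_ch = paired.columns.get_level_values("channel")
        cid = paired.index[0]
        for ch in ("red", "ir"):
            expect = cm.loc[(cid, ch)][cm.columns.get_level_values("channel") == ch]
            got = paired.loc[cid][col_ch == ch]
            assert got.tolist() == expect.tolist()

    def test_pair_counts_routes_by_channel(self, small_screen):
        truth = small_screen.truth
        pc = tb.pair_counts(truth.counts, truth.library)
        entry = truth.library.entries.iloc[0]
        label = f"{entry.bc_red}|{entry.bc_ir}"
        col_ch = pc.columns.get_level_values("channel")
        red_cols = pc.columns[col_ch == "red"]
        assert pc.loc[label, red_cols].tolist() == \
            truth.counts.loc[entry.bc_red, red_cols].tolist()
        ir_cols = pc.columns[col_ch == "ir"]
        assert pc.loc[label, ir_cols].tolist() == \
            truth.counts.loc[entry.bc_ir, ir_cols].tolist()


class TestMatrixIO:
    def test_tsv_round_trip(self, small_screen, tmp_path):
        m = small_screen.truth.counts.iloc[:20]
        path = tmp_path / "m.tsv"
        tb.write_matrix_tsv(m, path)
        again = tb.read_matrix_tsv(path)
        assert again.shape == m.shape
        assert (again.to_numpy() == m.to_numpy()).all()
        assert list(again.columns.names) == list(m.columns.names)

    def test_mtx_export_round_trips_values(self, small_screen, tmp_path):
        from scipy import io as spio
        m = small_screen.truth.counts.iloc[:15]
        tb.write_matrix_mtx(m, tmp_path / "m")
        sparse = spio.mmread(tmp_path / "m.mtx")
        assert (np.asarray(sparse.todense()) == m.to_numpy()).all()
        rows = pd.read_csv(tmp_path / "m.rows.tsv", sep="\t")
        assert rows.iloc[:, 0].tolist() == list(m.index)
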