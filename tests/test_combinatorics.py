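"""Phenotype enumeration, counting, marginalization and chunked storage."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytocomb import (
    ConfigurationError,
    CountingConfig,
    DataError,
    PhenotypeCode,
    StateMatrix,
    count_full_length,
    decode_codes,
    encode_states,
    expand_neutral,
    filter_by_parent,
    find_phenotypes_in_files,
    make_panel,
    parse_phenotype,
    render_phenotype,
    total_phenotype_count,
)
from cytocomb.combinatorics import ChunkManifest, place_values


def states_matrix(sample_id, rows):
    return StateMatrix(sample_id, np.array(rows, dtype=np.int64))


def brute_force_counts(state_matrices, panel, max_length=None):
    """Independent oracle: per phenotype, scan every cell and count matches."""
    m = len(panel)
    n_states = panel.n_states
    max_length = max_length or m
    result = {}
    for states in itertools.product(*(range(0, n + 1) for n in n_states)):
        length = sum(1 for s in states if s)
        if not 1 <= length <= max_length:
            continue
        idx = [i for i, s in enumerate(states) if s]
        vals = [states[i] for i in idx]
        counts = []
        for sm in state_matrices:
            match = (sm.states[:, idx] == vals).all(axis=1) if sm.n_cells else np.array([], bool)
            counts.append(int(match.sum()))
        result[states] = counts
    return result


class TestTotalCount:
    @pytest.mark.parametrize(
        "m,n,expected",
        [(12, 2, 531_440), (2, 2, 8), (1, 2, 2), (3, 2, 26), (3, 3, 63)],
    )
    def test_closed_form(self, m, n, expected):
        assert total_phenotype_count(make_panel(m, n)) == expected


class TestEncoding:
    def test_all_neutral_maps_to_zero(self):
        assert encode_states(np.zeros((1, 4), dtype=int), make_panel(4, 2))[0] == 0

    def test_mixed_radix_example(self):
        panel = make_panel(3, 2)  # radices (3, 3, 3)
        assert encode_states(np.array([[2, 1, 0]]), panel)[0] == 21

    def test_out_of_range_state_rejected(self):
        with pytest.raises(ConfigurationError):
            encode_states(np.array([[3, 0]]), make_panel(2, 2))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        panel = make_panel(int(rng.integers(1, 7)), int(rng.integers(2, 4)))
        states = rng.integers(0, panel.radices, size=(20, len(panel)))
        codes = encode_states(states, panel)
        np.testing.assert_array_equal(decode_codes(codes, panel), states)

    def test_codes_are_distinct(self):
        panel = make_panel(3, 2)
        all_states = np.array(list(itertools.product(range(3), repeat=3)))
        codes = encode_states(all_states, panel)
        assert len(np.unique(codes)) == len(codes)


class TestPhenotypeStrings:
    def test_render_lists_non_neutral_in_panel_order(self):
        panel = make_panel(3, 2)
        assert render_phenotype((2, 0, 1), panel) == "A+C-"

    def test_parse_round_trip(self):
        panel = make_panel(4, 3)
        p = PhenotypeCode((0, 2, 3, 1))
        assert parse_phenotype(p.render(panel), panel) == p

    def test_parse_canonicalizes_marker_order(self):
        panel = make_panel(2, 2)
        assert parse_phenotype("B-A+", panel).render(panel) == "A+B-"

    def test_parse_accepts_unicode_minus(self):
        panel = make_panel(2, 2)
        assert parse_phenotype("A−B+", panel).states == (1, 2)

    def test_unparseable_string_names_query(self):
        with pytest.raises(DataError, match="Z\\+"):
            parse_phenotype("Z+", make_panel(2, 2))

    def test_all_neutral_phenotype_invalid(self):
        with pytest.raises(ConfigurationError):
            PhenotypeCode((0, 0))


class TestFullLengthCounting:
    def test_hand_enumeration(self, panel_ab):
        # cells: (+,+), (+,-), (+,+), (-,-)
        sm = states_matrix("s1", [[2, 2], [2, 1], [2, 2], [1, 1]])
        table = count_full_length([sm], panel_ab)
        by_string = dict(zip(table.strings(), table.counts[:, 0]))
        assert by_string == {"A+B+": 2, "A+B-": 1, "A-B-": 1}
        assert "A-B+" not in by_string

    def test_single_cell(self):
        panel = make_panel(5, 2)
        table = count_full_length([states_matrix("s", [[1, 2, 1, 2, 1]])], panel)
        assert table.n_phenotypes == 1
        assert table.counts.sum() == 1

    def test_worst_case_materializes_all_full_length(self):
        from cytocomb import SynthConfig, discretize_events, generate_worst_case

        cfg = SynthConfig(m=4, n=2, cells_per_sample=160, n_samples=2,
                          seed=0, planted=None)
        tables, panel = generate_worst_case(cfg)
        sms = [discretize_events(t, panel) for t in tables]
        assert count_full_length(sms, panel).n_phenotypes == 16

    def test_zero_cell_sample_allowed(self, panel_ab):
        sm1 = states_matrix("s1", [[2, 2]])
        sm2 = StateMatrix("s2", np.empty((0, 2), dtype=np.int64))
        table = count_full_length([sm1, sm2], panel_ab)
        assert list(table.counts[:, 1]) == [0]

    def test_conservation(self, panel_ab):
        rng = np.random.default_rng(1)
        sms = [
            states_matrix(f"s{i}", rng.integers(1, 3, size=(50, 2)))
            for i in range(3)
        ]
        table = count_full_length(sms, panel_ab)
        np.testing.assert_array_equal(table.counts.sum(axis=0), table.sample_totals)


class TestExpandNeutral:
    def test_hand_marginals(self, panel_ab):
        sm = states_matrix("s1", [[2, 2], [2, 1], [2, 2], [1, 1]])
        full = count_full_length([sm], panel_ab)
        table = expand_neutral(full, CountingConfig(max_length=2))
        by_string = dict(zip(table.strings(), table.counts[:, 0]))
        assert by_string["A+"] == 3
        assert by_string["B+"] == 2
        assert by_string["A-"] == 1
        assert by_string["B-"] == 2

    @pytest.mark.parametrize("m", [3, 4, 5])
    def test_worst_case_yields_every_phenotype(self, m):
        from cytocomb import SynthConfig, discretize_events, generate_worst_case

        cfg = SynthConfig(m=m, n=2, cells_per_sample=2 ** m * 3, n_samples=2,
                          seed=m, planted=None)
        tables, panel = generate_worst_case(cfg)
        sms = [discretize_events(t, panel) for t in tables]
        full = count_full_length(sms, panel)
        table = expand_neutral(full, CountingConfig(max_length=m))
        assert table.n_phenotypes == 3 ** m - 1

    def test_matches_brute_force_oracle(self):
        panel = make_panel(4, 2)
        rng = np.random.default_rng(42)
        sms = [
            states_matrix(f"s{i}", rng.integers(1, 3, size=(120, 4)))
            for i in range(3)
        ]
        full = count_full_length(sms, panel)
        table = expand_neutral(full, CountingConfig(max_length=4))
        oracle = brute_force_counts(sms, panel)
        got = {
            tuple(s): list(c) for s, c in zip(table.states(), table.counts)
        }
        expected = {s: c for s, c in oracle.items() if any(c)}
        assert got == expected

    def test_max_length_respected(self):
        panel = make_panel(4, 2)
        rng = np.random.default_rng(0)
        sms = [states_matrix("s0", rng.integers(1, 3, size=(64, 4)))]
        full = count_full_length(sms, panel)
        table = expand_neutral(full, CountingConfig(max_length=2))
        assert table.lengths().max() == 2
        oracle = brute_force_counts(sms, panel, max_length=2)
        expected = {s: c for s, c in oracle.items() if any(c)}
        got = {tuple(s): list(c) for s, c in zip(table.states(), table.counts)}
        assert got == expected

    def test_frequency_filter_boundary(self, panel_ab):
        # phenotype A+ has >= 100 cells in exactly half of 4 samples
        rows_hi = [[2, 1]] * 100
        rows_lo = [[2, 1]] * 99 + [[1, 1]]
        sms = [
            states_matrix("s1", rows_hi),
            states_matrix("s2", rows_hi),
            states_matrix("s3", rows_lo),
            states_matrix("s4", rows_lo),
        ]
        full = count_full_length(sms, panel_ab)
        kept = expand_neutral(
            full, CountingConfig(max_length=2, min_count=100, min_sample_fraction=0.5)
        )
        assert "A+" in kept.strings()
        dropped = expand_neutral(
            full, CountingConfig(max_length=2, min_count=101, min_sample_fraction=0.5)
        )
        assert "A+" not in dropped.strings()

    def test_filter_not_transitive(self, panel_ab):
        # A+ itself fails the filter but its refinement A+B+ passes
        sms = [
            states_matrix("s1", [[2, 2]] * 100),
            states_matrix("s2", [[2, 1]] * 50 + [[2, 2]] * 49),
        ]
        full = count_full_length(sms, panel_ab)
        table = expand_neutral(
            full, CountingConfig(max_length=2, min_count=99, min_sample_fraction=1.0)
        )
        strings = table.strings()
        assert "A+" in strings  # 100 and 99
        assert "A+B+" not in strings  # 100 and 49

    def test_anti_monotonicity(self):
        panel = make_panel(4, 2)
        rng = np.random.default_rng(7)
        sms = [states_matrix("s", rng.integers(1, 3, size=(200, 4)))]
        table = expand_neutral(
            count_full_length(sms, panel), CountingConfig(max_length=4)
        )
        lookup = dict(zip(table.codes.tolist(), table.counts[:, 0]))
        states = table.states()
        for svec, count in zip(states, table.counts[:, 0]):
            for k in range(4):
                if svec[k] == 0:
                    total = sum(
                        lookup.get(
                            int(encode_states(
                                np.array([np.where(np.arange(4) == k, s, svec)]),
                                panel,
                            )[0]),
                            0,
                        )
                        for s in (1, 2)
                    )
                    assert total == count  # marginalization consistency

    def test_concurrency_identical_output(self):
        panel = make_panel(5, 2)
        rng = np.random.default_rng(11)
        sms = [
            states_matrix(f"s{i}", rng.integers(1, 3, size=(150, 5)))
            for i in range(4)
        ]
        full = count_full_length(sms, panel)
        a = expand_neutral(full, CountingConfig(max_length=5), n_workers=1)
        b = expand_neutral(full, CountingConfig(max_length=5), n_workers=4)
        np.testing.assert_array_equal(a.codes, b.codes)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestParentFilter:
    def _table(self, panel_ab):
        sm = states_matrix("s1", [[2, 2], [2, 1], [2, 2], [1, 2]])
        return expand_neutral(
            count_full_length([sm], panel_ab), CountingConfig(max_length=2)
        )

    def test_parent_refinements_retained(self, panel_ab):
        table = self._table(panel_ab)
        out = filter_by_parent(table, PhenotypeCode((2, 0)))  # A+
        assert sorted(out.strings()) == ["A+", "A+B+", "A+B-"]
        assert out.parent == PhenotypeCode((2, 0))

    def test_full_length_parent_keeps_only_itself(self, panel_ab):
        table = self._table(panel_ab)
        out = filter_by_parent(table, PhenotypeCode((2, 2)))
        assert out.strings() == ["A+B+"]

    def test_absent_parent_is_error(self, panel_ab):
        sm = states_matrix("s1", [[2, 2]])
        table = expand_neutral(
            count_full_length([sm], panel_ab), CountingConfig(max_length=2)
        )
        with pytest.raises(ConfigurationError):
            filter_by_parent(table, PhenotypeCode((1, 0)))  # A- unseen

    def test_expand_with_parent_keeps_parent_markers(self, panel_ab):
        sm = states_matrix("s1", [[2, 2], [2, 1], [1, 1]])
        full = count_full_length([sm], panel_ab)
        table = expand_neutral(
            full, CountingConfig(max_length=2, parent=PhenotypeCode((2, 0)))
        )
        assert sorted(table.strings()) == ["A+", "A+B+", "A+B-"]


class TestChunkedStorage:
    def _manifest(self, tmp_path, chunk_size=10):
        panel = make_panel(4, 2)
        rng = np.random.default_rng(5)
        sms = [
            states_matrix(f"s{i}", rng.integers(1, 3, size=(100, 4)))
            for i in range(2)
        ]
        full = count_full_length(sms, panel)
        manifest = expand_neutral(
            full,
            CountingConfig(max_length=4, chunk_size=chunk_size),
            out_dir=tmp_path / "counts",
        )
        return panel, full, manifest

    def test_chunked_equals_in_memory(self, tmp_path):
        panel, full, manifest = self._manifest(tmp_path)
        in_mem = expand_neutral(full, CountingConfig(max_length=4))
        loaded = manifest.load_table().sorted_by_code()
        np.testing.assert_array_equal(loaded.codes, in_mem.codes)
        np.testing.assert_array_equal(loaded.counts, in_mem.counts)

    def test_chunk_sizes_bounded(self, tmp_path):
        _, _, manifest = self._manifest(tmp_path, chunk_size=10)
        sizes = [t.n_phenotypes for t in manifest.iter_tables()]
        assert all(s <= 10 for s in sizes)
        assert sum(sizes) == manifest.n_phenotypes

    def test_manifest_round_trip(self, tmp_path):
        _, _, manifest = self._manifest(tmp_path)
        back = ChunkManifest.load(tmp_path / "counts")
        assert back.samples == manifest.samples
        assert back.chunks == manifest.chunks
        assert back.panel == manifest.panel

    def test_find_present_query(self, tmp_path):
        panel, full, manifest = self._manifest(tmp_path)
        hit = find_phenotypes_in_files(manifest, ["A+"])
        expected = expand_neutral(full, CountingConfig(max_length=4))
        row = expected.counts[expected.strings().index("A+")]
        assert hit.n_phenotypes == 1
        np.testing.assert_array_equal(hit.counts[0], row)

    def test_find_absent_query_is_empty(self, tmp_path):
        panel, _, manifest = self._manifest(tmp_path)
        # D++ cannot exist for a 2-state panel; use a valid-but-unobserved one
        hit = find_phenotypes_in_files(manifest, [])
        assert hit.n_phenotypes == 0

    def test_find_canonicalizes_query_order(self, tmp_path):
        panel, _, manifest = self._manifest(tmp_path)
        a = find_phenotypes_in_files(manifest, ["B-A+"])
        b = find_phenotypes_in_files(manifest, ["A+B-"])
        np.testing.assert_array_equal(a.codes, b.codes)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_find_unparseable_query_is_error(self, tmp_path):
        _, _, manifest = self._manifest(tmp_path)
        with pytest.raises(DataError, match="Q\\+\\+"):
            find_phenotypes_in_files(manifest, ["Q++"])
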