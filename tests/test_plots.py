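"""Plot builders: residue aggregation, guide placement, packing and the
drawn-element contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from matplotlib.collections import LineCollection

from hdxdiff import (
    Effect,
    GeneratorConfig,
    compare_states,
    generate_records,
    match_peptides,
    residue_matrix,
    robot_plot,
    significant_peptide_map,
    uptake_plot,
    volcano_plot,
    woods_plot,
)
from hdxdiff.plots import pack_intervals


@pytest.fixture(scope="module")
def effect_dataset():
    cfg = GeneratorConfig(
        n_states=2, n_peptides=20, protein_length=120,
        effects=(Effect(5, "State2", 1.0),), noise_sd_da=0.05, seed=43,
        include_fd=False,
    )
    records, truth = generate_records(cfg)
    table = match_peptides(records)
    results, intervals = compare_states(table)
    return dict(truth=truth, table=table, results=results,
                intervals=intervals)


class TestResidueMatrix:
    def test_mean_of_two_overlapping_significant(self):
        """Residue covered by dD +0.4 and +0.6 peptides averages to +0.5."""
        import dataclasses

        from hdxdiff.stats import ComparisonResult
        from hdxdiff import PeptideKey

        def res(key, dd, sig=True):
            return ComparisonResult(
                peptide=key, comparison=("a", "b"), timepoint_s=30.0,
                mean_ref=1.0, mean_test=1.0 + dd, delta_d=dd, sd_ref=0.05,
                sd_test=0.05, n_ref=3, n_test=3, t_stat=5.0, df=4.0,
                p_value=0.001, ci_da=0.2, significant=sig,
            )

        r1 = res(PeptideKey("A" * 10, 1, 10), 0.4)
        r2 = res(PeptideKey("A" * 10, 6, 15), 0.6)
        m = residue_matrix([r1, r2], mode="significant_only", protein_length=20)
        col = m.values[:, 0]
        assert col[0] == pytest.approx(0.4)     # residue 1: only r1
        assert col[7] == pytest.approx(0.5)     # residues 6-10: both
        assert col[12] == pytest.approx(0.6)    # residue 13: only r2
        assert np.isnan(col[16])                # uncovered

    def test_significant_only_all_uncovered_when_nothing_flagged(self):
        cfg = GeneratorConfig(n_states=2, n_peptides=10, seed=47, include_fd=False)
        records, _ = generate_records(cfg)
        results, _ = compare_states(match_peptides(records))
        m = residue_matrix(results, mode="significant_only")
        assert np.isnan(m.values).all()

    def test_matches_bruteforce_on_random_fixtures(self, effect_dataset):
        results = effect_dataset["results"]
        L = 120
        m = residue_matrix(results, mode="all", protein_length=L)
        for j, tp in enumerate(m.columns):
            for resi in range(1, L + 1):
                covering = [
                    r.delta_d
                    for r in results
                    if r.timepoint_s == tp
                    and r.peptide.start <= resi <= r.peptide.end
                ]
                if covering:
                    assert m.values[resi - 1, j] == pytest.approx(
                        np.mean(covering)
                    )
                else:
                    assert np.isnan(m.values[resi - 1, j])

    def test_multistate_axis(self):
        cfg = GeneratorConfig(n_states=3, n_peptides=8, seed=53, include_fd=False)
        records, _ = generate_records(cfg)
        results, _ = compare_states(match_peptides(records))
        tp = 30.0
        m = residue_matrix(
            [r for r in results if r.timepoint_s == tp], axis="comparisons"
        )
        assert m.columns == ["State2", "State3"]


class TestVolcano:
    def test_guides_at_ci_and_alpha(self, effect_dataset):
        (comparison, gci), = effect_dataset["intervals"].items()
        fig = volcano_plot(effect_dataset["results"], gci, alpha=0.01)
        ax = fig.axes[0]
        vlines = sorted(l.get_xdata()[0] for l in ax.lines if len(set(l.get_xdata())) == 1)
        hlines = [l.get_ydata()[0] for l in ax.lines if len(set(l.get_ydata())) == 1]
        assert vlines == pytest.approx([-gci.ci_da, gci.ci_da])
        assert hlines == pytest.approx([-np.log10(0.01)])

    def test_injected_point_in_significant_region(self, effect_dataset):
        (comparison, gci), = effect_dataset["intervals"].items()
        fig = volcano_plot(effect_dataset["results"], gci, alpha=0.01)
        offsets = fig.axes[0].collections[0].get_offsets()
        flagged = np.asarray(offsets)[
            (np.abs(np.asarray(offsets)[:, 0]) > gci.ci_da)
            & (np.asarray(offsets)[:, 1] > -np.log10(0.01))
        ]
        target = effect_dataset["truth"].peptides[5]
        n_tp = len(effect_dataset["table"].timepoints_s)
        assert len(flagged) == n_tp  # one injected peptide at each timepoint
        assert (flagged[:, 0] > 0).all()

    def test_self_comparison_on_axis(self):
        import dataclasses

        cfg = GeneratorConfig(n_states=1, n_peptides=8, seed=59, include_fd=False)
        records, _ = generate_records(cfg)
        cloned = records + [
            dataclasses.replace(r, protein_state="copy") for r in records
        ]
        results, intervals = compare_states(match_peptides(cloned))
        fig = volcano_plot(results, list(intervals.values())[0], 0.01)
        offsets = np.asarray(fig.axes[0].collections[0].get_offsets())
        assert np.allclose(offsets[:, 0], 0.0)


class TestWoods:
    def test_segment_count_all_mode(self, effect_dataset):
        tp = effect_dataset["table"].timepoints_s[0]
        fig = woods_plot(effect_dataset["results"], tp, mode="all")
        segs = [
            c for c in fig.axes[0].collections if isinstance(c, LineCollection)
        ]
        n_drawn = sum(len(c.get_segments()) for c in segs)
        assert n_drawn == len(effect_dataset["table"].peptides)

    def test_significant_only_subset(self, effect_dataset):
        tp = effect_dataset["table"].timepoints_s[0]
        fig = woods_plot(effect_dataset["results"], tp, mode="significant_only")
        segs = [
            c for c in fig.axes[0].collections if isinstance(c, LineCollection)
        ]
        n_drawn = sum(len(c.get_segments()) for c in segs)
        n_sig = sum(
            r.significant
            for r in effect_dataset["results"]
            if r.timepoint_s == tp
        )
        assert n_drawn == n_sig

    def test_segment_geometry_matches_results(self, effect_dataset):
        tp = effect_dataset["table"].timepoints_s[0]
        fig = woods_plot(effect_dataset["results"], tp, mode="all")
        segs = []
        for c in fig.axes[0].collections:
            if isinstance(c, LineCollection):
                segs.extend(c.get_segments())
        drawn = {
            (round(s[0][0]), round(s[1][0]), round(float(s[0][1]), 6))
            for s in segs
        }
        expected = {
            (r.peptide.start, r.peptide.end, round(r.delta_d, 6))
            for r in effect_dataset["results"]
            if r.timepoint_s == tp
        }
        assert drawn == expected


class TestRobot:
    def test_reference_above_test_below(self, effect_dataset):
        fig = robot_plot(effect_dataset["results"], effect_dataset["table"])
        heights = []
        for c in fig.axes[0].collections:
            if isinstance(c, LineCollection):
                for (x0, y0), (x1, y1) in c.get_segments():
                    if y0 == y1:  # horizontal %D bar
                        heights.append(y0)
        assert heights, "expected drawn peptide bars"
        assert any(h > 0 for h in heights) and any(h < 0 for h in heights)

    def test_only_significant_any_timepoint_drawn(self, effect_dataset):
        fig = robot_plot(effect_dataset["results"], effect_dataset["table"])
        table = effect_dataset["table"]
        n_tp = len(table.timepoints_s)
        horiz = 0
        for c in fig.axes[0].collections:
            if isinstance(c, LineCollection):
                horiz += sum(
                    1 for (a, b) in c.get_segments() if a[1] == b[1]
                )
        # one significant peptide x timepoints x two mirrored states
        assert horiz == 1 * n_tp * 2

    def test_null_data_empty_body(self):
        cfg = GeneratorConfig(n_states=2, n_peptides=10, seed=61, include_fd=False)
        records, _ = generate_records(cfg)
        table = match_peptides(records)
        results, _ = compare_states(table)
        fig = robot_plot(results, table)
        n = sum(
            len(c.get_segments())
            for c in fig.axes[0].collections
            if isinstance(c, LineCollection)
        )
        assert n == 0

    def test_multi_comparison_rejected(self):
        cfg = GeneratorConfig(n_states=3, n_peptides=8, seed=67, include_fd=False)
        records, _ = generate_records(cfg)
        table = match_peptides(records)
        results, _ = compare_states(table)
        with pytest.raises(ValueError, match="per.*comparison|one comparison"):
            robot_plot(results, table)


class TestPacking:
    def test_non_overlapping_single_row(self):
        assert pack_intervals([(1, 5), (7, 9), (11, 20)]) == [0, 0, 0]

    def test_mutually_overlapping_three_rows(self):
        assert sorted(pack_intervals([(1, 10), (2, 11), (3, 12)])) == [0, 1, 2]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(1, 80), st.integers(1, 15)),
            min_size=1,
            max_size=25,
        )
    )
    def test_rows_never_overlap(self, raw):
        spans = [(s, s + ln - 1) for s, ln in raw]
        rows = pack_intervals(spans)
        by_row = {}
        for span, row in zip(spans, rows):
            by_row.setdefault(row, []).append(span)
        for members in by_row.values():
            members.sort()
            for (s1, e1), (s2, e2) in zip(members, members[1:]):
                assert e1 < s2  # brute-force overlap check

    def test_map_figure(self, effect_dataset):
        tp = effect_dataset["table"].timepoints_s[0]
        fig = significant_peptide_map(effect_dataset["results"], tp)
        assert fig.axes[0].get_xlabel() == "Residue"


class TestUptake:
    def test_means_match_table(self, effect_dataset):
        table = effect_dataset["table"]
        pep = table.peptides[0]
        fig = uptake_plot(table, pep)
        ax = fig.axes[0]
        containers = {c.get_label(): c for c in ax.containers}
        assert set(table.states) <= set(containers)
        for state in table.states:
            line = containers[state].lines[0]
            expected = [
                float(np.mean(table.uptake_values(pep, state, tp)))
                for tp in table.timepoints_s
            ]
            assert list(line.get_ydata()) == pytest.approx(expected)

    def test_unknown_peptide_errors(self, effect_dataset):
        from hdxdiff import PeptideKey

        with pytest.raises(ValueError):
            uptake_plot(effect_dataset["table"], PeptideKey("AAAA", 900, 903))


def test_deterministic_rendering(effect_dataset, tmp_path):
    """Same inputs render byte-identical files."""
    (comparison, gci), = effect_dataset["intervals"].items()
    paths = []
    for i in range(2):
        fig = volcano_plot(effect_dataset["results"], gci, 0.01)
        p = tmp_path / f"v{i}.png"
        fig.savefig(p, dpi=100, metadata={"Software": None})
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
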