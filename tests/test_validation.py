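"""Annotation-conditioned error rates, heat grid, and the score regression."""

import numpy as np
import pytest

from coiminer import fixtures, pipeline
from coiminer.scoring import Thresholds
from coiminer.validation import (
    fn_rate,
    fp_rate,
    heat_grid,
    read_annotation_calls,
    regression_r2,
)


def calls(n_target, n_non_target, n_ambiguous):
    ann = {}
    ids = []
    for i in range(n_target):
        ann[f"t{i}"] = "target"; ids.append(f"t{i}")
    for i in range(n_non_target):
        ann[f"n{i}"] = "non_target"; ids.append(f"n{i}")
    for i in range(n_ambiguous):
        ann[f"a{i}"] = "ambiguous"; ids.append(f"a{i}")
    return ids, ann


class TestFpRate:
    def test_published_scale_arithmetic(self):
        """36 non-target and 632 ambiguous among 1,054,973 accepted."""
        ids, ann = calls(1_054_973 - 36 - 632, 36, 632)
        result = fp_rate(ids, ann)
        assert result.total == 1_054_973
        assert result.formatted() == "0.0034%"
        assert result.rate_percent == pytest.approx(100 * 36 / 1_054_973)

    def test_no_false_positives_is_zero(self):
        ids, ann = calls(10, 0, 2)
        assert fp_rate(ids, ann).rate_percent == 0.0

    def test_all_non_target_is_hundred(self):
        ids, ann = calls(0, 5, 0)
        assert fp_rate(ids, ann).rate_percent == 100.0

    def test_ambiguous_excluded_on_request(self):
        ids, ann = calls(90, 10, 100)
        assert fp_rate(ids, ann).rate_percent == pytest.approx(5.0)
        assert fp_rate(ids, ann, include_ambiguous=False).rate_percent == \
            pytest.approx(10.0)

    def test_missing_annotation_errors_with_ids(self):
        with pytest.raises(ValueError, match="ghost"):
            fp_rate(["ghost"], {})

    def test_fractions_partition_the_accepted_set(self):
        ids, ann = calls(70, 20, 10)
        r = fp_rate(ids, ann)
        total = r.n_target + r.n_non_target + r.n_ambiguous
        assert total == len(ids)
        assert (100 * r.n_target / total + r.rate_percent
                + 100 * r.n_ambiguous / total) == pytest.approx(100.0)


class TestFnRate:
    def test_published_scale_arithmetic(self):
        """154 target-annotated among the relaxed-only breakdown records."""
        ids, ann = calls(154, 280_048, 3_493)
        assert len(ids) == 283_695
        result = fn_rate(ids, ann)
        assert result.rate_percent == pytest.approx(100 * 154 / 283_695)
        assert result.formatted() == "0.054%"

    def test_no_targets_among_relaxed_only_is_zero(self):
        ids, ann = calls(0, 10, 3)
        assert fn_rate(ids, ann).rate_percent == 0.0

    def test_fixture_run_matches_generator_ground_truth(
        self, default_corpus, run_config_factory
    ):
        strict_pool, _ = pipeline.run(run_config_factory(Thresholds.strict()))
        relaxed_pool, _ = pipeline.run(run_config_factory(Thresholds.relaxed()))
        strict_ids = {c.id for c in strict_pool.values() if c.accepted}
        relaxed_only = {c.id for c in relaxed_pool.values()
                        if c.accepted} - strict_ids
        ann = {r.accession: ("target" if r.category == "target" else "non_target")
               for r in default_corpus.records}
        fp = fp_rate(strict_ids, ann)
        assert fp.rate_percent == 0.0  # generator scores straddle no threshold
        if relaxed_only:
            fn = fn_rate(relaxed_only, ann)
            assert fn.rate_percent == 0.0


class TestHeatGrid:
    def test_identical_points_share_one_cell(self):
        grid = heat_grid([(3.2, -1.1)] * 3, 1.0, 1.0)
        assert grid.counts.max() == 3 and grid.total() == 3

    def test_point_on_edge_goes_to_higher_bin(self):
        grid = heat_grid([(0.5, 0.5), (1.0, 0.5)], 1.0, 1.0)
        # 1.0 sits on the [1, 2) bin edge, away from 0.5's [0, 1) bin
        assert grid.counts.shape[0] == 2
        assert grid.counts[0].sum() == 1 and grid.counts[1].sum() == 1

    def test_counts_conserve_points(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 10, size=(500, 2))
        assert heat_grid(pts, 2.5, 4.0).total() == 500

    def test_uniform_points_not_rejected_as_nonuniform(self):
        rng = np.random.default_rng(42)
        pts = np.column_stack([rng.uniform(0, 10, 20_000),
                               rng.uniform(0, 10, 20_000)])
        grid = heat_grid(pts, 1.0, 1.0)
        from scipy.stats import chisquare
        inner = grid.counts[:10, :10].ravel()  # full-coverage bins
        assert chisquare(inner).pvalue > 0.001

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            heat_grid([(0, 0)], 0.0, 1.0)

    def test_tsv_export(self, tmp_path):
        grid = heat_grid([(0.5, 0.5), (1.5, 2.5)], 1.0, 1.0)
        out = tmp_path / "grid.tsv"
        grid.to_tsv(out)
        lines = out.read_text().splitlines()
        assert len(lines) == grid.counts.shape[0] + 1


class TestRegressionR2:
    def test_collinear_points_r2_one(self):
        pts = [(x, 2 * x + 1) for x in range(5)]
        slope, intercept, r2 = regression_r2(pts)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_scores_give_near_zero_r2(self):
        rng = np.random.default_rng(7)
        pts = np.column_stack([rng.normal(size=10_000), rng.normal(size=10_000)])
        _, _, r2 = regression_r2(pts)
        assert r2 < 0.01

    def test_duplicated_dataset_same_r2(self):
        rng = np.random.default_rng(1)
        pts = [(float(x), float(y)) for x, y in rng.normal(size=(30, 2))]
        assert regression_r2(pts)[2] == pytest.approx(regression_r2(pts + pts)[2])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            regression_r2([(1, 2), (2, 3)])
        with pytest.raises(ValueError):
            regression_r2([(1, 2), (1, 3), (1, 4)])


def test_read_annotation_calls(tmp_path):
    p = tmp_path / "ann.tsv"
    p.write_text("a\ttarget\nb\tNon_Target\nc\tambiguous\n")
    calls_map = read_annotation_calls(p)
    assert calls_map == {"a": "target", "b": "non_target", "c": "ambiguous"}
    p.write_text("a\ttarget\na\ttarget\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_annotation_calls(p)
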