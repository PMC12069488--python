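import numpy as np
import pandas as pd
import pytest

from isomirkit import abundance
from isomirkit.abundance import (
    ExpressionMatrix,
    compute_rpm,
    median_of_ratios_normalize,
    relative_abundance_filter,
    validate_filter_by_simulation,
)

from conftest import random_matrix


def make_matrix(counts, parents, classes=None, datasets=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"r{i}|SEQ{i}" for i in range(len(counts))]
    classes = classes or ["Canonical"] * len(counts)
    meta = pd.DataFrame(
        {
            "display_name": [f"r{i}" for i in range(len(counts))],
            "sequence": [f"SEQ{i}" for i in range(len(counts))],
            "mature_name": parents,
            "variant_class": classes,
            "seed_conserved": True,
        },
        index=counts.index,
    )
    datasets = datasets or {c: "ds1" for c in counts.columns}
    return ExpressionMatrix(counts=counts.astype(float), row_meta=meta, sample_datasets=datasets)


class TestRpm:
    def test_single_sequence_is_a_million(self):
        matrix = make_matrix({"s1": [10]}, ["mir-1"])
        assert compute_rpm(matrix).iloc[0, 0] == pytest.approx(1e6)

    def test_proportionality(self):
        matrix = make_matrix({"s1": [8, 2]}, ["mir-1", "mir-1"])
        assert compute_rpm(matrix)["s1"].tolist() == [800_000, 200_000]

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        matrix = random_matrix(rng)
        rpm = compute_rpm(matrix)
        assert np.allclose(rpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_sample_names_sample(self):
        matrix = make_matrix({"s1": [5], "s2": [0]}, ["mir-1"])
        with pytest.raises(ValueError, match="s2"):
            compute_rpm(matrix)


class TestRelativeAbundanceFilter:
    def test_share_below_threshold_removed(self):
        matrix = make_matrix({"s1": [995, 5]}, ["mir-1", "mir-1"])
        filtered, report = relative_abundance_filter(matrix, threshold=0.01)
        assert report.n_rows_removed == 1
        assert list(filtered.row_meta["display_name"]) == ["r0"]

    def test_share_exactly_at_threshold_retained(self):
        # "less than 1% removed" is a strict inequality
        matrix = make_matrix({"s1": [990, 10]}, ["mir-1", "mir-1"])
        _, report = relative_abundance_filter(matrix, threshold=0.01)
        assert report.n_rows_removed == 0

    def test_report_reconciles_with_dimensions(self):
        rng = np.random.default_rng(1)
        matrix = random_matrix(rng, n_rows=20)
        filtered, report = relative_abundance_filter(matrix, threshold=0.05)
        assert report.n_rows_before == 20
        assert report.n_rows_removed + len(filtered.counts) == 20
        assert sum(report.rows_removed_per_parent.values()) == report.n_rows_removed

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_matrix(rng, n_rows=30, n_parents=5)
        kept_sets = []
        for threshold in (0.001, 0.01, 0.05, 0.2):
            filtered, _ = relative_abundance_filter(matrix, threshold=threshold)
            kept_sets.append(set(filtered.counts.index))
        for looser, tighter in zip(kept_sets, kept_sets[1:]):
            assert tighter <= looser

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        matrix = random_matrix(rng, n_rows=15)
        filtered, _ = relative_abundance_filter(matrix, threshold=0.03)
        perm = rng.permutation(len(matrix.counts))
        shuffled = ExpressionMatrix(
            counts=matrix.counts.iloc[perm].copy(),
            row_meta=matrix.row_meta.iloc[perm].copy(),
            sample_datasets=dict(matrix.sample_datasets),
        )
        filtered_shuffled, _ = relative_abundance_filter(shuffled, threshold=0.03)
        assert set(filtered.counts.index) == set(filtered_shuffled.counts.index)

    def test_silent_parent_left_untouched(self):
        matrix = make_matrix({"s1": [100, 0]}, ["mir-1", "mir-2"])
        _, report = relative_abundance_filter(matrix, threshold=0.01)
        assert report.n_rows_removed == 0


class TestMedianOfRatios:
    def test_identical_samples_have_unit_factors(self):
        matrix = make_matrix({"s1": [10, 20, 30], "s2": [10, 20, 30]}, ["m"] * 3)
        result = median_of_ratios_normalize(matrix)
        assert np.allclose(result.size_factors, 1.0)
        assert np.allclose(matrix.layers["normalized"], matrix.counts)

    def test_hand_computed_three_by_two_fixture(self):
        # counts A=[1,4,16], B=[2,8,32]; geometric means [sqrt2, 4*sqrt2, 16*sqrt2]
        # ratios A = 1/sqrt2 (every row), B = sqrt2
        matrix = make_matrix({"A": [1, 4, 16], "B": [2, 8, 32]}, ["m"] * 3)
        result = median_of_ratios_normalize(matrix)
        assert result.size_factors["A"] == pytest.approx(2**-0.5, abs=1e-10)
        assert result.size_factors["B"] == pytest.approx(2**0.5, abs=1e-10)
        normalized = matrix.layers["normalized"]
        assert np.allclose(normalized["A"], normalized["B"], atol=1e-10)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(3)
        matrix = random_matrix(rng)
        base = median_of_ratios_normalize(matrix)
        scaled_counts = matrix.counts.copy()
        scaled_counts["s0"] = scaled_counts["s0"] * scale
        scaled = ExpressionMatrix(
            counts=scaled_counts,
            row_meta=matrix.row_meta,
            sample_datasets=dict(matrix.sample_datasets),
        )
        result = median_of_ratios_normalize(scaled)
        # under the geometric-mean convention, scaling one sample by c moves
        # the reference by c^(1/m): factor ratios isolate c and normalized
        # counts are invariant up to that common constant
        ratio = result.size_factors["s0"] / base.size_factors["s0"]
        other = result.size_factors["s1"] / base.size_factors["s1"]
        assert ratio / other == pytest.approx(scale, rel=1e-9)
        constant = scale ** (1.0 / matrix.counts.shape[1])
        assert np.allclose(
            scaled.layers["normalized"],
            matrix.layers["normalized"] * constant,
            rtol=1e-9,
        )

    def test_matches_independent_reference_implementation(self):
        # cross-check size factors against pydeseq2 on a random matrix
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(25, 4)), columns=list("ABCD")
        )
        matrix = make_matrix(counts, ["m"] * 25, datasets={c: "d" for c in "ABCD"})
        result = median_of_ratios_normalize(matrix)
        dds = DeseqDataSet(
            counts=counts.T,
            metadata=pd.DataFrame({"condition": ["x"] * 4}, index=list("ABCD")),
            design="~1",
            quiet=True,
        )
        dds.fit_size_factors()
        assert np.allclose(
            result.size_factors.to_numpy(), dds.obs["size_factors"].to_numpy(), rtol=1e-9
        )

    def test_no_positive_row_suggests_fallback(self):
        matrix = make_matrix({"s1": [0, 5], "s2": [5, 0]}, ["m", "m"])
        with pytest.raises(ValueError, match="pseudo_reference"):
            median_of_ratios_normalize(matrix)
        result = median_of_ratios_normalize(matrix, pseudo_reference=True)
        assert (result.size_factors > 0).all()


class TestFilterValidation:
    def test_no_errors_means_no_spurious_rows(self, syn_ref):
        table = validate_filter_by_simulation(
            syn_ref, error_rate=0.0, library_size=2000, thresholds=[0.0, 0.01], seed=5
        )
        assert (table["n_error_rows_before"] == 0).all()
        assert (table["n_error_rows_surviving"] == 0).all()

    def test_q30_errors_filtered_at_one_percent(self, syn_ref):
        table = validate_filter_by_simulation(
            syn_ref, error_rate=1e-3, library_size=20_000, thresholds=[0.0, 0.01], seed=5
        )
        open_row = table.set_index("threshold").loc[0.0]
        strict_row = table.set_index("threshold").loc[0.01]
        assert open_row["n_error_rows_surviving"] > 0
        # each single-substitution sequence has expected share error_rate/3 << 1%
        assert 1e-3 / 3 < 0.01
        assert strict_row["n_error_rows_surviving"] == 0
        assert strict_row["canonical_loss_fraction"] == pytest.approx(0.0, abs=1e-12)

    def test_survival_monotone_in_threshold(self, syn_ref):
        table = validate_filter_by_simulation(
            syn_ref,
            error_rate=5e-3,
            library_size=10_000,
            thresholds=[0.0, 0.001, 0.01, 0.1],
            seed=6,
        )
        survival = table["spurious_survival_fraction"].to_numpy()
        assert (np.diff(survival) <= 1e-12).all()

    def test_deterministic_under_seed(self, syn_ref):
        kwargs = dict(error_rate=2e-3, library_size=5_000, thresholds=[0.01], seed=9)
        first = validate_filter_by_simulation(syn_ref, **kwargs)
        second = validate_filter_by_simulation(syn_ref, **kwargs)
        pd.testing.assert_frame_equal(first, second)
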