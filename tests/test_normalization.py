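"""Filters and TMM normalization: threshold semantics, oracle equivalence,
and scale invariances."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import naive_tmm_factors
from soilfingerprint import (
    AttributeTable,
    FilterPolicy,
    apply_normalization,
    compute_tmm_factors,
    derive_min_total_count,
    filter_attributes,
    filter_samples,
    normalize_pipeline,
)
from soilfingerprint.io import TableFormatError
from soilfingerprint.normalization import TMMNormalizer

# A fixed 4 x 20 matrix (seeded draw, frozen) with a shallow sample and a
# block of zeros; expected factors from the independent step-by-step oracle.
FIXTURE_MATRIX = [
    [115, 101, 60, 276, 38, 483, 123, 74, 238, 201, 119, 495, 382, 203, 132,
     24, 299, 356, 14, 55],
    [251, 190, 201, 414, 407, 132, 66, 220, 252, 106, 153, 341, 111, 464, 113,
     491, 437, 235, 350, 45],
    [37, 13, 28, 36, 25, 23, 51, 46, 44, 58, 39, 59, 59, 22, 55, 24, 56, 12,
     20, 20],
    [0, 0, 0, 0, 0, 462, 57, 173, 133, 87, 47, 186, 179, 168, 411, 486, 410,
     399, 59, 129],
]
FIXTURE_FACTORS = [0.873508381, 0.935381506, 0.995324912, 1.229643647]


def _table(matrix, attribute_type="KO", sample_prefix="S"):
    frame = pd.DataFrame(
        matrix,
        index=[f"{sample_prefix}{i}" for i in range(len(matrix))],
        columns=[f"A{j:02d}" for j in range(len(matrix[0]))],
    )
    return AttributeTable(counts=frame, attribute_type=attribute_type)


def _fixture_table():
    return _table(FIXTURE_MATRIX)


class TestThresholds:
    def test_total_count_floor_matches_five_reads_per_compiled_sample(self):
        assert derive_min_total_count(5, 1512) == 7560
        assert FilterPolicy().min_total_count == 7560

    def test_policy_derivation_for_other_data_sizes(self):
        assert FilterPolicy.for_data_size(200).min_total_count == 1000


class TestFilterSamples:
    def test_genus_threshold_is_strict(self):
        # totals 3999 / 4000 / 4001 -> only the last survives "greater than"
        matrix = [[3999], [4000], [4001]]
        kept = filter_samples(_table(matrix, "GENUS"))
        assert kept.sample_ids == ["S2"]

    def test_tigrfam_uniform_pass(self):
        matrix = [[501]] * 4
        kept = filter_samples(_table(matrix, "TIGRFAM"))
        assert kept.n_samples == 4

    def test_ko_threshold_by_hand(self):
        matrix = [[1000], [2500], [7000]]
        kept = filter_samples(_table(matrix, "KO"))
        assert kept.sample_ids == ["S1", "S2"]

    def test_no_survivors_is_a_hard_failure(self):
        with pytest.raises(TableFormatError, match="2000"):
            filter_samples(_table([[10], [20]], "KO"))

    def test_idempotent(self):
        matrix = [[1000], [2500], [7000]]
        once = filter_samples(_table(matrix, "KO"))
        assert filter_samples(once).counts.equals(once.counts)


class TestFilterAttributes:
    def test_prevalence_branch_inclusive_at_half(self):
        # non-zero in exactly half of 4 samples, tiny total -> retained
        matrix = [[5, 1], [5, 1], [0, 1], [0, 1]]
        kept = filter_attributes(_table(matrix))
        assert "A00" in kept.attribute_ids

    def test_total_count_branch_single_sample(self):
        # present once with exactly the threshold total -> retained
        matrix = [[7560, 10], [0, 10], [0, 10], [0, 10]]
        kept = filter_attributes(_table(matrix))
        assert "A00" in kept.attribute_ids

    def test_both_criteria_fail_by_hand(self):
        # non-zero in 1 of 4 samples with total 10 -> removed
        matrix = [[10, 5], [0, 5], [0, 5], [0, 5]]
        kept = filter_attributes(_table(matrix))
        assert kept.attribute_ids == ["A01"]

    def test_prevalence_half_rounds_up(self):
        # 5 samples: ceil(2.5) = 3 non-zero required
        matrix = [[1, 1], [1, 1], [0, 1], [0, 0], [0, 0]]
        kept = filter_attributes(_table(matrix))
        assert kept.attribute_ids == ["A01"]

    def test_idempotent(self):
        matrix = [[10, 5], [0, 5], [0, 5], [0, 5]]
        once = filter_attributes(_table(matrix))
        assert filter_attributes(once).counts.equals(once.counts)


class TestTmmFactors:
    def test_identical_samples_give_unit_factors(self):
        matrix = [[10, 20, 30, 5], [10, 20, 30, 5]]
        tmm = compute_tmm_factors(_table(matrix))
        assert np.allclose(tmm.factor, 1.0)

    def test_pure_depth_difference_absorbed(self):
        base = [11, 25, 31, 7, 19]
        tmm = compute_tmm_factors(_table([base, [2 * v for v in base]]))
        assert np.allclose(tmm.factor, 1.0)

    def test_fixture_matches_independent_oracle(self):
        tmm = compute_tmm_factors(_fixture_table())
        oracle = naive_tmm_factors([[float(v) for v in r] for r in FIXTURE_MATRIX])
        assert np.allclose(tmm.factor.to_numpy(), oracle, atol=1e-9)
        assert np.allclose(tmm.factor.to_numpy(), FIXTURE_FACTORS, atol=1e-6)

    def test_geometric_mean_is_one(self):
        tmm = compute_tmm_factors(_fixture_table())
        assert np.exp(np.log(tmm.factor).mean()) == pytest.approx(1.0)

    def test_stable_under_rescaling_one_sample(self):
        """Rescaling one sample's counts leaves factors nearly unchanged.

        Invariance is approximate, not exact: M and A are depth-free but
        the delta-method precision weights shift with absolute depth (the
        reference TMM implementation behaves identically)."""
        scaled = [list(FIXTURE_MATRIX[0])] + [
            [10 * v for v in FIXTURE_MATRIX[1]]
        ] + [list(r) for r in FIXTURE_MATRIX[2:]]
        a = compute_tmm_factors(_fixture_table()).factor.to_numpy()
        b = compute_tmm_factors(_table(scaled)).factor.to_numpy()
        assert np.allclose(a, b, rtol=0.05)

    def test_no_shared_positive_attributes_names_sample(self):
        matrix = [[5, 5, 0, 0], [4, 6, 0, 0], [0, 0, 3, 3]]
        with pytest.raises(TableFormatError, match="S2"):
            compute_tmm_factors(_table(matrix))

    def test_matches_edger_reference_implementation(self, tmp_path):
        """Cross-check against Bioconductor edgeR's TMM on a random fixture."""
        rng = np.random.default_rng(3)
        matrix = rng.integers(0, 800, size=(6, 30))
        matrix[4] = rng.integers(0, 40, size=30)
        table = _table(matrix.tolist())
        tmm = compute_tmm_factors(table)
        counts_path = tmp_path / "counts.tsv"
        table.counts.T.to_csv(counts_path, sep="\t")
        script = (
            f'x <- as.matrix(read.delim("{counts_path}", row.names=1));'
            "suppressMessages(library(edgeR));"
            'cat(sprintf("%.10f\\n", calcNormFactors(x, method="TMM")))'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            timeout=300,
        )
        assert proc.returncode == 0, proc.stderr
        reference = [float(line) for line in proc.stdout.split()]
        assert np.allclose(tmm.factor.to_numpy(), reference, atol=1e-6)

    def test_multinomial_draws_from_one_composition_approach_unity(self):
        rng = np.random.default_rng(5)
        composition = rng.dirichlet(np.ones(60) * 2)
        counts = rng.multinomial(2_000_000, composition, size=8)
        tmm = compute_tmm_factors(_table(counts.tolist()))
        assert np.allclose(tmm.factor, 1.0, atol=0.01)


class TestApplyNormalization:
    def test_unit_factors_at_depth_one_million_reproduce_counts(self):
        row = [250_000, 250_000, 250_000, 250_000]
        table = _table([row, row])
        tmm = compute_tmm_factors(table)
        out = apply_normalization(table, tmm)
        assert out.normalized
        assert np.allclose(out.counts.to_numpy(), table.counts.to_numpy())

    def test_doubling_a_sample_leaves_its_normalized_row_unchanged(self):
        """Sequencing depth cancels out of the CPM values up to the small
        depth-dependence of the TMM precision weights."""
        doubled = [list(FIXTURE_MATRIX[0])] + [
            [2 * v for v in FIXTURE_MATRIX[1]]
        ] + [list(r) for r in FIXTURE_MATRIX[2:]]
        t1, t2 = _fixture_table(), _table(doubled)
        n1 = apply_normalization(t1, compute_tmm_factors(t1))
        n2 = apply_normalization(t2, compute_tmm_factors(t2))
        assert np.allclose(n1.counts.to_numpy(), n2.counts.to_numpy(),
                           rtol=0.02)

    def test_fixture_values_match_oracle_scaling(self):
        table = _fixture_table()
        out = apply_normalization(table, compute_tmm_factors(table))
        oracle = naive_tmm_factors(
            [[float(v) for v in r] for r in FIXTURE_MATRIX]
        )
        libs = np.array([sum(r) for r in FIXTURE_MATRIX], dtype=float)
        expected = (
            np.array(FIXTURE_MATRIX, dtype=float)
            / (libs * np.array(oracle))[:, None] * 1e6
        )
        assert np.allclose(out.counts.to_numpy(), expected, rtol=1e-9)

    def test_within_sample_rank_order_preserved(self):
        table = _fixture_table()
        out = apply_normalization(table, compute_tmm_factors(table))
        for sample in table.sample_ids:
            raw = table.counts.loc[sample].rank()
            norm = out.counts.loc[sample].rank()
            assert (raw == norm).all()

    def test_missing_factor_is_an_error(self):
        table = _fixture_table()
        tmm = compute_tmm_factors(table)
        partial = AttributeTable(
            counts=table.counts.iloc[:3], attribute_type="KO"
        )
        other = compute_tmm_factors(partial)
        with pytest.raises(TableFormatError, match="missing"):
            apply_normalization(table, other)


class TestEstimatorInterface:
    def test_transformer_fit_transform_on_dataframe(self):
        frame = pd.DataFrame(FIXTURE_MATRIX,
                             index=list("ABCD"),
                             columns=[f"A{j:02d}" for j in range(20)])
        normalizer = TMMNormalizer()
        out = normalizer.fit_transform(frame)
        assert normalizer.factors_.shape == (4,)
        assert normalizer.reference_sample_ in frame.index
        assert out.shape == frame.shape

    def test_get_params_round_trip(self):
        normalizer = TMMNormalizer(trim_m=0.2)
        params = normalizer.get_params()
        assert params["trim_m"] == 0.2
        normalizer.set_params(trim_a=0.1)
        assert normalizer.trim_a == 0.1


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_pipeline_filters_then_tmm_preserve_invariants(seed):
    """Property: the full pipeline yields positive factors with geometric
    mean one and a table flagged normalized, for arbitrary dense tables."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, 300, size=(5, 12))
    table = _table(counts.tolist(), "TIGRFAM")
    normalized, factors = normalize_pipeline(
        table, FilterPolicy.for_data_size(5)
    )
    assert (factors.factor > 0).all()
    assert np.exp(np.log(factors.factor).mean()) == pytest.approx(1.0)
    assert normalized.normalized
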