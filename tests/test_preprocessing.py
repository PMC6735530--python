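"""Scaling, stacking, stratified splitting, decline labels, stratum subsetting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tivae.preprocessing import (
    DECLINE,
    NO_DECLINE,
    PhenotypeLabels,
    ScalingParams,
    compute_decline_labels,
    scale_minmax,
    split_stratified,
    stack_tissues,
    subset_by_stratum,
)
from tivae.synthetic import CohortConfig, generate_cohort


class TestScaleMinmax:
    def test_endpoints_map_to_unit_interval(self):
        m = pd.DataFrame({"g": [0.0, 5.0, 10.0]})
        scaled, params = scale_minmax(m)
        assert list(scaled["g"]) == [0.0, 0.5, 1.0]
        assert params.minimum["g"] == 0.0 and params.maximum["g"] == 10.0

    def test_constant_gene_maps_to_zero(self):
        scaled, _ = scale_minmax(pd.DataFrame({"g": [3.0, 3.0, 3.0]}))
        assert (scaled["g"] == 0.0).all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(float, (20, 10), elements=st.floats(-50, 50)))
    def test_output_always_in_unit_interval(self, values):
        scaled, _ = scale_minmax(pd.DataFrame(values))
        out = scaled.to_numpy()
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_params_from_other_partition_clip(self):
        train = pd.DataFrame({"g": [0.0, 10.0]})
        _, params = scale_minmax(train)
        test, _ = scale_minmax(pd.DataFrame({"g": [-5.0, 15.0]}), params)
        assert list(test["g"]) == [0.0, 1.0]

    def test_idempotent_on_scaled_data(self):
        m = pd.DataFrame(np.random.default_rng(0).random((15, 4)))
        scaled, params = scale_minmax(m)
        again, _ = scale_minmax(scaled)
        rescaled, _ = scale_minmax(again)
        np.testing.assert_allclose(again.to_numpy(), rescaled.to_numpy(), atol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ScalingParams(minimum=pd.Series([1.0]), maximum=pd.Series([0.0]))


class TestStackTissues:
    def test_union_universe_and_zero_fill(self, small_cohort, small_stacked):
        universe = set()
        for t in small_cohort.tissues:
            universe |= set(small_cohort.matrices[t].columns)
        assert small_stacked.gene_universe == sorted(universe)
        # zero-fill exactness: columns outside a row's tissue hold exactly 0
        col = {g: j for j, g in enumerate(small_stacked.gene_universe)}
        for t in small_cohort.tissues:
            rows = small_stacked.row_meta["tissue"] == t
            absent = [col[g] for g in universe - set(small_cohort.matrices[t].columns)]
            assert (small_stacked.matrix[np.ix_(rows.to_numpy(), absent)] == 0.0).all()

    def test_row_conservation_and_range(self, small_cohort, small_stacked):
        n = len(small_cohort.labels) * len(small_cohort.tissues)
        assert small_stacked.n_rows == n
        assert small_stacked.matrix.min() >= 0.0
        assert small_stacked.matrix.max() <= 1.0

    def test_single_tissue_reduces_to_scaled_input(self):
        cfg = CohortConfig(
            n_tissues=1, n_individuals=20, n_cases=10, universe_size=30,
            genes_per_tissue=30, signature_genes_per_tissue=3, diff_genes_per_tissue=3,
            seed=4,
        )
        ds = generate_cohort(cfg)
        stacked = stack_tissues(ds)
        scaled, _ = scale_minmax(ds.matrices[ds.tissues[0]])
        np.testing.assert_allclose(
            stacked.matrix, scaled[stacked.gene_universe].to_numpy(), atol=1e-12
        )

    def test_duplicate_gene_ids_rejected(self, small_cohort):
        import copy

        broken = copy.deepcopy(small_cohort)
        t = broken.tissues[0]
        frame = broken.matrices[t]
        frame.columns = [frame.columns[0]] + list(frame.columns[1:-1]) + [frame.columns[0]]
        with pytest.raises(ValueError, match="duplicate"):
            stack_tissues(broken)

    def test_cross_tissue_signal_survives_scaling(self, small_cohort, small_stacked):
        """A tissue's signature genes stay high for that tissue's rows after
        scaling — the property the latent embedding depends on."""
        col = {g: j for j, g in enumerate(small_stacked.gene_universe)}
        t = small_cohort.tissues[0]
        rows = (small_stacked.row_meta["tissue"] == t).to_numpy()
        sig_cols = [col[g] for g in small_cohort.truth.signature_genes[t]]
        present_elsewhere = small_stacked.matrix[~rows][:, sig_cols]
        inside = small_stacked.matrix[rows][:, sig_cols].mean()
        outside = present_elsewhere[present_elsewhere > 0].mean()
        assert inside > outside + 0.2


class TestSplitStratified:
    def test_exact_division(self, small_stacked):
        split = split_stratified(small_stacked, 0.8, key="tissue", seed=0)
        per_tissue = small_stacked.row_meta.loc[split.train_rows, "tissue"].value_counts()
        assert (per_tissue == 32).all()  # 0.8 * 40 individuals

    def test_partition_and_determinism(self, small_stacked):
        a = split_stratified(small_stacked, 0.7, key="tissue", seed=5)
        b = split_stratified(small_stacked, 0.7, key="tissue", seed=5)
        assert np.array_equal(np.sort(a.train_rows), np.sort(b.train_rows))
        together = np.sort(np.concatenate([a.train_rows, a.test_rows]))
        assert np.array_equal(together, np.arange(small_stacked.n_rows))

    def test_round_half_up_allocation(self):
        # 808 rows per tissue at 0.8 -> round(646.4) = 646 train / 162 test
        assert int(np.floor(0.8 * 808 + 0.5)) == 646

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(fraction=st.floats(0.1, 0.9), seed=st.integers(0, 10_000))
    def test_per_stratum_fraction_within_one_row(self, small_stacked, fraction, seed):
        split = split_stratified(small_stacked, fraction, key="tissue", seed=seed)
        counts = small_stacked.row_meta.loc[split.train_rows, "tissue"].value_counts()
        for tissue, total in small_stacked.row_meta["tissue"].value_counts().items():
            assert abs(counts.get(tissue, 0) - fraction * total) <= 1

    def test_invalid_fraction_rejected(self, small_stacked):
        with pytest.raises(ValueError):
            split_stratified(small_stacked, 1.0, key="tissue", seed=0)


class TestDeclineLabels:
    @staticmethod
    def _labels(rows):
        table = pd.DataFrame(rows, columns=["mmse_baseline", "mmse_4y"])
        table["label"] = "case"
        table.index = [f"ind{i}" for i in range(len(rows))]
        return PhenotypeLabels(table=table)

    def test_zero_difference_is_no_decline(self):
        out = compute_decline_labels(self._labels([(28.0, 28.0)]))
        assert list(out.table["label"]) == [NO_DECLINE]

    def test_negative_difference_is_decline(self):
        out = compute_decline_labels(self._labels([(30.0, 26.0)]))
        assert list(out.table["label"]) == [DECLINE]

    def test_missing_followup_excluded(self):
        out = compute_decline_labels(self._labels([(30.0, np.nan), (28.0, 29.0)]))
        assert len(out.table) == 1
        assert list(out.table["label"]) == [NO_DECLINE]

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError):
            compute_decline_labels(self._labels([(np.nan, np.nan)]))


class TestSubsetByStratum:
    @staticmethod
    def _pheno(stacked):
        individuals = stacked.row_meta["individual"].unique()
        table = pd.DataFrame(
            {
                "label": "case",
                "sex": ["F" if i % 2 else "M" for i in range(len(individuals))],
                "onset_age": np.linspace(55, 85, len(individuals)),
            },
            index=individuals,
        )
        return PhenotypeLabels(table=table)

    def test_sex_filter(self, small_stacked):
        labels = self._pheno(small_stacked)
        subset = subset_by_stratum(small_stacked, labels, lambda r: r["sex"] == "F")
        kept = set(subset.row_meta["individual"])
        assert kept == set(labels.table.index[labels.table["sex"] == "F"])
        assert subset.gene_universe == small_stacked.gene_universe

    def test_age_boundary_is_late_onset(self, small_stacked):
        labels = self._pheno(small_stacked)
        labels.table.loc[labels.table.index[0], "onset_age"] = 65.0
        early = subset_by_stratum(small_stacked, labels, lambda r: r["onset_age"] < 65)
        assert labels.table.index[0] not in set(early.row_meta["individual"])

    def test_absent_covariate_is_error(self, small_stacked):
        labels = self._pheno(small_stacked)
        with pytest.raises(ValueError):
            subset_by_stratum(small_stacked, labels, lambda r: r["apoe4"] == 1)
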