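import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from toxinfer import (
    DEFAULT_THRESHOLDS,
    Dialect,
    ExpressionDataset,
    FilterLevel,
    FilterThresholds,
    genes_passing_filter,
    load_expression_matrix,
    log_summary,
    passes_filter,
    threshold_percentile,
    write_expression_matrix,
)
from toxinfer.expression import ExpressionLoadError

RNA = DEFAULT_THRESHOLDS[Dialect.RNA_TPM]
PPB = DEFAULT_THRESHOLDS[Dialect.PROTEIN_PPB]


def write_tsv(tmp_path, body, name="expr.tsv"):
    path = tmp_path / name
    path.write_text(body)
    return path


class TestLoading:
    def test_parses_genes_and_tissues(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "GeneID\tGeneName\tkidney\tbrain\n"
            "g1\talpha\t0.2\t1.5\n"
            "g2\tbeta\t0.7\t\n"
            "g3\tgamma\t6.0\t0\n",
        )
        ds = load_expression_matrix(path, "rna_tpm")
        assert ds.gene_count == 3
        assert ds.tissues == ["kidney", "brain"]
        assert math.isnan(ds.values.loc["g2", "brain"])  # empty = not measured
        assert ds.values.loc["g3", "brain"] == 0.0  # zero is measured

    def test_negative_value_names_the_cell(self, tmp_path):
        path = write_tsv(
            tmp_path, "GeneID\tGeneName\tkidney\ng1\ta\t-1\n"
        )
        with pytest.raises(ExpressionLoadError, match="g1.*kidney"):
            load_expression_matrix(path, "rna_tpm")

    def test_semiquant_words_become_ordinals(self, tmp_path):
        path = write_tsv(
            tmp_path,
            "GeneID\tGeneName\tkidney\tbrain\n"
            "g1\ta\tlow\thigh\n"
            "g2\tb\tmedium\t2\n",
        )
        ds = load_expression_matrix(path, "protein_semiquant")
        assert ds.values.loc["g1", "kidney"] == 1
        assert ds.values.loc["g1", "brain"] == 3
        assert ds.values.loc["g2", "kidney"] == 2

    def test_unknown_level_word_rejected(self, tmp_path):
        path = write_tsv(tmp_path, "GeneID\tGeneName\tkidney\ng1\ta\thuge\n")
        with pytest.raises(ExpressionLoadError, match="huge"):
            load_expression_matrix(path, "protein_semiquant")

    def test_malformed_header_rejected(self, tmp_path):
        path = write_tsv(tmp_path, "GeneID\tkidney\ng1\t1.0\n")
        with pytest.raises(ExpressionLoadError):
            load_expression_matrix(path, "rna_tpm")

    def test_duplicate_gene_ids_rejected(self):
        values = pd.DataFrame({"kidney": [1.0, 2.0]}, index=["g1", "g1"])
        with pytest.raises(ValueError, match="duplicate gene"):
            ExpressionDataset("X", Dialect.RNA_TPM, values)


class TestPassesFilter:
    @pytest.mark.parametrize(
        "value, level, thresholds, dialect, expected",
        [
            # values at a threshold are filtered out; strictly above passes
            (0.5, FilterLevel.LOW, RNA, Dialect.RNA_TPM, False),
            (0.51, FilterLevel.LOW, RNA, Dialect.RNA_TPM, True),
            (5.0, FilterLevel.HIGH, RNA, Dialect.RNA_TPM, False),
            (5.1, FilterLevel.HIGH, RNA, Dialect.RNA_TPM, True),
            (1500.0, FilterLevel.HIGH, PPB, Dialect.PROTEIN_PPB, False),
            (1500.1, FilterLevel.HIGH, PPB, Dialect.PROTEIN_PPB, True),
            (0.0, FilterLevel.NONE, RNA, Dialect.RNA_TPM, True),
            # 3-level scale: low keeps {2,3}; medium and high keep {3}
            (1, FilterLevel.LOW, None, Dialect.PROTEIN_SEMIQUANT, False),
            (2, FilterLevel.LOW, None, Dialect.PROTEIN_SEMIQUANT, True),
            (2, FilterLevel.MEDIUM, None, Dialect.PROTEIN_SEMIQUANT, False),
            (3, FilterLevel.HIGH, None, Dialect.PROTEIN_SEMIQUANT, True),
        ],
    )
    def test_boundary_semantics(self, value, level, thresholds, dialect, expected):
        assert passes_filter(value, level, thresholds, dialect) is expected

    def test_not_measured_never_passes(self):
        assert not passes_filter(math.nan, FilterLevel.LOW, RNA, Dialect.RNA_TPM)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            FilterThresholds(5.0, 1.0, 0.5)


class TestGenesPassingFilter:
    def test_low_and_high_levels(self, rna_dataset):
        assert genes_passing_filter(rna_dataset, "kidney", FilterLevel.LOW) == {
            "g2",
            "g3",
        }
        assert genes_passing_filter(rna_dataset, "kidney", FilterLevel.HIGH) == {"g3"}

    def test_none_returns_measured_genes_only(self, rna_dataset):
        assert genes_passing_filter(rna_dataset, "brain", FilterLevel.NONE) == {
            "g1",
            "g3",
        }

    def test_unknown_tissue_lists_alternatives(self, rna_dataset):
        with pytest.raises(KeyError, match="brain"):
            genes_passing_filter(rna_dataset, "liver", FilterLevel.LOW)

    def test_empty_dataset(self):
        ds = ExpressionDataset(
            "E", Dialect.RNA_TPM, pd.DataFrame({"kidney": []}, dtype=float)
        )
        assert genes_passing_filter(ds, "kidney", FilterLevel.LOW) == set()

    @settings(max_examples=50, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=0, max_value=1e4, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_filter_levels_are_nested(self, values):
        ds = ExpressionDataset(
            "P",
            Dialect.RNA_TPM,
            pd.DataFrame({"t": values}, index=[f"g{i}" for i in range(len(values))]),
        )
        sets = [
            genes_passing_filter(ds, "t", level)
            for level in (FilterLevel.NONE, FilterLevel.LOW, FilterLevel.MEDIUM, FilterLevel.HIGH)
        ]
        for larger, smaller in zip(sets, sets[1:]):
            assert smaller <= larger


class TestSummaries:
    def test_zero_with_pseudocount_gives_minus_two(self):
        ds = ExpressionDataset(
            "Z", Dialect.RNA_TPM, pd.DataFrame({"t": [0.0]}, index=["g1"])
        )
        row = log_summary(ds).loc["t"]
        assert row["min"] == pytest.approx(-2.0)
        assert row["max"] == pytest.approx(-2.0)

    def test_constant_values_collapse_quartiles(self):
        ds = ExpressionDataset(
            "C", Dialect.RNA_TPM,
            pd.DataFrame({"t": [1.0, 1.0, 1.0]}, index=["a", "b", "c"]),
        )
        row = log_summary(ds).loc["t"]
        expected = math.log10(1.01)
        for col in ("min", "q1", "median", "q3", "max"):
            assert row[col] == pytest.approx(expected)

    def test_quartiles_match_direct_computation(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 50, size=100)
        ds = ExpressionDataset(
            "U", Dialect.RNA_TPM,
            pd.DataFrame({"t": values}, index=[f"g{i}" for i in range(100)]),
        )
        row = log_summary(ds, pseudocount=0.01).loc["t"]
        logged = np.sort(np.log10(values + 0.01))
        assert row["median"] == pytest.approx(np.percentile(logged, 50))
        assert row["q1"] == pytest.approx(np.percentile(logged, 25))

    def test_semiquant_unsupported(self):
        ds = ExpressionDataset(
            "S", Dialect.PROTEIN_SEMIQUANT,
            pd.DataFrame({"t": [1.0, 2.0]}, index=["a", "b"]),
        )
        with pytest.raises(ValueError, match="semi-quantitative"):
            log_summary(ds)
        with pytest.raises(ValueError, match="semi-quantitative"):
            threshold_percentile(ds, "t", 1.0)


class TestThresholdPercentile:
    def test_direct_count(self):
        ds = ExpressionDataset(
            "T", Dialect.RNA_TPM,
            pd.DataFrame({"t": [0.0, 0.0, 1.0, 2.0]}, index=list("abcd")),
        )
        assert threshold_percentile(ds, "t", 0.5) == 50.0
        assert threshold_percentile(ds, "t", -0.1) == 0.0
        assert threshold_percentile(ds, "t", 2.0) == 100.0

    @settings(max_examples=30, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=20),
        t1=st.floats(0, 100),
        t2=st.floats(0, 100),
    )
    def test_monotone_in_threshold(self, values, t1, t2):
        ds = ExpressionDataset(
            "M", Dialect.RNA_TPM,
            pd.DataFrame({"t": values}, index=[f"g{i}" for i in range(len(values))]),
        )
        lo, hi = sorted([t1, t2])
        assert threshold_percentile(ds, "t", lo) <= threshold_percentile(ds, "t", hi)


def test_roundtrip_preserves_filter_decisions(tmp_path, rna_dataset):
    path = write_expression_matrix(rna_dataset, tmp_path / "out.tsv")
    reloaded = load_expression_matrix(path, Dialect.RNA_TPM, dataset_id="TEST-RNA")
    for tissue in rna_dataset.tissues:
        for level in FilterLevel:
            assert genes_passing_filter(reloaded, tissue, level) == genes_passing_filter(
                rna_dataset, tissue, level
            )
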