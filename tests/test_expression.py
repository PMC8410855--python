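"""I/O validation, variance filtering, the p<0.05 & 1.5-fold DEG rule, and
gene-trait correlation against hand-computed Pearson values."""

import numpy as np
import pandas as pd
import pytest

from modflex.expression import (
    ContrastError,
    ExpressionMatrix,
    FormatError,
    call_degs,
    filter_variance,
    gene_trait_correlation,
    read_expression,
)
from modflex.simulate import SimulationConfig, simulate_study


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestIO:
    def test_read_well_formed(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("gene_id\tS1\tS2\tS3\tS4\nG1\t1\t2\t3\t4\nG2\t0\t0\t1\t1\nG3\t5\t4\t3\t2\n")
        em = read_expression(p)
        assert em.shape == (3, 4)
        assert em.gene_ids == ["G1", "G2", "G3"]

    def test_duplicate_gene_id_named_in_error(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("gene_id\tS1\tS2\nG1\t1\t2\nG1\t3\t4\n")
        with pytest.raises(FormatError, match="G1"):
            read_expression(p)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("gene_id\tS1\tS2\nG1\t1\toops\nG2\t3\t4\n")
        with pytest.raises(FormatError, match="S2"):
            read_expression(p)

    def test_round_trip_identity(self, tmp_path, noise_matrix):
        path = tmp_path / "m.tsv"
        noise_matrix.write(path)
        back = read_expression(path)
        assert back.gene_ids == noise_matrix.gene_ids
        np.testing.assert_allclose(back.values, noise_matrix.values, atol=1e-12)

    def test_missing_values_dropped(self, caplog):
        df = pd.DataFrame(
            {"S1": [1.0, np.nan, 3.0], "S2": [2.0, 5.0, 6.0]}, index=["G1", "G2", "G3"]
        )
        em = ExpressionMatrix(df)
        assert em.gene_ids == ["G1", "G3"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(FormatError):
            ExpressionMatrix(pd.DataFrame())


class TestFilterVariance:
    def test_varying_gene_beats_constant(self):
        em = _em([[1, 1, 1, 1], [1, 2, 3, 4]], genes=["const", "vary"])
        assert filter_variance(em, 1).gene_ids == ["vary"]

    def test_top_n_equal_to_gene_count_is_identity_set(self, noise_matrix):
        out = filter_variance(noise_matrix, noise_matrix.shape[0])
        assert sorted(out.gene_ids) == sorted(noise_matrix.gene_ids)

    def test_tie_broken_lexicographically(self):
        em = _em([[1, 2, 3], [3, 2, 1], [0, 0, 0]], genes=["Gb", "Ga", "Gz"])
        assert filter_variance(em, 1).gene_ids == ["Ga"]

    @pytest.mark.parametrize("bad", [0, -1, 51])
    def test_invalid_top_n(self, noise_matrix, bad):
        with pytest.raises(ValueError):
            filter_variance(noise_matrix, bad)


def _two_group_setup(diff, n1=6, n2=6, jitter=0.01, seed=0):
    """Two tight groups whose log2 mean difference is exactly ~diff."""
    rng = np.random.default_rng(seed)
    g1 = diff + jitter * rng.standard_normal(n1)
    g2 = jitter * rng.standard_normal(n2)
    values = np.concatenate([g1, g2])[None, :]
    samples = [f"A{i}" for i in range(n1)] + [f"B{i}" for i in range(n2)]
    em = _em(values, genes=["G1"], samples=samples)
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": samples,
            "arm": ["DHI"] * n1 + ["control"] * n2,
            "timepoint": "Day30",
        }
    )
    return em, meta


class TestCallDegs:
    def test_fold_change_boundary_is_inclusive(self):
        # a fold change of exactly 1.50 with small p qualifies
        em, meta = _two_group_setup(np.log2(1.5), jitter=1e-6)
        row = call_degs(em, meta).iloc[0]
        assert row["p_value"] < 0.05
        assert row["fold_change"] == pytest.approx(1.5, abs=1e-4)
        assert bool(row["is_deg"])
        assert row["direction"] == "up"

    def test_sub_threshold_fold_change_rejected_despite_tiny_p(self):
        em, meta = _two_group_setup(np.log2(1.49), jitter=1e-6)
        row = call_degs(em, meta).iloc[0]
        assert row["p_value"] < 0.001
        assert not bool(row["is_deg"])

    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(5)
        values = np.concatenate([base, base])[None, :]
        samples = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)]
        em = _em(values, genes=["G1"], samples=samples)
        meta = pd.DataFrame(
            {"sample_id": samples, "subject_id": samples,
             "arm": ["DHI"] * 5 + ["control"] * 5, "timepoint": "Day30"}
        )
        row = call_degs(em, meta).iloc[0]
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["p_value"] == pytest.approx(1.0)
        assert not bool(row["is_deg"])

    def test_empty_side_raises_contrast_error(self):
        em, meta = _two_group_setup(1.0)
        meta = meta[meta["arm"] == "DHI"]
        em = em.subset_samples(list(meta["sample_id"]))
        with pytest.raises(ContrastError):
            call_degs(em, meta)

    def test_paired_contrast_uses_subject_pairing(self):
        # constant within-subject shift: paired t is overwhelming even though
        # between-subject spread is large
        rng = np.random.default_rng(2)
        subj_effect = 5.0 * rng.standard_normal(6)
        day0 = subj_effect
        day30 = subj_effect + 1.0
        samples = [f"P{i}_D0" for i in range(6)] + [f"P{i}_D30" for i in range(6)]
        em = _em(np.concatenate([day0, day30])[None, :], genes=["G1"], samples=samples)
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "subject_id": [f"P{i}" for i in range(6)] * 2,
                "arm": "DHI",
                "timepoint": ["Day0"] * 6 + ["Day30"] * 6,
            }
        )
        row = call_degs(em, meta, contrast="within_arm").iloc[0]
        assert row["p_value"] < 1e-6
        assert row["log2_fold_change"] == pytest.approx(1.0)

    def test_degenerate_paired_contrast_errors(self):
        # duplicated samples: every within-subject difference is identically zero
        samples = [f"P{i}_D0" for i in range(4)] + [f"P{i}_D30" for i in range(4)]
        base = np.arange(4.0)
        em = _em(np.concatenate([base, base])[None, :], genes=["G1"], samples=samples)
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "subject_id": [f"P{i}" for i in range(4)] * 2,
                "arm": "DHI",
                "timepoint": ["Day0"] * 4 + ["Day30"] * 4,
            }
        )
        with pytest.raises(ContrastError):
            call_degs(em, meta, contrast="within_arm")

    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(3)
        n_genes = 200
        values = rng.standard_normal((n_genes, 12))
        values[:5, :6] += 2.0
        samples = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
        em = _em(values, samples=samples)
        meta = pd.DataFrame(
            {"sample_id": samples, "subject_id": samples,
             "arm": ["DHI"] * 6 + ["control"] * 6, "timepoint": "Day30"}
        )
        raw = call_degs(em, meta)
        adj = call_degs(em, meta, adjust="bh")
        assert adj["is_deg"].sum() <= raw["is_deg"].sum()
        assert "p_adjusted" in adj.columns


def test_deg_recovery_on_synthetic_study():
    """Planted 0.75-log2FC genes at n=41 vs 21: power >= 70%, null FPR ~ alpha."""
    powers, fprs, raw_p_rates = [], [], []
    for seed in range(10):
        cfg = SimulationConfig(
            n_genes=800, module_sizes=(), dissolved_modules=(), deg_genes=100,
            deg_log2fc=0.75, seed=seed,
        )
        study = simulate_study(cfg)
        both = pd.concat(
            [study.samples_for("DHI", "Day30").data, study.samples_for("control", "Day30").data],
            axis=1,
        )
        table = call_degs(ExpressionMatrix(both), study.metadata).set_index("gene_id")
        true_degs = set(study.truth["deg_genes"])
        nulls = [g for g in table.index if g not in true_degs]
        powers.append(table.loc[list(true_degs), "is_deg"].mean())
        fprs.append(table.loc[nulls, "is_deg"].mean())
        raw_p_rates.append((table.loc[nulls, "p_value"] < 0.05).mean())
    assert np.mean(powers) >= 0.70
    # full rule (p AND fold change) can only be rarer than p < 0.05 alone
    assert np.mean(fprs) <= 0.055
    assert 0.03 <= np.mean(raw_p_rates) <= 0.07


class TestGeneTraitCorrelation:
    def test_perfect_correlation(self):
        em = _em([[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]])
        trait = pd.Series([1.0, 2, 3, 4, 5], index=em.sample_ids)
        out = gene_trait_correlation(em, trait)
        assert out["r"].tolist() == pytest.approx([1.0, -1.0])
        assert (out["p_value"] < 1e-8).all()

    def test_matches_hand_computed_pearson(self):
        # explicit sum-formula evaluation, independent of the implementation
        g = np.array([2.0, 4.0, 1.0, 7.0, 5.0])
        t = np.array([1.0, 3.0, 0.0, 9.0, 4.0])
        num = ((g - g.mean()) * (t - t.mean())).sum()
        den = np.sqrt(((g - g.mean()) ** 2).sum() * ((t - t.mean()) ** 2).sum())
        expected = num / den
        em = _em(g[None, :])
        out = gene_trait_correlation(em, pd.Series(t, index=em.sample_ids))
        assert out["r"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_reported_missing(self):
        em = _em([[1, 1, 1, 1], [1, 2, 3, 4]])
        trait = pd.Series([1.0, 2, 3, 4], index=em.sample_ids)
        out = gene_trait_correlation(em, trait)
        assert np.isnan(out["r"].iloc[0])
        assert out["r"].iloc[1] == pytest.approx(1.0)

    def test_too_few_samples(self):
        em = _em([[1, 2]])
        with pytest.raises(ValueError):
            gene_trait_correlation(em, np.array([1.0, 2.0]))
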