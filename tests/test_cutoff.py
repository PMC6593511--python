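import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from traitflow.cutoff import (
    CutoffInfeasibleError,
    GenomeMeta,
    PanGenomeModel,
    category_error_rates,
    detection_pmf,
    enumerate_detection_pmf,
    score_partition,
    select_cutoff,
    subdivide,
)
from traitflow.occurrence import OccurrenceMatrix


def uniform_meta(c, N=13):
    return [GenomeMeta(f"G{i:02d}", c) for i in range(N)]


class TestDetectionPmf:
    def test_certain_detection_concentrates_at_n(self):
        pmf = detection_pmf([1.0, 1.0, 1.0])
        assert pmf[3] == pytest.approx(1.0)
        assert pmf[:3].sum() == pytest.approx(0.0)

    def test_symmetric_binomial(self):
        assert detection_pmf([0.5, 0.5]) == pytest.approx([0.25, 0.5, 0.25])

    def test_matches_exhaustive_enumeration(self):
        p = [0.9, 0.8, 0.7]
        np.testing.assert_allclose(
            detection_pmf(p), enumerate_detection_pmf(p), atol=1e-12
        )

    def test_normalised(self):
        rng = np.random.default_rng(3)
        p = rng.random(11)
        assert detection_pmf(p).sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            detection_pmf([])


class TestCategoryErrorRates:
    def test_complete_genomes_have_no_error(self):
        er = category_error_rates(uniform_meta(1.0), 13)
        assert all(v == pytest.approx(0.0) for v in er.as_dict().values())

    def test_fn_core_is_binomial_cdf_for_uniform_completeness(self):
        er = category_error_rates(uniform_meta(0.9), 9)
        assert er.fn_core == pytest.approx(binom.cdf(8, 13, 0.9), rel=1e-9)

    @pytest.mark.parametrize("n", [2, 5, 9, 13])
    def test_missed_core_identity_fn1_eq_fp2(self, n):
        rng = np.random.default_rng(n)
        meta = [GenomeMeta(f"G{i}", c) for i, c in
                enumerate(rng.uniform(0.5, 1.0, 13))]
        er = category_error_rates(meta, n)
        assert er.fn_core == er.fp_disp

    @pytest.mark.parametrize("n", [3, 7, 12])
    def test_missed_dispensable_identity_fn2_eq_fp3(self, n):
        er = category_error_rates(uniform_meta(0.85), n)
        assert er.fn_disp == er.fp_spec

    def test_strain_specific_fn_is_worst_single_miss(self):
        meta = [GenomeMeta("G1", 0.95), GenomeMeta("G2", 0.80),
                GenomeMeta("G3", 0.99)]
        er = category_error_rates(meta, 2)
        assert er.fn_spec == pytest.approx(0.20)

    def test_fn_core_nondecreasing_fp_core_nonincreasing_in_n(self):
        meta = uniform_meta(0.9)
        rates = [category_error_rates(meta, n, contamination_scale=1.0)
                 for n in range(2, 14)]
        fn = [r.fn_core for r in rates]
        fp = [r.fp_core for r in rates]
        assert all(a <= b + 1e-12 for a, b in zip(fn, fn[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(fp, fp[1:]))

    def test_n_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            category_error_rates(uniform_meta(0.9), 1)
        with pytest.raises(ValueError):
            category_error_rates(uniform_meta(0.9), 14)


class TestSelectCutoff:
    def test_complete_genomes_select_strict_sharing(self):
        sel = select_cutoff(uniform_meta(1.0), 0.01)
        assert sel.cutoff_n == 13

    def test_complete_genomes_with_vanishing_threshold(self):
        sel = select_cutoff(uniform_meta(1.0), 1e-9)
        assert sel.cutoff_n == 13

    def test_hopelessly_incomplete_genomes_are_infeasible(self):
        sel = select_cutoff(uniform_meta(0.2), 0.01)
        assert not sel.feasible
        assert sel.cutoff_n is None
        assert len(sel.table) == 12  # full scan still reported

    def test_matches_exhaustive_scan_oracle(self):
        # independent scan: feasibility from the closed-form binomial CDF
        feasible = [
            n for n in range(2, 14) if binom.cdf(n - 1, 13, 0.9) < 0.01
        ]
        sel = select_cutoff(uniform_meta(0.9), 0.01)
        assert sel.feasible_n == feasible
        assert sel.cutoff_n == max(feasible) == 9

    def test_prefer_smallest_flag(self):
        sel = select_cutoff(uniform_meta(0.9), 0.01, prefer="smallest")
        assert sel.cutoff_n == 2

    def test_literal_all_rate_scope_needs_near_complete_genomes(self):
        # completeness floors (fn_spec, fn_disp) bind under scope="all"
        assert not select_cutoff(uniform_meta(0.9), 0.01, rate_scope="all").feasible
        assert select_cutoff(uniform_meta(0.999), 0.01, rate_scope="all").feasible

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_cutoff(uniform_meta(0.9), 0.0)


class TestSubdivide:
    def test_label_rule(self):
        presence = pd.DataFrame(
            np.zeros((3, 13), dtype=int),
            index=["a", "b", "c"],
            columns=[f"G{i:02d}" for i in range(13)],
        )
        presence.iloc[0, :13] = 1
        presence.iloc[1, :5] = 1
        presence.iloc[2, 0] = 1
        part = subdivide(OccurrenceMatrix(presence), 9)
        assert part.labels == {
            "a": "core", "b": "dispensable", "c": "strain_specific"
        }

    def test_labels_conserve_family_count(self, random_matrix):
        part = subdivide(random_matrix, 9)
        assert sum(part.counts().values()) == random_matrix.n_families
        assert sum(part.fractions().values()) == pytest.approx(1.0)

    def test_score_partition_against_known_truth(self, random_matrix):
        part = subdivide(random_matrix, 9)
        truth = dict(part.labels)  # perfect agreement
        sc = score_partition(part, truth)
        assert (sc["coverage"].dropna() == 1.0).all()
        assert (sc["accuracy"].dropna() == 1.0).all()


class TestPanGenomeModel:
    def test_fit_summary_reports_cutoff_and_partition(self, random_matrix):
        meta = [GenomeMeta(g, 0.9) for g in random_matrix.genome_ids]
        res = PanGenomeModel(random_matrix, meta).fit(0.01)
        assert res.cutoff_n == 9
        txt = res.summary()
        assert "9 of 13" in txt and "core" in txt

    def test_infeasible_fit_raises_with_rate_table(self, random_matrix):
        meta = [GenomeMeta(g, 0.2) for g in random_matrix.genome_ids]
        with pytest.raises(CutoffInfeasibleError) as exc:
            PanGenomeModel(random_matrix, meta).fit(0.01)
        assert isinstance(exc.value.table, pd.DataFrame)

    def test_missing_metadata_rejected(self, random_matrix):
        meta = [GenomeMeta(g, 0.9) for g in random_matrix.genome_ids[:-1]]
        with pytest.raises(ValueError, match="no metadata"):
            PanGenomeModel(random_matrix, meta)
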