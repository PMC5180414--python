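import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icages.errors import DataError, NotFittedError
from icages.fixtures import draw_class_predictors
from icages.formats_io import Category, SvKind, VariantRecord
from icages.tds import TdsDatabase
from icages.variant_layer import (
    CnvSignalRegion,
    CodingFeatureVector,
    EnsembleSvmModel,
    FEATURE_ORDER,
    ScoreCategory,
    VariantScore,
    annotate_coding,
    mmaf_filter,
    radial_kernel,
    score_coding,
    score_indel,
    score_noncoding,
    score_structural,
)

unit_vectors = st.lists(
    st.floats(-5, 5, allow_nan=False), min_size=11, max_size=11
).map(np.array)


def point(chrom="1", pos=100, ref="C", alt="G", category=Category.CODING_POINT):
    return VariantRecord(chrom, pos, pos, ref, alt, category)


class TestRadialKernel:
    def test_identical_inputs(self):
        u = np.linspace(0, 1, 11)
        assert radial_kernel(u, u, 0.001) == 1.0

    def test_closed_form_half(self):
        gamma = 0.3
        d = math.sqrt(math.log(2) / gamma)
        u = np.zeros(3)
        v = np.array([d, 0.0, 0.0])
        assert radial_kernel(u, v, gamma) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_distance(self):
        u = np.zeros(11)
        k = [radial_kernel(u, np.full(11, eps), 0.5) for eps in (0.1, 0.2, 0.4)]
        assert k[0] > k[1] > k[2]

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            radial_kernel(np.zeros(11), np.zeros(10), 0.001)

    @given(u=unit_vectors, v=unit_vectors)
    @settings(max_examples=50)
    def test_symmetry_and_range(self, u, v):
        k = radial_kernel(u, v, 0.01)
        assert k == pytest.approx(radial_kernel(v, u, 0.01), abs=1e-15)
        assert 0.0 < k <= 1.0

    @given(u=unit_vectors)
    @settings(max_examples=25)
    def test_formula_oracle(self, u):
        v = u + 0.3
        expected = math.exp(-0.02 * float(np.sum((u - v) ** 2)))
        assert radial_kernel(u, v, 0.02) == pytest.approx(expected, abs=1e-12)


def predictor_db(tmp_path, rows):
    p = tmp_path / "pred.tsv"
    with open(p, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(c) for c in r) + "\n")
    return TdsDatabase(p)


def full_row(chrom, pos, ref, alt, value=0.9, missing=()):
    cells = ["." if name in missing else f"{value}" for name in FEATURE_ORDER]
    return [chrom, pos, ref, alt, *cells, "0.001"]


class TestAnnotateCoding:
    def test_exact_hit(self, tmp_path):
        db = predictor_db(tmp_path, [full_row("1", 1234560, "C", "G")])
        vec = annotate_coding(point(pos=1234560), db)
        assert vec is not None
        assert vec.missing_mask == frozenset()
        assert vec.sift == pytest.approx(0.9)

    def test_absent_site_routes_noncoding(self, tmp_path):
        db = predictor_db(tmp_path, [full_row("1", 500, "A", "T")])
        assert annotate_coding(point(pos=999), db) is None

    def test_allele_mismatch_is_no_hit(self, tmp_path):
        db = predictor_db(tmp_path, [full_row("1", 100, "C", "T")])
        assert annotate_coding(point(pos=100, ref="C", alt="G"), db) is None

    def test_missing_predictor_is_masked_and_imputed(self, tmp_path):
        db = predictor_db(tmp_path, [full_row("1", 100, "C", "G",
                                              missing=("fathmm",))])
        vec = annotate_coding(point(pos=100), db)
        assert vec.missing_mask == frozenset({"fathmm"})
        assert np.isnan(vec.fathmm)
        # median imputation happens inside the model
        medians = np.arange(11, dtype=float)
        model = EnsembleSvmModel(training_medians=medians)
        imputed = model.impute(vec.values)
        assert imputed[FEATURE_ORDER.index("fathmm")] == medians[
            FEATURE_ORDER.index("fathmm")]
        assert not np.isnan(imputed).any()


class TestScoreCoding:
    def test_separable_poles(self, separable_model):
        model, _ = separable_model
        rng = np.random.default_rng(3)
        tp = draw_class_predictors(rng, 8, True, 6.0)
        tn = draw_class_predictors(rng, 8, False, 6.0)
        assert all(model.predict_proba(v) > 0.9 for v in tp)
        assert all(model.predict_proba(v) < 0.1 for v in tn)

    def test_deterministic(self, separable_model):
        model, _ = separable_model
        v = CodingFeatureVector(np.linspace(0, 1, 11))
        assert score_coding(v, model) == score_coding(v, model)

    def test_unfitted_model(self):
        with pytest.raises(NotFittedError):
            score_coding(CodingFeatureVector(np.zeros(11)), EnsembleSvmModel())

    def test_support_vector_order_invariance(self, separable_model):
        model, _ = separable_model
        v = CodingFeatureVector(np.linspace(0, 1, 11))
        before = score_coding(v, model)
        perm = np.random.default_rng(0).permutation(len(model.dual_coef))
        shuffled = EnsembleSvmModel(
            support_vectors=model.support_vectors[perm],
            dual_coef=model.dual_coef[perm],
            intercept=model.intercept,
            hyperparams=model.hyperparams,
            prob_a=model.prob_a,
            prob_b=model.prob_b,
            training_medians=model.training_medians,
            wide_min=model.wide_min,
            wide_max=model.wide_max,
        )
        assert score_coding(v, shuffled) == pytest.approx(before, abs=1e-12)

    def test_json_round_trip(self, separable_model, tmp_path):
        model, _ = separable_model
        model.to_json(tmp_path / "m.json")
        loaded = EnsembleSvmModel.from_json(tmp_path / "m.json")
        v = CodingFeatureVector(np.linspace(0, 1, 11))
        assert loaded.predict_proba(v) == pytest.approx(
            model.predict_proba(v), abs=1e-15)


class TestScoreNoncoding:
    def db(self, tmp_path, rows):
        p = tmp_path / "fun.tsv"
        with open(p, "w") as fh:
            for r in rows:
                fh.write("\t".join(str(c) for c in r) + "\n")
        return TdsDatabase(p)

    def test_lookup(self, tmp_path):
        db = self.db(tmp_path, [("1", 100, 0.8)])
        s = score_noncoding(point(pos=100, category=Category.NONCODING_POINT), db)
        assert s.value == 0.8
        assert s.score_category is ScoreCategory.FUNSEQ2

    def test_absent_site_scores_zero(self, tmp_path):
        db = self.db(tmp_path, [("1", 100, 0.8)])
        s = score_noncoding(point(pos=200, category=Category.NONCODING_POINT), db)
        assert s.value == 0.0


def region(start, end, signal, kind, gene, chrom="1"):
    return CnvSignalRegion(chrom=chrom, start=start, end=end, signal=signal,
                           kind=kind, gene=gene)


def sv(pos, end, kind=SvKind.DELETION):
    alt = "<DEL>" if kind is SvKind.DELETION else "<DUP>"
    return VariantRecord("1", pos, end, "N", alt, Category.STRUCTURAL, sv_kind=kind)


def indel(pos):
    return VariantRecord("1", pos, pos, "A", "-", Category.INDEL)


class TestScoreStructural:
    SUP = {"TSG1", "TSG2"}
    ONC = {"ONC1"}

    def test_deletion_over_suppressor(self):
        regions = [region(50, 150, 0.7, SvKind.DELETION, "TSG1")]
        s = score_structural(sv(100, 120), "loss_of_function", regions,
                             self.SUP, self.ONC)
        assert s.value == 0.7

    def test_outside_all_regions(self):
        regions = [region(500, 600, 0.7, SvKind.DELETION, "TSG1")]
        s = score_structural(sv(100, 120), "loss_of_function", regions,
                             self.SUP, self.ONC)
        assert s.value == 0.0

    def test_max_over_overlaps_and_order_independence(self):
        regions = [region(50, 150, 0.4, SvKind.DELETION, "TSG1"),
                   region(90, 200, 0.9, SvKind.DELETION, "TSG2")]
        for rs in (regions, regions[::-1]):
            s = score_structural(sv(100, 120), "loss_of_function", rs,
                                 self.SUP, self.ONC)
            assert s.value == 0.9

    def test_role_gating(self):
        # deletion region over a non-suppressor gene contributes nothing
        regions = [region(50, 150, 0.7, SvKind.DELETION, "ONC1")]
        s = score_structural(sv(100, 120), "loss_of_function", regions,
                             self.SUP, self.ONC)
        assert s.value == 0.0


class TestScoreIndel:
    SUP = {"TSG1"}
    ONC = {"ONC1"}

    def test_takes_more_deleterious_branch(self):
        regions = [region(50, 150, 0.6, SvKind.DELETION, "TSG1"),
                   region(50, 150, 0.2, SvKind.DUPLICATION, "ONC1")]
        assert score_indel(indel(100), regions, self.SUP, self.ONC).value == 0.6

    def test_both_zero(self):
        assert score_indel(indel(100), [], self.SUP, self.ONC).value == 0.0

    def test_overlapping_suppressor_and_oncogene_regions(self):
        regions = [region(50, 150, 0.3, SvKind.DELETION, "TSG1"),
                   region(50, 150, 0.8, SvKind.DUPLICATION, "ONC1")]
        lof = score_structural(indel(100), "loss_of_function", regions,
                               self.SUP, self.ONC).value
        gof = score_structural(indel(100), "gain_of_function", regions,
                               self.SUP, self.ONC).value
        combined = score_indel(indel(100), regions, self.SUP, self.ONC).value
        assert (lof, gof) == (0.3, 0.8)
        assert combined == max(lof, gof)
        assert combined >= lof and combined >= gof
        assert combined in (lof, gof)


class TestVariantScoreInvariants:
    def test_range_enforced(self):
        with pytest.raises(DataError):
            VariantScore(point(), ScoreCategory.RADIAL_SVM, 1.2)

    def test_category_consistency(self):
        with pytest.raises(DataError):
            VariantScore(point(), ScoreCategory.CNV_SIGNAL, 0.5)


class TestMmafFilter:
    def frame(self, values):
        return pd.DataFrame({
            "chrom": ["1"] * len(values),
            "pos": range(1, len(values) + 1),
            "ref": ["A"] * len(values),
            "alt": ["C"] * len(values),
            "mmaf": values,
        })

    def test_tp_boundary_inclusive(self):
        kept = mmaf_filter(self.frame([0.005, 0.01, 0.011]), "tp")
        assert kept["mmaf"].tolist() == [0.005, 0.01]

    def test_tn_boundary_inclusive(self):
        kept = mmaf_filter(self.frame([0.19, 0.20]), "tn")
        assert kept["mmaf"].tolist() == [0.20]

    def test_overlap_removed_from_tp(self):
        tp = self.frame([0.005, 0.002])
        tn = tp.iloc[[1]].copy()
        kept = mmaf_filter(tp, "tp", other=tn)
        assert kept["pos"].tolist() == [1]

    def test_out_of_range_mmaf(self):
        with pytest.raises(DataError):
            mmaf_filter(self.frame([1.2]), "tp")
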