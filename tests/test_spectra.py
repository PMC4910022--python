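"""Region stratification, variant filters, 96-category classification,
background correction and cosine similarity."""

import itertools

import numpy as np
import pytest

from ith_niche.spectra import (
    CATEGORIES,
    VariantRecord,
    classify_96,
    cosine_similarity,
    exome_triplet_background,
    functional_filter,
    normalize_spectrum,
    recurrence_filter,
    strand_bias_filter,
    stratify_regions,
    TripletSpectrum,
    similarity_report,
)


def _rec(pos, ref="C", alt="T", patient="P1", region="central", **kw):
    return VariantRecord(
        patient=patient, region=region, chrom="chrS", pos=pos, ref=ref, alt=alt, **kw
    )


class TestStratify:
    def test_set_algebra(self):
        a, b, c = _rec(10), _rec(20), _rec(30, region="peripheral")
        b_p = _rec(20, region="peripheral")
        out = stratify_regions([a, b], [b_p, c])
        assert [r.pos for r in out["central_only"]] == [10]
        assert [r.pos for r in out["peripheral_only"]] == [30]
        assert [r.pos for r in out["shared"]] == [20]

    def test_identical_sets_leave_no_private_variants(self):
        recs = [_rec(10), _rec(20)]
        recs_p = [_rec(10, region="peripheral"), _rec(20, region="peripheral")]
        out = stratify_regions(recs, recs_p)
        assert not out["central_only"] and not out["peripheral_only"]
        assert len(out["shared"]) == 2

    def test_duplicate_records_fail(self):
        with pytest.raises(ValueError, match="duplicate"):
            stratify_regions([_rec(10), _rec(10)], [])


class TestRecurrenceFilter:
    def _cohort(self, carriers, n_patients=8):
        per_patient = {f"P{i + 1}": [] for i in range(n_patients)}
        for i in range(carriers):
            per_patient[f"P{i + 1}"].append(_rec(100, patient=f"P{i + 1}"))
        for pid in per_patient:
            per_patient[pid].append(_rec(200 + hash(pid) % 50 * 3, patient=pid))
        return per_patient

    def test_six_of_eight_removed(self):
        kept, removed = recurrence_filter(self._cohort(6))
        assert all(r.pos == 100 for r in removed) and len(removed) == 6
        assert all(all(r.pos != 100 for r in recs) for recs in kept.values())

    def test_five_of_eight_kept(self):
        kept, removed = recurrence_filter(self._cohort(5))
        assert not removed

    def test_dbsnp_without_clinical_context_removed(self):
        per_patient = {"P1": [_rec(10, dbsnp_flag=True)], "P2": []}
        kept, removed = recurrence_filter(per_patient, threshold=2)
        assert len(removed) == 1 and not kept["P1"]

    def test_dbsnp_with_clinical_context_kept(self):
        per_patient = {"P1": [_rec(10, dbsnp_flag=True, clinical_flag=True)], "P2": []}
        kept, removed = recurrence_filter(per_patient, threshold=2)
        assert not removed and len(kept["P1"]) == 1

    def test_both_regions_count_as_one_patient_occurrence(self):
        per_patient = {
            "P1": [_rec(10), _rec(10, region="peripheral")],
            "P2": [_rec(10, patient="P2")],
            "P3": [],
        }
        kept, removed = recurrence_filter(per_patient, threshold=3)
        assert not removed  # 2 carrier patients < 3, despite 3 records

    def test_threshold_above_cohort_fails(self):
        with pytest.raises(ValueError):
            recurrence_filter({"P1": []}, threshold=2)


class TestFunctionalFilter:
    def test_functional_classes_kept_synonymous_dropped(self):
        recs = [
            _rec(10, functional_class="synonymous"),
            _rec(20, functional_class="stopgain"),
            _rec(30, functional_class="splice_site"),
            _rec(40, functional_class="nonsynonymous"),
            _rec(50, functional_class="stoploss"),
            _rec(60, functional_class="other"),
        ]
        kept, skipped = functional_filter(recs)
        assert sorted(r.pos for r in kept) == [20, 30, 40, 50]
        assert skipped == 0

    def test_indels_carried_through_with_own_class(self):
        indel = _rec(10, ref="A", alt="AT", functional_class="frameshift")
        kept, _ = functional_filter([indel])
        assert kept == [indel]

    def test_missing_class_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="without functional class"):
            kept, skipped = functional_filter([_rec(10, functional_class="")])
        assert skipped == 1 and not kept


class TestStrandBiasFilter:
    def _categories(self, records):
        return {r.key: "A[C>T]A" for r in records if r.is_snv}

    def test_biased_class_removes_low_opposite_support(self):
        pool = [_rec(i * 5 + 5, fwd_reads=20, rev_reads=0) for i in range(6)]
        victim = _rec(100, fwd_reads=7, rev_reads=1)
        survivor = _rec(110, fwd_reads=7, rev_reads=2)
        recs = pool + [victim, survivor]
        kept, removed, biased = strand_bias_filter(recs, self._categories(recs))
        assert biased == {"A[C>T]A"}
        assert victim in removed and survivor in kept

    def test_unbiased_class_keeps_everything(self):
        recs = [
            _rec(10, fwd_reads=7, rev_reads=1),
            _rec(20, fwd_reads=1, rev_reads=7),
            _rec(30, fwd_reads=5, rev_reads=5),
        ]
        kept, removed, biased = strand_bias_filter(recs, self._categories(recs))
        assert not biased and not removed and len(kept) == 3


class TestClassify96:
    def test_pyrimidine_reference_direct(self):
        ref = {"chrS": "AACAG"}
        assert classify_96("chrS", 3, "C", "T", ref) == "A[C>T]A"

    def test_purine_reference_reverse_complemented(self):
        ref = {"chrS": "ATGTG"}
        assert classify_96("chrS", 3, "G", "A", ref) == "A[C>T]A"

    def test_strand_involution(self):
        # an SNV and its reverse-complement representation share a category
        fwd_ref = {"chrS": "GACTG"}
        rev_ref = {"chrS": "CAGTC"}
        lab_f = classify_96("chrS", 3, "C", "A", fwd_ref)
        lab_r = classify_96("chrS", 3, "G", "T", rev_ref)
        assert lab_f == lab_r

    def test_exhaustive_enumeration_hits_96_distinct_labels(self):
        labels = set()
        for five, centre, three in itertools.product("ACGT", repeat=3):
            alts = {"C": "AGT", "T": "ACG", "A": "CGT", "G": "ACT"}[centre]
            for alt in alts:
                ref = {"chrS": f"A{five}{centre}{three}A"}
                labels.add(classify_96("chrS", 3, centre, alt, ref))
        assert labels == set(CATEGORIES)
        assert len(CATEGORIES) == 96

    def test_reference_mismatch_fails(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_96("chrS", 3, "T", "A", {"chrS": "AACAG"})

    def test_ambiguous_context_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            assert classify_96("chrS", 3, "C", "T", {"chrS": "ANCAG"}) is None


class TestBackground:
    def test_hand_enumerated_four_base_reference(self):
        bg = exome_triplet_background({"chrS": "ACGT"}, [("chrS", 0, 4)])
        # centres C (ACG) and G (CGT -> ACG after collapsing): 2 counts in one class
        assert bg["ACG"] == 2.0
        assert bg["CGT"] == 2.0  # mirrored purine-centred slot
        assert sum(v for k, v in bg.items() if k[1] in "CT") == 2.0

    def test_poly_a_reference_collapses_to_ttt_class(self):
        # purine-centred AAA pools into its reverse complement TTT
        bg = exome_triplet_background({"chrS": "AAAAAA"}, [("chrS", 0, 6)])
        assert bg["TTT"] == 4.0 and bg["AAA"] == 4.0

    def test_reference_without_unambiguous_triplets_fails(self):
        with pytest.raises(ValueError, match="pyrimidine"):
            exome_triplet_background({"chrS": "NNNNNN"}, [("chrS", 0, 6)])

    def test_uniform_random_reference_near_uniform_background(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        bg = exome_triplet_background({"chrS": seq}, [("chrS", 0, 30_000)])
        pyr = np.array([v for k, v in bg.items() if k[1] in "CT"])
        from scipy import stats

        chi2, p = stats.chisquare(pyr)
        assert p > 0.001

    def test_out_of_bounds_target_fails(self):
        with pytest.raises(ValueError, match="bounds"):
            exome_triplet_background({"chrS": "ACGT"}, [("chrS", 0, 10)])

    def test_empty_targets_fail(self):
        with pytest.raises(ValueError, match="no target"):
            exome_triplet_background({"chrS": "ACGT"}, [])


class TestNormalize:
    def test_uniform_background_reduces_to_proportions(self):
        counts = np.zeros(96)
        counts[0] = 3
        counts[50] = 1
        bg = {k: 10.0 for k in exome_triplet_background({"chrS": "ACGTACGTAC"}, [("chrS", 0, 10)])}
        out = normalize_spectrum(counts, bg)
        np.testing.assert_allclose(out, counts / counts.sum())

    def test_background_scale_invariance(self):
        counts = np.zeros(96)
        counts[[3, 17, 80]] = [5, 2, 1]
        bg1 = {k: float(10 + (hash(k) % 7)) for k in _all_triplets()}
        bg2 = {k: 2.0 * v for k, v in bg1.items()}
        np.testing.assert_allclose(
            normalize_spectrum(counts, bg1), normalize_spectrum(counts, bg2)
        )

    def test_rare_context_upweighted(self):
        counts = np.zeros(96)
        i_aca = CATEGORIES.index("A[C>A]A")
        i_gcg = CATEGORIES.index("G[C>A]G")
        counts[[i_aca, i_gcg]] = [5, 5]
        bg = {k: 100.0 for k in _all_triplets()}
        bg["GCG"] = bg["CGC"] = 10.0  # rare context
        out = normalize_spectrum(counts, bg)
        # equal raw counts, but the rare-context category dominates: 5/10 vs 5/100
        assert out[i_gcg] == pytest.approx(10 * out[i_aca])

    def test_zero_background_with_nonzero_count_fails(self):
        counts = np.zeros(96)
        counts[0] = 1
        bg = {k: 1.0 for k in _all_triplets()}
        bg["ACA"] = bg["TGT"] = 0.0
        with pytest.raises(ValueError, match="absent"):
            normalize_spectrum(counts, bg)


def _all_triplets():
    return ["".join(t) for t in itertools.product("ACGT", repeat=3)]


class TestCosine:
    def test_identical_vectors(self):
        v = np.arange(1.0, 97.0)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        u = np.zeros(96)
        v = np.zeros(96)
        u[:48] = 1
        v[48:] = 1
        assert cosine_similarity(u, v) == 0.0

    def test_closed_form_half(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_vector_fails(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestSimilarityReport:
    def _spectrum(self, idx_weights):
        counts = np.zeros(96)
        for i, w in idx_weights.items():
            counts[i] = w
        return TripletSpectrum(counts)

    def test_single_patient_still_defined(self):
        spectra = {"P1": {"central": self._spectrum({0: 5}), "peripheral": self._spectrum({0: 3})}}
        rep = similarity_report(spectra)
        assert rep.cross_patient.shape == (1, 1)
        assert rep.merged == pytest.approx(1.0)
        assert rep.per_patient["P1"] == pytest.approx(1.0)

    def test_empty_stratum_reported_missing_not_zero(self):
        spectra = {
            "P1": {"central": self._spectrum({0: 5}), "peripheral": self._spectrum({})},
            "P2": {"central": self._spectrum({1: 5}), "peripheral": self._spectrum({1: 2})},
        }
        rep = similarity_report(spectra)
        assert rep.missing == ["P1"]
        assert np.isnan(rep.per_patient["P1"])
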