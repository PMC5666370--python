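"""Deconvolution, mass assignment and b/y fragment-confirmation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venompep.precursor import MaturePeptideCandidate
from venompep.spectrum import (
    MatchTolerance,
    ObservedMass,
    PeakList,
    charge_project,
    deconvolute,
    fragment_ions,
    match_masses,
    score_msms,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


class TestDeconvolution:
    @pytest.mark.parametrize("mz, z", [(1031.5520, 2), (688.0371, 3)])
    def test_multiply_protonated_ion_gives_neutral_mass(self, mz, z):
        assert deconvolute(mz, z) == pytest.approx(2061.0895, abs=5e-4)

    @given(
        m=st.floats(min_value=100.0, max_value=20000.0),
        z=st.integers(min_value=1, max_value=8),
    )
    def test_round_trip_to_1e9(self, m, z):
        assert abs(deconvolute(charge_project(m, z), z) - m) < 1e-9

    def test_nonpositive_charge_is_error(self):
        with pytest.raises(ValueError, match="charge"):
            deconvolute(500.0, 0)


def _cand(seq, c_term="free_acid", pid="p"):
    return MaturePeptideCandidate(parent_id=pid, sequence=seq, c_term=c_term)


class TestMatchMasses:
    def test_close_mass_is_unique_within_half_ppm(self):
        cand = _cand("GILDWGKKVMDWIKDKM", "amide")
        [a] = match_masses([ObservedMass(mass=2061.089)], [cand])
        assert a.status == "unique"
        assert a.best.error_da == pytest.approx(-0.001, abs=5e-4)
        assert abs(a.best.error_ppm) < 1.0

    def test_no_candidate_within_tolerance_stays_unassigned(self, plp_candidates):
        [a] = match_masses([ObservedMass(mass=6367.557, label="Om6368")], plp_candidates)
        assert a.status == "unassigned" and not a.hits

    def test_equidistant_candidates_are_ambiguous_with_both_listed(self):
        c1, c2 = _cand("GWKSDFLHTE"), _cand("GWKSDFLHET")  # same composition
        m = c1.mass
        [a] = match_masses([ObservedMass(mass=m)], [c1, c2])
        assert a.status == "ambiguous" and len(a.hits) == 2

    def test_empty_candidate_list_warns_and_unassigns(self):
        with pytest.warns(UserWarning, match="empty candidate"):
            [a] = match_masses([ObservedMass(mass=1000.0)], [])
        assert a.status == "unassigned"

    def test_every_observed_mass_gets_exactly_one_assignment(self, plp_candidates, venom_observed):
        assignments = match_masses(venom_observed, plp_candidates)
        assert len(assignments) == len(venom_observed)
        assert {a.observed.label for a in assignments} == {o.label for o in venom_observed}

    def test_output_sorted_by_retention_time(self, plp_candidates, venom_observed):
        assignments = match_masses(venom_observed, plp_candidates)
        rts = [a.observed.rt for a in assignments]
        assert rts == sorted(rts)

    def test_shrinking_tolerance_never_assigns_more(self):
        rng = np.random.default_rng(7)
        cands = [_cand("".join(rng.choice(list("GAKLVSTE"), size=12))) for _ in range(20)]
        observed = [
            ObservedMass(mass=float(c.mass * (1 + rng.normal(0, 5e-6)))) for c in cands
        ] + [ObservedMass(mass=float(rng.uniform(800, 1400))) for _ in range(10)]
        counts = []
        for ppm in (50.0, 20.0, 10.0, 5.0, 2.0, 0.5):
            asg = match_masses(observed, cands, MatchTolerance(ppm=ppm, da_floor=0.0001))
            counts.append(sum(a.status != "unassigned" for a in asg))
        assert counts == sorted(counts, reverse=True)

    def test_loose_window_flags_near_miss(self):
        cand = _cand("IWGALLGTLIPAITSAIQ")  # 1837.071
        tol = MatchTolerance(ppm=10, da_floor=0.02, loose_da=0.1)
        [a] = match_masses([ObservedMass(mass=1836.995)], [cand], tol)
        assert a.status == "unique" and a.loose_only
        [a] = match_masses([ObservedMass(mass=1836.995)], [cand])
        assert a.status == "unassigned"


class TestFragmentIons:
    def test_b2_and_y1_of_short_peptide(self):
        ions = dict(fragment_ions(_cand("GWGSLFK")))
        assert ions["b2"] == pytest.approx(244.108, abs=1e-3)
        assert ions["y1"] == pytest.approx(147.113, abs=1e-3)

    def test_ion_count_is_2n_minus_2_per_charge(self):
        for z in (1, 2):
            ions = fragment_ions(_cand("GWGSLFKTVGKM"), max_charge=z)
            assert len(ions) == 2 * (12 - 1) * z

    def test_amidation_shifts_y_ions_only(self):
        free = dict(fragment_ions(_cand("GWGSLFK")))
        amide = dict(fragment_ions(_cand("GWGSLFK", "amide")))
        for i in range(1, 7):
            assert amide[f"b{i}"] == pytest.approx(free[f"b{i}"], abs=1e-9)
            assert amide[f"y{i}"] == pytest.approx(free[f"y{i}"] - 0.98402, abs=1e-4)

    def test_doubly_charged_ions_follow_projection(self):
        singles = dict(fragment_ions(_cand("GWGSLFK"), max_charge=2))
        neutral_b2 = singles["b2"] - 1.00727646
        assert singles["b2+2"] == pytest.approx((neutral_b2 + 2 * 1.00727646) / 2, abs=1e-9)

    def test_homodimer_rejected(self):
        cand = MaturePeptideCandidate(
            parent_id="x", sequence="GWCSLFK", multimer="disulfide_homodimer"
        )
        with pytest.raises(ValueError, match="monomer"):
            fragment_ions(cand)


def _peaklist_for(cand, keep_fraction=1.0, rng=None):
    ions = fragment_ions(cand)
    rng = rng or np.random.default_rng(0)
    peaks = [
        (mz, 50.0) for _lbl, mz in ions if keep_fraction >= 1.0 or rng.random() < keep_fraction
    ]
    return PeakList(
        peaks=tuple(peaks),
        precursor_mz=charge_project(cand.mass, 2),
        precursor_charge=2,
        rt=10.0,
        id="t",
    )


class TestScoreMsms:
    def test_noiseless_self_spectrum_matches_fully(self):
        cand = _cand("GWGSLFK")
        a = score_msms(_peaklist_for(cand), cand)
        assert a.matched_fraction == 1.0

    def test_decoy_of_equal_mass_scores_strictly_lower(self):
        # composition-preserving shuffles keep the precursor mass but break
        # the fragment series
        true = _cand("GWGSLFKTVGKMIAKAAVKE")
        spectrum = _peaklist_for(true)
        rng = np.random.default_rng(11)
        full = score_msms(spectrum, true).matched_fraction
        for _ in range(10):
            shuffled = "".join(rng.permutation(list(true.sequence)))
            if shuffled == true.sequence:
                continue
            decoy = _cand(shuffled)
            assert score_msms(spectrum, decoy).matched_fraction < full

    def test_half_dropout_matches_about_half(self):
        cand = _cand("GWGSLFKTVGKMIAKAAVKEGILDWGKKVM")
        rng = np.random.default_rng(3)
        fractions = [
            score_msms(_peaklist_for(cand, keep_fraction=0.5, rng=rng), cand).matched_fraction
            for _ in range(20)
        ]
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.1)

    def test_empty_peak_list_flags_zero_matches(self):
        cand = _cand("GWGSLFK")
        empty = PeakList(
            peaks=(), precursor_mz=charge_project(cand.mass, 2), precursor_charge=2
        )
        with pytest.warns(UserWarning, match="empty"):
            a = score_msms(empty, cand)
        assert a.matched_ions == 0 and a.status == "unassigned"

    def test_wrong_precursor_mass_is_an_error(self):
        cand = _cand("GWGSLFK")
        bad = PeakList(peaks=((147.113, 1.0),), precursor_mz=500.0, precursor_charge=1)
        with pytest.raises(ValueError, match="tolerance"):
            score_msms(bad, cand)
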