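"""Precursor matching, neutral-loss scoring and candidate ranking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depsimatch.annotate import (
    FLAG_PRECURSOR_ONLY_ISOBARIC,
    AnnotationError,
    EmptyLibraryError,
    FragmentSpectrum,
    InvalidDepthError,
    InvalidToleranceError,
    Observation,
    annotate,
    expected_loss_masses,
    expected_losses,
    match_precursor,
    score_spectrum,
)
from depsimatch.chem import adduct_mz
from depsimatch.library import composition_from_key

BEA = composition_from_key("Hiv,Hiv,Hiv|161,161,161")
COMPOUND_TEN = composition_from_key("Hiv,Hiv,Hiv|113,127,161")
TEN_ISOBAR = composition_from_key("Hiv,Hiv,Hmp|113,113,161")


def _loss_spectrum(composition, losses, adduct="sodium"):
    precursor = adduct_mz(composition.mass, adduct)
    return FragmentSpectrum(
        precursor_mz=precursor,
        peaks=tuple((precursor - loss, 100.0) for loss in losses),
        precursor_adduct=adduct,
    )


# ---------------------------------------------------------------------------
# precursor matching
# ---------------------------------------------------------------------------

def test_isobaric_candidates_for_compound_ten_precursor(library):
    hits = match_precursor(702.4344, ("proton",), library, tol_ppm=5.0)
    keys = {h.composition.key for h in hits}
    assert len(keys) >= 2
    assert {COMPOUND_TEN.key, TEN_ISOBAR.key} <= keys


def test_ammoniated_beauvericin_matches(library):
    hits = match_precursor(801.4426, ("ammonium",), library, tol_ppm=5.0)
    assert BEA.key in {h.composition.key for h in hits}


def test_mass_outside_library_matches_nothing(library):
    assert match_precursor(500.0, ("proton", "ammonium", "sodium"), library) == []


def test_matcher_preconditions(library):
    with pytest.raises(EmptyLibraryError):
        match_precursor(800.0, ("proton",), [])
    with pytest.raises(InvalidToleranceError):
        match_precursor(800.0, ("proton",), library, tol_ppm=0.0)


# ---------------------------------------------------------------------------
# expected losses
# ---------------------------------------------------------------------------

def test_beauvericin_single_residue_losses():
    masses = expected_loss_masses(BEA, depth=1)
    assert masses == pytest.approx((100.0524, 161.0841), abs=5e-4)


def test_compound_ten_single_residue_losses():
    masses = expected_loss_masses(COMPOUND_TEN, depth=1)
    assert masses == pytest.approx((100.0524, 113.0841, 127.0997, 161.0841), abs=5e-4)


@pytest.mark.parametrize("comp", [BEA, COMPOUND_TEN, TEN_ISOBAR])
def test_loss_sets_nest_with_depth(comp):
    d1 = set(expected_loss_masses(comp, 1))
    d2 = set(expected_loss_masses(comp, 2))
    d3 = set(expected_loss_masses(comp, 3))
    assert d1 <= d2 <= d3


def test_invalid_depth_rejected():
    with pytest.raises(InvalidDepthError):
        expected_losses(BEA, depth=0)
    with pytest.raises(InvalidDepthError):
        expected_losses(BEA, depth=4)


# ---------------------------------------------------------------------------
# spectrum scoring
# ---------------------------------------------------------------------------

def test_full_coverage_for_beauvericin_losses():
    spec = _loss_spectrum(BEA, [161.084, 100.052])
    score = score_spectrum(spec, BEA, frag_tol=0.01)
    assert score.coverage == 1.0
    assert score.explained == 2


def test_diagnostic_losses_resolve_compound_ten_from_isobar():
    """Observed losses 100/113/127/161 fit {3 Hiv;113,127,161} fully but
    leave the isobaric {2 Hiv,Hmp;113,113,161} without Hmp evidence and
    with an unexplainable -127 Da loss."""
    losses = [100.0524, 113.0841, 127.0997, 161.0841]
    spec = _loss_spectrum(COMPOUND_TEN, losses)
    assert score_spectrum(spec, COMPOUND_TEN, 0.01).coverage == 1.0
    rival = score_spectrum(spec, TEN_ISOBAR, 0.01)
    assert rival.coverage < 1.0
    assert rival.explained < 4


def test_unmatched_or_absent_spectrum_scores_zero():
    spec = _loss_spectrum(BEA, [55.5, 77.7])
    assert score_spectrum(spec, BEA, 0.01).coverage == 0.0
    assert score_spectrum(None, BEA, 0.01).coverage == 0.0


def test_fragment_tolerance_must_be_positive():
    spec = _loss_spectrum(BEA, [100.052])
    with pytest.raises(InvalidToleranceError):
        score_spectrum(spec, BEA, frag_tol=0.0)


_ALL_TEN_LOSSES = tuple(e.mass for e in expected_losses(COMPOUND_TEN, 2))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    subset=st.lists(
        st.sampled_from(range(len(_ALL_TEN_LOSSES))), unique=True, min_size=1
    ),
    extra=st.lists(
        st.sampled_from(range(len(_ALL_TEN_LOSSES))), unique=True, min_size=1
    ),
)
def test_coverage_monotone_in_observed_peaks(subset, extra):
    """Adding fragment peaks never lowers the coverage score."""
    losses = [_ALL_TEN_LOSSES[i] for i in subset]
    more = losses + [_ALL_TEN_LOSSES[i] for i in extra if i not in subset]
    base = score_spectrum(_loss_spectrum(COMPOUND_TEN, losses), COMPOUND_TEN, 0.01)
    grown = score_spectrum(_loss_spectrum(COMPOUND_TEN, more), COMPOUND_TEN, 0.01)
    assert grown.coverage >= base.coverage


# ---------------------------------------------------------------------------
# end-to-end annotation
# ---------------------------------------------------------------------------

def test_compound_ten_inference(library, registry):
    """Precursor 702.4344 [M+H]+ plus losses 100/113/127/161 identifies the
    previously unreported analogue {3 Hiv; 113,127,161} uniquely."""
    spec = _loss_spectrum(COMPOUND_TEN, [100.0524, 113.0841, 127.0997, 161.0841])
    obs = Observation(mz=702.4344, adducts=("proton",), spectrum=spec)
    ann = annotate(obs, library, registry=registry)
    assert ann.status == "assigned"
    assert ann.top.composition == COMPOUND_TEN
    assert ann.top.names == ("BEAE *",)
    assert ann.top.coverage == 1.0
    runner_up = ann.candidates[1]
    assert runner_up.coverage < 1.0


def test_precursor_only_isobaric_flagged(library, registry):
    """Without fragments, an ion whose formula group has several members is
    flagged unresolved (beauvericin's C45H57N3O9 group has two members)."""
    obs = Observation(mz=801.4426, adducts=("ammonium",))
    ann = annotate(obs, library, registry=registry)
    assert ann.top.names == ("BEA",)
    assert FLAG_PRECURSOR_ONLY_ISOBARIC in ann.flags


def test_unmatched_observation_is_unassigned(library, registry):
    ann = annotate(Observation(mz=500.0), library, registry=registry)
    assert ann.status == "unassigned"
    assert ann.candidates == ()


def test_annotation_is_deterministic(library, registry):
    spec = _loss_spectrum(COMPOUND_TEN, [100.0524, 127.0997])
    obs = Observation(mz=702.4344, spectrum=spec)
    first = annotate(obs, library, registry=registry)
    second = annotate(obs, library, registry=registry)
    assert [c.composition.key for c in first.candidates] == [
        c.composition.key for c in second.candidates
    ]
    assert first == second


def test_candidates_sorted_by_coverage_then_ppm(library, registry):
    spec = _loss_spectrum(COMPOUND_TEN, [100.0524, 113.0841, 127.0997, 161.0841])
    obs = Observation(mz=702.4344, adducts=("proton",), spectrum=spec)
    ann = annotate(obs, library, registry=registry)
    coverages = [c.coverage for c in ann.candidates]
    assert coverages == sorted(coverages, reverse=True)


def test_isobaric_compositions_have_distinct_loss_ladders(library):
    """Every pair of compositions sharing a neutral formula differs in its
    depth-2 expected-loss mass set (depth-1 alone does not always separate:
    some CH2-transfer pairs share identical single-residue loss sets)."""
    from depsimatch.library import isobaric_groups

    for members in isobaric_groups(library).values():
        for a, b in zip(members, members[1:]):
            set_a = {round(m, 4) for m in expected_loss_masses(a, 2)}
            set_b = {round(m, 4) for m in expected_loss_masses(b, 2)}
            assert set_a != set_b, (a.key, b.key)


def test_noiseless_spectra_separate_every_library_composition(library, registry):
    """Given a complete noiseless loss ladder, the annotator ranks the true
    composition first for all 100 library members, including every isobaric
    group member."""
    import numpy as np

    from depsimatch.simulate import NOISELESS, simulate_observation

    rng = np.random.default_rng(0)
    for comp in library:
        obs = simulate_observation(comp, NOISELESS, rng)
        ann = annotate(obs, library, registry=registry)
        assert ann.top.composition == comp, comp.key


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def test_observation_validation():
    with pytest.raises(AnnotationError):
        Observation(mz=-1.0)
    with pytest.raises(AnnotationError):
        Observation(mz=800.0, adducts=())


def test_fragment_spectrum_validation():
    with pytest.raises(AnnotationError):
        FragmentSpectrum(precursor_mz=800.0, peaks=())
    with pytest.raises(AnnotationError):
        FragmentSpectrum(precursor_mz=800.0, peaks=((900.0, 1.0),))
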