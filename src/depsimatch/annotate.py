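"""Precursor matching and neutral-loss scoring of candidate compositions.

The identification logic mirrors how cyclodepsipeptide analogues are
assigned from LC-HRMS data: a precursor ion is matched against the
enumerated composition library within a ppm tolerance under one or more
adduct hypotheses ([M+H]+, [M+NH4]+, [M+Na]+), and isobaric ambiguity is
then resolved by comparing the neutral losses observed in the product-ion
spectrum of the sodiated ion with the losses expected from each candidate's
residues (single residues and cumulative two-residue losses by default:
-161 Da for N-Me-Phe, -127 for N-Me-Leu/Ile, -113 for N-Me-Val/Leu,
-100 for D-Hiv, -114 for D-Hmp, -86 for D-Hbu, plus their pairwise sums).

Candidate ranking
-----------------
Candidates are ordered by

1. residue-class coverage (descending) — fraction of a candidate's residue
   classes evidenced by at least one observed loss;
2. number of observed losses the candidate explains (descending);
3. absolute precursor ppm error (ascending);
4. registry-named candidates before systematic (unnamed) ones;
5. canonical composition key (ascending) as the final deterministic tie-break.

An observed loss that matches several expected sub-multisets of a candidate
(cumulative losses can be exactly isomeric, e.g. Hiv+127 and Hmp+113 are
both C12H21NO3) only evidences the residue classes common to *all* matching
explanations: an ambiguous loss proves no more than what every explanation
agrees on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .chem import ADDUCT_NAMES, adduct_mz, get_adduct, ppm_error
from .library import Composition, CompoundRegistry, RegistryEntry, SYSTEMATIC


class AnnotationError(ValueError):
    """Base class for annotator errors."""


class EmptyLibraryError(AnnotationError):
    """Precursor matching was asked to run against an empty library."""


class InvalidDepthError(AnnotationError):
    """Cumulative-loss depth outside the supported range {1, 2, 3}."""


class InvalidToleranceError(AnnotationError):
    """A matching tolerance is not strictly positive."""


@dataclass(frozen=True)
class FragmentSpectrum:
    """Product-ion spectrum of one precursor (sodiated ion by default)."""

    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]
    precursor_adduct: str = "sodium"

    def __post_init__(self):
        if not self.peaks:
            raise AnnotationError("fragment spectrum must contain at least one peak")
        peaks = tuple((float(mz), float(inten)) for mz, inten in self.peaks)
        if any(mz <= 0 or mz >= self.precursor_mz for mz, _ in peaks):
            raise AnnotationError(
                "fragment m/z values must lie in (0, precursor m/z)"
            )
        get_adduct(self.precursor_adduct)
        object.__setattr__(self, "peaks", peaks)

    @property
    def losses(self) -> tuple[float, ...]:
        """Observed neutral losses, precursor m/z minus each fragment m/z."""
        return tuple(self.precursor_mz - mz for mz, _ in self.peaks)


@dataclass(frozen=True)
class Observation:
    """One precursor ion with optional retention time and fragment data."""

    mz: float
    intensity: float = 1.0
    rt: float | None = None
    adducts: tuple[str, ...] = ADDUCT_NAMES
    spectrum: FragmentSpectrum | None = None
    obs_id: str = ""

    def __post_init__(self):
        if self.mz <= 0:
            raise AnnotationError(f"precursor m/z must be positive, got {self.mz}")
        adducts = tuple(self.adducts)
        if not adducts:
            raise AnnotationError("at least one adduct hypothesis is required")
        for name in adducts:
            get_adduct(name)
        object.__setattr__(self, "adducts", adducts)


@dataclass(frozen=True)
class ExpectedLoss:
    """One expected neutral loss: a non-empty sub-multiset of residues."""

    mass: float
    residue_ids: tuple[str, ...]
    classes: frozenset[str]


@lru_cache(maxsize=4096)
def _expected_losses_cached(c: Composition, depth: int) -> tuple[ExpectedLoss, ...]:
    residues = c.residues
    seen: dict[tuple[str, ...], ExpectedLoss] = {}
    for size in range(1, depth + 1):
        for indices in combinations(range(len(residues)), size):
            subset = tuple(sorted(residues[i].id for i in indices))
            if subset in seen:
                continue
            mass = sum(residues[i].mass for i in indices)
            seen[subset] = ExpectedLoss(
                mass=mass, residue_ids=subset, classes=frozenset(subset)
            )
    return tuple(sorted(seen.values(), key=lambda e: (e.mass, e.residue_ids)))


def expected_losses(c: Composition, depth: int = 2) -> tuple[ExpectedLoss, ...]:
    """Expected losses of ``c``: all residue sub-multisets of size <= depth.

    Depth 1 yields the distinct single-residue class losses; depth 2 adds
    the dipeptidol-like pair losses seen in sodiated-ion loss ladders.
    """
    if depth not in (1, 2, 3):
        raise InvalidDepthError(f"loss depth must be 1, 2 or 3, got {depth}")
    return _expected_losses_cached(c, depth)


def expected_loss_masses(c: Composition, depth: int = 2) -> tuple[float, ...]:
    """Sorted distinct expected-loss masses (Da)."""
    return tuple(sorted({e.mass for e in expected_losses(c, depth)}))


@dataclass(frozen=True)
class LossMatch:
    """An observed loss explained by one or more expected sub-multisets."""

    observed_loss: float
    expected_masses: tuple[float, ...]
    residue_classes: tuple[str, ...]  # classes evidenced (intersection rule)
    tolerance: float


@dataclass(frozen=True)
class SpectrumScore:
    """Loss-coverage score of one candidate for one spectrum.

    ``diagnostic_recall`` is the fraction of the candidate's *expected*
    single-residue (depth-1) losses that are actually observed; a candidate
    whose predicted diagnostic losses are absent is less supported even
    when every observed loss has some explanation.
    """

    coverage: float
    matches: tuple[LossMatch, ...]
    diagnostic_recall: float = 0.0

    @property
    def explained(self) -> int:
        """Number of observed fragment peaks explained by the candidate."""
        return len(self.matches)

    def __iter__(self):  # allow ``coverage, matches = score``
        yield self.coverage
        yield self.matches


def score_spectrum(
    spectrum: FragmentSpectrum | None,
    c: Composition,
    frag_tol: float = 0.01,
    depth: int = 2,
) -> SpectrumScore:
    """Score how well observed neutral losses evidence a candidate.

    Coverage is the fraction of the candidate's distinct residue classes
    evidenced by at least one observed loss; an absent or unmatched
    spectrum scores 0 with no matches (not an error).
    """
    if frag_tol <= 0:
        raise InvalidToleranceError(f"fragment tolerance must be > 0, got {frag_tol}")
    class_ids = c.residue_class_ids
    if spectrum is None:
        return SpectrumScore(0.0, (), 0.0)
    expected = expected_losses(c, depth)
    matches: list[LossMatch] = []
    evidenced: set[str] = set()
    for observed in spectrum.losses:
        hits = [e for e in expected if abs(observed - e.mass) <= frag_tol]
        if not hits:
            continue
        common: frozenset[str] = hits[0].classes
        for hit in hits[1:]:
            common = common & hit.classes
        evidenced.update(common)
        matches.append(
            LossMatch(
                observed_loss=observed,
                expected_masses=tuple(sorted({h.mass for h in hits})),
                residue_classes=tuple(sorted(common)),
                tolerance=frag_tol,
            )
        )
    coverage = len(evidenced & class_ids) / len(class_ids)
    singles = expected_loss_masses(c, 1)
    observed = spectrum.losses
    recalled = sum(
        1 for mass in singles if any(abs(o - mass) <= frag_tol for o in observed)
    )
    return SpectrumScore(coverage, tuple(matches), recalled / len(singles))


@dataclass(frozen=True)
class PrecursorMatch:
    """A (composition, adduct) pair matching an observed precursor m/z."""

    composition: Composition
    adduct: str
    theoretical_mz: float
    ppm: float


def match_precursor(
    mz: float,
    adducts: Sequence[str],
    library: Sequence[Composition],
    tol_ppm: float = 5.0,
) -> list[PrecursorMatch]:
    """All library (composition, adduct) pairs within ``tol_ppm`` of ``mz``."""
    if tol_ppm <= 0:
        raise InvalidToleranceError(f"precursor tolerance must be > 0, got {tol_ppm}")
    if not library:
        raise EmptyLibraryError("cannot match against an empty composition library")
    hits = []
    for comp in library:
        neutral = comp.mass
        for adduct in adducts:
            theo = adduct_mz(neutral, adduct)
            err = ppm_error(mz, theo)
            if abs(err) <= tol_ppm:
                hits.append(
                    PrecursorMatch(
                        composition=comp, adduct=adduct, theoretical_mz=theo, ppm=err
                    )
                )
    hits.sort(key=lambda h: (abs(h.ppm), h.composition.key, h.adduct))
    return hits


@dataclass(frozen=True)
class Candidate:
    """One ranked candidate in an annotation."""

    composition: Composition
    adduct: str
    theoretical_mz: float
    ppm: float
    coverage: float
    matches: tuple[LossMatch, ...]
    explained: int
    diagnostic_recall: float
    names: tuple[str, ...]
    isomer_group: str
    confidence: str

    @property
    def display_name(self) -> str:
        return "/".join(self.names)


UNASSIGNED = "unassigned"
ASSIGNED = "assigned"

FLAG_PRECURSOR_ONLY_ISOBARIC = "precursor-only; isobaric candidates unresolved"
FLAG_TIE_UNRESOLVED = "fragment evidence tied; resolved by registry/canonical order"


@dataclass(frozen=True)
class Annotation:
    """Ranked candidate compositions for one observation."""

    observation: Observation
    candidates: tuple[Candidate, ...]
    status: str
    flags: tuple[str, ...] = ()

    @property
    def top(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None

    @property
    def is_ambiguous(self) -> bool:
        return bool(self.flags)


def _abs_ppm(candidate: Candidate) -> float:
    # quantized so that isobaric candidates (identical formula, float
    # summation order aside) compare as exact ties
    return round(abs(candidate.ppm), 4)


def _rank_key(candidate: Candidate, with_spectrum: bool):
    registry_rank = 0 if candidate.confidence != SYSTEMATIC else 1
    if with_spectrum:
        return (
            -candidate.coverage,
            -candidate.explained,
            _abs_ppm(candidate),
            -candidate.diagnostic_recall,
            registry_rank,
            candidate.composition.key,
        )
    return (_abs_ppm(candidate), registry_rank, candidate.composition.key)


def annotate(
    obs: Observation,
    library: Sequence[Composition],
    registry: CompoundRegistry | None = None,
    tol_ppm: float = 5.0,
    frag_tol: float = 0.01,
    depth: int = 2,
) -> Annotation:
    """Match one observation against the library and rank the candidates."""
    registry = registry or CompoundRegistry.default()
    precursor_hits = match_precursor(obs.mz, obs.adducts, library, tol_ppm)
    if not precursor_hits:
        return Annotation(observation=obs, candidates=(), status=UNASSIGNED)

    has_spectrum = obs.spectrum is not None
    candidates = []
    for hit in precursor_hits:
        entry: RegistryEntry = registry.lookup(hit.composition)
        score = score_spectrum(obs.spectrum, hit.composition, frag_tol, depth)
        candidates.append(
            Candidate(
                composition=hit.composition,
                adduct=hit.adduct,
                theoretical_mz=hit.theoretical_mz,
                ppm=hit.ppm,
                coverage=score.coverage,
                matches=score.matches,
                explained=score.explained,
                diagnostic_recall=score.diagnostic_recall,
                names=entry.names,
                isomer_group=entry.isomer_group,
                confidence=entry.confidence,
            )
        )
    candidates.sort(key=lambda c: _rank_key(c, has_spectrum))

    flags: list[str] = []
    top = candidates[0]
    top_formula = str(top.composition.formula)
    group = {
        c.composition.key
        for c in candidates
        if str(c.composition.formula) == top_formula
    }
    if not has_spectrum and len(group) > 1:
        flags.append(FLAG_PRECURSOR_ONLY_ISOBARIC)
    if has_spectrum and len(candidates) > 1:
        second = candidates[1]
        tied = (
            top.coverage == second.coverage
            and top.explained == second.explained
            and _abs_ppm(top) == _abs_ppm(second)
            and top.diagnostic_recall == second.diagnostic_recall
        )
        if tied:
            flags.append(FLAG_TIE_UNRESOLVED)
    return Annotation(
        observation=obs,
        candidates=tuple(candidates),
        status=ASSIGNED,
        flags=tuple(flags),
    )


def annotate_all(
    observations: Iterable[Observation],
    library: Sequence[Composition],
    spectra: Mapping[str, FragmentSpectrum] | None = None,
    registry: CompoundRegistry | None = None,
    tol_ppm: float = 5.0,
    frag_tol: float = 0.01,
    depth: int = 2,
) -> list[Annotation]:
    """Annotate many observations, attaching spectra by observation id."""
    registry = registry or CompoundRegistry.default()
    out = []
    for obs in observations:
        if obs.spectrum is None and spectra and obs.obs_id in spectra:
            obs = replace(obs, spectrum=spectra[obs.obs_id])
        out.append(
            annotate(
                obs,
                library,
                registry=registry,
                tol_ppm=tol_ppm,
                frag_tol=frag_tol,
                depth=depth,
            )
        )
    return out
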