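"""Seeded simulation of precursor observations and sodiated-ion loss spectra.

The generator emulates what the annotator sees in practice for these
compounds on a high-resolution instrument:

* one precursor ion per simulated compound, with the adduct drawn from an
  ammonium-dominant distribution (the ammoniated ion carries most of the
  signal in electrospray; protonated and sodiated ions are minor);
* multiplicative Gaussian mass noise expressed in ppm, matching how
  high-resolution mass accuracy is specified and reported;
* a fragment spectrum of the sodiated precursor built from the expected
  neutral-loss ladder (single residues and two-residue sums by default),
  with each expected peak detected with a fixed probability;
* uniform random decoy fragment peaks emulating chemical noise;
* log-normal intensities (irrelevant to scoring, exercised by the I/O).

All randomness flows from one :class:`numpy.random.Generator`, so a config
plus a seed reproduces a dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import (
    Annotation,
    FragmentSpectrum,
    Observation,
    annotate,
    expected_losses,
)
from .chem import adduct_mz, ppm_error
from .library import Composition, CompoundRegistry


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model and spectrum-generation settings.

    ``ppm_sigma`` is the standard deviation of the relative mass error in
    ppm (applied to precursors and fragments alike); ``adduct_probs`` the
    sampling weights of the precursor adduct; ``detection_prob`` the
    probability that any one expected loss peak is actually observed;
    ``n_decoys`` the number of uniform decoy peaks added per spectrum.
    """

    ppm_sigma: float = 2.0
    adduct_probs: Mapping[str, float] = field(
        default_factory=lambda: {"ammonium": 0.7, "proton": 0.2, "sodium": 0.1}
    )
    fragment_depth: int = 2
    detection_prob: float = 0.9
    n_decoys: int = 5
    decoy_mz_min: float = 150.0
    include_fragments: bool = True
    intensity_log_mean: float = 13.0
    intensity_log_sigma: float = 1.0

    def __post_init__(self):
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be >= 0")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must lie in [0, 1]")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        total = sum(self.adduct_probs.values())
        if total <= 0:
            raise ValueError("adduct probabilities must sum to > 0")


NOISELESS = SimulationConfig(ppm_sigma=0.0, detection_prob=1.0, n_decoys=0)
"""Idealised acquisition: exact masses, complete loss ladder, no decoys."""


def _jitter(value: float, ppm_sigma: float, rng: np.random.Generator) -> float:
    return value * (1.0 + rng.normal(0.0, ppm_sigma) / 1e6) if ppm_sigma > 0 else value


def simulate_observation(
    c: Composition,
    cfg: SimulationConfig = SimulationConfig(),
    rng: np.random.Generator | None = None,
    obs_id: str = "sim",
) -> Observation:
    """Simulate one precursor observation (and spectrum) of a composition."""
    obs, _ = _simulate_one(c, cfg, rng, obs_id)
    return obs


def _simulate_one(
    c: Composition,
    cfg: SimulationConfig,
    rng: np.random.Generator | None,
    obs_id: str,
) -> tuple[Observation, str]:
    rng = rng if rng is not None else np.random.default_rng(0)
    names = list(cfg.adduct_probs)
    weights = np.array([cfg.adduct_probs[n] for n in names], dtype=float)
    adduct = names[int(rng.choice(len(names), p=weights / weights.sum()))]

    neutral = c.mass
    mz = _jitter(adduct_mz(neutral, adduct), cfg.ppm_sigma, rng)
    intensity = float(
        np.exp(rng.normal(cfg.intensity_log_mean, cfg.intensity_log_sigma))
    )

    spectrum = None
    if cfg.include_fragments:
        sodiated = adduct_mz(neutral, "sodium")
        precursor_mz = _jitter(sodiated, cfg.ppm_sigma, rng)
        peaks: list[tuple[float, float]] = []
        for loss in expected_losses(c, cfg.fragment_depth):
            if rng.random() <= cfg.detection_prob:
                frag_mz = _jitter(sodiated - loss.mass, cfg.ppm_sigma, rng)
                frag_int = float(
                    np.exp(
                        rng.normal(
                            cfg.intensity_log_mean - 3.0, cfg.intensity_log_sigma
                        )
                    )
                )
                peaks.append((frag_mz, frag_int))
        for _ in range(cfg.n_decoys):
            decoy_mz = float(rng.uniform(cfg.decoy_mz_min, precursor_mz - 1.0))
            decoy_int = float(
                np.exp(rng.normal(cfg.intensity_log_mean - 5.0, cfg.intensity_log_sigma))
            )
            peaks.append((decoy_mz, decoy_int))
        if peaks:
            spectrum = FragmentSpectrum(
                precursor_mz=precursor_mz,
                peaks=tuple(sorted(peaks)),
                precursor_adduct="sodium",
            )
    obs = Observation(
        mz=mz,
        intensity=intensity,
        rt=None,
        adducts=("proton", "ammonium", "sodium"),
        spectrum=spectrum,
        obs_id=obs_id,
    )
    return obs, adduct


@dataclass(frozen=True)
class SimulatedRecord:
    """A simulated observation together with its ground truth."""

    observation: Observation
    composition: Composition
    adduct: str
    precursor_ppm: float  # realised signed ppm error of the precursor


def simulate_dataset(
    compositions: Sequence[Composition],
    cfg: SimulationConfig = SimulationConfig(),
    n_per_compound: int = 1,
    seed: int = 0,
) -> list[SimulatedRecord]:
    """Simulate ``n_per_compound`` observations for each composition."""
    if n_per_compound < 1:
        raise ValueError("n_per_compound must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    index = 0
    for comp in compositions:
        for _ in range(n_per_compound):
            obs, adduct = _simulate_one(comp, cfg, rng, obs_id=f"obs{index:05d}")
            records.append(
                SimulatedRecord(
                    observation=obs,
                    composition=comp,
                    adduct=adduct,
                    precursor_ppm=ppm_error(obs.mz, adduct_mz(comp.mass, adduct)),
                )
            )
            index += 1
    return records


@dataclass(frozen=True)
class RecoveryResult:
    """Top-1 assignment accuracy of the annotator on simulated data."""

    accuracy: float
    per_composition: Mapping[str, float]
    #: fraction of *assigned* observations whose top candidate could not be
    #: resolved from the available evidence (isobaric precursor-only matches
    #: or fully tied fragment scores)
    ambiguity_rate: float
    mean_ppm_error: float
    n_observations: int


def recovery_experiment(
    compositions: Sequence[Composition],
    cfg: SimulationConfig = SimulationConfig(),
    n_per_compound: int = 10,
    library: Sequence[Composition] | None = None,
    registry: CompoundRegistry | None = None,
    tol_ppm: float = 5.0,
    frag_tol: float = 0.01,
    depth: int = 2,
    seed: int = 0,
) -> RecoveryResult:
    """Simulate, annotate, and score top-1 accuracy against ground truth.

    ``library`` defaults to the full default enumeration, so recovery is
    tested against all isobaric competitors, not just the simulated truths.
    """
    from .library import enumerate_compositions

    library = list(library) if library is not None else enumerate_compositions()
    registry = registry or CompoundRegistry.default()
    records = simulate_dataset(compositions, cfg, n_per_compound, seed)

    correct: dict[str, int] = {c.key: 0 for c in compositions}
    totals: dict[str, int] = {c.key: 0 for c in compositions}
    ambiguous = 0
    assigned = 0
    ppm_errors = []
    for record in records:
        totals[record.composition.key] += 1
        ppm_errors.append(record.precursor_ppm)
        ann: Annotation = annotate(
            record.observation,
            library,
            registry=registry,
            tol_ppm=tol_ppm,
            frag_tol=frag_tol,
            depth=depth,
        )
        if ann.candidates:
            assigned += 1
            if ann.is_ambiguous:
                ambiguous += 1
        if ann.top is not None and ann.top.composition == record.composition:
            correct[record.composition.key] += 1
    n = len(records)
    per_composition = {
        key: correct[key] / totals[key] for key in totals if totals[key]
    }
    return RecoveryResult(
        accuracy=sum(correct.values()) / n,
        per_composition=per_composition,
        ambiguity_rate=(ambiguous / assigned) if assigned else 0.0,
        mean_ppm_error=float(np.mean(ppm_errors)),
        n_observations=n,
    )
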