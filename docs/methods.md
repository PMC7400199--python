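# Methods

## The analysis

Beauvericins (BEA), allobeauvericins (ALLOBEA), enniatins (ENN) and
beauvenniatins (BEAE) are cyclic hexadepsipeptides assembled from three
alternating hydroxy-acid and three N-methyl amino-acid residues.  Because
every analogue is a ring of six in-chain residues, its neutral monoisotopic
mass is the plain sum of the residue masses — no terminal water — and its
elemental formula is the element-wise sum of the residue formulas.  The
package models an analogue as a *composition*: an unordered multiset of
3 hydroxy-acid + 3 amino-acid residues.  Ring sequence and stereochemistry
are deliberately out of scope; positional isomers (e.g. BEA B vs
ALLOBEA B) are indistinguishable by mass spectrometry and share a single
registry entry.

### Building blocks

| id  | class       | in-chain formula | mass (Da)  | nominal loss | members              |
|-----|-------------|------------------|------------|--------------|----------------------|
| Hbu | hydroxy acid| C4H6O2           | 86.0368    | −86          | D-2-hydroxybutyric   |
| Hiv | hydroxy acid| C5H8O2           | 100.0524   | −100         | D-2-hydroxyisovaleric|
| Hmp | hydroxy acid| C6H10O2          | 114.0681   | −114         | 2-hydroxyisocaproic  |
| 113 | amino acid  | C6H11NO          | 113.0841   | −113         | N-Me-Val (≡ Leu)     |
| 127 | amino acid  | C7H13NO          | 127.0997   | −127         | N-Me-Leu / N-Me-Ile  |
| 161 | amino acid  | C10H11NO         | 161.0841   | −161         | N-Me-Phe             |

Amino residues are *mass classes*, not named amino acids: members of a
class share an in-chain formula and cannot be told apart by MS.  The six
nominal losses are exactly the diagnostic product-ion losses used to
assign residue content from sodiated-ion MS/MS spectra.

Enumerating all multisets of size 3 over each block set gives
C(5,2) × C(5,2) = 100 compositions spanning 34 distinct neutral formulas.
Compositions serialize canonically as e.g. `Hiv,Hiv,Hmp|113,113,161`
(residues ascending by mass within each part), so registries and reports
are diffable.

### Masses and adducts

Atomic masses are monoisotopic IUPAC/CODATA values (C = 12 exactly,
H = 1.00782503, N = 14.0030740, O = 15.9949146, Na = 22.9897693) stored in
a versioned plain-text table shipped with the package.  Singly charged
adduct ions are formed by adding the cation mass — the adduct formula mass
minus one electron mass (0.00054858 Da):

    m/z([M+X]+) = M + mass(X) − m_e,   X ∈ {H, NH4, Na}

Mass accuracy is expressed as the signed relative error

    ppm = (measured − theoretical) / theoretical × 1e6.

Under these constants the recomputed errors for the published survey ions
differ from the printed ones by up to ~0.9 ppm (the original instrument
software's constant set is unknown); all are well inside the 5 ppm
matching window.

### Annotation

1. **Precursor matching.**  An observed m/z is compared against every
   (composition, adduct-hypothesis) pair; candidates within the precursor
   tolerance (default 5 ppm, the usual extracted-ion-chromatogram window
   for this instrument class) are kept.  Compositions sharing a formula
   match together or not at all.
2. **Neutral-loss scoring.**  Losses are computed from the product-ion
   spectrum of the sodiated precursor (configurable), as precursor m/z
   minus fragment m/z.  Expected losses of a candidate are the mass sums
   of all non-empty residue sub-multisets up to depth 2 (single residues
   plus dipeptidol-like pairs — the ladder actually visible in these
   spectra; depth 3 is available but adds little and more degeneracy).
   *Coverage* is the fraction of the candidate's distinct residue classes
   evidenced by at least one observed loss.  An observed loss matching
   several expected sub-multisets (cumulative losses can be exactly
   isomeric: Hiv+127 ≡ Hmp+113 = C12H21NO3; 2×Hiv ≡ Hbu+Hmp = C10H16O4)
   evidences only the classes common to **all** matching explanations —
   an ambiguous loss proves no more than what every explanation agrees on.
3. **Ranking.**  Candidates sort by coverage (desc), number of observed
   losses explained (desc), |ppm| (asc, quantized to 1e-4 ppm so isobaric
   candidates tie exactly), diagnostic recall (desc; the fraction of the
   candidate's predicted single-residue losses actually observed — a
   candidate whose predicted diagnostic ions are absent is less
   supported), registry-named before systematic candidates (known natural
   products are a legitimate prior over hypothetical combinations), and
   finally the canonical key for determinism.

Precursor-only annotations whose formula group holds more than one
composition are flagged `precursor-only; isobaric candidates unresolved`;
fragment-scored annotations whose top two candidates tie on all evidence
are flagged as resolved only by the registry/canonical order.

With complete noiseless loss ladders this scheme ranks the true
composition first for **all 100** library members, including every member
of every isobaric group — the class-intersection rule plus the
explained-loss and diagnostic-recall criteria are each necessary for that;
class coverage alone cannot separate CH2-transfer isobars (several pairs
even share identical depth-1 loss sets, e.g. `Hiv,Hiv,Hmp|113,127,127` vs
`Hiv,Hmp,Hmp|113,113,127`).

### Tolerances and profiles

| parameter        | hrms default | iontrap default | meaning                          |
|------------------|--------------|-----------------|----------------------------------|
| precursor tol    | 5 ppm        | 300 ppm         | precursor matching window        |
| fragment tol     | 0.01 Da      | 0.3 Da          | loss matching window             |
| loss depth       | 2            | 2               | max residues per cumulative loss |

The ion-trap profile mirrors the unit-resolution screening runs these
compounds are first detected in; all headline numbers use the hrms
profile.

## The synthetic-data generator

`simulate_observation` emulates one high-resolution observation of a known
composition:

* adduct drawn from an ammonium-dominant distribution (defaults
  0.7 / 0.2 / 0.1 for NH4+ / H+ / Na+ — the ammoniated ion carries most of
  the electrospray signal for these compounds, the others a few percent);
* multiplicative Gaussian mass noise with standard deviation `ppm_sigma`
  (default 2 ppm, matching the magnitude of the published survey errors),
  applied to precursors and fragments alike — noise is modelled in ppm,
  not Da, because that is how high-resolution accuracy behaves and is
  reported;
* a sodiated-precursor fragment spectrum containing each expected loss
  (depth ≤ 2) with detection probability 0.9, plus 5 uniform decoy peaks
  in [150 Da, precursor − 1 Da] emulating chemical noise;
* log-normal intensities (exercised by I/O, ignored by scoring).

All randomness flows from a single seeded `numpy` generator: a config plus
a seed reproduces a dataset byte-identically through the writers.  The
`NOISELESS` configuration (sigma 0, detection probability 1, no decoys) is
the idealised acquisition used for exact round-trip checks.

What the generator does **not** emulate: chromatographic peak shape and
retention behaviour, isotope envelopes, in-source fragmentation,
intensity-dependent mass error, and fragment intensities with any
relationship to structure.  Passing recovery tests therefore demonstrate
the correctness of the matching/scoring logic under the stated noise
model, not performance on real chromatograms.

`recovery_experiment` simulates n observations per composition, annotates
each against the full 100-member library, and reports top-1 accuracy,
the ambiguity rate (fraction of *assigned* observations whose top
candidate was not resolved by the evidence), and the mean signed precursor
ppm error.  Typical problem sizes used by the test suite: 8 reference
compositions × 100 replicates at sigma 2 (accuracy ≈ 0.98 — residual
losses are almost entirely precursors drawn outside the 5 ppm window,
expected at ~1.2% for Gaussian noise at sigma 2), and 2 × 50 precursor-only
replicates of the C38H59N3O9 isobaric pair (ambiguity 1.0).

## Numerical choices

* Full float precision internally; m/z printed to 4 decimals in reports.
* |ppm| rank comparisons quantized to 1e-4 ppm: isobaric candidates'
  masses differ only by float summation order (~1e-10 Da) and must compare
  as exact ties.
* Loss matching is absolute (Da) because neutral-loss error is the
  difference of two nearly equal m/z errors and does not scale with mass.
* Degenerate inputs: empty residue sets, empty libraries, non-positive
  tolerances and out-of-range depths raise named errors; an absent or
  unmatched fragment spectrum scores 0 rather than erroring; malformed
  peak-list rows are skipped with line-numbered warnings.

## Known limitations

* Ring sequence, positional isomerism and stereochemistry are invisible:
  an isomer group is the finest reachable identification level.
* The registry follows the published elemental compositions where the
  descriptive text conflicts with them (BEA E, BEAE B, BEAE G1/G2/G3);
  the registry's note column records each discrepancy.
* A candidate is never penalised for expected losses that are absent
  (detection is probabilistic), so pathological spectra could still tie;
  ties are flagged and broken deterministically.
* Negative-ion mode, multiply charged ions and isotope patterns are out
  of scope.
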