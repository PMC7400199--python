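# depsimatch

Combinatorial enumeration and LC-HRMS/MS annotation of cyclic
hexadepsipeptides — beauvericins (BEA), allobeauvericins (ALLOBEA),
enniatins (ENN) and beauvenniatins (BEAE).

These fungal metabolites are rings of three alternating hydroxy-acid and
three N-methyl amino-acid residues.  Analogues differ only in residue
content, so an untargeted LC-HRMS survey can be annotated purely
computationally: enumerate every 3+3 residue multiset over the known
building blocks, compute each composition's neutral monoisotopic mass
(the plain residue-mass sum — the ring adds no water) and its
[M+H]⁺ / [M+NH₄]⁺ / [M+Na]⁺ adduct m/z, match observed precursors within a
ppm tolerance, and resolve *isobaric* compositions (distinct multisets
sharing one elemental formula) from the diagnostic neutral losses of
sodiated-ion product spectra: −161 Da (N-Me-Phe), −127 (N-Me-Leu/Ile),
−113 (N-Me-Val/Leu), −100 (D-Hiv), −114 (D-Hmp), −86 (D-Hbu).

The core quantities:

    m/z([M+X]⁺) = M + mass(X) − mₑ,          X ∈ {H, NH₄, Na}
    ppm         = (measured − theoretical) / theoretical × 10⁶
    coverage(c) = |residue classes of c evidenced by observed losses|
                  / |residue classes of c|

Who it is for: metabolomics / natural-products researchers screening
fungal extracts for depsipeptide analogues, and anyone needing a tested
reference implementation of adduct-mass arithmetic and neutral-loss-based
isobar resolution for this compound family.

See `docs/methods.md` for the full model, scoring rules and limitations.

## Worked example

```python
import depsimatch as dm

lib = dm.enumerate_compositions()
print(len(lib), "compositions,", len(dm.isobaric_groups(lib)), "formulas")

bea = dm.composition_from_key("Hiv,Hiv,Hiv|161,161,161")  # beauvericin
print("BEA", bea.formula, round(bea.mass, 4))
for adduct in ("proton", "ammonium", "sodium"):
    print(f"  [M+{adduct}]  {dm.adduct_mz(bea.mass, adduct):.4f}")
```

prints

```
100 compositions, 34 formulas
BEA C45H57N3O9 783.4095
  [M+proton]  784.4168
  [M+ammonium]  801.4433
  [M+sodium]  806.3987
```

— 100 enumerable compositions collapsing onto 34 neutral formulas, and
beauvericin's three adduct ions (the ammoniated ion, 801.4433, is the
dominant one in electrospray and sits 0.9 ppm from a typical measured
value of 801.4426).

Resolving an isobaric precursor with fragment evidence — a protonated ion
at m/z 702.4344 (formula C38H59N3O9) matches several compositions, but
observed losses of 100/113/127/161 Da single out one:

```python
truth = dm.composition_from_key("Hiv,Hiv,Hiv|113,127,161")
precursor = dm.adduct_mz(truth.mass, "sodium")
spectrum = dm.FragmentSpectrum(
    precursor_mz=precursor,
    peaks=tuple((precursor - loss, 100.0)
                for loss in (100.0524, 113.0841, 127.0997, 161.0841)),
)
obs = dm.Observation(mz=702.4344, adducts=("proton",), spectrum=spectrum)
ann = dm.annotate(obs, lib)
for cand in ann.candidates[:3]:
    print(f"{cand.display_name:<40s} coverage={cand.coverage:.2f} ppm={cand.ppm:+.1f}")
```

```
BEAE *                                   coverage=1.00 ppm=+2.8
cHD[Hbu,Hiv,Hiv|127,127,161]             coverage=0.75 ppm=+2.8
cHD[Hiv,Hiv,Hmp|113,113,161]             coverage=0.75 ppm=+2.8
```

Only `{3 Hiv; 113, 127, 161}` — the analogue registered as "BEAE \*" —
explains every loss and has all four of its residue classes evidenced;
the isobaric alternatives lack evidence for one residue class each and
cannot explain the −127 Da (or −113 Da) loss.

## Command line

```sh
depsimatch enumerate --out compositions.tsv      # the full 100-row library
depsimatch fixtures --out-dir fx                 # canned example dataset
depsimatch annotate fx/example_peaklist.csv --mgf fx/example_spectra.mgf --out report.tsv
depsimatch simulate --out-prefix sim --seed 7    # synthetic peaklist + MGF + truth
depsimatch recover --sigma 2 --seed 7            # seeded recovery experiment
```

Peak lists are comma-delimited text (`id,mz,intensity,rt,adducts`);
fragment spectra are MGF with the TITLE field carrying the observation id.
Instrument profiles (`--profile hrms|iontrap`) set the precursor (5 ppm /
300 ppm) and fragment (0.01 Da / 0.3 Da) tolerances; individual flags or a
YAML `--config` file override them.

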