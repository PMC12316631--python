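# peptaibiomics

Mass-spectrometric sequence analysis for **peptaibols** and
**lipopeptaibols** — the Aib-rich, N-acylated, amino-alcohol-terminated
nonribosomal peptides of *Trichoderma* and related fungi. The package
turns what peptaibiomics studies do semi-manually into a tested,
reusable pipeline: theoretical mass and fragment-ion calculus over
nonproteinogenic residues, de novo sequence assembly from MS² fragment
ladders, novelty / positional-isomer / module-skip annotation against a
reference sequence set, and relative quantification of a strain's
peptaibiome — plus a seeded synthetic-spectrum generator so every stage
is testable without instrument data.

## Who it is for

Analysts characterising fungal secondary metabolomes by LC-MS/MS
(Orbitrap-class accuracy) who need reproducible, scriptable versions of
the by-hand steps: reading b/y ladders, writing substitution notation,
placing module-skip gaps, and computing peptaibiome percentages.

## The calculus at its core

A compound is `cap — R1…Rn — amino alcohol`. With monoisotopic residue
masses (amino acid − H₂O), the acyl cap as a neutral substitution delta
(Ac = +42.01057, Oc = +126.10446 Da) and the amino alcohol as its free
molecule, the neutral mass is

```
M = Δcap + Σᵢ m(Rᵢ) + m(alcohol)        [terminal hydrogens cancel]
```

Long peptaibols cleave in-source at the central Aib–Pro bond, giving the
diagnostic pair

```
b = Δcap + Σ(residues before Pro) + H⁺        y = Σ(Pro…end) + m(alcohol) + H⁺
```

with `b + y = [M+H]⁺ + H⁺` at every bond (the compound tables of this
field print `b + y` as their precursor column; both conventions are
exposed, as `reported_precursor` and `mh_plus`). Consecutive ladder ions
differ by exactly one residue mass, which is what the de novo reader
inverts. Isobaric pairs are collapsed to ambiguity codes: Leu/Ile → Lxx,
Val/Iva → Vxx.

## Worked example

```pycon
>>> import peptaibiomics as pb
>>> seq = pb.parse_sequence("Oc-Aib-Gly-Lxx-Aib-Gly-Lxx-Lxxol")   # 7-residue lipopeptaibol
>>> round(pb.mh_plus(seq), 2)
754.54
>>> xii = pb.parse_sequence(
...     "Ac-Vxx-Ser-Aib-Aib-Lxx-Gln-Aib-Aib-Aib-Ser-Lxx-Aib-Pro-Vxx-Aib-Aib-Gln-Gln-Lxxol")
>>> b, y = pb.diagnostic_pair(xii)
>>> round(b.mz, 2), round(y.mz, 2), round(pb.reported_precursor(xii), 2)
(1180.69, 740.47, 1921.16)
```

754.54 is the protonated molecular ion of the octanoylated
7-residue compound; 1180.69/740.47 are the in-source Aib¹²–Pro¹³
cleavage fragments of a 19-residue peptaibol and 1921.16 their sum, the
value its compound table prints as the precursor. The same numbers come
from the CLI (`peptaibiomics mass …`, `peptaibiomics fragments …`).

Round trip through the synthetic generator and the de novo reader:

```pycon
>>> from peptaibiomics import assembly, synthetic
>>> cfg = synthetic.SimulationConfig(seed=1, mass_error_ppm=3.0, decoy_per_100da=0.2)
>>> peaks, truth = synthetic.ladder_spectrum(seq, "y", cfg)
>>> assembly.infer_from_ladder(peaks, assembly.LadderParams(series="y"))[0].inferred.token_string()
'Oc-Aib-Gly-Lxx-Aib-Gly-Lxx-Lxxol'
```

## Layout

- `src/peptaibiomics/` — the library: `chemistry` (residue library, mass
  calculus), `fragmentation` (b/y ladders, water loss), `assembly`
  (de novo ladder reading, repeat detection, positional isomers),
  `annotate` (reference comparison, substitution notation, skip
  alignment, Roman-numeral naming), `quantify` (peptaibiome
  percentages, consensus), `synthetic` (seeded generator), `io` (TSV /
  MGF adapters), `cli`.
- `src/peptaibiomics/data/` — the residue library and curated compound
  tables / reference sequences used as fixtures.
- `analysis/01…05_*.py` — numbered narrative drivers: mass
  reproduction, novelty annotation, peptaibiome shares, family
  consensus, recovery-vs-noise; each writes its table under `results/`.
- `tests/` — the pytest suite, including property-based invariants.

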