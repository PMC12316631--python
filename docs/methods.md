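# Methods

## Mass conventions

All masses are monoisotopic and carried at full double precision;
reports round to 2 dp. Constants: proton 1.007276, hydrogen 1.007825,
water 18.010565, Na⁺ (atomic Na minus one electron) 22.989218 Da.

Internal residues enter as residue masses (amino acid − H₂O); the
terminal amino alcohol as its free molecule; the N-terminal acyl cap as
the neutral delta of substituting one amine hydrogen (Ac +42.01057,
Oc +126.10446 Da). Under these conventions the terminal hydrogen
bookkeeping cancels and

    M = Δcap + Σ residues + alcohol.

This reproduces every internally consistent printed [M+H]⁺ and
diagnostic-ion value in the packaged compound tables to ≤ 0.02 Da
(analysis/01, 716 values, max |dev| 0.019). The residue table ships as
TSV with chemical formulas; a test recomputes every tabulated mass from
its formula through an independent formula-mass calculator. Average
masses, isotope envelopes and elemental-formula inference are out of
scope. Lysine is deliberately absent from the default library — the
compound families handled here do not use it, and its near-isobar with
Gln (0.036 Da) would otherwise demand needlessly tight windows; users
can register it via a custom residue TSV.

Two precursor conventions coexist in this field's compound tables: the
true [M+H]⁺ and the sum b + y of the diagnostic in-source fragments,
which is one proton higher (both fragments are protonated). The package
exposes both (`mh_plus`, `reported_precursor`) and never mixes them.
Fragment ions are indexed by the number of residues they contain (the
amino alcohol counts as one for y ions); display labels from tables
that number fragments differently are metadata only.

## Fragment model

Only singly charged b and y ions are generated, plus optional H₂O loss
(observed as [y−H₂O]⁺ for amino-alcohol termini); a-ions, internal
ions, multiply charged fragments and intensities are not modeled —
interpretation in this domain rests on the +1 b/y series. The
diagnostic pair requires exactly one Pro; zero Pro routes to
whole-molecule MS² (the lipopeptaibol case, which has no Pro), several
Pro raises an ambiguity error listing candidate sites.

## De novo ladder reading

Peaks are nodes; an edge joins two peaks whose difference matches an
internal-residue mass. The matching window treats `tol_ppm` (default
5 ppm, Orbitrap at resolution 70 000) as a per-peak error scale: a
difference of two measured peaks gets the quadrature-combined budget of
both, times a `sigma_mult` of 3.5 (with an absolute floor of 0.005 Da).
The multiplier is what makes an 18-step ladder pass end-to-end with
high probability — at a bare ±5 ppm window the per-edge pass rate under
5 ppm Gaussian error is ~84%, i.e. essentially no long ladder survives
intact — while costing no discrimination: the closest residues in the
library sit 0.94 Da apart.

The longest chain is found by a deterministic forward pass keeping a
beam of 5 states per node; ties break by cumulative |ppm| error, then
lower starting m/z. Terminals are anchored by matching the low-mass end
against the amino alcohol (y) or cap-plus-first-residue (b) and the gap
to the precursor against the complementary terminus, allowing up to two
lumped residues per anchor; whatever terminal mass no combination
explains becomes the unexplained residual, stored at full precision and
displayed as integer Da (the "…Gln + 146" style of truncated
compounds). Competing solutions rank by peaks explained, then score
(fraction of bonds explained), then mean |ppm|: peak coverage must lead
because exact isobaric lumpings (Aib+Aib = Lxx+Gly,
Oc+Aib+Gly = Ac+Lxx+Lxx) make peak-skipping interpretations internally
complete and indistinguishable by score. Output tokens are always
ambiguity codes (Lxx/Vxx); Gln vs Glu (0.98 Da) and Gln vs Lys
(0.036 Da) are separated by mass.

Positional isomers — identical token strings eluting at different
retention times, i.e. unresolved Leu/Ile/Val/Iva isomerism — group at
an rt tolerance of 0.1 min (no threshold is stated in this field's
tables; 0.1 min is well under the smallest printed separation between
genuine isomers and above run-to-run jitter at these gradients).

## Annotation

Substitution distance is position-wise token mismatch between
equal-length sequences, the terminal alcohol counting as a position;
ambiguity codes match their members. All co-minimal references are
reported, alphabetically. Notation is `[REF]^i → [OBS]^i; …` ascending.
Token-multiset equality with different order is flagged separately as a
compositional isomer (swap), keeping the two substitutions explicit.

Length deficits (≤ 3 by default — the largest observed module-skip
count) are resolved by exhaustive gap placement into the template
coordinates, minimising substitutions. Two refinements make the
canonical solution match how skip positions are printed: placements
that delete different members of a run of identical residues collapse
onto the rightmost position of the run (an Aib skipped from an
Aib-Aib-Aib run prints as `Aib-Aib-(skip)-Ser`), and remaining
co-minimal placements tie-break by the total absolute mass difference
of their substituted pairs (the chemically closest leftover pairing)
before the leftmost-gap-vector order.

Names are a family stem plus Roman numerals in elution order; the stem
(nearest known compound for variants, producer species for wholly new
groups) is the caller's choice.

## Quantification and consensus

Areas are inputs (EIC integration happens upstream): y-ion areas
quantify peptaibols, [M+H]⁺ areas lipopeptaibols. Percentages are plain
ratios within strain and class at full precision, rounded only for
display; class shares per strain sum to 100 by construction.
Lipopeptaibol length classes: 6–7 short, 10–11 medium, 15 long,
anything else "other" with a warning.

The consensus takes, per position, the most abundant residue *present*
— each co-produced variant counted once (`mode="unweighted"`, the
default), with area weighting available as an option. The default was
fixed by checking both modes against the published family summaries:
counting variants reproduces them (Gln at R17 of the Trikoningin family
against the most-produced member's Glu; Lxx at R14 of the Trichorzianin
family against Vxx), whereas area weighting flips the Trikoningin R17
call (Glu 50.2% vs Gln 49.8% of summed areas). Gaps count as tokens so
skip variants do not shift full-length positions; consensus is defined
within equal-length families. Ties break alphabetically and are
flagged.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with
defaults fixed at the study conditions:

- **Families.** A 19-residue SF1 peptaibol template with the conserved
  Gln6–Aib7–Aib8–Aib9–Ser10–Lxx11–Aib12–Pro13–Vxx14 core (probability 1)
  and per-position substitution at rate 0.15 across the minor residues
  observed in such families; octanoyl lipopeptaibol templates of
  7/11/15 residues on the Vxx/Lxx-Aib-Gly repeat. The 0.15 rate gives
  variant diversity comparable to the dozens of co-produced variants per
  family in real peptaibiomes; it is a modeling choice, not a fitted
  value.
- **Abundances** log-normal (σ = 1.5): one to four dominant compounds
  and a long minor tail, as strains actually produce.
- **m/z error** Gaussian and relative, σ = 3 ppm by default (5 ppm in
  the stress tests), matching Orbitrap-class accuracy; **decoys**
  Poisson-uniform at 0.2 per 100 Da; **intensities** rank-decay
  (∝ rank^−0.5), since intensities are used only qualitatively;
  **retention times** uniform over 5–55 min with jitter, distinct by
  construction.
- **Determinism.** One seed per run; per-compound substreams derive
  from (seed, counter) so outputs are independent of generation order.

What the generator does *not* emulate — chromatographic peak shapes,
isotope envelopes, charge-state mixtures, chimeric spectra, co-elution,
systematic mass-calibration drift — bounds what green tests mean for
real data: they validate the calculus and the inference logic under the
stated error model, not robustness to instrument artifacts outside it.

## Problem sizes

The default suite simulates 200 spectra for the noisy-recovery check
and 25–60 per grid point elsewhere; the recovery analysis
(analysis/05) uses 60 spectra per condition. These sizes put binomial
noise on a 95% recovery estimate near ±1–3 points, tight enough for the
monotonicity and threshold checks the suite makes. Recovery at the
default conditions (≤ 5 ppm, 0.2 decoys/100 Da) is 100%; it degrades to
~40% at 10 ppm + 0.5 decoys and to 0 at 25 ppm + 1.0 — the de novo
reader is deliberately not tuned to survive conditions the instrument
model does not produce.

## Known limitations

- The curated compound fixtures carry a `consistent` flag: rows whose
  printed values disagree with their own printed sequences beyond
  0.02 Da (18 of 257 in the peptaibol table) are flagged and excluded
  from curated subsets rather than reconciled; one printed lipopeptaibol
  value (669.48 vs 669.491 computed) is treated as a measured-value
  deviation and the constants are not tuned to it.
- Ladder reading assumes one series per spectrum (the CLI trims peaks
  above the precursor before inference); chimeric or mixed-series
  spectra are out of scope.
- Skip alignment is exhaustive and capped at deficit 3 (configurable);
  it aligns within one terminal chemistry class only.
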