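# Methods

## Scope and model

The package implements the computational side of an MRM meat-speciation
assay. The measurement model is deliberately minimal and matches how such
assays are built in practice:

- **Digestion.** Trypsin cleaves C-terminal to K/R; the Keil rule (no cut
  before proline) is on by default and configurable. Up to a configurable
  number of missed cleavages (default 2, the usual database-search setting)
  are enumerated. Protein N- and C-termini count as tryptic termini, so a
  protein C-terminal peptide that does not end in K/R (e.g. the lamb marker
  NLVHIITHGEEKD in the built-in panel) is still "fully tryptic". Initiator
  methionine is never clipped — without annotation that is guesswork.
  Ambiguous residues (B, Z, X, U) have no defined monoisotopic mass; peptides
  containing them stay in the index with a flag but are never markers.
- **Uniqueness.** A peptide is species-specific when its canonical key occurs
  in exactly one species. The canonical key folds I onto L by default: a
  triple quadrupole cannot distinguish the isobaric pair, and treating them
  as distinct would produce false "specific" calls. Uniqueness is assessed in
  tryptic space (the peptides a digest can actually produce), which mirrors
  how markers are screened from observed digests; an optional strict mode
  additionally rejects candidates occurring as a substring of any other
  species' protein, guarding homologous context that digestion parameters
  might hide.
- **Marker filter.** Length 9–17 residues, zero missed cleavages, tryptic at
  both ends, no methionine (Met oxidation makes responses unstable; Cys is
  allowed because it is carried carbamidomethylated). All gates are
  configurable. Abundance and signal-to-noise cannot be computed from
  sequence; an optional empirical intensity table is used only to order
  candidates, never to admit them.
- **Masses.** Standard monoisotopic residue masses (5-decimal precision),
  water 18.010565 Da, proton 1.007276 Da. Fixed carbamidomethyl-Cys
  (+57.02146 Da) and variable Met oxidation (+15.99491 Da). Precursors
  default to 2+, products to singly charged y-ions — every mass-consistent
  entry of the built-in reference panel is consistent with that convention.
  m/z is exported with 6 decimals; internal comparisons use a 0.01 m/z
  tolerance to absorb mass-table rounding.
- **Collision energy.** The vendor-standard charge-dependent linear ramp
  `CE = slope·(m/z)/100 + offset`, reported to 0.1 V. The default 2+ ramp
  (3.1 V per 100 m/z, +1.0 V) reproduces all 15 reference-panel CE values
  exactly after rounding; no 3+ ramp is preconfigured because the panel
  contains no 3+ precursor to anchor it.
- **Product-ion choice.** Which y-ion responds best is an instrument
  property, not a sequence property (panel indices range y7–y13), so the
  default selection mode is *empirical* (caller supplies the observed best
  product); *rank* mode emits the top-k high-m/z y-ions (index ≥ 3, inside
  the 300–1400 m/z window) as a starting panel. Ties in candidate ordering
  break by ion index ascending. Retention times are stored, never predicted.
- **Quantification.** Per-peptide ordinary least squares of raw intensity on
  target mass fraction over the 0/20/.../100 % binary-mixture design (≥3
  levels required; replicates averaged per level by default, configurable to
  fit all points). r² is the squared correlation; the residual SD uses n−2
  degrees of freedom. Inverse prediction is (I−a)/b with the first-order
  interval `s/|b|·sqrt(1 + 1/n + (x̂−x̄)²/Sxx)` and a t quantile; estimates
  are clipped to [0,1] with an explicit flag rather than silently truncated.
  Consensus across a species' markers is the median with MAD spread — robust
  to a single corrupted marker. Detection limit is the calibration-based
  `3.3·σ_blank/slope`; the per-transition detection threshold is
  `mean(blank) + 3·σ_blank`. Slopes below 1e-12 raise rather than divide.

## Reference panel

`meatmarkers.panel.REFERENCE_PANEL` holds the published 15-peptide panel
(beef, chicken, duck, pork, lamb) with its empirical product ions, retention
times, and published m/z / CE values. One entry (beef FLEELLTTQC) is flagged
`mass_consistent=False`: its published precursor cannot be derived from the
printed sequence under any standard Cys modification (computed 2+
carbamidomethyl ≈ 627.31 vs published 762.87, a likely truncation or typo at
source), so it participates in CE checks only; the other 14 entries
reproduce to well under 0.01 m/z.

## Synthetic data

`simulate.make_toy_proteomes` emulates the multi-species screening setting
with known ground truth: per species, random proteins are assembled from
tryptic segments, and marker-grade peptides (9–17 residues, K/R terminus,
no M/C/I/L, non-proline start so no cut is suppressed) are planted at
segment boundaries — unique peptides in one species, shared peptides in all.
Background segment lengths deliberately avoid the 9–17 marker window (80 %
length 2–8, 20 % length 18–30, giving a K/R frequency of roughly 1/9,
close to the natural ~11 %): with natural-looking uniform backgrounds,
random species-specific peptides inside the marker window would swamp the
planted truth and no exact-recovery guarantee could hold. The generator
verifies its own output by digesting and screening it, regenerating on
collision (bounded at 100 attempts). Consequences: fixtures exercise the
screening logic exactly, but they do not model cross-species homology,
shared protein families, or realistic residue composition — passing tests
show the algorithms are correct, not that any particular real proteome
yields a given marker count.

`simulate.simulate_mixture_intensities` draws
`intensity = slope·fraction + intercept + N(0, σ)`, floored at 0, with
independent replicates — a linear-response idealisation of calibration
measurements. It does not model matrix effects, ionisation competition, or
heteroscedastic (intensity-proportional) noise, so curve statistics on
simulated data are best-case.

## Test problem sizes

Property tests run on hypothesis-generated peptides (≤60 residues, 60
examples, derandomised) with pyteomics as an independent mass/digestion
oracle. The end-to-end checks use 60 random proteins for the digestion
oracle, 5 species × 20 proteins for the uniqueness oracle, 100 seeded
simulations for slope-interval coverage and 200 for the 1 %-spike detection
boundary — sizes chosen so the whole suite completes in a few seconds while
the binomial tolerances stated in the tests remain meaningful.

## Known limitations

- No retention-time prediction, fragment-intensity prediction, dwell-time
  scheduling, or vendor method export.
- Only b/y singly-to-doubly charged fragment arithmetic; no a/c/x/z series,
  neutral losses, or isotope envelopes (monoisotopic only).
- Uniqueness is only as good as the proteome databases supplied; marker
  counts depend entirely on database version and are therefore demonstrated
  on fixtures, not asserted for real species databases.
- Quantification assumes a linear, single-analyte response without internal
  standards; real matrices may need normalisation upstream.
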