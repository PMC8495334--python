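# meatmarkers

Dry-lab design and readout of targeted mass-spectrometry assays for **meat
speciation** — detecting and quantifying one animal species mixed into the
meat of another (pork in beef, chicken in lamb, ...).

The package is for analysts building multiple-reaction-monitoring (MRM)
panels on triple-quadrupole instruments. It covers four stages:

1. **In-silico trypsin digestion** of per-species proteomes (cuts after K/R,
   Keil proline rule, configurable missed cleavages, full provenance).
2. **Marker screening** — a peptide is *species-specific* (proteotypic for a
   species) when its sequence occurs in exactly one species' digested
   proteome. Because Ile and Leu are isobaric and indistinguishable on a
   triple quadrupole, uniqueness is assessed on I/L-merged keys by default.
   Assay-suitability gates: length 9–17, no missed cleavages, tryptic at both
   ends (protein termini count), no methionine.
3. **Transition design** — for each marker, the doubly protonated precursor
   m/z, singly charged y-ion product m/z, and collision energy from the
   standard linear ramp. With monoisotopic residue masses `m_i`:

   ```
   M        = Σ m_i + m_H2O                      (neutral peptide mass)
   [M+zH]z+ = (M + z·m_H+) / z                   (precursor, default z = 2)
   y_n      = (Σ last n residues + m_H2O + m_H+) (product, default 1+)
   CE       = 3.1 V · (m/z / 100) + 1.0 V        (2+ ramp, rounded to 0.1 V)
   ```

   Fixed carbamidomethyl-Cys (+57.02146 Da) is applied throughout; Met
   oxidation (+15.99491 Da) is available as a variable modification.
4. **Quantification** — binary-mixture standard curves
   (0/20/40/60/80/100 % target in background) fitted by ordinary least
   squares, inverse prediction of an unknown's mass fraction with a
   t-based interval, median consensus across a species' markers, detection
   limit `LOD = 3.3·σ_blank / slope`, and per-species contamination calls
   at a `mean(blank) + 3·σ_blank` threshold.

A built-in 15-peptide reference panel for beef, pork, chicken, duck and lamb
(`meatmarkers.REFERENCE_PANEL`) anchors the mass and CE arithmetic; the
`verify-panel` command recomputes it from sequence.

## Worked example

```python
import meatmarkers as mm

p = mm.apply_fixed_modifications("TLEDQVNELK")       # a beef marker
print(f"precursor 2+ : {mm.precursor_mz(p, 2):.6f}")
print(f"y7 1+        : {mm.fragment_mz(p, 'y', 7, 1):.6f}")
print(f"CE           : {mm.collision_energy(mm.precursor_mz(p, 2), 2):.1f}")
```

prints

```
precursor 2+ : 594.808958
y7 1+        : 845.436311
CE           : 19.4
```

— the 2+ precursor of TLEDQVNELK, its y7 product (the last seven residues
DQVNELK plus water and a proton), and the ramp CE in volts. Screening toy
proteomes with planted markers:

```python
proteomes, truth = mm.make_toy_proteomes(mm.ProteomeSpec(n_species=3, seed=1))
peps = mm.digest_collection([q for ps in proteomes.values() for q in ps], max_missed=0)
index = mm.build_index(peps)
for sp in sorted(proteomes):
    print(sp, [m.sequence for m in mm.find_species_specific(index, sp)])
```

```
species_A ['HSPDAWTVPVK', 'NTYAEVYFGWHFR', 'VDGDNYDHHWEPK']
species_B ['NGDHQNTHQTWK', 'TAFNNDYTR', 'TGPWFTEGR']
species_C ['EQVFGVQPSPYTAEPR', 'STVWEPVHK', 'TPWNHANQR']
```

each species' marker list is exactly its planted ground truth (`truth`).

The same pipeline runs from the shell against FASTA inputs and a YAML
config: `meatmarkers simulate | digest | screen | design | quantify |
verify-panel` (see `meatmarkers --help`).

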