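# lissoir

Tools for non-destructive ZooMS (Zooarchaeology by Mass Spectrometry)
identification of bone artifacts, and a Bayesian test of whether the
makers of rib-based smoothing tools (*lissoirs*) picked their raw
material opportunistically or preferred ribs of larger-bodied taxa.

The package covers the full computational chain around a MALDI-TOF
collagen peptide mass fingerprint:

1. **In-silico digestion** — tryptic peptides of reference proteins
   (collagens, keratins, trypsin, serum albumin, hemoglobins) with
   hydroxyproline and deamidation variants, as a sorted peptide mass
   library.
2. **Peak processing** — noise estimation (windowed 1.4826×MAD), peak
   picking at S/N > 3, and monoisotopic selection that distinguishes a
   deamidated satellite (+0.984 Da) from an isotopologue (+1.003 Da).
3. **Identification** — marker-series matching at 50 ppm against a
   taxon marker database with clade merge rules (aurochs and bison are
   indistinguishable on collagen: "Bos sp./Bison sp."), biogeographic
   exclusions, a two-peptide rule for protein acceptance, and a
   contamination screen (endogenous collagen vs process contaminants vs
   usage-derived proteins).
4. **Deamidation** — the extent of deamidation of peptide P1105
   (GVQGPPGPAGPR + hydroxyproline, 1105 m/z) by non-negative
   least-squares fitting of its isotope-envelope region; 1.0 = pristine
   collagen, archaeological bone falls well below.
5. **Selectivity** — the statistical heart. With tool counts
   *n = (n₁, …, n_K)* over taxon categories and rib-fragment
   frequencies *p* in the same layer,

   - H₀ (opportunism): *P(E|H₀)* = Multinomial(*n*; *p*),
   - H_A (size selection): *P(E|H_A)* = Dirichlet-Multinomial(*n*; α),
     α_i = *c* · ln(mass_i in kg), with a strong (large *c*) and a weak
     (small *c*) variant,

   compared by posterior odds *P(E|H_A)/P(E|H₀) × P(H_A)/P(H₀)* with
   prior odds 1. Odds above 1 favour strategic selection.
6. **Synthetic data** — seeded generators for marker spectra (isotope
   ladders, deamidation, low-mass bias above 2500 m/z, noise) and for
   assemblages drawn under either hypothesis, so the whole pipeline runs
   and is tested without any external download.

Packaged fixtures include the layer tables for Pech-de-l'Azé I Layer 4
and Abri Peyrony Layers L-3A/L-3B (NISP and rib tallies per taxon
category). Marker masses, body masses and protein sequences are
synthetic stand-ins (files named `*_synthetic.*`) chosen at realistic
values; swap in your own TSV/FASTA for real analyses.

## Worked example

```bash
lissoir simulate --taxon "Bos sp." --snr 10 --seed 7 --out bos.txt
lissoir identify --spectrum bos.txt --exclude "Ovibos moschatus"
```

prints (abridged):

```json
{
  "clade": "Bos sp./Bison sp.",
  "status": "identified",
  "matched_markers": [{"marker": "P1", "theoretical_mz": 1105.5748, "...": "..."}],
  "excluded_alternatives": [{"taxon": "Ovibos moschatus", "...": "..."}]
}
```

The five markers below the 2500 m/z low-mass cutoff match both large
bovids and musk ox; musk ox is excluded on biogeographic grounds and the
call collapses to the merged clade. The selectivity test on the packaged
tables:

```bash
lissoir select-test --layer L-3B --obs "large_bovid:3"
```

```
Layer L-3B:
  P(E|H0) = 0.00088
  strong: P(E|HA) = 0.068, posterior odds HA:H0 = 77.86 (reported 77.9) -> the alternative (strategic selection) is better supported
  weak: P(E|HA) = 0.084, posterior odds HA:H0 = 95.59 (reported 95.6) -> the alternative (strategic selection) is better supported
```

Three large-bovid ribs from a reindeer-dominated layer are very unlikely
under opportunistic selection (P ≈ 0.0009) and far better supported
under a preference for large-bodied taxa. For Layer L-3A (one tool,
large bovids well represented, P(E|H₀) = 0.6) the same test favours the
null. The HA magnitudes depend on the packaged default body masses and
concentration scalings; the H₀ values follow directly from the rib
tallies.

The `analysis/` directory walks the same pipeline as numbered scripts
(build library → simulate extracts → identify → deamidation →
selectivity), writing tables under `results/`.

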