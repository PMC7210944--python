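# Methods

## Peptide chemistry

Neutral monoisotopic masses are sums over an embedded residue table
(five decimals, cross-checked against pyteomics in the test suite) plus
one water (18.010565 Da); singly protonated m/z adds 1.007276 Da.
Modifications are *counted, not positioned* — a MALDI-TOF fingerprint
cannot localise a hydroxyproline — with fixed shifts of +15.994915 Da
per hydroxylation and +0.984016 Da per deamidation (amide → carboxyl:
+O −N −H). Counts are validated against the sequence (deamidations ≤
N+Q, hydroxylations ≤ P).

Integer marker labels ("P1 at 1105 m/z") use the nominal-mass
convention: sums of integer nominal residue masses plus water,
modifications and one proton. Rounding the monoisotopic m/z
(1105.5748…) half-up would give 1106 and disagree with the established
marker names, so nominal mass is the deliberate choice.

Isotope envelopes are aggregated by neutron count: per-element
neutron-shift distributions at standard terrestrial abundances are
convolved (binary exponentiation over atom counts), peak k sits at
(monoisotopic + k·1.00336 + z·1.007276)/z, and peaks below a relative
abundance threshold (default 1e-4, matching practical MALDI dynamic
range) are dropped after normalisation. The convolution is verified
against an exhaustive multinomial expansion for compositions up to 60
atoms (max deviation < 1e-8).

## Digestion and the mass library

Trypsin cleaves C-terminal to K/R except before P. The library
enumerates peptides with 0–1 missed cleavages (default), lengths 6–40
residues, all hydroxylation counts the sequence allows, and at most two
deamidations — typical ZooMS practice; the bounds are configurable.
Entries are sorted by m/z and keyed by (protein, sequence, modification
counts). Protein records carry a taxon label used by the contamination
screen.

## Spectrum processing

Noise is 1.4826 × the median absolute deviation of intensities within
100-Da windows tiling the spectrum; the windowed median is the baseline.
Peaks are local maxima whose height above baseline exceeds
`snr_threshold` × noise (default 3). Two shape criteria suppress
single-sample noise spikes on profile data: the apex's neighbours must
stay above half its height, and maxima within 0.2 Da merge into the
tallest. The reported m/z is the intensity-weighted centroid of the
half-height run after matched-filter smoothing (Gaussian kernel sized
from the run's own width); S/N decisions always use the raw data. Input
with median point spacing above 0.1 Da is treated as already centroided
and only thresholded.

Monoisotopic selection walks peaks in ascending m/z and classifies each
against two hypotheses relative to already retained peaks: the next
isotopologue of an open cluster (+1.00336/z) or a deamidated variant of
a retained monoisotopic peak (+0.984016/z). Whichever residual is
smaller wins within a 0.02 Da tolerance — chosen because it separates
the two spacings (0.0193 Da apart) at MALDI-TOF mass accuracy. Deamidated
variants are retained and flagged; isotopologues are dropped.

Spectrum I/O: two-column text (whitespace or comma separated, `#`
comments) and a minimal mzML subset (single run, 64- or 32-bit
little-endian floats, zlib or no compression) read with the standard
library; the established mzML bindings were not usable here, and the
subset reader is verified against text twins round-tripped through
both zlib and uncompressed encodings.

## Identification

Matching uses signed ppm error with a 50 ppm acceptance (absolute
value). Library matching assigns each monoisotopic peak to its nearest
entry within tolerance (ties: smaller |ppm|, then lower m/z) and accepts
a protein only with ≥ 2 distinct matching peptide sequences. Marker
matching is greedy nearest-pair per taxon (one peak supports at most one
marker and vice versa, preventing double counting).

The clade call: count matched markers per taxon; taxa on the
biogeographic exclusion list never compete (but are recorded as excluded
alternatives when they matched at least as many markers as the best
survivor); the candidate set is the non-excluded taxa with the maximal
count, provided it reaches 2 markers (mirroring the two-peptide rule at
marker level — below that the spectrum is *unidentifiable*). Candidates
that collapse under a merge rule give an *identified* call with the
merged clade label; candidates spanning clades give a *less-specific*
joint label. The procedure is deterministic given peaks, database and
configuration.

The contamination screen classifies accepted proteins by identifier:
collagens are endogenous candidates; porcine trypsin and human keratins
are known process contaminants; albumins, hemoglobins and non-human
keratins are usage-derived candidates and raise a flag.

## Deamidation extent

For a peptide with q = #N+#Q deamidatable residues, theoretical
envelopes of the 0…q-deamidation forms are binned onto the parent's
isotopologue positions (the j-deamidated form's peak k falls 0.0194 Da
below parent position k+j, within the bin). Observed intensity is
integrated within ±0.05 Da of each position after baseline subtraction
(negatives kept so noise stays zero-mean), and non-negative least
squares gives weights w; the value is w₀/Σw, so 1.0 = fully
non-deamidated. The fit is withheld (*insufficient signal*) unless the
apex within the parent's or the singly-deamidated form's monoisotopic
bin exceeds 3 × the local noise. NNLS was chosen over apex-ratio methods
because the deamidated envelope overlaps the parent's isotopologues at
MALDI-TOF resolution.

Simulation-based calibration (in the test suite): across true values
{0, 0.25, 0.5, 0.75, 1} at S/N 10, 100 seeds each, recovery bias is
below 0.02 and RMSE below 0.05; the estimate is exactly invariant to
uniform intensity scaling.

## Selectivity test

Model categories are the taxon/size classes with nonzero rib counts,
pooled by an explicit grouping map shipped with the tables (Bison/Bos
and large-ungulate rib categories pool into "large bovid"; the
medium-sized categories into "medium ungulate"; species-level categories
keep their own labels). Relative rib frequencies p_i are rib counts over
total ribs after pooling.

P(E|H₀) is the multinomial probability of the tool counts at p;
P(E|H_A) is the Dirichlet-multinomial probability with concentrations
α_i = c·s_i, selectivity s_i = ln(body mass in kg) — masses must exceed
1 kg so every α is positive. Both likelihoods include the multinomial
coefficient (it cancels in the odds) and are evaluated in log space with
log-gamma. Posterior odds are (P(E|H_A)/P(E|H₀)) × prior odds, default
prior odds 1; reports carry full precision plus a one-decimal rounding.

Verified properties: both pmfs sum to one over all outcomes (exhaustive
enumeration, K ≤ 4, n ≤ 5, tolerance 1e-10); with a single observation
the DM likelihood is invariant to rescaling c (so strong and weak
variants coincide at n = 1) up to log-gamma cancellation (~1e-9
relative at extreme c); as c → ∞ with fixed proportions the DM converges
to the multinomial (relative error < 1e-3 at c = 1e6); the DM pmf
matches a 10⁶-draw Monte-Carlo Dirichlet integration within 3 standard
errors; and the generating c is recovered within a factor of two by
maximum likelihood on 500 simulated samples of 10 draws.

`c_strong = 10` and `c_weak = 1` are package defaults that express
"rigid" vs "noisy" preferences; they are configurable inputs, not
calibrated constants, and the strong/weak likelihood magnitudes move
with them (single-observation layers do not). The default body-mass
table is likewise a stand-in at standard wildlife values (large bovid
700 kg, red deer 160, medium ungulate 150, reindeer 100, roe deer 25,
horse 400).

## Synthetic data

The spectrum generator renders a taxon's marker series as Gaussian peaks
(width from resolving power 5000: FWHM = m/z / 5000) on a noisy baseline
(offset 5σ, additive normal noise, clipped at zero), with full isotope
ladders and +0.984 Da deamidated satellites where a marker carries
peptide provenance, apex = S/N × noise per marker, optional exponential
intensity decay, and a high-mass cutoff (default 2500 m/z) emulating the
low-molecular-weight bias of triboelectric extraction. The assemblage
generator draws rib tallies multinomially from specified frequencies and
tool observations under either hypothesis (multinomial, or Dirichlet
then multinomial). All generators are deterministic per seed with no
shared global state.

What the generator does **not** emulate: matrix/chemical noise peaks
with collagen-like spacing, mass-calibration drift, detector saturation,
isotope-pattern distortions, or real inter-laboratory marker variation.
Passing tests therefore demonstrate the correctness and calibration of
the algorithms under controlled conditions, not identification
performance on real archaeological spectra.

## Fixture provenance and reconstruction

The packaged layer tables carry the published NISP tallies (totals 642,
68 and 541). Published rib information is given as percentages per
category; the packaged per-category rib *counts* are reconstructed to be
consistent with those percentages — L-3A: 2/2/1 (medium, Bison/Bos,
large ungulate; 40/40/20 %), L-3B: 2/83/7/2 over 94 ribs (2/88/7/2 %),
Pech I Layer 4: 3/12/9/1/30/14/22 over 91. The L-3A pooled large-bovid
frequency is exactly 0.6 and the L-3B probability of three large-bovid
draws is 0.00088, matching the reported values at their printed
precision. Marker masses and the merge rules are a small synthetic
reference set sufficient to exercise every code path (shared P1;
Bos/Bison identical; musk ox identical below 2500 m/z, differing above).

## Problem sizes and numerical choices

Simulation-backed tests use 100 seeds per condition for recovery rates
and deamidation calibration, 10⁶ draws for the Monte-Carlo Dirichlet
oracle, 4,000 replicates for the generator-vs-pmf chi-square check, and
exhaustive enumeration up to K = 4 categories × n = 5 observations —
sizes chosen so the full suite runs in well under a minute per module on
one CPU. Spectra default to a 0.02 Da grid over 1000–3500 m/z. Ties in
matching are broken by smaller |ppm| then lower m/z; degenerate inputs
(empty spectra, zero ribs, zero-signal regions, zero H₀ likelihood) are
rejected or flagged rather than silently propagated — posterior odds on
a zero H₀ likelihood return infinity with a warning.

## Known limitations

* Species-level separation of aurochs vs bison is impossible on these
  markers by design; the merged clade is the terminal label.
* The HA likelihood magnitudes depend on the body-mass table and the
  strong/weak scalings, which are package defaults; conclusions should
  be drawn from sensitivity over those inputs, not a single value.
* The deamidation model fits only deamidation counts as mixture
  components; other near-isobaric modifications would alias into them.
* The mzML reader covers the minimal subset described above, not the
  full standard.
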