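# Methods

This note documents the models and numerical choices behind matriquant: what
each stage assumes, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## Data model

The interchange format is long/tidy delimited text: one quantified peptide
observation per row (`sample_id, fraction, peptide, accession, intensity,
score, is_decoy`). Missing cells in derived matrices are NaN and never zero
— zero means "observed at zero area", NaN means "not observed" — because
the downstream statistics must distinguish absence from a measured zero.
Peptide identity everywhere is the pair (sequence including modification
annotations, accession): modified forms quantify independently, and shared
peptides are taken as pre-assigned to one accession by the input table
(protein inference is out of scope).

Fraction merging sums a peptide's intensity over the LC fractions in which
it eluted. Summing is idempotent, so tables whose intensities are already
fraction-merged pass through unchanged; there is no flag to get wrong.
Decoy records are excluded from matrices but tallied, so total intensity is
conserved exactly — a property the test suite asserts at 1e-12 relative
tolerance.

## Identification FDR

Decoy-based thresholding uses the plain target-decoy ratio, estimated
FDR = decoys passing / targets passing, scanned over all observed score
thresholds; the chosen threshold is the most permissive one meeting the
target (2% by default). The 2d/(t+d) variant is available
(`formula="combined"`). Both directions are exposed: target FDR → threshold
and threshold → estimated FDR, since it is generally unknowable from a
published table which direction produced it.

## Error-weighted ANOVA

Instrument-vendor "error-weighted" ANOVA implementations are proprietary.
The reconstruction here: duplicate runs of the same digest differ only by
technical noise, so for every protein present in both runs of a duplicated
digest, the squared log2 difference / 2 estimates the technical variance at
that intensity. A line is fitted to log(variance) versus mean log2
intensity (variances clipped to the 5th–95th percentile of the observed
values to keep weights bounded), and each observation's weight is the
inverse predicted variance. With fewer than 8 usable duplicate pairs the
weights fall back to unity, in which case the statistic is *exactly* the
textbook one-way fixed-effects ANOVA (asserted against
`scipy.stats.f_oneway` at 1e-10). Weights enter as W-weighted group means
and sums of squares; any common rescaling of the weights cancels.

Multiple testing uses Benjamini–Hochberg within each tissue's protein list
(the two tissues are processed independently end to end). Hochberg's
step-up FWER procedure is offered as an option because both names circulate
for this kind of curated table; the default is the FDR procedure. Cohen's d
is computed on the same log2 scale as the ANOVA with the pooled (n−1)
standard deviation, so its sign always agrees with the fold-change
direction. Curation keeps proteins with more than one matched peptide,
adjusted p < 0.05 and |d| > 0.8 ("large"); all three thresholds are flags.

Fold changes are ratios of linear-scale group means over duplicate-averaged
subject intensities, printed in the signed convention (r if r ≥ 1, else
−1/r) so a halving reads −2.0.

## Hi3 absolute quantification

For each protein with at least two peptides, the three peptides with the
highest mean log intensity across the dataset's runs are fixed as its
fliers (two if only two exist, recorded in `n_peptides_used`; ties broken
by lexicographically smallest sequence for determinism). Ranking on the log
scale makes the choice — and hence every downstream quantity — invariant to
a global per-sample intensity rescaling, which the per-run calibration then
cancels exactly. The response factor per run is the standard's top-3 mean
intensity divided by its known on-column amount, spike level × injected
digest mass (25 fmol/µg × 3 µg = 75 fmol by default). Molar amounts convert
to mass through the sequence-average molecular weight (average residue
masses + one water; residue modifications are ignored in mass, an error far
inside the method's two-fold envelope). "% dry weight" normalizes each
protein's ng to the summed ng of all quantified native proteins in that
run; the spiked standard is excluded from numerator and denominator. The
summed quantified protein mass, not the weighed tissue aliquot, is the
denominator — the tissue aliquot is not observable from the data.

Cross-tissue comparisons are computed on dry-weight percentages (the two
tissue datasets are acquired and processed independently, so raw
intensities are not comparable), with two-sided pooled-variance t-tests and
log2-scale Cohen's d, plus female-only and male-only 3-vs-3 strata.
Collagen ratios (type I:III; α1(VI):α2(VI):α3(VI) against α2(VI)) are
computed per donor and then summarized as mean ± SD — a deliberate choice:
the ratio of group means is not the mean of donor ratios, and donor-level
ratios carry the biological variance the summary should show. Blood-protein
enrichment compares each protein's dry-weight fraction with albumin's in
the same run; a group-mean ratio ≥ 1 flags a protein held in the tissue at
or above the dominant blood protein, i.e. preferentially retained.

## Synthetic data generator

The generator states the experiment it emulates: 2 tissues × 2 sexes × 3
donors, one donor per tissue run in duplicate (14 runs), 8 LC fractions,
3 µg digest per injection, ADH1 yeast standard spiked at 25 fmol/µg, and a
bundled ~55-protein panel whose concentrations are set so the quantitative
outputs have the composition of real tendon/ligament: total type I collagen
≈ 80% of dry weight in PT and ≈ 52% in ACL, type III ≈ 6% / 25%, type VI
chain stoichiometry near 2:1:4–6, a decorin-led proteoglycan complement,
and a small blood-protein contingent led by albumin. Programmed sex effects
mirror the published differential pattern (e.g. alcohol dehydrogenase 1B
strongly female-enriched, myocilin and albumin male-enriched); the two
sexes sit symmetrically (×√fc, ÷√fc) around the tissue baseline.

The intensity model is multiplicative:
`I = conc(tissue, sex) · injected_µg · exp(ε_bio) · eff(peptide) ·
scale(run) · exp(ε_tech)`, with

- `bio_sigma` (default 0.25, natural-log scale) per (protein, donor),
  shared by duplicate runs — the biological variance the group statistics
  see;
- `sigma` (default 0.15) per record — the technical noise that separates
  duplicate runs and feeds the error-weight curve;
- `run_scale_sigma` (default 0.10) per run — residual global drift after
  BCA concentration normalization and equal loading; kept modest because
  the real workflow normalizes loads, and chosen before any test was run;
- `eff(peptide)` log-normal (σ = 1), drawn once per peptide as a stable
  property of its sequence, giving the "flier" structure. Efficiencies are
  rescaled per protein so its top-min(3, n) efficiencies average exactly 1
  — the Hi3 assumption (protein-independent mean response of the best
  fliers) made exact, so noise-free quantification recovers programmed
  femtomoles identically.

Peptides come from an in-silico tryptic digest (cleave after K/R except
before P; peptides of 6–30 residues; the observed forms use 0 missed
cleavages, while the digestion routine itself supports any `max_missed`) of
synthetic sequences generated deterministically from the accession, so
catalogs and molecular weights are reproducible without bundling any real
database. Fraction assignment hashes the peptide sequence to 1..8, with a
~15% minority split 70/30 over two adjacent fractions, reproducing the
observed fraction-uniqueness regime without modeling chromatography.
Dropout is missing-at-random but logistic in log intensity (low-intensity
peptides drop preferentially, the standard DIA artifact); the spiked
standard is exempt because calibration must exist in every run and the
spike is far above the dropout regime. Decoy records carry scores from the
null N(0, 1) against targets at N(separation, 1), separation 3 by default.

For FDR calibration experiments, `simulate_scores` additionally plants
incorrect *target* matches, equinumerous with the decoys, both drawn from
the null — the standard target-decoy assumption (an incorrect spectrum hits
target or decoy space with equal probability) under which the decoy count
is an unbiased estimate of the incorrect-target count. A hidden
`is_correct` label lets tests measure the realized false-discovery
proportion directly.

What the generator does **not** emulate: retention-time structure, spectral
interference, ion-mobility signal attenuation, shared/homologous peptides,
protein inference ambiguity, or intensity-dependent detector saturation. A
green test therefore establishes correctness of the quantitative chain
under the stated noise model, not robustness to alignment or identification
pathologies.

## Numerical and degenerate-case choices

- ANOVA with zero within-group variance everywhere reports F = ∞ and a
  p-value floored at the machine tiny, flagged degenerate; identical groups
  give F = 0, p = 1.
- Cohen's d with zero pooled SD returns a signed infinity sentinel.
- Signed fold change is NaN (flagged) when a group mean is missing or ≤ 0.
- PCA imputes missing cells with the peptide's row mean before z-scoring
  (imputed cells become exactly 0 and are uninformative), drops
  zero-variance rows with a count, and fixes each component's sign so its
  largest-magnitude loading is positive — coordinates are then invariant to
  row and column order.
- Surrogate RSD uses the sample (n−1) standard deviation, the small-n
  convention.
- All tables are written with fixed column order, stable sorts and a
  `%.10g` float format; identical config + seed reproduce outputs byte for
  byte.

## Known limitations

With n = 3 donors per sex and realistic biological noise, the BH-corrected
sex comparison is deliberately conservative: at the default noise levels
only the strongest programmed effects survive curation, and the
male/female curated lists can be empty in a given tissue. The error-weight
curve is fitted from a single duplicated digest per tissue (all proteins
pooled), so it captures the intensity trend of technical variance, not
protein-specific behaviour. Dry-weight percentages are compositional;
tissue fold changes computed on them are influenced by the dominant
collagen signal in the denominator, which is also true of the original
measurement procedure they reproduce.
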