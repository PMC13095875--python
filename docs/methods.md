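# Methods

## Fragmentation model

Secondary alcohols are modelled as their trimethylsilyl (TMS) ethers,
the form in which they are actually chromatographed after BSTFA
derivatization. Electron-impact α-cleavage at the two C–C bonds flanking
the carbinol carbon yields two singly charged ions, each retaining the
carbinol CH and the OTMS group:

* short side: C(k+3) H(2k+9) O Si → nominal m/z 14k + 89
* long side: C(n−k+4) H(2(n−k)+11) O Si → nominal m/z 14(n−k) + 103

for chain length *n* and hydroxyl locant *k* (lowest-locant convention,
2 ≤ k ≤ (n+1)/2). The pair sum 14n + 192 equals the molecular mass of
the TMS ether (14n + 90) plus 102, a conservation identity asserted for
every valid (n, k) in the tests. All masses are nominal integers
(C = 12, H = 1, O = 16, Si = 28): unit-resolution quadrupole spectra are
the intended input, and the printed diagnostic m/z values in this field
are nominal. Monoisotopic masses, isotope patterns and other
fragmentation channels (M⁺, −15, −90 losses) are deliberately out of
scope, as is bis-TMS fragment enumeration for diols.

## Isomer quantification

Within one GC peak, each candidate isomer's score is the arithmetic
mean of its two fragment intensities; fractions are the scores
normalized to 1. The estimator is exact when fragment response is
proportional to isomer amount and both fragments of an isomer respond
equally; it is scale-invariant and independent of candidate order.
Candidate discovery (`scan_positions`) requires both fragments of a
locant to exceed a floor (default: strictly positive; the pipeline uses
1 % of the base peak), because single-ion evidence is too easily
produced by unrelated fragments. A >5-fold disagreement between the two
fragments of one isomer emits a warning but keeps the mean — no outlier
rule is applied. Quantification is per peak: isobaric overlap between
homologues (m/z 369 belongs to both C29 k=10 and C27 k=8) is not
deconvolved, on the assumption that homologues are chromatographically
separated.

## Quantification and aggregation

Loads follow area ratio × IS mass / leaf area with an FID response
factor of 1 for all analytes relative to the tetracosane internal
standard; no correction is applied. A compound absent from a replicate
is a measured zero (it was below detection on a scale where other
replicates measured it), so it enters means and standard errors as 0
rather than as missing. Chain-length profiles sum exactly six classes —
aldehydes, alkanes, secondary alcohols, diols, fatty acids, primary
alcohols — because ester "chain length" is the total carbon count of
two condensed moieties and triterpenoids have no homologous chain;
esters and triterpenoids still count toward totals and class
percentages. Standard errors are sd(ddof=1)/√n; n=1 yields NaN.

## Compositional statistics

CLR: zeros are replaced multiplicatively at 0.65 × the smallest
positive entry of the row (configurable), positive parts shrunk to
preserve the row total, then rows are closed and log-centred. The 0.65
factor is the common detection-limit heuristic in compositional-data
practice; results are insensitive to it so long as it is ≪ 1. HCA uses
Euclidean distance on CLR values with Ward linkage — the standard
choice in Aitchison geometry — and sorts rows by label first so the
dendrogram is independent of input order; it is exported as Newick with
branch lengths equal to merge-height differences. PCA z-scores columns
by default (profiles mix percentages with total loads, which are not
commensurable otherwise), keeps all min(rows−1, cols) components so
variance sums to 100 %, and orients each loading vector so its
largest-magnitude entry is positive; zero-variance columns are dropped
with a warning under standardization. ANOVA/Tukey run on untransformed
percentages, and the compact-letter display uses the insert–absorb
algorithm with alphabetical group ordering, which guarantees that two
groups share a letter exactly when their adjusted pairwise p ≥ α.
HCA and morphology operate on species-mean profiles (replicate-mean
loads per compound), which is the natural row unit when the question is
between-species structure.

## Morphology rules

The cascade tests total-wax shares against a crystallizer threshold
θ = 15 %, the phase-separation level below which a compound cannot
segregate into epicuticular crystals. Epicuticular concentrations are
at least as high as total-wax shares (intracuticular wax dilutes them),
so the calls are conservative. R1 (tubules) precedes R2 (platelets)
because the tubule–secondary-alcohol relationship is the
better-established one; ties resolve by precedence, not margin. When
isomer data are available the tubule call additionally requires the
dominant C29 locant in {9, 10, 11}; without isomer data C29 dominance
suffices. The default call records a dominant non-crystallizing class
(triterpenoids or esters) when it exceeds 25 %, as the likely
explanation for a smooth surface despite a high wax load. The rule set
does not attempt per-surface (abaxial/adaxial) calls or upright
platelets: no compositional rule is defensible for those cases, and the
cascade intentionally does not guess.

## Synthetic data

The generator emulates the comparative survey design: species specs
carry a total load, class percentages summing to 100, per-class
chain-length weights, per-homologue isomer fractions, 5 replicates and
a multiplicative noise CV. Three archetypes ship as defaults — a
tubule former (secondary alcohols 53 %, C29-dominant, C-10-dominant
isomer), a platelet former (C31/C33 alkanes at 15/21 % of total wax
with C31/C33 secondary alcohols) and a film former (triterpenoids
38 %) — with the remaining classes filled to 100 % as documented
constants and totals of 35/30/20 µg cm⁻², inside the 3–40 µg cm⁻²
range typical of such surveys. Noise is lognormal with unit mean
(areas are positive and replicate CVs roughly scale-free); the default
CV is 0.15. The internal-standard area is fixed per sample so that all
quantification noise is attributable to analytes. Spectra carry both
α-fragments of each isomer at intensities proportional to its fraction
plus 8 background ions at 10–20 % relative intensity on non-diagnostic
m/z, exercising lookup specificity. Peak areas are the true loads
pushed backwards through the quantification equation, so at zero noise
the full chain recovers the configuration to ~1e−12 relative error.

What this does **not** emulate: retention behaviour and co-elution,
detector nonlinearity and saturation, response-factor differences
between classes, correlated (batch) replicate error, and fragment-pair
asymmetry within an isomer. Passing round-trip tests therefore
demonstrates the correctness of the analysis algebra and its inverses,
not robustness to instrument artefacts.

## Numerical and interface choices

All randomness flows from one `numpy.random.default_rng(seed)`; equal
seeds give byte-identical datasets. Fractions, class percentages and
chain percentages are asserted to their natural closure (1 or 100)
within 1e−9. Problem sizes throughout the tests and the acceptance
script are the study-design sizes themselves (3 archetypes × 5
replicates; fragment enumeration over chains C5–C40), which run in
seconds. The command-line interface is a thin click wrapper
(`simulate`, `quantify`, `isomers`, `stats`, `predict-morphology`,
`run-all`); the manifest records input/output SHA-256 hashes, options
and the seed, making re-runs verifiable.

## Known limitations

* Measured survey data for real species are not bundled; published
  variance percentages or absolute species loads can only be compared
  qualitatively against the archetype panel.
* The isomer estimator assumes equal response of the two α-fragments;
  systematic low/high-mass bias in a detector would bias fractions.
* The morphology cascade is a hypothesis encoder, not a trained
  classifier; categories outside its three calls (rodlets, upright
  platelets) are reported as `film_or_crust` by construction.
* Ester chain lengths are total carbon counts; acid/alcohol moiety
  decomposition is not modelled.
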