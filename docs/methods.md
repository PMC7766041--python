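# Methods

## Models

Both demographic models share a common archaic scaffold and differ only
in how the modern, non-African populations descend from Africa.

Demes: sampled Neandertal (N) and Denisova (D); unsampled
"introgressing" archaics — a Neandertal-related deme (NR), two
Denisovan demes (D1, D2) and a deep unknown archaic (AR); modern demes —
African (Y), European (E), Asian (A), Australo-Melanesian (P), two
African ghosts (G1, G2) and Basal Eurasian (BE); internal ancestors YG
(modern root), NNR, D12, DDR, DN, ADN and AM (global root).

**MD (multiple dispersals).** YG splits into Y and G1 at `tdYG1`; a
second African source G2 branches from Y at `tdYG2`. The first wave
leaves G1 at `tdOA1`, founding P (bottleneck at `tOAbot1`); the second
leaves G2 at `tdOA2`, founding the Eurasian stem EA (bottleneck at
`tOAbot2`), which splits into E and A at `tdEA`. BE branches from G2 at
`tdG2BE` and later contributes a fraction `paBEE` to E. Archaic pulses:
NR→G2 (`taNG2`, constrained between the second exit and G2's origin, so
the introgressed material is carried out of Africa), NR→EA (`taNEA`),
AR→P (`taARP`), D1→P (`taD1P`), D2→A (`taD2A`). Ten present-day
migration rates connect Y↔G1, G1↔G2, G2↔E, E↔A, A↔P; four "ancient
window" rates (prefix `m1`) connect G2↔EA and EA↔P between `tdEA` and
`tdOA2`. 50 free parameters.

**SD (single dispersal).** One exit: the stem G2 branches from G1 at
`tdOA1`; P branches from the stem at `tOAbot1`, BE at `tdG2BE`, and E/A
at `tdEA`. Both Neandertal pulses enter the stem — `taNG2` before P
branches (hitting all non-Africans), `taNEA` after (hitting only the
Eurasian ancestor). SD therefore drops exactly five MD parameters:
`tdYG2`, `tdOA2`, `tOAbot2`, and the two ancient-window rates tied to
the G2/EA coexistence window (`m1G2EA`, `m1EAG2`) — 45 free parameters.

The exact wiring of the ghost lineages, the onset convention of the
growth rates and the archaic split times are not uniquely determined by
the published model description; the choices above are this package's
own, recorded here and expressed declaratively in
`src/fdss_abc/models/{sd,md}.yaml`, which users can edit (the Discussion
variant with a single Eurasian→Papuan admixture pulse is expressible by
replacing the `m1EAP`/`m1PEA` windows with a pulse event).

### Fixed constants

Generation time 29 y; mutation rate 1.25 × 10⁻⁸ /bp/gen; intra-locus
recombination 1.12 × 10⁻⁸ /bp/gen (switchable off); fragment geometry
500 bp × 10,000. Archaic split times are fixed model-file constants:
AM 655 ky, ADN 590 ky, DN 415 ky, DDR 300 ky, D1–D2 250 ky, N–NR
150 ky; archaic sampling ages default to 120 ky (N) and 72 ky (D), all
configurable. Out-of-Africa founder (bottleneck) size: 250 diploids.

### Growth convention

The growth rates `rP` and `rEA` are in the 0.01–0.1 /generation range,
which makes exponential growth over a whole epoch numerically absurd
(e⁻³⁰-scale sizes); they can only describe a brief recovery. We
therefore model each exit as founder size `nBot` at the bottleneck
time, exponential recovery at the growth rate until the deme's modern
size is reached, and constant size afterwards. For the MD Eurasian stem
(which has no size parameter of its own) the recovery target is
max(nE, nA).

### Priors

The published prior table is not part of the main text; shipped priors
are uniform distributions whose bounds bracket the reported posterior
5–95% quantiles with margin: sizes U(100, 50,000) diploids; growth
rates U(0.01, 0.1); admixture proportions U(0, 0.1) except `paBEE`
U(0, 0.5); migration rates U(0, 10⁻³) per generation; times uniform on
ranges bracketing each reported posterior (e.g. `tdOA1` U(45, 125) ky,
`tdOA2` U(40, 65) ky). They are declared approximations, not published
values. Ordering constraints (each divergence older than every event on
its daughter lineages; each pulse younger than the divergence creating
source and sink) are enforced by rejection: only the parameters named
in violated constraints are redrawn (up to 10,000 rounds), which
preserves the marginal priors of untouched parameters better than
whole-vector rejection at similar cost.

## Simulation

msprime simulates each fragment as an independent replicate
(`num_replicates`), with merges expressed as ms-style full lineage
movements so ghost demes persist after daughters branch off. Mutations
are dropped by the package's infinite-sites generator (Poisson per
marginal tree on total branch length, branch-proportional placement,
ancestral 0/derived 1) — the semantics of classic ms, and ~2× faster at
500-bp fragments than the engine's finite-site generator, which remains
available (`mutations="engine"`) and is checked against it in the test
suite. Per-fragment θ ≈ 10⁻⁴–10⁻³, so recurrent mutation is negligible
and the infinite-sites approximation is safe. Reference-table row
(model *i*, index *j*) derives all randomness from the seed sequence
(master seed, *i*, *j*): tables are bit-reproducible row by row and
independent of worker count.

## Forests

Classification: 500 trees, sqrt(p) candidate features per split
(scikit-learn and ranger defaults); prior error rate and confusion
matrix from OOB votes. Posterior probability of the selected model:
1 − ε̂ with ε̂ from a 500-tree regression forest (p/3 features per
split, min leaf 5) on the OOB misclassification indicator, clipped to
[0, 1] — monotone in the predicted local error by construction. Ties in
the majority vote break toward the higher mean per-tree class
probability, then lexicographically.

Regression (per parameter): 500 trees, p/3 features per split, min leaf
5. Posterior summaries use quantile-regression-forest weights: a
training row's weight is its leaf co-occupancy with the observed point,
averaged over trees; quantiles are type-1 weighted empirical quantiles
(first value whose cumulative weight reaches q), which makes all
outputs deterministic given the forest seed. OOB R² is
1 − MSE_OOB/Var(θ); constant parameter columns are reported as skipped
(R² undefined). Zero-variance FDSS columns (empty histogram bins) are
dropped inside the forest wrappers; the external 6,060-column layout is
unchanged and checked, with the first mismatching column named on
error.

## Synthetic data and the real-data path

The generator emulates the real-data inputs: a sorted multi-sample VCF
(six unphased diploids, REF/ALT arbitrarily A/G — the FDSS is
allele-label agnostic), fragments laid end-to-start with exactly 10-kb
spacers on one synthetic contig, a BED fragment catalog, a trivial
all-callable inclusion mask and empty exclusion mask, a population map
and a JSON truth record (including the engine seed, so the data can be
re-simulated exactly). It does **not** emulate sequencing error,
coverage variation, genotype-likelihood uncertainty, linked selection
or reference bias; passing round-trip and recovery tests therefore
validates the statistical machinery, not robustness to real-data
artefacts. Fragment selection for real data is a greedy left-to-right
scan with a seeded random offset (the original placement procedure is
unspecified); sites with any missing or half-called genotype are
dropped site-wise, indels and multi-allelic records ignored.

## Reduced-scale study conditions

The full-scale design (100,000 simulations per model × 10,000 fragments
each; 1,000 pods) is a cluster-scale computation. The package's default
reduced scale, used by the test suite and `scripts/acceptance.py`, is:

* reference tables: 500 rows per model × 250 fragments per dataset;
* power-trend comparison: 100 vs 500 rows per model (the design's 5:1
  ratio), five subsample replicates;
* 10 pseudo-observed MD datasets for the end-to-end check;
* toy calibration: 5,000 rows × 200 fragments, 200 pods, on a
  one-parameter constant-size model whose two "populations" merge one
  generation ago (the single free parameter is the diploid size,
  U(1,000, 30,000)).

At this scale the prior error rate is substantially higher than the
full-scale ≈ 0.26 (fewer fragments mean noisier FDSS rows and fewer
training rows a weaker forest), but the qualitative results — SD/MD
distinguishable well above chance, error decreasing with table size,
deep-ancestor effective sizes (nAM, nYG) far more estimable than
migration rates and admixture proportions, near-nominal interval
coverage on the toy model — are scale-stable and are what the
acceptance checks assert.

## Known limitations

* Prior bounds and archaic split times approximate an appendix that is
  not reproduced here; absolute posterior numbers depend on them.
* The posterior-probability recipe is the single published
  error-regression variant; no local-error alternatives.
* ms command emission drops archaic sampling ages (ms cannot express
  ancient samples); it is intended for structural parity checks only.
* One diploid per population is assumed throughout the FDSS real-data
  path, as in the study design.
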