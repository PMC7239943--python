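# Methods

## Scope and data model

`icmet` models the computational half of an untargeted IC-MS experiment.
Its substrate is the *compound feature* — a retention-time/m-z pair written
as `"RT_mz"` (e.g. `14.33_146.0453`) with one intensity per sample — and the
*standards library*: authentic compounds with an elemental formula, the
adduct they ionise as, an experimentally determined retention time and,
where acquired, a reference HCD MS/MS spectrum. Sample metadata carries a
group label, a batch label and a role (`sample` or `QC`, the latter being
pooled mixtures of all study samples injected repeatedly).

## Theoretical chemistry

Atomic masses and isotope abundances are pinned in
`src/icmet/data/isotopes.csv` (masses from CODATA 2018 / AME2020,
representative abundances from CIAAW 2021); every theoretical mass in the
package derives from this one table. Deprotonation removes a *proton*, not
a hydrogen atom: the [M−H]⁻ delta is −(m_H − m_e) = −1.00727646688 Da, and
multiply charged species divide by |z|.

Isotope envelopes are computed exactly by polynomial expansion of each
element's isotope distribution (convolution with binary exponentiation over
atom counts), then **aggregated by nominal mass shift** (M, M+1, M+2, …).
An orbitrap at ~70k resolution does not resolve the fine structure within a
shift bin, so binned envelopes are what the instrument actually measures;
peak k is placed at (M + Δ_adduct + k·1.0033548)/|z|, the ¹³C spacing that
dominates CHNOPS metabolites. Envelope agreement is scored as
1 − mean_k |obs_k − theo_k| / max(theo_k, floor) over the first K bins
(defaults K = 3, floor = 0.01), clipped to [0, 1]. The score is
abundance-only: m/z spacing is already enforced by the binning convention,
and the comparison floor keeps near-absent theoretical peaks from dominating
the score. The metric is a package decision (thresholded "% matched" does
not itself define one) and both knobs sit in `IdentificationCriteria` so a
dot-product alternative can be swapped in.

## Identification

Four criteria, each with its own tolerance (defaults in parentheses):
accurate mass (5 ppm), retention time (30 s), isotope similarity (0.85),
and MS/MS (base peak + 2 further fragments, 12 ppm). Tier `identified`
requires all four; `identified_no_ms2` requires the first three when no
MS/MS exists on either side (a *failed* MS/MS comparison is disqualifying,
not ignorable). Features lacking a measured envelope have an unevaluable
isotope criterion: they are capped at `identified_no_ms2` and flagged
`no_observed_envelope` rather than silently promoted. The `putative` tier
matches an offline candidate table (a synthetic stand-in for a live
structure-database query, `data/putative_candidates_synthetic.csv`) at
< 5 ppm with isotope similarity > 0.90 and fragments where possible. The
0.85 library threshold and the 0.90 putative threshold are deliberately
distinct parameters. Ties among fully passing candidates are broken
lexicographically on (|ΔRT|, |ppm|, isotope score descending).

Isomers are first-class: records may share a theoretical m/z and are told
apart purely by retention time, which is why the RT gate matters — with
library isomers separated by more than twice the RT tolerance and jitter
below a third of it, cross-isomer assignment does not occur (enforced in
the test suite).

Exclusion rules remove features before annotation and are logged with a
reason; the canonical case is buffer-derived phosphate and its ion
clusters, which share one retention time and would otherwise dominate any
abundance-weighted multivariate model.

## Signal processing

EICs sum centroid intensities within a ppm window per scan. The peak
detector is intentionally simple — local maxima above a height floor,
valley-to-valley bounds with a 1%-of-apex baseline stop, trapezoidal
integration — and is a documented stand-in for vendor co-detection
software; it is excluded from any benchmark claim and is adequate for the
well-formed Gaussian peaks the simulator emits. In-source neutral loss
(e.g. PO₄³⁻ loss from nucleotide triphosphates) is quantified as the area
of the satellite peak *co-eluting* with the parent (default window 0.1 min)
divided by the parent area; a peak at the satellite mass eluting minutes
away is the endogenous metabolite and contributes zero. Across a dilution
series the satellite area is regressed on parent area: linearity (R² near
1) means the loss scales with concentration and does not distort relative
quantification.

mzML I/O is self-contained (stdlib XML): the reader handles centroided MS1
spectra with 32/64-bit base64 arrays, plain or zlib-compressed, RT in
minutes or seconds; the writer emits uncompressed 64-bit arrays. No
installed Python package in the target environment parses mzML, so this is
authored here rather than delegated.

## Preprocessing

Order is fixed: exclusions → missing-value filter → imputation →
normalisation → statistics-specific scaling. The missing-value rule keeps a
feature present (nonzero, non-missing) in ≥ 80% of the samples of at least
one group — a transparent, documented replacement for the opaque
co-detection heuristics of vendor software. Surviving missing
values are imputed as half the feature's minimum observed value. "Normalise
to all ions" divides each sample by its total ion signal and rescales to
the median total so values stay on the native intensity scale; scalar
(e.g. DNA-content) normalisation is available separately. Pareto scaling is
(x − mean)/√sd per feature (sd with n−1); it damps large fold changes
without flattening them, and a scaled row's variance equals the original
row's sd — the defining property, tested to 1e−9. QC %CV (100·sd/mean over
pooled-QC columns) is reported on **raw** intensities by default — %CV is a
ratio and is invariant to per-feature scaling but not to per-sample
normalisation, so the raw convention is the conservative one; callers can
pass a normalised table instead.

## Statistics

Fold change is mean(A)/mean(B) on normalised intensities; a zero
denominator leaves FC undefined rather than infinite. The default test is
Welch's (unequal variances are the norm for metabolite intensities);
Student and Mann–Whitney are one keyword away since the choice rarely moves
the significant set. BH-FDR is implemented directly (step-up with monotone
enforcement) and cross-checked against statsmodels in the suite; volcano
significance uses the FDR-adjusted q, not raw p, at FC > 2 and q < 0.05,
with "depleted" meaning FC < 1/2.

PLS-DA regresses a one-hot class matrix on the scaled intensity matrix
(NIPALS PLS2 via scikit-learn, no internal rescaling — scaling is an
explicit upstream step). VIP is computed from unit-norm weights and
per-component explained class variance; ΣVIP² = p to 1e−8 is asserted, and
the fitted weights/scores are cross-checked against an independent
hand-rolled NIPALS in the tests. Validation is leave-one-out: each sample
held out, the model refit, class assigned by argmax over predicted dummy
columns; Q² = 1 − PRESS/TSS. Defaults to 2 components. A training fold that
loses an entire class raises — the refit model would be degenerate — which
makes 2+2 the smallest validatable two-class design. Anchor correlation is
plain Pearson r across sample columns (QC excluded), split into positive
and negative passing lists at |r| ≥ 0.8. The Euclidean sample-distance
matrix is exported for heat-map use; rendering is out of scope.

## Pathways

A pathway is a member set plus an undirected reaction-adjacency graph.
Impact = Σ importance over significant members / Σ over all members, with
importance = betweenness centrality normalised by (n−1)(n−2)/2 **within
each connected component**; members absent from the graph carry zero.
Enrichment is an exact hypergeometric upper tail by default. The
permutation global test — Q = ‖Xᵀ(y − ȳ)‖² on sum-normalised,
Pareto-scaled member intensities, with group labels permuted ≥ 999 times
under a fixed seed — replaces the asymptotic version for transparency: the
permutation null needs no distributional assumptions and is exactly
reproducible. The bundled pathway library is a small curated mini-map
(10 pathways of human central metabolism, including tryptophan metabolism,
lysine degradation, TCA cycle, pentose phosphate, butanoate, glyoxylate);
it exercises the algorithms and is not a substitute for a full pathway
database.

## Synthetic data

The generator emulates what the statistics consume, with defaults chosen as
the study design the workflow targets:

| parameter | default | rationale |
|---|---|---|
| groups | 9 vs 9 | replicate tissue-culture design |
| features / library compounds | 200 / 50 | desk-scale table exercising all tiers |
| effect | 20 features at FC 4 | strong, unambiguous group signal |
| intensity model | lognormal, median 1e6, 20% CV | positive, right-skewed abundances |
| mass error | 1.5 ppm sd | typical orbitrap external calibration, inside the 5 ppm gate |
| RT jitter | 5 s sd | anion-exchange RT stability, inside the 30 s gate |
| QC | 3 pooled replicates at 5% CV | pooled-mixture re-injections |
| decoys | > 20 ppm off-library | unidentifiable by construction |

Observed envelopes get 2% multiplicative abundance noise and observed MS/MS
2 ppm mass noise. Scan sets place each compound as a Gaussian elution
profile (σ = 0.05 min, 0.05-min scans) with its theoretical envelope and
optional co-eluting loss satellites.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: chromatographic pathology (fronting, tailing,
the split peaks that zwitterions like glutamate can produce under
suppressed anion exchange), ionisation suppression and matrix effects,
correlated biology between metabolites (features are independent given
their group means), batch and injection-order drift, and missingness that
depends on abundance. The perfect identification and classification scores
on synthetic data are the expected behaviour of a correct implementation
under in-gate noise, not a claim about instrument data.

## Numerical choices and degenerate inputs

Envelope bins with zero probability are dropped; base-peak normalisation
makes abundances scale-free. Constant rows Pareto-scale to zero; constant
anchors raise. ppm errors require positive theoretical mass. BH output is
clamped to [p, 1] to absorb float rounding. Permutation p-values use the
add-one rule (1 + exceedances)/(1 + permutations). m/z-window queries use a
sorted index with bisection and are property-tested against a linear scan.
Library records without RT are admitted as "mass-only" and can never reach
an identified tier. All randomness flows through `numpy` Generators seeded
from explicit config fields; identical (config, seed) reproduces every
dataset byte-for-byte.

## Limitations

The identification engine assumes pre-aligned feature tables (no RT
alignment across runs); whole-run untargeted feature detection is not
attempted at vendor fidelity; positive-mode adducts beyond [M+H]⁺ and
charge states beyond |z| = 3 are out of scope; pathway namespace mapping
between identifier systems is limited to the names used in the library
files.
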