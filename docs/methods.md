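# Methods

## Harmonization

Inputs arrive as fitted Hill parameters (AC50, slope, Top) per
compound–assay pair, the form in which curated HTS repositories publish
concentration–response data. Each fit is evaluated on a shared grid of
45 log10-uniform molar concentrations from 1 pM to 100 µM; responses
are computed as `Top · expit(slope · (ln C − ln AC50))`, which is
algebraically identical to the rational Hill form but stable across the
grid's eight decades. Normalization rescales each curve so its own
baseline is 0 % and its own Top is 100 %, keeping direction in a
separate flag; the signed Top is retained on the curve object so
response units can be restored. Replicate profiles for one pair are
reconciled by *selection*: the replicate closest (mean squared
deviation) to the pointwise median is kept, on the view that the most
reproducible observed profile is preferable to a synthetic average.

Assays are screened by the sign pattern of their fitted Tops: positive
(both beyond +ε), negative (both beyond −ε), mixed (straddling), or
excluded (within ±ε, minimal modeled activity). ε defaults to 1 %
response — the cutoff is a tunable parameter because no consensus value
exists; results are insensitive to it unless assays cluster near zero
response. Because min ≤ max by construction, the "contradictory"
quadrant (minTop > 0 > maxTop) is unreachable.

## Hierarchical factorization

The harmonized tensor is decomposed through
`Assay = M1·Prot`, `Prot = M2·Path`, `Path = M3·Tox`, with all losses
masked MSEs over observed entries only. Mapping matrices `M1`/`M2` are
restricted to the sparsity of the curated annotation files; a dense,
unconstrained factorization of this size would be unidentifiable.
Weights are additionally kept nonnegative by default (`nonneg=False`
lifts this): the layers represent contributions of positive activities
to positive readouts, and nonnegativity removes the sign indeterminacy
that would otherwise leave recovered pathway scores defined only up to
±1. Scale per latent entity remains free; all downstream consumers use
reconstructions or correlations, which are scale-invariant.

Training per stage: a deterministic warm start by masked alternating
least squares (ALS), then refinement with Adam (initial step 1e-3), a
plateau scheduler that multiplies the step by 0.1 after 20
non-improving epochs, early stopping when the relative loss improvement
stays below 1e-6 for 20 consecutive epochs, and a 1000-epoch cap.
Pure small-variance random initialization was rejected: with Adam's
step size bounded near 1e-3, parameters starting at ~0.01 cannot reach
the data scale within the epoch budget, whereas ALS lands in the
correct basin in a handful of sweeps and Adam then minimizes the exact
masked MSE. A seeded N(0, 0.01) jitter is added after the warm start so
repeated trainings with different seeds probe basin stability.

Two numerical safeguards matter in practice. First, factor scales are
rebalanced every ALS sweep (latent rows normalized to unit RMS, the
scale folded into the mapping columns); without this, scale disparities
inherited from one layer cripple the conditioning of the next. Second,
the alternating solves use a scale-free Tikhonov ridge (1e-4 relative
to the Gram trace). Unregularized ALS occasionally produces
cancellation solutions — paired weights of order 10²–10³ with nearly
opposite latent rows — for entities that co-occur in promiscuous
assays; the ridge suppresses these while biasing well-scaled solutions
by ~0.01 %, and the subsequent Adam stage minimizes the unpenalized
loss.

Observability propagates through the hierarchy: a protein fiber is
flagged as modeled for a chemical only if at least one mapped assay was
actually observed for it, and likewise pathways from proteins and
endpoints from pathways. Latent values in unmodeled fibers are
numerically arbitrary (no loss term touches them) and are reported as
missing rather than as spurious zeros.

`Path`/`Tox` tensors are collapsed to scalar per-chemical scores by the
arithmetic mean over the concentration axis (maximum available as an
option). The mean weights the full response range rather than only the
asymptote; for monotone curves on a fixed grid it is a strictly
monotone function of potency and amplitude. Min–max normalization maps
each endpoint's scores to [0, 1]; a constant score vector maps to 0.5,
since with no spread there is no ranking information and the midpoint
avoids manufacturing extremes.

## Statistical filtering (building M3)

Continuous endpoints are stored as −log10 of the dose (mg/kg), so
higher values mean higher potency. A pathway–endpoint pair is retained
iff r ≥ 0.1, BH-FDR q < 0.05, and r ≥ 2/√n; the 2/√n floor rejects
correlations indistinguishable from noise at the pair's sample size,
and only positive correlations qualify (a pathway that *reduces* an
adversity score is not an adverse-outcome link). Binary endpoints use
a two-group rank comparison — exact Wilcoxon rank-sum when the pooled
sample has no ties (ties detected after rounding to 12 significant
digits, so binary-valued score paths through floating point are caught)
and Brunner–Munzel otherwise — with the rank-biserial correlation
(2·AUC − 1, half-credit for ties) as effect size and the r_rb > 0,
q < 0.05 retention rule. Confidence intervals use the Fisher
z-transform (sd 1/√(n−3)); dose endpoints can additionally request a
seeded percentile bootstrap (2000 resamples; degenerate constant
resamples are redrawn and counted).

FDR adjustment is applied within each endpoint across its candidate
pathways (a global-family mode is available). Per-endpoint families
match the per-endpoint retention counts this design reports and keep an
endpoint with many strong pathways from masking weak-but-real signals
in another.

## Scoring, classification, clustering, exposure

Quartiles are rank-based with edges at ⌈n/4⌉, ⌈n/2⌉, ⌈3n/4⌉ and stable
id-order tie-breaking; Q4 holds the highest predicted toxicity. GHS
acute-oral bands: high (LD50 ≤ 50 mg/kg), moderate (50 < LD50 ≤ 2000),
low (> 2000). NOAEL bands: high (≤ 15 mg/kg bw/day), moderate
(15 < NOAEL ≤ 300), low (> 1000); the (300, 1000] interval is not
assigned by the banding scheme and is reported as `unclassified` rather
than forced into a neighboring band.

Cluster toxicity profiles standardize each cluster's median endpoint
value against the mean and population sd of all compound-level values.
For binary endpoints coded toxic = 1, standardizing the reversed coding
and negating — the directional-consistency recipe — is algebraically
the same as standardizing the toxic = 1 coding directly, which is what
the implementation computes; either way higher z means more toxic.

Structural clustering uses 166-bit MACCS keys and Taylor–Butina sphere
exclusion at Tanimoto 0.7: candidates ranked by neighbor count,
ties broken by chemical-id order (making the procedure fully
deterministic and order-invariant), clusters under 5 members reported
with a null id. The largest common substructure per retained cluster
comes from an MCS search capped at 10 s with the best-so-far pattern
returned.

EC50 of a modeled curve is the concentration at half of the curve's own
maximal absolute response, located by linear interpolation of
|response| against log10 concentration; curves whose maximum stays
under 1 % of scale get no EC50. The curve's own maximum (not a fitted
Top) anchors the definition because layer-level modeled curves are not
Hill-parametrized. A compound is exposure-relevant when any target's
EC50 lies at or below its 95th-percentile Css (the slow-clearance
subpopulation), per layer; Css values are consumed from a table and
never computed here.

## Synthetic data generator

The generator emulates the statistical structure the model assumes,
with every generating quantity exposed as ground truth.

* **Latent pathway activity** is Hill-shaped per (pathway, chemical):
  slope uniform in [0.5, 3], AC50 log-uniform over the grid interior
  (one-decade margins), amplitude fixed at 100. The amplitude is fixed
  deliberately: per-curve Top normalization rescales every harmonized
  curve to its own plateau, so cross-chemical amplitude variation would
  be erased in preprocessing and is unrecoverable in principle; with it
  fixed, normalization reduces to a per-assay scaling and the bilinear
  structure survives harmonization exactly.
* **Potency coherence.** By default each chemical draws a compound-level
  log-potency and pathway AC50s scatter around it with sd 0.5 decades —
  a compound acts on its pathways at related concentrations. This keeps
  assay-level mixtures of pathway curves close to Hill-shaped, so the
  least-squares Hill refit (the format in which the generator emits the
  assay table) loses little information. With fully independent AC50s
  spanning six decades, the single-Hill refit of mixture curves is so
  lossy that even an oracle holding the true mapping weights cannot
  recover pathway scores — a property of the data, not the method. The
  independent mode remains available (`ac50_coherence_sd=None`) and is
  the default for the pathway/endpoint sub-generator used to
  characterize the association filter, where it is the least favorable
  (zero cross-pathway correlation) regime.
* **Mappings** are sparse Bernoulli masks with positive uniform weights
  in [0.5, 1.5], anchored: every column receives one dedicated row
  (each protein has a selective assay, each pathway a dedicated
  protein). Anchoring mirrors curated panels — screening programs
  include selective assays per target, and pathway databases contain
  genes unique to a pathway — and is the condition under which the
  masked factorization is identifiable up to scale; without it no
  method could recover the truth. At densities well below one entry
  per row every chain is single-valued, assay fibers are exactly Hill,
  and the emitted parameters reproduce the generating curves to
  numerical precision (the round-trip regime used by the exactness
  tests).
* **Endpoints.** Continuous endpoints are linear in the standardized
  true pathway score with Gaussian noise calibrated so the population
  correlation equals the requested r_true, placed on a −log10(mg/kg)
  scale centered near 300 mg/kg (location −2.5, scale 0.8 — spanning
  roughly 10–10⁴ mg/kg, the range of the dose bands). Binary endpoints
  come from a logistic link with slope 2r/√(1−r²) and default
  prevalence 0.5 (maximal rank-test power). Unlinked endpoints are pure
  noise.
* **Css** tables cover 15 % of compounds (log-normal percentiles),
  matching the sparse toxicokinetic coverage typical of real chemical
  inventories; **SMILES** come from a packaged library of ~90 small
  valid molecules in scaffold families (phenothiazines,
  organophosphates, alkanols, phthalates, …) so clustering has known
  family structure.

What the generator does **not** emulate: heterogeneous assay noise,
non-Hill (bell-shaped, cytotoxicity-confounded) curves, correlated
missingness, realistic chemical-space diversity, or annotation errors
in the mapping files. Passing tests therefore demonstrate correctness
of the algorithms under the model's own assumptions, not performance on
real screening data.

## Problem sizes and defaults

The default study is 20 assays × 45 concentrations × 300 chemicals with
8 proteins, 5 pathways, 5 endpoints (3 continuous, 2 binary), response
noise sd 0.05 %, and 10 % missing compound–assay pairs — large enough
that every stage (including promiscuous assays and masked fibers) is
exercised, small enough that a full staged fit takes seconds. The
association-filter characterizations use 50-seed repeats at n = 500
compounds (null: 100 pathways × 5 endpoints; power: r_true = 0.3), and
quartile enrichment averages 20 seeded studies of 150 chemicals.
Everything is deterministic given the seed; all randomness flows from
`numpy.random.default_rng`.

## Known limitations

* Factor recovery is only defined up to per-entity scale; raw `M1`/`M2`
  weights should not be interpreted quantitatively.
* Sequential (layer-by-layer) training matches the staged model
  description but cannot trade error between layers; no joint
  refinement is attempted.
* The Brunner–Munzel t-approximation is unreliable below ~5
  observations per group (a warning is emitted); its degenerate 0/0
  case (identical or fully separated groups) is resolved by the
  estimated dominance probability.
* `run_pipeline` aborts (with a FAILED marker) if no pathway survives
  filtering for some endpoint — such an endpoint is unmodelable by
  construction, and silently dropping it would hide the failure.
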