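# Methods

## The screening model

The pipeline analyzes screens of chemicals across a panel of 12 stimulated
human primary-cell co-culture systems (3C, 4H, LPS, SAg, BT, BE3C, BF4T,
HDF3CGF, KF3CT, CASM3C, MyoF, Mphg) read out by 148 biomarker endpoints,
each keyed `"SYSTEM:Biomarker"`.  Every adherent system carries an SRB
total-protein endpoint (a viability proxy); the two suspension-cell systems
(SAg, BT) carry PBMC-viability endpoints; five systems carry proliferation
endpoints.  Endpoints whose canonical response is a loss of signal
(viability, proliferation, secreted IgG, suppressible cytokines, collagen
III) are marked `is_down_readout` and sign-inverted before hit calling so
that all responses can be treated as positive; signature rules and all
profile-level analyses (similarity, clustering) operate on the un-inverted
matrix, and both orientations are retained.

Each chemical is screened as two blinded duplicate samples, one well per
endpoint per concentration over a 4-point series (2.2/6.7/20/60 µM by
default; series membership is per-sample, since solubility can truncate
series).  Every plate carries 8 vehicle wells per endpoint.

## Normalization and the significance envelope

A well's response is `log10(raw / mean of the 8 same-plate vehicle wells)`
for its endpoint.  Significance is judged against a historical-control
envelope: for each endpoint, the central interval covering 95% of
historical vehicle Log10Ratios.  The envelope estimator is the empirical
quantile interval (distribution-free, reproducible); a normal-theory
alternative (mean ± z·sd) is available behind `envelope_method="normal"`
since the historical estimator used in production screens is not uniquely
determined.  Envelope comparisons are strict: a value exactly on a bound is
inside (conservative).  Bounds are clipped to contain 0 so the envelope is
always vehicle-centered.

## Hit calls and LOEC

Per endpoint, baseline variability (bmad) is the median absolute deviation
of the responses pooled from every sample's two lowest tested
concentrations, scaled by 1.4826 (the normal-consistency constant; 1.0 is
available via `mad_scale` since conventions differ).  The response cutoff
is `coff = max(3·bmad, log10 1.2)`, i.e. never less than a 1.2-fold change
(0.0791812 in log10 units).  A sample is active on an endpoint when its
direction-corrected response at any concentration strictly exceeds coff
(ties inactive); the LOEC is the lowest such concentration.  Each blinded
duplicate is hit-called independently; replicate concordance (percent of
endpoints with equal hit calls) is reported per chemical with a mean ± sd
screen summary.  Samples contributing a single concentration enter the
bmad pool with that concentration.  Whether production pipelines pool both
duplicates' baseline responses is not documented; this implementation
pools them.

## Cytotoxicity

Two notions are deliberately kept apart:

* **overt cytotoxicity** — any cytotoxicity-role endpoint (SRB, PBMC
  viability) strictly below −0.3 at a sample-concentration (threshold rule
  on the profile itself; the signature engine re-applies the −0.3 level
  with `≤`, and a `signature_cytotox_strict` switch covers the `<`/`≤`
  ambiguity between the two published phrasings);
* **positive cytotoxicity endpoints** — the count of cytotoxicity-role
  endpoints with hitc = 1 and LOEC ≤ the concentration of interest.

Chemicals active on ≥2 cytotoxicity endpoints are nonspecifically
cytotoxic.  Chemical-level reports average the count over duplicates
(hence fractional counts like 4.5).  Profiles with more than two positive
cytotoxicity endpoints are removed before clustering and similarity
search, because broad suppression mimics every inhibitory mechanism.

## The nine-signature engine

Signatures are small biomarker rule sets associated with in-vivo toxicity
risks.  Evaluation is stepwise per sample-concentration on un-inverted
values: acute toxicity first (≥3 SRB endpoints ≤ −0.3, at least one in an
endothelial system 3C/4H/LPS/Mphg); acute-flagged concentrations are not
assessed for anything else.  Liver toxicity (3C:SRB ≤ −0.3) flags and
continues.  The remaining rules combine envelope significance with a 20%
effect size: organ toxicity (3C:Proliferation < −0.1 without 3C
cytotoxicity), immunosuppression (T-cell proliferation loss, or combined
IgG + B-cell proliferation loss, or PBMC cytotoxicity < −0.3), thrombosis
(3C:TF > 0.1 without 3C cytotoxicity), skin irritation (LPS:PGE2 > 0.1
with TNFα not significantly decreased), skin sensitization (Collagen III
< −0.1), skin rash (HDF3CGF:VCAM-1 > 0.1), vascular toxicity (CASM3C:SAA
> 0.1).  Design readings where the published wording is ambiguous: the
IgG/B-proliferation pair is a conjunction; its thresholds reuse the
−0.1 + envelope criterion; "increased or unchanged TNFα" means not both
outside the envelope and negative; only 3C:Proliferation drives organ
toxicity (other endothelial proliferation endpoints are an extension
point).

A chemical's flag at a concentration requires both duplicates flagged
there.  The summary lists the minimum flagged concentration when flagged
at ≥2 concentrations (rendered `>=conc`) or at the top concentration
(rendered bare); a single non-top flag summarizes to `nd` (the listing
convention defines only those two branches — an explicit choice); `NA`
means no concentration was assessable (e.g. acute toxicity everywhere).

## Similarity search

Profiles are matched by sample Pearson correlation over the intersection
of endpoint panels (≥3 shared endpoints; queries overlapping <50% of the
reference panel are rejected with a warning).  The search returns at most
10 matches with r strictly above 0.6, ranked by descending r with
deterministic ties (label, then concentration); reference profiles with
more than two positive cytotoxicity endpoints are excluded by default.
Same-mechanism profile pairs are expected at r > 0.7.

## SOM clustering

Batch self-organizing map on a rectangular grid: codebooks are initialized
deterministically on the first two principal-component axes (±2 sd), and
each epoch reassigns profiles to nearest codebooks (unweighted Euclidean —
values share the Log10Ratio scale, so no standardization) and replaces
codebooks with Gaussian-neighborhood-weighted means, the radius decaying
linearly from max(grid)/2 to 1 over 100 epochs.  Cluster ids run from the
lower-left node to the top-right (`r·cols + c + 1`).  The production tool's
hyperparameters are unpublished, so these defaults are this package's own
(all configurable); exact reproduction of any particular published map is
out of scope.  The workflow is two-pass: 7×7 on all profiles, then 6×6
after removing rows with >2 positive cytotoxicity endpoints.  With a final
radius of 1 codebooks remain neighborhood-smoothed (on very small grids
they sit between cluster means), which affects codebook values, not
partitions.

## QC

Plate %CV is `100·sd/mean` of vehicle raw values, computed per
plate × endpoint and aggregated to the plate by the maximum (a plate is as
good as its worst endpoint; configurable).  The positive-control test:
each reference profile is correlated with the mean of the others
(leave-one-out); the 1st percentile of those values (linear interpolation
between order statistics — the percentile rule is not otherwise specified)
is the 1% false-negative cutoff; a new control passes when its correlation
with the mean reference profile exceeds it.  An assay is accepted when the
positive control passes and ≥95% of plates have %CV < 20%.

## The synthetic-screen generator

Measurement noise is multiplicative lognormal on raw values — vehicle wells
are `B·10^N(0,σ)`, treatment wells `B·10^(effect + N(0,σ))` — so that
normalized Log10Ratios are Normal around the planted effect, matching the
ratio-then-log processing.  One noise sd is shared by all endpoints;
σ = 0.05 log10 units by default, chosen as a realistic assay noise level:
it yields a 95% envelope of ±0.098, blinded-duplicate hit-call concordance
near 99%, and same-archetype profile correlations near 0.8.  Historical
controls default to 23 runs × 8 wells per endpoint.

Chemical archetypes place effects on named endpoints in each endpoint's
canonical direction, zero at the two lowest concentrations (so the bmad
pool stays baseline) and stepping to full size at an onset concentration,
making the planted LOEC exact.  Effect magnitudes (0.3–0.8) follow the
response patterns of the corresponding reference-compound classes: strong
IgG/proliferation/cytokine suppression for the calcineurin-inhibitor-like
archetype, broad cytokine suppression with an SAA increase for the
glucocorticoid-like one, strong IgG loss with multi-system
anti-proliferative effects for the antimetabolite-like one.  Magnitudes
were set analytically so every archetype's expected same-mechanism
correlation at σ = 0.05, `r ≈ s/(s+σ²)` with `s` the across-endpoint
effect variance, is ≥ ~0.8, satisfying the r > 0.7 mechanism benchmark
with margin.  The default archetype mix makes ~21% of chemicals bioactive,
typical of broad environmental-chemical screens.  The cytotoxic archetype
alternates between top-concentration-only and all-concentration
suppression so both the top-concentration listing and the fully-masked
(`NA`) summarization branches occur; single-signature actives alternate
onset for the same reason.

`ScreenTruth` records archetypes, planted LOECs, cytotoxicity counts and
expected signature outcomes via an independent transcription of the rules;
at σ = 0 the pipeline must reproduce it exactly, and does (this is the
strongest end-to-end test).  What the generator does **not** emulate —
plate-position effects, donor-pool variability, per-endpoint noise
heterogeneity, raw ELISA optics, correlated biological responses outside
the planted patterns — bounds what passing tests show about real screens:
they verify the analysis logic, not robustness to structured artifacts.

## Problem sizes and numerical choices

The shipped analysis uses a 100-chemical screen (130,240 wells); recovery
statistics use 50 chemicals with uniform 0.3 planted effects; similarity
recovery uses 200 query draws; SOM purity uses 4 archetypes × 30 profiles;
QC pass rates use 100 reference profiles and 2,000 draws.  These sizes
give stable statistics while keeping every script and the test suite fast.
Degenerate inputs are defined errors: correlations of constant profiles,
envelopes from fewer than two values, %CV of a single well, SOMs on empty
profile sets.  All tie-breaks (cutoff exceedance, envelope bounds,
similarity ordering) are documented above and covered by boundary tests.

## Known limitations

Concentration–response curve fitting and potency modeling are explicitly
out of scope (the LOEC convention replaces them).  The signature engine
implements the nine published rules only.  Analytical-QC grades are
carried as metadata and never gate computation.  The reference database
and SOM reproduce the published *procedures*; reproducing any specific
published cluster memberships or similarity tables would require the
original proprietary reference data.
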