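# Methods

This note records the models, the parameter choices that matter, what the
synthetic-data generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## The RH retention model

A hybrid clone retains a random set of fragments of the irradiated donor
genome. We model breakage along each chromosome as a homogeneous Poisson
process with rate 1/(100·kb_per_cR) per kb, so the probability of at least
one break between two points d kb apart is θ = 1 − exp(−d/(100·kb_per_cR)),
and map distances come out directly in centirays, d(cR) = −100·ln(1−θ).
The irradiation dose is absorbed into the kb_per_cR constant (default
27.5 kb/cR for a 3500-rad panel) rather than modelled mechanistically.
Each fragment is retained independently with probability r (default
0.117). The diploid donor is treated as haploid-equivalent — one fragment
lattice per chromosome — because presence/absence genotyping cannot
observe copy number; this is the standard RH approximation for a
homozygous clonal donor line.

### Two-point likelihood

For a marker pair the informative clones (both calls in {0,1}) form a 2×2
table. Under equal retention the cell probabilities are P(1,1) =
r(1−θ)+r²θ, P(1,0) = P(0,1) = rθ(1−r), P(0,0) = (1−θ)(1−r)+θ(1−r)².
The MLE is found by L-BFGS-B with an analytic gradient from three starts
(the moment initializer r₀ = (2n₁₁+n₁₀+n₀₁)/2N, θ₀ = (n₁₀+n₀₁)/(2N·r₀(1−r₀));
a high-θ start; a central start), plus an exact evaluation of the θ = 1
boundary where the model degenerates to independent margins. Against an
exhaustive 10⁻³-lattice search over all informative tables with N ≤ 40 the
optimizer never falls below the lattice optimum (max deficit ~10⁻¹⁴).

The unlinked (null) likelihood uses marker-specific retentions
rA = (n₁₁+n₁₀)/N, rB = (n₁₁+n₀₁)/N rather than a shared r, which guards
against spurious LOD from retention differences between markers. Ambiguous
calls drop the clone for that pair only (missing at random). θ̂ is capped
at 1−10⁻⁶ and distances at 300 cR to keep arithmetic finite; pairs with
fewer than 25 informative clones cannot form group edges.

### Grouping and refinement

Groups are single-linkage components at LOD ≥ 4.0. With ~10⁴–10⁵ null
pairs in a panel, spurious LOD ≥ 4 edges between chromosomes occur at a
small but real rate; the pipeline therefore re-analyses any group whose
best internal order contains an adjacent θ̂ > 0.8 (a bridge no real
adjacency should show) at stepwise thresholds 4.5, 5.0, …, 7.0 until the
group is clean or the schedule is exhausted (then it is flagged
`persistent-aberration`, never silently kept). The θ-ceiling test is an
explicit stand-in for the "obvious aberrations" a human analyst would
spot; it is injectable for testing.

### Multipoint likelihood and ordering

Along an order, each clone's states follow a two-state Markov chain with
stationary start (r, 1−r) and transitions
T(ret→ret) = (1−θ)+θr, T(ret→lost) = θ(1−r), T(lost→ret) = θr,
T(lost→lost) = (1−θ)+θ(1−r). Calls are emissions with an optional flip
error ε (default 0 — vectors are assumed pre-cleaned; exposed as a
parameter); ambiguous calls contribute no emission factor, i.e. both
states are marginalized. The chain is stationary and reversible, so an
order and its reversal have identical likelihood — verified to 10⁻⁹.

Group retention r is the presence fraction over *unique* call vectors, so
typing the same position twice never shifts the estimate (and adding a
duplicated marker provably leaves the group length unchanged). When ε = 0
and no call is ambiguous the chain is fully observed and the profile
log-likelihood decomposes into per-edge terms; ordering then becomes a
symmetric maximum-weight Hamiltonian path problem with precomputable edge
weights, which is the fast path for search and for the exhaustive test
oracle. With ambiguity, candidate moves are screened with plug-in pairwise
thetas (a lower bound on the profile likelihood) and refitted by
coordinate ascent (≥2 sweeps, until the gain is < 10⁻⁶) at acceptance
points. Search is greedy best-insertion from the highest-LOD pair, 2-opt,
and a sliding window-4 ripple, best of 10 seeded restarts; ties break
toward the canonical orientation (lexicographically smaller end marker),
then first-found. Coordinates are written at 0.1 cR precision.

Markers with fitted adjacent θ = 0 — identical informative call vectors —
are merged into one map position. We read "co-localized" as exactly
identical vectors; a nonzero tolerance is configurable.

## What the generator emulates, and what a green test establishes

The generator produces: the fragment lattice and call matrix described
above; genotyping noise (false negatives on true presents, false positives
on true absents, then uniform ambiguity blanking, each from an independent
seeded substream); a two-cluster fluorescence mixture for scoring tests; a
meiotic map over the microsatellite subset with cM = kb / kb_per_cM
(default 840 kb/cM) and an optional split-LG label to create a mergeable
pair; and model-species genomes derived from the true order by fusions,
fissions, reciprocal translocations and inversions plus per-species
ortholog dropout, emitted as aligner-style hit tables.

Defaults are the panel this package models: 190 clones, r = 0.117,
27.5 kb/cR, 840 kb/cM, one marker per 800 kb (the real map's density),
11% microsatellites (154/1358 in the real marker set), noise rates
fp 0.005 / fn 0.01 / ambiguous 0.02 (the vectors genotyping platforms
deliver after cluster-quality filtering), and four model species whose
missing-ortholog rates (0.22–0.47) mirror published anchor recovery from a
close percomorph relative out to a distant outgroup.

Not emulated: dose–response physics, clone-level retention heterogeneity
(the panel's per-clone retention spread suggests some; the default is
homogeneous, left as a config extension), selection-marker-linked
retention bias, and chimeric fragments. A green recovery test therefore
establishes correctness of the inference given the model, not robustness
to these real-data pathologies.

## Statistical limits the tests respect

Two limits follow from the information content of a 190-clone panel at
r = 0.117 and shape what "recovery" can mean:

* **Per-edge distance error.** For θ fitted on one panel the per-clone
  Fisher information gives SE(d)/d ≈ 0.30 even at the most favorable gap
  (~35 cR), so a single panel cannot achieve a 15% median per-edge error —
  no estimator can. Distance calibration is therefore judged on fitted
  distances averaged over 20 independent seeded panels of the same genome
  (median |error| ≈ 3–6%); the single-panel pooled median is ≈ 0.29,
  consistent with the Cramér–Rao bound.
* **Resolution floor.** A 5 cR gap produces about two informative
  (discordant) clones, so markers a few cR apart are not orderable; real
  maps show the same as co-localized positions. Order recovery is judged
  up to whole-group reversal and permutation of markers with identical
  call vectors, and recovery worlds use gaps ≥ ~10 cR between distinct
  positions. Similarly, adjacent gaps beyond ~35 cR have an appreciable
  chance of a two-point LOD < 4, so exact-partition grouping tests use
  gaps of 5–30 cR; at realistic uniform density chromosomes legitimately
  split into several RH groups, as real maps do.

## Comparative conventions

Hit filtering uses the score ≥ 250 floor with the 80–300 nt alignment
window (a 50 bp minimum appears in one description of the same filter;
both bounds are configurable). The anchor is the best surviving hit's
interval midpoint; strand is ignored and orientation inferred from
coordinate monotonicity. Hits on an "unknown" chromosome count toward
Venn totals but are excluded from anchors. Non-anchored markers do not
break CS runs (per-species anchor sets are independent). CSO decomposition
is greedy left-to-right into maximal strictly monotone runs — chosen over
minimal decomposition for determinism; the two agree except that a greedy
run can absorb one marker of an adjacent inverted block when the boundary
continues the running direction, which is why breakpoint-recovery tests
allow a one-marker flank. Tied ortholog coordinates are an error by
design. Whether a CS may span arbitrarily many skipped non-anchored
markers is unstated upstream; there is no gap limit by default and a limit
is configurable.

## Calibration conventions

cR/cM is the pooled ratio of summed distances of consecutive shared-marker
pairs within (RH group ∩ LG); zero-cM pairs are excluded. The
consecutive-pair rule is an explicit stand-in for an unstated historical
choice of 82 pairs. kb/cM is an input constant (default 840) rather than
recomputed from genome size over genetic length, because the two published
values disagree (1060 Mb / 1311 cM ≈ 808); reported ratios round to one
decimal, coverage to integer percent, and the reported physical size uses
the 1-decimal kb/cR (the convention under which the published chain's
numbers are self-consistent: 34,084 × 27.5 = 937,310 kb). kb-per-marker is
truncated to the kilobase (1,060,000/1358 → 780); mean spacing is total cR
over the number of map positions (34,084/1255 → 27), the convention that
reproduces the published figure. Shared-pair spacing matters: in sparse
simulated worlds the consecutive shared markers sit 100+ cR apart, where
the convexity of −100·ln(1−θ̂) inflates distance estimates and with them
the cR/cM ratio — the familiar RH map-expansion effect, visible in the
07_calibrate driver's simulated-world chain.

## Known limitations

* The HMM-path order search screens neighbours with plug-in thetas; for
  groups ≳50 markers with many ambiguous calls a full profile-likelihood
  2-opt would be slow and is not attempted.
* `select_clones` rescues sole carriers only; a coverage-curve criterion
  (marginal marker gain per clone) is not implemented.
* FISH constraints order and orient groups but intra-group marker order is
  never altered by FISH; contradictions are reported, not resolved.
* The calibration chain assumes cM ∝ kb genome-wide; regional
  recombination-rate variation is not modelled.
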