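# radmap

Radiation-hybrid (RH) map construction, genetic-map integration and
comparative synteny for fish genomes — built as a tested, fully offline
pipeline with a synthetic-panel generator so every stage runs without
external data.

## The problem

An RH panel is a collection of rodent–donor hybrid cell lines, each
retaining a random subset of fragments of a γ-irradiated donor genome.
Two markers that are physically close tend to survive on the same fragment
and are therefore co-retained across clones; co-retention statistics order
markers at a resolution between genetic linkage and sequencing. This
package implements the whole chain for a tilapia-style panel (190 clones,
~11.7% fragment retention, dose-calibrated so that 1 cR ≈ 27.5 kb):

1. **Genotyping** — threshold scoring of two-channel fluorescence
   intensities into present/absent/ambiguous calls (default threshold
   0.30, explicit ambiguity band), retention statistics, clone selection
   with a sole-carrier rescue rule.
2. **Two-point linkage** — for each marker pair with counts
   n₁₁, n₁₀, n₀₁, n₀₀ over informative clones, the haploid equal-retention
   model

       P(1,1) = r(1−θ) + r²θ
       P(1,0) = P(0,1) = rθ(1−r)
       P(0,0) = (1−θ)(1−r) + θ(1−r)²

   is maximized over the breakage fraction θ and retention r; the LOD
   compares it against independent retention with marker-specific rates.
   Groups form by single linkage at LOD ≥ 4.0; groups with an aberrant
   internal order (adjacent θ̂ > 0.8) are re-analysed at stepwise
   thresholds up to 7.0. Distances are d(cR) = −100·ln(1−θ).
3. **Multipoint ordering** — each clone's retention pattern along a
   candidate order is a two-state Markov chain (retained/lost) with
   stationary start (r, 1−r); ambiguous calls are marginalized. Order
   search is greedy insertion from the highest-LOD pair plus 2-opt and a
   window-4 ripple, best of 10 seeded restarts. Markers with identical
   informative calls co-localize at one map position.
4. **Integration** — RH groups anchor to genetic linkage groups (LGs)
   through shared microsatellites; one group carrying ≥2 anchors from each
   of two LGs merges them into one chromosome; groups are ordered by mean
   anchor cM and oriented by rank correlation or end-marker LOD; FISH
   constraints override statistics and conflicts are reported.
5. **Comparative synteny** — ortholog hits filtered (score ≥ 250,
   alignment 80–300 nt, best hit per species), conserved segments (≥2
   consecutive markers on one model chromosome), singletons, CSO runs
   (maximal strictly monotone coordinate runs), Oxford grids.
6. **Calibration** — shared marker pairs give cR/cM; with kb/cM known,
   kb/cR, the physical map size and genome coverage follow.

## Worked example

```python
from radmap import calibrate_from_sums, map_stats_from_counts

cal = calibrate_from_sums(n_pairs=82, sum_cr=18_446, sum_cm=604,
                          total_map_cr=34_084, kb_per_cm=840,
                          genome_size_kb=1_060_000)
print(cal.reported_cr_per_cm, cal.reported_kb_per_cr,
      cal.reported_map_size_kb, cal.reported_coverage_percent)
# 30.5 27.5 937310.0 88
```

30.5 cR per cM is the pooled ratio of RH to genetic distances over the 82
shared pairs; dividing 840 kb/cM by it gives 27.5 kb per cR; a 34,084 cR
map is then 937,310 kb, i.e. 88% of a 1060 Mb genome.

The full synthetic-world analysis is a sequence of numbered drivers:

```sh
python analysis/01_simulate_panel.py --seed 1     # panel + truth files
python analysis/02_score_genotypes.py --seed 1    # intensity scoring
python analysis/03_two_point_groups.py --seed 1   # LOD groups
python analysis/04_order_groups.py --seed 1       # cR maps
python analysis/05_integrate_genetic_map.py --seed 1
python analysis/06_comparative_synteny.py --seed 1
python analysis/07_calibrate.py --seed 1
```

Each prints what it found (e.g. `0 groups mix chromosomes`,
`CS decomposition matches simulator truth on 16/16 combinations`) and
writes tab-delimited tables under `results/`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch on a seeded synthetic world
(simulation → scoring → two-point → grouping with refinement → multipoint
ordering → integration → synteny → calibration) and the published-input
calibration chain, then writes the acceptance JSON. It takes ~2 minutes on
one CPU.

## Layout

    src/radmap/       the library: simulate, genotyping, linkage,
                      ordering, integration, comparative, calibration,
                      io, evaluate
    analysis/         numbered narrative drivers over the library
    tests/            pytest suite; tests/test_acceptance.py holds the
                      end-to-end acceptance checks
    docs/methods.md   model assumptions, parameter choices, limitations
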