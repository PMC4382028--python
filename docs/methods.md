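# Methods

## The assay being modelled

The package analyses (and simulates) a sectored-colony reciprocal-crossover
(RCO) assay in a W303-1A × YJM789-like hybrid diploid. The two daughter
cells of the division in which a crossover occurred found the red and white
halves of one colony, so a sector pair carries the four chromatids of that
division: two per sector. Allele-specific hybridization gives each sector a
per-SNP ratio pair (ratio_A, ratio_B); one copy of an allele hybridizes at
~1, two copies at 1.5–2, zero at 0–0.5.

The model of event formation is the standard DSB-repair one: a lesion on one
homolog is repaired off the intact homolog, writing a gene-conversion tract
adjacent to the exchange point. A G2 lesion breaks one chromatid, so among
the four chromatids exactly one is converted (a 3:1 tract). A G1 lesion is
replicated into two broken sister chromatids; both are repaired off the
homolog, giving 4:0 where their tracts overlap (equal repair lengths → pure
4:0; unequal → a nested hybrid 4:0/3:1). Patchy correction of heteroduplex
produces complex tracts: interleaved converted/unconverted intervals.

## Zygosity calling and segmentation

Calls: HET when both ratios lie in [0.7, 1.3]; HOM_A when ratio_A ≥ 1.4 and
ratio_B ≤ 0.6 (HOM_B symmetric); otherwise AMBIGUOUS. The bands sit inside
the conventional ranges with a guard gap, so borderline ratios abstain
rather than vote. The defaults are configurable (`CallingThresholds`).

Segmentation is a transparent run-length rule rather than an HMM: transition
coordinates must be exactly the flanking observed SNPs (that is how the
tract-length arithmetic is defined), which an HMM's posterior smoothing
would obscure. AMBIGUOUS calls are skipped; isolated runs shorter than
`min_run` (default 2 SNPs) whose two neighbours agree are reassigned to the
neighbour state. Absorption passes are synchronous — all decisions in a pass
are made from the same run structure before any is applied — which keeps the
rule invariant under reversing the profile (mirror symmetry); edge runs are
never absorbed, since a genuine LOH transition can sit at the profile end.
Smoothing trades a small amount of resolution for noise robustness: a true
single-SNP conversion patch is indistinguishable from an isolated miscall
and is smoothed away at the defaults; analyses of noiseless simulations use
`min_run=1`.

## Classification, timing, donor, tract lengths

The two sectors' per-SNP states combine as HET→(1,1), HOM_A→(2,0),
HOM_B→(0,2) copies of allele A, giving a partition of the chromosome into
regions labelled 2:2 (ground or reciprocal), 3:1, or 4:0 at the union of
both sectors' transition points. An event must end in reciprocal LOH (red
homozygous A, white homozygous B, or the converse) — otherwise it is not an
RCO and the classifier raises.

The conversion zone runs from the first non-ground region to the start of
the reciprocal zone. Classes: NO_GC (empty zone: both sectors' transitions
coincide); SIMPLE_3_1 / SIMPLE_4_0 (a single region of that count);
HYBRID_4_0_3_1 (one contiguous block with exactly one 4:0 region and
adjacent 3:1 region(s) sharing its donor); COMPLEX otherwise — interior
returns to 2:2, donor switches, or multiple 4:0 blocks. Timing: 3:1 → G2;
4:0 or hybrid → G1; complex with ≥1 4:0 region → G1, else G2; NO_GC is
unclassifiable. The donor homolog is the allele with count > 2 in the zone
(MIXED when regions disagree).

Tract lengths: min = distance between the outermost SNPs inside the tract,
max = distance between the closest flanking SNPs outside it, avg =
(min+max)/2 exactly. Complex tracts use only the first and last transitions.
NO_GC events use min = 1 bp and max = the distance between the heterozygous
and homozygous SNPs closest to the breakpoint. Distances are coordinate
differences (right − left, endpoints exclusive); a tract whose outermost
SNPs coincide is floored at 1 bp, and a tract reaching the map edge is
reported open-ended (max and avg undefined) rather than guessed. All
coordinates are 1-based inclusive; BED input is converted on read and
nowhere else.

## Breakpoint enrichment

Each crossover contributes one window, from the last SNP heterozygous in
both sectors to the first SNP of the reciprocal zone — the region most
likely to have contained the initiating break. The window fraction is
f = Σ window lengths / (screened length × number of sectors); per-event
windows are summed without merging (each sector is an independent screen of
the same interval; a merge flag exists for sensitivity analysis). Expected
in-window features = features-per-interval × sectors × f; observed counts
feature-window overlaps, so a feature hit by k events' windows counts k
times, matching the expectation's replication. Features whose size would
inflate their overlap (Ty-like elements) are collapsed to midpoints when
`midpoint_rule` is set. The test is a two-cell (in-window / out-of-window)
1-df Pearson χ² with no continuity correction; expected counts below 5 are
flagged. Feature classes are tested independently without multiple-testing
correction (a Bonferroni helper is trivial for callers that want it).

## Statistics

* Sectoring rates are events per colony screened (the assay design makes
  the frequency a per-division rate), with Wilson score 95% intervals —
  the score interval without continuity correction, i.e. Newcombe's
  method 3. Endpoints at 0/n and n/n are exactly 0 and 1.
* Fisher exact p is two-sided by the minimum-likelihood convention (sum of
  hypergeometric probabilities ≤ the observed table's); the χ² on 2×2
  tables is Pearson, 1 df, no Yates correction by default (flag available).
  Both are scipy-backed; the tests verify them against exhaustive
  enumeration on all small tables.
* Mann-Whitney uses exact enumeration for tie-free samples with n ≤ 20 per
  group and the tie-corrected normal approximation otherwise.
* The deletion/addition asymmetry of tandem-array alterations is tested as
  a two-sided exact binomial against 0.5 — the natural test of the
  symmetry hypothesis; no specific test is canonical for this comparison.
* Tandem-array copies = round((fragment − flank)/unit), the exact inverse
  of the simulator's fragment-size formula. The reference CUP1 arrays are
  14 × 2.0 kb (flank 2.0 kb → ~30 kb EcoRI fragment) and 7 × 1.2 kb (flank
  3.6 kb → ~12 kb); the flank lengths are back-solved from those fragment
  sizes and are configuration, not measurement.
* SpeI genotype: {~750, ~500, ~250} bp → HET; {~500, ~250} → homozygous
  YJM789; {~750} → homozygous W303-1A; anything else UNRESOLVED; matching
  tolerance ±30 bp.

## The simulator and what it does (not) emulate

`generate_snp_map` draws marker positions uniformly (default scale: 2300
SNPs over 1.1 Mb, the density of the assay interval). `simulate_rco_event`
implements the four-chromatid bookkeeping above; `sample_rco_events` draws
the event mix: 13% of crossovers without detectable conversion, 75% of
lesions in G1 (half of G1 events with equal repair lengths), tract lengths
log-normal with median 10.6 kb and log-sd 0.9 (spontaneous tracts span
<100 bp to >50 kb; the generative law is a modelling choice — only medians
are observable). Complex tracts are produced by patchy repair: Poisson
switch points (default rate 0, typical 1/5 kb when used) alternate
converted/unconverted pieces, anchored converted at the break.

Ratio noise is i.i.d. Gaussian (sd 0.12) around means 1.0 / 1.75 / 0.25 —
the midpoints of the conventional calling ranges — floored at 0. Real
microarray noise is neither Gaussian nor homoscedastic and has spatially
correlated artifacts; passing round-trip tests therefore demonstrates the
logic of the calling/classification chain and its noise tolerance at a
realistic amplitude, not performance on any particular array platform. The
sd default was chosen so that noiseless recovery is exact while noisy
recovery is high but imperfect.

The tandem-array CNV simulator fires unequal-exchange events per homolog
per subculture (Bernoulli, default p = 0.1), deleting with probability 0.78
(the observed 47:13 deletion bias) and stepping a truncated-geometric
number of repeats (p = 0.5, max 5); copy number is floored at 1. No
per-event magnitude distribution is observable in fragment-size data, so
the step law is a simulation choice, not an inference.

Out of scope by design: break-induced replication vs crossover distinction
distal to the rDNA, events inside the rDNA (the arrays carry no rDNA SNPs),
probe-level microarray simulation, and whole-genome CNV calling beyond the
three-state zygosity call plus the tandem-array arithmetic.

## Numerical and design notes

* Determinism: every stochastic function takes a seed (numpy Generator);
  the CLI refuses stochastic runs without one.
* The classifier resolves the crossover only to the transition interval
  between flanking SNPs; simulated truths are scored against the class
  *observable at marker resolution* (a tract covering no SNP is NO_GC), so
  round-trip tests measure the pipeline, not marker density.
* Problem sizes in the test suite and acceptance script (500-event
  round-trips, 10,000-replicate coverage runs, 1,000-run null calibration,
  4,000 CNV trajectories) were chosen as the smallest sizes at which the
  Monte-Carlo error is well below the tolerance being checked.
* Known limitations: no support for multi-chromosome profiles in a single
  table (one map per chromosome); the enrichment module assumes a single
  screened interval; transition curation of very noisy real profiles may
  need manual review, as the smoothing rule is deliberately simple.
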