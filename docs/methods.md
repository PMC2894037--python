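# Methods

## Signal model

For hybridization *i* ∈ {N, T} (matched normal, tumor) and SNP *j*, the input
is a pair of nonnegative summarized allele intensities (θ_ijA, θ_ijB),
re-expressed as the total signal θ_ij = θ_ijA + θ_ijB and the allele B
fraction β_ij = θ_ijB/θ_ij. The transform is bijective except at θ = 0, where
β is stored as NaN (an explicit missing marker produced deliberately, never a
0/0 artifact). Derived quantities:

- tumor total copy number: C_Tj = 2·θ_Tj/θ_Nj (diploid reference scaled to 2;
  NaN when θ_Nj = 0);
- allele-specific copy numbers: (C·(1−β), C·β), summing back to C;
- mirrored BAF |β − ½| and decrease in heterozygosity DH = 2|β − ½|, defined
  so DH ≈ 0 under allelic balance and DH ≈ 1 in pure-tumor LOH. DH is
  computed for any SNP but is only meaningful for SNPs heterozygous in the
  normal, and all downstream defaults restrict to those.

Positions are 1-based; region intervals are closed in base pairs (the CLI
accepts Mb and converts). Non-polymorphic probes carry θ but no β; they pass
through untouched.

## The normalization

The observed BAF decomposes as β = μ + δ, where μ is the true allele B
fraction and δ a SNP-specific effect that is reproducible between the two
hybridizations of a pair. From the normal, δ̂_Nj = β_Nj − μ̂_j with μ̂_j the
called genotype. The tumor correction is genotype-stratified:

- μ̂ ∈ {0, 1}: β̂_Tj = β_Tj − β_Nj + μ̂_j. Not truncated to [0, 1] by default
  (an optional clamp exists): keeping the correction linear avoids biasing
  downstream segmentation statistics.
- μ̂ = ½: β̂_Tj = β_Tj − η_j·(β_Nj − ½), η_j = β_Tj/β_Nj if β_Tj ≤ β_Nj else
  (1 − β_Tj)/(1 − β_Nj). In regions of allelic imbalance the heterozygous
  cloud is compressed toward ½ (regression slope < 1), so subtracting the full
  normal deviation would overcorrect; η ∈ [0, 1] scales the correction by
  exactly the observed compression. Closed forms: β̂ = β_T/(2β_N) on the lower
  branch and 1 − (1−β_T)/(2(1−β_N)) on the upper, so the heterozygous output
  always lies in [0, 1] and is monotone in β_T.

Degenerate cases: a het call with β_N ∈ {0, 1} leaves η undefined; the SNP is
passed through unnormalized and flagged rather than silently fabricated.
Missing β or missing genotype likewise pass through flagged. Applying the
correction to the normal itself returns μ̂ bit-for-bit — the SNP effect is
removed completely — which is the strongest self-consistency check and is
asserted in the tests.

On the intensity scale the same correction reads
(θ̂_TA, θ̂_TB) = (θ_T·(1 − β̂_T), θ_T·β̂_T): signal is moved between the two
alleles of the tumor while their total is preserved (the identifiability
constraint of the paired design — implemented as (θ − θβ̂, θβ̂), which
conserves the sum to one ulp, and bitwise for β̂ ≥ ½). Total signals and TCN
are never modified: only methods using allele B fractions gain from the
normalization.

The correction is strictly per-SNP (no cross-SNP coupling), so it runs in
O(J) time; tables are processed in chunks (default 10⁶ SNPs) so memory is
bounded by the chunk size, not by J.

## Naive genotyping of the normal

When no population-based calls are available, the normal's genotypes are
called from {β_Nj} alone: a Gaussian-kernel density estimate (Silverman
bandwidth by default, overridable) is evaluated on a 512-point grid over
[0, 1], with kernel mass reflected at both boundaries so the homozygous bands
at 0 and 1 register as proper modes and the density integrates to ≈ 1 on the
unit interval. The thresholds are the density minima between the three
largest-prominence modes (two thresholds; one for the two-class hemizygous
case), and every SNP is called with the same thresholds. A SNP exactly on a
threshold is assigned to the heterozygous (middle) class — the documented tie
rule. Pooling all autosomal SNPs into one density is the default; callers can
genotype chromosome subsets separately if desired.

The confidence score is the distance from β_N to the nearest threshold — zero
exactly on a density valley, growing with distance — the simplest monotone
score consistent with "close to a valley means doubtful". `filter_by_confidence`
keeps the ⌈(1 − f)·n⌉ most confident calls (ties broken by genomic order);
dropping the lowest-confidence 10% measurably lowers the het-call error rate,
because naive miscalls are by construction SNPs near a valley. External calls
(AA/AB/BB/A/B/NC TSV) can be used in place of naive calls; SNPs missing from
the external set pass through unnormalized.

## Contamination model

The tumor sample is modelled as a fraction κ (purity) of homogeneous tumor
cells with parental copy number (C₁, C₂), C₁ ≤ C₂, mixed with 1 − κ normal
diploid cells, with average tumor ploidy two. For a normal-heterozygous SNP:

    β* = (κ·b + (1 − κ)) / (κ·(C₁ + C₂) + 2(1 − κ)),  b ∈ {C₁, C₂}
    DH* = κ·(C₂ − C₁) / (κ·(C₁ + C₂) + 2(1 − κ)) = 2|β* − ½|

(NaN for a pure homozygous deletion, the one zero-DNA case). The power to
detect a change point is driven by Δ(κ) = |DH*₂ − DH*₁| of its flanking
states, under the approximation that DH variance is level-independent. For
deletion (0,1) vs copy-neutral LOH (0,2), Δ(κ) = κ(1 − κ)/(2 − κ) vanishes at
both κ = 0 and κ = 1 and peaks at κ = 2 − √2 ≈ 0.59 — an intermediate purity
is *best* for that transition. `argmax_purity` finds maximizers by a
1001-point grid scan refined with bounded golden-section search (tolerance
10⁻⁶, ties to the smallest κ). The model assumes one tumor clone; no
multi-clone mixtures, and the package does not estimate κ, call states or
estimate ploidy.

## Detectability evaluation

Each change point is specified by a region, the change-point position, a
safety margin excluded on both sides (absorbing localization error) and the
two flank states. Signals compared — raw DH, normalized DH, TCN — are always
evaluated on the same normal-heterozygous SNPs, with the same per-flank
sample size, so numbers are comparable across signals:

- **bootstrap t**: B repetitions (default 100) of drawing J′ SNPs (default
  250) from each flank without replacement (a with-replacement mode exists)
  and computing the absolute pooled-variance Student t statistic (Welch
  behind a flag); reported as mean ± sd.
- **ROC**: flank values pooled after balancing class sizes by sampling; the
  positive state is the flank whose total copy number differs from two; the
  orientation (whether larger values indicate positive) is chosen from the
  sign of the mean difference and recorded, because the DH direction flips
  for deletion-vs-LOH comparisons. AUC is trapezoidal with ties collapsed to
  single threshold steps.
- **binning**: values averaged (non-robust mean) in non-overlapping,
  position-ordered bins of exactly H SNPs; a trailing incomplete bin is
  dropped so per-bin variance stays constant. H = 1 is the identity. At
  H > 1 the bootstrap draws J′/H bins so the genomic span sampled stays
  comparable across resolutions — a package choice, since the t statistic is
  usually quoted at full resolution only.

All randomness flows from a single seed through one named generator; the
full report is bit-reproducible.

## Synthetic data generator

`simulate_pair` emulates the signal structure the method relies on, and only
that:

1. positions uniform within tiling, non-overlapping segments; genotypes by
   Hardy-Weinberg with per-SNP MAF ~ U(0.2, 0.5);
2. per-SNP, per-allele multiplicative affinities (φ_A, φ_B), log-normal with
   log-scale sd σ_φ = 0.3, *shared between tumor and normal* — the
   mechanistic source of the reproducible SNP effect (and of the η < 1
   compression in aberrant regions, with no extra parameters);
3. tumor-cell allele copy numbers from the segment's (C₁, C₂), allele B
   placed on either parental copy with probability ½ at het SNPs; mixture
   copy numbers κ·c_tumor + (1 − κ)·c_normal;
4. intensities θ = φ·(c/2)·scale + offset + ε, ε Gaussian with sd
   σ_ε = 0.03 (in units of the diploid total signal), truncated at zero. The
   additive offset (default 0) reproduces the BAF compression of incomplete
   offset correction.

Defaults are the conditions used throughout the tests; with σ_φ = 0, offset 0
and σ_ε = 0 the observed TCN equals the true mixture TCN exactly. What the
generator does **not** emulate: genomic waves, GC bias, batch effects,
probe-specific crosstalk beyond the affinity model, or multi-clone tumors —
so passing tests demonstrate correctness of the method's arithmetic and its
qualitative behavior under the stated model, not performance on real arrays.

`table1_scenario` lays out the five canonical transitions — normal/gain
(N/G), gain/copy-neutral-LOH (G/L), normal/deletion (N/D), deletion/LOH
(D/L) and a no-change control (N/N) — on two synthetic chromosomes, one
10 Mb block per flank with a 1 Mb safety margin, sized so each flank carries
the requested number of heterozygous SNPs. The default study runs at
κ = 0.7 with 500 het SNPs per flank, J′ = 250, B = 100 — small enough to
complete in seconds while leaving the bootstrap summaries stable.

## Known limitations and numerical notes

- Homozygous-path outputs can leave [0, 1] (by design; optional clamp).
- The generator's homozygous SNPs have zero B-allele signal when offset = 0,
  hence no hom SNP effect; claims about within-genotype variance reduction
  are therefore exercised at offset > 0, where all three genotype bands carry
  a shared effect (as on real arrays).
- Under additive intensity noise, DH variance is *not* level-independent: a
  hemizygous-deletion flank has roughly half the DNA of a gain flank and
  proportionally noisier BAFs. Consequently the fine-grained ordering of
  detectability between the two easiest transitions (G/L vs N/D) can deviate
  from the Δ(κ) ordering, while the coarse ordering — {G/L, N/D} far above
  N/G, D/L hardest — is robust and is what the tests assert.
- Mean normalized DH per region tracks DH* closely but is not calibrated:
  the package normalizes across SNPs, it does not calibrate mean levels.
- KDE genotyping assumes all three bands are populated; very small inputs
  (< 100 defined BAFs) or missing modes raise informative errors instead of
  guessing.
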