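# Methods

## Data model

The pipeline's canonical intermediate is the per-sample, per-site count
pair (*m*, *k*): the number of reads carrying the deaminated base and the
total coverage at a transcript-strand cytidine (genomic C on "+"
transcripts, genomic G with A-reads on "−"). All internal coordinates are
0-based half-open; VCF input is converted from 1-based on load and BED
output is written 0-based. Tables can be derived from coordinate-sorted
BAM + indexed FASTA (base quality ≥ 20, mapping quality ≥ 10,
duplicate/secondary/QC-fail reads excluded — the pileup thresholds mirror
the Q20 trimming convention of the upstream processing), or read from TSV,
or generated synthetically. When a site falls in an unannotated region it
is evaluated on both strands and tagged; annotated positions are evaluated
on the transcript strand only.

## Statistical test and filters

Each site is tested against a per-base background mismatch probability *e*
with a one-sided binomial upper tail P[X ≥ m], X ~ Bin(k, e). A binomial
null is the simplest defensible model for sequencing-plus-alignment error
at a single site and makes every downstream decision reproducible and unit
testable. *e* defaults to 10⁻³ (Q30-scale error); when a count table
carries non-deamination mismatch pools the rate is estimated by pooling
those and clamping to [10⁻⁵, 0.05].

The filter cascade per sample (or per cell) is: SNP-mask removal, k ≥ 10,
m ≥ 2, Benjamini–Hochberg FDR < 0.01 across the sample's surviving sites,
then m/k > 5 % (strict inequality, matching the printed "> 5 %"). Hard
count filters precede FDR so the multiple-testing family contains only
sites that are testable on counts alone; the ratio filter comes last so it
cannot shrink the family. BH ties are resolved by a stable sort on
(p, chrom, pos). The FDR family is one sample — or one cell, where the
family is small and per-cell FDR is correspondingly weakly powered (a
documented caveat, not a bug).

Bulk composition: sites present in ≥ 2 of 3 YTH replicates are merged by
summing m and k over the supporting replicates; the WT and APOBEC1-only
backgrounds are removed as the union over their replicates (maximally
conservative); the surviving sites must show editing ≥ 1.5× the
replicate-merged mutant ratio. The 1.5× comparison is inclusive ("at
least") and evaluated exactly on integer cross-products
(m_yth·k_mut ≥ 1.5·m_mut·k_yth) so threshold cases do not depend on
floating-point rounding. A site absent from the mutant control passes with
infinite fold.

## Cluster-specific background correction (single cells)

Nonspecific deamination differs between cell clusters, so a global control
is not enough. For each cluster the APOBEC1-YTHᵐᵘᵗ cells provide two
"average editing" summaries: the pooled editing rate (Σm/Σk over unmasked,
non-control sites — the cluster's scalar average C-to-U activity) and the
per-site mean mutant ratio over cells covering the site at k ≥ 10. A
called site in a YTH cell of that cluster survives only if

1. its per-cell ratio exceeds the per-site mutant mean (the adjusted
   ratio, ratio − mean, is positive and recorded), and
2. it remains significant when re-tested against the cluster null
   max(e, pooled rate, per-site mean), with BH control within the cell.

The first rule is a direct per-site subtraction of the cluster background
average. The second exists because called false positives are, by
construction, the upper tail of the background distribution (calling
already demanded m ≥ 2 and m/k > 5 %), so subtracting a *mean* can never
remove the background excess on its own: whatever remains above the mean
is exactly the part a mean subtraction cannot see. Re-testing against the
cluster's own rate restores calibrated error control in every cluster and
is what makes high-background clusters comparable to clean ones. With a
zero background both rules reduce to the original per-cell call (the
correction is the identity), and a background that is uniform across
clusters gives the same result as a single global correction — both are
enforced as tests. Known variant positions and sites already removed as
bulk-control background are excluded from the pooled rate, which should
describe uniform nonspecific editing, not site-specific artifacts that are
handled per site. Clusters with no mutant cells fall back to the global
mutant background and are flagged; unlabeled cells form an "unassigned"
pseudo-cluster corrected with the global average.

Cluster labels are an input (barcode → cluster TSV), produced by any
external clustering; the pipeline is agnostic to how they were obtained.

## Stoichiometry and homogeneous sites

m/k at a site estimates the fraction of transcript copies modified there.
Ratio analyses exclude observations with k < 10, and m/k = 1 means exact
integer equality m == k — counts are integers and no floating tolerance is
appropriate. Histograms use 0.05-wide bins over [0.05, 1.0] with a
dedicated terminal bin for exactly 1. The homogeneous-site rule — at least
one cell at m/k = 1 plus ≥ 5 *other* cells (any cluster) below m/k = 0.9
at k ≥ 10 — exists to reject unannotated germline variants, which are
saturated in every covering cell and therefore can never produce five
sub-stoichiometric witnesses. Condition contrasts (e.g. WT vs
METTL3-depleted) classify matched sites as lost (ratio 0), reduced, or
unchanged on replicate-pooled ratios; sites without adequate contrast
coverage are reported "uncalled" rather than conflated with "lost".

## Metagene coordinates

Sites are mapped to the longest mature isoform of the gene whose exons
contain them (ties by lexicographic transcript id), in spliced coordinates.
Offset 0 is the first nucleotide 3′ of the stop codon's last base;
profiles count sites in 25-nt bins over ±500 nt. Sites up to 500 nt
(genomic, strand-aware) past an annotated 3′ end are classified
TTS_downstream and included in profiles with offset = 3′UTR length +
downstream distance; sites on transcripts without a CDS are ncRNA and
excluded from stop-codon profiles; sites intronic in every containing
isoform are excluded and logged. The profile anchor is the stop codon
throughout (transcription-termination labels in common visualizations are
treated as the stop codon, the anchor the density axes actually use).

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes; it
defines the study conditions for every test.

* **Transcriptome** — random multi-exon coding genes on both strands:
  5′UTR 100–250 nt, CDS 600–1500 nt (whole codons), 3′UTR 600–1200 nt,
  1–4 exons, introns 100–400 nt; extra isoforms share the structure with a
  truncated 3′UTR so the longest-isoform rule is exercised. Written as
  standard GTF + FASTA.
* **m⁶A sites** — offsets from the stop codon drawn from Normal(+118, 30)
  nt and snapped to the nearest transcript-strand C (the 3′-biased
  placement typical of this modification); stoichiometry π per site,
  default U[0.2, 1]. The bulk preset places 20 % of sites uniformly along
  the mature transcript so region composition is non-degenerate (~80 % of
  sites in the 3′ region, as in real DART-seq data).
* **Counts** — coverage k ~ NegBin(μ = 50, φ = 0.5) (heavily
  overdispersed, so low-coverage dropout is common, as in practice); then
  m ~ Bin(k, p) with p = e + b_cond + [YTH]·π·η at m⁶A sites, p = 1 − e at
  SNPs (every condition — germline variants look saturated everywhere),
  and p = e + b_cond elsewhere. Defaults: e = 10⁻³, nonspecific
  deamination b = 5·10⁻³ for every APOBEC1-bearing condition, b = 0 for
  WT, editing efficiency η = 1.
* **Background ("artifact") sites** — the WT/APOBEC1 controls in real
  experiments call specific deamination-prone sites; a uniform rate cannot
  reproduce that, so the generator plants condition-independent sites
  edited at rate 0.25 in every condition. The rate is chosen so that these
  sites are robustly detectable in control samples at the study's coverage
  — being *called* in controls is their defining property; a rate near the
  m ≥ 2 / 5 % detection floor would instead model sites the controls
  cannot see.
* **Single cells** — per-cluster background multipliers λ scale b; at an
  active m⁶A site a cell is homogeneous with probability h (then
  p = 1 − e, so m = k up to sequencing error) and heterogeneous otherwise.
  h = 1 produces SNP-mimics (saturated in every cell but absent from
  variant databases), the adversarial case for the homogeneity heuristic;
  the default homogeneous sites use h = 0.3 and π = 0.5 so plenty of
  sub-stoichiometric witness cells exist. Cells use a restricted site
  universe (all planted sites plus 600 random null cytidines) to keep the
  per-cell matrix sparse and desk-sized.
* **Determinism** — every stream derives from one integer seed via
  numpy SeedSequence lists (all below 2³¹); integer count outputs make
  reruns byte-identical across platforms.

Study presets: `bulk-basic` (80 genes, 200 m⁶A, 50 SNPs, 100 background
sites, 3 replicates × 4 conditions), `sc-clusters` (40 genes, 4 clusters ×
30 YTH + 30 mutant cells, one cluster at λ = 5, 15 homogeneous sites at
h = 0.3, 10 SNP-mimics, matched bulk controls on the same site universe),
and `ko-contrast` (300 sites on a π grid {0.1, …, 1.0} × 30, simulated
with e = 0 and b = 0 so observed m/k isolates binomial sampling of the
stoichiometry — with nonzero backgrounds the mean ratio estimates
e + b + π rather than π; the KO genotype sets π to 0 for half the sites
and halves it for the rest). These problem sizes keep any full run within
seconds while leaving every rate estimate enough observations to be
meaningful.

## What the synthetic tests do and do not show

Passing tests demonstrate that the statistical machinery is correct under
its own assumptions: binomial editing given coverage, independent sites,
cluster-constant nonspecific rates, exhaustive SNP masks, correct cluster
labels. Real data violate several of these — editing probability depends
on sequence context and distance from the m⁶A site, deamination can hit
several neighboring cytidines per binding event (a window-radius stress
option exists but defaults to single-site planting), coverage tracks
expression, clusters are imperfect, and variant databases are incomplete.
Recovery rates measured here are therefore upper bounds on real-data
performance, not predictions of it.

## Numerical choices and degenerate inputs

Binomial tails come from scipy's survival function (m = 0 gives exactly
1). BH uses statsmodels with a deterministic pre-sort. Fold thresholds are
integer cross-product comparisons (see above). Empty tables, empty cells,
header-only VCFs and zero-transcript GTFs all yield empty results rather
than errors; malformed VCF rows and exon-less transcripts are skipped with
warnings; missing conditions and min_rep exceeding the replicate count are
configuration errors. Zero-coverage pileup columns are dropped. Histogram
bin edges are rounded to 10 decimal places so 0.05-stepped grids are
exact.

## Known limitations

Per-cell FDR is weakly powered (few testable sites per cell). The
error-rate estimator needs non-deamination mismatch pools that pileup
emits but the count-TSV schema only carries optionally. The mutant fold
rule compares replicate-merged ratios on both sides; per-replicate fold
variants are not implemented. The generator does not model UMIs, doublets,
ambient RNA, context-dependent editing, or read-level artifacts, and its
optional SAM emission exists only to exercise the pileup path.
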