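# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the problem was genuinely open.

## R-gene classification

A gene model is called an R-gene when it satisfies one of three rules, in
order: (i) it carries a canonical resistance domain (NB-ARC, TIR or RPW8);
(ii) it carries a common-but-unspecific domain (LRR, kinase, Malectin)
together with at least one R-gene-associated motif hit anywhere in the
protein; or (iii) a curated override is supplied. LRR + kinase
architectures without an NLR anchor are labelled RLK-like (receptor-like
kinase candidates). Rule (ii) deliberately requires only one motif hit with
no positional constraint: motif evidence is treated as corroboration, not
localisation.

NLR subtypes are assigned from domain presence flags {TIR, RPW8, CC,
NB-ARC, LRR}. The N-terminal class uses the precedence TIR > RPW8 > CC,
which matches the empirical disjointness of TIR- and RPW8-bearing proteins;
a simultaneous TIR + RPW8 architecture is classified TNL and logged as an
anomaly, never silently dropped. The LRR flag is recorded in the subtype
only on top of a nucleotide-binding domain — the taxonomy has no X-LRR
class without NBS, and no RPW8-NBS-LRR class, so RPW8-NBS-LRR flags
collapse to RPW8-NBS. Families are a pure function of subtype: NBS-only
{NBS, NBS-LRR}, CNL {CC-NBS, CC-NBS-LRR}, RPW8-type {RPW8, RPW8-NBS}, TNL
{TIR, TIR-NBS, TIR-NBS-LRR}. The classifier is exhaustively tested against
a hand-written 32-row truth table.

Two accounting functions exist on purpose: `subtype_table` aggregates
call-level subtypes (families are exact component sums), while
`family_summary` operates on family-level counts directly, for comparison
with published family tables whose printed family rows do not exactly equal
their printed component sums.

### Coiled-coil detection

Coiled coils are detected by sliding heptad-register scoring: every residue
receives the maximum geometric-mean propensity over all windows (14, 21 or
28 residues; default 21) and all seven register phases covering it, using a
bundled heptad position-weight profile constructed for this package
(hydrophobics favoured at core positions a/d, charged residues at e/g,
helix breakers G/P penalised throughout; `data/coil_profile.tsv`). Scores
map to probabilities through a two-Gaussian model — P = N_cc / (N_cc +
30·N_glob) with per-window mean/s.d. constants calibrated so that ideal
heptad repeats exceed 0.99 and glycine runs stay near 0 — and segments are
maximal runs with probability ≥ 0.5. This is the structure of the classic
ncoils method; the profile and Gaussian constants are this package's own
calibration, and all tests validate against a brute-force scorer using the
same bundled profile. Unknown residues and X are neutral (propensity 1).

### Tandem clusters

Clusters are maximal runs of R-genes on one chromosome with consecutive
inter-gene gaps ≤ `max_gap` (default 100 kb) and ≥ `min_size` members
(default 3). Both parameters are configurable; the defaults are round
numbers at the scale of plant NLR clusters, since no operational definition
accompanies published cluster counts.

## Subgenome ancestry

Each gene is scored against both ancestor CDS sets with a seeded local
alignment: an exact shared `word_size`-mer (25) is required, after which
the score is the exact Smith–Waterman optimum under match +1 / mismatch −1
and a linear gap cost of 2 per column (gap existence 0 + extension 2
reduces affine gaps to linear). The significance filter is a raw score ≥
word_size — one perfect seed — standing in for a permissive e-value
threshold; the decision is dominated by the A-vs-B argmax, not the filter.
Ties and no-pass cases are labelled `neither` rather than broken
arbitrarily, because an arbitrary tie-break would bias the headline
retention statistic. N never matches. The kernel is numba-compiled;
candidate subjects are pre-filtered through a 25-mer index, so only
sequences that can seed are aligned.

Retention bias is the per-category share of gene counts; expression bias is
the per-category share of summed TPM averaged over a sample subset; the
delta (expression % − retention %) quantifies expression dominance beyond
gene-content dominance. Chromosome labels of the form
`<prefix><group>-<homeolog>` (e.g. `Fvb5-2`) drive per-group dominant-
homeolog flags; unparseable labels are counted under "unplaced" and logged.

## dN/dS (Nei–Gojobori 1986)

Ortholog pairs come from a provided synteny map when available, otherwise
from the best seeded-alignment hit above threshold. Proteins are aligned
globally (BLOSUM62, gap open 10 / extend 0.5, via Biopython's
PairwiseAligner, whose internal deterministic tie-break is adopted); codon
alignments are built by expanding each aligned residue to its source codon
(gaps to `---`), with trailing stop codons trimmed and any
translation mismatch reported with its codon position.

Counting follows classic NG86: per-codon synonymous site fractions from the
standard code (changes to stop codons count as nonsynonymous); observed
differences averaged with equal weight over all minimal substitution
pathways, excluding pathways through stop codons unless all are (then all
are used); pN = Nd/N, pS = Sd/S; Jukes–Cantor correction
d = −¾ ln(1 − 4p/3), flagged saturated at p ≥ ¾; ω = dN/dS, flagged
undefined at dS = 0. Codon pairs containing gaps, N or stops are excluded
from both site and difference counts. NG86 is used instead of an ML codon
model deliberately: it is closed-form and verifiable by exhaustive pathway
enumeration, which the test suite does with an independently written
oracle; published ML-based medians are therefore not expected to be
bit-reproduced. Group contrasts use scipy's one-way ANOVA and Pearson
correlation of ω against mean log10(TPM + 1).

## eQTL mapping

Phenotypes are per-gene fruit TPM vectors, Box-Cox transformed with λ
maximising the profile log-likelihood over [−5, 5] by golden-section search
(tolerance 1e-5), with an offset of 1 applied when any value is ≤ 0 (TPM
zeros are routine).

Markers pass QC in three steps: only PHR/NMH quality classes are kept;
progeny calls impossible under the recorded parental genotypes are set to
missing (individuals without pedigree entries are retained unchecked); and
markers left monomorphic are dropped. Every action is counted in an audit
log.

Association uses y = μ + family covariates + marker·β + u,
u ~ N(0, σg²K), with K the VanRaden genomic relationship matrix
(mean-imputed dosages, monomorphic markers excluded). K is spectrally
decomposed once; the variance ratio δ = σe²/σg² is profiled per model fit
by a coarse log-grid plus bounded refinement of the *restricted* likelihood.
REML rather than ML is load-bearing here: the centred-dosage K is exactly
singular along the intercept direction, and the ML profile degenerates to
δ → 0 there, while the REML term cancels the divergence. With K omitted the
model reduces to OLS, and with K = I the mixed-model p-values equal the OLS
p-values to numerical precision (a test asserts this). Family membership
enters as fixed covariates to absorb the multi-family structure.

Per-gene marker p-values are BH-adjusted; an eQTL locus requires ≥ 2
significant (q < 0.05) markers co-locating within a 5 Mb window on one
chromosome — the multiple-co-locating-marker rule — with the minimum-q
marker as peak. A locus is cis when its peak lies on the gene's
diploid-projected chromosome within the 5 Mb cis window, giving gene phases
cis, cis+trans or none; trans-only outcomes are reported but logged as
unusual. The 0.05 gate is applied per marker (per-gene gating is available
through the q_threshold argument). Heritability is σg²/(σg² + σe²) =
k̄/(k̄ + δ̂) from the null mixed model, falling back to the adjusted R² of
the peak-marker regression (clipped to [0, 1]) when no kinship is
available.

## RenSeq probes

Per exon of length ≥ 120 nt, 120-mers are tiled at offsets 0, step, 2·step
(default step 120, i.e. abutting) plus a final probe anchored to the exon
end, guaranteeing ≥1× coverage of every CDS base of that exon; no probe
crosses an exon–exon junction, so panels work for genomic and cDNA
libraries alike. Exons shorter than 120 nt remain uncovered with a logged
warning — the junction rule is absolute. Conserved NB-ARC/TIR/RPW8
intervals (protein coordinates ×3 lifted through the exon structure) are
densified with half-step probes. Screening drops probes matching any
intergenic window at ≥ 90% identity over the full 120 nt (seeded alignment
score ≥ 108) or with GC outside [0.30, 0.70]; the GC window is this
package's stated stand-in for proprietary hybridisation-thermodynamics
selection.

The capture simulator places reads (100 nt) either uniformly within
probe-covered intervals ± 200 nt flank (probability = on-target affinity,
intervals weighted by width) or uniformly in the genome, and reports read
fractions in R-genes, other genes and intergenic space plus per-R-gene
depth. The acceptance checks compute the exact geometric expectation of the
R-gene read fraction and verify the simulator reproduces it to binomial
error.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions. A common-ancestor gene
set (random codons, clean ORFs) is split into two diploid descendants at
10% mutual divergence (5% per branch, synonymous-biased: nonsynonymous
proposals accepted with probability 0.5, stop-creating proposals rejected,
start/stop codons protected). The octoploid carries 7 groups × 4 homeologs
× 72 genes; each gene derives from ancestor A with probability 0.65,
boosted by +0.15 on homeolog 1 to emulate the dominant subgenome and
compensated by −0.05 on homeologs 2–4 so the genome-wide A fraction is
exactly the nominal bias. Copies drift 3% from their ancestor. About 10% of
loci are NLRs (multi-exon, subtypes drawn from the octoploid subtype
frequency table, most placed in tandem clusters of 3 with 1 kb within-
cluster and 8 kb between-gene spacing) and 3% are RLK-like (an exact GLPL
motif is planted at the codon level so the common-domain-plus-motif rule
has true positives). A-derived genes are transcriptionally upweighted 1.6×,
which reproduces the observed ~10-point gap between expression share and
retention share.

The population is three biparental families (2 parents + 18 progeny each,
n = 60) genotyped at 80 markers per diploid chromosome over a 25 Mb map.
Parental haplotypes are mosaics of six founder haplotypes with ~2 Mb
blocks, so nearby markers are in strong local LD across the population —
the property that makes the multiple-co-locating-marker rule discoverable,
as on a real SNP array. Progeny gametes recombine under a Haldane model at
2.5 cM/Mb. Planted cis-eQTL (default 12 genes, additive β = 8 TPM per
allele, per-gene h² = 0.75, within the upper range of observed fruit eQTL
heritabilities) are placed only at markers that segregate within families
(within-family dosage variance ≥ 0.15 after family centring) and have a
local LD partner (|r| ≥ 0.8 within 1.2 Mb): a biparental eQTL study can
only discover effects that segregate in its families, and the calling rule
requires LD support, so the generator plants truth where the design can
see it. Marker quality classes are drawn 70/15/6/5/4% PHR/NMH/OTV/CRBT/
Other; Mendelian errors are injected at 2% per progeny call as genotypes
impossible for the cross, so the filter's sensitivity is measurable
exactly. Codon-evolution pairs accept synonymous proposals with probability
1 and nonsynonymous ones with probability ω (inverted above 1), which under
the uniform proposal process yields an expected NG86 ω equal to the target.

Not emulated: read-level sequencing error, alignment and multi-mapping (a
fixed 50% TPM down-scaling of a random 10% of genes stands in for
multi-mapper discard), recombination-map heterogeneity, homeologous
exchange, gene family birth/death, and realistic codon usage or amino-acid
composition. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated generative model, not
performance on real octoploid data, where divergence between homeologs is
lower and more variable than the clean 10%/3% separation simulated here.

## Problem sizes and determinism

Default sizes (2,016 genes, ~18.5 Mb genome, 560 markers, n = 60) were
chosen so that the full test suite and the acceptance script each run in a
few minutes on one CPU. All generators and simulators are byte-
deterministic under a fixed seed; the acceptance script derives every seed
from its `--seed` argument. Degenerate inputs are handled explicitly:
empty sequences score 0 in alignment, constant vectors pass through Box-Cox
and clustering with warnings, empty NLR subsets return empty bias tables,
and saturated Jukes–Cantor corrections are flagged rather than silently
clipped.

## Known limitations

- The coiled-coil profile is a calibrated stand-in, not a fit to solved
  coiled-coil structures; segment boundaries should not be interpreted at
  single-residue resolution.
- NG86 with equal pathway weighting ignores transition/transversion bias
  and codon frequencies; ω is mildly compressed at high divergence.
- The EMMA-style model profiles one variance ratio; multi-locus and
  multi-trait models are out of scope.
- cis/trans phasing depends on the diploid-projected map; genes whose
  physical position projects poorly (e.g. rearranged regions on real data)
  can be mis-phased, and a long LD block can carry a peak marker outside
  the cis window.
- The capture simulator models hybridisation as an interval-sampling
  process with a single affinity parameter; it does not model probe
  thermodynamics or GC-dependent capture efficiency.
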