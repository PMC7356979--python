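# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Repeat model and family typing

A MYB repeat is modelled as a 52-column position-specific scoring profile
with Laplace-smoothed (pseudocount 0.5) column frequencies over the 20
canonical amino acids and a uniform background; scores are log2 odds.
The profile is built from an alignment of at least five anchor repeats.
The three columns with maximal tryptophan frequency are recorded as the
canonical W positions.  The shipped anchor set is *synthetic*: a
hand-designed plant-MYB-style consensus with deterministic per-anchor
variation (`synthetic_data.default_anchor_alignment`).  Any curated
anchor alignment can be supplied instead (`--anchors`); the profile
machinery is unchanged.

Scanning slides ungapped 52-residue windows over the protein
(vectorised), then refines promising windows with a banded global
alignment to the profile (±3 indels, gap penalty 2.0 bits), which yields
a residue→column map per hit.  Acceptance rules:

* score ≥ the relaxed threshold (0.45 × mean anchor self-score); hits
  below the strict threshold (0.6 ×) are marked *weak*;
* ≥2 of the 3 canonical columns must carry an exact W — conservative
  substitutions (F/Y) are not credited, a deliberate strictness that is
  configurable;
* non-overlapping hits are chosen greedily by descending score (ties:
  smaller start, for determinism) and chained when separated by ≤12
  residues (`max_linker`; R2–R3 linkers are short).  Isolated weak hits
  are discarded.

The best chain (most repeats, then highest total score) defines the
family: 1–4 repeats → 1R/2R/3R/4R; a 3-repeat chain containing a weak
hit is typed **3R-like** — the distinction between typical and "-like"
3R proteins is not crisply defined in the survey literature, so the
weak-repeat rule is this package's documented operationalisation and is
flagged as such.  Five or more chained repeats collapse to 4R with a
warning.  A chain whose aligned columns cover <70% of the expected
domain length is treated as a long domain deletion and excluded from
classification (it would also leave no comparable sites for tree
building).

## Phylogeny

The domain alignment is *induced* from the scan's residue→column maps —
repeats are placed on a repeat-slot × profile-column grid, right-aligned
so 2R and 3R proteins share their C-terminal two slots — rather than by
running an external aligner.  This keeps the pipeline self-contained and
deterministic; an externally computed alignment can be substituted.

Distances are p-distances with pairwise deletion; a pair with fewer than
20 comparable sites (`min_sites`) is undefined, and offending taxa are
iteratively dropped before tree building.  Neighbor joining follows
Saitou–Nei with the Studier–Keppler Q criterion; ties in Q are broken by
the lexicographically smallest pair of cluster labels (a cluster's label
is its smallest leaf id), making the topology independent of input
order.  Negative branch lengths are clamped to zero (MEGA-style
behaviour differs by option; clamping keeps lengths interpretable).

Bootstrap supports resample alignment columns with replacement;
replicates that leave a pair undefined are redrawn up to 10 times.
Support is the percentage of replicates containing the same bipartition,
attached to the original tree's internal edges.  The library default is
100 replicates — supports are stochastic estimates either way and 100
keeps desk-scale runs fast — with the replicate count a parameter
(1000 mirrors full-survey practice).

Subfamily assignment works on bipartition sides rather than rooted
clades, so calls are invariant to rerooting and input order.  A query
takes the label of the smallest clade with support ≥ 70 containing it
and at least one anchor, provided the contained anchors agree; on
conflict the next larger supported clade is tried (the widening rule is
this package's resolution — published surveys do not state one).
Queries never reaching an anchor are grouped by the largest
fully-supported (100%) anchor-free clade they share and labelled
`NEW-1, NEW-2, …` by descending clade size; a query with no such clade
is `unclassified`.

## Intron patterns

Intron phase is the number of coding nucleotides of the interrupted
codon preceding the intron (0/1/2), computed from cumulative exon CDS
lengths in transcription order, so plus- and minus-strand genes with the
same exon structure give identical events.  Only introns whose
interrupted residue maps into a detected repeat contribute to the domain
signature — regions outside the domain are too divergent to compare.

Signatures are matched to a lettered catalog: same event count, same
slots and phases, columns within ±3 (tolerance for indel wobble in the
induced alignment).  Between two matching letters the smaller total
column deviation wins; exact ties are an error rather than an arbitrary
pick.  Unmatched signatures are grouped by exact equality into
`novel-k` labels by descending group size.  The shipped catalog
(`data/intron_patterns.yaml`) is a configuration artifact: the letters
mirror the a–l convention of earlier family surveys (no 'k'), but the
canonical coordinates are this package's own editable defaults, since
the prior designations are defined only by citation.

## Duplication classification

*B. napus* is an allopolyploid of *B. rapa* (Ar → subgenome An) and
*B. oleracea* (Co → Cn).  Per colinear pair, with precedence
TD > HE > SE > SD:

* **TD** — same chromosome, adjacent gene ranks, same subfamily.
  "Physically adjacent without intervening sequences" is
  operationalised as rank adjacency in the gene order of one
  annotation, which is robust to assembly gaps; no block is required.
* **HE** — cross-subgenome pair on chromosomes declared homeologous.
* **SE** — pair on different, non-homeologous chromosomes.
* **SD** — duplicated block within one chromosome.

A gene participating in several pairs accumulates several event tags.
Progenitor origin comes from An–Ar / Cn–Co blocks (expected sides) and
An–Co / Cn–Ar (exchanged sides); both sides are recorded as evidence,
but HE classification itself uses only the intra-napus homeologous
pairing — whether progenitor-side evidence should additionally be
required is not settled, so both signals are kept.  Summary shares are
integer-rounded (half-up) percentages of the genes with at least one
colinear relationship; origin shares use genes with any progenitor
origin as the denominator.

## Expression

Genes with FPKM < 1 in every sample are removed (the bound is
inclusive: one sample at exactly 1.0 keeps the gene).  The transform is
log2(FPKM + 1) with per-gene median centering — the survey convention
says "log2-transformed" without a zero rule, and +1 keeps zeros at zero;
log2(max(FPKM, ε)) is available as a config switch.  Clustering is
average linkage on 1 − Pearson correlation (zero-variance rows at
distance 1 to all), mirroring classic gene-expression clustering tools;
leaf ordering is made deterministic by putting the subtree holding the
lexicographically smallest gene id on the left of every merge.

Fold changes are computed on raw FPKM (not transformed values) with a
pseudocount of 0.1 on both numerator and denominator: a published
"≥1.5-fold" reads as a ratio of expression levels, and the pseudocount
stabilises near-zero controls.  Replicates are averaged per condition;
controls are the time-0 samples (per hormone, or one shared set — both
60-sample layouts, 5 hormones × 6 times × 2 replicates and 5 × 12, are
supported since the source design is ambiguous).  A hormone direction
needs one qualifying time point ("under most conditions" is not used as
a hard criterion, but the per-time-point call grid is emitted so
stricter summaries can be derived).  Groups: up-all / down-all when all
five hormones are up (or both) / down (or both); everything else among
expressed genes is mixed.

## Synthetic data

The generators emulate the *structure* of the real inputs, not their
biology:

* proteomes plant exact or noise-mutated consensus repeats with 3–8
  residue linkers and 10–40 residue flanks; decoys are random
  composition.  Noise never hits the canonical W columns, so recovery
  failures isolate scoring (not the W rule); noise ≥ 0.5 is refused.
* gene models back-translate proteins with seeded synonymous codon
  sampling and insert canonical GT..AG introns (80–300 nt) exactly at
  the coding positions a designed signature dictates; genes land on
  random strands to exercise coordinate arithmetic.
* collinearity sets lay genes on A01–A10/C01–C09 with A_i ~ C_i
  homeology and build one block per requested event.
* expression matrices use a lognormal baseline (median 8, floored at 5)
  with multiplicative noise (CV 0.1) and planted folds of 2.0/0.5 at
  2–5 post-treatment time points — decisively beyond the 1.5 call
  threshold, so closed-loop recovery is noise-robust; non-expressed
  genes are uniform on [0, 0.9).

Passing the closed loops therefore shows the machinery is correct under
its own assumptions; it does not show robustness to diverged real
repeats, non-canonical splice sites, fragmented assemblies, or
heavy-tailed RNA-seq noise.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen as representative:
200-protein proteomes, 50 synthetic gene models, 200 random block sets,
300 genes × 60 samples, 100 additive matrices of 5–12 leaves, and
50–100 bootstrap replicates.  The pI solver bisects the
Henderson–Hasselbalch net charge over the EMBOSS pKa table to
|charge| < 1e-4; molecular weight uses average residue masses with `X`
excluded (warned).  All randomness flows from explicit seeds;
generators, trees and the full pipeline are byte-stable under a fixed
seed.

## Known limitations

* No profile-HMM insert/delete states; long insertions inside one
  repeat can defeat the ±3 band.
* CDC5-like atypical MYB domains are not a separate class.
* First mRNA per gene only; alternative isoforms are not reconciled.
* Synteny detection itself is out of scope — collinearity blocks are
  consumed, not computed.
* No model-corrected distances (Poisson/JTT) or likelihood trees.
* No differential-expression statistics; calls are threshold-based,
  as in the surveys this mirrors.
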