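# Methods

## The model

`phagehost` treats host prediction as a multi-label classification
problem over gene content. The underlying biological assumption is that
phages infecting the same bacterial genus share homologous gene families
— not necessarily the same genome architecture or gene order — so a
phage is summarised as a bag of gene-family counts and the position of
genes in the genome is deliberately ignored. Each host genus gets its
own binary classifier; prediction is the set of genera whose classifier
fires. This accommodates broad-host-range phages (several positives)
and out-of-corpus hosts (no positives) without a forced single answer.

## Gene calling

A six-frame maximal-ORF scanner stands in for a statistical gene
finder. An ORF runs from the first start codon (ATG/GTG/TTG, genetic
code 11) after the previous in-frame stop to the next in-frame stop;
alternative starts translate to M; ORFs shorter than `min_aa = 30`
residues are dropped. The 30-residue floor suppresses micro-ORFs in
intergenic sequence while keeping every planted synthetic marker
(≥ 50 aa) callable. Codons containing N are untranslatable: they
truncate an open ORF at that point, and the truncated call is kept only
if it still reaches `min_aa`. Overlapping calls in different frames are
all retained — phage genomes genuinely overlap genes, and the
downstream clustering is robust to a minority of spurious translations.
The scanner has no coding-potential model; for real data, protein FASTA
from a dedicated gene finder can be substituted at the `cluster` stage
(protein ids keyed `<genome>_<serial>`).

## Similarity graph and clustering

Thorough all-vs-all alignment is avoided with two standard reductions:

* **Deduplication** (greedy, descending length): a protein joins the
  first representative with global-alignment identity ≥ 0.95
  (identity = matches / alignment columns, computed with edlib);
  duplicates inherit their representative's final cluster.
* **Candidate pairing**: only pairs sharing ≥ 2 distinct 4-mers are
  aligned. For desk-scale corpora this seeding is a recall-oriented
  superset of BLAST seeding; it replaces E-value-based screening, and
  the edge-weight threshold below substitutes for "significant"
  similarity.

Candidate pairs are aligned with exact Smith–Waterman (BLOSUM62; the
unknown residue X is scored at the matrix minimum, −4; affine gaps with
open 11 / extend 1, i.e. a gap of length *k* costs 11 + *k*). The
aligner is the Biopython `PairwiseAligner` in local mode; the test
suite checks it against an independent brute-force Gotoh dynamic
program on random peptides. Edge weights are raw scores normalised by
the smaller self-score and clipped to [0,1] — symmetric, scale-free,
exactly 1 for identical sequences — and edges below 0.4 are discarded.
Self-loops of weight 1 are added to every node, as the Markov Cluster
Algorithm requires.

MCL then alternates expansion (matrix square), inflation (elementwise
power 2.0 and column renormalisation) and pruning (entries < 1e-5
zeroed, but never an entire column) until the flow matrix changes by
less than 1e-6, capped at 200 iterations with a warning on
non-convergence. Clusters are the connected components of the converged
matrix's nonzero pattern, which guarantees the output is a partition
and that clusters never straddle components of the input graph.
Inflation 2.0 is the MCL package default; it is configurable and
recorded in the model file. Finally, clusters whose members come from
fewer than 1% of training phages (strict `<`) are removed, and the
survivors are re-indexed 0..K−1 by descending prevalence.

## Features and trees

The feature matrix holds integer counts `a_{i,j}` (genes of phage *i*
in cluster *j*). A presence-based variance filter binarises each column
(count ≥ 1) and drops it when the presence or absence fraction strictly
exceeds 0.99. The prevalence filter (on clusters) and the variance
filter (on columns) encode near-identical ideas; they are kept as
separately switchable steps with both defaults on, since composing them
is idempotent for rare clusters.

Per genus, a CART tree is grown with Gini impurity, exhaustive split
search (thresholds at midpoints between consecutive distinct values,
left branch = "≤"), and deterministic tie-breaking (smallest feature
id, then smallest threshold). A node is split only while its weighted
impurity strictly exceeds `min_impurity_split = 0.03`; there is no
depth or leaf-size limit. Zero-gain splits are accepted when impurity
is above the threshold — Gini never increases under a split, both
children are always non-empty (so training terminates), and this lets
XOR-like interactions resolve one level down, matching the behaviour of
standard CART implementations.

**Class balancing is on by default.** With hundreds of phages and rare
genera, an unweighted root has Gini ≈ 2p(1−p) below 0.03 whenever the
genus covers < ~1.5% of the corpus, and the tree would degenerate to a
constant-negative leaf. Up-weighting positives to total parity restores
the intended semantics of the impurity threshold for rare classes;
unweighted training remains available by flag. A vector is classified
positive when its leaf's weighted positive fraction exceeds 0.5.

Novel genomes are vectorised against the frozen cluster database:
each protein is aligned to every cluster representative with the
training scoring configuration, clusters with normalised score ≥ 0.4
are candidates, and the protein counts once toward the best-scoring
candidate (ties → smallest cluster id). Counting once keeps row sums
equal to the number of assigned genes. Representative-first matching is
deterministic and fast; an opt-in fallback searches all cluster members
for proteins with no representative hit.

## Evaluation

Per genus over a shared test universe: TP/TN/FP/FN, sensitivity
TP/(TP+FN), specificity TN/(TN+FP), informedness TPR+TNR−1, accuracy
(TP+TN)/total, plus aggregate accuracy Σ(TP+TN)/Σtotal. Metrics with a
zero denominator are reported as `undefined` (`None`/`"undefined"` in
JSON/TSV), never silently 0 or 1 — a genus with no positive test phage
has no sensitivity. The shipped 50-genus benchmark confusion table
(1202 test phages) is used as a worked-example input for these
formulas; its aggregate accuracy under Σ(TP+TN)/Σtotal is what the
acceptance script reports.

## Synthetic corpus

The generator emulates the statistical structure the method assumes and
nothing more. Per genus it draws `markers_per_genus = 3` random marker
proteins (50–150 aa, starting with M); a shared pool of 20 background
families models host-uninformative genes, of which each phage draws 5.
A genome is the shuffled concatenation of one gene per family
(`ATG` + codons + `TAA`) separated by spacers of 20–80 random
nucleotides, each prefixed with a 12 nt insulator carrying stop codons
in all six frames — like real intergenic DNA, spacers terminate any
reading frame, so no ORF spans a gene junction. Point substitutions are applied per nucleotide at
`mutation_rate = 0.02`, never touching start/stop codons and redrawn
when they would create an in-frame stop, so every planted gene stays a
single intact ORF and gene-calling and clustering concerns remain
separable. Each family has a single ancestral gene sequence and copies
diverge only through the mutation model, as homologous genes do; at
mutation 0 all copies of a family are byte-identical.
The default corpus (5 genera × 40 phages, seed 42) runs end-to-end in
roughly a minute; sizes were chosen so the whole suite completes in a
few minutes on one core.

Ground truth records each planted gene's genomic span. A gene call is
attributed to a family when it is the planted gene's own reading (same
strand, stop and frame); an alternative locus-overlap attribution marks
antisense/frame-shifted readings of a planted locus, which is the right
notion when asking whether a tree root carries marker-derived signal.
Clustering quality is summarised as purity: the majority-family share
summed over clusters, divided by all marker-derived genes (background
excluded). Purity is insensitive to splitting a family but penalises
merging two families.

What the generator does **not** model — and therefore what passing
tests do not demonstrate about real data: genome mosaicism and
horizontal transfer, gene order and operon structure, shared families
between related genera, GC/codon bias, insertions/deletions, tRNAs and
terminal repeats, and label noise in public host metadata. Results on
the synthetic corpus validate the machinery (recovery of planted
structure under noise), not field accuracy.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; training itself has no randomness
  (exhaustive search + fixed tie-breaks), so retraining is bit-stable.
* Similarity thresholds are inclusive (≥); removal thresholds are
  strict (<  1% prevalence, > 99% presence).
* The train/test split takes |train| = round(fraction·total) (half-up);
  stratified splitting is available but off by default, matching plain
  random sampling; multi-genus phages stratify under their
  alphabetically first genus.
* Genus names are normalised by capitalisation only; taxonomy
  resolution is out of scope and labels are taken as given.
* Corpus-level record deduplication is not implemented; input corpora
  are assumed non-redundant.
* The model file is a single schema-versioned JSON document containing
  the trees, the cluster database (with representative sequences) and
  the full configuration; round-tripping preserves every prediction.

## Known limitations

* The ORF caller over-calls (reverse-strand and frame-shifted ORFs
  inside real genes); harmless here because such calls form
  low-prevalence clusters that the filters drop, but on real genomes a
  proper gene finder should be used upstream.
* Representative-based novel-gene assignment can miss a family whose
  representative diverged from the query more than 0.4; the full-member
  fallback trades speed for the literal any-member matching rule.
* With very small corpora the 1% prevalence rule keeps everything
  (1 phage is already > 1%), so the variance filter does the work.
* A genus without genetically coherent phages cannot be learned — its
  tree trains but generalises poorly; informedness per genus makes this
  visible rather than hiding it in aggregate accuracy.
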