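# Methods

## Library model and scope

`gbsnp` models a two-enzyme GBS library: genomic fragments cut by a rare
cutter on one side and a frequent cutter on the other, ligated to barcoded
adapters and sequenced as paired 150 bp reads. R1 starts with a 6–10 bp
barcode followed by the rare-cutter remnant (`TGCAG` for *PstI*-type
protocols); R2 starts with the frequent-cutter remnant (`CCG` for
*MspI*-type). Both remnant strings are configurable; the enzymes themselves
are not modelled beyond their remnants. Only substitutions are handled as
sequencing errors; the pipeline is SNP-exclusive and removes every position
with indel evidence rather than attempting indel genotyping.

## Stage 1: parsing and demultiplexing

Barcodes are matched longest-first against the R1 prefix with at most one
mismatch; the bases after the candidate barcode must equal the rare-cutter
remnant exactly (a mismatch-tolerant remnant would erode the "high-confidence"
structure check, so remnant tolerance is exposed only through configuration of
the remnant string itself). An equal-distance tie between same-length barcodes
discards the pair, and barcode tables containing same-length barcodes within
Hamming distance 1 are rejected at load because one-mismatch assignment would
be inherently ambiguous.

Fragments shorter than the read length read through into the adapter. On R1
the in-line signature is rc(common remnant) + the first 12 adapter bases; on
R2 the fragment is followed by rc(rare remnant) + rc(barcode), which is the
signature searched there (the matched barcode is known at that point). The
search is exact first, then tolerates up to two mismatches via a split-seed
scan, then trims partial signature prefixes (≥ 4 bases) hanging off the 3′
end. Without the tolerant and partial matching, reads from fragments within
~15 bp of the read length retain junk tails that later corrupt merging and
clustering; with it, a read whose adapter signature is error-free or carries
one to two errors is truncated at the same base. The R2 5′ remnant is trimmed
when present (within one mismatch) and never required, so libraries whose R2
reads lack the remnant still parse.

Quality trimming reproduces the LEADING/TRAILING/SLIDINGWINDOW/MINLEN scheme
with defaults 30/30/4:30/32: leading and trailing bases below Q30 are removed,
the read is scanned 5′→3′ in 4-base windows and cut at the first window whose
mean Phred drops below 30 — keeping any immediately following bases that
individually meet the threshold, which is what the canonical trimmer actually
does at the cut point — and reads shorter than 32 bases are discarded. Pairs
with a strict majority of N in either mate are dropped earlier, at parse time.

## Stage 2: mock reference

Merging searches for the best 3′(R1)–5′(rc R2) overlap of at least 10 bases
with a mismatch fraction of at most 0.1 (the tolerance inside the overlap is
not pinned down by the protocol; 0.1 is exposed as `max_mismatch_frac`).
Candidate overlaps come from exact 16-mer probes with an exhaustive fallback
over all overlap lengths, so the longest acceptable overlap is always found;
mismatching columns resolve toward the higher-quality base (tie → R1).
Merged products shorter than 32 bases are discarded. Pairs that do not merge
are stitched as R1 + 20 A's (quality Q40) + rc(R2) when both mates are ≥ 32
bases. One guard sits between the two paths: an unmerged pair whose one mate
is contained in the other at high identity is a short fragment whose adapter
tail escaped trimming, and stitching it would duplicate the fragment inside a
single read; such pairs are dropped.

Pairwise identity is matched columns over alignment columns of an optimal
end-free alignment, computed with edlib in infix (HW) mode — the shorter
sequence aligned within the longer with free terminal gaps on the longer —
with internal gap columns counting as mismatches. At the default threshold of
0.93 the shortest 32-base reads may differ at up to two positions and still
co-cluster. Clustering is greedy in descending length order (ties broken
lexicographically for reproducibility): each read joins the first centroid
meeting the threshold or founds a new one, with the founding read — not a
polished consensus — as the centroid sequence, so downstream coordinates stay
anchored to an observed read. A k-limited edlib distance bound
(k = (1−t)/t·|shorter| + 1, which cannot reject a true match) prescreens
candidates, and exact duplicates are dereplicated first; a `best_fit` option
replaces first-fit assignment. Clustering runs within each selected genotype
and, when more than one genotype is selected, once more across the pooled
genotype-specific centroids. Genotype selection defaults to the single
genotype with the most parsed reads.

The mock "genome" is the in-order concatenation of centroids with 1-based
inclusive offsets that tile it exactly; no spacer is inserted, and instead of
guarding junctions with padding the mapper works per centroid, which makes
centroid boundaries impossible to cross by construction.

## Stage 3: mapping and pileups

The built-in mapper indexes the reference with exact 20-mers (posting lists
longer than 8 loci — in practice the poly-A stitch junctions — are masked as
repeats) and evaluates seed-implied diagonals by direct base comparison, with
an edlib fallback that produces gapped alignments up to an edit fraction of
0.07 per read; the ceiling mirrors the 93 % clustering identity so any read
that helped build a centroid can map back to it. Candidates are seed-derived,
so a true locus sharing no intact 20-mer with a read is invisible; at 0.2 %
per-base error the probability that all seven-plus non-overlapping seeds of a
150 bp read are corrupted is negligible. A pair is kept only when both mates
have a unique best-scoring locus, on the same centroid, in opposite
non-inverted orientations; a tie at best score means the read would have
secondary alignments and the pair is discarded. Alignments spanning both
sides of a ≥ 20-base A-run (a stitch junction) are rejected, since the
junction is an artifact, not sequence.

Pileups count A/C/G/T depths at 1-based positions, counting each molecule
once in the mate-overlap region (higher base quality wins, tie → R1), and
flag indel evidence at deleted positions and positions flanking insertions.
The same `PileupColumn` stream can come from the samtools-mpileup text
dialect (`.`/`,`, case substitutions, `^`+mapq, `$`, `+n`/`-n` indels, `*`),
parsed with per-line error reporting, so users may substitute an external
aligner toolchain; the built-in exporter writes the same dialect, and the two
paths round-trip exactly.

## Stages 4–5: matrices and calls

Count files keep one row per covered, indel-free position. Candidate
positions are deliberately liberal — any read disagreeing with the reference
base qualifies — and the master matrix is the sorted union of candidates over
genotypes with every genotype's full depth 4-tuple, zero when uncovered. A
position with indel evidence in *any* genotype is excluded population-wide
(the conservative reading of SNP-exclusivity). Conflicting reference bases
across genotypes are a hard error rather than a warning, because they mean
the inputs were piled against different references.

Allele ranking sums depths across the population and breaks ties in the fixed
order A<C<G<T. The independence filter requires the secondary allele at depth
≥ 3 in ≥ 3 distinct genotypes, each genotype individually meeting the depth —
the reading most consistent with independent instances across genotypes; a
pooled-depth alternative is expressible through the two parameters. The
altStrength filter is strict (> 0.90), heterozygote ratio strict (> 0.1),
homozygote depth thresholds inclusive (≥ 11 / ≥ 48). Average depth is the
mean of total four-base depth over **all** genotypes including zero-coverage
ones, which is what makes the ≤ 4 cull meaningful; a flag restricts it to
covered genotypes. Rows whose secondary allele has zero population depth are
monomorphic and dropped before genotyping. Genotyping is vectorised over the
matrix; a scalar rule implementation is kept as the public `call_genotype`
and the two agree cell-for-cell (tested exhaustively on the [0,60]² grid).

## Downstream

The numeric export maps primary homozygote → 0, heterozygote → 0.5, secondary
homozygote → 1, missing → NA. HapMap heterozygotes are written
primary-then-secondary base (genotypes are unordered; the fixed order is for
determinism), and PLINK TFAM uses family id = genotype id, parents 0, sex 0,
phenotype −9. The modified Gower coefficient weights out any locus missing in
either column and is undefined — an error, not 0 — when no locus is shared.

## Simulator

The generator emulates the library design end to end: uniform-random
fragments (default 300, 120–400 bp, spanning both the merge régime
< 2·150−10 and the stitch régime above it), 24 genotypes plus optional
replicate re-sequencings of the first genotype, 150 planted bi-allelic SNPs
at distinct sites, tri-state truth (hom-ref / het / hom-alt) with
heterozygote probability 0.3 and the remainder split evenly, per-fragment
depth ~ Poisson(40), uniform 0.2 % substitution errors, uniform Q40
qualities, and barcode sets of lengths 6–10 with same-length Hamming
separation ≥ 3. Heterozygous sites emit alleles 50/50 per read. Everything is
a deterministic function of the seed.

What it does not model — quality-score error profiles, PCR duplicates,
chimeras, indels, repetitive or homologous loci, allele-specific bias — bounds
what passing tests show: they validate the pipeline's logic and its behaviour
under calibrated random error, not robustness to the full error structure of
real instruments or polyploid genomes.

## Evaluation conventions

Planted-SNP recovery is measured against *design-eligible* SNPs: positions
observable under the library design (on stitched fragments the un-sequenced
middle cannot be genotyped by any method; positions past the shortest
R1 coverage are invisible to long-barcode genotypes) whose truth has at least
3 carriers of each allele — fewer carriers and the independence filter culls
the site by design. Truth coordinates are translated onto centroids through
the provenance of each centroid's founding read. A called SNP at a position
with no planted SNP counts as false.

Problem sizes in the test suite and acceptance script (24×300×40× for the
study run and its null, 10 genotypes + 1 replicate × 150 fragments for the
replicate run, 1,000 fragments for merge/stitch) are the package's chosen
study conditions; a full run of the suite takes a few minutes on one CPU.

## Known limitations

- Centroid sequences inherit their founding read's errors (~0.5 errors per
  250 bp read at 0.2 %): reference bases may be wrong at isolated positions.
  This shifts `ref_base` but not the primary/secondary alleles, which are
  depth-ranked across the population.
- Greedy first-fit clustering is order-dependent; the length-then-lexicographic
  order makes it reproducible but not optimal, and threshold monotonicity,
  while observed, is not guaranteed for adversarial inputs.
- The mapper's uniqueness rule discards reads from genuinely repeated
  fragments; paralogous loci above 93 % identity collapse into one centroid
  and then genotype as spurious heterozygotes — the standard failure mode of
  reference-free reduced-representation pipelines, mitigated upstream by the
  clustering threshold, not solved.
- `--threads` is accepted for interface compatibility but execution is
  sequential; results are therefore trivially independent of thread count.
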