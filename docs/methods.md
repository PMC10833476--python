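# Methods

## Cluster models and nomenclature

The registry (`data/registry.json`) is the package's single source of
nomenclature: ~90 canonical gene names (universal r-proteins with uS/uL
prefixes, Archaea/Eukarya-specific families with e-suffixed names, and the
non-ribosomal genes that are constitutive cluster members — RNA-polymerase
subunits, NusA, translation factors, and so on), an alias table keyed by
whitespace-normalized, case-folded product strings and gene symbols, and
twelve cluster models grouped into five top-level families.

Grouping decisions worth noting:

* The small S10 cluster (*uL3-uL4-uL23-uL2*) and the bacterial 21-gene
  S10+spc block are sub-models of the single `S10-spc` family, and the
  S24e–S27ae cluster shares the `L7ae-S24e` family with the L7ae cluster.
  With that grouping the archaeal "superstring" arrangement in which the
  str, S10–spc, alpha and L7ae/S24e regions run back to back counts exactly
  four co-occurring families, which is the organisationally meaningful
  number.
* The 14-gene S10–spc core excludes uS19; uS19 is a regular (non-core)
  member of the archaeal model.  The source descriptions are inconsistent on
  this point and the methods-level core listing (which omits uS19) is
  followed.  Similarly, the L31e family's conserved core is stored as the
  four explicitly listed genes (*S19e-COG2118-L39e-L31e*) even though it is
  sometimes described as a 5-gene core.
* The bacterial 21-gene S10+spc roster and the 9-gene B. subtilis-style str
  core are not spelled out gene-by-gene in the source material; they are
  transcribed as the E. coli S10+spc operon order (including uL16) and as
  the bacterial counterparts of the archaeal str/L30e listing minus the
  Archaea/Eukarya-specific L30e.  The *counts* are the published ones; part
  of the *identity* is reconstruction, and both rosters are plain data in
  `registry.json` where they can be audited or edited.
* Genes tolerated inside otherwise contiguous blocks without breaking them
  — IF(Sui) and secY inside the archaeal S10–spc block, tRNA-Leu and uS2
  around the archaeal alpha block, dUTPase inside L7ae — are *accessory*:
  they neither count toward the gap budget nor appear as insertions.

## Annotation input

All three readers (NCBI assembly feature table, GFF3, GenBank) produce the
same in-memory annotation: 1-based inclusive coordinates, `start <= end`
always, orientation only in the strand field, genes sorted by start within
each contig.  Pseudogene rows in feature tables (bare `gene` rows with a
`pseudo` attribute) are kept as coding features so cluster occupancy still
counts them.  Joined/fuzzy GenBank locations collapse to their outer span;
fuzzy boundaries (`<`, `>`) set both `partial` and `contig_edge`.  Because a
fuzzy location implies a contig edge on re-reading, the GenBank writer
encodes a *mid-contig* partial gene with a `/note="partial"` qualifier
instead, keeping the three formats losslessly interconvertible.  Feature
tables carry no contig length, so contig extent is inferred from the
furthest feature end; the synthetic generator places its first gene at base
1 and ends each contig at its last gene so this inference is exact.

## Rescue by local alignment

The manual homology search used to recover mislabelled genes is replaced by
an internal Smith–Waterman aligner: BLOSUM62, affine gaps with cost
`open + (k-1)*extend`, defaults open 11 / extend 1.  The dynamic program is
a numba-compiled Gotoh recursion; an affine-aware traceback yields identity
(matches / alignment columns) and coverage (reference residues aligned /
reference length).  In the test suite the score is cross-checked against an
independent exhaustive aligner (Biopython's `PairwiseAligner` under the
same gap convention) on hundreds of random sequence pairs.

Every CDS whose symbol/product resolves to no registered name is aligned
against all panel entries; the best score wins (ties broken by the
lexicographically smallest gene name, making the result independent of
panel iteration order), and a call is *accepted* at identity ≥ 0.30 and
coverage ≥ 0.50.  The thresholds are package decisions — no acceptance
criterion for the original manual step was published — and are exposed in
the CLI.  Hypothetical records without a protein sequence are skipped with
a warning, never translated from coordinates.  Accepted calls are an
overlay consumed by the mapping stage; the annotation is never mutated.

Partial-gene flagging compares each assigned gene's coding length with its
family's typical length (from the panel): shorter than 70 % of typical, or
truncated at a contig edge, flags the gene partial.  The per-genome partial
fraction uses cluster-assigned genes as the denominator (the natural choice
given the pipeline only inspects cluster genes; whole-proteome fractions
would need all genes' lengths).

## Segment mapping

Member hits (after the rescue overlay) are grouped per contig into maximal
runs in which consecutive hits are separated by at most `gap_tolerance`
foreign genes (default 2).  Rules around that budget:

* accessory genes are invisible to the gap count and to insertion
  reporting;
* unannotated hypothetical proteins count toward the budget (so a run of
  3+ background genes splits segments) but are *not* reported as
  insertions — only named foreign genes are, with their flanking members
  (this is how the Hsp20 insertion is detected);
* segments never span contigs; `at_contig_edge` marks potential continuity
  instead;
* duplicate member hits (paralogs) are claimed by the segment with the most
  distinct members; surplus hits are reported as `extra_copies`.

Statuses: `complete_contiguous` (all members, one segment), `split` (≥ 2
segments, at most `allowed_missing` members absent — default 1, needed
because the canonical three-way-split genome lacks uS19 yet is described as
split), `absent` (nothing found), otherwise `partial`.  Pseudogene members
count as present but are listed separately.

Orientation per segment follows the trend of member indices along the
genome (reverse segments are presented in model order so reports align
across genomes); single-gene segments are forward by convention, exact
ties fall back to the majority strand.  Mapping results are invariant under
reverse-complementing the genome — checked as a property test.

Family co-occurrence: two families co-occur when any two of their segments
on the same contig are separated by at most `adjacency_window` intervening
genes (default 12 — wide enough to bridge the 5-gene and 10-gene spacer
runs seen inside the known four-cluster superstring region, and
deliberately calibrated to reproduce that arrangement); groups are
transitive closures.

## Cross-genome aggregation

The status matrix has one cell per genome × family, taken from the family's
*primary* model (the archaeal S10–spc core rather than the small-S10
sub-cluster, etc.).  Dispersion = mean segment count over present families;
completeness = fraction of present families that are complete and
contiguous.  Both are this package's own summaries of what the cluster maps
show qualitatively; they are not literature statistics and reports label
them as such.  Assembly concerns: `universal_genes_missing` (any of
uL3/uL4/uL23 absent genome-wide), `universal_gene_pseudo` (a 14-gene-core
member pseudogenised), `core_split` (the S10–spc core in ≥ 2 segments in a
*complete* genome), `high_partial_fraction` (≥ 10 % of found cluster genes
partial).

## Synthetic genomes

Templates (`data/templates.json`) transcribe the characteristic
arrangements block by block, with a provenance note per template.  Each
template is realised deterministically from a seed: genes get pseudo-protein
sequences (per-gene base sequence of fixed length 60–250 aa derived from a
hash of the name, point-mutated at the template's mutation rate — 0.10 for
the mislabel-rescue template so rescued identities sit near 90 %, 0.05
elsewhere), 40 bp intergenic spacing, and background "hypothetical protein"
filler genes drawn from a fixed pool of 64 random sequences.  The pool is
rejection-sampled against the reference panel so that no filler reaches
identity 0.27 at coverage 0.40 — safely inside the 0.30/0.50 acceptance
margin — because under a local-alignment identity definition short
high-identity alignments between random proteins are unavoidable, so a raw
identity bound would be meaningless.  The sequences are synthetic
stand-ins: they share no real homology structure, so tests exercise the
pipeline's logic (naming, ordering, thresholds), not the biology of remote
homology detection.

Perturbations (`split_at`, `relabel_hp`, `mark_pseudo`, `truncate_partial`,
`delete`, `insert`, `invert`, `fragment_contigs`) are applied in order with
coordinates re-laid-out after each step.  Planted truth is *not* patched
incrementally: after all perturbations, an independent mini-scanner walks
the ground-truth names (with the relabel overlay) and re-derives expected
segments, statuses, missing/pseudo/partial sets, insertions and
co-occurrence groups.  The scanner shares the segmentation *definitions*
but none of the pipeline's machinery (no parsing, no alignment, no
orientation or paralog handling), which makes it the oracle for the master
property test: across ≥ 100 seeded random specs the full pipeline must
reproduce the planted truth exactly.

What the synthetic data does not emulate: real protein families (lengths
and divergence are arbitrary), nucleotide sequence, transcription signals,
intergenic length distributions, and annotation noise beyond the modelled
pathologies.  Passing tests therefore demonstrate correctness of the
mapping/rescue logic under the modelled conditions, not recall of remote
homologs in real MAGs.

## Numerical and degenerate-input choices

* Alignment scores are integers; identity/coverage are exact ratios.
* Zero-score alignments report identity = coverage = 0 and empty spans.
* Empty genomes map to `absent`; an empty panel yields no rescue calls.
* Duplicate locus_tags are deterministically suffixed `_2`, `_3`, … with a
  warning.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; identical inputs give byte-identical outputs.

## Problem sizes

Synthetic genomes span 25–137 genes.  The acceptance script and the
property suite (108 random specs plus several hundred oracle alignments)
complete in well under two minutes on a single CPU; these sizes were chosen
because every organisational count being reproduced is a property of the
arrangements, which the smallest faithful transcription already exhibits.

## Known limitations

* Contiguity is purely gene-order based; no intergenic-distance or
  transcription-unit modelling.
* No six-frame translation: feature-table input without a protein FASTA
  cannot be rescued.
* The bacterial str and S10+spc rosters are partly reconstructed (see
  above); counts, not identities, are the tested quantities.
* `eq`-style equality of the dispersion metric across packages is not
  meaningful — it is a package-defined summary.
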