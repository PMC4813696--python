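# Methods

## The record model

A proBAM record is one peptide-spectrum match aligned to the genome. The
dialect (version 1) constrains standard SAM fields as follows:

* FLAG takes exactly five values: 0/16 primary mapped on the
  forward/reverse strand, 256/272 secondary mapped, 4 unmapped. Any
  other value is rejected on read.
* POS is the 1-based leftmost mapped base; internally all coordinates
  are 0-based half-open and converted only at serialization.
* CIGAR is `M` segments separated by `N` gaps; the sum of `M` lengths
  equals three times the peptide length and equals |SEQ|. An `N` gap is
  by construction an intron of the encoding transcript.
* SEQ stores the coding nucleotides in forward-genome orientation
  (reverse-complement of the mRNA for minus-strand records), so genome
  browsers render the bases correctly.
* MAPQ is fixed at 255 ("unavailable"): mapping here is deterministic
  given the annotation, and identification confidence lives in the XS
  score tag.
* Tags, in fixed order XP/XM/XS/XC/NH/XD: peptide sequence,
  modifications (`pos:delta;…` with 1-based residue positions and mass
  deltas in Da, `-` if unmodified), search score, charge, number of
  genomic locations, decoy indicator. Unknown tags from other producers
  are preserved opaquely.

Records for one PSM: one per distinct genomic location
(chromosome, blocks, strand) across all matched proteins, deduplicated —
a peptide lying in an exon shared by two isoforms yields a single
record. The location with the smallest (chromosome, position) is
primary; the tie-break is arbitrary but deterministic, so repeated runs
produce byte-identical files. A PSM with no validated location yields a
single flag-4 record that keeps all payload tags, so no identification
is silently lost.

## Mapping and validation

Mapping is protein-mediated: (1) find every occurrence of the peptide in
each matched protein sequence (exact string match; no I/L equivalence by
default); (2) take the corresponding slice of the protein's coding
sequence; (3) convert the CDS offsets to genomic blocks through the
transcript's exon structure. Every candidate location is validated by
translating the genomic bases back (standard genetic code, table 1,
strand-aware); a location whose presumed coding sequence does not
reproduce the peptide — in real data usually incorrect annotation — is
discarded with a warning rather than emitted.

Decoy PSMs carry reversed peptide sequences matched against
`rev_`/`DECOY_`-prefixed accessions. They are placed at the genomic
location of the forward (un-reversed) peptide with the strand flag
flipped and `XD:i:1`, reusing the forward twin's CIGAR. Keeping decoys
in the file is what makes protein- and gene-level FDR estimation
possible after merging and reannotation.

Transcripts whose CDS length is not a multiple of three, or whose CDS
falls outside the annotated exons, are loaded but excluded from the
protein index (logged); proteins without an annotated transcript are
reported as unmapped rather than dropped. A CDS that includes the stop
codon is handled by `coding_sequence(trim_stop=True)`; peptide
coordinates never reach into the stop codon, so mapping is unaffected by
either GTF convention.

## PSM-level FDR

Plain target-decoy ratio: records are ranked by score (direction
configurable, higher-better default; ties rank decoys first, which is
conservative), FDR at each threshold is #decoys / max(1, #targets) at or
above it, and q-values are the running minimum from the worst score
upward, capped at 1. Only rank-1 hits per spectrum are ingested.
Filtering at a q-value threshold retains passing decoys deliberately.
No rescoring (PeptideProphet/Percolator-style) is attempted.

## Inference, FDR and counting

The bipartite graph connects peptides to features (proteins or genes)
purely by genomic overlap: an edge requires the peptide's blocks to be
splice-consistent with a CDS of the feature — every block inside the
feature's CDS exons and every junction coinciding *exactly* with one of
its introns. No tolerance is allowed: bases are exact, and fuzziness
would silently admit wrong isoforms. Decoy peptides connect to marked
decoy twins of features.

Parsimony inference then (1) collapses features with identical peptide
sets into one indistinguishable group, (2) discards features whose
peptide set is a strict subset of another's (subsumed), (3) greedily
selects the group explaining the most unexplained peptides, breaking
ties by the lexicographically smallest representative identifier, and
(4) removes groups with fewer than two distinct peptides into a
retained single-hit list (these matter for integration statistics and
rescue). The group-level FDR is the number of groups whose members are
all decoys divided by the number of target groups; mixed groups count as
target, which is conservative. Greedy set cover is the standard
parsimony heuristic for this problem; it is provably minimal whenever
sharing is confined to pairs of isoforms (the dominant situation, since
shared peptides arise mostly from isoforms of one gene), and the test
suite verifies minimality against exhaustive search on cluster-
structured random graphs of that shape.

"Distinct peptide" always means the exact unmodified sequence string;
modifications distinguish PSMs, not peptides. Count tables report, per
feature, overall and feature-specific spectral and peptide counts. PSMs
are tallied from primary records, so a PSM counts once per feature
however many isoform locations it hits, and counts stay additive under
file merging. Decoys are excluded from all counts, coverage and
classification.

## Coverage statistics

Coverage is |union of mapped target bases ∩ CDS union| / |CDS union| at
gene, chromosome or genome level. The chromosome test is a per-base
one-proportion z-test of the chromosome's coverage fraction against the
genome-wide fraction, one-sided for lower coverage and reported without
multiple-testing correction; treating bases as independent trials is an
approximation (neighbouring bases are covered by the same peptides), so
the p-values are descriptive rather than strictly calibrated. The
saturation curve draws, for every subset size k, a fixed number of
random k-subsets of samples without replacement and computes union
coverage, seeded for reproducibility.

## Reannotation

Re-expressing records under a new annotation scheme filters in three
steps, in order: (1) drop records with any base outside the new scheme's
CDS union; (2) drop records not splice-consistent with any transcript of
the new scheme (same predicate as graph construction); (3) drop records
whose blocks, read in the matching transcript's frame, do not translate
to the peptide. Decoys are filtered by the same geometry via their
forward twins (strand flipped back, peptide reversed). The output is
always a subset of the input — reannotation can never introduce new
identifications. Unmapped records cannot be associated with any scheme
and are dropped. The genome build is checked by comparing sequence
lengths between the file header and the new annotation's genome;
cross-build conversion is out of scope (liftover tools operate on the
SAM files directly).

## Integration and rescue

Studies are merged on the shared sequence dictionary (record multiset
union, provenance lines concatenated), then the PSM filter is re-applied
from the XS scores across the merged set — rather than trusting each
study's original threshold — so a stricter threshold refines the
combined protein/gene FDRs. After reannotation to one scheme, inference
runs at both levels and count tables are produced per study and
combined. The two-step rescue keeps the strict-filter record set and
adds back PSMs with q-value in (strict, relaxed] whose peptides connect
exclusively to confidently identified features.

## The synthetic-data generator

`make_reference(seed, n_genes=20, isoform_rate=0.5)` builds genes
alternating strands across two chromosomes, each with 1–4 exons of
10–30 whole codons separated by 40–200 nt introns and ≥100 nt intergenic
gaps; coding sequences are random sense codons behind an ATG. With
probability `isoform_rate`, a gene with ≥3 exons gains a second isoform
skipping one internal exon — the exon-skipping model mirrors the fact
that shared peptides come primarily from transcript isoforms of one
gene, and whole-codon exons keep skipping frame-preserving so ground
truth stays exact. `simulate_psms` digests the proteome in silico
(cleavage after K/R, zero missed cleavages by default, minimum peptide
length 6), draws target scores from N(separation, 1) and decoy scores
from N(0, 1) (any monotone score behaves identically since FDR depends
only on rank), attaches methionine-oxidation modifications to a
configurable fraction, and lists every protein containing a sampled
peptide as a hit. Defaults: 10% decoys, separation 3.

The engineered alternative scheme used in reannotation tests removes one
gene entirely (step-1 drops), extends one multi-exon gene's first exon
3 nt into its first intron so junctions over that intron no longer match
(step-2 drops), and extends one gene's CDS outward by bases that shift
its reading frame (step-3 drops); the expected casualty of every record
is predictable from geometry alone.

What the generator does **not** emulate: sequence homology between genes
(so multi-location peptides are essentially absent and the
unique-location fraction is ~100%, higher than in real proteomes),
overlapping genes, UTRs distinct from CDS, stop codons inside annotated
CDS, semi-tryptic or missed-cleavage peptides, mass-accuracy or
retention-time structure, and realistic score distributions. Passing
tests therefore demonstrate the correctness of the coordinate
arithmetic, the format, and the inference/counting/reannotation logic —
not search-engine behaviour on real spectra.

## Problem sizes and experiment conditions

The default verification runs use a 20-gene reference, 2,000 simulated
PSMs with 10% decoys for the single-study pipeline, and five studies of
600 PSMs each for the integration experiment. The integration experiment
uses a heavier decoy load (30%) and smaller score separation (2.5) than
the single-study default: probing how group-level FDRs respond to the
PSM threshold requires a mixture in which a measurable number of decoys
survives a 1% filter. These sizes keep every check exact (exhaustive
per-base coordinate comparison, exhaustive minimum set cover up to 12
features) while the full suite runs in seconds.

## Known limitations

* No trans-splicing, selenocysteine recoding or circular chromosomes.
* No spliced placement of peptides lacking a protein hit, and no
  variant-aware placement.
* Primary-location choice is a deterministic convention, not a claim
  about which locus generated the peptide.
* The z-test's one-sided choice and the absence of multiple-testing
  correction are conventions; both are trivial to change downstream.
* pepXML support covers the spectrum_query/search_hit subset; richer
  identification formats should be converted externally.
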