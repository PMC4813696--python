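# probam

Genome-based representation and analysis of shotgun-proteomics
identifications.

Mass-spectrometry search engines report peptide-spectrum matches (PSMs)
against protein databases, which makes it hard to ask genome-shaped
questions: which exon–exon junctions have peptide evidence, how much of
the coding genome is covered, which peptides are shared because two
isoforms of one gene overlap on the chromosome, and how to combine
studies that searched different protein databases. `probam` answers these
by placing every PSM on the genome and storing it in a SAM text dialect
in which **the aligned unit is a PSM, not a sequencing read**: the CIGAR
is junction-aware (`6M70N6M` is a peptide crossing one intron), SEQ holds
the coding nucleotides, and proteomics payloads live in tags
(`XP` peptide, `XM` modifications, `XS` search score, `XC` charge,
`NH` number of genomic locations, `XD` decoy flag). Standard SAM tooling
(samtools, pysam, genome browsers) reads the files unchanged.

On top of the format the package provides:

* **Mapping** — peptide → protein position → coding-sequence slice →
  genomic blocks, with translation-based validation of every placement.
  Decoy PSMs (reversed sequences) are placed at the location of their
  forward twin on the opposite strand and kept in the file, so
  false-discovery rates can be estimated at every level downstream.
* **PSM FDR** — target-decoy estimation: at any score threshold
  FDR = #decoys / #targets at or above it, monotonized into q-values;
  filtering keeps passing decoys on purpose.
* **Analysis toolset** — peptide classification (genomic multiplicity,
  junction status), CDS coverage at gene/chromosome/genome level with a
  one-proportion z-test and a resampling saturation curve, bipartite
  peptide↔feature graphs from genomic overlap, parsimony protein/gene
  inference (collapse indistinguishable features, discard subsumed ones,
  greedy set cover, minimum two peptides per group) with group-level
  target-decoy FDR, overall/specific spectral and peptide count tables,
  three-step reannotation to a different gene-annotation scheme
  (out-of-CDS → structure-inconsistent → out-of-frame), multi-study
  integration and two-step PSM rescue.
* **Synthetic references** — a generator for fully self-consistent toy
  genomes, annotations, proteomes and PSM tables with recorded ground
  truth, used by the test-suite and the acceptance script.

## Worked example

```python
from probam import *

ref = make_reference(seed=7, n_genes=20, isoform_rate=0.5)
gtf, fasta, prot = ref.write("example")
ann = load_annotation(gtf, fasta, name="schemeA")

psms = simulate_psms(ref.truth, seed=8, n_psms=1000, decoy_fraction=0.1)
kept = filter_psms(compute_psm_fdr(psms), fdr=0.01)
pro = build_probam(kept, ann, ref.truth.proteins, psm_fdr=0.01)
write_sam(pro, "example/run.sam")

rows = classify_peptides(pro)
unique = sum(r.n_locations == 1 for r in rows)
junction = sum(r.junction for r in rows if r.n_locations == 1)
print(f"PSMs kept at 1% FDR: {len(kept)}/{len(psms)}")
print(f"peptides: {len(rows)} ({unique} unique-location, {junction} junction)")
print(f"genome CDS coverage: {coverage(pro, ann, 'genome'):.1%}")

result = parsimony_infer(build_bipartite(pro, ann, "gene"))
print(f"gene groups: {sum(not g.is_decoy for g in result.groups)} "
      f"(group FDR {result.group_fdr:.2%})")
```

prints

```
PSMs kept at 1% FDR: 845/1000
peptides: 88 (88 unique-location, 30 junction)
genome CDS coverage: 80.8%
gene groups: 19 (group FDR 5.26%)
```

155 of the 1,000 simulated PSMs fall below the 1% q-value threshold and
are removed (including most decoys); every retained PSM maps to the
genome and translates back to its peptide. All 88 distinct peptides map
to a unique genomic location because the toy genome has no repeated
coding sequence; 30 of them cross at least one intron. The 19 gene
groups recover the 19 genes with at least two observed peptides, and the
one all-decoy group that slipped through the 1% PSM filter puts the
gene-level FDR at 1/19 ≈ 5.3%.

The same steps are available from the shell:

```bash
probam simulate --seed 7 --genes 20 -o fx/
probam filter fx/psms.tsv --fdr 0.01 --out fx/filtered.tsv
probam map --psms fx/filtered.tsv --gtf fx/schemeA.gtf \
           --genome fx/genome.fa --proteins fx/proteins.fa -o fx/run.sam
probam coverage fx/run.sam --gtf fx/schemeA.gtf --genome fx/genome.fa
probam infer fx/run.sam --gtf fx/schemeA.gtf --genome fx/genome.fa --level gene
```

## Scope notes

The package reads and writes the SAM **text** dialect only — BAM
conversion, sorting and indexing are delegated to samtools. Database
searching, variant-peptide databases and browser hosting are out of
scope. See `docs/methods.md` for the model, parameter defaults and known
limitations.
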