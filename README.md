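# cleavescan

In-silico mismatch-cleavage mutation scanning (CEL I / EcoTILLING-style),
from haplotype sequences to virtual dual-channel gel band patterns and back:

- **variantmodel** — domain types (genes, amplicons, polymorphism events),
  haplotype ⇄ event conversion, mismatch enumeration, and gene ⇄ amplicon
  coordinate mapping (1-based, adaptor-aware, both strands).
- **gelsim** — virtual heteroduplex digestion: a mismatch at amplicon
  position *p* in an *L*-bp product yields a *p*-bp forward-labelled band
  (700 nm channel) and an *L − p*-bp reverse-labelled band (800 nm channel),
  plus a retained full-length product. An explicit `DetectionModel`
  reproduces the empirical failure modes (insensitive terminal windows,
  suppression of dense mismatch clusters). `predict_mixture` computes the
  band positions expected when re-running the assay with a mutated sample
  as reference.
- **bandcall** — the inverse problem: exact maximum-cardinality /
  minimum-deviation pairing of observed 700/800 band sizes into mutation
  positions, with deterministic tie-breaking and never-dropped leftovers;
  presence-matrix parsing.
- **popstats** — detection rate (A1/A2), screened base pairs
  (samples × gene length), mutation frequency (bp screened per mutated
  base pair), and per-position tabulation under both base-weighted and
  occurrence counting conventions.
- **phylo** — Kimura two-parameter distances, Saitou–Nei neighbour
  joining with deterministic tie-breaks, column-resampling bootstrap
  supports, haplotype reconstruction from event tables and multi-gene
  supermatrix concatenation.
- **synthcohort** — seeded synthetic cohorts (shared haplotype clusters,
  SNPs/MNPs/short deletions, recurrent multi-allelic positions, dense
  mutation bursts) with exact round-trip truth tables, plus the packaged,
  checksum-pinned study tables used by the acceptance surface.
- **cli** / **io** — `cleavescan` command-line interface and the shared
  FASTA / TSV / VCF 4.2 / newick readers and writers.

## CLI

```sh
cleavescan synth    --config cohort.json --out cohort/        # synthetic cohort
cleavescan simulate --ref cohort/reference.fasta \
                    --samples cohort/samples_g1.fasta \
                    --amplicon amplicon.json --out bands.tsv   # virtual digestion
cleavescan call     --bands bands.tsv --length 827 --out calls.tsv [--vcf out.vcf]
cleavescan stats    --events truth.tsv --n-samples 96 \
                    --genes accD:1470,matK:1575,rbcL:1440 \
                    [--called calls.tsv] --out report.tsv
cleavescan mixref   --events-x x.tsv --events-q q.tsv \
                    --amplicon amplicon.json --out positions.tsv
cleavescan tree     --alignment aln.fasta --out tree.nwk --bootstrap 1000 --seed 1
```

Every run writes a `*.meta.json` sidecar with version, parameters and seed.
An amplicon JSON looks like:

```json
{"gene": "accD", "gene_length_bp": 1476, "product_length_L": 827,
 "forward_start": 1, "strand": "sense",
 "adaptor_len_fwd": 19, "adaptor_len_rev": 20, "label_scheme": "M13-two-step"}
```

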