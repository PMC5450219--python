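# bhlh-survey

A tested, reusable pipeline for genome-wide surveys of the plant
**basic helix-loop-helix (bHLH)** transcription-factor family — the kind
of analysis run for hexaploid wheat, where 225 family members were
characterized from sequence to expression.

The bHLH domain is a ~60-residue unit with four sub-regions: a basic
region (~14 residues, Lys/Arg/His-rich, contacts DNA), two amphipathic
helices and a connecting loop.  Family surveys answer a standard set of
questions, and this package implements each step as a library function
with a thin CLI on top:

1. **Domain detection** — a position-weight profile (log-odds in bits,
   pseudocounted) is built from a seed alignment of known domains and
   located in each protein by glocal dynamic programming with affine
   gaps; the domain is partitioned into basic / helix 1 / loop / helix 2
   spans in profile coordinates.
2. **DNA-binding classification** — each basic region is placed into one
   of four categories (E/G-box binding, E-box-only, other-binding,
   non-binding) from its basic-residue count (≥ 6 of K/R/H for binding
   competence) and the residues at the conserved E-box (Glu-7, Arg-10)
   and G-box (His-2, Arg-11) contact positions.
3. **Conservation profiling** — per-column modal residues with two
   tiers: *conserved* (modal count strictly above a configurable
   fraction of the family, default the "more than 100 of 225" rule) and
   *highly conserved* (≥ 75%), plus per-column variant reports
   (e.g. which members replaced or lost an otherwise invariant Leu-22).
4. **Phylogeny and subfamilies** — uncorrected p-distances on the
   profile-aligned domains, Saitou–Nei neighbor joining, bootstrap
   support by column resampling, and subfamily assignment of query
   domains from labeled reference domains by nearest patristic distance.
5. **Orthologs and redundancy** — Smith–Waterman best hits (BLOSUM62,
   affine gaps) filtered at aligned length > 60 and identity > 80%, and
   greedy longest-first redundancy clustering at 0.95 identity.
6. **Expression analysis** — FPKM matrices are divided per sample by the
   mean of reference (housekeeping) genes, standardized per gene to
   mean 0 / sd 1, clustered agglomeratively into subgroups, and each
   subgroup is tested for tissue-specific expression by the margin
   between its top two tissue means; qPCR/RNA-seq agreement is measured
   by per-gene Pearson correlation of log2(x+1) values.

A synthetic-data module generates inputs with the statistical structure
the analysis assumes (subfamily-structured domains in random flanks with
planted binding categories, block-structured tissue-specific FPKM
matrices with constant reference genes and a noised qPCR panel), so the
whole pipeline is testable end to end without any download.

## Worked example

Simulate a 5-subfamily, 30-protein family plus a 225-gene, 7-tissue
expression panel, then run every stage:

```bash
bhlh-survey simulate --seed 5 --out sim --subfamilies 5 --members 6
bhlh-survey all --seed 5 \
    --proteins sim/proteins.fasta \
    --seed-alignment sim/seed_alignment.fasta \
    --reference-domains sim/reference_domains.fasta \
    --reference-labels sim/reference_labels.tsv \
    --matrix sim/expression.tsv --meta sim/samples.tsv \
    --reference-genes sim/reference_genes.txt --qpcr sim/qpcr.tsv \
    --out run
```

which prints (and writes to `run/summary.tsv`):

```
                    quantity  value
                  n_proteins     30
           n_with_domain_hit     30
                    n_eg_box     18
                n_e_box_only      6
             n_other_binding      4
               n_non_binding      2
       n_conserved_positions      6
n_highly_conserved_positions      2
          n_subfamilies_used      5
                  n_unplaced      0
       n_redundancy_clusters     30
                 n_subgroups     14
    n_tissue_specific_blocks     14
```

All 30 proteins carry a domain hit; the classifier partitions them
18/6/4/2 across the four binding categories (exactly the planted mix);
all 5 labeled subfamilies attract their members; and with the default
14-subgroup clustering every subgroup in this strongly block-structured
simulation is tissue-specific.  Per-stage tables (`domain_hits.tsv`,
`classification.tsv`, `conservation.tsv`, `tree.nwk`,
`subfamilies.tsv`, `orthologs.tsv`, `normalized.tsv`, `subgroups.tsv`,
`blocks.tsv`, `qpcr_agreement.tsv`) land in `run/` together with a
`manifest.yaml` recording config, input checksums and outputs.
Re-running with the same seed and inputs reproduces every TSV
byte-identically.

The same functionality is available as a library:

```python
from bhlh_survey import (FamilySpec, generate_family, build_profile,
                         scan_protein, default_regions, classify)
from bhlh_survey.synthetic_data import true_domain_alignment

records, truth = generate_family(FamilySpec(seed=1))
profile = build_profile(true_domain_alignment(records, truth))
hit = scan_protein(profile, records[0], min_score=15.0)
category = classify(hit, default_regions(profile))
```

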