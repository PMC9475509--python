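# codondep

Codon-dependency analysis for wobble-uridine (U34) tRNA-modification-dependent
translation.

The Elongator complex (catalytic subunit **Elp3**) and Ctu1/2 write the
mcm⁵s²-modification on uridine 34 of the tRNA anticodons that decode
**AAA (Lys)**, **CAA (Gln)** and **GAA (Glu)**. When the modification is lost,
transcripts enriched in these codons are translated inefficiently: their
protein levels drop while their mRNA levels stay flat. `codondep` implements
the computational workflow for finding such codon-dependent translational
targets:

1. **Codon-set frequency** — for each gene *g* with a coding sequence of
   *n* sense codons, the fraction

   *f*₉ = (#AAA + #CAA + #GAA) / *n*

   counted in frame 0, excluding the terminal stop and any N-containing codon.
2. **Enrichment z-score** against the corpus-wide background
   (μ, σ² of per-gene frequencies over all coding sequences):

   z_sd = (*f*₉ − μ)/σ  (default), z_var = (*f*₉ − μ)/σ²  (the verbatim
   source convention; z_var = z_sd/σ, so rankings are identical).
3. **Proteome/transcriptome integration** — genes with BH-adjusted protein
   p < α and |log2FC| > threshold but non-significant mRNA are classified
   `translational_down`/`translational_up`; other combinations map to
   `concordant`, `mrna_only`, `unchanged` or `unclassified`.
4. **Synonymous recoding** — AAA→AAG, CAA→CAG, GAA→GAG: the protein is
   unchanged but decoding no longer requires the U34 modification
   (construct design for rescue experiments).
5. **Synthetic data with known ground truth** — a CDS corpus generator with
   controlled per-gene codon-set frequency, paired differential tables with
   protein log2FC = β·z₉ + noise, and an OLS + bootstrap estimator that
   recovers β. This makes the entire pipeline verifiable without any download.

## Worked example

```sh
codondep simulate --preset figure4f --seed 1 --out sim/
codondep run --cds-fasta sim/corpus.fa --protein sim/protein.tsv \
             --mrna sim/mrna.tsv --out run/
```

The `figure4f` preset simulates a U34-knockout screen over 2,000 genes
(β = −2): codon-enriched genes lose protein but not mRNA. The run summary
(`run/summary.txt`) printed by the second command begins:

```
codondep pipeline summary
=========================
codon set            : AAA,CAA,GAA
background genes     : 2000
background mean freq : 0.072291
background SD        : 0.025018  (variance 6.259e-04)
policy               : variance=sample;transcripts=longest

translational classes:
  translational_down  : 701
  translational_up    : 816
  concordant          : 0
  ...
```

Reading: the corpus-wide mean combined AAA/CAA/GAA frequency is ≈ 7.2 %
(SD ≈ 2.5 %); 701 of 2,000 genes show significantly decreased protein with
unchanged mRNA — the codon-dependent translational targets — and the top-N
table ranks them by enrichment z for heatmap rendering. (The simulated effect
is linear in z, so codon-*depleted* genes gain protein under knockout; that is
why `translational_up` is also populated — see `docs/methods.md`.)

The same objects are available as a library:

```python
from codondep import (read_cds_fasta, codon_counts, codon_set_frequency,
                      DEFAULT_U34_CODON_SET)
records, report = read_cds_fasta("corpus.fa", transcript_policy="longest")
freqs = {r.gene_id: codon_set_frequency(codon_counts(r), DEFAULT_U34_CODON_SET)
         for r in records}
```

## Checking a real gene

One published check needs an external sequence: the mouse *Ric8b* CDS carries
9.45 % combined AAA/CAA/GAA codons. Download its CDS from Ensembl (GRCm38) to
`data/ric8b_cds.fa` and run either the test
`tests/test_acceptance.py::test_ric8b_codon_set_frequency` or simply:

```sh
codondep count data/ric8b_cds.fa
```

## Layout

| Module | Contents |
| --- | --- |
| `codondep.codon_core` | CDS parsing/validation, codon counting, set frequency, translation, synonymous recoding |
| `codondep.enrichment` | background model, z-scores (both conventions), top-N ranking |
| `codondep.omics_integration` | differential-table IO, BH adjustment, translational-target classification, set intersections, correlation summaries |
| `codondep.synthetic_data` | corpus and differential-table generators, planted cohorts, effect recovery |
| `codondep.pipeline` / `codondep.cli` | orchestration, manifests, reports; `codondep count|enrich|integrate|recode|simulate|run` |

See `docs/methods.md` for the model, its assumptions and the design choices.
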