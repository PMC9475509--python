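# Methods

## The analysis in brief

Loss of the mcm⁵s² modification at wobble uridine 34 (written by
Elongator/Elp3 with Ctu1/2) slows decoding of AAA, CAA and GAA. A gene's
exposure to this defect is summarised by its **codon-set frequency**: the
fraction of its sense codons belonging to the set {AAA, CAA, GAA}. Enrichment
is judged against the distribution of that frequency over an entire CDS
corpus, and candidate **translational targets** are genes whose protein level
responds to U34 loss while their mRNA does not. `codondep` implements this
chain plus the synthetic data needed to verify it end to end.

## Codon accounting

A CDS is read in frame 0 from its first base; no ORF scanning is performed
because the expected input is a pre-extracted CDS export (e.g. Ensembl).
Rules, applied uniformly:

* **Trailing partial codon** — trimmed with a `had_partial_tail` flag rather
  than rejecting the record; real CDS dumps contain such records.
* **Terminal stop** — detected and excluded from the sense-codon count: a stop
  is not decoded by an elongator tRNA, so it belongs in neither the numerator
  nor the denominator of a codon-set frequency.
* **Internal stops** — flagged and retained by default (counted like other
  codons); a strict mode rejects such records instead. Whether they are
  biologically sense codons is moot — they are rare annotation artifacts, and
  either convention changes frequencies negligibly; retaining keeps parsing
  loss-free.
* **Ambiguous (N-containing) codons** — excluded from both numerator and
  denominator and tallied per record: unknown bases should not be absorbed by
  either the codon set or its complement.
* **Case / RNA input** — normalised to uppercase DNA (U→T).
* **Multiple transcripts per gene** — default policy keeps the longest CDS per
  gene; `all` and an explicit transcript list are available. The right choice
  for reproducing any particular published per-gene number depends on the
  transcript set that analysis used, which is why the policy is recorded in
  the background's `policy_tag`.

## Background and z-scores

The background is built over **per-gene** frequencies, each gene weighted
equally regardless of CDS length — the statistic of interest is "how unusual
is this gene", not "how unusual is this codon occurrence". Mean μ, variance
σ² and SD σ are computed with the sample (n−1) convention by default; with
corpus sizes in the thousands the choice is numerically immaterial, but it is
recorded for reproducibility.

Two standardisation modes exist because the convention this analysis
historically used divides by the **variance**:

* `sd` (default): z = (f − μ)/σ — the standard z-score;
* `variance`: z = (f − μ)/σ² — the verbatim historical convention.

They satisfy z_var = z_sd/σ exactly. Since σ > 0, the transform is strictly
monotone, so any ranking (top-N selection, heatmap ordering) is identical
between modes; the test suite asserts this. Degenerate backgrounds (all
frequencies equal, σ = 0) fail loudly rather than returning infinities.

Top-N ranking sorts by z descending, breaking ties by frequency descending
and then gene id ascending, so output order is deterministic across runs and
platforms.

## Integration of protein and mRNA layers

Per-layer p-values are Benjamini–Hochberg adjusted by default (`none`
disables adjustment). A gene is *significant* in a layer when adjusted
p < α (default 0.05) and |log2FC| > fc_threshold (default 0). The class
decision table is a partition — every gene joined across both layers gets
exactly one label:

| protein | mRNA | same sign | class |
| --- | --- | --- | --- |
| sig down | ns | — | translational_down |
| sig up | ns | — | translational_up |
| sig | sig | yes | concordant |
| sig | sig | no | unclassified |
| ns | sig | — | mrna_only |
| ns | ns | — | unchanged |

**Limitation:** "mRNA did not change" is operationalised as *non-significance*
at α, not as an equivalence test; with few replicates an underpowered mRNA
layer inflates the translational classes. Joining is by exact gene id —
identifier harmonisation (aliases, orthologs) is the caller's job.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
sequence biology:

* **Corpus** — per-gene codon-set target frequencies are logit-normal
  (default location logit(0.07), scale 0.3 → mean ≈ 7 %, SD ≈ 2–2.5 %, the
  neighbourhood in which enriched U34-dependent genes live); lengths are
  normal (default 400 ± 150 sense codons) truncated at 30. Each sequence is
  ATG, body codons drawn per position (set codon with the gene's target
  probability, uniform within the set; otherwise uniform over non-stop,
  non-set codons), and a single terminal stop. Generated corpora contain no
  internal stops, partial tails or ambiguous bases by construction.
* **Differential tables** — mRNA log2FC ~ N(0, σ_mRNA) (default 0.2);
  protein log2FC = β·z_g + N(0, σ_protein) (default 0.5), where z_g is the
  gene's sd-mode codon-set z. Per-gene p-values come from a two-sided
  one-sample t-test over n_rep = 3 simulated replicates (SD 0.25) that are
  recentred so their mean equals the reported log2FC exactly — the reported
  fold-change and the tested mean coincide, and with σ_protein = 0 the effect
  is recovered to machine precision.
* **Effect model is linear in z** — the simplest structure consistent with
  "codon-enriched genes lose protein". A side effect worth knowing: genes
  *below* the corpus mean (z < 0) gain protein under β < 0, populating the
  `translational_up` class. Real knockouts are not expected to behave
  symmetrically; the linearity is a modelling convenience for parameter
  recovery, not a biological claim.
* **What it does not emulate** — GC gradients, amino-acid composition of real
  proteomes, length–frequency correlations, peptide-level proteomics noise,
  or mRNA/protein measurement correlation. Passing tests therefore certify
  the *arithmetic and inference machinery*, not robustness to every property
  of real data.

### Seeding

All randomness is NumPy PCG64. Corpus and effect generators derive their
streams as `default_rng([seed, k])` with distinct stream keys k, so passing
the same integer seed to both (a natural thing to do) cannot make their
streams collide — without the key, identical seeds made the protein noise a
deterministic function of the latent frequency draws, badly attenuating
recovered effects. Identical spec + seed reproduces every output
bit-for-bit.

## Effect recovery

β is estimated by ordinary least squares of protein log2FC on z (intercept
included), with a 95 % percentile bootstrap interval over genes (default
B = 1000, deterministic under its seed). The bootstrap-coverage study used in
validation runs 200 simulated datasets of 200 genes (CDS length 200) with
B = 200 — sizes chosen to make the study a routine desk-scale computation
while keeping the Monte-Carlo error on coverage (≈ ±2 %) well inside the
90–99 % acceptance band.

## Pipeline determinism

All tables are UTF-8, tab-delimited, header row, `.` decimal separator, LF
line endings. The run manifest freezes the resolved config, SHA-256 of every
input, package version and per-stage row counts; identical inputs and config
produce byte-identical tables. A stage failure aborts with the stage name and
writes the manifest with `failed_stage` set, so partial outputs are
identifiable.

## Known limitations

* Per-gene enrichment has no p-value — only a z against the corpus background
  (permutation testing is out of scope by design).
* The frequency denominator excludes the terminal stop; analyses that include
  it will report slightly lower frequencies (≈ 1/(n+1) relative).
* The transcript-per-gene policy materially affects per-gene frequencies for
  genes with isoforms of very different lengths; compare `policy_tag`s before
  comparing numbers across runs.
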