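# igtrace

Trace intrathecally produced oligoclonal IgG back to single B-lineage cells.

In diseases with chronic central-nervous-system antibody synthesis (multiple
sclerosis being the canonical case), IgG purified from cerebrospinal fluid
(CSF) contains a locally produced, clonally restricted fraction — the
oligoclonal bands.  Which of the B-lineage cells sampled from the same CSF
actually secrete that IgG can be resolved by proteogenomics: translate each
patient's single-cell B-cell-receptor (BCR) transcripts into a
patient-specific protein library, digest it in silico with trypsin, match
the peptides quantified in CSF and serum against it, and keep only chains
whose abundance is clearly CSF-enriched.  `igtrace` implements that pipeline
for researchers working with paired single-cell BCR repertoires and
label-free IgG peptide quantification, together with a synthetic-cohort
generator so every stage is testable without access to controlled patient
data.

## Method

**Clonal grouping.** Heavy chains of one patient are partitioned by shared
(allele-stripped) V- and J-gene sets and equal CDR3 (junction) length, then
clustered by single linkage at a normalized junction nucleotide distance
strictly below 0.2 (uniform mismatch weights by default; a 5-mer
context-weight table emulating biased hypermutation targeting can be
supplied).  Light chains refine the result: cells within a heavy-chain clone
whose light chains are incompatible are split apart.  Clonally related cells
are collapsed and treated as a single unit (a *clonotype*); a clonotype with
≥ 2 cells is *expanded*, otherwise a *singleton*.

**Library, digestion and iBAQ.** Per patient, the full recombined V regions
(extended 24 nt into the constant region) are translated, deduplicated into
chain groups, and digested with trypsin rules (cleave after K/R, not before
P; up to 2 missed cleavages; observable window 7–30 residues).  Observed
peptides are matched by exact sequence to every chain group whose
theoretical digest contains them.  Chain-group abundance per compartment is

    iBAQ = (summed intensity of assigned peptides) / (number of theoretical
           fully tryptic peptides in the observable window)

**Intrathecal filter.** A chain group passes when, strictly,

    iBAQ_CSF − iBAQ_serum > 5·10⁴   and   iBAQ_CSF / iBAQ_serum > 1.2

(with zero serum signal, the difference test alone decides).  A clonotype is
called intrathecal when a heavy and a light chain group both pass (*pair*
rule), or a heavy chain group passes with ≥ 3 unique CSF peptides
(*single-heavy* rule).  Uniqueness is evaluated at clonotype scope.

**Cell types and statistics.** Cells are labeled antibody-secreting (ASC)
when CD27-high, CD38-high and the immunoglobulin read fraction exceeds 10%
of the transcriptome (strictly); otherwise the flow index-sort gate decides
memory vs naive.  Per patient, the fraction of collapsed units matching
intrathecal IgG is computed overall, per cell type and by expansion status,
and paired fractions are compared with a two-tailed Wilcoxon signed-rank
test that is exact (full sign enumeration, average ranks for ties) up to
n = 25.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
simulated cohort:

```bash
python analysis/01_simulate_cohort.py   # ten patients, 90 cells each
python analysis/02_trace_igg.py         # full tracing pipeline
python analysis/03_match_statistics.py  # fractions, exact tests, dot plots
python analysis/04_robustness.py        # decoy rejection, clone-size effect
```

Output of `03_match_statistics.py` on the default cohort (seed 7):

```
overall: median 13.2% (range 11.5-14.6%) of collapsed B-lineage units matched intrathecally produced IgG
ASC_vs_memory: medians 0.197 vs 0.000, W=55.0, exact two-tailed p=0.001953 (n=10 patients)
ASC_vs_naive: medians 0.197 vs 0.000, W=55.0, exact two-tailed p=0.001953 (n=10 patients)
expanded_vs_singleton: medians 0.191 vs 0.075, W=50.0, exact two-tailed p=0.01953 (n=10 patients)
```

Reading: about one in seven collapsed B-lineage units per patient traces to
intrathecally produced IgG; the matches concentrate in ASCs (no memory or
naive unit is matched, exact paired p ≈ 0.002), and expanded clonotypes are
matched more often than singletons (p ≈ 0.02) because secretion probability
was coupled to clone size in the simulation.  `02_trace_igg.py` additionally
reports recovery against the planted ground truth — sensitivity 1.000 with 0
false calls on this noise-free cohort.

The same pipeline runs on user data from the shell:

```bash
igtrace run --cells cells.tsv --peptides-csf csf.tsv \
            --peptides-serum serum.tsv --out results/run
igtrace simulate --config sim.yaml --out results/cohort
```

Input formats are documented in `docs/methods.md` (AIRR-style rearrangement
TSV; peptide tables with patient, compartment, peptide sequence, intensity).

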