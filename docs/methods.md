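# Methods

## The procedure

`igtrace` decides, per patient, which clonally collapsed B-lineage units
from CSF are the source of intrathecally produced IgG.  The chain of
reasoning is: (1) a cell's BCR transcripts define the exact protein its
clone would secrete; (2) tryptic peptides of IgG purified from CSF and from
serum, quantified label-free, measure how abundant each candidate protein
is in each compartment; (3) a protein made inside the CNS is enriched in
CSF relative to serum, while blood-derived IgG is not.  Everything else —
clonal grouping, iBAQ normalization, uniqueness accounting, the paired
statistics — serves that comparison.

The pipeline assumes its inputs are already reconstructed and quantified:
in-frame full-length recombined V-region nucleotide sequences per cell
(one heavy, at most one light chain), extended 24 nt into the constant
region so constant-region-spanning peptides can match, and peptide-level
summed intensities per compartment.  Spectral search, FDR control and
chain reconstruction from reads are upstream concerns and out of scope.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| junction distance threshold | 0.2 | mismatches/nt, normalized | clones = single-linkage components strictly below it |
| mismatch weights | uniform | — | 5-mer targeting table is pluggable input; published parameter values are external data |
| iBAQ difference threshold | 5·10⁴ | intensity units | minimum absolute CSF excess (strict) |
| iBAQ ratio threshold | 1.2 | — | minimum CSF/serum enrichment (strict) |
| unique CSF peptides (single-heavy rule) | 3 | count | guards heavy-only calls against shared-peptide ambiguity |
| Ig read fraction for ASC | 0.10 | fraction of transcriptome | strict >; CD27 and CD38 must also be high |
| missed cleavages (matching) | 2 | count | matches typical search settings |
| observable peptide window | 7–30 | residues | iBAQ denominator counts 0-missed peptides in this window; configurable |
| exact-test cutoff | n ≤ 25 | pairs | above it, normal approximation with continuity and tie correction |

Decision conventions worth stating: all thresholds are strict inequalities
(a difference of exactly 5·10⁴, a ratio of exactly 1.2 or an Ig fraction of
exactly 0.10 never triggers); when a chain has zero serum iBAQ the ratio is
undefined and the difference test alone decides (any detected CSF abundance
with no serum signal is maximally CSF-enriched); a locus passes the filter
when any of the clonotype's chain groups at that locus passes; shared
peptide intensities count toward every matching chain group (no razor
assignment), and uniqueness — evaluated at clonotype scope, because
clonally related chains share most of their sequence — gates only the
single-heavy rule.  Peptide matching treats I and L as distinct by default;
an I=L mode exists for search outputs that fold them together.

Cells without a productive heavy chain are excluded from clonotyping and
from every denominator, with a logged count.  Multiple chains per locus per
cell keep the highest-support one (``duplicate_count`` column) or the first
seen.  Rows whose frame-1 translation contains an internal stop are
rejected as unproductive rather than frame-searched: the upstream
reconstruction tool emits in-frame V regions, so a frame failure indicates
a broken record, not a frame shift.

## The exact Wilcoxon signed-rank test

Per-patient fractions are paired, n is small (a ten-patient cohort), and
zeros and ties are common, so the asymptotic test is inappropriate.  The
implementation drops zero differences, assigns average ranks to tied
absolute differences, and computes the two-sided p as twice the smaller
tail probability of the positive-rank sum W over all 2ⁿ equiprobable sign
assignments, capped at 1.  The enumeration is realized as a convolution
over doubled ranks (integers even under midpoint ties) — identical to the
literal 2ⁿ sum, which the tests verify for every n ≤ 12 — and switches to
a tie-corrected normal approximation with continuity correction above
n = 25.  Strata that are undefined or contain fewer than two collapsed
units are excluded pairwise from comparisons, generalizing the exclusion
of a single-cell outlier stratum from statistical analysis; no
multiple-testing correction is applied across the three stratum
comparisons, which are reported as raw p-values.

A clonotype spanning several cell types contributes one unit to each type
it spans: collapsing happens within each population, which is the only
reading that keeps per-type denominators well-defined when clones cross
type boundaries.

## What the synthetic cohorts emulate — and what they do not

The generator produces paired heavy/light single cells in clonal lineages
(geometric clone sizes; per-site substitutions at `shm_rate` with the
junction mutation load capped so every member stays strictly within 0.1 of
its founder, hence pairwise within the 0.2 threshold), ASC/memory/naive
labels with Ig read fractions straddling the 10% rule, planted secretor
clonotypes whose chains appear in CSF with lognormal intensities
(log-location `csf_intensity_mu` = 13 ≈ 4.4·10⁵ intensity units, shape
`csf_intensity_sigma` = 0.5), serum-dominant decoy chains built from
reserved germline segments with per-chain CSF/serum ratios drawn uniformly
in [0.5, 1.1], and an optional noise floor below which peptide draws are
dropped (applied per draw, before same-peptide summation; default 0, since
IgG-derived peptides in this setting sit far above detection limits).
Secretors are drawn among ASC clonotypes, uniformly or with probability
proportional to clone size (`secretion_coupling`), emulating preferential
secretion by expanded clones.  Defaults — ten patients, 90 cells each,
70/20/10% ASC/memory/naive, six secretors per patient — mirror a small
CSF sorting study dominated by antibody-secreting cells.

Synthetic germlines are constructed, not downloaded: V segments (270–300
nt, in-frame, stop-free) carry all K/R cleavage sites at 9–13 codon
spacing, while junctions, J segments (45–60 nt) and the 24-nt constant
extension are K/R-free.  Consequently every observable tryptic peptide
(7–30 aa, fully tryptic) overlaps the V segment, and since each clone in a
patient draws a *distinct heavy V segment*, heavy-chain peptides identify
their clonotype unambiguously.  Light V segments are drawn from a small
shared pool, preserving realistic cross-clone light-chain homology (a
light-only match can never create a call, because the pair rule requires
the heavy chain to pass).  A user-supplied germline FASTA loader exists
for realistic repertoires.

This construction is what makes the planted ground truth *exactly*
recoverable, and it is also the generator's main departure from reality:
real repertoires reuse heavy V genes across clones, so germline-derived
peptides are shared and peptide-to-transcript attribution is genuinely
ambiguous — the reason the decision rules demand paired-chain evidence or
multiple unique peptides in the first place.  Passing the recovery tests
therefore demonstrates that the pipeline's bookkeeping is correct under
identifiable conditions, not that real-data attribution is unambiguous.
A trace of the real ambiguity survives even here: under nonzero `shm_rate`,
mutations can create a tryptic site at the junction–J boundary in both a
secreted chain and a bystander clone sharing the same J segment, yielding a
shared J/constant peptide and, rarely (about one cohort in twenty in the
robustness runs), a false pair call carried by a non-unique peptide.  Other
absent features: indels and class switching, cross-type clonal sharing
(clones are type-pure, so memory-compartment hits via ASC-related clones
are not reproduced), spectra-level noise, charge states and modifications,
and intensity correlation structure beyond lognormal draws.

## Numerical and design choices

- Digestion order is deterministic (N→C by start, then missed-cleavage
  count); the digest, the clustering and the exact test are each verified
  against independent brute-force oracles in the test suite, and the
  digest additionally against `pyteomics.parser.cleave`.
- Clone labels are order-independent: members and clusters are sorted by
  cell id, so shuffling input rows relabels nothing.
- Cells lacking a light chain stay with the largest compatible sub-clone
  during light-chain refinement (ties toward the lowest clone id);
  refinement only splits, never merges.
- `50 k` on the intensity scale is read as 5·10⁴ iBAQ units.
- Deterministic outputs: identical config (including seed) produces
  byte-identical cohort files and pipeline reports; all stochastic draws
  flow through one `numpy` generator seeded from the config.
- Problem sizes in the acceptance script (5×300-cell cohorts for recovery,
  20 seeds for decoy rejection, 100 cohorts for the expansion effect, 100
  and 500 instances for the oracle checks) were chosen as the smallest
  scales at which every planted effect is structurally expressed —
  hundreds of clones per patient and double-digit secretor counts — while
  a full run stays in the tens of seconds.

## Known limitations

Beyond the generator gaps above: the pipeline trusts upstream chain
reconstruction (no re-assembly or frame search); memory/naive labels come
from sort gates, not transcriptomes; the 5-mer targeting weights ship
empty (uniform fallback) until a user provides a table; and the intrathecal
filter's fixed thresholds are taken as given rather than calibrated — on
cohorts whose intensity scale differs from the defaults they must be
adjusted via the CLI flags.
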