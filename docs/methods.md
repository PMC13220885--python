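# Methods

This note records the scientific and numerical choices behind the package:
what is modelled, which parameters matter, what the synthetic world does and
does not emulate, and where the design was genuinely open.

## The screening model

The screen treats fusion-caller output as *per-sample detection events*, not
expression levels. A chimera is identified by the exact tuple
(5′ gene, 3′ gene, 5′ breakpoint, 3′ breakpoint); detection is binary per
individual (multiple calls of one chimera in one sample count once). This
matches how recurrence ("found in ≥ k individuals") and the sex-association
table are defined, and deliberately ignores read counts and expression —
quantification is out of scope.

### Junction classification

A breakpoint side is "E" when it lies within `tolerance_bp` (default 2,
**inclusive** — the plain reading of "within 2 bp") of a canonical exon
boundary, where "canonical" means the union of boundaries over all annotated
transcripts of the gene; the nearest boundary wins, with ties broken by
lexicographic transcript id, then smaller exon ordinal. The 5′ side is
compared only against splice-**donor** ends and the 3′ side only against
splice-**acceptor** starts, because a spliced junction joins a donor to an
acceptor. This donor/acceptor restriction is this package's choice — the
underlying screen description says only "exon boundary" — and is the one
deliberate sharpening of the published rule; it can only relabel a side from
E to M (a breakpoint near a wrong-kind boundary), never the reverse.

Boundaries are strand-aware: on the minus strand a donor end is the
genomically *smaller* coordinate of the exon. Offsets are signed in
transcript orientation (query − boundary), so −2 always means "2 bp inside
the exon from its donor end" regardless of strand. All coordinates are
1-based inclusive (GTF convention).

### Filter cascade and accounting

Order: score → homology → classification → M/M removal → aggregation →
recurrence. Boundary semantics follow the published thresholds exactly:
score *strictly below* 0.6 removed (a call at exactly 0.6 is kept); homology
identity *strictly above* 0.90 removed (exactly 0.90 kept); recurrence
*at least* 5 kept. The recurrence comparator is ≥ 5 because the figure
defining the recurrent set says "(≥5)", although the running text says
"more than five"; the threshold and comparator are both configurable.

Every stage books input = kept + removed and consecutive stages chain. The
aggregation stage changes units (calls → chimeras): its `removed_n` counts
calls collapsed into an already-recorded (sample, chimera) detection, so the
conservation identity holds across the unit bridge.

Calls whose parental genes are missing from the annotation are routed to an
`unannotated` bin and appear in the rejects log; they are never silently
dropped.

### Homology filter

The junction probe is aligned to every annotated transcript by full
Smith–Waterman with linear gap penalty (defaults +1 match, −1 mismatch,
−2 gap; `N` never matches). Identity is **matches / probe length** — a
coverage-weighted identity, chosen so that a genuine chimeric probe half of
which matches one parent perfectly scores 0.5, while a probe copied from a
single transcript scores near 1. This diverges from BLAT's exact identity
formula by design at desk scale. Among co-optimal alignments the one with
the most matched columns is reported, then the smallest target start; both
tie-breaks are resolved inside the dynamic program, which therefore keeps
zero-score non-empty prefixes alive (a clipped-at-zero variant would
under-report matches on co-optimal alignments).

Whether the published homology filter required the high-identity alignment
to span the junction itself is unknown; this package filters on whole-probe
best identity and logs the alignment span per removal.

A pigeonhole k-mer prefilter (enabled by default) skips transcripts that
share no exact k-mer with the probe, with k = ⌈min_matches/(errors+1)⌉
derived from the threshold and probe length (k = 10 at 90% over a 50-mer).
An alignment exceeding the threshold under substitution/deletion divergence
must contain such a shared k-mer, so skipping cannot change a keep/remove
decision in that regime; pathological insertion-rich co-optimal alignments
could in principle evade the seed, which is why the prefilter is a config
flag and a test asserts agreement with the full scan on simulated cohorts.

### Sex-association statistics

Pearson's chi-squared on the 2×2 detection table, df = 1, **no Yates
continuity correction** — "Pearson's chi-squared" is taken at its word, and
zero-cell tables like (24, 133, 0, 268) remain testable under Pearson. A
zero *column* margin (detected by nobody or everybody) is flagged untestable
instead of producing a number; in practice the recurrence filter guarantees
a nonzero detected margin. The headline significance flag compares the raw p
against −log10(0.05) = 1.3 exactly as the screen's bubble plot does;
BH-adjusted values and a two-sided Fisher exact p (scipy's hypergeometric
summation) are extra columns, not inputs to the flag. The bubble table's x
axis — unspecified in the published plot — is the genomic rank of the 5′
breakpoint.

The validation cohort's published P = 2.7 × 10⁻⁵³ is *not* reproduced by
Pearson chi-squared on its printed table (474, 51, 173, 554), which gives
χ² ≈ 540 and a far smaller p; the test used there is unstated. This package
reports both Pearson and Fisher values and treats only the χ² value it can
derive (≈ 540) as checkable.

## The synthetic world

`simulate` generates adjacent same-strand gene pairs (strands alternate
between pairs so minus-strand logic is always exercised), one transcript per
gene, uniform-random ACGT sequences. Defaults, chosen once:

| parameter | default | why |
|---|---|---|
| n_female / n_male | 157 / 268 | the discovery cohort's sex split |
| planted penetrance (F, M) | 0.15, 0 | reproduces a ~24/157 vs 0/268 pattern |
| background chimeras | 50, detect prob 0.1 | no published per-sample rate exists; 0.1 sits mid-range of plausible 0.05–0.3 and yields recurrences comfortably above the ≥5 cut |
| artifacts per class | 5 | enough to make stage checks non-vacuous, small enough to keep runs fast |
| junction arm length | 25 bp/side | typical caller junction-probe arm; gives the 50-mer probes the homology filter expects |
| gene-pair spacing | 9,124 bp | the printed breakpoint distance of the motivating X-linked pair; keeps pairs inside the 100-kb proximal cut |
| exons per gene | 6 | smallest count that distinguishes "third from last" (exon 4) from "second to last" (exon 5) with room around them |
| exon / intron lengths | 60–120 / 200–800 bp | small but larger than 2× the arm length, so probes never span three exons |
| real / artifact score ranges | [0.6, 1.0] / [0.05, 0.59] | consistent with the 0.6 decision boundary |

Detection is an independent Bernoulli draw per (sample, chimera) with the
sex-appropriate penetrance. Planted chimeras join the donor's
third-from-last exon to the acceptor's exon 2 (the e24e2-like architecture);
background donors use a random internal exon. Genuine probes are one arm
from each parent around true exon boundaries (hence E/E and parental
identity ≈ 0.5); M/M artifacts shift both breakpoints 3–10 bp into their
exons; homology artifacts copy a 50-mer from one transcript with at most one
substitution (identity ≥ 0.98). Artifact chimeras are guaranteed at least
one emission so "removed at its intended stage" is never vacuously true.
Randomness flows from one seed through fixed named substreams per component,
so adding an artifact class never perturbs the background draws.

What the generator does **not** emulate — and what a green test therefore
does not establish: read-level evidence (no FASTQ, no alignment ambiguity),
caller-specific score distributions (scores are uniform in their range),
correlated detection between chimeras or between samples, expression levels,
partially homologous gene families, and annotation errors. The recovery
rate measured here is a property of the stated world, not an estimate of
the screen's sensitivity on real cohorts.

## Numerical choices and degenerate inputs

- Chi-squared p-values come from `scipy.stats.chi2.sf`; `p = 0` underflow
  maps to `neg_log10_p = inf`, which still compares correctly against the
  cutoff.
- The two Pearson formulas (closed form and Σ(O−E)²/E) are both implemented
  and asserted equal to 1e-9 relative tolerance in tests.
- Empty call tables, empty transcript sets (homology becomes a warned
  no-op), and cohorts with zero detections are all legal and keep the
  accounting identities.
- Output tables are deterministically sorted (chrom, position, gene pair);
  the only timestamp lives in a single summary.json field so byte-level
  comparison of reruns works.
- `merge_window_bp` (default 0 — exact junction identity, since callers
  report consistent junctions per event) optionally clusters keys of the
  same gene pair whose breakpoints each differ by at most the window,
  merging under the smallest key.

## Known limitations

- The homology filter's identity denominator and whole-probe scope are
  documented approximations of a BLAT-style screen, not a reimplementation.
- Single-transcript genes are the generator's norm; multi-isoform boundary
  competition is exercised only in hand-built fixtures.
- Covariate-adjusted association (age, BMI, population) is out of scope; the
  metadata columns are carried through untouched, and karyotype is recorded
  but never modelled.
- The CLI's `report` subcommand recomputes only the counts derivable from
  the results table (tested, significant, cutoff), not stage accounting.
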