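# Methods

This note records the conventions, algorithms and design decisions behind
pirkit, in the order data flows through the pipeline.

## Structure parsing and residue annotation

A template's *polymer sequence* is the depositor's construct, not just the
residues with coordinates.  `structure_io.parse_pdb` therefore merges three
sources:

* **Observed residues** from ATOM records, grouped by
  (chain, author number, insertion code, residue name), in file order.
  Alternate locations collapse to the first conformer; occupancy is ignored
  — sequence and topology, not geometric fidelity, drive this pipeline.
* **Missing residues** primarily from REMARK 465, inserted at their author
  positions as atom-less records.  When REMARK 465 is absent but SEQRES is
  present, missing runs are inferred by exact-match anchoring of the
  observed residue codes against SEQRES (difflib matching blocks); if the
  anchoring is ambiguous the chain is assumed complete.  Author numbers for
  inferred positions are extrapolated from the nearest anchored neighbour.
* **Modified residues** from MODRES records first; otherwise any polymer
  HETATM whose author number falls inside the chain's ATOM numbering range
  and whose code has a known parent amino acid (built-in table: MSE→M,
  SEP→S, TPO→T, PTR→Y, CSO→C; anything else renders `X`).

Everything else in HETATM records becomes a ligand record carrying its
0-based ordinal within the chain's coordinate section; waters (HOH/WAT/DOD)
are flagged and excluded from ligand listings unless requested.

Rendering is a pure function of status: alignment mode masks missing and
modified positions as `X` (so external aligners see a neutral residue); PIR
mode renders missing as `-` and modified as `.`, the characters the modeling
engine expects.  Chain breaks never split chains — a chain is defined purely
by its chain identifier — and insertion codes are part of residue identity,
with ordering following the file, never a numeric sort.

## Hit parsing

BLAST XML is read with Biopython's NCBIXML parser; one hit is kept per
subject (the lowest-E-value HSP), because downstream modeling needs one
alignment per template.  Identity follows BLAST's own convention
(identities / alignment length, gap columns included); coverage is the HSP
query span over the query length.  Subject IDs of the forms `pdb|1ABC|A`,
`1abc_A` and `1abc|A` are recognized; others are skipped with a warning.

No installed library parses HHsearch `.hhr`, so that parser is hand-written:
the summary table fixes the expected hit count, per-hit `Q`/`T` alignment
lines (skipping consensus and secondary-structure rows) are concatenated
across blocks, identity is taken from the `Identities=NN%` field when
present and otherwise recomputed from the alignment, and coverage is always
recomputed from the query span — the report's own coverage notion is not
trusted.  Probability and score columns are carried as metadata only;
ranking is by ascending E-value with identity as tie-break.

## Alignment bookkeeping

* **Identity** = 100 × identical both-non-gap columns / both-non-gap
  columns.  `X` never counts as identical, so masked (missing/modified)
  positions depress identity rather than inflate it.  BLAST-reported
  identity is kept separately on the hit object; the recomputed value is
  the default for binning.
* **Bins** are decades on [20, 90), lower bound inclusive: 30 % belongs to
  [30, 40), 40 % to [40, 50).  Outside that range `assign_bin` returns
  `None`, which the benchmark treats as "excluded".
* **Trimming** removes leading/trailing columns until the first/last column
  where the target has a residue *and* at least one template supports it
  (template positions with missing status count as gaps).  Requiring
  support from one template — not all — lets a second template extend a
  terminal region the first one lacks, which is the main reason to model
  with multiple templates.
* **Coverage** divides the supported target residues inside the trimmed
  span by the *full* untrimmed target length.  With the trimmed span as
  denominator an 80 % threshold could never fail; with the full length it
  measures what fraction of the protein actually gets modeled.
* **Edit validation**: a template row is valid iff its ungapped sequence is
  a contiguous substring of the original's — gaps may be added or moved
  anywhere, but residues may only be trimmed from the outside (an internal
  deletion would desynchronize the row from the template coordinates).  A
  target row only needs valid characters (letters and `-`), since the
  target sequence is the user's own to define.

## PIR construction

Template rows render observed→letter, missing→`-`, modified→`.`; the target
renders verbatim.  Each template's start/end residues are resolved by
matching the gap-stripped row against the chain's observed residues (`.`
matching modified positions); zero or multiple matches abort with the
candidate list.  Before serialization every template row is re-verified
position-by-position against the structure — the check that catches
misthreaded alignments before an expensive modeling run.

Ligand grafting follows the convention that the template's ending residue
becomes the *last selected* ligand in coordinate-section order: every
polymer residue and HETATM between the old end and that ligand contributes
one appended column (`.`, letter, or `-` by status; `.` for HETATMs), the
target row is padded with `-` and then given `.` exactly at selected-ligand
columns, and all other entries pad with `-`.  Unselected HETATMs that
precede the last selected ligand therefore keep a `.` column in the
template but stay `-` in the target — they are present in the coordinates
read by the modeling engine but not modeled into the target.  HETATMs after
the last selected ligand are excluded entirely; this minimizes unrequested
ligand columns while honouring the ending-residue rule.  Ligands from
different chains append in global coordinate order.

Serialization is byte-stable: `>P1;name` headers,
`structureX:file:start:chain:end:chain::::` or `sequence:name::::::::`
descriptors, 75-column wrap, LF endings, one trailing `*` per entry.  Job
configurations default to 10 models per run with very-slow refinement
(`none` and `fast` are the other accepted levels); the HETATM/water read
flags follow directly from the ligand selection.  The emitted modeling
script is a template-filled stub and is never executed here.

## Comparison scores

All residue pairing is by alignment-derived labels, never by raw author
numbering across different proteins.  Default representation is CA-only for
RMSD/TM/GDT-HA (the convention of the standard scoring programs); lDDT
defaults to all heavy atoms with a CA-only option.

* **RMSD**: least-squares rigid superposition via SVD (Kabsch), proper
  rotation enforced; collinear inputs are rejected as ill-conditioned.
* **TM-score**: d0(L) = 1.24·(L−15)^⅓ − 1.8 floored at 0.5 Å, normalized by
  the reference length.  The maximization seeds superpositions from sliding
  windows of lengths {L, L/2, 7} and refines each seed by iteratively
  re-fitting on the residues within the distance cutoff until the subset
  stabilizes (cutoff d0, relaxed in 0.5 Å steps when fewer than 3 residues
  qualify); the best score over all candidate transforms is kept.  This is
  an approximation of the search in the reference implementations, and the
  test suite pins it against an independent loop-level re-implementation of
  the same published search rather than against external binaries.  GDT's
  discrete objective is inherently sensitive to the seed schedule — even an
  exhaustive all-window search disagrees with any subsampled schedule by a
  few tenths of a unit in both directions — so agreement is defined against
  the same schedule, independently coded (observed agreement: exact over 60
  toys at noise 0.5–1.5 Å).
* **GDT-HA**: mean over 0.5/1/2/4 Å of the maximal fraction of pairs under
  each threshold across the candidate transforms (each threshold also used
  as a refinement cutoff; candidates are shared across thresholds).
* **lDDT**: superposition-free; over all reference atom pairs from
  different residues within a 15 Å inclusion radius, the fraction of
  distances preserved within 0.5/1/2/4 Å, averaged over thresholds.  Pairs
  within one residue are excluded; there is no sequence-separation filter
  and no stereochemistry penalty.  Atoms missing from the model count as
  unpreserved.
* **RMSD difference** = model-vs-target RMSD − template-vs-target RMSD; a
  negative value means the model landed closer to the target than its own
  template.
* **Longest common segment** trims a model set to the longest run of labels
  shared by all models, where contiguity means consecutive author numbers
  (falling back to list adjacency for non-numeric labels); ties break to
  the earliest start.

## Benchmark protocol

A set is one (target, template) pair aligned by five options (mafft,
muscle, clustalo, tcoffee, and the search program's own alignment).
Filters run in a fixed order and each is idempotent:

1. *Bin consistency*: all five recomputed identities must fall in the same
   decade bin — realigning the same pair with different programs shifts
   identity, and sets straddling a bin edge are not comparable across
   aligners.
2. *Coverage*: at least 80 % of the target modeled under every alignment
   option (boundary inclusive).
3. *RMSD outliers*: per bin, sets whose template–target RMSD exceeds the
   upper Tukey fence (Q3 + 1.5·IQR) are dropped.  The source protocol states
   that outliers were removed without giving the rule; the Tukey fence is
   this package's choice, deliberately one-sided (a low RMSD is never
   suspect) and configurable.  Note the fence is uninformative for fewer
   than about four regular sets per bin.

Model quality scores (e.g. DOPE Z-scores) arrive as a table and are never
computed here; the top model is the minimum score, native-like when
≤ −1.0.  The bookkeeping identity *total models = kept sets × alignment
options × models per run* is exposed as `count_models` (with the published
benchmark sizes, 5,869 × 5 × 10 = 293,450).  The self-template control
(`remodel_control`) models a target from its own structure: the two PIR
rows are identical except that missing residues are gap columns in the
template entry, and the pairing's identity is exactly 100 %.

## Synthetic fixtures

The generator emulates the benchmark's collection stage at miniature scale.
A target is a random 20-letter sequence on an idealized helical CA trace
(2.3 Å radius, 1.5 Å rise, 100°/residue ≈ 3.8 Å CA–CA spacing); a template
is derived from it by mutating a deterministic position subset to hit the
requested identity (rounding resolved toward lower identity), adding
isotropic Gaussian coordinate noise, deleting terminal runs, inserting
missing-residue runs (REMARK 465 + absent ATOMs), marking modified
positions (MODRES + in-chain HETATM MSE), and appending ligand HETATMs.
All randomness flows through a seeded PCG64 generator, so equal seeds give
byte-identical files.

The benchmark generator samples identities 4–8 points above each bin's
lower edge and template noise that grows as identity falls (σ from ≈0.4 Å
in the 80–90 % bin to ≈2.2 Å at 20–30 %, jittered ±30 % within a bin so the
per-bin RMSD spread is short-tailed and the Tukey fence is well-behaved).
Planted failures carry ground-truth labels: one low-coverage set, one
bin-straddling set, and one RMSD outlier (σ = 12 Å) per bin.  Aligner
variation is simulated by splitting aligned columns into half-gapped pairs,
with a guard that a regular set's perturbed identity never leaves its bin.

What the fixtures do *not* emulate: real side-chain geometry, realistic
gap structure from actual alignment programs, conformational change between
homologs (noise is isotropic and memoryless), or the scale of the real
benchmark (thousands of sets).  Passing tests therefore demonstrate the
correctness of the bookkeeping, formats, filters and scores — not modeling
accuracy on real proteins.

## Problem sizes and numerics

The default test and acceptance runs use fixture lengths 20–100 residues,
100 end-to-end PIR builds, 50 self-comparisons, 20 oracle toys (30
residues), 20 seeds per noise level for the monotonicity check, and a
benchmark of 6 regular sets per bin plus planted failures — sizes chosen so
the whole suite exercises every code path in about a minute while keeping
the per-bin statistics (Tukey fences, mean trends) stable.  Tolerances:
superposition agreement to 1e-6 Å against the quaternion oracle; TM within
0.01 and GDT-HA within 1 unit of the search oracle; exact (floating-point)
agreement for lDDT against its brute-force definition.
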