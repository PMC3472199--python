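# Methods

This note documents the models and conventions behind `ppofam`: what each
stage assumes, the tunable parameters and their defaults, what the synthetic
generator does and does not emulate, and the numerical choices a maintainer
would want written down.

## Coordinates and formats

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) is converted at the I/O boundary only. Exons of '-'-strand genes
are stored ascending genomically and spliced in reverse for transcription.
Nucleotides outside {A,C,G,T,N} are a hard error: inputs containing other
ambiguity codes must be sanitized deliberately, not silently coerced.
Translation uses the standard genetic code; a terminal stop is removed, and
internal stops are rendered `X` with their codon indices recorded — the
validation stage, not the I/O layer, decides rejection. Newick I/O preserves
branch-length text (integral lengths print without a decimal point) and
integer support labels, so trees round-trip byte-identically.

## Validation filters

A candidate is retained iff

* CDS length ≥ 1200 nt (`min_cds_length`, configurable). The length **includes
  the terminal stop codon** — gene-model lengths in annotation practice do —
  and the boundary is inclusive: 1200 nt is kept, 1199 rejected.
* no internal stop codon (`PREMATURE_STOP`);
* both copper domains located (`INCOMPLETE_DOMAIN` otherwise) with three
  conserved histidines each (`MISSING_HIS` if an anchored domain has fewer).

`FRAME` (CDS length not a multiple of 3) is reported only for models that
pass the length filter; a trailing partial codon on an already-too-short
model is subsumed by `TOO_SHORT` (truncated models almost always break the
frame, and double-reporting obscures the primary defect). For translation in
the validation path the trailing partial codon is trimmed. No repair of
broken models is attempted: models that would need exon re-splicing are
rejected with reason codes, by design.

## Domain annotation

* **CuA**: first HxxxC anchor whose following 60 residues (`his_window`)
  contain ≥ 2 further histidines; span = anchor through the third His,
  inclusive. If no anchor satisfies the histidine rule, the best anchor's
  His count is still reported so validation can tell "no domain" from
  "missing histidines".
* **CuB**: first HxxxH anchor 60–160 residues (`linker_min/max`) past the CuA
  end whose window holds a third His and a phenylalanine downstream of the
  second motif His (that Phe is invariant in PPOs). The "hydrophobic fourth
  position" of HxxxH is the 4th residue of the 5-residue motif, drawn from
  {A,V,L,I,M}.
* **Segmentation**: NTERM = [0, CuA start); LINKER = (CuA end, CuB start);
  DWL = 50 residues (`dwl_length`) past the CuB end, extended to cover a YxY
  hit falling 40–70 residues past CuB (the proteolytic processing site);
  KFDV = remainder. A protein ending inside the DWL window is flagged
  (`kfdv_empty`). The thylakoid-transfer domain is not modelled separately
  from the cTP call; Pfam HMMs are not used — segmentation runs off the
  stated approximate lengths.
* **Targeting** is a deliberately simple, documented stand-in for
  ChloroP/TargetP (which are external tools): CTP iff the Ser fraction of the
  first 35 residues ≥ `ser_threshold` (default 0.15) *and* an AxA cleavage
  motif occurs in residues [35, 110); else SP iff some 8-residue window in
  residues [5, 30) has mean Kyte–Doolittle hydropathy ≥ `hyd_threshold`
  (default 2.5); else UNKNOWN. The 0.15 serine default operationalizes
  "serine-enriched" and is reported as a stand-in in `run_metadata.json`;
  2.5 sits between the scores of genuine hydrophobic h-regions (poly-L
  windows score 3.8) and what random protein background reaches. A parsed
  external predictor table overrides the heuristic per gene.
* **Conservation**: per-column information content in bits,
  `log2(20) − H(column)`, with gaps and `X` excluded from the frequencies and
  columns > 50% gaps reported missing. No small-sample correction — the
  simplest defensible definition, stated so the numbers are comparable.

## Alignment and trimming

The recommended path supplies an externally computed alignment (MUSCLE,
MAFFT, …), which is validated (every row must degap to its input sequence)
and used verbatim. The built-in fallback is a standard progressive aligner:
UPGMA guide tree on 3-mer count distances, profile–profile merges by global
affine-gap dynamic programming (gap of length k costs `open + extend·k`,
defaults 10 + 1·k, PAM250 substitution scores), deterministic tie-breaking
(diagonal, then gap in the first profile, then the second). It makes no
claim to MUSCLE's accuracy; it exists so the pipeline is self-contained and
its score is verified against a brute-force alignment enumeration in tests.

Trimming to the core keeps the union span from the first column hosting any
row's CuA start to the last column hosting any row's DWL end (union, not
intersection, so no copper-domain column of any row is lost). Trimming
happens after alignment; per-row left offsets are recorded so intron
coordinates can be projected either way.

## Distances, NJ, bootstrap

p-distances use pairwise deletion by default (sites where both rows hold a
residue; `complete` deletion is available), with per-pair site counts kept.
The Dayhoff correction builds the 1-PAM transition matrix from the vendored
Dayhoff (1978) exchangeabilities and equilibrium frequencies (rate matrix
scaled to 0.01 expected substitutions/site, then exponentiated), tabulates
the expected-difference curve D(n) for n = 0..500, and inverts it by
monotone interpolation; p at or beyond the curve's plateau (~0.911) raises a
saturation error and the pair is excluded. This is a model-level
re-implementation of the classic "Dayhoff distance"; numeric identity with
any particular legacy program is not claimed.

Neighbor joining follows Saitou–Nei (Q criterion, standard branch-length
formulas). Negative branch-length estimates are clamped to zero with the
deficit moved to the sister branch. Q ties are broken toward the pair whose
sorted cluster labels (each cluster labelled by its smallest leaf name) are
lexicographically smallest, so results are order-independent. Outgroup
rooting splits the outgroup's pendant edge at its midpoint. Bootstrap
support is the percentage of column-resampled replicates whose NJ tree
contains the same bipartition; replicates with a saturated or zero-overlap
pair are redrawn (capped at 10× the replicate count). The report layer hides
supports ≤ 50%.

## Intron homologization and reconstruction

An intron is (codon index, phase) = (cumulative exonic nt 5' of it) divmod 3.
Phase is tracked because two distinct introns one or two nucleotides apart
within a codon would otherwise merge. Canonical = GT..AG in transcription
orientation. Homology: identical alignment column **and** identical phase,
tolerance 0 — the only reproducible reading of "same position";
`column_tolerance` exists for sensitivity analysis only. Characters are
labelled by the majority segment of their column across member rows
(N/A/L/D/K codes plus C for positions 3' of the last aligned residue) and
numbered by ascending column within each code. Note two conventions: the
label set has no CuB code, so an intron inside CuB would be labelled L
(none of the generator's default slots are in CuB); and the ordinals are a
deterministic artifact of this pipeline's alignment — they are not claimed
to match any particular published figure's numbering, which depends on an
alignment we do not possess.

Fitch parsimony is implemented as unit-cost Sankoff DP (exact on
multifurcating nodes too), ties resolved toward absence; equally
parsimonious ancestral labellings are enumerated exactly (count by DP,
enumeration capped at 10,000 scenarios with the true count still reported).
Dollo parsimony fixes the single gain on the edge above the MRCA of the
presence leaves and takes one loss per maximal absent subtree below it.
Reconstruction runs on the outgroup-rooted tree when an outgroup is given,
otherwise on the NJ tree as returned (trifurcating root surrogate).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes — it
is the test bed, not a claim about real genomes.

* **Archetype protein** (default 462 aa): NTERM 75 (60–90 plausible), CuA 46
  (anchor..third His), linker 100, CuB 46, DWL 50, KFDV 145. Planted,
  invariant motifs: `HCAYC` + two His (CuA); `HRVMH`, Phe, third His (CuB);
  `DWL` and `YDY` (DWL); `EEEEEVLVI`, `KFDV`, `EFAGSF`, `HHH` (KFDV region);
  for the cTP variant 11 serines in the first 35 residues (6 invariant, so
  the Ser fraction never decays below ~0.17) and an AxA at NTERM end − 20;
  for the SP variant an 8-residue invariant poly-L core in the h-region.
* **Background sites** are drawn from the Dayhoff equilibrium restricted to
  the 18 non-His/non-Cys residues, and substitutions are conditioned to stay
  in that set — so copper-domain anchors are unambiguous in truth and every
  recovery failure is attributable to the pipeline, not to motif collisions.
  The DWL segment's background additionally avoids Tyr so the YxY-extension
  rule fires only on the planted motif at zero divergence. These restrictions
  (plus the absence of indels in the default families) are exactly what
  passing tests do *not* exercise about real data: real PPOs have His/Cys
  outside the copper sites, indels, and fuzzier motif boundaries.
* **Evolution**: gene trees by a duplication–loss birth–death process along
  the species tree (defaults: duplication 0.8, loss 0.25 per gene per unit
  branch length on a 4-species tree of depth 0.4 substitutions/site,
  expected family size ≈ 10); sequences evolve by the discretized PAM chain
  (branch length × 100 × `pam_scale` rounded to 1-PAM steps), matching the
  Dayhoff model assumed downstream so estimator-bias tests are meaningful.
* **Introns**: a fixed menu of candidate slots (one per region code, two in
  the linker; each a codon index + phase on archetype coordinates), an
  ancestral set (default {L1}), and per-edge gain/loss events at configurable
  rates (default 0.3/0.3), with optional forced events keyed to an MRCA for
  deterministic planting. Intron sequences are GT..AG (one GC..AG decoy on
  request), lengths uniform in `intron_length_range` (default 60–400 nt,
  well inside the tens-to-thousands span of real plant introns). Genes are
  placed on per-species genome strings on random strands with ≥ 500 nt
  spacers.
* **Decoys** copy a valid gene and violate exactly one rule: truncation to
  1199 nt; one mid-linker codon → TAA; third CuA His → Ala; CuB anchor His →
  Arg. Decoys are emitted intronless (retroduplicated copies).
* **Determinism**: one `numpy` generator seeded from the config; identical
  configs give byte-identical FASTA/GFF3/truth files. The event log replays
  to each gene's emitted intron set (checked internally on every run).

## Reproducibility studies and problem sizes

`ppofam.benchmarks` (used by the acceptance tests and
`scripts/acceptance.py`) runs: validation recovery on 50 families of 8–15
valid genes + 4 decoys (family size is a realized birth–death variable; the
harness scans seeds and keeps qualifying families); NJ on 100 additive
matrices from random 5–8-leaf trees, with 20 of the ≤ 6-leaf cases checked
against exhaustive topology enumeration under OLS branch-length fitting;
Fitch and scenario counts against brute-force enumeration on 500 random
characters; Dayhoff estimator bias at PAM 10/50/100 over 10,000 sites × 100
replicates; intron-character recovery on 100 families with 3 shared + 2
unique planted characters; bootstrap sanity at 200 replicates on a six-gene
family with unambiguous clades; and double execution of the full survey for
byte-level determinism. These sizes keep the whole suite under a few minutes
on one core while leaving each statistic's sampling error far below its
acceptance margin.

## Known limitations

* The fallback aligner is for convenience and testing, not benchmark-grade
  multiple alignment; supply a real aligner's output for publication work.
* The targeting heuristic approximates, and does not reproduce,
  ChloroP/TargetP; its thresholds are honest defaults, not fitted values.
* No rate heterogeneity across sites in the distance model; no probabilistic
  intron gain/loss model (parsimony only); no U12-intron classification or
  intron-sliding detection.
* The generator does not simulate indels within the core, pseudogenization
  beyond the four decoy classes, or genome assembly artifacts.
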