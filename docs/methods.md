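# Methods

This note records the models, conventions and design choices behind
`genedecay`, and what the test suite does and does not establish.

## Lesion detection and verdicts

All scans run against a single designated reference — the intact ortholog —
whose annotated coding start defines the reading frame for every sequence in
the alignment.  Query sequences never redefine the frame: codon *i* of a
query means "the residues aligned under reference codon *i*".  This mirrors
how decayed orthologs are read in comparative studies; it also means that
downstream of an unrepaired frameshift the per-codon calls describe the
reference frame, not the (biologically meaningless) shifted one.

* **Premature stops.** Every complete query codon strictly before the
  reference's terminal stop is compared against the stop set (default
  standard-code TAA/TAG/TGA).  Codons containing gaps or IUPAC ambiguity
  codes are skipped and logged, never guessed — alignment artifacts must not
  fabricate stops.  The terminal stop position itself is exempt; a query
  *lacking* a stop there is reported as a note ("missing terminal stop"), not
  an event, since by itself it proves read-through rather than truncation.
* **Indels.** A deletion is a maximal column run with query gap / reference
  residue; an insertion the converse; both-gap columns belong to neither and
  terminate runs.  `length mod 3 != 0` makes a run `frameshift_indel`, else
  `inframe_indel`.  Distinct runs are separate events with no net-frame
  compensation (+1 and −1 indels are two frameshifts, not a silent pair);
  the per-sequence net frame offset, `ungapped(query) − ungapped(reference)`,
  is reported alongside so compensated cases stay visible.
* **Motifs.** Required residues at fixed codons (for CC chemokines, cysteines
  at mature-protein codons 53–54) are checked by translation.  A stop codon
  there is `motif_stop_loss`; any other residue is `motif_substitution` with
  the observed residue recorded (`C53K`); gapped codons record `gap`.  When
  both the stop scanner and the motif checker see the same codon, the merged
  scan reports the single lesion once, as `motif_stop_loss` — one mutation,
  one event.
* **Verdicts.** `pseudogene` iff at least one truncating lesion
  (premature stop, motif stop loss, frameshift, start loss); otherwise
  `impaired_motif` if a motif residue is substituted; otherwise `functional`.
  In-frame indels alone do not demote an allele: they preserve the frame, and
  an in-frame insertion of, say, 24 nt merely lengthens the product.  A
  species is functional with ≥ 1 functional allele (a heterozygote still
  makes protein), pseudogene only when every allele is, `impaired` otherwise.
  `impaired_motif` is deliberately distinct from `pseudogene`: a Cys→Lys
  substitution most likely compromises the disulfide bond but is not proof of
  loss the way a truncation is.

## Coordinates

Positions are 1-based, intervals closed.  Two numbering modes exist because
published figures and genome annotation disagree: `alignment_columns` numbers
every column, gap columns included (the convention of alignment figures, and
the default), while `ungapped_reference` numbers only reference residues.
The two coincide whenever the reference is ungapped.  Indel events anchor to
the first reference position of the run (deletions) or the first position at
or after it (insertions).

## Splice-acceptor scanning

Candidates are pure dinucleotide matches within a window upstream of the
annotated intron 3' end — no position-weight matrix and no neural scoring;
this is a deliberate replacement of black-box splice predictors by an
auditable motif scan.  Both the canonical intron-terminal reading (default
motif `AG`, the last two intron nucleotides the site would use) and an
exon-initial reading (the first two nucleotides of the retained segment, for
the "CA flanking the exon" description found in the literature) are
supported, because the published wording does not settle which was meant.
Retention arithmetic is exact: using a site `k` nt upstream retains `k`
intron nucleotides; the frame survives iff `k mod 3 == 0`, inserting `k/3`
residues translated in the downstream-exon frame.

## Tajima's relative-rate test

Implemented from first principles on aligned triples: five mutually exclusive
site categories (unique to A, unique to B, unique to outgroup, all different,
all identical), `chi^2 = (nA − nB)^2 / (nA + nB)` with 1 df, upper-tail p
(for 1 df this equals `erfc(sqrt(x/2))`, which the tests use as an
independent oracle against the scipy implementation).  No continuity
correction — the published table values are reproduced exactly by the
uncorrected statistic.  Complete deletion drops every column with a gap or
ambiguity code in any of the three sequences; for a bare triple the
"pairwise-complete" policy necessarily coincides (every category compares all
three sequences) and is accepted as an alias.  Rounding to the 2 dp of
published tables happens only in the presentation layer (`rrt_table`).

One published figure does not survive recomputation: the p-value printed as
0.16 for chi-square 1.92 is exactly 0.1658, which rounds to 0.17 (the
printed value truncates).  The package reports full precision.

## The simulator

Sequences evolve root→leaves along a rooted newick tree with branch lengths
in expected substitutions/site.  Substitution models are JC69 and K80
(closed-form transition matrices, K80 normalized to α + 2β = 1 with
κ = α/β, default 2.0; κ = 1 reproduces JC69 exactly).  Per branch, each
site's state is drawn from the corresponding row of P(t) — exact sampling,
no discretization.

**Planted events are the experiment.**  Stop gains rewrite a codon to the
nearest stop (minimal base changes, ties broken TAA < TAG < TGA — the
single-nucleotide TGC>TGA lesion arises naturally); motif substitutions pick
the minimal-change codon for the target residue (ties lexicographic);
deletions and insertions act on root coordinates.  Events apply at their
branch's midpoint: noise runs for half the branch at the inherited rate, the
lesions land, and the second half runs at the post-event rate.  A
frame-disrupting indel or stop gain marks the lineage *lost*, multiplying all
subsequent branch lengths by `rate_multiplier_after_loss`.  Substitution
noise never creates indels, so the emitted alignment is exactly gapped and no
aligner (with its own error mode) sits between simulation and scanning.

**Planted lesion codons are frozen** against later substitution noise.  This
is a deliberate departure from pure neutrality: it keeps the truth ledger
well-defined (a planted stop that noise silently reverts would make "recall
of planted events" unmeasurable) at the cost of slightly understating
post-loss divergence at the handful of frozen sites.  Events later on a
root-to-leaf path overwrite earlier ones at the same codon in the *effective*
truth (the raw inherited list is kept separately), and codon lesions fully
erased by a later deletion are dropped from it.

**Functional constraint.**  Lineages that have not lost the gene can evolve
under a minimal purifying filter (`functional_constraint`): substitutions
creating an in-frame stop are rejected, and the start codon, terminal stop
and any declared constrained codons (the CC motif in the preset) are held
fixed.  Without it, a neutral simulation of realistic divergence sprinkles
stop codons into "functional" leaves, which no real intact gene under
purifying selection would fix — the constraint is what makes
intact-vs-pseudogene contrasts meaningful.  A loss lesion lifts the filter,
producing exactly the asymmetry the relative-rate test detects.  The bare
unconstrained model remains available and is what the JC69 closed-form check
and the rate-test calibration use, since those validate the neutral
machinery itself.

**Determinism.**  One `numpy` generator seeded from the run seed, consumed in
pre-order over branches (left to right as written in the newick string);
identical (config, seed) pairs give byte-identical FASTA.

### The Glires-like preset

The preset encodes the study conditions the package is demonstrated on: a
120-codon CDS (ATG … TAA, Cys-Cys motif at codons 53–54) at the root of a
13-record design — an outgroup, a seven-leaf "leporid-like" clade whose stem
carries the codon-53 stop gain, subclade deletions of 16 and 19 nt at
position 40 (the signal-peptide region), a cottontail-like sub-branch where a
Cys53→Lys substitution overwrites the stop and a 20-nt deletion lands at
position 170, and an intact "pika-like" clade with one heterozygous leaf
(second allele: the same codon-53 stop).  Post-loss branches run at twice the
base rate; root-to-leaf paths stay under 0.3 substitutions/site, a realistic
within-superorder divergence.  Lesion positions were chosen once so that no
two events on one path overlap each other or the motif.

What the preset does *not* emulate: alignment error (truth gaps are exact),
selection beyond the minimal constraint above (no dN/dS structure), indel
noise, base-composition bias, and rate variation across sites.  Passing
recovery tests therefore show the scanners are exact on correctly aligned
input, not that they are robust to misalignment.

## Calibration and problem sizes

* Rate-test level and power use 1,002-site JC69 triples on
  `((A:0.06,B:0.06):0.04,OUT:0.12)` with a rate shift on B's terminal branch,
  400 replicates per condition — enough for the 3-standard-error band around
  the nominal 0.05 level while keeping the whole acceptance run in seconds.
  The observed null rate sits slightly below 0.05 (typically 0.03–0.05): with
  nA + nB ≈ 100 the chi-square approximation to the underlying binomial is
  mildly conservative, as expected for discrete counts.
* The JC69 sanity check pools 20 replicates of a 10,002-site branch of length
  0.1 and compares against (3/4)(1 − e^(−4t/3)) at 3 standard errors of the
  pooled proportion.
* Oracle-equivalence tests draw 500 random triples (≤ 100 columns) and 200
  random gapped alignments (≤ 30 codons, substitutions + deletion runs +
  optionally-carried insertion blocks) and demand exact agreement with
  independent brute-force enumerators.

## Known limitations

* Reverse-strand coordinates, spliced-transcript↔genome liftover, and
  GenBank/EMBL flat files are out of scope; inputs are coding-strand FASTA.
* Ambiguity codes are treated as missing wherever a decision would otherwise
  be a guess (stop calling, site classification).
* The scanner reports lesions in the reference frame; it does not reconstruct
  when along a phylogeny each lesion arose, and no selection inference
  (dN/dS, branch tests) is attempted.
* `classify_sites` on a triple cannot distinguish the two deletion policies;
  batch workflows that want alignment-wide masking should pre-filter columns
  before calling.
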