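# Methods

This note documents the models, conventions and design choices behind
`castkit`, in the spirit of a methods section: what each stage assumes, which
parameters matter, and what the synthetic-data tests do and do not show.

## Coordinates and distance conventions

All internal coordinates are 0-based half-open; GFF3 and TSS tables are
1-based inclusive, converted in exactly one place (`seqio.to_one_based` /
`from_one_based`).  Distances between a feature boundary and a TSS follow one
convention throughout generator and detector: *the first nucleotide past the
boundary is position 1, and a distance of D means the TSS is the D-th
nucleotide*.  So "tracrRNA TSS 35 nt downstream of the cas12k stop" places
the TSS 35 positions past the last codon, and "413 nt upstream of the first
repeat" places it 413 positions past the array edge.  The regulator–cas12k
distance is the number of nucleotides strictly between the two corrected
start codons (82 in the default architecture).  Circular contigs carry a
flag but detection windows do not wrap.

## ORF catalogue and leaderless start correction (orfcat)

ORFs are called in six frames with start codons ATG/TTG/GTG and a 50-aa
minimum.  Per stop codon and frame the primary ORF takes the 5'-most start
(longest product); internal in-frame starts are retained as alternatives.
GTG/TTG-initiated proteins report Met as the first residue (initiator-fMet
convention), so a corrected protein equals the original from its second
residue onward.  Start correction re-initiates at the 5'-most in-frame start
whose first nucleotide coincides with a same-strand TSS; the coincidence
tolerance defaults to 0 nt (exact), configurable to ±1 for noisy TSS maps.
Correction never lengthens a protein and is idempotent.  Protein masses are
isotope-averaged (Biopython residue tables), reported in kDa to two
decimals.

## Homology classification (homsearch)

Family membership (Cas12k, TnsB, TnsC, TniQ, CvkR, Arc_1, Arc_2) is called
by optimal Smith–Waterman local alignment under BLOSUM62 with BLAST-style
affine gap costs (a gap of length L costs 11 + L).  Raw scores convert to
e-values with E = K·m·n·exp(−λS) using the published gapped BLOSUM62
calibration (λ = 0.267, K = 0.041); n is the total residue count of the
reference set.  The classification cutoff is E ≤ 10⁻²⁰.  Numeric
equivalence with NCBI BLAST is a non-goal (no heuristic seeding, no
composition-based statistics); what matters is the behaviour of the
threshold, which the tests pin against an independent brute-force
affine-gap DP.  Co-optimal traceback ties resolve to the aligner's first
reported path, which is deterministic across runs.

The shipped reference FASTA is synthetic (seeded random family prototypes
plus ~15%-diverged variants, lengths 639/560/430/220/185/72/70 aa).  This is
a deliberate stand-in: classification against it exercises the statistics,
but says nothing about real CAST protein diversity.

## Array, anchor and tracrRNA detection (crisprdet)

Array detection seeds on exact 13-mers recurring at 40–110-nt periods,
chains consecutive occurrences, and extends each aligned unit set
column-wise: a column belongs to the repeat while its majority base reaches
75% of units.  Units are trimmed until terminal spacers fall within 20–60 nt;
arrays need ≥ 3 repeats of 20–50 nt, each ≥ 80% identical to the
column-majority consensus (ties break to the lexicographically smallest
base).  Overlapping candidates deduplicate to the one with the most repeats,
then the longest span.  Because seeding requires an intact shared 13-mer in
*consecutive* units, a unit whose mutations destroy every shared 13-mer
drops out of the chain; this is the known cost of exact seeding.

Orientation: with a left-end position in context, the array reads toward the
LE; without context, the more conserved repeat half decides (3'-segment
conservation), and fully uniform repeats stay "unknown".

The anchor module is sought between array and LE: R* is the best match
(≥ 9/12 identities) of the consensus repeat's conserved 12-nt segment;
candidate anchor spacers of 15–19 nt (prior 17) sit directly LE-ward of R*
and must match a protospacer within 200 nt outside the LE with ≤ 1 mismatch
and an upstream GTN PAM read toward the LE.  Candidates rank by
(mismatches, |length − 17|, PAM-to-LE distance).  A PAM-to-LE distance
outside the observed 46–82 nt band is a warning, not a rejection (147-nt
outliers exist).

tracrRNA: a same-strand TSS 10–100 nt downstream of the cas12k stop defines
the locus (span TSS→array); otherwise the stop→array interval is reported as
a prediction.

## Promoters and the operator motif (motifkit)

`derive_palindromic_consensus` keeps positions of a site that agree with its
own reverse complement and masks the rest to N — the operation that turns
the protected promoter 15-mer into the degenerate palindromic operator.
IUPAC scanning is asymmetric by design: degeneracy lives in the motif; an
ambiguity code in the *sequence* matches only when its base set is contained
in the motif position's set, and a sequence N counts as a mismatch unless
explicitly allowed (conservative on gappy genomes).  Palindromic motifs
deduplicate plus/minus hits at the same window to the plus representative.
PWM information content is Σ p·log2(p/q) per column (uniform q by default).

σ70 element calling scores −10/−35 hexamer pairs against TATAAT/TTGACA with
conservation-weighted identity (the strongly conserved positions — T-A····T
of the −10, TTG of the −35 — weigh 1.0, the rest 0.5; 0–9 scale).  Flat
identity was rejected because a weakly matching but genuine −35 box
(e.g. TTGTAT, 3/6 identities) ties chance background matches, making the
documented 21-nt-spacer call nondeterministic; the weighted scheme separates
them while remaining far simpler than an energy model, which is out of
scope.  The −10 must end 4–9 nt upstream of the TSS, the spacer is 15–22 nt,
and spacers ≥ 19 nt raise the long-spacer flag characteristic of
MerR-regulated promoters.

## System assembly and ends (caster)

Assembly is permissive, validation explicit: the system object always
carries whatever was found, and rule violations (transposase order ≠
tnsB-tnsC-tniQ from the RE, transposases not facing away from the RE, array
not oriented toward the LE) append to `flags`.  A missing regulator is not a
violation.  Regulator candidates must be on the opposite strand with the
proximal gene edge within 3 kb of the cas12k start; gaps down to −60 nt are
tolerated because divergent genes can overlap before start correction.

End detection is a heuristic of this package's own design: the longest
inverted-repeat match (seed 10-mers, single-mismatch bridging, trimmed to
exact ends, ≥ 15 nt, ≥ 80% identity, ≤ 40 nt) between a 500-nt window
LE-ward of the array/anchor and a 500-nt window RE-ward of tnsB.  Absent a
TIR pair, ends fall back to the protospacer/tnsB flanks with
`confidence: low`, so downstream users can ignore them.

## Synthetic genomes (synth)

The generator emits the canonical architecture with these defaults, which
are the study conditions for all end-to-end tests: 37-nt repeats × 4, 35-nt
spacers, 17-nt anchor spacer, 12-nt R*, GTN PAM with PAM-to-LE drawn
uniformly from 46–82 nt, tracr TSS offset 35, TSS 413 nt from the array,
82-nt divergent gap, CvkR regulator (length uniform 139–185 aa; Arc 53–72),
2 cargo genes, 25-nt TIRs, 12-kb random background at 41% GC (typical
cyanobacterial), protein placeholders as 10%-diverged copies of the bundled
references, mutation rate 0.  The 12-kb background keeps a full annotation
under a second; the array/anchor false-positive property is additionally
exercised on 50-kb backgrounds.

Two constructions deserve note.  First, the 82-nt divergent gap is built
jointly: it hosts the cas12k −10/−35 boxes (21-nt spacer), a concrete
operator instance inside that spacer, and the annotated 5' extensions of
both leaderless genes (13 codons for cas12k, 20 for the regulator, bounded
by planted in-frame stops) — mirroring how the real promoter region overlaps
the over-annotated reading frames.  The tnsB promoter (17-nt spacer,
operator overlapping the TSS) is planted in the tnsB–RE gap.  Second,
*boundary guards*: random bases flanking each repeat unit and TIR are
resampled so no flanking alignment column reaches the detector's 75%
threshold and no TIR flank extends the inverted-repeat match.  This makes
the planted intervals the unique maximal extensions — without the guards,
"the" repeat boundary is genuinely ambiguous by a base whenever flanking
random bases happen to agree, and exact-recovery assertions would be
ill-posed.  Every gene except the two leaderless ones gets an in-frame stop
immediately upstream of its start codon so the annotated ORF is well
defined.

What passing tests show — and do not show.  Exact recovery (recall =
precision = 1.0 over 50 seeded genomes at mutation rate 0) demonstrates that
the detectors invert the generative architecture faithfully, with no
off-by-one drift anywhere in the coordinate plumbing.  It does not
demonstrate performance on real genomes: real repeats diverge non-uniformly,
real TIRs are imperfect, tRNA genes are structured rather than a fixed
token, real intergenic DNA is not i.i.d., and real protein families are far
more diverse than the synthetic references.  Point-mutation robustness is
exercised separately (`mutate_genome`) and degrades gracefully rather than
exactly.

## Numerical and degenerate-input choices

Ties everywhere resolve deterministically (documented per operation above).
Empty FASTA files, duplicate ids, 0-based TSS positions, out-of-bounds
features, non-ACGTN characters (mapped to N with a warning beyond the IUPAC
set → error), empty proteins and unknown residues all raise informative
errors.  Promoters clipped at contig ends warn; σ70 calling requires ≥ 43 nt
upstream of the TSS and reports a low-confidence flag below a weighted score
of 5.

## Known limitations

- Array seeding needs an intact 13-mer shared by consecutive units; heavily
  diverged single units can drop out of arrays.
- End detection trims TIRs to exact-match boundaries, so point mutations
  near TIR edges shorten the reported TIR (confidence stays informative).
- The tRNA "detector" recognises the package's own placeholder token only;
  real tRNA scanning (covariance models) is out of scope.
- σ70 calling is a simplified consensus scorer, not a promoter predictor.
- Real-data spot checks (published genome/protein accessions) require
  network access and user-supplied files; the CLI operates on any local
  FASTA/TSS input.
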