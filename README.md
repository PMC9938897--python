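# castkit

Annotation toolkit for cyanobacterial **type V-K CRISPR-associated transposon
(CAST)** loci.

Type V-K CASTs are Tn7-like mobile elements that carry a nuclease-dead
CRISPR effector (Cas12k) to guide their own transposition.  The canonical
locus reads, from left end (LE) to right end (RE): a tRNA gene pointing into
the transposon, the LE terminal inverted repeat, a truncated repeat R*
(~12 nt) with a truncated **anchor spacer** (~17 nt) matching an **anchor
protospacer** just outside the LE (upstream GTN PAM, PAM-to-LE distance
46–82 nt), the CRISPR array (37-nt repeats, reverse orientation), a tracrRNA
whose TSS lies 35 nt downstream of the *cas12k* stop codon and 413 nt
upstream of the first repeat, the divergent *cvkR*/*cas12k* pair — both
translated from **leaderless mRNAs** whose TSS coincides with the start
codon — cargo genes, and *tnsB–tnsC–tniQ* reading away from the RE.  The
associated regulator is a MerR-family repressor (CvkR, 139–185 aa) or one of
two small Arc/ribbon-helix-helix repressors (Arc_1/Arc_2, 53–72 aa), encoded
upstream of and divergent from *cas12k*.  CvkR binds a degenerate 15-nt
palindromic operator, 5'-AnnACATnATGTnnT-3', obtained by masking the
protected promoter sequence ATAACATTATGTGTT against its reverse complement.

`castkit` provides, for people studying or engineering these systems:

- **orfcat** — six-frame ORF catalogue (ATG/TTG/GTG starts, ≥ 50 aa),
  TSS-based leaderless start correction, average protein mass;
- **homsearch** — Smith–Waterman local alignment (affine gaps, BLOSUM62)
  with Karlin–Altschul e-values, `E = K·m·n·e^(−λS)`, thresholded at
  10⁻²⁰ for family classification against bundled reference sets;
- **crisprdet** — k-mer-seeded repeat-spacer array detection, anchor module
  (R* + anchor spacer + protospacer + GTN PAM) recovery, tracrRNA
  localisation;
- **motifkit** — palindromic consensus derivation, IUPAC/PWM scanning,
  σ70 −10/−35 calling with the long-spacer (MerR-context) flag;
- **caster** — assembly into validated `CastSystem` objects with
  terminal-inverted-repeat end detection and JSON/GFF3 reports;
- **synth** — a seeded synthetic-genome generator with complete ground
  truth, so the entire pipeline is testable without downloads.

The bundled protein reference sets are deterministic *synthetic* stand-ins
(random sequences of realistic family lengths plus diverged variants); they
exercise the classification machinery and anchor the generator, but are not
biological sequences.

## Worked example

Simulate a CAST genome with ground truth, then annotate it:

```sh
castkit simulate --seed 1 --out demo
# wrote demo/genome.fa (20013 nt) + truth
castkit annotate demo/genome.fa --tss demo/tss.tsv -o demo-out
# 1 system(s) -> demo-out/systems.json
```

`demo-out/systems.json` (coordinates 0-based half-open) contains, for this
seed:

| quantity | value | meaning |
|---|---|---|
| `le`, `re` | 6000, 14013 | transposon ends from the paired 25-nt TIRs (`ends_confidence: high`) |
| `array` | 6134–6387, 4 repeats, `-` | repeat-spacer array read toward the LE |
| `anchor.pam`, `pam_to_le_distance` | `GTG`, 63 | GTN PAM read toward the LE, inside the observed 46–82 nt band |
| `tracr.distance_from_cas12k_stop` | 35 | tracrRNA TSS 35 nt downstream of the *cas12k* stop |
| `cas12k` | 6834–8754 (−), 639 aa | leaderless-corrected effector gene |
| `regulator` | `CvkR`, 82 nt from *cas12k*, `length_ok: true` | divergent MerR-family repressor; 82 nt between the corrected start codons |
| `flags` | `[]` | no architecture-rule violations |

Motif and mass utilities:

```sh
castkit motif derive ATAACATTATGTGTT   # -> ANNACATNATGTNNT
castkit mass GGGGG                     # -> 0.30  (kDa)
```

`castkit correct-starts genome.fa --tss tss.tsv` reports every ORF whose
mRNA TSS coincides with an in-frame start codon (leaderless candidates), and
`castkit motif scan` writes BED-like operator hits.

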