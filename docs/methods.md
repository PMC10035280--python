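# Methods

## Matching model

A primer is a 5'→3' IUPAC string; canonicalization uppercases, maps RNA
`U`→`T` and inosine `I`→`N` (inosine pairs broadly, and `N` is the most
permissive IUPAC stand-in; the transform is lossy and is applied once, at
load time). Primers with byte-identical canonical sequences are merged,
the first-seen identifier acting as representative, so deduplication is
reproducible under input order.

Matching is zero-mismatch and asymmetric: a primer letter `p` matches a
sequence letter `s` iff `s` is a concrete base (A/C/G/T) contained in
`p`'s IUPAC set. Ambiguity codes in the *database* (`N` etc.) and gap
characters never satisfy a primer position — the conservative reading of
"no mismatches allowed", since an `N` in a deposit is missing evidence,
not a wildcard. Databases store sense-strand sequences; reverse primers
are reverse-complemented once (IUPAC-aware) and searched along the sense
strand with the same single code path as forward primers. All
(overlapping) occurrences are reported via a regex of character classes
under a look-ahead group; match coordinates are 1-based positions in the
reference frame, where leading alignment gaps occupy positions.

The engine has an intentionally naive counterpart (`oracle.py`): expand
the degenerate primer into every concrete sequence and compare each
against every window. Engine and oracle share no code — separate IUPAC
and complement tables — so their agreement, tested across seeded random
fixtures and a property-based sweep, is a genuine dual-route check.

## Coverage ratios

VC = 100 × matched variants / total variants; SC = 100 × species with at
least one matched variant / total species. Raw fractions are kept on the
result object; reported percentages are rounded to exactly two decimals,
halves away from zero. The printed values of interest here are
insensitive to half-even vs half-up, but one fixed rule is required for
byte-stable outputs. Candidate selection (SC ≥ 75.00%, inclusive)
compares the rounded value, matching how such thresholds are applied to
printed two-decimal percentages; specificity classification instead uses
the exact species count (SC of 0.00% means literally zero species
covered).

## Position statistics and region assignment

For every match the first/last primer-nucleotide positions follow primer
orientation: a reverse primer's first (5') base sits at the *high* sense
coordinate of its footprint, its last (3') base at the low one, so a
pair's span runs from the forward primer's first position to the reverse
primer's last. Means and modes are taken over the multiset of positions
across all matches; a multi-modal population takes the mode closest to
the mean, and a residual equidistant tie goes to the smaller position.
Primers with zero matches get undefined statistics (not an error) and are
excluded from pairing with a log entry.

The 16S map is an editable TSV tiling positions 1–1542 with 10 conserved
(C1–C10) and 9 hypervariable (V1–V9) regions; the bundled boundaries are
the coordinates in common use for the *E. coli* reference and are
configuration, not ground truth. A primer's region number is the
hypervariable region containing its mode position or, when the mode falls
in a conserved flank, the next hypervariable region *downstream* — for
both forward and reverse primers, clamped to V9 past the last variable
region. The downstream rule is forced by how universal primer pairs are
conventionally named: a forward primer annealing in the conserved stretch
before V3 (say, position 342) and a reverse primer annealing in the flank
after it (position 529, in C4) advertise a "3-4" amplicon, which only the
downstream rule reproduces on both sides; assigning the reverse primer
its upstream neighbour would collapse that label to "3-3". Positions
beyond 1542 but within the 2000-position frame still count for coverage
but render as `undefined` in region labels, with the reason logged. Pair
labels join the two sides ("3-4") and collapse when equal ("3").

## Pair admission and evaluation

Candidates are split by direction; the F × R Cartesian product is
filtered by (1) mean F-first < mean R-last and (2) a distance of ≥ 100 nt
between the means. Mean amplicon length is inclusive
(`mean_r_last − mean_f_first + 1`); categories are applied to the
rounded-to-integer length with edges 100/300/600 (so 300 and 301 fall in
different categories). Enumeration runs per domain with that domain's
position statistics, and pairs admitted in both domains are merged by
(forward, reverse) identifier and evaluated once.

Pair coverage demands both primers hit the *same* variant with
amplifiable geometry (an F site starting before an R site's 3' end);
amplification physically requires co-occurrence on one molecule, so the
per-species-anywhere alternative was rejected as biologically incoherent.
The longest amplifiable product per variant is recorded for diagnostics.
Specificity: bacteria-specific ⇔ archaeal species count 0 and bacterial
count > 0; symmetric for archaea-specific; both positive → non-specific;
both zero → dead.

## Reference frame and normalization

Raw sequences are placed in a 1-based frame (position 1 = first reference
nucleotide, J01859.1 numbering; frame limit 2000) by pairwise alignment
to a single reference with Biopython's `PairwiseAligner` (match +1,
mismatch −1, gap open −5, gap extend −1). Local mode realises the
free-end-gap intent exactly — truncated ends, 5'/3' extensions and
duplicated tails hang off the alignment unpenalised, whereas global mode
is forced to stack simultaneous query and reference overhangs against
each other. A per-record pairwise alignment replaces any multi-sequence
step because the only purpose is to impose reference coordinates on each
record independently.

After alignment: bases mapping below position 1 are trimmed; the aligned
sequence is the leading-gap run followed by the record's own bases with
all alignment-internal gaps removed (so downstream coordinates are
leading-offset plus base count, drifting past indels exactly as the
stored databases do); positions above 2000 are truncated. Records are
excluded, never silently altered, when identity over the aligned span is
< 60% or when the alignment covers < 50% of the record (both land in the
QC report as `unalignable`); records whose length exceeds 120% of the
reference span they align to are flagged `redundant` for human review but
are not auto-deleted, because no principled deletion criterion exists for
duplicated segments. Normalization is idempotent, and leading offsets of
exact reference subsequences are recovered exactly.

The bundled reference is a deterministic **synthetic** 1542-nt stand-in
(`data/reference_16s_synthetic.fasta`, ~54% GC); any 1542-nt replacement
— in particular the real *E. coli* J01859.1 16S sequence — can be
supplied via configuration. Nothing in the machinery depends on which
reference anchors the frame.

## Synthetic fixtures

The generator emulates the load-bearing features of real 16S databases:
species with one-to-several variants (species ~5% diverged from the
reference, variants ~0.5% from their species), exact implanted annealing
sites (a fresh concrete realization of the degenerate footprint per
variant), variants truncated at the 5'/3' ends so VC < SC, leading-gap
frame padding, and sparse `N`s outside implanted windows. Identical seed
and spec give byte-identical output. Truth tables are computed by the
enumeration oracle, never the engine.

It does **not** emulate phylogenetic covariance between species, chimeras,
indel-rich variants, or near-miss primer sites (single-mismatch decoys),
so passing tests demonstrate correctness of the matching/accounting
machinery, not field performance of any particular primer on real data.

The acceptance study (`scripts/acceptance.py`) uses 60 bacterial and 16
archaeal species, 1–5 variants each, full 1542-position sequences, 20%
(bacteria) / 10% (archaea) of variants 5'-truncated by 50 nt, 0.5%
ambiguity, and a six-primer panel (after removing two deliberate
duplicates) with site fractions between 0.7 and 1.0 — sizes chosen so the
whole study, including the oracle cross-check, completes in about one
second while exercising every pipeline stage and all three amplicon
categories.

## Degenerate inputs and edge cases

Empty databases raise; primers with no matches yield undefined position
statistics and drop out of pairing; fully-trimmed records are dropped
with a QC entry; a fixture site that does not fit its sequence length is
a validation error. Sorting everywhere is lexicographic by identifier, so
every output is invariant to input order and reruns are byte-identical.

## Known limitations

- Zero-mismatch only: no melting-temperature model, no mismatch-tolerant
  coverage curves, no primer design.
- Region labels inherit whatever boundary table is active; they are
  reporting conveniences, not coordinates-free truths.
- The same-variant pair rule is the strict reading; databases whose
  variants are heavily fragmented may under-report pair coverage relative
  to a per-species interpretation.
- The redundancy flag is a heuristic (length ratio > 1.2) and is advisory.
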