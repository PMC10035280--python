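# primercover

In silico coverage evaluation of degenerate 16S rRNA gene primers and
primer pairs against species-annotated, reference-aligned sequence
databases — for microbiome researchers choosing amplicon primers for a
specific ecosystem (e.g. the oral cavity) rather than trusting coverage
numbers computed on broad, taxonomically noisy references.

## What it computes

A sequence variant (ASV) is **covered** by a primer when every primer
nucleotide matches it exactly — IUPAC degeneracy expands the primer
(R = A/G, …), mismatches are never allowed, and ambiguous bases or
alignment gaps in the database never satisfy a primer position. From the
zero-mismatch matches, two coverage ratios are reported per database:

- **VC (variant-level coverage)** = 100 × (variants matched) / (variants
  in the database);
- **SC (species-level coverage)** = 100 × (species with ≥ 1 matched
  variant) / (species in the database).

SC exists because public 16S deposits frequently miss the first/last bases
of the gene: a primer that targets a sequence end can miss a truncated
variant yet still amplify the species, so SC is robust where VC is not.

Primer pairs are built from all forward × reverse combinations of
candidates (SC ≥ 75.00%), admitted when the mean position of the forward
primer's first nucleotide precedes the mean position of the reverse
primer's last nucleotide by at least 100 nt. Each pair gets:

- a **mean amplicon length** (inclusive; positions 342–529 span 188 nt)
  and a length category — 100–300, 301–600, > 600 bp — matching
  short-read, long-read and full-length sequencing regimes;
- a **gene region label** ("3-4", "5-9", …) on the *E. coli* 16S map of
  conserved (C1–C10) and hypervariable (V1–V9) regions;
- pair coverage (both primers must hit the *same* variant with
  amplifiable geometry), and a **specificity class**: bacteria-specific
  (archaeal SC literally 0), archaea-specific, non-specific, or dead;
- a list of the species it does **not** cover.

All sequences live in a 1-based reference coordinate frame (position 1 =
first nucleotide of the *E. coli* 16S rRNA gene, J01859.1 numbering;
positions beyond 2000 trimmed). `primercover build-db` places raw FASTA
into this frame by local pairwise alignment. The bundled reference is a
synthetic 1542-nt stand-in; pass a real J01859.1 FASTA via `--reference`
for genuine *E. coli* framing.

## Worked example

```python
from primercover import DomainSpec, FixtureSpec, ImplantSite, generate_fixture, evaluate

spec = FixtureSpec(
    seed=11,
    primers=[
        ("OP_F001", "F", "CCTACGGGNGGCWGCAG"),
        ("OP_R001", "R", "GGACTACNVGGGTWTCTAAT"),
    ],
    bacteria=DomainSpec(
        n_species=12, variants_per_species=(2, 4), sequence_length=1542,
        sites=[
            ImplantSite("OP_F001", fraction_species=1.0, fraction_variants=1.0, position=342),
            ImplantSite("OP_R001", fraction_species=0.9, fraction_variants=1.0, position=785),
        ],
        truncation=0.25, truncation_bases=400,  # 5' clips erase the F site in some variants
    ),
    archaea=DomainSpec(n_species=4, sequence_length=1542),
)
fixture = generate_fixture(spec)
result = evaluate(fixture.primers, fixture.bacteria, fixture.archaea)
```

prints (via the snippet in `scripts/` style reporting):

```
OP_F001  bacterial VC 77.14%  SC 100.00%
OP_F001  positions: mean_first 342.0  mode_first 342
OP_F001-OP_R001: region 3-5, bacterial SC 91.67% (11/12 species), mean length 444 nt (category 2), bacteria_specific
```

Reading it: every species carries the forward site, but 5'-truncated
variants lost it, so VC (77.14%) sits below SC (100.00%) — exactly the
effect SC was defined to absorb. The pair covers 11 of 12 species (one
species lacks the reverse site), yields a ~444 nt product spanning
regions 3–5, and is bacteria-specific because its archaeal SC is 0.00%.

The same pipeline is available from the shell:

```
primercover make-fixture --spec spec.yaml --out fixtures/
primercover build-db     --in raw.fasta --domain bacteria --out db.fasta
primercover eval-primers --primers primers.tsv --bacteria bac.fasta --archaea arc.fasta --out report/
primercover eval-pairs   --primers primers.tsv --bacteria bac.fasta --archaea arc.fasta --out report/
primercover report       --pairs report/pairs.tsv --domain bacteria --min-sc 90
```

Inputs: primers as TSV (`primer_id  direction  sequence  [source]`);
databases as FASTA whose headers carry variant id, accession, species id
and a seven-rank taxonomy. Outputs are TSV plus a `manifest.json` with
input checksums and a `run.log` with per-stage counts.

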