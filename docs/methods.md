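# Methods

## Scope and model

`ampliguide` designs 20-nt Cas9 target sites that distinguish a host's 18S
rRNA V4 amplicon from protistan and fungal reference amplicons, and
predicts how well two rounds of Cas9 cutting plus SPRI size selection
deplete host molecules from an amplicon library. Everything operates on
the amplicon a primer pair would produce, because only a cut *between* the
two primer-extension start points abolishes amplification.

### In-silico PCR

A primer binds where every base of the subject falls inside the primer's
IUPAC code set; degeneracy is therefore free, and the default mismatch
tolerance is 0 (exact degenerate matching is the reproducible in-silico
proxy for a real PCR; the tolerance is exposed for sensitivity analysis).
Ambiguity codes in the *subject* never match — missing data is not
evidence of binding. Each forward-primer hit is paired with the nearest
downstream reverse-primer footprint whose product length falls inside the
length window (the innermost product, which dominates PCR when several
pairings exist); both template orientations are scanned and products are
returned in forward-primer orientation, which makes every downstream step
strand-closed. The length window defaults to [50, 2000] bp so the same
machinery serves arbitrary genes; with the default V4 pair, real products
land around 380–450 bp. References where the pair matches more than once
simply yield several amplicons.

### Guide enumeration and specificity

A Cas9-compatible site is a 20-mer whose 3′ neighbour is an NGG PAM, on
either strand; the full 23-nt window must sit inside the search region,
and windows containing ambiguity codes are skipped (an ambiguous guide is
not synthesizable; ambiguity in references is missing data, not biology).
The default search region is the amplicon *interior* (primer footprints
excluded): footprint sequence is near-universal and could never be
specific, and a cut inside a footprint would not prevent re-amplification.
`region="full"` is available for parity checks.

Specificity screening asks whether the 20-mer occurs — exact match, either
strand — anywhere in the microeukaryote side of the reference. Off-target
PAM context is deliberately ignored: requiring a PAM in the off-target
would only ever *promote* guides, and cutting a protist sequence is the
failure mode the screen exists to prevent, so the PAM-free criterion is
the conservative direction. A `max_mismatch` of up to 3 switches the
screen to an exhaustive Hamming scan. The screening scope defaults to the
extracted microeukaryote amplicons (the region the method sequences);
`screen_scope="full_sequence"` indexes whole reference sequences instead,
relevant because the first cutting round acts on genomic DNA.

Screening uses an exact 20-mer hash index over both strands of every
indexed sequence; a substring scan over the same sequences is kept as the
independent oracle in the test suite, never as the implementation's own
path.

Surviving sites are deduplicated by protospacer (accessions aggregated)
and ranked by: fewest microeukaryote taxa with a 1-mismatch near-hit, GC
fraction closest to 0.5, 5′-most position, then the protospacer string as
a final deterministic tie-break. The ranking is a stable convenience
ordering, not a cutting-activity model — no Doench-style efficiency
scoring is attempted.

### sgRNA template oligos

Templates are promoter + [G] + protospacer + 14-nt scaffold overlap. The
promoter and overlap strings are configuration (`data/primers.yaml`),
defaulting to the published single-tube synthesis-kit scheme; a leading G
is prepended only when the scheme requires one for T7 initiation and the
protospacer lacks it, and the flag recording that is part of the output.

### Per-taxon database

The database is keyed by species name (the deepest taxonomy label), with
accession provenance per entry: multiple sequence variants of a species
are aggregated by name, and a protospacer found in several species is
listed under each — breadth summaries need the cross-listing. Coverage
statistics report uniqueness in both senses (distinct specific
protospacers, and specific species–site pairs) since the two counts
diverge exactly when guides are broad. Species whose records the primers
do not amplify are recorded with an explicit no-amplicon flag rather than
dropped. Serialization is a TSV (one row per guide) plus a JSON sidecar
carrying the design parameters, species list, no-amplicon set and a schema
version; the round-trip is lossless and version-checked.

### Depletion simulation

Each community member's template is amplified in silico; members the
primers do not amplify are excluded with a warning. A member is cuttable
iff any guide 20-mer occurs, either strand, in its amplicon. Per round,
every intact cuttable molecule is cut independently with probability
`efficiency`; a single cut separates the two primer footprints, so cut
molecules are unamplifiable and are removed deterministically at size
selection. Molecules without a guide match are never touched, and PCR
between rounds is treated as composition-preserving — amplification bias
is explicitly out of model. The observed residual host fraction is
reported next to its closed form `(1 − efficiency)^rounds`.

Parameter defaults: `efficiency = 0.97` per round, calibrated so a single
round leaves ~3% of host amplicons intact, the midpoint of the 0.6–3.5%
single-round residual range reported for this kind of assay (a
calibration, not ground truth); `rounds = 2`; `size_threshold = 300` bp,
the cutoff a 0.8:1 bead:DNA SPRI ratio imposes; `cut_offset = 3` nt 5′ of
the PAM, the standard SpCas9 blunt-cut position (the offset is
configurable; nothing downstream depends on it beyond fragment
coordinates). A single shared efficiency covers both rounds; genomic-DNA
and amplicon cutting could in principle differ, and two efficiencies can
be configured by running the rounds separately.

### Synthetic references

The generator emits seeded host and microeukaryote records that all
amplify exactly once with the configured primer pair (degenerate codes are
concretized once per reference, seeded). Interiors are built over a
PAM-free backbone alphabet — strings over {A, C, T} with no CC
dinucleotide contain no NGG on either strand — so the *only*
Cas9-compatible windows in a synthetic interior are the planted ones:
`n_specific_per_host` protospacer+TGG blocks absent from every micro
record, and `n_shared` blocks whose 20-mer is copied into at least one
micro record. That construction makes the truth table exact (recovery
tests can demand set equality, no false guide, no miss) and is verified at
generation time by an independent substring scan. Identical seeds give
byte-identical output.

Default generator conditions, used by the test suite and the acceptance
script: 5 host taxa, 20 microeukaryote records, 400-nt records,
2 specific + 2 shared sites per host — small enough for exhaustive oracles
to run in seconds, large enough that every pipeline stage (partitioning,
extraction, enumeration, screening, dedup, ranking, database, simulation)
is exercised. What the generator does *not* emulate: real 18S sequence
composition and conservation structure, length variation of the V4 region
across clades, shared homologous backbone between host and
microeukaryotes (real amplicons are ~90% identical; synthetic interiors
share only the planted k-mers), sequencing error, and incomplete reference
coverage. Passing the recovery tests therefore demonstrates the
correctness of the algorithmic pipeline, not the biological breadth of any
particular reference release — counts per taxon on a real reference depend
entirely on that reference's contents.

## Numerical and degenerate-input choices

* Simulation uses `numpy.random.default_rng(seed)` throughout; identical
  seeds give identical reports, and per-molecule cutting is drawn as one
  binomial per taxon per round.
* Closed-form agreement is asserted as the mean of 20 replicates at 10⁵
  host molecules lying within 3 binomial standard errors of
  `(1 − e)²` — a bound derived from the model, not tuned.
* Empty outcomes are states, not errors: no primer pairing → empty
  amplicon list; zero specific sites → empty design (with a warning);
  species absent from the database is distinguished from species present
  with zero sites. The only hard designer error is a primer pair that
  amplifies nothing at all.
* Site enumeration and ranking are fully deterministic; ties cannot
  reorder across runs.

## Known limitations

* Exact-match (optionally low-Hamming) screening ignores RNA:DNA wobble
  tolerance and bulges, so real off-target cutting can exceed the
  screen's prediction; conversely requiring a perfect 20/20 host match
  ignores that Cas9 tolerates distal mismatches, so host variants may
  escape.
* No guide-activity model: all specific sites are treated as equally
  cleavable, while measured efficiencies vary severalfold between sites.
* The depletion model has no PCR bias, no partial cutting products
  surviving re-amplification, and no fragment re-annealing; its residual
  fraction is the Bernoulli ideal of the workflow.
* Taxon identity is the species-name string of the reference taxonomy;
  synonyms or inconsistent labels in a real reference split or merge taxa
  accordingly.
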