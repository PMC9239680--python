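# Methods

This note records the models, rules, parameters and numerical conventions
behind donorforge, and what its synthetic test data does and does not show.

## Coordinates and gene models

Internally every interval is 0-based, half-open, on the forward genomic
strand; GFF3 is converted from/to its 1-based closed dialect only at the file
boundary.  Design logic reasons in *gene orientation* (5′/3′ relative to the
transcribed strand) while storing genomic coordinates.  A cut site is a
*boundary* coordinate (between two bases), which makes "the window of an
N-nt intron after a b-nt buffer on each side" exactly `N − 2b` cut positions
wide with no off-by-one ambiguity.

An intron is classified **coding** when the CDS reaches both the upstream
exon's donor end and the downstream exon's acceptor start; introns wholly 5′
(3′) of the CDS are 5′UTR (3′UTR) introns; anything else is `mixed` and only
arises from inconsistent annotation.  Intron **phase** is the cumulative
upstream CDS length mod 3.  A **shared** intron has identical genomic
coordinates, and is coding, in *every* annotated isoform — the strictest
reading of "shared among all isoforms"; overlap-based relaxations are not
implemented.  Transcripts whose CDS falls outside their exons are skipped
with a warning rather than aborting a whole-genome survey, because real
annotations contain such records.

## Suitability and strategy routing

A gene is suitable for the intronic artificial exon iff it has a shared
coding intron strictly longer than `min_suitable_intron_length` (default
100 nt; the bound is exclusive) that still contains at least one cut position
after subtracting `splice_buffer` (default 30 nt, configurable — the source
method requires only "sufficient distance" from both splice sites) from each
side.  The survey reports the length criterion and the window criterion
separately, uses the longest-isoform CDS length as the per-gene CDS
statistic, counts a gene as protein-coding iff at least one transcript has a
CDS, and orders rows by gene id so reruns are byte-identical.

Routing order for a gene: intronic T2A-GAL4 if suitable and a specific guide
exists; else Kozak replacement if both flanking guides are findable (any
tier); else the splice-acceptor Kozak cassette if a shared 5′UTR intron
>100 nt exists; else the two-cut T2A-GAL4 variant if a shared coding intron of
at least 23 nt (one protospacer+PAM) is present along with a 3′ guide; else
undesignable — a valid, reported outcome.  The two-cut variant requires the
intron cut within the 20 acceptor-proximal positions of the intron
(configurable), excluding a cut at the junction itself.  Genes whose isoforms
have distinct transcription starts are handled uniformly by these rules; the
reference transcript for UTR coordinates is the one with the 5′-most TSS
(ties broken by transcript id).

## Guide selection

SpCas9 geometry is fixed: 20-nt protospacer, NGG PAM, blunt cut 3 bp 5′ of
the PAM.  Enumeration returns all sites on both strands whose cut falls in
the query interval, ordered by (cut, strand).

The specificity screen is a deliberately simple, fully specified stand-in for
web off-target finders (whose exact versions and settings are unspecifiable):
a guide fails if any other genomic site has (a) ≤3 mismatches over the 20-mer
next to an NGG or NAG PAM, or (b) a perfect 12-nt PAM-proximal seed next to
an NGG.  All thresholds are configurable.  The scan is exhaustive (every
window of every contig, both strands, vectorized), which keeps it exactly
equal to the brute-force oracle used in tests.

Placement rules: intronic guides maximize the smaller of the distances to
donor and acceptor; 5′ guides cut in the 5′UTR strictly upstream of the ATG,
minimizing the distance to the start codon, with a promoter fallback
(default 500 nt upstream of the TSS, closest-to-TSS wins) that extends the 5′
homology arm to the TSS and requires a PAM-kill edit; 3′ guides cut in the
3′UTR minimizing distance to the stop codon (the method itself imposes no
preference there, so the stop-proximal choice is documented as ours), with a
CDS-near-stop fallback.  Ties always break to the smaller genomic cut
coordinate, then the + strand, so selection is reproducible; re-running after
masking the winner yields the documented next-best site.

## Donor construction

Homology arms default to 200 nt (100–200 accepted; a warning is appropriate
below 150 — enforced range only).  Arms are verbatim genomic sequence except
for recorded single-base edits that destroy a selected guide's full target
(protospacer+PAM) when it survives intact inside an arm: in non-coding
sequence the PAM's second G becomes C; in retained coding sequence a
synonymous substitution inside the 12-nt seed is chosen instead, scanning
PAM-proximal first.  Each edit is recorded with offset, reference and
alternate base, and reason.

The 30-nt cloning site carries two outward-cutting type-IIS sites (BbsI
`GAAGAC(2/6)` or BsaI `GGTCTC(1/5)`), releasing 4-nt overhangs that match the
cassette carrier.  For the Kozak cassette the left overhang *is* the CAAA
Kozak sequence, which guarantees the assembled junction reads
`...arm + CAAA + ATG` by construction.  T2A-GAL4 phase-`p` cassettes pad
`(3 − p) mod 3` bases between the splice acceptor and the 2A codons so the
cassette ORF continues the interrupted reading frame (phases 0/1/2 carry
0/2/1 pad bases — the frame arithmetic, not a 0/1/2 literal).

The vendor's assembly of the synthesized fragment into the backbone is
modeled as seamless replacement of the 6-nt EcoRV marker (the vendor uses
Gibson assembly; EcoRV only marks the insertion point), which keeps the
backbone's split tRNA contiguous with the fragment's completing half.  The
tRNA split point is a config offset, defaulting to the midpoint, since only
the placement — not the split — is externally constrained.

Synthesis feasibility flags undesigned BbsI/BsaI/EcoRV sites (both
orientations; fatal), homopolymers >9 nt and 100-nt windows with GC outside
25–70% (vendor-typical, configurable; reported, not fatal).

## Assembly, linearization and HDR simulation

Golden Gate is simulated by cutting both circles at every recognition site,
discarding any fragment that still carries a recognition site (it would be
re-cut), and enumerating circular ligations by overhang complementarity; the
unique circle containing material from both inputs is the product, and
anything else — zero products, several, only re-circularized inputs — is an
error listing what was found.  Plasmid identity is rotation-invariant
(Booth's minimal rotation; orientation is normalized at construction to the
cassette strand).

Linearization cuts the assembled donor at every target of the
backbone-specific guide after verifying, under the same off-target policy,
that the guide has *zero* genomic targets.  Cas9 leaves ≤6-nt vector tails
on the released fragment; since HDR resects them, the report distinguishes
the raw released fragment from the exact `arm5 + cassette + arm3` payload it
contains, and downstream prediction uses the payload.

HDR is modeled as perfect, seamless, arm-mediated repair (no indels, no NHEJ
branch): the genomic span between the arm boundaries is replaced by the
payload, after verifying that each arm's reference sequence still matches the
locus (re-applying a design to an already-edited locus fails) and occurs
exactly once in the genome.

Product prediction: T2A designs yield the truncated native protein ending in
the 2A `...NPG` and `P`+GAL4 — the 2A event is modeled as a ribosomal skip
between NPG|P; Kozak designs yield GAL4 initiated at the CAAA-ATG junction
(possible reinitiation downstream of the cassette polyA is not modeled).
A stop codon upstream of the cassette ORF end on a phase-matched design is a
frame-inconsistency error, never silently reported as a product.  Molecular
weights use average (not monoisotopic) residue masses plus one water,
reported in kDa to one decimal.

Protein-trap donors replace the coding region with an in-frame sfGFP fusion
(N-terminal: after the ATG; C-terminal: before the stop; internal: after
residue k, rejecting indices that would require splitting a codon across a
splice junction) and place a PiggyBac-IR–3XP3-DsRed–PiggyBac-IR marker at the
first TTAA after the 3′UTR end, duplicating the TTAA on both flanks so
transposase excision is scarless.

## Validation reagents

Flank PCR: for each side, the search walks outward from the homology-arm
boundary (window 600 nt) for an 18–25-nt gene-specific primer with Tm
58–62 °C (SantaLucia nearest-neighbor, 50 mM monovalent salt, 250 nM oligo —
the wet protocol specifies only a 58 °C annealing temperature, so these are
explicit parameters), GC 35–65%, and a 3′ self-complementary run ≤4 nt,
keeping the first qualifying primer whose amplicon to the cassette primer is
200–800 nt.  Cassette primers default to 20-mers 40 nt inside each cassette
end, pointing outward; production primer sequences are config entries.

smiFISH: 20-nt antisense probes greedily tiled 5′→3′ with ≥2-nt gaps,
per-probe GC 30–70% and homopolymers ≤5; the shared 28-nt flap is prepended,
giving 48-mers, and the X-flap (the flap's reverse complement) carries the
dye.  The commercial probe designer's scoring is not reproduced — only the
48-mer length is externally constrained, so this tiling is a documented
stand-in; short mRNAs simply return fewer probes.

## Synthetic test data

The fixture generator emits genomes in which every design decision has a
planted, known answer: multi-isoform genes with shared or isoform-specific
coding introns of chosen lengths and phases, 5′UTR introns, UTRs sampled
around 214/224 nt medians (fly-like defaults), unique guide sites written
into exactly the regions each placement rule scans (competing sites and
stray enzyme sites are removed by a deterministic, stop-codon-safe
sanitizer), optional mismatch decoys for the off-target screen, and a
self-scan guaranteeing planted guides are genome-unique and the
linearization guide is genome-absent.  Background sequence is i.i.d. uniform
ACGT with no repeat families, which keeps the exhaustive off-target oracle
exact and fast.

What passing tests show: the rules, simulations and oracles agree exactly on
genomes where the truth is known by construction.  What they do not show:
behavior on repetitive or biased real genomes (off-target screening there is
as good as the mismatch/seed model), annotation pathologies beyond the
skip-with-warning path, or any wet-lab efficiency — cutting, repair and
expression outcomes are out of scope.  Toy parts (GAL4 and marker stand-ins
of a few hundred nt, shortened attP/PiggyBac ends, a synthetic
back-translation of sfGFP) are deliberately non-functional; production
sequences drop into the parts library from YAML.

Problem sizes used by the shipped tests and the acceptance script: fixture
genomes of 6–50 genes (≈25–130 kb), chosen so every oracle remains exhaustive;
the acceptance script's tagged-protein example uses a 494-aa surrogate at the
WDR37 ortholog-family protein length, since no real protein sequence ships
with the package.

## Known limitations

- One genome-wide off-target policy; no efficiency scoring (selection is
  purely positional, as in the source method).
- No RMCE product design beyond annotating attP/FRT sites; no repair-outcome
  distributions; no GTF input.
- The second linearization-guide target on the gRNA backbones is placed
  immediately downstream of the insertion point; its exact position in the
  production vectors is supplement-dependent and configurable.
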