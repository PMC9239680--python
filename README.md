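# donorforge

Design automation for CRISPR knock-in homology donors with short,
commercially synthesizable homology arms, for Drosophila-style gene models
(any genome FASTA + GFF3 with similar gene structure works).

## The problem

Gene trapping by homologous recombination inserts a swappable integration
cassette (SIC) — e.g. an artificial exon carrying
`attP-FRT-SA-T2A-GAL4-polyA-3XP3-EGFP-polyA-FRT-attP` — into a coding intron,
truncating the native polypeptide at the viral 2A peptide and reinitiating
translation of GAL4 in the gene's own expression pattern.  This only works
when the gene has a coding intron, shared by every annotated isoform, that is
strictly longer than 100 nt (so an sgRNA can cut at a safe distance from both
splice sites).  Genes that fail this test — more than half of a typical fly
annotation — are instead handled by *coding-region replacement*: two cuts, one
in the 5′UTR as close as possible to the start codon and one in the 3′UTR,
replace the gene body with a `CAAA-ATG-GAL4-polyA-FRT-3XP3-EGFP-polyA-FRT`
(KozakGAL4) cassette.  Fallbacks cover guide-poor UTRs (promoter scan with a
PAM-killing donor edit; CDS cut near the stop codon), 5′UTR introns
(splice-acceptor Kozak cassette), and small coding introns (two-cut T2A-GAL4).

The gene-specific part of each donor is a single synthesis order: homology
arms of 100–200 bp (default 200) around a 30-nt Golden Gate cloning site, in
one of three architectures:

| architecture | synthesized parts (5′→3′) | backbone |
|---|---|---|
| `int200` | arm5 – cloning site – arm3 | pUC57_Kan_gw_OK |
| `gRNA_int200` | tRNA-completion – gene sgRNA – sgRNA1 target – arm5 – cloning site – arm3 | pUC57_Kan_gw_OK2 |
| `2XgRNA_int200` | as above with two gene sgRNAs separated by a full tRNA | pUC57_Kan_gw_OK2 |

The backbone carries a U6-driven guide (sgRNA1) with no genomic target that
linearizes the donor in vivo; the `gRNA_int200` designs additionally encode
the gene-targeting sgRNA(s) in the synthesized fragment via a split-tRNA
multiplexing trick, so a single plasmid delivers everything.

donorforge covers the full desk workflow: genome-wide intron-suitability
survey, per-gene strategy choice, rule-based sgRNA selection with an
exhaustive mismatch/seed off-target screen, synthesis-feasibility checks,
in-silico Golden Gate assembly (type-IIS digestion and overhang ligation),
donor linearization, HDR outcome prediction (edited locus, transcripts,
protein products with average molecular weights), sfGFP protein-trap fusion
donors with a PiggyBac-excisable marker, flank-validation PCR primers, and
smiFISH probe sets (20-nt antisense probes carrying a shared 28-nt flap,
ordered as 48-mers, detected with the dye-labelled X-flap oligo).

## Worked example

Everything is testable without downloads: the `fixtures` module generates
deterministic synthetic genomes with planted ground truth.

```
$ donorforge fixtures --seed 7 --n-genes 6 --out fx
wrote 6-gene fixture to fx

$ donorforge survey --fasta fx/genome.fa --gff3 fx/genome.gff3 --out sv
3 suitable / 3 unsuitable of 6

$ donorforge design --fasta fx/genome.fa --gff3 fx/genome.gff3 \
      --gene g001_suitable --out d
g001_suitable: T2AGAL4_INTRONIC / gRNA_int200 / T2AGAL4-phase0, fragment 585 nt

$ donorforge simulate --fasta fx/genome.fa --gff3 fx/genome.gff3 \
      --gene g001_suitable --out sim
g001_suitable-trunc-T2A: 108 aa, 11.6 kDa
GAL4: 103 aa, 11.8 kDa

$ donorforge validate --fasta fx/genome.fa --gff3 fx/genome.gff3 \
      --gene g001_suitable --out val
amplicons: 279 nt (5'), 284 nt (3')

$ donorforge probes --fasta fx/genome.fa --gff3 fx/genome.gff3 \
      --transcript g001_suitable.t1 --out pr
48 probes (full)
```

Reading the output: `g001_suitable` has one coding intron (199 nt) shared by
both isoforms, so it takes the intronic artificial-exon strategy with the
phase-0 cassette (its upstream CDS length is divisible by 3); the 585-nt
`gRNA_int200` fragment is the complete synthesis order.  Simulation installs
the cassette by Golden Gate, linearizes the donor, performs seamless HDR, and
predicts two translation products: the truncated native protein ending in the
2A `...NPG`, and `P`+GAL4.  The validation amplicons (gene-specific primer
outside the homology arm × cassette primer) fall inside the required
200–800 nt window, and every smiFISH oligo is flap(28) + probe(20) = 48 nt.

All commands are deterministic: identical inputs give byte-identical outputs,
and each writes a JSON run record with the tool version and a config hash.

Real designs use your own genome FASTA/GFF3; production cassette, backbone
and primer sequences can be dropped into the parts library from YAML without
code changes (the shipped parts are deliberately shortened, clearly synthetic
stand-ins for testing).

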