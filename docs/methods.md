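# Methods

This note documents the models, parameter choices and numerical conventions
behind `saltmir`, and what the synthetic validation does and does not show.

## Coordinates, alphabets, formats

Internal coordinates are 0-based half-open everywhere; GFF3 and
human-readable reports are 1-based inclusive, converted at a single point in
`iofmt`.  DNA is the storage alphabet; folding converts T→U explicitly at
its boundary.  FASTQ is strict 4-line Phred+33 (configurable offset, never
auto-detected); malformed records raise format errors naming the line.

## Read cleaning

Seven ordered elimination rules; each read is charged to the first rule it
violates, so raw = clean + Σ removed holds exactly:

1. *Low quality*: mean Phred < 20 or > 10 % of bases below Q10.  The source
   protocol names but never defines this step; these are standard
   vendor-pipeline semantics, both thresholds configurable.
2. *5′ primer contaminant*: the read begins with a ≥ 8-nt prefix of the 5′
   adapter at ≤ 1 mismatch.
3. *No 3′ adapter*: no prefix of the 3′ adapter of length 12 down to 6 is
   found (longest prefix first, leftmost occurrence wins — deterministic).
4. *No insert*: the adapter starts at position 0.
5. *Poly-A*: the trimmed insert is ≥ 80 % A.
6. *Length*: insert outside 16–36 nt.

Surviving inserts are collapsed to unique tags with per-library counts; tag
ids are assigned in lexicographic sequence order so output is reproducible.

## Mapping

Ungapped alignment with ≤ 2 mismatches on both strands, all placements
reported, and tags with > 20 placements (the genome copy-number cap) flagged
`over_copy_cap` and excluded from discovery.  Completeness is by pigeonhole:
a tag of length L is split into 3 non-overlapping parts of length ⌊L/3⌋, so
any 2-mismatch placement leaves one part exact; the index therefore keeps
k-mer tables for every part length 5–12 (12 is the configured maximum seed
length — a single 12-mer table alone cannot give the guarantee for 16-nt
tags).  N never matches, in either the genome or the tag.  The test suite
proves exact equivalence with a sliding-window Hamming scan.

## Annotation

Each mapped tag receives exactly one class by the priority rule
rRNA etc. (GenBank-like set before Rfam-like set) > known miRNA > repeat >
exon > intron > unannotated, using the same ≤ 2-mismatch matcher as genome
mapping against the reference sequence sets.  Known miRNAs match a mature
reference within 2 mismatches and 2-nt end shifts, or sit on an annotated
precursor within ±2 nt of the mature — or of the derived miRNA\* position,
which is how star species (sometimes far more abundant than their mature)
are recognised and counted separately.

The miRNA\* geometry is one shared rule: the star interval is the pairing
partner of the mature, shifted +2 nt along the precursor, which leaves the
canonical 2-nt 3′ overhang on both duplex strands for a mature on either
arm.  Arms are 5p/3p by position relative to the pairing partner.

Exon/intron classification uses the gene models registered in the
*annotation database* subset.  The synthetic generator deliberately omits
the host genes of planted novel hairpins from that subset — this emulates
the incomplete expressed-sequence databases real studies annotate against,
and is the mechanism by which genuine intronic/exonic miRNAs survive the
priority filter and reach discovery (as they demonstrably did in published
plant studies).  Context classification for reporting (Fig-4-style) uses
the full gene set.

## Folding

The bundled backend is a Zuker-style dynamic program over an integer
parameter table in units of 0.01 kcal/mol: sequence-dependent stacking for
the six canonical pairs (G:U included), length-dependent hairpin, bulge and
internal-loop penalties with 1.75·RT logarithmic extrapolation, a Ninio
asymmetry term (0.48 kcal/nt, capped at 3.0), and an affine multibranch
model (a = 3.4, b = 0.4 per branch, c = 0.1 per unpaired nt).  Minimum
hairpin loop 3 nt; interior loops capped at 30 unpaired nt; no dangles,
coaxial stacks or tetraloop bonuses.  Integer energies make the DP exactly
comparable with the reference scorer: for every sequence the DP minimum
equals the exhaustive-enumeration minimum over all non-crossing structures
(tested for sequences up to 28 nt).  Ties prefer the structure with fewer
pairs, so MFE = 0 if and only if the structure is unpaired.  Absolute
energies approximate, but do not reproduce, full thermodynamic folders; the
−18 kcal/mol precursor cutoff applies to whichever backend is configured
(`nn`, `vienna`, or any callable).

## Novel miRNA discovery

Unannotated mapped tags of 18–26 nt seed two windows per placement (tag at
the 5′ end extending 3′ and vice versa), each `max_precursor` = 320 nt,
strand-aware and clipped at chromosome edges.  The window is folded, the
star derived, and the precursor then *trimmed* to the duplex extent plus
20-nt flanks and refolded — mirroring how hairpin-excision tools report the
minimal stem-loop rather than the whole scan window; MFE, MFEI and A+U are
evaluated on the trimmed precursor.  All criteria always run (full
diagnosis, no short-circuit) and each failure appends a distinct rejection
reason.

Duplex statistics: `paired_bp` is the number of mature positions paired to
the opposite arm; per-strand unpaired counts exclude each strand's 2-nt 3′
overhang; mismatches = min of the two unpaired counts, asymmetry their
absolute difference, bulge the longest unpaired run on either strand.
The mismatch cap defaults to 2: the source criteria say "less than 2 nt
mismatches" in one place and "no more than 2" in another; 2-inclusive is
the adopted, configurable reading.

The MFEI floor (default |MFEI| ≥ 0.85, standard plant-miRNA practice) is the
one threshold with no published number; MFEI is always reported and the
filter can be disabled (`mfei_min: 0`).  The boundary probes in
`scripts/acceptance.py` run with the MFEI filter off so that each published
threshold (−18 kcal/mol, 19 bp, 30–70 % A+U) is isolated from this coupled,
non-published one.

Accepted candidates are deduplicated on mature sequence, grouped by
overlapping precursor loci, and named `oco-miRNNN-5p/-3p` in locus order;
two matures from one hairpin share a number.  Genomic context is assigned
by majority overlap of the precursor with gene features (ties
5′UTR > 3′UTR > exon > intron; no overlap → intergenic).

## Homology search

Reference precursors (or bare matures) are searched against a cDNA set on
both strands.  Instead of heuristic seed-and-extend, the search does
pigeonhole-seeded *full-query* ungapped verification: the word size is
chosen per query so that any placement within the mismatch budget implied by
`min_identity` (0.90) over `min_coverage` (0.90) must contain an exact seed;
candidates are then verified by direct Hamming identity.  This makes the
search exactly equivalent to the brute-force sliding scan (tested), at the
cost of ignoring gapped homology — acceptable for short, highly conserved
hairpins, and documented as a limitation.  Precursor hits carrying a mature
annotation are refolded and validated with the discovery criteria.

## Differential expression

TPM = count/total × 10⁶.  Zero counts are reported as 0 TPM; only the
fold-change computation substitutes a 0.01-TPM floor (log₂ of zero is
undefined, and library-exclusive miRNAs still need a finite fold-change).
The exact test is Audic–Claverie; the printed two-sided construction
(doubling the smaller of the inclusive lower/upper tails conditioned on x)
is *not* exchange-symmetric, so the implementation doubles the smaller of
the two conditional lower tails P(K ≤ y | x) and P(K ≤ x | y), which sum to
exactly 1 — symmetry p(x,y,N₁,N₂) = p(y,x,N₂,N₁) then holds as a theorem,
and the value differs from the naive construction only in which tail the
observed count is assigned to.  Summation is in log space
(`gammaln` + `logsumexp`); the pmf normalises to 1 within 1e-12.  Calls use
raw p (thresholds inclusive: log₂FC ≥ 1 at P ≤ 0.05); BH q-values are
reported alongside but do not drive the calls.  Fisher's exact test can be
substituted by the caller; no replicate dispersion model is fitted because
the emulated design pools replicates into one library per condition.

The comparative-Ct utility averages replicates on the Ct scale, forms
ΔΔCt = (Ct_t − Ct_ref)_treated − (Ct_t − Ct_ref)_control, reports
RQ = 2^−ΔΔCt, and propagates the two ΔCt standard deviations in quadrature.

## Target prediction and enrichment

Scoring is against the reverse complement, position by position from the
miRNA 5′ end: match 0, G:U wobble 0.5, mismatch 1.0, gap 2.0, all doubled at
seed positions 2–13; expectation = Σ penalties, reported at ≤ 3.0.  Up to 2
gaps are allowed via a banded alignment; penalties are handled in integer
deci-units so the vectorised scanner and the traceback scorer agree exactly
with brute-force window evaluation (one hit per site end: the best window).
Inhibition is `translation` when a mismatch or gap faces positions 9–11,
else `cleavage`, with the slice site mapped gap-aware between the target
bases paired to positions 10 and 11.  Target-accessibility energy (UPE) is
not modelled — it would require partition-function folding of full mRNAs —
and this is the main deviation from the web-server original.

Enrichment is a per-term hypergeometric upper tail over the supplied
gene→term map with BH FDR control at 0.05; target genes missing from the
background are an input error listing the offenders.

## The synthetic study

The generator's defaults emulate the study design at desk scale: 12
chromosomes × 50 kb; 30 known hairpins (mature lengths weighted to 21 nt)
from 20 recognisable plant families; 24 novel hairpins spread over all five
genomic contexts (≥ 2 each of intronic, exonic, 5′UTR, 3′UTR; the rest
intergenic); 19 decoy ncRNA loci across rRNA/tRNA/snoRNA/snRNA/scRNA split
into GenBank-like and Rfam-like reference sets; repeat families at 5, 10 and
20 copies (20 being the copy cap); two ~25,000-read libraries with a fixed
12-mer 3′ adapter, 50-nt reads, 0.1 % substitution errors applied to clean
inserts only, and per-rule contaminant fractions totalling ≈ 8.5 %.
Planted expression draws counts as Poisson around expected values; 12 known
and 8 novel miRNAs carry |log₂FC| = 2 (expected counts ≥ 50 in both
libraries), plus one showcase hairpin whose star is vastly more abundant
than its mature.  A degradation-tag pool with a length profile peaking at
24 nt then 21 nt reproduces the canonical plant clean-read size
distribution.  Five reference precursors exist only in the transcript set,
so the homology stage discovers them *in silico*; planted target sites and
a small GO universe exercise the target and enrichment stages.

Two design details make the manifest an *exact* oracle rather than an
approximate one.  First, every generated read is classified through the
same cleaning rules the pipeline applies, and the manifest records the
outcome — per-rule contaminant counts and per-sequence clean counts are
therefore exact by construction, not by hoping no read strays across a rule
boundary.  Second, each novel hairpin is validated *in its genomic context*
at planting time: the generator excises and evaluates the candidate exactly
as discovery will, and redesigns or relocates the hairpin until it passes,
so recovery failures in the tests would indicate real pipeline defects, not
unlucky flanking sequence.

What passing these tests does **not** show: performance on real libraries
with instrument-specific error profiles, isomiR spectra, RNA editing,
heterogeneous adapter chemistry, gapped homology, or genomes at full scale
— the generator produces none of these, and the default scale
(~25 k reads/library vs tens of millions) is chosen so the full pipeline
and its validation complete in about half a minute.

## Degenerate inputs and tie-breaks

Empty FASTA → empty stream; empty read set → all-zero statistics; empty
transcriptome → no homology hits.  Sequences shorter than 5 nt cannot pair
and fold to the trivial structure.  Equal-energy structures resolve by a
fixed traceback preference (unpaired first, then hairpin, interior,
multibranch), so all outputs are byte-reproducible for a given seed, and
each pipeline stage is skipped on rerun when its outputs already exist.
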