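# Methods

This note documents the models and procedures serkdup implements, the
defaults and why, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Gene models and coordinates

GFF3 input is 1-based inclusive; internally all coordinates are 0-based
half-open, with the conversion isolated in the readers. Exons are numbered
1..n in transcription order and intron *i* is the genomic gap between
exons *i* and *i*+1 (so intron 5 immediately precedes exon 6). Genes
annotated on the minus strand are normalized at load time — the gene's
sequence is stored as the reverse complement of the reference and exon
coordinates are remapped — so every downstream computation is
strand-free. Lowercase (softmasked) input is accepted and uppercased.

Tandem-cluster geometry is plain interval arithmetic on chromosome
positions in Kb: the span is max(end) − min(start), rounded to the nearest
integer Kb; overlapping annotated loci produce a warning, not an error,
because overlapping gene loci in draft annotations are common and the
span is still well defined.

## Pairwise alignment

Global Needleman–Wunsch with affine gap costs, scored as +2 per identical
column, −3 per substitution, and −(open + extend·L) per maximal gap run of
length L. Published tool settings of the form "gap cost 5, gap extension
2" are ambiguous between charging the extension on every gapped base
(open + extend·L) or on every base after the first (open + extend·(L−1));
both rules are implemented, `open_plus_L` is the default, and the rule in
force is carried on every result. N scores as a mismatch against
everything by default (conservative for divergence counting); a neutral
0-score option exists.

The optimal alignment is computed by Biopython's `PairwiseAligner` (an
affine three-state dynamic programme in C); this package owns the cost
conversion, per-column classification (match / mismatch / gap per row),
and score recomputation — the reported score is always recomputed from the
emitted alignment and asserted equal to the DP optimum. Co-optimal
alignments are resolved by the aligner's deterministic first traceback, so
outputs are byte-stable across runs. An independent brute-force oracle
(`brute_force_align`) enumerates every global alignment of sequences up to
8 nt with incremental affine costing; the test suite checks DP–oracle
agreement on hundreds of seeded random pairs under both gap rules.

## Molecular-clock duplication dating

After a duplication both copies accumulate mutations independently, so
pairwise divergence grows at 2μ and the age is T = K/(2μ). The default
rate is μ = 3×10⁻¹⁰ substitutions·site⁻¹·yr⁻¹, a standard plant nuclear
rate. Counting rules:

* substitutions = mismatch columns;
* each maximal gap run counts as one indel event, contributing one
  mutation (default `subs_plus_indel_events` mode; `subs_only` available)
  and one site;
* sites = ungapped columns + indel events;
* K = mutations/sites, uncorrected by default. At the divergences this
  clock is meant for (p < 0.01) the Jukes–Cantor correction changes K by
  under 1%; it is available as an option and raises an error at p ≥ 3/4.

For a gene pair, intron *i* is aligned against intron *i* and counts are
pooled across introns before forming one K (length-weighted pooling, not a
mean of per-intron ratios — lower variance, one age per pair).

Event inference is UPGMA (average-linkage) agglomeration of the age
matrix: each merge is one duplication event and its linkage height —
already in years, since the clock conversion did the factor-of-two — is
the event time. Ties are broken by the lexicographically smallest member
name, so the result is invariant to input order. Deviations from
ultrametricity are summarized as the worst within-merge coefficient of
variation of cross-clade ages and never repaired. The event tree is
serialized as ultrametric Newick with branch lengths in Myr.

**Precision at realistic scale.** The age of a pair duplicated T years ago
estimated from L sites carries ~Binomial(L, 2μT) counting noise: the
relative SD of T̂ is ≈ 1/√(2μTL). With 10 kb of introns and T ≈ 2–3 Myr
that is 13–20 expected mutations and a 23–28% relative SD, and event times
0.2–0.45 Myr apart differ by only 2–4 expected mutations. Single-run date
estimates and merge orders at that scale are therefore intrinsically
noisy; no estimator can do better without more sequence. The test suite's
sharp recovery checks accordingly use larger simulated intron totals
(50 kb–1 Mb) and tolerances set at 2–3.5 binomial SDs; an end-to-end check
at the 10 kb scale with a 15% tolerance is retained in the acceptance
tests to document this limit, and fails for the stated statistical reason.

## Degenerate primers

Degeneracy is the product over positions of IUPAC ambiguity-set sizes
(R,Y,S,W,K,M = 2; B,D,H,V = 3; N = 4). The 3′-specific run is the maximal
A/C/G/T-only suffix. In-silico PCR matches the forward primer by exact
IUPAC compatibility (every primer position's set contains the template
base; zero mismatches — a mismatch-tolerance flag is reserved but defaults
to 0), and the reverse primer — supplied 5′→3′ on the antisense strand, as
primers are ordered — as its reverse complement downstream. Template N is
permissive, since genomic drafts contain N runs. All forward/reverse site
pairs within a maximum product size (default 5,000 bp) are reported,
sorted by length.

## Splice variants

Transcripts are assumed error-free relative to the genome (clean synthetic
or curated data), so mapping is greedy exact-segment matching over the
ordered genomic segments (exon 1, intron 1, exon 2, …): an exon either
matches in full (kept) or is skipped in full; an intron matching in full
between two kept exons is retained. The recovered structure is re-spliced
and must reproduce the transcript exactly, otherwise a mapping error with
the failing offset is raised. This replaces spliced-alignment tools, which
are only needed for noisy cDNA.

The primary ORF starts at the annotated start codon — not the longest
ORF — because variant transcripts of one gene are read from the canonical
start. A premature termination codon (PTC) is a stop strictly upstream, in
genomic coordinates, of the canonical stop; comparing genomic positions
(rather than protein lengths) means that skipping an in-frame exon is
correctly *not* a PTC. When the stop's first base lies inside a retained
intron, that intron is reported. For PTC transcripts the longest
ATG-initiated ORF downstream of the premature stop (leftmost on ties,
stop codon required) is reported as a secondary ORF.

Variants are grouped by exact predicted-protein equality; variants that
retain the same stop-bearing intron with identical upstream kept segments
necessarily encode the same protein, however their 3′ ends differ.

## Protein features

The leucine-zipper scan searches every 22-residue window for the literal
consensus Leu-X₆-Leu-X₆-Leu-X₆-Leu (strictly leucine, X any residue); a
protein with no full window but at least one Leu-X₆-Leu is "partial",
matching the usage for SERK relatives that keep only the first heptad.
The SPP motif defaults to the literal tripeptide SPP and is configurable,
since the signature is a highlighted alignment region rather than a
published regex.

Molecular weight is the sum of average-isotopic residue masses plus one
water (Biopython's ProtParam table). The isoelectric point is solved by
bisection of the net-charge curve to 0.001 pH using the Bjellqvist pKa
set, including its residue-specific N- and C-terminal pKa values
(e.g. N-terminal Thr 6.82, C-terminal Glu 4.75); the tests cross-check
against Biopython's independent implementation, with agreement to
< 0.001 pH on random proteins.

## qPCR quantification

Efficiency estimation is a deliberately simplified window-of-linearity
method. After subtracting a crude baseline (mean of the first 5 cycles),
candidate windows are 4–6 consecutive points that are above the noise
floor (3 baseline SDs, and at least 0.1% of the dynamic range), rise by at
least a factor 2 (excludes plateau windows), and lie in the lowest 5% of
the dynamic range (the exponential phase proper; the restriction is
dropped if no window qualifies). Among windows within 5×10⁻⁴ of the best
r² the earliest and longest is chosen — the lowest-fluorescence window has
the least saturation bias. Finally the baseline is refined on that window
alone by a bounded 1-D search maximizing log-linearity, because the crude
first-cycles mean contains amplification signal and would otherwise
steepen the apparent slope. E = 10^slope, clamped to [1, 2.2] with a
warning. On noiseless exponentials recovery is exact to < 10⁻⁵; at 1%
multiplicative noise on saturating curves the worst error over 200 seeded
curves is < 0.03. A full iterative per-well baseline reconstruction (as in
dedicated efficiency tools) is intentionally out of scope, so per-curve
efficiencies from real instrument exports should be preferred when
available.

Relative expression is the Pfaffl ratio E_t^ΔCt(target) / E_ref^ΔCt(ref)
with ΔCt = Ct(calibrator) − Ct(sample), computed per biological repeat and
summarized as mean ± SE (sample SD/√n) per timepoint; the calibrator
timepoint has mean ratio 1 by construction. Per-run mean efficiencies are
used (per-well efficiencies would also be valid; the choice is exposed
through the `efficiencies` argument). Ct values are taken as given —
threshold crossing is the instrument's job — with a linear-interpolation
helper for synthetic curves.

## Synthetic data

`simulate_duplication_history` evolves introns down a caterpillar tree
whose node heights are the event times (defaults 3.25, 3.05, 2.65,
2.2 Myr, ten introns with lengths uniform on [400, 1600] nt, μ = 3×10⁻¹⁰).
Along a branch of duration t each site substitutes with the Jukes–Cantor
transition probability ¾(1 − e^(−4μt/3)) to a uniformly chosen different
base; optional indels are Poisson events with geometric lengths (off by
default — the clock signal is substitutional). Expected pairwise
p-distance is 2μT, which the tests verify on 1 Mb of pooled sequence. Not
emulated: codon/GC bias, rate heterogeneity among introns or lineages,
and selection; recovery results on this generator say nothing about clock
violations in real data, only about the estimator's sampling behaviour.

`make_sv_fixture` builds the 11-exon splice-variant fixture. CDS exon
lengths are 150, 150, 72, 75, 75, 96, 96, 96, 300, 300, 351 nt (1761 nt,
587 codons): exon 1 begins with the ATG, exon 11 ends with TAA, and the
codon opening exon 9 is ATG. Coding codons are drawn from the 60 codons
that are neither stops nor ATG, so the annotated start and the planted
exon-9 ATG are the only in-frame methionines. Introns (61–120 nt) are
random over {C, G, T} — with no A, no stop codon or ATG can occur in any
frame — except intron 5, which opens with 12 nt of sense codons then TGA,
and intron 8, which opens with one sense codon then TAA (the base after
each designed stop is fixed to C so the stop's trailing A cannot seed an
ATG across the junction). Consequences, by construction: exon boundaries
2|3 and 3|4 fall on codon boundaries and exon 3 is 72 nt, so skipping it
preserves frame and shortens the protein by exactly 24 aa; upstream kept
lengths at introns 5 and 8 are divisible by 3, so the designed stops are
read in frame; and every PTC variant's secondary ORF starts at the exon-9
ATG and runs 316 codons to the canonical stop. The seven transcripts
realize: canonical (SV1), intron-8 retention (SV2), exon-3 skip (SV3),
both (SV4), and exon-3 skip with intron 5 retained alone (SV7) or together
with intron 6 (SV5) or intron 8 (SV6) — giving protein lengths 586, 271,
562, 247 and 154 (×3) aa and five distinct proteins. The fixture is an
engineered correspondence to those published lengths, not a recovered
gene sequence.

`simulate_qpcr` produces logistic-saturating curves
F_c = P / (1 + (P/F₀ − 1)·E^(−c)) with optional multiplicative Gaussian
noise; `simulate_ct_table` inverts the Pfaffl formula to plant exact
fold-changes with a constant reference gene.

All generators are byte-reproducible from (parameters, seed).

## Problem sizes used by the tests

Unit tests run in seconds: alignments up to a few kb, oracle enumeration
at ≤ 8 nt, clock recovery on 50–100 kb of simulated introns, divergence
calibration on 1 Mb, 200 qPCR curves. The acceptance tests add 100
simulated five-gene families at the 10 kb intron scale (~2 minutes) and
500 alignment-oracle pairs (~1 minute).

## Known limitations

* No multiple-hit correction beyond optional JC69; no synonymous-site
  (Ks) dating, rate heterogeneity, or bootstrap confidence intervals.
* Transcript mapping requires error-free transcripts; partial-exon events
  and cryptic splice sites are out of scope.
* In-silico PCR is exact-match only; no melting temperature or
  mismatch-tolerant annealing model.
* The efficiency estimator is a simplified window method; its numbers are
  not those of full iterative baseline-reconstruction tools.
* Signal-peptide, transmembrane and kinase-subdomain prediction are
  external-tool territory and deliberately excluded.
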