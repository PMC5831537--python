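# Methods

This note documents the models behind each signal, the tunable
parameters and their defaults, what the synthetic benchmark does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Sequence handling

Sequences are restricted to {A, C, G, T, N}; lowercase is uppercased and
U mapped to T on ingest. N is retained but never matches anything:
k-mer windows containing N are skipped rather than distributed
fractionally, and alignments treat N as a mismatch. Coordinates are
0-based half-open throughout; reverse-strand features are described by
their forward-strand interval plus strand −1.

The ORF caller is a deliberately plain prokaryotic scanner: starts
{ATG, GTG, TTG}, standard stops, leftmost start per stop-to-stop
segment, both strands, default minimum 60 encoded amino acids. Where
records carry CDS annotations those are used instead, and the codon and
translated-homology signals share one gene set per record. Only the
standard genetic code is supported.

## Composition profiles

Canonical k-mer profiles (k = 1–8) count each word and its reverse
complement in one bin, the representative being the lexicographic
minimum of the pair; profiles are therefore strand-invariant, and the
bin count is 4^k/2 for odd k and 2^k + (4^k − 2^k)/2 for even k
(even-length palindromic words are their own bin). Codon usage is the
in-frame codon frequency over coding regions, strand-resolved, pooled
across genes; all 64 codons are counted, stops included — excluding the
three stops would barely move a normalised 64-vector and including them
keeps the dimension at the conventional 64. GC content is the k = 1
special case (AT, GC).

Distances are computed on relative frequencies, never raw counts, so
genome length cancels (phages and hosts differ by orders of magnitude).
The default metric is Euclidean; Manhattan, cosine distance and Pearson
correlation are selectable (Pearson flips the table orientation to
higher-is-better).

## Exact matches

The longest identical stretch between a phage and a host is found in
two steps: all shared 15-mers are listed via a per-host sorted-array
index (hosts are indexed one record at a time; there is no all-pairs
scan), then seeds on the same diagonal — constant phage_pos − host_pos
on the forward strand, constant anti-diagonal on the reverse — whose
intervals overlap or abut are merged, and each merged run is extended
base-by-base to maximality. This reproduces maximal exact matches
without ambiguity; equivalence with a brute-force longest-common-
substring oracle is asserted in the tests whenever the LCS reaches the
seed length. Matches shorter than 15 bp are invisible by construction,
which is intentional: identities at the scale of integrase core sites
cannot be told from random matches. Both host strands are searched by
default; a forward-only flag exists. Pair scores are the match length,
0 where no seed is shared, and ties across hosts are preserved —
several hosts legitimately share a phage's longest match when a
prophage is conserved among relatives.

## CRISPR spacers

The array detector is a simplified repeat-spacer finder, not a port of
any existing tool: exact 16-mer anchors recurring at gaps of 39–120 bp
seed candidate arrays; anchors are grown into repeats column-by-column
while ≥90% of copies agree; candidates qualify with ≥3 repeat copies,
repeat length 21–48 bp and spacer lengths 18–72 bp. Three identical
16-mers at spacer-like intervals essentially never occur in i.i.d.
random sequence, so the detector's false-positive rate is negligible
(tested over 10 × 100 kb replicates). Pre-extracted spacers can be
imported from FASTA (ids `host|array|ordinal`) to bypass detection.

Spacer-to-phage matching mirrors a short-query nucleotide search: word
size 7, match +1, mismatch −1, both strands, no low-complexity masking.
The classic gap penalties for this regime (open 10, extend 2) exceed
what the acceptance floor can absorb, so qualifying alignments are
gap-free and are evaluated exactly as ungapped placements: a hit must
cover at least spacer_length − 2 bases (edge clipping only) and reach
score ≥ spacer_length − 2·max_mismatch. A database-size-dependent
significance value would not be reproducible across collections, so
this deterministic floor replaces it. Mismatches are substitutions
only; the gap field is reported (always 0) for format compatibility.

Two scores: best percent identity of any qualifying spacer
(`max_mismatch` default 2, sweepable to the 13-mismatch priming bound),
and the number of distinct spacers from a host hitting the phage
(identical spacer sequences within a host count once; `min_spacers` 2
gives the stricter multi-spacer variant). Hosts without arrays — and
pairs without qualifying hits — are no-evidence, not zero: roughly
40% of bacteria carry no CRISPR system at all, and the distinction
matters for ranking.

## Homology

The internal aligner is a seeded ungapped extender, deliberately
simple; it does not attempt parity with full gapped search statistics,
and a 12-column tabular adapter lets externally computed alignments
drive the identical summaries. Nucleotide mode: 11-mer seeds, match
+1 / mismatch −2, X-drop 20, alignments qualify at score ≥ 28 (the
word-derived floor a default nucleotide search implies); the pair score
is the union length of phage intervals covered by qualifying
alignments, making it invariant to how hits are split or overlap.
Translated mode: each phage ORF is searched against the host proteome
by exact 4-amino-acid word seeds plus BLOSUM62 X-drop extension
(proteins are concatenated with sentinel separators that no extension
can cross); an ORF matches at raw score ≥ 50, and the pair score is the
number of matching ORFs. The two cell definitions — total aligned
length and matching-protein count — are the only readings consistent
with how such scores are conventionally plotted. Pairs with no
qualifying alignment are no-evidence rather than 0, so a phage without
hits predicts nothing instead of trivially tying every host.

## Abundance co-occurrence

Profiles are compared with Pearson correlation after two guards applied
in sequence: samples where either member is absent (abundance exactly
0; no detection threshold) are excluded from that pairwise comparison,
and the correlation is computed only when more than six samples survive
— i.e. at least 7 — otherwise the pair is no-evidence. Correlations
are computed on raw abundances by default (a log option exists but is
off). The exclusion rule makes scores invariant to adding samples where
either member is absent; Pearson makes them invariant to positive
affine rescaling.

## Ranking, ROC and the random baseline

All hosts tied at a phage's row-optimal score are predicted; a
prediction is correct at a rank if any predicted host shares the true
host's lineage name there (case-folded exact match against a flat
six-rank lineage table — no live taxonomy service, no synonym
resolution). Because an all-tied row is trivially "correct", every
accuracy is accompanied by the mean prediction-set size. ROC curves
sweep distinct score values from max to min, tied pairs entering
together; no-evidence pairs are excluded from the sweep by default
(imputing them as worst scores is available for sensitivity analysis),
and the area is trapezoidal. The random baseline assigns each phage
1–4 uniformly random hosts; its species accuracy has closed form
E[k]/H, and the sampler draws the true host's permutation position
directly, which is distributionally exact.

## The synthetic benchmark

Hosts are drawn from per-host first-order Markov (dinucleotide) models:
transition rows are a mixture of uniform (¼) and a host-specific
Dirichlet(1,1,1,1) draw, weighted by `host_bias` (default 1.0, i.e.
fully host-specific — at this setting a genome half is closer to its
other half than to any other host for ≥95% of pairs at k = 4). Hosts
sit in a balanced toy taxonomy (2 species per genus, 2 genera per
family, …), making the rank-nesting invariants exactly testable.

Each phage receives one true host and one planting mode, rotated so all
five modes are equally represented:

- **prophage** — a verbatim copy of 80% of the phage (12 kb at
  defaults) is spliced into the host;
- **shared_gene** — one 900 bp ORF-shaped gene is planted verbatim in
  the host and at 5% divergence in the phage;
- **spacer_donor** — a CRISPR array (28 bp repeat, three 32 bp spacers
  taken from the phage with 0/1/2 substitutions) is spliced into the
  host;
- **composition_only** — the phage is sampled from the host's observed
  dinucleotide model mixed with uniform at weight `amelioration`
  (default 1.0), a concrete stand-in for compositional amelioration;
- **abundance_only** — sequences stay unrelated; only abundances are
  coupled.

Splice positions within a host are reserved so material planted for one
phage is never overwritten by a later phage sharing that host.
Abundances are sparse log-normals over 40 samples (host presence 0.75
per sample); a phage is zeroed wherever its host is absent and thinned
by 5% dropout, and its log-abundance is c·host + (1−c)·noise with
c = 0.9 for abundance_only phages and c = 0 otherwise. Restricting the
coupling to abundance_only phages keeps each mechanism recoverable by
exactly one signal, which is what makes the per-mechanism recovery
matrix interpretable; it also means overall abundance accuracy tops out
near the abundance_only share of phages, mirroring the real situation
where co-occurrence is informative only for the subset of phages whose
ecology happens to be sampled.

Default scale is 20 hosts × 40 kb and 40 phages × 15 kb, chosen so the
complete benchmark (generation plus all nine signals) runs in a few
minutes on one CPU while keeping seed statistics meaningful (e.g. ~1
shared random 15-mer expected per unrelated pair, so exact-match rows
are not degenerate). Everything derives from one master seed;
rebuilding a bundle with the same seed is byte-identical.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: realistic phage genome architecture
(modules, terminal repeats, tRNAs), amelioration above dinucleotide
order, horizontally shared genes between *unrelated* hosts, CRISPR
repeat degeneracy and array turnover, read-level metagenome noise,
compositional biases of sequencing, and host ranges wider than one
host per phage. Accuracies on this benchmark characterise the
machinery, not expected performance on reference databases.

## Known limitations

- The internal aligners are ungapped; indel-rich homology is
  under-reported in both nucleotide and translated modes (the tabular
  adapter is the escape hatch).
- The CRISPR detector requires an exact 16-mer shared across repeat
  copies; heavily degenerate repeats can fall below the anchor and be
  missed, so externally extracted spacers are first-class input.
- Ensemble combination of signals is intentionally out of scope: each
  signal is evaluated on its own.
- The exact-match score reports 0 (not no-evidence) when no 15-mer is
  shared, following the definition of the signal as a length; rows that
  are all-zero therefore tie all hosts, which the mean prediction-set
  size column makes visible.
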