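# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `redsearch`, in the order data flows through the
package.

## Reduced alphabets and the seed screen

A reduced alphabet is a partition of the 20 standard residues; sequences
are rewritten by replacing each residue with its group's representative
character (the first residue listed in the group). Reduction can only merge
symbols, so the per-column identity of any pair of aligned sequences is at
least its 20-letter identity — the monotonicity that makes long exact seeds
between homologs common. The registry (`data/alphabets.tsv`) ships eleven
published alphabets spanning 4–20 groups; `murphy.10` is the search
default.

Ambiguity codes fold into canonical groups (B→D, Z→E, U→C, O→K, standard
NCBI practice). X and `*` map to a dedicated wildcard symbol that never
matches anything — including itself — so unknown residues and stops can
never seed.

Alphabets are compared by **coverage** (fraction of homolog pairs sharing
at least one exact reduced substring of a given length) and **efficiency**
(log ratio of homologous to non-homologous pairs sharing one). The log base
is 10; the bases differ only by a constant factor and the choice is a
package convention. When the non-homolog count is zero it is replaced
by 1 so the statistic stays finite on small synthetic sets; a zero homolog
count yields −inf. Coverage is computed per *pair* (a pair counts if its
two members share a seed); counting individual proteins instead would
change the estimate by at most a factor bounded by 2 and not the ranking of
alphabets, which is what the screen is for.

## Database index

The reduced database is concatenated into one integer text. Group symbols
are coded 1..k, the wildcard is 0, and the sentinel terminating record *j*
is the negative value *j − n*: distinct per record and lexicographically
below every symbol. Distinct sentinels guarantee no suffix comparison ever
runs across a record boundary, so cross-sequence matches are structurally
impossible; because they sort before all real suffixes, the suffix array
over non-sentinel positions is obtained by slicing the first *n* entries
off the full array (the first retained LCP entry is reset to 0).

The suffix array is built by prefix doubling (numpy `lexsort`,
O(n log² n)); the LCP array by Kasai's algorithm. Correctness is contracted
by brute-force oracles in the test suite (full suffix sort and
character-by-character LCP on randomized texts), not by the construction
strategy.

Word statistics, computed once at indexing:

* `hexamer_counts` — occurrences of every reduced 6-mer in windows free of
  sentinels and wildcards;
* `median_hexamer_freq` — the median over the *distinct observed* hexamers'
  counts (not over all 10⁶ possible words, most of which are absent in any
  realistic database and would drag the median to zero);
* `composition` — frequency of each reduced symbol over the database text
  (wildcards excluded).

Both conventions are deliberate choices where the underlying description is
ambiguous; composition is measured on the database rather than the query so
seed-length decisions depend only on the index, not on each read.

The index persists as a versioned container: magic string, JSON header
(records, alphabet, median) with sorted keys, then raw `.npy` blocks. No
timestamps or compression archives are involved, so rebuilding the same
input is byte-identical — a property the CLI tests assert. Truncated files
and version mismatches raise errors.

## Seed detection

**Minimum seed length.** For the query position *p*, let *f* be the
database frequency of the reduced 6-mer at *p* and *M* the median hexamer
frequency. If *f ≤ M* the minimum seed length is 6. Otherwise the word is
lengthened one symbol at a time, multiplying the running expected frequency
by the database composition of each appended query symbol, for as long as
the expectation remains above *M*, to at most length 9. A frequency-only
form (`min_seed_length_from_stats`) exposes the rule for analysis; the
index-backed wrapper feeds it real frequencies and stops lengthening at the
query end. The rule is monotone in *f* and always lands in [6, 9].

The printed ancestral form of this loop compares the shrinking expectation
*against* the median with the opposite inequality, which cannot terminate;
the implementation uses the only reading consistent with "longer seeds for
frequent words" and with the stated 6–9 range: extend while the expectation
is still above the median, stop as soon as it drops to or below it.

**MEMs.** For every query position, the suffix array is binary-searched for
the interval of database suffixes sharing the minimum-length prefix; every
occurrence is grown to its maximal extent in both directions (wildcards and
sentinels block), and duplicates of the same maximal match reached from
different starting positions are suppressed. No two-hit rule is applied —
every single seed is extended. The enumeration is tested equal to a naive
O(nm) diagonal scan.

**Mismatch seeds.** Windows of exactly 10 query symbols have the symbol at
offset 3, 4, 5 or 6 (0-based) replaced by each other group symbol in turn;
exact occurrences of the modified word are looked up in the suffix array
and grown rightwards only, so the substituted offset keeps its position in
the window. Growing leftwards would shift the mismatch out of the allowed
slots. By construction the database symbol at the mismatch differs from the
query's, so no mismatch seed duplicates an exact MEM. Between unrelated
random sequences such windows essentially never exist (probability
~k·(k−1)·k^−10 per position pair); tests and the acceptance script plant
them by querying high-identity mutants of database records.

## Extension and scoring

Extension happens in the original 20-letter space with BLOSUM62, shipped as
an NCBI-format text file and adjusted at load: all X scores are clamped to
≤ 0 and the entire `*` row/column is forced to −4 (the stock file scores
`*`:`*` at +1, which would let an extension cross a stop codon profitably).
Gap of length g costs 11 + g (open 11, extend 1) — the parameterization the
Karlin–Altschul constants assume.

**Ungapped.** From the seed, each direction accumulates column scores and
stops once the running sum falls `xdrop_ungapped` below that direction's
best; the result is the best-scoring ungapped segment containing the seed.
With the X-drop disabled this equals the exhaustive maximum over all
segments containing the seed (tested).

**Gapped.** If the ungapped score reaches the trigger, an affine-gap DP
runs outward from the segment's highest-scoring column (leftmost on ties):
one half-extension over the suffixes, one over the reversed prefixes, each
anchored at its origin and free to end anywhere, concatenated through the
anchor column. Cells in the match and query-gap states falling more than
`xdrop_gapped` below the running best are discarded; every retained value
still corresponds to a genuine alignment, so the extension score never
exceeds the Smith–Waterman optimum, and with the X-drop disabled and an
anchor on an optimal local path it equals it (both tested against
Biopython's independent `PairwiseAligner`).

Thresholds are not stated by the method's description anywhere, so they are
package defaults, expressed in bits and converted to raw units via the
matching λ: ungapped X-drop 7 bits, gapped X-drop 15 bits, gapped trigger
22 bits — the conventional BLAST-like regime. All are overridable through
`SearchConfig`.

**Statistics.** Bit score S′ = (λS − ln K)/ln 2; E = m′n′·2^(−S′). Gapped
BLOSUM62 parameters λ = 0.267, K = 0.041, H = 0.14 (published BLAST values
for 11/1), ungapped λ = 0.3176, K = 0.134, H = 0.4012. The edge-effect
correction subtracts the expected HSP length ln(Kmn)/H from both lengths
(floored at 1/K); it is on by default and can be disabled, which makes the
closed forms exactly testable. *n* is the total residue count of the
original 20-letter database; *m* is the length of the peptide (frame)
actually searched. All reported hits are scored with the gapped parameters,
including the rare alignments that never triggered gapped extension — one
consistent scale for ranking and cutoffs.

## Query preparation

Nucleotide reads are translated with the standard genetic code in frames
+1/+2/+3 and, on the reverse complement, −1/−2/−3. Stops are kept in the
frame as `*` — the frame is searched whole, and the −4 stop scores confine
alignments to single ORFs naturally. Codons containing N translate to X.
Each frame carries an affine map back to read coordinates; reported hits on
the minus strand have start > end, the translated-search convention. Reads
shorter than 3 nt yield no frames and are logged.

Masking is a single-pass entropy filter in the spirit of SEG: Shannon
entropy of each 12-residue window; windows under 2.2 bits trigger masking
and extend through flanking windows under 2.5 bits; all covered residues
become X. Windows already containing X neither trigger nor extend and
existing X is preserved, which makes the operation idempotent in one pass
and prevents masking from cascading through its own output. This is a
simplification of the published SEG program (no recursive subsequence
refinement); the contract that matters to search — biased runs cannot seed
or score — holds, and alignments are re-displayed with the original
residues afterwards. On uniform random 200-mers the filter masks well under
5% of residues. Masking applies to queries; database masking is available
in principle but off — the index stores unmasked text.

## Search pipeline

Per query (per frame for reads): mask → encode → exact MEM seeds +
mismatch seeds → extension. Seeds are processed longest-first; a seed whose
query and subject intervals both fall inside an alignment already produced
for that record is skipped (band deduplication, preventing duplicate HSPs).
Alignments with non-positive raw score are dropped. Hits are ranked by
(E-value, −bit score, subject id) — a total order, so output is
deterministic and byte-stable under re-runs — truncated to `max_hits`
(default 100) at `evalue_cutoff` (default 10), and written as 12-column
BLAST tabular rows. Query ids of translated frames are the read id
unadorned; the frame is recoverable from the coordinates.

## Synthetic data

`simulate` provides the study conditions:

* `generate_protein_db` — i.i.d. residues, uniform composition by default
  (length range 80–200), seedable and bit-reproducible;
* `mutate_homolog` — per-position substitution at rate 1 − target identity,
  sampled ∝ exp(BLOSUM62 score) over the 19 alternatives so divergence
  resembles real substitution biases (uniform mode retained for worst
  cases); indels opened at rate 0.01/residue with geometric lengths
  (p = 0.5); the realized identity (matches over non-gap aligned columns of
  the recorded truth alignment) must land within ±5 points of target or the
  pair is resampled;
* `simulate_reads` — uniform fragments of coding sequences
  (back-translated with uniform codon choice), either strand, with a truth
  table (source, offset, strand) for recall scoring. The default read
  length used in the examples is 72 nt, a realistic short-read scale.

What this emulates — and does not: synthetic proteins are compositionally
uniform and unstructured, so there are no real protein families, no domain
architecture, no shared motifs between "unrelated" sequences, and the
substitution process is position-independent. Passing tests therefore
demonstrate algorithmic correctness and the qualitative behavior of the
seeding trade-offs, not sensitivity figures transferable to real
metagenomes. Real databases also have biased composition, which raises
hexamer medians and engages the adaptive seed-length rule more often than
uniform synthetic text does.

## Experiment scales

Chosen as the package's own desk-scale defaults: oracle-equivalence tests
run 100 randomized trials per operation with texts up to ~2,000 symbols and
queries up to ~200; the sensitivity experiment uses a 200-protein database
(lengths 90–180) with 50 queries at 60% and 50 at 25% identity, cutoff
E ≤ 1e−3, recall measured against full Smith–Waterman scans scored through
the same statistics module.

## Known limitations

* Single-threaded by design.
* No composition-based score adjustment or sum statistics for multi-HSP
  E-values; λ/K are table constants, not recomputed from the matrix.
* Mismatch seeds use the fixed ≥ 10 rule regardless of the adaptive
  minimum for exact seeds.
* The masking filter is not the published SEG program and will not
  reproduce its output exactly.
* The suffix-array search is a clean O(L log n) binary search per query
  position rather than an O(n+m) LCP-interval traversal; at desk scale this
  is far from the bottleneck (extension dominates), but it leaves headroom
  for large databases.
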