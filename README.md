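# redsearch

Fast protein similarity search built on reduced amino-acid alphabet seeds —
for annotating protein-coding sequence in short-read (e.g. metagenomic)
datasets, where translated BLAST-style searches against large protein
databases dominate compute budgets.

## The idea

BLAST-style protein search is seed-and-extend: find short exact word
matches, extend each into a local alignment, keep the significant ones.
With 20 amino acids, homologous proteins share only very short exact words,
so protein search needs permissive 3-residue seeds and drowns in chance
matches. Chemically similar residues, however, substitute for one another
freely: rewriting sequences over a **reduced alphabet** — here murphy.10,
which merges e.g. {I,L,V,M}, {K,R}, {E,D,N,Q} into single symbols — makes
homologs far more identical, so much longer exact seeds survive between
them. A 6-symbol seed in a 10-letter alphabet addresses a space of
10⁶ words versus 20³ for BLAST's 3-residue words: over a hundred-fold fewer
chance seeds per position, with little loss of true ones.

The pipeline:

1. **Index** — the database is rewritten in reduced symbols, concatenated
   with per-sequence sentinels, and indexed with a suffix array + LCP
   array; a 6-mer frequency table (and its median) and the residue
   composition are precomputed.
2. **Seeds** — all maximal exact matches (MEMs) between reduced query and
   database of an adaptive minimum length: 6 for words at or below the
   median database frequency, stretched up to 9 while the expected
   frequency of the lengthened word stays above the median. Long seeds
   (≥ 10) may additionally carry one mismatch at offset 3–6 of the window.
3. **Extension** — each seed is extended on the *original* residues with
   BLOSUM62: ungapped X-drop extension first, then affine-gap (11/1)
   X-drop dynamic programming from the best column once the ungapped score
   passes a trigger.
4. **Statistics** — Karlin–Altschul: bit score S′ = (λS − ln K)/ln 2 and
   E = m′n′·2^(−S′) with edge-corrected effective lengths, using the
   published BLAST parameters for BLOSUM62 (gapped λ = 0.267, K = 0.041).
   Hits with E ≤ cutoff are ranked, up to 100 per query.

Nucleotide queries are translated in all six frames (stops kept as `*`,
which scores −4 against everything; N-codons become X); peptides pass an
entropy-based low-complexity filter (SEG-style, 12-residue windows,
2.2/2.5-bit thresholds) so biased runs neither seed nor score.

## Worked example

```python
from redsearch import SearchConfig, build_index, get_alphabet, search_record
from redsearch.simulate import MutationModel, generate_protein_db, mutate_homolog

db = generate_protein_db(100, (90, 180), rng_seed=10)
index = build_index(db, get_alphabet("murphy.10"))
query, identity, _ = mutate_homolog(db[0].residues, MutationModel(0.6), rng_seed=100)
for hit in search_record(index, "q0", query, SearchConfig(evalue_cutoff=1e-3)):
    print(hit.m8_row())
```

prints one BLAST-tabular row per alignment, e.g.

```
q0	prot00000	62.5	160	60	0	1	160	1	160	4.5e-65	233.8
```

— the query aligns to its true source protein over 160 columns at 62.5%
identity with 60 mismatches and no gap openings, spanning residues 1–160 of
both; the E-value 4.5e-65 says an alignment with bit score 233.8 is
essentially impossible by chance in this 13k-residue database.

The same is available from the shell:

```sh
redsearch index -d db.fasta -o db.idx --alphabet murphy.10
redsearch search -q reads.fasta -d db.idx -o hits.m8 -e 1e-3
```

`examples/` holds narrative scripts for each capability: the alphabet
coverage/efficiency screen, protein search, translated short-read search,
and sensitivity versus evolutionary distance measured against a
Smith–Waterman oracle.

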