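# Methods

## The genomic-context model

The pipeline rests on a single empirical regularity of prokaryotic genomes:
genes under common regulation cluster physically (operons and super-operonic
neighborhoods), and although any one lineage may break a cluster up by
insertion, deletion or rearrangement, the association between a regulator
and its regulon reappears when many genomes are examined jointly.  The
method therefore never requires strict gene-order conservation; it only
counts co-occurrence of functional labels inside windows centered on the
regulator's homologs, one window per genome, and lets the recurrent signal
rise above lineage-specific noise.

The unit of counting is the *neighborhood*, not the gene: an EC number's
frequency is the number of distinct windows that contain it at least once.
This presence/absence convention means a tandem duplication inside one
genome adds nothing, while independent occurrences across genomes add one
each — which is exactly the evidence the model values.  Pathway scores sum
the frequencies of every mapped enzyme and compound (`score_mode:
weighted`); a `distinct` mode counting each mapped entity once is provided
because raw-count and entity-count readings of "hits per pathway" are both
defensible.  Weighted is the default: it preserves the frequency
information the two upstream tables were built from.

Metabolites deliberately enter the pathway score even though they are
derived from the enzymes: a pathway whose member compounds are produced by
several *different* neighborhood enzymes accumulates corroborating hits
that an enzyme-only count would miss.  Compound frequencies are recounted
per neighborhood (a compound shared by two enzymes in one window counts
once), never summed over enzymes.

### Homolog selection

Similarity follows the conventions of pairwise-genome similarity databases:
Smith–Waterman local alignment with BLOSUM62, affine gaps costing
`11 + k·1` for a gap of length *k*, a stored-pair floor of score 100, and
bidirectional best hits (BBH) between genome pairs as the orthology proxy.
The homolog list for a query is its BBH partners at or above the amino-acid
identity cutoff (default 40%), at most one per genome, ranked by score with
lexicographic tie-breaks, truncated to the requested count (default 100);
the query's own neighborhood is always analyzed alongside.  Percent
identity uses the full alignment length, gap columns included, in the
denominator (the BLAST convention).  A cutoff near 40% is the working
boundary between functional homologs and mere family membership; pushing it
lower pulls in same-family regulators of different function, higher filters
true homologs away.

Alignment is delegated to Biopython's `PairwiseAligner` (Gotoh algorithm).
The test suite verifies it against an independent exhaustive
dynamic-programming reference (`tests/oracles.py`) on hundreds of random
sequence pairs, and verifies all three summary tables against brute-force
recounts.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_homologs` | 100 | maximum homologs (≤ 1 per genome) |
| `n_neighbors` | 10 | window half-width in genes; 5–20 is the useful range |
| `aa_idc` | 40% | amino-acid identity cutoff for homologs |
| `score_mode` | weighted | pathway scoring (see above) |
| `exclude_compounds` | off | optional currency-metabolite blacklist (H2O, ATP, NAD(H), …) |

Currency-metabolite exclusion ships as an opt-in list
(`funcdisc.context.CURRENCY_COMPOUNDS`) rather than a default because the
reference tables a user supplies may already curate their compound sets.

### Degenerate inputs and tie-breaking

All rankings sort by count descending, then identifier ascending, so equal
evidence resolves deterministically; two runs on identical inputs produce
byte-identical HTML and JSON (timestamps are omitted unless explicitly
requested).  Windows truncate at the ends of linear replicons and wrap on
circular ones without ever duplicating a gene.  An enzyme absent from the
reaction table contributes no metabolites; an enzyme or compound absent
from the pathway table contributes no pathway hits — a populated enzyme
table with an *empty* pathway table is a legal and meaningful outcome
(typical for transport ATPases, which often carry an EC number but no
pathway membership), and the report renders all five sections regardless.

## The synthetic pangenome

Because the pipeline's inputs are normally a database snapshot, the package
ships a generator that fabricates a pangenome with known ground truth: each
genome is one circular replicon carrying a TR ortholog and, with
probability `conservation_prob`, an intact cluster of `cluster_size` enzyme
genes immediately beside it, every cluster EC mapped to one planted
pathway.  With the complementary probability the cluster is relocated to a
uniform random position or deleted, with odds `rearrangement_rate :
indel_rate`.  Decoy ECs — grouped into decoy pathways of the same size as
the planted cluster, so no pathway is structurally favored — are scattered
uniformly, one gene each per genome.  Ortholog sequences are a shared
random ancestor mutated at 3% of sites (~97% identity, comfortably above
any cutoff up to 90%); decoy sequences are independent random proteins,
whose pairwise scores stay far below the score-100 floor and therefore
never enter the similarity table.  The similarity table itself is computed
by running the package's own BBH machinery over the generated proteomes,
not written from the ground truth.

Default study conditions: 20 genomes × 45 genes, cluster of 4,
conservation 0.8, rearrangement 0.1, indel 0.05, 8 decoy ECs, proteins of
50 residues.  Forty-five genes per genome keeps the default ±10-gene window
well under half the replicon, so a relocated cluster genuinely leaves the
neighborhood; the protein length keeps all-vs-all alignment of a 20-genome
pangenome around ten seconds on one core.

What the generator does **not** emulate: phylogenetic structure (all
orthologs are independent draws around one ancestor, so there is no tree
correlation), operon strandedness, intergenic distances, paralogy, partial
cluster decay, or annotation error beyond outright absence.  Passing the
planted-pathway tests therefore demonstrates that the counting and ranking
machinery recovers a contextual signal of realistic strength from realistic
perturbation rates — not that real databases are this clean.

## The binding model

Anisotropy titrations are fitted with the Hill saturation form

    ΔA(E) = ΔA_T · E^H / (K_d^H + E^H)

by unweighted nonlinear least squares (`scipy.optimize.least_squares`,
positivity bounds, tight tolerances), initialized at H = 1, ΔA_T = max
observed ΔA, and K_d = the concentration nearest half-max signal.  The
functional form satisfies ΔA(0) = 0 and ΔA(K_d) = ΔA_T/2 for any H; it is
the standard single-site saturation curve generalized with a cooperativity
exponent, the default choice for plate-reader anisotropy data when no
mechanistic competition model is warranted.  Fits are unweighted, matching
the plain least-squares treatment typical of such data.  Standard errors
come from the Jacobian at
the optimum (`s²·(JᵀJ)⁻¹`); non-convergence is flagged on the result, not
raised.  Units (nM for protein–operator titrations, mM for effector
conditions) are carried as tags and never converted.

`scripts/acceptance.py` regenerates the recovery study — 50 replicate
12-point log-spaced titrations per condition, 2% Gaussian noise, reference
affinities 19.0 nM and 2.1 mM — and reports the mean fitted K_d for each.
Problem sizes throughout the test suite (6–20 genomes, 12–45 genes,
50-residue proteins, 50 fit replicates) were chosen as the smallest at
which each property is meaningfully exercised.

## Known limitations

- No statistical significance testing: rankings are raw counts, as the
  method's evidence is meant to be read comparatively, not inferentially.
- No operon-boundary or strand-aware modeling; windows are purely
  positional.
- BBH orthology is a proxy; in-paralogs and fission/fusion events are
  outside the model.
- The Hill fit models a single binding transition; competitive-effector
  mechanisms are not modeled, so effector-condition K_d values are
  *apparent* constants.
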