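# Methods

## The problem

Profile-HMM searches (HMMER against Pfam-style family libraries) score each
candidate domain hit on a protein independently. Curated per-family bit-score
thresholds ("gathering" thresholds, T_i) then separate trusted hits from
noise, discarding genuine domains that score just below threshold and keeping
an occasional high-scoring false positive. Domains, however, are not
independent: family pairs co-occur on proteins in strongly non-random ways.
`domctx` exploits this by scoring each candidate *in the context of the other
selected candidates* and solving, per protein, for the score-maximal
consistent set.

## Context scores

**Corpus.** The training input is a database of domain architectures — each
protein's ordered list of domain families, repeats included. Architectures
observed in only one sequence are removed (they are disproportionately
erroneous); the family universe size n is recomputed from the survivors.
Two architectures are identical only as exact ordered lists.

**Counts.** Let e_ip be the number of domains of family i on protein p and
e_p the total. Only multidomain proteins (e_p ≥ 2) contribute:

    c_ij = Σ_p e_ip · e_jp / (e_p − 1)            (i ≠ j)
    c_ii = Σ_p e_ip · (e_ip − 1) / (e_p − 1)

The denominator makes each protein contribute exactly e_p to the grand total
c = Σ_ij c_ij (ordered pairs), so long proteins do not dominate; the diagonal
form prevents a domain pairing with itself while still crediting genuine
repeats. Mass conservation is asserted by unit test for random corpora.

**Probabilities and log-odds.** With regularization α (default 1) spread
uniformly over the n² ordered pairs,

    p_ij = (c_ij + α/n²) / (c + α),    Σ_ij p_ij = 1 by construction.

Against the uniform null q_ij = 1/n² (random hits at permissive E-values land
approximately uniformly across families), the context score in base-b logs
(default b = 2, bits, matching HMM bit scores) is s_ij = log_b(p_ij/q_ij).
Every zero-count pair collapses to the same closed-form penalty

    s_unobs = −log_b(1 + c/α) ≤ 0,

stored once; observed pairs with negative raw scores are floored to 0, so
observed pairs are never penalized. Self-pairs are first-class: repeated
domains earn context with each other.

## Selection model

For one protein, candidates P are all hits passing a permissive domain
E-value cutoff (default E ≤ 1). For a subset D and i ∈ D the
context-adjusted score is

    S_{i,D} = (H_i − T_i) + Σ_{j ∈ D, j≠i, j non-overlapping i} C_ij.

We maximize the total score — node weights H_i − T_i plus context-edge
weights over non-overlapping selected pairs — subject to (a) overlapping
pairs in D must be curated allowed-nesting pairs, and (b) S_{i,D} ≥ 0 for
every i ∈ D. With all C_ij = 0 constraint (b) reduces to the plain
threshold H_i ≥ T_i. Context edges exist only between non-overlapping
pairs; allowed-nested pairs coexist without exchanging context.

**Edge counting.** Summing S_{i,D} over D counts each context edge twice;
the graph formulation (node plus edge weights) counts it once. The two can
disagree in argmax, so both are implemented: `edge-once` is the default
objective, `edge-twice` a config mode. The feasibility constraint is the
same in both.

**ILP.** One binary x_i per candidate, one x_ij per non-overlapping pair,
linearized by x_ij ≤ x_i, x_ij ≤ x_j, x_ij ≥ x_i + x_j − 1; disallowed
overlaps give x_i + x_j ≤ 1; constraint (b) is enforced conditionally via
big-M with M_i = |H_i − T_i| + Σ_j |C_ij| + 1. Solved with HiGHS through
`scipy.optimize.milp`. Correctness is certified against an exhaustive
enumeration oracle (independent code path) on hundreds of seeded random
instances of up to 15 candidates; feasibility tolerance is S_{i,D} ≥ −1e−9
to absorb float noise. A safe preprocessor removes any candidate whose
normalized score plus best-case positive context is negative (it can never
satisfy (b)), iterated to a fixed point; the optimum is provably unchanged.

An optional per-family sequence-threshold hook exists in the problem
interface but defaults to disabled; the selection model above is complete
without it.

**Tie-breaking.** The enumeration oracle prefers, at equal total score,
larger selections and then the lexicographically smallest hit_id tuple (so a
hit at exactly H = T is kept). The ILP guarantees score equality, not
argmax identity; all cross-checks compare scores.

## Baselines

* `standard_filter`: keep H ≥ T. No published rule fixes how disallowed
  overlaps among passers are resolved; we use greedy admission by descending
  H − T (tie: hit_id), configurable in spirit via the E-value variant.
* `extended_ga_filter`: all thresholds shifted by δ bits (antitone in δ).
* `evalue_filter`: keep E ≤ cutoff, greedy by ascending E-value.
* `codd_filter`: positive-context transfer — candidates in ascending
  E-value order join the prediction set iff their family has positive
  context with a *trusted* (threshold-passing) member and they introduce no
  disallowed overlap. Promoted candidates do not promote others, so two
  sub-threshold candidates can never rescue each other — the structural gap
  the exact optimizer closes.
* `ncodd_filter`: adds a negative step — iteratively remove members forming
  never-observed pairs with members of strictly higher normalized score,
  weakest first, to a fixed point. The published version of this rule is in
  an unavailable supplement; this variant implements the documented
  "double positive and negative" semantics and is labelled non-canonical.

The positive network for the transfer filters defaults to the strictly
positive pairs of the log-odds network; excluding self-pairs or adding a
hypergeometric count filter (the published transfer-filter network) can be
emulated by passing a reduced positive-pair set.

## Benchmarks

**Estimated FDR.** Each protein's residues are permuted uniformly
(composition and length preserved) and the shuffled copy is concatenated
*after* the real sequence, so context acting from real domains can rescue
noise on the shuffled half — the failure mode a context method must be
charged for. Predictions are attributed to the shuffled portion when > 50%
of the envelope lies past the boundary (ties to real; strict containment is
a config option — the attribution of straddling hits is our choice, made for
determinism and lack of bias). With R the per-protein real-sequence count
and A the per-protein shuffled-portion count averaged over the replicates
(default 20), FDR = mean(A)/mean(R). The FDR of only the *novel* domains a
context method adds is (A − A_n)/(R − R_n), with the n-subscripted counts
from a negative-context-only run; this difference form is a reconstruction
of the described procedure.

**Ortholog coherence.** Hits are mapped through each protein's row of its
ortholog group's multiple alignment (gap characters consume columns, not
residues). A predicted domain's coherence is the fraction of the *other*
group members (denominator: group size − 1; in-paralogs count like
orthologs) with at least one same-family prediction overlapping it by ≥ 1
alignment column (no minimum overlap fraction). A method's score is the
unweighted mean over all predicted domain instances; groups larger than 13
members are excluded. True domains are conserved across orthologs, so
coherence is inversely related to the spurious-prediction rate.

## Synthetic data

The generator emulates the statistical structure the method consumes, not
protein evolution:

* **Architectures** — template-based: one template per planted enriched
  pair (default 10 pairs at weight 10 vs background 1) plus random
  background templates (lengths 1–5, small repeat probability); every
  template is emitted ≥ 2 times so default corpora survive singleton
  filtering. Defaults: 50 families, 500 proteins — large enough for planted
  pairs to dominate the count matrix, small enough for second-scale tests.
* **Hits** — scores are drawn directly in bit-space relative to T_i (the
  method consumes scores, not sequences): true domains at offset
  N(3, 4²) — roughly a quarter sub-threshold, where only context can
  recover them — laid without overlaps in architecture order; decoys
  (Poisson, mean 1/protein) carry families foreign to the architecture,
  offsets uniform in (−0.9, −0.1) (inside the E ≤ 1 pool, never above
  threshold). E-values are the monotone transform E = 2^(−offset−1).
* **Ortholog groups** — one architecture per group, members derived by
  point substitution only (rate 0.05), so alignments are trivially
  consistent and zero-dropout coherence is exactly 1.
* **Proteomes** — i.i.d. uniform amino-acid sequences for the shuffling
  benchmark's noise controls.

What passing these fixtures does *not* show: robustness to correlated HMM
score errors, alignment artefacts, gene-model errors, or realistic family
abundance distributions — real corpora have heavy-tailed architecture
frequencies this generator does not model.

## Numerical and design choices

* Coordinates 1-based inclusive; overlap is ≥ 1 shared residue (no
  tolerance). Allowed-overlap legality is an unordered family-pair relation
  (nesting direction not modelled).
* Scores are plain floats serialized at 17 significant digits; writers sort
  canonically so outputs are byte-deterministic.
* Problem sizes in the test and acceptance runs (300–500-protein corpora,
  150-protein noise proteomes, 500 oracle cross-check instances of ≤ 15
  candidates) were sized so Monte-Carlo standard errors sit well inside the
  asserted bands while a full run stays in the tens of seconds.
* Known limitations: the overlap-resolution rule inside the standard filter
  is a convention, not a reproduction; nCODD is a documented variant; the
  published transfer-filter network file is not reproduced.
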