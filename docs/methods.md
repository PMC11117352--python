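# Methods

## Scope and model

`tetraltr` annotates full-length LTR retrotransposons in nucleotide
assemblies by structure alone: an element is a pair of similar direct
repeats (the LTRs, 100–1500 bp) bounding a 4–10 kb span that encodes the
retroelement polyproteins. Downstream it applies the survey protocol for
compact tetraodontiform genomes: length filter (4–10 kb inclusive), 4 kb
flank extension before translation, a full-length verdict (LTRs at both
ends ∧ an encoded ORF strictly longer than 500 aa ∧ a reverse-transcriptase
domain hit), greedy clustering at 50% identity, consensus building, family
and superfamily classification against an RT/Pol reference panel with
structural overrides, and insertion-time estimation t = K/2r.

Internally all coordinates are 0-based half-open; emitted GFF3 is 1-based
inclusive and round-trips through the bundled reader. IUPAC ambiguity codes
collapse to N on input; translation uses the standard genetic code
(vertebrate nuclear sequences).

## Detection

Seed-and-extend over exact k-mers (default k = 13): two occurrences of a
k-mer separated by an element-compatible distance seed a diagonal; seed
runs on one diagonal merge across gaps up to 500 bp and extend without gaps
under an X-drop rule (X = 20, match +1/mismatch −1). The extended repeat
pair is kept when both copies are 100–1500 bp, do not overlap, and align at
≥ 80% identity. Direct-repeat geometry is orientation-symmetric — an
element inserted on the minus strand still presents its LTR pair as a
plus-strand direct repeat, and the TG…CA terminus motif is its own reverse
complement — so a single plus-strand scan covers both strands; element
strand is resolved later from ORF orientation.

Overlapping candidates are resolved by **maximum-total-score weighted
interval scheduling** (score = identity × mean LTR length, ties to the
leftmost start). For a conflicting pair this reduces to "keep the higher
score"; its value is for chimeras: a candidate pairing the 3′ LTR of one
insertion with the 5′ LTR of a same-family neighbour conflicts with *two*
true candidates whose combined score always wins. TG…CA termini and 4–6 bp
target-site duplications are annotated, never used as filters.

## Annotation

ORFs are maximal stop-to-stop runs in all six frames. The full-length
verdict uses the strict > 500 aa criterion; domain scanning and layout
typing consider ORFs down to 100 aa, because gag (≈ 220–450 aa) and env
ORFs are routinely shorter than 500 aa. Domains (GAG, POL, RT, RH, INT,
ENV) are detected by affine-gap Smith–Waterman against per-column log-odds
score models (bits; default +3 consensus / −1 otherwise, gap open 10,
extend 2, threshold 25 bits), a deliberately lightweight stand-in for
profile HMMs that keeps scoring exact and dependency-free. The bundled
profiles and the reference panel are *synthetic*, built from fixed
consensus peptides shared with the genome generator; they are internally
consistent with every synthetic benchmark but are not distilled from
curated seed alignments, so hit sets on real assemblies will differ from
any published HMM-based annotation.

The integrase catalytic triad is located inside the best INT hit as the
ordered D..D..E triple whose residues deviate least from the model's
catalytic columns under the hit alignment (ties → leftmost D1). Spacing
D2→E of 35 aa is flagged canonical (the conserved geometry in Gypsy, Copia
and ERV integrases); BEL-PAO integrases are modelled with spacing 42 to
reproduce that superfamily's heterogeneity. The triad is reported, never
filtered on.

Layout typing: an ENV hit ⇒ `gag+pol+env`; one ORF carrying GAG plus a
pol-region hit (POL/RT/RH/INT) ⇒ `gag-pol fused` (the Gmr/Mag pattern); no
GAG hit anywhere ⇒ `pol-only` (CsRN1/BEL-PAO/Orthoretrovirinae pattern);
otherwise `gag+pol`.

## Identity, clustering, classification

Pairwise identity is matches / alignment columns (terminal gaps included)
under global affine alignment. The default scoring is the stringent
clustering-tool convention (match +2, mismatch −4, gap open −20, extend
−2): under permissive scores (e.g. match 1/mismatch −1/gap −2) two
*unrelated* DNA sequences align at > 50% "identity", which would make a 50%
clustering threshold meaningless; under the default, unrelated DNA scores
≈ 40%. For long nucleotide pairs the library uses a fast path: a k-mer
containment gate (≥ 0.05 at k = 13, i.e. pairs diverged by ≲ 20%
substitutions) followed by edit-distance alignment, which is exact for
substitution-dominated divergence; pairs failing the gate are reported as
0% since they cannot reach the clustering threshold. The gate is the fast
path's operating regime, not a biological claim — exact identities for
distant pairs are available via `method="affine"`.

Greedy clustering is longest-first (ties by id); each sequence joins the
first centroid at ≥ 50% identity, else founds a cluster. Element sequences
are extracted in coding orientation before clustering. Consensus building
is center-star around the longest member: per-column majority base,
lexicographically smallest base on ties, majority-gap columns dropped.
Majority voting over two members is tie-dominated, so classification
queries prefer the longest RT-bearing ORF among member records over the
consensus ORF.

LTR boundary refinement re-calls termini on consensuses of clusters with
≥ 3 members (repeat-pair search restricted to element-end geometry);
smaller clusters adopt the best already-defined end LTR by infix alignment
at ≥ 70% identity, or are flagged (never dropped).

Classification takes the best-hit identity of the cluster's RT-bearing ORF
against the reference panel (floor 20%, below which the family is
`unclassified`), with structural overrides resolved in favour of structure
and recorded: an env layout forces the ERV superfamily; a fused gag-pol
layout restricts to Gmr/Mag. The distance tree is standard neighbor-joining
on (100 − identity)/100 with deterministic tie-breaks (lowest-index pair)
and negative branch lengths clamped to zero — a classification aid, not a
maximum-likelihood phylogeny.

## Divergence and insertion age

`count_divergence` computes transition (P) and transversion (Q) proportions
over gap/N-free columns; `kimura2p` applies
K = −½ ln((1 − 2P − Q)·√(1 − 2Q)), returning a NaN sentinel on saturation
(excluded from landscapes with a logged count). Equal-length pairs are
compared positionally — under the substitution-only model an edit alignment
would trade mismatches for spurious indels and deflate P and Q; unequal
lengths fall back to edit alignment.

Clock convention: the generative reading of t = K/2r assigns each copy an
expected divergence K = 2·r·t from its ancestor (r = 1e-8
substitutions/site/year by default). Consequently the two LTRs of one copy,
mutating independently from an identical state, separate at 4r per year,
and `inter_ltr` mode converts with t = K/(4r). Both modes recover true age
on the generator; `vs_consensus` is the default (dating against the family
representative) and `inter_ltr` is exact per copy. Consensus-based dating
of very small families is biased toward the family mean age because the
consensus interpolates between members — visible in any 2-member cluster.

Age landscapes bin genome coverage (percent of genome length) per family in
1 My bins from 0; a family is flagged recently active when its modal bin
lies below 5 My.

## Synthetic genomes

The generator implants elements built from nine family templates matching
the tabulated survey geometry (consensus 4337–9854 bp, LTRs 174–1116 bp,
the four ORF layouts, fused gag-pol for Gmr/Mag, env for the epsilon
retrovirus template). Template LTR pairs start identical; copies are aged
by drawing every site independently from the exact two-parameter
substitution probabilities (kappa = 2 by default), so the K2P estimator is
exactly self-inverting on the generator at any divergence. Substitutions
that would create an in-frame stop inside a template ORF are retargeted to
another base (or, rarely, reverted) — emulating the purifying selection
that keeps recently active elements coding-intact; without this, neutral
mutation destroys a 1000-codon ORF with ~95% probability already at 2%
divergence and no decayed copy could satisfy the full-length criteria.

The background is i.i.d. with configurable GC (default 0.45) so detection
precision is well-defined. Implants are placed uniformly, non-overlapping,
with a default minimum gap of 10 kb — the element-length upper bound — so
no pair of distinct insertions can mimic a single element's repeat
geometry and per-implant recall/precision stay attributable; the gap is
configurable down to 0 for stress tests. Truncated copies lose the 5′ LTR
plus 30–60% of the internal region; solo LTRs are a single LTR copy; about
30% of copies insert on the minus strand. No indels, no nested insertions,
no recombination dynamics in v1.

What passing tests therefore do *not* show: robustness to indels and
assembly gaps, to nested/fragmented repeats, to non-uniform base
composition, or to real domain sequence diversity — the synthetic profiles
recognise exactly the domain cores the generator embeds.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
genomes of 0.2–1 Mb, ≤ 30 implants, 100 replicates for clock-recovery
checks, 10⁴ sites for the K2P inversion — sizes at which every stage's
expected behaviour is analytically checkable. Deterministic tie-breaks are
documented at each operation (leftmost candidate, lexicographic consensus
base, lowest-index NJ pair, leftmost D1); all sampling flows from one root
seed per run. The survey's published per-genome counts depend on ten real
assemblies and unspecified external-tool parameterizations, so they are
shipped as versioned TSV tabulations consumed by the reporting
aggregations rather than being re-derived from raw data; the tabulated
819 full-length sequences and the 443 element-table copies are kept
verbatim without attempting the reconciliation the source leaves open.
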