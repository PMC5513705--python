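# Methods

## Scope and data model

`vircomp` operates on three inputs: an OTU count table with a taxonomy map
(amplicon community structure), a gene annotation table split into a
`virome` and a `microbiome` fraction (the tabular output of upstream
orthology/pathway alignment — we consume such tables, we never run the
alignments), and a pathway database. A pathway is a directed
compound–reaction hypergraph: compounds are nodes; a reaction consumes a
substrate *set* and produces a product *set*. Compounds carry two flags that
anchor all downstream semantics: `is_seed` (an input assumed available to
the cell, including compounds whose upstream producers were collapsed away
because nothing was detected for them) and `is_target` (a product the host
is assumed to require). Multi-subunit enzymes are complex records with a
subunit list; two-component signalling is a rule record
(signal, sensor, regulator, effects), where each effect activates or
inhibits a reaction or complex.

## Reachability

Reachability is a conjunctive fixed point: starting from the seeds, a
reaction fires when **all** of its substrates are reachable, adding its
products; reversible reactions fire in either direction; iteration stops at
the fixed point, reached in at most `|reactions| + 1` sweeps. Conjunctive
firing is the conservative metabolic convention; currency metabolites and
cofactors are deliberately not encoded rather than special-cased, so they
never block firing. Transformations drawn as two opposed arrows with
distinct enzymes (e.g. thioredoxin ⇌ thioredoxin-disulfide) are encoded as
two irreversible reactions, not one reversible one, so that each enzyme's
fraction of origin stays attached to its own direction.

## Presence calls

A reaction's origin is `microbial`, `viral`, `both`, or `absent` according
to which fraction(s) contain a gene matching its enzyme. EC match is
preferred; when a reaction has no EC the gene symbol (carried in the
annotation table's `ko` column) matches case-insensitively. EC strings are
normalized by stripping an optional `EC ` prefix, trimming and lowercasing;
partial ECs ending in `-` match only identical partial strings. A reaction
is viral-unique only if no gene in the microbiome matches its enzyme;
identical substrate→product edges carried by *different* enzymes in the two
fractions remain viral-unique (and typically classify as `parallel_branch`),
because the host demonstrably does not encode that enzyme.

## The compensation classifier

For each viral-unique reaction, with `M` = reactions of origin
`microbial`/`both` (a `both` reaction is available to the host and routes as
microbial) and `detected` = `M` plus viral reactions, the decision order is
fixed:

1. **disconnected** — the reaction's substrates are not reachable from the
   seeds even using all detected reactions;
2. if every product is reachable from the reaction's *own substrates* via
   `M` alone: **shortcut** when the shortest microbial cascade needs more
   than one reaction step, **parallel_branch** when one step suffices. Route
   length is the sweep index at which the product first appears in the
   conjunctive closure started from the reaction's substrates (substrates
   only — seeds are not added, so a product that happens to be a seed is not
   spuriously "already reachable"). Reactions firing in the same sweep count
   as one step; since the class boundary is 1 versus >1 step, this agrees
   exactly with a minimum-reaction-subset route definition, which is what
   the brute-force oracle in the test suite enumerates;
3. otherwise (some product microbially unreachable): **gap_fill** when a
   product is itself a declared target, or when some declared target is
   reachable with the reaction but not without it (a target downstream of
   the product via detected reactions); **branch_extension** otherwise.

Complexes: `microbial` if every subunit is annotated in the microbiome,
`viral` if every subunit is in the virome, `combined_only` if the full set
exists only when pooling fractions, `absent` otherwise, checked in that
order; `viral` and `combined_only` count as `complex_completion`.

Regulation: a rule's regulator is active iff its signal is in the scenario
and its sensor, when declared, is annotated in either fraction (a viral
sensor can thus drive host regulation). An active regulator suppresses
inhibited targets regardless of origin and expresses activated targets whose
status is not absent. `regulatory_rerouting` is flagged when an activated
target is expressible only through viral (or combined-only) genes while a
microbial alternative is suppressed within the same rule. Default scenarios
are one per distinct signal in the database plus the empty scenario, so
mutually exclusive signals (nitrate versus oxygen) are evaluated separately.
A pathway is *compensated* iff at least one element classifies into
{gap_fill, shortcut, parallel_branch, branch_extension, complex_completion,
regulatory_rerouting}. Classification is presence-based; no claim is made
about in-vivo expression, activity or flux.

The packaged six-pathway fixture encodes the published vent compensation
panels. Two encoding choices were genuinely open: (i) the arabinose branch
declares only its end product (the undecaprenyl-phosphate sugar) as a
target, with the two detected microbial steps that connect the viral
aminotransferase's product to it encoded explicitly, so the `gap_fill` call
falls out of reachability rather than being asserted; (ii) the oxygen
activation of the viral nitrate reductase is a rule without a sensor, and
the viral sugar-phosphate sensor UhpC is encoded as the sensor of a
hexose-phosphate rule whose transporter target is undetected — the
two-component pathway's compensated flag is carried by the all-viral Nar
complex and by rerouting under the nitrate/nitrite scenarios, either of
which suffices.

## Diversity estimators

Shannon uses natural log; its 95% CI is the normal approximation with
`var(H) = [Σ pᵢ ln²pᵢ − (Σ pᵢ ln pᵢ)²]/N + (S−1)/(2N²)`. Simpson is the
finite-sample **dominance** form `D = Σ nᵢ(nᵢ−1)/(N(N−1))` (not 1−D, not
1/D) — the probability that two reads drawn without replacement share an
OTU — with CI from the asymptotic variance `var(D) ≈ 4/N (λ₃ − λ₂²)`,
`λₖ = Σ pᵢᵏ`, truncated to [0, 1]. These CI constructions are this package's
documented choice; published tables produced by other software may use a
different construction, and no reproduction of any particular published
interval is claimed. Good's coverage is `(1 − F₁/N)·100`. Rarefaction is the
exact hypergeometric expectation evaluated with log-gamma functions;
resampling appears only as a Monte-Carlo oracle in the tests. For Venn
regions, an OTU is present in a sample iff its count is nonzero.

## Synthetic generators

`generate_community` emulates the structure of a low-diversity vent
amplicon study. Defaults (chosen once, as the study conditions): 3 samples,
16 OTUs per sample, read depth 60,000, dominant family share 0.85, 8 OTUs
shared by all samples, symmetric-Dirichlet(1.0) abundances for the
non-dominant OTUs, multinomial reads. To make "exactly `n_shared_otus` OTUs
nonzero in every sample" hold at any finite depth, each of a sample's OTUs
receives one guaranteed read and the multinomial probabilities are rescaled
(`p′ᵢ = (depth·pᵢ − 1)/(depth − k)`) so expected relative abundances are
unchanged; Dirichlet weights too small for one expected read are clipped to
zero extra probability (bias O(k/depth)). The generator is structural: it
reproduces dominance, sharing and depth, not any real community's abundance
vector, read errors, chimeras or sequence content — passing tests say the
estimators and classifier behave correctly on tables with this structure,
not that any field study's numbers are recovered.

`generate_annotations` plants ground-truth compensation events into linear
microbial chains (seed → … → target, 4–8 reactions by default). Events are
placed at chain positions at least three steps apart, which provably
prevents interaction between planted events (a shortcut's two-step microbial
route never overlaps a gap, a gap is never bridged by a planted bypass), so
the classifier's output must equal the label file exactly; infeasible
requests fail with a parameter error rather than silently dropping events.
Ground truth is emitted as a sidecar label table, never re-derived.

## Numerical and formatting choices

All randomness flows through a single integer seed per generator call
(numpy `default_rng`). Output tables are sorted on stable keys, so reruns at
a fixed seed are byte-identical. Reports print percentages to 2 decimals and
indices to 2 decimals (4 internally); the diversity report's header comments
state the exact formulas used. Degenerate inputs fail loudly: empty samples,
N < 2 for Simpson, rarefaction depth beyond the sample, missing taxonomy
entries (naming the OTU), unknown regulatory signals (naming the
vocabulary), dangling compound references (naming pathway and id).

## Problem sizes used in the checks

The randomized verification uses deliberately small instances where
exhaustive oracles are tractable: reachability against a naive
repeated-scan fixpoint on 200 random graphs (≤6 compounds, ≤6 reactions);
the classifier against a subset-enumeration route oracle on ~150 random
pathways of the same size; exact ground-truth recovery on 100 random planted
scenarios (6–8 pathways each); rarefaction against 10,000-fold resampling on
50 random tables (S ≤ 10, N ≤ 50). These sizes give exhaustive or tight
Monte-Carlo guarantees while keeping the default suite fast.

## Known limitations

No stoichiometry, flux, thermodynamics or SBML import; no OTU clustering or
read-level processing (tables in, tables out); route length ignores enzyme
kinetics; the gap-fill necessity test is evaluated against the detected
reaction set, so redundant viral routes to the same target each classify by
their own necessity; complex status checks subunit presence only, not
stoichiometry or operon structure.
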