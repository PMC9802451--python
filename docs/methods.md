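# Methods

## Scope and model

`regulogic` quantifies the *regulatory logic* of Boolean network models:
each node of such a model carries a k-input Boolean update rule
f : {0,1}^k → {0,1}, and the package asks how special the rules used in
biological models are, relative to the space of all 2^(2^k) functions.
It implements:

* the standard biologically meaningful rule classes — effective (EF),
  unate (UF), canalyzing (CF), nested canalyzing (NCF) and read-once
  (RoF) functions — as executable classifiers;
* two rule-complexity measures: the **Boolean complexity** (literal
  count of a shortest AND/OR/NOT formula) and the **average
  sensitivity** S_f (expected number of output-changing single-input
  flips under a uniform input distribution);
* Hart's edge-maximizing vertex sets ("good sets") on the k-cube, which
  realize the minimum of S_f at fixed bias P and connect that minimum
  to the NCF class;
* census, enrichment and network-level machinery to compare a reference
  rule collection against the uniform random ensemble.

## Conventions

**Row order.** The output for the assignment (x_1, …, x_k) is stored at
row index m whose bit i−1 equals x_i, i.e. x_1 is the least-significant
bit. Printed truth-table strings are most-significant row first, so a
string reads like cube vertex labels x_k…x_1. A `--bit-order lsb` /
`lsb_first=True` dialect is accepted everywhere strings are parsed.

**Isomorphism.** Two rules are isomorphic when they agree up to
permutation and negation of *inputs*; output complementation is not
part of the orbit. `canonical_form` returns the lexicographically
smallest output vector over the 2^k·k! transforms (k ≤ 6).

**Constants.** Constant rules are admitted as truth tables (bias 0 or
2^k). They are ineffective and never NCF/RoF, but they *do* count as
canalyzing: every value of every input forces the output, and the
classical CF counts (4, 14, 120, 3514 for k = 1…4) that the census
reproduces include them. Their Boolean complexity is 0.

**Average sensitivity** is reported unnormalized, in [0, k], so the
dynamical critical regime sits at s ≈ 1. On the k-cube it is
S_f = 2·E01/2^k, where E01 counts edges joining vertices with differing
outputs; E01 + 2·E11 = k·P ties it to the count E11 of edges internal
to the "on" set.

## Boolean complexity pipeline

Finding a literal-minimal formula is computationally hard, so the
estimate follows logic-synthesis practice with fully deterministic
tie-breaks:

1. Four seed expressions are built for the function: the full DNF, the
   full CNF, and exact-minimum two-level forms in both polarities from
   Quine–McCluskey prime implicants with a Petrick-style branch-and-
   bound cover (objective: fewest terms, then fewest literals, then
   lexicographically smallest sorted implicant list).
2. Each seed is factored by recursive single-literal division: the most
   frequent literal is extracted as a divisor (ties: lowest variable
   index, positive before negative), recursively on quotient and
   remainder.
3. The shortest of the four factored results is reported, an upper
   bound on the true Boolean complexity.

For k ≤ 4 an exact dynamic program provides the gold standard: cost-1
functions are the 2k signed literals, and the cost-s set is every
g ∧ h / g ∨ h with cost(g) + cost(h) = s; the first level at which a
function appears is its true complexity. (Negations need never appear
on internal nodes: De Morgan rewriting preserves literal counts.) The
default budget is 16 literals — enough for every 4-input function; the
4-input parity function is the worst case at exactly 16.

On the 238 isomorphism classes of 4-input functions with P ≤ 8, the
four-seed estimate exceeds the exact value on 62 classes, by at most 6
literals; it is exact on every NCF and RoF.

## Good sets

Hart's recursion places P vertices on the k-cube to maximize E11: find
r with 2^r < P ≤ 2^(r+1), fill one r-subcube, and recurse with P − 2^r
on the sibling r-subcube. The construction here fixes every free
choice: recursion always splits on the highest free coordinate, fills
the half where it is 0, descends into subcubes with higher coordinates
set to 1, and takes the all-ones vertex as the P = 1 base case. Reading
the binary digits of P (k bits, most significant first) then yields a
nested canalyzing chain directly — digit 1 ↦ ~x_c followed by OR,
digit 0 ↦ x_c followed by AND, with c running from k down to 1 — so odd
P induces an NCF and even P (trailing zero digits) induces an
ineffective function whose truncation is an NCF on k − t variables,
where t is the number of trailing zeros. Optimality and the
minimum-sensitivity property are verified against brute-force
enumeration over all C(2^k, P) placements for k ≤ 4 in the test suite.

## Catalogs and census

NCF catalogs enumerate every chain X_σ(1) ⊙ (X_σ(2) ⊙ (… X_σ(k)))
over permutations σ, sign choices and operator choices, deduplicating
truth tables. RoF catalogs are generated recursively: the functions
over a variable set V are every g ⊙ h with g, h read-once functions
over the two blocks of a bipartition of V, base case the signed
literals. Both generations enumerate all variable orders, so the
resulting truth-table sets are closed under isomorphism and membership
is a direct lookup. Counts through k = 6:

| k | NCF | RoF |
|---|-----|-----|
| 1 | 2 | 2 |
| 2 | 8 | 8 |
| 3 | 64 | 64 |
| 4 | 736 | 832 |
| 5 | 10 624 | 15 104 |
| 6 | 183 936 | 352 256 |

The RoF counts independently equal (number of two-terminal
series-parallel networks with k labeled edges) × 2^k signs:
52·16 = 832, 472·32 = 15 104, 5504·64 = 352 256 — a useful external
cross-check on the generator. The default catalog bound is k = 6
(configurable; generation at k = 6 takes a couple of seconds).

Full-space scans classify all 2^(2^k) functions for k ≤ 4 (about a
second at k = 4 using bitmask arithmetic); k = 5 scans exist behind an
explicit opt-in. Fractions with huge denominators use exact integer
arithmetic and are rendered to 3 significant digits.

## Enrichment statistics

For a reference collection, the per-k abundance f1 of a type is
compared to the full-space fraction f0 through the enrichment ratio
E = f1/f0, and a subtype's excess within an englobing type through
E_R = (f_s1/f1)/(f_s0/f0). Significance uses the exact one-sided
binomial tail P(X ≥ observed | n, f0) — the null that the n rules at
in-degree k are i.i.d. uniform draws (for E_R: that the englobing-type
rules are i.i.d. draws from the full-space englobing set). No
multiple-testing correction is applied. Rules with in-degree above the
catalog bound are classified for EF/UF/CF/NCF by the direct algorithms,
but their RoF status is unknown and they are excluded from read-once
tallies with a logged count.

## Network ensembles

The network average sensitivity of a model is the mean of its nodes'
rule sensitivities. Type-constrained ensembles keep the wiring fixed
and resample every rule uniformly from the type at the node's
in-degree — by catalog index for NCF/RoF/non-NCF RoF, by rejection from
uniform random functions otherwise (exactly uniform; attempts capped at
10^6, after which an error directs the user to catalog types).
Distribution overlap is summarized by the fraction of one sample lying
outside the other's empirical central 95% interval (percentiles by
linear interpolation). The default replicate count per model is 100 (a
package convention).

## Synthetic collections

The fixture generator emulates the gross shape of curated model
compilations so the enrichment and ensemble pipelines run end-to-end
without external data: a categorical in-degree distribution decaying
quickly with k (defaults 0.34/0.28/0.22/0.16 for k = 1…4) and a rule
mixture dominated by NCFs (defaults NCF 0.70, RoF 0.05, CF 0.08,
UF 0.04, EF 0.08, uniform 0.05). Models have 8–16 nodes by default and
regulators drawn without replacement from the model's nodes (self-loops
allowed). Everything is driven by one seeded generator; regeneration is
byte-identical. What the generator does *not* emulate: real in-degrees
above 4 (rejection sampling of unate functions is impractical at k ≥ 5,
so desk-scale defaults stop at 4), degree–degree correlations, biased
regulator choice, or any real network topology — so passing ensemble
tests demonstrate the machinery and the qualitative NCF-vs-random
contrast, not quantitative agreement with any published model set.

## Known limitations and deviations

* Boolean-complexity values for k ≥ 5 are upper bounds (no exact DP).
* The complexity–sensitivity Pearson correlation over 4-input functions
  with P ≤ 8 computes to 0.873 with the four-seed estimates and 0.874
  with exact complexities (the two differ on only 62 of 238 classes).
  Published analyses based on external multi-level synthesis tools
  report a lower value; since even exact literal counts give 0.874,
  that difference traces to the estimation error of those tools, and
  this package reports its own computed value.
* The full-space census at k ≥ 5 covers only catalog types; UF/CF/EF
  fractions at k = 5 require the opt-in slow scan.
* Read-once recognition is catalog-bounded (k ≤ 6 by default); a
  decomposition-based recognizer for larger k is out of scope.
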