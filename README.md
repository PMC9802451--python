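# regulogic

Quantitative analysis of regulatory logic in Boolean network models.

In the logical-modeling framework a gene (or protein) is on or off, and
each node of a network updates through a k-input Boolean function. Only
a vanishing fraction of the 2^(2^k) possible functions looks like
biology: the *effective* functions (every input matters), the *unate*
ones (each input purely activating or inhibiting), the *canalyzing*
ones (some input value forces the output), and their nested refinements
— *nested canalyzing functions* (NCFs), canalyzing layer by layer down
to a single literal, and *read-once functions* (RoFs), writable with
every variable appearing exactly once. This package implements those
classifiers and the two complexity measures that explain why such
rules dominate curated models:

* **Boolean complexity** — the number of literals in a shortest
  AND/OR/NOT formula for f. RoFs achieve the minimum (= k) among all
  effective k-input functions.
* **Average sensitivity** — S_f = ⟨Σ_i f(x ⊕ e_i) ⊕ f(x)⟩_x, the
  expected number of output-changing input flips. With E01 the
  boundary-edge count on the k-cube, S_f = 2·E01/2^k and
  E01 + 2·E11 = k·P at bias P; NCFs attain the theoretical minimum of
  S_f within their k[P] set, via Hart's edge-maximizing "good sets".

On top sit a full-space census (counts and fractions of each type),
enrichment statistics comparing a reference rule collection against the
uniform random ensemble (ratios E = f1/f0 and E_R, exact one-sided
binomial tests), network-level sensitivity ensembles, and a seeded
synthetic-collection generator so every pipeline runs without external
data. See `docs/methods.md` for conventions and algorithms.

## Worked example

The 3-input function given by the DNF
x̄1x̄2x̄3 + x̄1x̄2x3 + x̄1x2x̄3 (9 literals) has a two-level minimum of 4
literals, but factoring reaches the true minimum x̄1(x̄2 + x̄3) with 3:

```
$ regulogic complexity --expr "~x1 ~x2 ~x3 + ~x1 ~x2 x3 + ~x1 x2 ~x3"
function        k       P       boolean_complexity      exact   sensitivity     E01     E11
00010101        3       3       3       False   1.25    5       2
```

The truth-table string `00010101` lists outputs for rows 111…000
(x_1 is the least-significant bit of the row index); the rule has bias
P = 3, Boolean complexity 3, and average sensitivity 2·5/8 = 1.25.

The minimum-sensitivity function at k = 3, P = 5 is built from a good
set — five vertices, five internal edges, and a nested canalyzing
chain:

```
$ regulogic goodset 3 5
vertices        000 001 010 011 111
induced 10001111
E11     5
ncf     ~x3 | x2 & x1
```

A census of all 65 536 four-input functions (constants count as
canalyzing; see the methods note):

```
$ regulogic census --k 4
k       type    count   fraction
4       EF      64594   0.985626
4       IEF     942     0.0143738
4       UF      2170    0.0331116
4       CF      3514    0.0536194
4       NCF     736     0.0112305
4       RoF     832     0.0126953
4       nonNCF-RoF      96      0.00146484
```

Only 1.27% of 4-input functions are read-once and 1.12% nested
canalyzing — the classes that dominate curated biological models.

From Python:

```python
from regulogic import TruthTable, classify, boolean_complexity

tt = TruthTable.from_string("0001")      # 2-input NOR-type rule
profile = classify(tt)
print(profile.is_ncf, profile.is_rof)    # True True
print(boolean_complexity(tt).boolean_complexity)   # 2
```

Other subcommands: `classify`, `catalog` (NCF/RoF catalog generation up
to k = 6), `enrich` (Tables of E and E_R for a reference TSV or BoolNet
file), `netsens` (network average-sensitivity ensembles), and
`fixtures` (seeded synthetic model collections).

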