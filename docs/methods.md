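# Methods

## Model

`fedbn` fits a Tree-Augmented Naive Bayes (TAN) classifier to complete
categorical records. The class variable (fraud type) is a parent of every
feature; feature–feature edges form a spanning tree chosen to maximize the
plug-in class-conditional mutual information, in natural log units. Only the
ordering of edge weights matters for the tree, so the log base is a
documentation convention, not a modeling choice. Zero-count cells contribute
zero to the CMI sum, and tiny negative totals from floating-point rounding
are clamped to zero.

Structure search is Kruskal's maximum-weight spanning-tree algorithm with
ties broken by the lexicographic edge key `(min name, max name)`.
Zero-weight edges remain eligible, so the result is always a spanning tree
even when all features are conditionally independent. The root is the first
feature in canonical schema order (configurable); edges are oriented away
from it by breadth-first traversal with sorted neighbor order. All of this
makes structure learning a deterministic function of the counts.

Parameters are posterior means under a uniform Dirichlet prior ("Bayes"
fitting): θ(k | pa) = (N(k,pa) + iss/(r·q)) / (N(pa) + iss/q), where r is the
child's state count, q the number of parent configurations, and iss the
imaginary sample size — the total pseudo-count spread over the whole CPT.
Defaults: iss = 1.0 (exposed as `--iss`). As iss → 0 rows tend to empirical
frequencies; as iss → ∞ they tend to uniform. With iss > 0 every entry is
strictly positive, which is what lets a station that never observed a class
still receive a proper posterior over it. With iss = 0 an unobserved parent
configuration has an undefined row; we fall back to uniform there rather
than fail.

Prediction multiplies the class prior by one CPT entry per feature, in log
space, and normalizes. Argmax ties go to the first class state in canonical
(lexicographic) order. Records must be complete; missing values are a hard
error by contract — incomplete records are rejected and counted at
ingestion, keeping all estimation complete-data.

## Federation

The federated protocol exchanges *sufficient statistics*, not fitted
parameters: per-station dense count tensors — class counts, per-feature
(class × state) counts, and per-feature-pair (class × state × state) counts —
over a harmonized state space. Since every quantity the learner needs (CMI
weights and CPT numerators/denominators) is a function of these counts, and
counts add across disjoint partitions, the coordinator's model is exactly
the pooled-data model for *any* partition of any dataset into stations.
This exactness is the package's headline property and is enforced by tests
at a 1e-12 CPT sup-norm.

The protocol is: (1) handshake — each station discloses variable names and
*observed* state lists (no counts); (2) the coordinator harmonizes schemas
by lexicographic union of states per variable and broadcasts the schema
fingerprint (SHA-256 of the canonical schema JSON); (3) stations send
versioned JSON statistics messages; (4) the coordinator sums and trains.
Transport is in-process with fully serialized payloads, so a network
transport could replace it without touching the math; an audit log retains
every serialized byte for inspection.

Disclosure policy: counts do leak small-cell information (a class count of 1
names a record's existence). Stations may set a minimum-cell-count
threshold; a class count strictly between zero and the threshold makes the
station abstain entirely. We deliberately refuse rather than perturb — no
noise mechanism is implemented, so abstention is the only honest option.

Because no principled rule exists for combining separately fitted parameters, the
package defines count pooling as its protocol; a comparison mode
(`--combine=average-cpt`) implements the obvious alternative — adopt the
largest station's structure, have every station refit that structure
locally, and average CPTs weighted by local sample size. It is lossy and
non-default; its only role is to make the cost of parameter averaging
measurable.

## Synthetic scenario

The generator emulates three-station categorical surveillance data with a
fixed composition: per-station class counts are exact (202 = 105+97,
144 = 1+135+8, 95 = 21+23+51), year spans are 2008–2013, 2014–2018 and
2008–2018, and class imbalance ranges from 1 % to 94 %. Year is categorical
("2008" … "2018") throughout — state lists, not numbers.

Feature distributions are invented: each fraud type gets a peaked
multinomial (dominant state mass 0.5, remainder uniform) over 6 products, 8
origin countries and 6 reporting countries, with distinct dominant states
per class, and years uniform within the station's span. The peak mass was
chosen once so that the class signal is learnable at n ≈ 440 and
individual-vs-combined differences are visible; it makes no attempt to match
the real incident databases' marginals, and externally reported AUC values are
explicitly not reproduction targets. A green test therefore establishes
protocol exactness, estimator correctness and qualitative transfer-of-
knowledge behavior — not agreement with numbers measured on the real data.

Generation draws from one seeded stream per call in a fixed order (per
profile, per record, per feature in canonical order, then one shuffle), so
identical seeds give byte-identical CSVs and adding a variable cannot
perturb earlier columns. Class counts are deterministic for every seed; only
attribute values are stochastic. The three stations derive their sub-seeds
from the scenario seed by a fixed affine map kept below 2³¹.

## Splits and evaluation

The 80/20 split is seeded; `round(fraction·n)` uses half-up rounding
(0.8 × 441 → 353). Stratified splitting is the default: each class
contributes round(fraction·n_class) to train, corrected by largest
remainder so the global total is exact, and a single-record class is pinned
to train (protecting the station that holds one record of a class).
Stratification is a genuinely open choice here, so the unstratified
mode is also exposed; the pooled-data harness (Experiment 2) uses the
unstratified "random split" reading.

Per-class sensitivity and specificity are one-vs-rest rates at the argmax
decision; "average" is the unweighted mean over classes observed in the test
set (undefined sensitivities of never-observed classes are excluded and
flagged; a frequency-weighted mean is available behind a flag). The
aggregate score is the micro-average ROC/AUC: all (record, class)
one-vs-rest decisions are pooled into one binary problem, thresholds sweep
the distinct scores descending with ties grouped, and the area is
trapezoidal — equivalently the concordance probability with ties counted ½,
which an enumeration oracle and scikit-learn both confirm in tests.

When a model's class space exceeds the test label space (the two-class
station judged by the three-class combined model), binarization uses the
model's class space; absent classes contribute negatives only. In the
experiment harnesses both arms are built over the states actually observed
in the training partition — exactly what a centralized analyst pooling raw
records would infer — and the rare test record carrying a state unseen in
training is dropped with a logged count, identically for both arms.

Experiment 1 trains each station's individual model on its local train
partition but over the harmonized state space, so individual and combined
models predict over the same class list; a class the station never saw is
then carried by the Dirichlet prior alone (uniform CPT rows), which is the
precise sense in which the federation adds knowledge the station lacks.
A combined model could plausibly see other stations' full data or their
train splits is ambiguous; we use train splits.

## Numerical and design notes

- All tie-breaking (state order, edge keys, argmax, root choice) is
  lexicographic/canonical-order; repeated runs are bit-identical.
- Posteriors are computed in log space and renormalized after subtracting
  the max, so long feature chains cannot underflow.
- Statistics tensors are int64; CPTs float64; CPT rows are validated to sum
  to 1 within 1e-9.
- RDF ingestion supports N-Triples and a restricted Turtle subset (prefix
  declarations, `a`, `;`/`,` lists, plain literals; language tags and
  datatypes are stripped; ontology IRIs are opaque — an IRI object falls
  back to its local name when the full IRI is not a declared state). Blank-
  node structures and collections are out of scope.
- Degenerate inputs: an empty CSV is an empty dataset, not an error; a
  single observed class still learns a structure (CMI conditions on one
  class) and predicts over the harmonized class space; fewer than two
  features is a hard error (plain naive Bayes is out of scope).

## Known limitations

- Complete-data only: no EM for missing values; incomplete records are
  dropped at ingestion.
- No differential privacy: count pooling leaks marginal counts by design;
  the min-cell policy mitigates but does not remove this.
- The synthetic generator does not reproduce real product/country marginals,
  inter-feature correlations beyond the class-conditional tree, or reporting
  drift over years.
- No general DAG search, continuous variables, or secure aggregation.
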