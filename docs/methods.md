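# Methods

## Feature model

A cluster profile partitions the 20 standard amino acids into k ordered,
disjoint groups. The five built-ins derive from the protein-blocks
structural alphabet:

| profile | groups |
|---|---|
| CP(13) | G-IV-FYW-A-L-M-E-QRK-P-ND-HS-T-C |
| CP(11) | G-IV-FYW-A-LM-EQRK-P-ND-HS-T-C |
| CP(9)  | G-IV-FYW-ALM-EQRK-P-ND-HS-TC |
| CP(8)  | G-IV-FYW-ALM-EQRK-P-ND-HSTC |
| CP(5)  | G-IVFYW-ALMEQRK-P-NDHSTC |

A sequence of reduced length L′ is described by the frequencies of its
L′−n+1 length-n windows over the group alphabet, a vector of dimension
kⁿ. Dividing counts by the window count makes every vector sum to 1;
this is the standard k-mer frequency definition and pins down the
"normalized frequency" semantics for n ≥ 2. Cells are ordered row-major
over group indices, (g₁,…,g_n) ↦ Σ g_j·k^(n−j); the ordering is
arbitrary but deterministic and is irrelevant to the classifier as long
as it is consistent. n is limited to 1–3 (beyond that the dimension
defeats the purpose of the reduction).

Ambiguity codes (B, Z, X, U, O, J, `*`) are dropped before reduction by
default — they are rare in practice and removing them perturbs the
composition minimally — with an `"error"` policy available for strict
pipelines. Input is uppercased first. Group indices are 0-based in code
and 1-based in any report output (column names such as `CP8_n3_g1g5g2`).

A protein pair is encoded as the ordered concatenation [a ; b] of the
two per-protein vectors (length 2kⁿ), the dominant convention in
sequence-based PPI work. Since interaction is symmetric, the order-free
alternative [a+b ; |a−b|] is exposed as `combine="sym"`, but
concatenation remains the default.

## Classifier

Training pairs form a dictionary X ∈ R^(d×n) whose columns are scaled
to unit ℓ₂ norm. For a query y:

1. (WSRC only) each unit column x_j is scaled by
   w_j = exp(−‖x_j − y‖²/2σ²), forming X′. Distances are measured on the
   unit-normalized columns — the same objects the solver sees.
2. Solve min ‖α‖₁ s.t. ‖y − X′α‖₂ ≤ ε (basis pursuit denoising).
3. Compute per-class residuals g_k = ‖y − X′δ_k(α)‖₂, where δ_k zeroes
   coefficients outside class k.
4. Predict argmin_k g_k; ties break to the lowest class index.

The weighted dictionary X′ is used consistently in both the ℓ1 program
and the residuals: weighting only one of the two stages would leave the
weights without influence on the decision, defeating the purpose of the
weighting. The query itself is never rescaled. Defaults σ = 50,
ε = 0.05.

Scaling a column by w is equivalent to charging its coefficient
1/w in the ℓ1 objective, so training pairs close to the query (w ≈ 1)
are preferred atoms. If every weight underflows (query extremely far
from all training data at small σ) the classifier warns and falls back
to unweighted SRC rather than coding against a numerically zero
dictionary. With σ → ∞ all weights tend to 1 and WSRC reduces exactly
to SRC; the suite checks prediction-level identity at σ = 10⁹.

### ℓ1 solver

The constrained program is solved via the exact LARS/lasso homotopy
(`sklearn.linear_model.lars_path`): the lasso solution is piecewise
linear in the penalty, so the residual norm is a quadratic along each
path segment and the point where ‖y − X′α‖₂ = ε is found in closed form
by solving ‖(1−t)r_prev + t·r_next‖² = ε² within the first segment that
crosses the tolerance. That point is the BPDN optimum (the lasso
solution at the penalty where the constraint becomes active). If
‖y‖₂ ≤ ε the zero code is optimal and returned directly; if even the
end of the path stays infeasible (the dictionary's least-squares
residual floor exceeds ε, possible for overdetermined dictionaries) the
solver raises an explicit `SolverError` — never a silent zero vector.
Feasibility is asserted to a 1e-9 relative slack in the tests, and the
test suite cross-checks 100 random instances against an independent
generic convex solver (SLSQP on the split-variable formulation, with a
trust-region fallback) at 1e-4 objective tolerance.

Note that SRC carries a sign ambiguity: coefficients are unconstrained,
so a class whose columns point opposite to the query can still
reconstruct it with negative weights. Composition features are
non-negative, which keeps dictionary columns in the positive orthant and
avoids the degenerate antipodal geometry.

## Evaluation

ACC = (TP+TN)/total, SN = TP/(TP+FN), PE = TP/(TP+FP),
MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)), all reported as
percentages. A metric whose denominator vanishes is reported as
undefined with an explanation, never as 0 — a silent zero is misleading
in aggregate tables. (For MCC this matches the convention of leaving
table cells as N/A when a confusion-table margin is empty.)

ROC curves use the residual margin g_neg − g_pos as the score — WSRC
has no native probability; the margin is monotone in decision
confidence and recovers the argmin decision at threshold 0. AUC is the
trapezoidal area; tied scores enter at a single operating point, so a
constant score yields the chance diagonal and AUC 0.5.

Cross-validation is stratified (shuffled `StratifiedKFold`): the
intended datasets are class-balanced and stratification preserves that
in every fold. Per-fold ACC/SN/PE/MCC are reported with mean ± sd
across folds, plus AUC pooled over the out-of-fold scores.

Length filtering removes proteins with fewer than 50 residues (a
50-residue protein is kept — the boundary convention is stated because
off-by-one conventions differ), and drops any pair touching a removed
protein.

## Synthetic data

The generator emulates labeled pairs whose classes differ in residue
composition. Emission distributions over the 20 residues are mixtures

    D1 = (1−s)·uniform + s·Unif{I,V,F,Y,W}
    D2 = (1−s)·uniform + s·Unif{N,D,H,S,T,C}

whose total-variation distance is exactly the separation s ∈ [0,1] (the
enriched sets are disjoint, and each falls inside a single CP(5)
group). Proteins are i.i.d. residue strings; interacting pairs draw
both proteins from D1, non-interacting pairs both from D2 (a mixed
D1/D2 mode is available). Defaults: 200 pairs per class, lengths
uniform on 50–300 residues (above the 50-residue filter floor, at
typical protein scale), separation 0.9.

What this does and does not show: the generator produces
composition-separable classes with no homology structure, no shared
proteins between pairs, no domain architecture, and no label noise.
Passing the recovery tests demonstrates that featurization, solver,
weighting and evaluation are wired correctly and that accuracy responds
monotonically to class separation — it says nothing about accuracy on
real interactomes, where class differences are far subtler and pairs
share proteins. Published evaluations of this method family on curated
yeast (DIP) and *H. pylori* datasets report best five-fold accuracies
around 90.91% and 83.04% respectively; those datasets are not
redistributable here, and two further preprocessing steps they use — the
40% sequence-identity redundancy filter and negative sampling by
subcellular localization — require external tools and annotations and
are deliberately out of scope. (The source reports the best yeast MCC
inconsistently as 84.43% in prose and 83.43% in its table and abstract;
neither is reproduced here.) The SVM comparator used in those studies
(RBF kernel, C = 16, g = 16) is likewise out of scope and recorded here
only for completeness.

## Numerical and design choices

- Solver feasibility slack: solutions are accepted at ‖y − X′α‖ ≤
  ε(1+1e-9); path interpolation uses exact closed-form roots.
- Tie-breaking: argmin over residuals takes the lowest class index
  (deterministic).
- Queries equal to ≤ ε in norm code to α = 0, making all residuals
  equal ‖y‖; the tie rule then picks the first class.
- Problem sizes in the test and acceptance runs (200 pairs/class for
  recovery, 100/class for the separation grid, dictionaries of a few
  hundred columns) were chosen as the smallest sizes at which fold
  metrics are stable to a few percent.
- The model archive is a single `.npz` with a format-version tag,
  holding the normalized dictionary, per-column class labels, σ, ε,
  mode, and the feature-encoding metadata needed to validate prediction
  inputs.

## Known limitations

- Per-query solve cost grows with dictionary width; tens of thousands
  of training pairs would need a batched or screened solver.
- The residual-margin ROC score is a heuristic ordering, not a
  calibrated probability.
- Binary classification only; the residual machinery supports K classes
  but the evaluation layer assumes two.
- i.i.d. emission is an intentionally crude null model of protein
  sequences (no composition bias by position, no motifs); a motif mode
  is a possible extension.
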