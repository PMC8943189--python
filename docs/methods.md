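# Methods

This note documents the models, conventions and numerical choices behind
hemiconn, the assumptions they rest on, and what the synthetic validation
suite does and does not demonstrate about real data.

## Data model and hemispheric split

A connectome is a symmetric, nonnegative, zero-diagonal weight matrix
bound to an ordered node table. The default atlas has 79 nodes: per
hemisphere 31 Desikan–Killiany–Tourville cortical labels, 7 subcortical
gray-matter labels and one cerebellar label, plus a single midline
brainstem node. The cortical + subcortical labels give the 76 gray-matter
nodes; 39 nodes per hemisphere are lateralized. The subcortical set
(thalamus, caudate, putamen, pallidum, hippocampus, amygdala, accumbens)
is the conventional FreeSurfer-style septet; the parcellation source this
emulates does not enumerate them, so the composition is a reconstruction
from the printed node counts.

Splitting by lesion side keeps, per hemisphere, the 39 lateralized nodes
plus the brainstem (40 × 40). Interhemispheric edges are excluded.
Brainstem edges are assigned to the hemisphere of their lateralized
endpoint — whether the original split dropped or duplicated
brainstem-contralateral edges is not documentable, and this assignment is
the only one that partitions the retained weight without double counting.
The contralesional matrix is permuted through the left/right homolog
bijection so that row k of both matrices refers to homologous regions;
consequently a perfectly mirror-symmetric brain splits into two identical
matrices, which is the generator-template invariant the tests use.

Matrices are serialized as dense labeled TSV (79 × 79 is small enough that
human inspectability beats sparse storage). On read, asymmetries up to
1e-9 are symmetrized as (W + Wᵀ)/2; anything larger is a validation error
naming the worst cell. Write/read round-trips are exact to 1e-12
(`%.17g` formatting).

## TFNBS

Edge statistic: for subjects s = 1..n, the paired difference
d_s = w_contra − w_ipsi (negated for the ipsi>contra direction) is fit by
OLS as d_s = β0 + β1·side_s with the lesion side coded ±1 and
mean-centered. The centered covariate is orthogonal to the intercept, so
t(β0) = mean(d) / sqrt(s²/n) with s² the residual variance on n−2 df
(n−1 when the covariate is constant and dropped). Negative t values are
truncated to zero; each contrast direction is run separately, mirroring
how signed asymmetry findings are usually reported. Whether the original
analyses were one- or two-sided is not stated anywhere authoritative;
one-sided-per-direction was chosen because it reports signed subnetworks
directly.

Enhancement: score(i,j) = Σ_k e_k(i,j)^E · h_k^H · dh over thresholds
h_k = k·dh, k = 1..n_steps, with E = 0.4, H = 3 as in the method's
standard parameterization. The grid is adaptive, dh = max(t)/n_steps
(default 100 steps), so scores are defined for any statistic scale; note
that published implementations use a fixed dh, so absolute score values
are not comparable across software — p-values are. An all-zero map scores
zero everywhere. Threshold membership is closed (t ≥ h_k), so the maximal
edge contributes at the top step; with the single-edge unit-extent map
this makes the score a right Riemann sum of h^H, converging to
max(t)^4/4.

Extent has two definitions in circulation: the connected-component edge
count of the suprathreshold graph (the TFNBS tool family) and the
node-incident suprathreshold edge count (a literal reading of the
method's verbal description). Both are implemented (`extent_mode`);
"component" is the default. The component extent is computed by an
incremental union-find over descending thresholds (edges only ever join
components as h falls), vectorized per threshold; the tests verify it
against scipy's connected-components routine.

Inference: the exchangeable unit under the no-asymmetry null is the sign
of each subject's difference vector. The side covariate is handled by
Freedman–Lane: residuals from the covariate-only reduced model are
sign-flipped and the fitted covariate part added back; with a constant
covariate this reduces exactly to pure sign-flipping. Each of n_perm
(default 5000) draws records the maximal enhanced score;
p_fwe = (1 + #{null_max ≥ score}) / (n_perm + 1), giving a p floor of
1/(n_perm+1) and strictly valid (slightly conservative) error control.
Requesting more permutations than the 2^n distinct sign patterns logs a
warning and keeps sampling with replacement.

## Graph topology

* Edge length = 1/weight on raw streamline counts; no weight
  normalization. This is deliberate: the hemispheric efficiency values
  this pipeline is meant to mirror are on the ~5·10³ scale, which only
  arises unnormalized. Efficiency is therefore homogeneous of degree one
  in the weights (E(cW) = cE(W)), a property the tests assert exactly.
* Disconnected pairs have infinite path length and contribute zero to
  efficiencies. Global efficiency is the mean inverse shortest-path
  length over ordered pairs and equals the mean of the nodal
  efficiencies.
* Local efficiency of node i is the global efficiency of the subgraph
  induced by i's neighbors with original weights and i removed (one of
  several literature variants; chosen for compatibility with the GRETNA
  analysis style this emulates); fewer than two neighbors scores zero.
* Clustering is the Onnela geometric-mean form with weights normalized by
  the global maximum; hierarchy β is the negative OLS slope of log C on
  log k over nodes with degree ≥ 2 and C > 0 (NaN below three eligible
  nodes; slope 0 when both logs are constant).
* Betweenness is Brandes' algorithm on reciprocal-weight lengths
  (endpoints excluded, unnormalized pair counts), delegated to networkx
  and verified against an exhaustive path-enumeration oracle and an
  independent path-counting oracle.
* Rich club: φ_w(k) = weight among nodes of degree > k divided by the sum
  of the E_{>k} largest edge weights anywhere in the graph. No random
  normalization is applied, since the emulated analyses report raw
  coefficients only.
* Small-worldness: C and L from the observed graph (L averaged over
  connected pairs only, because degree-preserving nulls may disconnect —
  efficiency keeps the zero-for-disconnected rule instead), nulls by
  Maslov–Sneppen double-edge swaps (10·E swaps attempted, weight multiset
  reshuffled onto the rewired topology), γ = C/⟨C_null⟩, λ = L/⟨L_null⟩,
  σ = γ/λ. Rigid graphs that exhaust the swap budget keep their achieved
  randomization with a logged warning. Default 100 nulls.

Which clustering form, null count and path-length convention the original
GRETNA-based analyses used is not recoverable; all of the above are
compatibility assumptions and are stated as such.

## Cohort statistics

Paired hemisphere contrasts report both the two-sided paired t and the
two-sided Wilcoxon signed-rank (zero differences dropped; exact null
distribution for ≤ 25 nonzero differences, otherwise normal approximation
with tie and continuity correction) — text-style t statistics and
figure-style Wilcoxon tests coexist in this literature, so both are
always emitted. Degenerate inputs are flagged rather than hidden: all-zero
differences give t = 0, p = 1 with an undefined Wilcoxon; a constant
nonzero shift gives a signed infinite t with p = 0.

Spearman families are explicit lists of (feature, variable) pairs;
Benjamini–Hochberg runs across exactly the declared family, with constant
or too-sparse pairs dropped (family shrinks, with a warning). P-values
default to a seeded two-sided permutation null (999 permutations of the
mid-ranked feature). The classical n−2 df t-approximation is available as
`p_method="t"`, but it is measurably anticonservative in the far tail for
the heavily tied ordinal scales used here (MRC concentrated on two of six
levels, three-level tumor grades): under the global null, 12-edge ×
5-variable families showed a family-wise BH false-positive rate of ~0.10
with the t-approximation versus ~0.003 with permutation p-values. Since
the pipeline's contract is family-wise-controlled screening of edge ×
clinical families, the permutation default is the defensible choice.

Cross-algorithm agreement is plain Pearson per metric, optionally within
hemisphere groups or pooled over hemispheres (doubling n, as in rs(72)
style reporting on 37 subjects × 2 hemispheres).

## Synthetic cohort generator

The generator is the package's stand-in for non-shareable patient data;
its defaults are the modeled study conditions, not tuning knobs.

* Template: lateralized regions are assigned to 5 mirrored modules
  (contiguous blocks); intra-hemispheric edges exist with probability 0.8
  within and 0.3 between modules; weights are log-normal
  (log-mean 8.25, log-sd 0.8); homotopic interhemispheric edges appear
  with probability 0.8 and brainstem connections with probability 0.3 per
  node, all mirrored. The log-mean was calibrated once, in closed form
  (efficiency is linear in weight scale), so the hemispheric global
  efficiency of the default template averages ≈ 5.0·10³ over seeds —
  matching the magnitude of the efficiency means the pipeline is meant to
  make interpretable. The weight-probability defaults themselves are a
  realistic-density choice (hemispheric density ≈ 0.5, right-skewed
  weights), not an empirical fit.
* Subjects: template weights times symmetric log-normal noise
  (log-sd 0.2). Lesion side is Bernoulli(21/37 right); subgroup
  memberships are sampled 16:15:8:3 with a 5/37 chance of a second
  membership (the marginal counts sum to 42 over 37 subjects, implying
  overlap). The lesion neighborhood is the primary subgroup's seed region
  (precentral, postcentral, insula, or superior frontal) plus its most
  strongly connected same-module neighbors, 4 nodes by default; all
  ipsilesional edges incident to the neighborhood are multiplied by
  (1 − δ), with δ Beta-distributed around 0.3 (concentration 30) and
  shifted up with WHO grade and log tumor volume. The multiplicative
  localized mechanism is the simplest one producing both a TFNBS
  subnetwork signal and an ipsilesional efficiency decrease; it is a
  modeling device, not a biological claim, and δ = 0.3 is a test-design
  default with no empirical anchor.
* Clinical: WHO grades 13:10:14 over II/III/IV; tumor volume log-normal
  moment-matched to mean 24.97, SD 23.84 cm³; RMT ratio normal(1.02,
  0.166) truncated positive, with the pathological RMT normal(35.13,
  7.61) and the healthy RMT derived; NIHSS = clip(round(15 · fractional
  ipsilesional weight loss + N(0,1)), 0, 42), missing with probability
  3/37 (the 15-point gain puts the default cohort mean near 0.94); MRC is
  mapped from cohort damage quantiles onto the fixed marginal
  {2:1, 3:1, 4:12, 5:23}/37, so the most damaged subjects get the lowest
  grades.
* Replicate: the second "algorithm" connectome is the subject's matrix
  scaled by 0.92 (deterministic tractography reconstructs systematically
  fewer streamlines) with symmetric log-normal noise (log-sd 0.15),
  preserving the zero pattern; this yields edge-weight and efficiency
  correlations above 0.8-0.9, the agreement regime the real two-algorithm
  comparison showed.
* All randomness flows from one root SeedSequence (template, then one
  child per subject), so cohorts are reproducible to the byte.

What the generator does **not** emulate: spatial tract geometry, edema or
mass effects, distance-dependent connection probabilities, realistic
modular anatomy, tractography false positives with distance bias, or
longitudinal change. Passing recovery and calibration suites therefore
demonstrates the statistical machinery is correct and calibrated under
the stated noise model — not that the pipeline's power or error rates
transfer to any particular scanner, tractography algorithm, or patient
population.

## Pipeline and problem sizes

`run_pipeline` analyzes each algorithm replicate within each configured
subgroup filter (whole cohort plus the four location subgroups): split,
TFNBS in both directions, per-hemisphere metric sets, paired efficiency
contrasts, and three Spearman families (ipsilesional, contralesional and
contra-minus-ipsi strengths of the TFNBS-significant edges against the
five clinical variables). Subgroups with fewer than three subjects are
skipped with a warning — small location subgroups are exactly where such
analyses become fragile. A JSON manifest records the seed, a
configuration hash and the resolved parameters; identical configurations
produce identical bundles.

Validation suites run at reduced but honest sizes chosen as the package's
own test design: permutation calibration uses 100 null cohorts × 500
permutations (familywise false-positive band [0.01, 0.11] at α = 0.05),
recovery uses one 37-subject cohort at 2000 permutations, FDR control
uses 200 replicate families, and metric-oracle equivalence uses 50 random
graphs of up to 20 nodes at 1e-10 agreement. Example scripts likewise
reduce subject counts or permutations where full defaults would be slow;
every reduction is stated inline.

## Known limitations

* The atlas composition and all GRETNA/TFNBS variant choices are
  reconstructions from printed counts and common practice, flagged above.
* Adaptive-dh TFNBS scores are not numerically comparable to fixed-dh
  implementations (inference is).
* The incident extent mode is a literal-reading alternative, not the
  default inference path.
* Rich-club coefficients are unnormalized; hierarchy is undefined on
  graphs with fewer than three clustered nodes.
* The generator's clinical couplings are linear in damage with additive
  noise; real clinical scales are neither linear nor homoscedastic.
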