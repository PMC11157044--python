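# Methods

This note documents the model implemented in `mlfcn`, the conventions and
numerical choices behind it, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Parcellation and node sets

The default layout has 138 ROIs: 90 GM regions partitioned into 14
macroscale resting-state networks (MRSNs) with member counts matching the
Stanford FIND functional atlas (ASN 7, PSN 12, AN 3, BGN 5, DDMN 9,
VDMN 10, PVN 2, HVN 2, LN 7, LECN 6, RECN 6, PN 4, SMN 6, VSN 11), and the
48 JHU probabilistic WM tracts treated as a single WM MRSN. GM ROI labels
are placeholders (`"AN 1"`): only the network partition enters the
computation, and a full named mapping can be supplied as a TSV
(`roi_index, label, tissue, mrsn_name`). The hypergraph layer is built
over the 14 GM MRSNs only; the WM MRSN carries a reserved id and is
excluded from the hypergraph node set.

Theoretical maximum degrees, which normalize the multilayer degree, follow
from the node sets alone. For a GM ROI in an MRSN of size `n_S`:
`M − 1 = 13` in the hypergraph layer (a node is never a member of its own
central hyperedge, which is the convention that makes the layer-1 maximum
13 rather than 14), `n_S − 1` within its MRSN, and 48 in the WM–GM layer.
For a WM ROI the only layer is WM–GM, with maximum 90.

## Windowing

Windows are half-open ranges `[t·S, t·S + W)`, `t = 0 … T−1`, with
`T = ⌊(L − W)/S⌋ + 1`. The canonical parameter sets divide evenly
(`(L, W, S) = (1200, 200, 100) → T = 11`; `(150, 20, 10) → T = 14`); when
they do not, trailing time points are dropped with a warning. Internally
all indices are 0-based half-open; user-facing tables are 1-based.

## MRSN representative signals

How the MRSN-level signal fed to the Lasso is formed is a genuinely open
design point. The default is the unweighted mean of the member ROI series
— the simplest convention consistent with treating each MRSN as a single
central node — with a first-principal-component alternative
(`mrsn_method="pc1"`, sign-fixed to correlate positively with the member
mean) exposed for sensitivity analyses.

## Hypergraph estimation

Each central MRSN signal is regressed on all others with an L1 penalty.
Columns are standardized (zero mean, unit population variance) first so
the penalty is scale-free, and the objective is the per-sample-normalized
Lasso `(1/2W)‖X_i − B_i α‖² + λ‖α‖₁` (scikit-learn's convention), making
λ comparable across window lengths. With a single standardized predictor
the solution is the soft-thresholded sample correlation, which the test
suite uses as a closed-form oracle; small multi-predictor problems are
checked against an independent split-variable bound-constrained solver.

Membership is *strictly positive* coefficients only: anticorrelated
signals never join a hyperedge. λ defaults to 0.1 on standardized series;
no principled value is forced by the model, so λ is a first-class
parameter (`--lam`) and hyperedge-size curves over a λ grid are cheap to
produce with `lasso_hyperedges`. Zero-variance signals yield empty
hyperedges with a warning.

## Threshold rule for the simple-graph layers

Binarization uses the adaptive threshold *mean + 1 SD of the FC strengths
of the matrix being thresholded*: the off-diagonal upper triangle for a
within-MRSN block, all 48×90 entries for the WM–GM matrix. The scope is
deliberately per matrix (per block, per window) rather than pooled, so
each matrix adapts to its own correlation level; pooling is the main
alternative and would couple blocks of very different sizes. FC strength
is the signed Pearson r by default (`abs_corr=True` thresholds |r|). The
SD is the sample standard deviation (`ddof=1`). Degenerate matrices — a
single off-diagonal value, or all values identical — produce an empty
adjacency with a warning, since nothing strictly exceeds mean + SD when
the spread is zero; the default layout's two 2-member MRSNs (PVN, HVN)
therefore always have empty within-network blocks, which is the honest
consequence of the rule rather than a special case.

## Core selection and the four metrics

Per layer, multilayer degree is the sum over the three layers, with a GM
ROI inheriting its MRSN's hyperedge-membership count as its layer-1
degree. The top `n_core = 15` ROIs by normalized degree (matching the 15
predefined MRSNs) form the core; all 138 ROIs compete, WM included. Ties
at the cutoff are broken by ascending ROI index — deterministic and
reportable.

- **TC** is the mean of the core indicator over layers. Its sum over ROIs
  is exactly `n_core` for every subject; consequently the whole-brain mean
  of TC is the constant `n_core / N`, and whole-brain TC is flagged in
  aggregates and skipped by the group tests (no variance).
- **TS** is defined over the `T − 1` consecutive layer pairs (the printed
  upper summation limit would require a nonexistent layer `T + 1` and is
  truncated). The *literal* reading, one minus the mean consistency,
  scores a never-switching node 0; since the metric is described as a
  stability measure, the *prose* reading (the mean consistency itself,
  scoring stable nodes 1) is the default, and both are always reported.
  They sum to 1 elementwise.
- **P, LF, JF.** `β_ij^t` counts core nodes connected to both `i` and `j`
  at layer `t`, provided both are peripheral there (an all-pairs mode
  exists). The sum runs over all `T` layers with normalizer `T·n_R` — `β`
  is an instantaneous per-layer quantity, so the natural sum is over every
  layer; a `t_minus_1` mode reproduces the truncated sum. `LF_i` divides
  the same-MRSN sum by `n_S` (the sum has `n_S − 1` terms; the literal
  denominator is kept, with an `n_S − 1` option); `JF_i` averages over the
  `N − n_S` ROIs *outside* the node's network.
- **Cross-layer connectivity.** "Connected to a core node" must be
  evaluated across layers that live on different node sets. The package
  uses a per-layer union graph: A1 edges within MRSNs, A2 edges between
  WM and GM, and — the largest interpretive decision — GM–GM edges across
  MRSNs when the two MRSNs co-occur in at least one hyperedge (clique
  expansion at MRSN level, each hyperedge's node set taken as its members
  plus its central MRSN). Same-MRSN connectivity is left to A1 so the
  hypergraph does not swamp the within-network structure, and WM–WM pairs
  are never connected (no layer relates them). The policy is isolated
  behind a single interface (`policy="union" | "adjacency_only"`).

## Statistics

ICC is the one-way random-effects coefficient
`(MS_B − MS_W) / (MS_B + (n−1)·MS_W)` with `n = 2` sessions — the ANOVA
reading of "variance among individuals" vs "variance between the two scans
of an individual" (ICC(1,1); cross-checked against pingouin in the test
suite). It can be negative (bounded below by −1 for two sessions) and is
undefined (NaN, warned) when both components vanish. Benchmarks: > 0.6
(GM) or > 0.5 (WM) = individual differences; > 0.8 = significant, either
tissue; inequalities strict.

Group contrasts use the pooled-variance Student t-test — its df
`n1 + n2 − 2` matches the published cohort dfs (158 for 80 vs 80, 171 for
87 vs 86), which a Welch test would not guarantee — with
Benjamini–Hochberg FDR applied within each metric × scale family
(the correction scope is not dictated by the model; per-family is the
configurable default). Units with no variance in either group are skipped
with a warning rather than producing undefined statistics.

## Synthetic data

The generator is a Gaussian latent-factor model: a global factor `g`, one
factor per MRSN loading on `g` with weight `cross_block_corr` (hubs,
default 0.7) or `background_cross_corr` (default 0.15), GM ROIs loading on
their MRSN factor with weight `within_block_corr` (default 0.6, which is
then exactly the within-block correlation at `noise_sd = 0`), and a subset
of WM ROIs (default 4 of 6) loading on the active hub factor with weight
`wm_gm_corr` (default 0.7). Square-root weight mixing keeps the implied
covariance positive semidefinite by construction. Regime switches rotate
the active hub at stated window starts; group B's hub coupling is offset
by `group_effect_size`; the retest session blends session-1 innovations
with fresh ones at weight `retest_reliability`, so reliability 1
reproduces session 1 bit for bit. All randomness descends from one
`SeedSequence` (PCG64), with stateless per-subject child keys, so a seed
fully determines a cohort across platforms.

Defaults are set so that the planted hub MRSN's members dominate the
rich-club core — strong enough coupling that recovery is expected, weak
enough that it is not trivial. The test and calibration runs use the toy
layout (5 MRSNs × 4 GM ROIs + 6 WM ROIs, `n_core = 5`, `L = 120`,
`W = 40`, `S = 20`, `T = 5`) with 6 subjects per group, and 200 seeds for
the null-calibration study — sizes chosen to keep brute-force oracles
exhaustive and Monte-Carlo margins meaningful. The group-effect power
scenario lowers the baseline hub coupling to the background level and
removes WM coupling, so that core membership is decided by the planted
cross-block effect rather than saturated by construction.

What the generator does **not** emulate: hemodynamics, autocorrelated
fMRI noise spectra, spatial smoothness, motion artifacts, site effects,
or realistic between-subject topology variation. Passing recovery tests
therefore shows that the pipeline detects the structure it is designed to
detect under its own assumptions — not that it would do so at real-data
noise levels.

## Numerical choices and degenerate inputs

- Lasso: coordinate descent, `tol = 1e-10`, 50k iterations max;
  non-convergence raises with diagnostics rather than returning silently.
- Correlations of zero-variance columns are set to 0 (never NaN) and the
  columns flagged.
- `T ≥ 2` is required for any temporal metric; `TS` additionally errors at
  `T < 2` when called directly.
- Parcellation validation rejects duplicate/non-contiguous indices, GM
  ROIs without an MRSN, multi-MRSN membership, and empty MRSNs.
- Degenerate parcellations where some ROI has a zero maximum-degree sum
  (e.g. a single one-ROI network) are rejected at normalization.

## Limitations

- Layers are binary; no weighted variant.
- No between-MRSN pairwise GM–GM adjacency: the hypergraph is the only
  between-network structure.
- No inter-layer coupling terms in the degree; layers are summed.
- The classical rich-club coefficient φ(k) and degree-preserving null
  models are out of scope; the core is defined by rank, not by a null
  comparison.
- fMRI preprocessing is upstream; inputs are assumed clean ROI series.
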