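# Methods

## Model

### Structural-alphabet encoding

Local backbone dynamics are represented by overlapping fragments of four
consecutive Cα atoms: a chain of n residues yields n − 3 fragments, each
named by its first residue (f115 spans residues 115–118), and fragments
never span chain breaks. A fragment conformation is summarised by three
internal angles — pseudo-bond angles θ1 (Cα 1-2-3) and θ2 (Cα 2-3-4) and
the pseudo-torsion τ (Cα 1-2-3-4, IUPAC sign convention, cis = 0,
τ ∈ (−180°, 180°]) — and assigned a letter from a finite alphabet of
canonical fragment conformations. Two assignment rules are implemented
and config-selectable, because published descriptions of this family of
methods are ambiguous between them:

- `rmsd_local_fit` (default): the letter whose canonical 4-point
  coordinates have minimal RMSD after optimal proper superposition
  (closed-form Kabsch with the determinant correction, evaluated in batch
  via the singular values of the 3×3 cross-covariance);
- `descriptor_nearest`: nearest neighbour in (θ1, θ2, τ) space with τ
  compared on the circle.

Ties break to the lowest letter index. Assignment is per frame with no
temporal smoothing, so encoding is stateless: encoding a concatenation of
trajectories equals the concatenation of encodings.

The shipped default alphabet (`data/alphabet25_synthetic.json`) is a
**synthetic stand-in**: 25 states on a deterministic (θ1, θ2, τ) grid
rendered to coordinates at 3.8 Å pseudo-bonds. The canonical 25-letter
alphabet of the structural-alphabet literature is not redistributable
here; any transcription of it can be plugged in as a JSON file with the
same schema. The test suite deliberately uses small synthetic alphabets
(2–4 states) so correctness never depends on which alphabet is loaded.

### Normalized mutual information and the coupling network

For fragment columns C_i, C_j of the string alignment (T frames):

    I_LLn(C_i; C_j) = ( I(C_i; C_j) − ε(C_i; C_j) ) / H(C_i, C_j)

with plug-in estimates of mutual information and joint entropy (computed
in nats; the ratio is base-invariant) and the first-order finite-size
bias term

    ε = (B_ij − B_i − B_j + 1) / (2T),

where B are counts of occupied joint/marginal histogram cells. ε is
floored at 0, and I_LLn is clamped to [0, 1]; constant columns (zero
joint entropy) are defined to have I_LLn = 0 with every partner, which is
forced by the normalization's divide-by-zero case. The diagonal of the
pairwise matrix is set to 1 for non-constant columns and excluded from
cutoff statistics.

Known limitation (quantified in the test suite and decisions of record):
the first-order correction leaves an O(1/T²) residual bias — about
+0.0014 nats for independent 5-letter columns at T = 200, shrinking ~13×
at T = 800. For network construction this is negligible relative to the
MI cutoff, but a Monte-Carlo unbiasedness check at T = 200 resolves it at
roughly 2 standard errors per 500 replicates.

Edges: fragment pairs within `d_cut` (default 30 Å between time-averaged
first-Cα positions; a single-reference-frame convention is available) and
with I_LLn at or above `mi_cut` (default `mi_frac = 0.33` × the maximum
off-diagonal I_LLn, an absolute override available) are connected with
weight w = 1 − I_LLn. Raising `mi_frac` can only remove edges.

### Paths, centrality, global coupling

The allosteric path between binding-site fragment sets A and B is the
minimum-total-weight path over all (a ∈ A, b ∈ B) pairs, computed by a
label-setting Dijkstra whose labels are (total weight, edge count, path);
tuple ordering yields the deterministic tie-break: minimal weight, then
fewest edges, then lexicographically smallest fragment sequence. Sites in
different components report "no path" — the expected outcome for
uncoupled conditions. Note the method reports the graph path only:
physically intermediate fragments that fall below the MI cutoff are not
interpolated.

Eigenvector centrality uses I_LLn (not w) as edge strength, so high
information exchange means a strong tie; w is a traversal cost, not a
strength. Power iteration runs with a diagonal shift equal to the maximum
strength — the shift leaves eigenvectors unchanged but makes convergence
robust on bipartite-like structures and keeps the spectral gap
scale-relative — to tolerance 1e-10 (max 10 000 iterations,
non-convergence is an error; pure-noise networks of disjoint near-equal
edges have genuinely degenerate spectra and the pipeline records the
failure as a warning rather than ranking noise). Scores are normalized to
max = 1 and reported with percentile ranks; a helper flags the top k%
(default 12%).

I_LGn applies the identical normalized-MI formula between each fragment
column and a discretized global-motion state series: frames are projected
onto the first principal component of the superposed Cα coordinates and
cut into n_states = 25 equal-frequency bins (occupancy F/n_states ± 1);
the PC sign is fixed so the first frame projects non-positive, making the
series deterministic. The upstream description of global states is not
fully specified in this literature; this construction is validated only
by its own contract.

### Trajectory geometry

Superposition is closed-form Kabsch (always a proper rotation). RMSF uses
the two-pass convention — superpose onto frame 0, then onto the time-mean
structure — and measures fluctuation about the mean position. Residue-pair
distance series default to Cα atoms with a named-atom override, since the
motivating analyses do not state the atom choice; 2D occupancy maps
default to 0.25 Å bins and a 21% rendering saturation, both
config-exposed rather than fixed truths.

### Lifetime and titration fitting

Decays are tail-fit from the histogram peak (no instrument-response
deconvolution: ns lifetimes vs 16 ps bins make the tail fit adequate)
with Σ a_k exp(−t/τ_k), k = 1 or 2. Fitting maximizes the exact Poisson
likelihood via least squares on signed deviance residuals. This is a
deliberate departure from the common shortcut of weighting squared
residuals by 1/max(counts, 1): weighting by *observed* counts
systematically over-weights downward-fluctuating low-count tail bins and
biases lifetimes low (measured: τ₁ ≈ −3%, τ₂ ≈ −10% at 10⁶ photons),
whereas the deviance fit is unbiased at the same photon budget (τ within
3%, amplitude-weighted τ within ~0.4%). Components are reported in
descending τ; parameters pinned at bounds are flagged.

FRET efficiency is E = 100·(1 − τ_DA/τ_D) with τ_D = 3.52 ns as the donor
default; τ_DA > τ_D yields a small negative E that is reported as-is
(flagged, not fatal). The Förster distance (R₀ = 63.34 Å default) is
carried as metadata only — no distance inversion is performed.

The global Hill fit optimizes {n} ∪ {START_c, END_c, log10 K_c} by
trust-region least squares with bounds n ∈ [0.3, 5] and K ∈ [1 nM, 1 mM],
five deterministic multi-starts (data-driven first start, seeded random
restarts), best loss kept; standard errors come from the Jacobian
curvature at the optimum (delta method for K). Concentrations are molar
internally; free ligand concentrations are taken as given (buffer
speciation is out of scope). All points are weighted equally. Fitting a
single condition with the same machinery is the ordinary free fit, which
makes the shared-n/free-n nesting inequality directly checkable. K values
across conditions are compared by one-way ANOVA; the post hoc is
all-pairs pooled-variance t tests with the Šidák family-wise adjustment
p_adj = 1 − (1 − p)^m — "Dunn–Šidák" names the correction, not a specific
base test, and the choice is recorded in the output metadata.

## Synthetic data: what it emulates, and what a green test establishes

The generators are statistical stand-ins, not physical models. They are
bit-reproducible per seed and write JSON ground-truth sidecars.

- **Planted chain**: a root fragment toggles between two letters with
  probability 0.5/frame; each downstream chain fragment copies its
  upstream neighbour with probability γ (default 0.9), else draws
  uniformly; off-chain fragments are uniform noise; T = 2000 frames,
  12 fragments, 7-fragment chain (mirroring the length of the motivating
  pathway). Chain fragments sit 25 Å apart on a line: consecutive pairs
  pass the 30 Å gate, next-nearest pairs (which carry genuine γ²
  coupling whose single-edge cost would undercut two chain edges) do
  not. Recovery of the planted chain therefore tests the estimator and
  the gates jointly — as in the real method, where the distance cutoff
  is what forces paths through physical neighbours.
- **Two-state polymer**: a planar zigzag Cα chain (3.8 Å bonds) whose
  last segment rotates rigidly about a hinge; rotation angles are solved
  (Brent) so a probe residue pair straddling the hinge sits at exactly
  15 Å (closed) and 20 Å (open); symmetric Markov switching (0.1/frame)
  plus 0.3 Å isotropic jitter. It reproduces a bimodal 15/20 Å distance
  signature and a mobile-vs-scaffold RMSF contrast, but nothing about
  real binding-site geometry or E1/E2 mechanics.
- **Decays**: per-bin Poisson draws around Σ a_k exp(−t/τ_k) at 16 ps
  binning (defaults a = 0.6/0.4, τ = 3.5/1.5 ns, 10⁶ photons, 50 ns
  window). No instrument response, background, or pile-up.
- **Titrations**: Hill curves plus iid Gaussian noise (0.5% FRET), 12
  log-spaced points (10 nM–100 µM), defaults mirroring the motivating
  design: shared n = 1 and K = 1.8 µM / 332 nM / 702 nM / 334 nM for the
  four conditions (no nucleotide, +nucleotide, +nucleotide+inhibitor,
  +nucleotide+phosphomimetic). Replicate noise is independent; real
  replicate structure (shared preparations) is not modelled.

A green recovery test therefore establishes that the estimators are
correct and well-calibrated on data that *obeys the model exactly*; it
says nothing about force-field adequacy, sampling convergence, or
instrument artefacts in real data.

## Reproducibility

Every pipeline run writes a manifest (config echo, SHA-256 of inputs,
stage list, package version) with sorted keys and no timestamps;
identical config + seed reruns are byte-identical. All randomness flows
through explicitly seeded numpy Generators.

## Known limitations

- The default 25-letter alphabet is a synthetic stand-in (above).
- The ε correction is first-order; see the quantified residual above.
- Dijkstra tie-breaking (fewest edges, then lexicographic) is a
  determinism convention, not a physical claim; ties are reported as the
  single canonical path rather than an ensemble.
- Per-replicate K estimates from shallow titration spans (START ≈ END)
  are noisy and can pin at bounds; such fits are flagged and excluded
  from comparisons only by the caller.
- No betweenness/community analysis, no transfer-entropy or time-lagged
  variants, no PBC unwrapping, no free-energy estimates from densities.
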