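# Methods

## Model overview

`memprop` treats a membrane protein as residing in two thermodynamic
environments — the lipid slab (TM) and everything outside it (EM) — and asks,
per residue, which environment the residue's sequence/structure context is
optimized for. The machinery has three layers: environment-specific
statistical potentials, a per-residue free-energy decomposition, and a linear
scoring model trained against membrane annotations.

Structures are used as their biological assemblies: all chains in the file
act as interaction context, while scoring can be restricted to selected
chains. Waters, ligands and non-canonical residues are excluded from the
residue list (kept as het records).

## Descriptors

* **s** — amino-acid type, 20 canonical types, indexed alphabetically by
  one-letter code.
* **d** — distance between side-chain geometric centers (unweighted mean of
  side-chain heavy atoms; CA for Gly or when no side-chain atom is present),
  binned on [3.0, 8.0) Å in 0.2 Å steps. Same-chain pairs require sequence
  separation ≥ 2; inter-chain pairs have no separation constraint, so the
  quaternary environment counts.
* **t** — backbone torsion domain from (φ, ψ, ω). The default map has seven
  domains: a cis-ω domain **O** (|ω| < 90°) that overrides the rest, then by
  (φ, ψ): helical **A**, **C**, polyproline-band **P**, extended **B**,
  left-handed **G**, and catch-all **E**. ω of residue *i* is the peptide
  bond preceding it; terminal residues and residues at chain breaks
  (C–N > 2.5 Å) carry an "undefined" sentinel and are excluded from every
  observation that needs their torsion. The map is configuration data, not
  code.
* **a** — relative solvent accessibility: residue ASA in the assembly divided
  by a per-type extended Gly-X-Gly reference (bundled, editable; theoretical
  maxima of Tien et al. 2013), in percent, binned at [0, 5, 15, 30, 50, ∞).
  ASA uses Shrake–Rupley with a 1.4 Å probe over all heavy atoms via
  biotite; 10 000 sphere points per atom keep the orientation dependence of
  the discretization below ~0.25% absolute, comfortably inside the 0.5%
  tolerance the rotation-invariance test enforces.

All intervals are half-open [lo, hi) except the membrane slab, which is
closed: a residue is TM iff its centroid z ∈ [z\_lo, z\_hi].

## Counting and the inverse Boltzmann law

For each descriptor combination χ (default list: st, sa, sst, ssa, sd, tt,
aa, sds, saa, stt, ss; any ≤ 3-slot string over {s,d,t,a} matching a
supported pattern is accepted) and each environment μ ∈ {TM, EM},
observations are counted over all structures, admitting an observation only
if **every** participating residue is labeled μ. Torsion and accessibility
descriptors must lie within 8 positions of the amino-acid descriptor they
pair with (a 17-residue window centered on *s*); the pure-pair combos ss,
tt, aa use same-chain separations in [2, 8] — the ss window is stated for
the method, and tt/aa adopt it for consistency since nothing fixes them
separately.

Counting conventions, chosen so that every later identity is exact:

* exchangeable slot pairs (ss, tt, aa; the two s of sst/sds; the two a of
  saa; the two t of stt) are counted in both orders, making those tables
  exactly symmetric;
* each distance pair {i, j} under sd contributes both endpoint observations
  (s\_i, d\_ij) and (s\_j, d\_ij).

A pseudocount (default 1) is added to every joint cell; marginals and
lower-order joints are re-derived from the regularized joint, so
marginalization consistency holds exactly and no logarithm sees zero. With
the pseudocount disabled, unobserved cells are set to ΔW = 0 with a warning.
Energies are in units of kT with kT = 1: the regression coefficients absorb
any absolute scale, so fixing the temperature conventionally loses nothing.

First-order tables are ΔW(x,y) = −kT ln[F(x,y)/(F(x)F(y))]; second-order
ΔW(x,y,z) = −kT ln[F(x,y,z)F(x)F(y)F(z)/(F(x,y)F(x,z)F(y,z))]. Note what
this construction can and cannot see: because each environment's table is
normalized by that environment's own marginals, a pure composition shift
between TM and EM leaves the *tables* near zero — the discriminative power
of the final score comes from within-environment correlations and from
evaluating each environment's table on the actual window content of a
residue. This observation drives both the design of the synthetic data
(below) and the interpretation of individual tables.

## Per-residue energies

Every residue receives, for every (χ, μ), a folding free-energy contribution
regardless of where the residue actually sits — the TM/EM *difference* per
residue is what the model exploits.

Allocation follows "equal shares to the structure-descriptor carriers":

* st, sa, sst, ssa: the full ΔW of each observation goes to the residue
  carrying the torsion/accessibility descriptor, summed over all s-partners
  (or unordered partner pairs) in its window;
* ss, tt, aa, sds, saa, stt: each interaction's ΔW is split half/half
  between the two carriers (for saa/stt the s-carrier receives nothing);
  where counting symmetrized an observation into two orders, each order
  carries half of the symmetric ΔW, so the halves recombine exactly;
* sd: each endpoint observation carries ΔW/2 — i.e. the pair energy is the
  *mean* of its two endpoint values — split half/half between the
  endpoints. This symmetric convention keeps the conservation identity
  Σ\_i ΔG\_i = Σ\_interactions ΔW exact; any fixed alternative scaling would
  be absorbed by the regression coefficients.

Residues lacking a descriptor the combo requires (undefined torsion) are
masked: they contribute to no observation of that combo and carry 0.

Profiles are smoothed over the 5-residue window [i−2, i+2] with weights
(γ, β, 1, β, γ), normalizing by the weights of the residues actually present
at chain termini. Smoothing is linear and constant-preserving; with the
dyadic grid weights used in training it is constant-preserving bit-exactly.

## The scoring model

Features per residue: the 2 × |χ| smoothed energies plus ln L, with L the
residue count of the chain containing the residue (configurable to the whole
selection; "protein length" reads most naturally per polypeptide). The model

MPr\_i = Σ α\_χ^μ ΔḠ\_χ^(i,μ) + α\_L ln L + α\_N

is fitted by ordinary least squares (scikit-learn's LinearRegression)
against O\_i ∈ {0, 1}; a logistic variant is available but not default.
Constant feature columns are dropped (coefficient 0) with a warning. The
smoothing weights β, γ are selected by a grid search over
{0, 0.25, 0.5, 0.75, 1}² minimizing the training cost C under a full OLS
refit per grid point — a two-parameter grid is cheap, reproducible, and
avoids a nested optimization.

The classification threshold φ0 maximizes balanced accuracy
(½(TP/P + TN/N)) over the exhaustive candidate set of midpoints between
adjacent sorted unique training scores; ties resolve to the smallest
threshold. Balanced accuracy rather than raw accuracy is used because the
evaluation metric is balanced accuracy. σ^TM and σ^EM are the standard
deviations of the fitted training scores over TM- and EM-labeled residues.

Nine stability classes partition the score axis at
φ0 − 2σ^EM, −3/2σ^EM, −σ^EM, −½σ^EM, +½σ^TM, +σ^TM, +3/2σ^TM, +2σ^TM, with
upper-inclusive intervals. The printed class definitions assign the single
point φ0 + 2σ^TM to both of the top two classes; the partition here gives it
to "Highly stable in lipids", matching that row's ≥ and keeping the classes
a true partition.

Evaluation is strict protein-level leave-one-out: for each held-out protein
the potentials (per-structure count tensors are cached and subtracted, which
makes the fold suites exact and cheap), the β/γ grid, the coefficients and
φ0 are all re-derived from the remainder, and the held-out residues are
scored blind; predictions are pooled.

## Downstream analyses

* **Association score** T = [Σ MPr(complex) − Σ\_monomers Σ MPr] / n, n ∈
  {2, 4}. Monomer/complex residues correspond by (chain, residue number,
  insertion code); an explicit mapping handles renumbered conformers.
* **ΔMPr** between conformations on the shared residue keys (intersection
  with a warning when incomplete).
* **B-factor normalization**: per-residue means over heavy main-chain
  (N, CA, C, O) and side-chain atoms separately; outliers trimmed per chain
  by an iterative |x − median| > 3 · 1.4826 · MAD rule (≤ 5 iterations,
  optional — a robust, deterministic stand-in for the various published
  trimming recipes); then per-chain zero-mean-unit-variance or min-max
  scaling. Degenerate inputs (zero variance/range, < 2 residues) raise.
* **PyMOL writer**: one `color` command per residue using the bundled
  nine-step blue→grey→green palette (blue = water-stable,
  green = lipid-stable; editable data file).

## Synthetic data

The generator builds ideal α-helical bundles oriented along z: backbones are
extended atom-by-atom from ideal bond lengths/angles at (φ, ψ, ω) =
(−57°, −47°, 180°) (verified to reproduce those torsions exactly and a
1.556 Å/residue rise), each chain's helix axis rotated onto z with its TM
span centered at z = 0, chains placed on a ring with 9.5 Å axis separation.
The side chain is a single pseudo-atom at a residue-dependent 1.5–2.5 Å
offset along the *radial* direction from the helix axis; with the offset
horizontal, the centroid height equals the CA height, which makes the
construction guarantee (TM span inside the ±15 Å slab) exact and slab-mode
annotation identical to the stored labels. TM spans are capped at 20
residues because a longer ideal helix no longer fits a 30 Å slab.

Residue types are drawn iid from a lipid-facing composition inside the span
(L/I/V/F/A-rich, charged types at ~0.25%) and a solvent-exposed polar
composition outside (D/E/K/R/S/N-rich); both are editable data. The default
dataset emulates the protein class such analyses are trained on — polytopic
α-helical bundles of 6–10 TM helices, 45–55 residues per chain, ≈ 40% TM
residues overall. This scale matters: with an order of magnitude fewer
residues per protein, the fold-wise potential tables become noise-dominated
and pooled cross-validation scores degrade for statistical rather than
algorithmic reasons.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no rotamers or real side-chain packing, no
β-barrels, no loops or secondary-structure variety (every defined torsion is
helical, so the t-based potentials are nearly uninformative here), no
orientation-dependent burial correlations, no experimental noise or missing
atoms, and labels that are perfectly consistent with geometry (real membrane
annotations are themselves predictions). Synthetic benchmark numbers are
wiring checks of the pipeline under clean, separable conditions, not
estimates of performance on experimental structures.

Two further generators serve the tests: an iid-descriptor chain for the
independence null (any correct inverse-Boltzmann implementation must give
ΔW → 0 on it), and a linear-model instance (standard-normal features,
O = Xα + α\_N + ε clipped to [−0.5, 1.5]) for parameter recovery.

## Numerical choices

* Counting uses integer tensors; suites are order-invariant and
  deterministic by construction.
* Serialization (potential suites, models) writes floats with `repr`
  (shortest round-trip), so save/load is bit-identical; manifests carry a
  config hash and provenance, and scoring refuses descriptor tables built
  under a different configuration.
* Altloc conformers resolve to highest occupancy, ties to first in file.
* Residue keys are (chain id, residue number, insertion code) taken verbatim
  from the file; internal indices are 0-based and contiguous per chain.
* Grid/tie-breaks: the β/γ grid scans in lexicographic order keeping the
  first minimum; φ0 ties resolve to the smallest candidate.
* Degenerate inputs raise typed errors (single-label training sets, empty
  chain selections, invalid slabs, zero-variance B-factors); leave-one-out
  skips single-label folds with a warning and reports them.

## Known limitations

* The per-residue decomposition is a bookkeeping convention; only sums over
  interactions are physically meaningful, and alternative split conventions
  rescale features in ways the trained coefficients absorb.
* OLS on collinear energy features gives unstable individual coefficients at
  small training scale; predictions are stable, coefficient interpretation
  is not. No regularization is applied by design.
* The accessibility reference table and torsion-domain boundaries are
  conventional choices; both are configuration data and swapping them
  changes descriptor bins without code changes.
* The method's spatial resolution is bounded by the 17-residue window and
  the 5-residue smoothing: classification near TM/EM boundaries is
  intrinsically blurred by roughly ±3–4 residues.
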