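# Methods

## Kinetic model

The monomeric aqua synthon *fac*-[Re(CO)₃(H₂O)₃]⁺ (M) condenses into
dinuclear (D), trinuclear (T) and tetranuclear (Q) hydroxide-bridged
species. The package treats the overall formation orders as 2, 3 and 4 in
the monomer and keeps two layers deliberately separate:

* **Half-life algebra.** For −d[M]/dt = k[M]ⁿ, t½ = ln2/k (n = 1) and
  t½ = (2ⁿ⁻¹ − 1)/((n−1)·k·c₀ⁿ⁻¹) (n ≥ 2). `scale_half_life` uses only the
  proportionality t½ ∝ c₀^(1−n) and is independent of k;
  `calibrate_rate_constant` is the exact closed-form inverse. These carry
  the headline claim (tenfold concentration → thousandfold speed-up at
  order 4) without any integration.
* **ODE network.** `simulate_network` integrates mass action with LSODA
  (stiff-capable), rtol 1e−8, atol 1e−12·c₀, and asserts the rhenium
  balance [M] + 2[D] + 3[T] + 4[Q] = const to 1e−6·c₀ afterwards, raising
  instead of returning an unphysical trajectory.

Two modes exist because the chemistry narrative (stepwise monomer
addition) and the order argument (overall orders) are different idealisations:

* `stepwise` (default): M+M→D at k₂[M]², D+M→T at k₃[D][M], T+M→Q at
  k₄[T][M]. Here k₂ is an elementary bimolecular constant; the monomer
  decay with only k₂ active is 1/[M] = 1/c₀ + 2k₂t.
* `direct`: parallel empirical sinks with kₙ defined as the **observed
  monomer-consumption constant**: d[M]/dt = −Σ kₙ[M]ⁿ and
  dQ/dt = k₄[M]⁴/4 (the ¼ is the stoichiometric conversion of consumed
  monomer into cluster). This convention is chosen so that a constant
  calibrated by `calibrate_rate_constant` reproduces its target half-life
  inside the integrator exactly — the two code paths are mutually
  consistent by construction, and the test suite checks the round trip.

Whether the orders are elementary or empirical is not asserted; both
pictures are provided and neither is privileged beyond the default flag.

`formation_half_time` reads the time at which a product has captured half
(configurably, any fraction of) the convertible rhenium off the sampled
trajectory by linear interpolation between grid points. Its accuracy is
therefore grid-limited; sample densely around the expected crossing when
precision matters. A threshold never reached returns `None`, not an error.

Speciation: the aqua fraction follows Henderson–Hasselbalch,
1/(1 + 10^(pH−pKa)), pKa default 7.5. Coupling to the kinetics is **off**
by default because the mechanism linking protonation state to condensation
rate is not specified by the underlying chemistry; the opt-in coupling
simply multiplies all condensation rates by the deprotonated fraction.

Feasibility: ratio = formation half-time / isotope half-life; verdict
"accessible" for ratio ≤ 1 (inclusive), "marginal" to 10, else
"inaccessible"; both thresholds are parameters. One year is 8766 h
(365.25 d) everywhere.

`fit_rate_constants` refits (k₂,k₃,k₄) in log₁₀ space by
Levenberg–Marquardt on concentration residuals scaled by c₀. Recovery to
within 0.1 in log₁₀k from 1%-noise trajectories is demonstrated on a
40-point grid spanning roughly ten monomer half-lives; much longer
horizons with the same point count undersample the informative early
transient and degrade identifiability.

## Structural analysis

* **Distances and uncertainty.** σ(d) = √2·DPI, treating the Cruickshank
  DPI as an isotropic per-atom coordinate error with the two atoms
  independent. Whether deposited-structure esds are produced exactly this
  way varies by refinement protocol, so reports label σ as DPI-propagated.
* **Contact classification.** Default table: covalent sums Re–N 2.07,
  Re–O 2.03, Re–Re 2.74 Å; vdW limits Re–N 3.70, Re–O 3.67, Re–Re 4.30 Å.
  `bond_tolerance` = 0.8 Å above the covalent sum bounds coordination: it
  accepts the longest reported Re bonds (Re–N 2.6 Å) and rejects the
  2.9 Å contacts as van der Waals. Re–C (2.26/3.75 Å) and Re–Br
  (2.71/3.90 Å) entries are standard covalent-radii magnitudes added so
  the complex's own carbonyl and halide ligands classify; all entries are
  user-replaceable. `classify_contact` raises on a pair missing from the
  table; the batch scan `find_metal_sites` instead skips unknown-pair
  partners unless `strict=True`, so one exotic solvent atom cannot abort
  a whole-structure report.
* **Quasi bite angle.** Vertex at the metal: the angle between metal→a₁
  and metal→a₂ for two atoms of one residue. The alternative reading
  (vertex on a residue atom) is not implemented. `site_report` emits an
  angle for every amino-acid residue contributing ≥ 2 classified contacts
  to one metal, using the two shortest; the metal complex's own ligands
  (HETATM partners) are excluded from this grouping.
* **Cluster detection.** Graph on metal atoms, edge iff d ≤ 4.3 Å (the
  Re⋯Re van der Waals bound); edges ≤ 3.6 Å are labelled "formal", a
  cutoff placed just above the typical cluster distances 3.46/3.40 Å and
  the observed 3.2 Å contact. Components sort by descending nuclearity,
  then lowest serial. The implementation uses a KD-tree plus networkx
  components; tests hold it against a brute-force all-pairs union-find.
* **PDB handling.** Native fixed-column parser (element from columns
  77–78, falling back to the atom-name prefix; "RE" is rhenium, never
  carbon). Alternate locations collapse to the highest-occupancy
  conformer, ties broken by altloc letter. Occupancy is reported but
  never gates detection by default (sites down to 13% matter);
  `min_occupancy` filters on request. A single model is analysed as-is —
  no symmetry expansion, so crystal-contact geometry is out of scope.
  DPI travels in an artifact-defined `REMARK 3 DPI <value>` line.

## Anomalous-signal arithmetic

Peak height is taken proportional to occupancy × f″. The two shipped
reference points are Re f″ = 12.1 e at 0.9763 Å (L_I edge) and 5.9 e at
1.5418 Å (Cu Kα); their ratio 2.05 is the wavelength-choice enhancement,
independent of occupancy. No Kramers–Kronig computation, edge scanning or
data-quality modelling is attempted — arbitrary user-supplied (λ, f″)
points are accepted instead.

## Synthetic structures

The generator emulates the *motifs* of rhenium-soaked lysozyme structures,
not the protein fold: isolated ideal residues (imidazole as a regular
pentagon of side 1.37 Å, carboxylate with C–O 1.25 Å and O–C–O 124°)
carrying metal sites, plus the ideal cubane. Construction defaults the
underlying structures do not print — Re–O(μ₃-OH) 2.17 Å, Re–C 1.92 Å,
C–O 1.15 Å, aqua Re–O 2.18 Å — are standard small-molecule magnitudes,
exposed as parameters and recorded in the ground truth. The cubane edge
default 3.43 Å is the mean of the two typical cluster distances. The
cubane builder places the four μ₃-OH on outward face normals at the exact
Re–O distance (feasible only above the face circumradius, else it
raises) and the twelve carbonyls trans to the hydroxides.

Ground truth records pre-noise expectations (contacts with classes,
nuclearities, bite angles) as a JSON sidecar. Gaussian coordinate noise of
sd `noise_sigma` is seeded; noise-free output draws nothing from the
generator and is therefore seed-independent unless a motif requests a
random orientation. Because the fixtures are ideal and isolated, passing
tests demonstrate the correctness of the measurement/classification
machinery, **not** robustness to real-structure features: conformational
heterogeneity, solvent networks, symmetry mates and refinement artefacts
are absent by design.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs: ODE grids of 40–2000
points, random cluster fixtures of ≤ 30 metal atoms (100 seeds), and
single-motif structures of ≤ 50 atoms; the whole suite completes in a few
seconds. Tie-breaks and orderings (contact sort by metal serial then
distance, cluster sort by size then serial, altloc ties by letter) are
fixed so identical inputs give byte-identical outputs. Degenerate inputs
fail loudly: empty PDB files, zero-length angle vectors, non-increasing
time grids and mass-balance breaches all raise typed errors.

## Known limitations

* The kinetic orders are an idealisation; no mechanism fitting to
  spectroscopic data is attempted, and solvent effects (DMSO etc.) are
  not modelled.
* DPI propagation ignores correlation between refined positions and
  anisotropy of the error.
* The PDB writer emits the minimal record set (REMARK/CRYST1/ATOM/HETATM/
  END); anisotropic displacement and connectivity records are out of
  scope.
* mmCIF input is not parsed natively; convert to PDB first.
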