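# Methods

This note documents the mechanical model, every parameter default, the
numerical methods, and the deliberate scope limits of `perturbnet`.

## 1. Coarse-grained elastic network

Each residue is reduced to its Cα position; the assembly becomes a
network of N nodes joined by Hookean springs:

    V = 1/2 · Σ_(i<j) γ_ij (r_ij − r_ij⁰)²

where `r_ij` is the instantaneous and `r_ij⁰` the equilibrium
(input-structure) distance. Springs are placed by a distance cutoff and
their stiffness depends only on covalency:

| parameter            | default | unit  | meaning                                   |
|----------------------|---------|-------|-------------------------------------------|
| `cutoff`             | 10.0    | Å     | contact iff `r_ij⁰ < cutoff` (strict `<`) |
| `gamma_covalent`     | 82.0    | RT/Å² | consecutive residues of the same chain    |
| `gamma_noncovalent`  | 3.166   | RT/Å² | all other contacts within the cutoff      |

Consecutive residues of a chain (|Δindex| = 1) are always bonded with
the covalent constant, regardless of distance; the cutoff applies only
to noncovalent contacts. Energies are expressed in units of RT, so
spring constants carry RT/Å² and all displacement outputs are in
arbitrary units — only ratios of displacements are meaningful.

## 2. Hessian, spectrum, covariance

The second derivative of V at equilibrium gives the 3N×3N ANM Hessian
built from 3×3 super-elements

    H_ij = −(γ_ij / r_ij⁰²) · d_ij d_ijᵀ   (i ≠ j, d_ij = r_i − r_j)
    H_ii = −Σ_(j≠i) H_ij

The Hessian is symmetric positive semidefinite. It is diagonalized
densely (`scipy.linalg.eigh`); an eigenvalue counts as null when it is
below `1e-8 × λ_max`. A connected rigid body has exactly six null modes
(three translations, three rotations); any other count signals a
disconnected or floppy network and raises an error (the switch-off
screen relies on exactly this check to detect disconnecting removals).

The mechanical covariance is the Moore–Penrose pseudoinverse over the
non-null modes:

    C = Σ_(k>6) (1/λ_k) v_k v_kᵀ

## 3. Linear response to perturbing forces

Linear response theory maps a static force to the expected displacement

    Δr = β · C · F

with β a scalar force constant (default 1.0; only its sign and ratios
matter). Two force constructors are provided; both produce unit force
vectors per targeted residue so responses are shape-only:

- **Ligand-pocket force** — for each subunit, unit vectors pointing
  from a pseudo-ligand centre toward each pocket Cα, applied to all
  four subunits simultaneously (C4-symmetric perturbation mimicking
  pocket opening on ligand (un)binding). The pseudo-ligand centre for
  synthetic structures is the pocket centroid displaced 2 Å toward the
  symmetry axis, standing in for a bound ligand's heavy-atom centre
  which does not exist at Cα resolution.
- **Voltage-mimicking force** — `sign(formal charge) ×` unit axis on
  each formally charged residue (ARG/LYS +1, ASP/GLU −1; axis default
  (0,0,1), the membrane normal). Magnitude 1 per residue regardless of
  |charge|, matching the pocket-force convention.

## 4. Mode classification and response decomposition

For a C4 tetramer, gating-relevant cooperative modes move all four
subunits identically. Classification: for each non-null mode, compute
the N-vector of per-residue displacement magnitudes, split it into the
four chain quarters, and compute all six pairwise Pearson correlations.
The mode is **non-degenerate** iff the minimum correlation strictly
exceeds the threshold (default 0.95). A quarter with zero variance
contributes correlation 0 (logged). Additionally, members of numerically
degenerate eigenvalue pairs (relative gap < 1e-9) are always classified
degenerate: within an exactly degenerate eigenspace the solver returns
an arbitrary rotation of the pair, so a single member's magnitude
pattern is not well defined and can pass the correlation test by
accident — this matters on exactly symmetric structures, where E-type
pairs are exactly degenerate.

The overlap of two 3N vectors is the absolute cosine of their angle.
The best k-mode description of a response uses only non-degenerate
modes; because eigenvectors are orthonormal, ranking candidates by
individual overlap and keeping the top k **is** the exact best subset,
with coefficients `a_i = v_i · d̂`. Cumulative overlap is reported for
k = 1..k_max (default 10); it is non-decreasing by construction.

## 5. Symmetric contact switch-off screen

Candidates are **contact classes**: orbits of noncovalent contacts
under the chain successor permutation A→B→C→D (4 members, or 2 for
diagonal A–C-type pairs). Covalent springs are excluded — removing a
backbone bond models chain scission, not contact loss. Switching off a
class removes all member springs simultaneously, preserving C4
symmetry.

Significance criterion: both the baseline and the perturbed per-residue
magnitude profiles are divided by the **baseline** maximum magnitude
(LRT units are arbitrary, so the 0.1 threshold means "10 % of the peak
baseline displacement"); a class is significant iff in **every** subunit
at least `min_residues` residues (default 15) have |Δ magnitude| >
`delta_threshold` (default 0.1). Records are sorted by minimum
per-subunit count descending, ties broken lexicographically by the
representative pair. Raising either threshold can only remove
significant classes (monotonicity, tested).

Fast path: removing m springs is a rank-limited downdate H′ = H − BBᵀ,
where B has one column `√γ · n̂` per removed spring (entries +n̂ at node
i, −n̂ at node j). By the Woodbury identity the perturbed response is

    C′F = CF + CB (I_m − BᵀCB)⁻¹ BᵀCF

computed without re-diagonalizing. If `I_m − BᵀCB` is singular (minimum
eigenvalue < 1e-9) the removal creates a mechanism/disconnection; the
record is flagged `disconnecting` and no response is scored. The slow
path (full rebuild) flags the same condition through the null-count
check. Fast and full paths agree to better than 1e-8 of the peak
magnitude on every tested fixture.

## 6. Synthetic C4 tetramers

Since suitable real tetramer coordinates are not redistributable, the
generator builds toy assemblies with the features the analysis needs:
four equal chains related by exact 90° rotations about z, consecutive
Cα spacing ≈ 3.8 Å, a connected 10 Å contact graph, a six-residue
pocket per subunit, and charged residue types. One chain is laid out as
vertical helical segments (ideal 100°/residue twist, per-residue rise
±1.5 Å, local radius chosen so consecutive spacing is exactly 3.8 Å)
joined by circular-arc loops; segment axes are fanned around the
symmetry axis at ring radius 12 Å. Gaussian jitter (σ = 0.05 Å, seeded)
is applied to chain A **before** symmetrization, so the C4 symmetry of
the output is exact to machine precision — this keeps the
degenerate/non-degenerate eigensplit clean and makes the symmetry
assertions meaningful. If the contact graph is disconnected the build
retries at 0.85× the radius (up to 5 attempts).

Defaults (120 residues/chain, segments (1–55, +1.5 Å) and (66–120,
−1.5 Å), pocket residues 40, 42, 46, 58, 67, 108, seed 1) are fixed
study conditions, not tuned quantities; `default_segments(n)` scales the
two-helix layout proportionally for other chain lengths. The repeating
20-name pseudo-sequence includes ARG/LYS/ASP/GLU so voltage forces have
targets and the net charge per chain is zero.

## 7. Numerical choices and problem sizes

- Dense symmetric eigendecomposition (LAPACK via `scipy.linalg.eigh`);
  N ≈ 480 nodes (3N = 1440) diagonalizes in ~1 s and is the default
  study size. The implementation is dense throughout; structures beyond
  a few thousand residues would need sparse/iterative methods (out of
  scope).
- Contact search via `scipy.spatial.cKDTree`.
- Null tolerance 1e-8 relative to λ_max; Woodbury singularity tolerance
  1e-9 on the minimum eigenvalue of `I_m − BᵀCB`.
- All floating-point report files carry 10 significant digits; summary
  JSON is key-sorted, so identical configs and seeds give byte-identical
  summaries.
- The pipeline caches the spectrum keyed by a content hash of the
  network (node coordinates, contacts, spring constants); invalidation
  is by hash, never by timestamp.

## 8. Open choices, made explicit

- **Displacement-change scale.** "Change > 0.1" is undefined in
  absolute LRT units; we normalize both profiles by the baseline peak
  magnitude so 0.1 means 10 % of the peak. Documented because other
  scalings (per-residue relative change, RMS normalization) are
  defensible and change the significant set.
- **Classes vs springs.** The screen counts and ranks symmetric
  classes, not individual springs; one class removal always removes the
  whole orbit (2 or 4 springs).
- **Ligand centre at Cα resolution.** The pseudo-ligand point is a
  geometric construction (pocket centroid displaced toward the axis);
  with real structures a bound-ligand centre should be supplied
  explicitly.

## 9. Limitations

- Harmonic, topology-only mechanics: uniform noncovalent spring
  constant, no sequence-specific stiffness, no anharmonicity, no
  solvent or membrane.
- Responses are shape-only (arbitrary units); no absolute free energies
  or timescales.
- The screen removes one class at a time; simultaneous multi-class
  knockouts and alanine-scan-style per-residue deletions are non-goals.
- C4-specific: classification quarters and class orbits assume four
  equal chains; other symmetries would need generalized orbit and
  quarter definitions.
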