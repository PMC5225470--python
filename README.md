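# perturbnet

Elastic-network analysis of ligand- and voltage-driven conformational
responses in C4-symmetric (tetrameric) protein assemblies.

`perturbnet` implements a complete anisotropic network model (ANM) /
linear response theory (LRT) pipeline at Cα resolution:

1. **Structure → network.** Cα coordinates (read from a PDB file or
   generated synthetically) become an elastic network: springs connect
   residue pairs closer than a 10 Å cutoff, with a stiff backbone
   constant (82 RT/Å²) for consecutive residues of a chain and a softer
   uniform constant (3.166 RT/Å²) for all other contacts.
2. **Network → spectrum.** The 3N×3N ANM Hessian is diagonalized; a
   connected rigid assembly has exactly six zero modes (rigid-body
   translations/rotations), which is asserted, and the Moore–Penrose
   pseudoinverse over the remaining modes gives the mechanical
   covariance `C`.
3. **Perturbation → response.** Linear response theory maps an applied
   force to a displacement field, `Δr = β·C·F`. Two forces are built
   in: a ligand-pocket force (unit vectors from a pseudo-ligand centre
   toward each pocket Cα, applied symmetrically to all four subunits)
   and a voltage-mimicking force (membrane-normal push on formally
   charged residues, signed by charge).
4. **Mode decomposition.** Non-null modes are classified as
   *non-degenerate* (all four subunits move identically — the
   cooperative, gating-relevant modes) or *degenerate* using pairwise
   Pearson correlations between the four chain quarters of the
   per-residue magnitude pattern (threshold 0.95, strict). The LRT
   response is then decomposed into the best k-mode combination of
   non-degenerate modes, reporting cumulative overlaps.
5. **Contact switch-off screen.** Every noncovalent contact class (the
   orbit of a contact under the C4 chain permutation A→B→C→D) is
   switched off in turn — symmetrically, all four springs at once — and
   the perturbed LRT response is compared to the baseline. A class is
   *significant* when at least 15 residues of **every** subunit change
   their normalized displacement magnitude by more than 0.1 (fractions
   of the baseline peak). A Woodbury low-rank update makes the full
   screen run in seconds; removals that disconnect the network are
   flagged, never silently scored.

Because real tetrameric channel coordinates are not redistributable,
the package ships a generator for exactly C4-symmetric synthetic
tetramers (helical segments joined by arc loops, jitter applied before
symmetrization so the symmetry is exact to machine precision) that
exercise every part of the pipeline.

## Quick start (library)

```python
from perturbnet import (generate_c4_tetramer, build_network_model,
                        tetramer_pocket_force, pocket_centroid,
                        lrt_response, classify_degeneracy,
                        cumulative_overlap_report, screen_contacts)
from perturbnet.synthetic import DEFAULT_POCKET

structure = generate_c4_tetramer()                  # 480 residues, exact C4
network, spectrum, covariance = build_network_model(structure)
print(spectrum.null_count)                          # 6

force = tetramer_pocket_force(structure, DEFAULT_POCKET, pocket_centroid)
response = lrt_response(covariance, force)

cls = classify_degeneracy(spectrum, structure)
print(cumulative_overlap_report(spectrum, cls, response.delta_r, 3))
#    k  modes   overlap
# 0  1      1  0.914405
# 1  2    1,3  0.975538
# 2  3  1,3,2  0.993230

records = screen_contacts(network, structure, force, covariance=covariance)
print(len(records))                                 # 1069 contact classes
```

On the default synthetic tetramer the pocket-opening response is
dominated by the softest non-degenerate mode (overlap 0.91 with one
mode, 0.99 with three) — the same qualitative picture reported for
tetrameric channel gating, where a handful of soft cooperative modes
carry the ligand-induced motion.

## Quick start (CLI)

```sh
perturbnet makesim --n 120 --seed 1 --out tetramer.pdb
perturbnet pdb2net --in tetramer.pdb --out network.tsv
perturbnet lrt --structure tetramer.pdb --pocket 40,42,46,58,67,108 --out profile.tsv
perturbnet modes --structure tetramer.pdb --out overlap.tsv
perturbnet switchoff --structure tetramer.pdb --out screen.tsv
perturbnet run --config run.yaml        # full pipeline, reproducible bundle
```

Exit codes: 0 ok, 2 configuration/usage error, 3 stage error. A full
`run` writes `structure.pdb`, `network.tsv`, `profile.tsv`,
`response.nmd` (loadable in normal-mode viewers), `modes.tsv`,
`overlap.tsv`, `screen.tsv`, `summary.json` and `run.log` to the output
directory; the same config and seed give a byte-identical summary.

Minimal `run.yaml`:

```yaml
synthetic: true
n_residues_per_chain: 120
seed: 1
out_dir: out
```

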