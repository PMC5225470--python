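"""End-to-end orchestration with config, caching, logging and reporting.

One call runs the whole analysis in method order: structure (read or
synthesised) -> contact map -> Hessian spectrum -> pocket (and
optionally voltage) force -> LRT response -> mode classification and
cumulative-overlap decomposition -> contact switch-off screen.  Every
run writes a reproducible bundle: network edge list, displacement
profile and arrow fields, overlap table, screen table, a machine-
readable JSON summary embedding the resolved config and content hashes,
and a log.  Given the same input, config and seed the summary is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enm import (DEFAULT_CUTOFF, GAMMA_COVALENT, GAMMA_NONCOVALENT,
                  build_contact_map, build_hessian, diagonalize, pseudoinverse)
from .lrt import displacement_profile, lrt_response, tetramer_pocket_force, voltage_force
from .modes import DEGENERACY_THRESHOLD, classify_degeneracy, cumulative_overlap_report
from .structure import read_pdb_calpha, write_displacement_field, write_pdb
from .switchoff import (DELTA_THRESHOLD, MIN_RESIDUES, screen_contacts,
                        screen_to_frame)
from .synthetic import (DEFAULT_POCKET, TetramerSpec, default_segments,
                        generate_c4_tetramer, pocket_centroid)

logger = logging.getLogger("perturbnet")

SUMMARY_SCHEMA_VERSION = 1
_FLOAT_FMT = "%.10g"  # 10 significant digits in all report files


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class RunConfig:
    # input: either a PDB path or a synthetic tetramer spec
    structure_path: str | None = None
    synthetic: bool = True
    n_residues_per_chain: int = 120
    seed: int = 1
    # network
    cutoff: float = DEFAULT_CUTOFF
    gamma_covalent: float = GAMMA_COVALENT
    gamma_noncovalent: float = GAMMA_NONCOVALENT
    # perturbation
    pocket_residues: tuple = DEFAULT_POCKET
    beta: float = 1.0
    voltage: bool = False
    voltage_axis: tuple = (0.0, 0.0, 1.0)
    # mode analysis
    degeneracy_threshold: float = DEGENERACY_THRESHOLD
    k_max: int = 10
    # switch-off screen
    run_screen: bool = True
    delta_threshold: float = DELTA_THRESHOLD
    min_residues: int = MIN_RESIDUES
    exhaustive_screen: bool = False
    # output
    out_dir: str = "perturbnet_out"

    def validate(self) -> None:
        if not self.synthetic and not self.structure_path:
            raise ConfigError("either synthetic=true or a structure_path is required")
        for name in ("cutoff", "gamma_covalent", "gamma_noncovalent",
                     "degeneracy_threshold", "delta_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.k_max < 1 or self.min_residues < 0:
            raise ConfigError("k_max must be >= 1 and min_residues >= 0")

    # -- serialization round trip -------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pocket_residues"] = list(self.pocket_residues)
        d["voltage_axis"] = list(self.voltage_axis)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        d = dict(d)
        if "pocket_residues" in d:
            d["pocket_residues"] = tuple(d["pocket_residues"])
        if "voltage_axis" in d:
            d["voltage_axis"] = tuple(d["voltage_axis"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    have = {getattr(h, "_perturbnet_tag", None) for h in logger.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._perturbnet_tag = "stderr"
        h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(h)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh._perturbnet_tag = "file"
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    for h in [h for h in logger.handlers if getattr(h, "_perturbnet_tag", None) == "file"]:
        logger.removeHandler(h)
        h.close()
    logger.addHandler(fh)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("perturbnet %s starting", __version__)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - annotate with the stage name
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    # structure -------------------------------------------------------
    if config.synthetic:
        spec = TetramerSpec(n_residues_per_chain=config.n_residues_per_chain,
                            helix_segments=default_segments(config.n_residues_per_chain),
                            pocket_residues=tuple(config.pocket_residues),
                            seed=config.seed)
        structure = stage("synthesize", generate_c4_tetramer, spec)
        stage("write-structure", write_pdb, structure, out / "structure.pdb")
    else:
        structure = stage("read-structure", read_pdb_calpha, config.structure_path)
    logger.info("structure: %d nodes, chains %s", structure.n_nodes, structure.chains)

    # network + spectrum ---------------------------------------------
    network = stage("contact-map", build_contact_map, structure, config.cutoff,
                    config.gamma_covalent, config.gamma_noncovalent)
    network.to_tsv(out / "network.tsv")
    net_hash = network.content_hash()
    spectrum = stage("diagonalize", diagonalize, build_hessian(network),
                     1e-8, True, net_hash)
    covariance = stage("pseudoinverse", pseudoinverse, spectrum)
    # cache the spectrum keyed by network content hash (invalidation is by
    # hash only; the screen's baseline is reused, never recomputed)
    cache = out / f"spectrum-{net_hash}.npz"
    if not cache.exists():
        np.savez_compressed(cache, eigenvalues=spectrum.eigenvalues,
                            eigenvectors=spectrum.eigenvectors,
                            null_count=spectrum.null_count)
    logger.info("network: %d contacts; null modes: %d",
                len(network.contacts), spectrum.null_count)

    # force + response -------------------------------------------------
    if config.voltage:
        force = stage("voltage-force", voltage_force, structure, config.beta,
                      config.voltage_axis)
    else:
        force = stage("pocket-force", tetramer_pocket_force, structure,
                      tuple(config.pocket_residues), pocket_centroid, config.beta)
    response = stage("lrt", lrt_response, covariance, force, net_hash)
    profile = displacement_profile(response, structure)
    profile.to_csv(out / "profile.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)
    write_displacement_field(structure, response.delta_r, out / "response.nmd",
                             format="nmd", name="lrt_response")
    write_displacement_field(structure, response.delta_r, out / "response.tsv",
                             format="tsv")

    # mode decomposition ----------------------------------------------
    classification = stage("classify-modes", classify_degeneracy, spectrum,
                           structure, config.degeneracy_threshold)
    classification.to_frame().to_csv(out / "modes.tsv", sep="\t", index=False,
                                     float_format=_FLOAT_FMT)
    overlap_table = stage("overlap", cumulative_overlap_report, spectrum,
                          classification, response.delta_r, config.k_max)
    overlap_table.to_csv(out / "overlap.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
    n_nondeg = len(classification.non_degenerate_indices)
    logger.info("modes: %d non-degenerate of %d; best k=%d overlap %.4f",
                n_nondeg, len(classification.modes),
                int(overlap_table["k"].iloc[-1]),
                float(overlap_table["overlap"].iloc[-1]))

    # switch-off screen ------------------------------------------------
    summary_screen = None
    if config.run_screen:
        records = stage("switchoff", screen_contacts, network, structure, force,
                        config.delta_threshold, config.min_residues, covariance,
                        not config.exhaustive_screen)
        screen_to_frame(records).to_csv(out / "screen.tsv", sep="\t", index=False,
                                        float_format=_FLOAT_FMT)
        summary_screen = {
            "n_classes": len(records),
            "n_significant": int(sum(r.significant for r in records)),
            "n_disconnecting": int(sum(r.disconnecting for r in records)),
            "top_contacts": [r.contact_class.label for r in records[:5]],
        }
        logger.info("screen: %d classes, %d significant",
                    summary_screen["n_classes"], summary_screen["n_significant"])

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "perturbnet_version": __version__,
        "config": config.to_dict(),
        "network_hash": net_hash,
        "n_nodes": structure.n_nodes,
        "n_contacts": len(network.contacts),
        "null_mode_count": spectrum.null_count,
        "force": force.description,
        "n_non_degenerate_modes": n_nondeg,
        "overlap_table": [
            {"k": int(r.k), "modes": r.modes, "overlap": float(f"{r.overlap:.10g}")}
            for r in overlap_table.itertuples()
        ],
        "screen": summary_screen,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", out)
    return summary
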