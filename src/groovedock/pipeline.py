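"""Round orchestration, ensemble pooling, evaluation, and output writing.

One round = anchor alignment -> backbone sampling -> sidechain packing ->
energy minimization -> anchor filtering. The receptor used in round k > 1 is
taken from the best-scored pose pooled so far (the minimized receptor), so
receptor sidechain rearrangements feed back into sampling. The ensemble is
the union of surviving poses over all rounds; nothing is pruned. Anchor
positions can optionally be re-derived from the best pose each round
(anchor-template recycling), but this is off by default.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .anchors import (
    AnchorSpec,
    TemplateEntry,
    TemplateRegistry,
    anchor_deviation,
    anchor_spec_from_peptide,
    default_template_registry,
    extract_anchor_spec,
    groove_superpose,
)
from .geometry import superpose
from .loop_closure import ClosureConfig, sample_backbones
from .scoring import (
    EnergyBreakdown,
    MinimizeConfig,
    ScoringWeights,
    minimize_pose,
    select_flexible_sidechains,
)
from .sidechains import build_sidechains
from .structure import Structure, chain_sequence, read_pdb, write_pdb

__all__ = [
    "PipelineConfig",
    "ScoredPose",
    "Ensemble",
    "EmptyEnsembleError",
    "run_round",
    "run_pipeline",
    "best_pose",
    "ensemble_min_rmsd",
]

logger = logging.getLogger("groovedock")

GROOVE_RESIDUES = 180  # heavy-chain ordinals used for evaluation superposition


class EmptyEnsembleError(RuntimeError):
    """No pose survived any round."""


@dataclass
class PipelineConfig:
    peptide_sequence: str = ""
    receptor_source: str | Structure = ""
    template_source: str | TemplateEntry | TemplateRegistry = "default"
    n_rounds: int = 10
    closure: ClosureConfig = field(default_factory=ClosureConfig)
    weights: ScoringWeights = field(default_factory=ScoringWeights)
    minimize: MinimizeConfig = field(default_factory=MinimizeConfig)
    anchor_filter_threshold: float = 2.0
    flexible_radius: float = 4.0
    rng_seed: int = 0
    output_dir: str | None = None
    carry: str = "pooled"  # or "last-round"
    update_anchor_template: bool = False
    dump_backbones: bool = False  # write sampled backbones as PDB fragments

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.peptide_sequence and not (8 <= len(self.peptide_sequence) <= 15):
            raise ValueError("peptide length must be 8-15")
        if self.carry not in ("pooled", "last-round"):
            raise ValueError("carry must be 'pooled' or 'last-round'")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(
            replace(self,
                    receptor_source=str(getattr(self.receptor_source, "label",
                                                self.receptor_source)),
                    template_source=str(getattr(self.template_source, "source_id",
                                                self.template_source))))
        return d


@dataclass
class ScoredPose:
    peptide: Structure
    receptor: Structure
    energy: EnergyBreakdown
    round_index: int
    sample_index: int
    anchor_deviations: dict[int, float]
    seed: int = 0

    @property
    def anchor_dev_max(self) -> float:
        return max(self.anchor_deviations.values())


@dataclass
class Ensemble:
    poses: list[ScoredPose] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.poses)


def best_pose(e: Ensemble | list[ScoredPose]) -> ScoredPose:
    """Pose with minimum total energy; ties break to the earlier round, then
    the lower sample index."""
    poses = e.poses if isinstance(e, Ensemble) else e
    if not poses:
        raise EmptyEnsembleError("ensemble is empty")
    return min(poses, key=lambda p: (p.energy.total, p.round_index, p.sample_index))


def run_round(receptor: Structure, spec: AnchorSpec, cfg: PipelineConfig,
              round_index: int) -> list[ScoredPose]:
    """One sampling round; returns only poses passing the anchor filter."""
    closure_cfg = replace(cfg.closure, rng_seed=cfg.rng_seed * 1009 + round_index)
    backbones = sample_backbones(cfg.peptide_sequence, spec, receptor, closure_cfg)
    if cfg.dump_backbones and cfg.output_dir:
        _dump_backbones(cfg, backbones, round_index)
    if not backbones:
        logger.warning("round %d: no clash-free closed backbone sampled", round_index)
        return []
    survivors: list[ScoredPose] = []
    for sample_index, backbone in enumerate(backbones):
        peptide = build_sidechains(backbone, cfg.peptide_sequence, receptor,
                                   chain_id="P")
        flexible = select_flexible_sidechains(receptor, peptide, cfg.flexible_radius)
        result = minimize_pose(peptide, receptor, flexible, cfg.weights, cfg.minimize)
        if result is None:
            continue
        pep_min, rec_min, energy = result
        deviations = anchor_deviation(pep_min, spec)
        if max(deviations.values()) > cfg.anchor_filter_threshold:
            continue
        survivors.append(ScoredPose(
            peptide=pep_min, receptor=rec_min, energy=energy,
            round_index=round_index, sample_index=sample_index,
            anchor_deviations=deviations, seed=closure_cfg.rng_seed,
        ))
    logger.info("round %d: %d/%d poses survive; best %s", round_index,
                len(survivors), len(backbones),
                min((p.energy.total for p in survivors), default=float("nan")))
    return survivors


def _dump_backbones(cfg: PipelineConfig, backbones, round_index: int) -> None:
    from .structure import Atom, Chain, Residue
    from .structure import ONE_TO_THREE

    out = os.path.join(cfg.output_dir, "backbones")
    os.makedirs(out, exist_ok=True)
    for k, b in enumerate(backbones):
        chain = Chain(id="P")
        for i, aa in enumerate(b.sequence):
            res = Residue(name=ONE_TO_THREE[aa], seq_id=i + 1)
            for j, nm in enumerate(("N", "CA", "C", "O")):
                res.atoms.append(Atom(nm, nm[0], b.coords[i, j].copy(), i + 1))
            chain.residues.append(res)
        path = os.path.join(out, f"backbone_r{round_index:02d}_s{k:03d}.pdb")
        with open(path, "w") as fh:
            fh.write(write_pdb(Structure(chains=[chain], label="backbone")))


def _resolve_receptor(cfg: PipelineConfig) -> Structure:
    if isinstance(cfg.receptor_source, Structure):
        return cfg.receptor_source.copy()
    with open(cfg.receptor_source) as fh:
        return read_pdb(fh.read(), label=os.path.basename(str(cfg.receptor_source)))


def _resolve_template(cfg: PipelineConfig, n: int) -> TemplateEntry:
    src = cfg.template_source
    if isinstance(src, TemplateEntry):
        return src
    if isinstance(src, TemplateRegistry):
        return src[n]
    if src == "default":
        return default_template_registry()[n]
    with open(src) as fh:
        structure = read_pdb(fh.read(), label=os.path.basename(str(src)))
    peptide_chains = [c for c in structure.chains if len(c) == n]
    if len(peptide_chains) != 1:
        raise ValueError(
            f"template {src}: expected exactly one chain of {n} residues, "
            f"found {len(peptide_chains)}"
        )
    return TemplateEntry(n, structure, peptide_chains[0].id,
                         os.path.splitext(os.path.basename(str(src)))[0])


def run_pipeline(cfg: PipelineConfig) -> Ensemble:
    """Multi-round ensemble generation (the full method)."""
    receptor = _resolve_receptor(cfg)
    n = len(cfg.peptide_sequence)
    template = _resolve_template(cfg, n)
    ensemble = Ensemble(config=cfg.snapshot())
    log_lines = [f"peptide {cfg.peptide_sequence}  template {template.source_id}  "
                 f"seed {cfg.rng_seed}"]
    for round_index in range(1, cfg.n_rounds + 1):
        transform = groove_superpose(receptor, template)
        spec = extract_anchor_spec(template, transform, n)
        poses = run_round(receptor, spec, cfg, round_index)
        ensemble.poses.extend(poses)
        best_total = min((p.energy.total for p in ensemble.poses),
                         default=float("nan"))
        log_lines.append(f"round {round_index}: {len(poses)} survivors, "
                         f"pooled {len(ensemble.poses)}, best {best_total:.4f}")
        if ensemble.poses:
            pool = poses if cfg.carry == "last-round" else ensemble.poses
            carrier = best_pose(pool) if pool else best_pose(ensemble.poses)
            receptor = carrier.receptor
            if cfg.update_anchor_template:
                combined = Structure(
                    chains=[carrier.receptor.chains[0], carrier.peptide.chains[0]],
                    label=f"round{round_index}-best")
                template = TemplateEntry(n, combined,
                                         carrier.peptide.chains[0].id,
                                         f"round{round_index}-best")
    if not ensemble.poses:
        raise EmptyEnsembleError(
            "no pose survived any round; increase n_samples, restarts, or the "
            "anchor filter threshold"
        )
    if cfg.output_dir:
        _write_outputs(cfg, ensemble)
        with open(os.path.join(cfg.output_dir, "run.log"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    return ensemble


def scores_tsv(e: Ensemble) -> str:
    """Fixed-format per-pose score table (byte-stable for a given run)."""
    cols = ["pose_id", "round", "sample", "gauss1", "gauss2", "repulsion",
            "hydrophobic", "hbond", "electrostatic", "total", "anchor_dev_max"]
    lines = ["\t".join(cols)]
    for p in e.poses:
        pose_id = f"r{p.round_index:02d}_s{p.sample_index:03d}"
        en = p.energy
        lines.append("\t".join([
            pose_id, str(p.round_index), str(p.sample_index),
            f"{en.gauss1:.6f}", f"{en.gauss2:.6f}", f"{en.repulsion:.6f}",
            f"{en.hydrophobic:.6f}", f"{en.hbond:.6f}", f"{en.electrostatic:.6f}",
            f"{en.total:.6f}", f"{p.anchor_dev_max:.6f}",
        ]))
    return "\n".join(lines) + "\n"


def _write_outputs(cfg: PipelineConfig, e: Ensemble) -> None:
    out = cfg.output_dir
    assert out is not None
    os.makedirs(os.path.join(out, "poses"), exist_ok=True)
    for p in e.poses:
        pose = Structure(chains=[p.receptor.chains[0], p.peptide.chains[0]],
                         label="pose")
        path = os.path.join(out, "poses",
                            f"pose_r{p.round_index:02d}_s{p.sample_index:03d}.pdb")
        with open(path, "w") as fh:
            fh.write(write_pdb(pose))
    bp = best_pose(e)
    best = Structure(chains=[bp.receptor.chains[0], bp.peptide.chains[0]],
                     label="best")
    with open(os.path.join(out, "best.pdb"), "w") as fh:
        fh.write(write_pdb(best))
    with open(os.path.join(out, "scores.tsv"), "w") as fh:
        fh.write(scores_tsv(e))
    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump(e.config, fh, indent=2, default=str)


def _find_peptide_chain(reference: Structure, sequence: str):
    for chain in reference.chains:
        try:
            if chain_sequence(chain) == sequence:
                return chain
        except KeyError:
            continue
    raise ValueError("reference has no peptide chain matching the sequence")


def _groove_cas(chain) -> np.ndarray:
    pts = []
    for res in chain.residues[:GROOVE_RESIDUES]:
        a = res.atom("CA")
        if a is not None:
            pts.append(a.pos)
    return np.array(pts).reshape(-1, 3)


def _matched_peptide_coords(pose_chain, ref_chain, ca_only: bool):
    a_pts, b_pts = [], []
    for pres, rres in zip(pose_chain.residues, ref_chain.residues):
        for atom in pres.atoms:
            if ca_only and atom.name != "CA":
                continue
            ref_atom = rres.atom(atom.name)
            if ref_atom is not None:
                a_pts.append(atom.pos)
                b_pts.append(ref_atom.pos)
    return np.array(a_pts).reshape(-1, 3), np.array(b_pts).reshape(-1, 3)


def ensemble_min_rmsd(e: Ensemble, reference: Structure) -> tuple[float, float]:
    """Minimum (full-heavy-atom, CA-only) peptide RMSD to a reference pose.

    Each pose's receptor groove is superposed onto the reference groove and
    the peptide deviation is measured in that frame with no further fitting,
    so translated binding modes are penalized. Sidechain symmetry (e.g. the
    two PHE ring orientations) is not relabelled.
    """
    if not e.poses:
        raise EmptyEnsembleError("ensemble is empty")
    sequence = chain_sequence(e.poses[0].peptide.chains[0])
    ref_pep = _find_peptide_chain(reference, sequence)
    ref_rec = next(c for c in reference.chains if c is not ref_pep)
    ref_cas = _groove_cas(ref_rec)
    best_full = best_ca = float("inf")
    for p in e.poses:
        pose_cas = _groove_cas(p.receptor.chains[0])
        m = min(len(ref_cas), len(pose_cas))
        t, _ = superpose(ref_cas[:m], pose_cas[:m])
        pose_pep = p.peptide.copy().chains[0]
        for res in pose_pep.residues:
            for a in res.atoms:
                a.pos = t.apply(a.pos)
        full_a, full_b = _matched_peptide_coords(pose_pep, ref_pep, ca_only=False)
        ca_a, ca_b = _matched_peptide_coords(pose_pep, ref_pep, ca_only=True)
        if len(full_a) == 0 or len(ca_a) == 0:
            raise ValueError("no matched peptide atoms between pose and reference")
        best_full = min(best_full,
                        float(np.sqrt(np.mean(np.sum((full_a - full_b) ** 2, axis=1)))))
        best_ca = min(best_ca,
                      float(np.sqrt(np.mean(np.sum((ca_a - ca_b) ** 2, axis=1)))))
    return best_full, best_ca
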