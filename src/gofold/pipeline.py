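"""End-to-end pipeline: prepare → unfold → fold ensemble → analyze → report.

Orchestrates the library over one system (one native structure, optionally
carrying the m2,2G modification) with full seed management: a master seed
spawns independent per-trajectory seeds, and the manifest written at the end
records every seed and parameter needed to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    classify_pathway,
    contact_frequency_map,
    corner_vs_diagonal,
    free_energy_profile,
    pathway_fractions,
    q2d_histogram,
    trajectory_order_parameters,
)
from .contacts import build_native_contacts, write_contact_tsv
from .dynamics import (
    SimulationState,
    generate_unfolded_ensemble,
    run_folding,
    spawn_seeds,
)
from .energy import GoParameters, GoSystem
from .structures import (
    StructureError,
    apply_m22g,
    assign_domains,
    parse_domain_config,
    read_structure,
    write_frame,
    write_trajectory_pdb,
)
from .synthetic import randomize_unfolded

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_from_manifest"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial results are preserved on disk."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one system)."""

    structure_path: str
    domains_path: str
    out_dir: str
    modification: int | None = None     # residue index for m2,2G, or None
    n_trajectories: int = 60
    t_unfold: tuple[float, float] = (550.0, 700.0)
    t_fold: float = 353.0
    q_stop: float = 0.8
    max_steps_unfold: int = 500_000
    max_steps_fold: int = 2_000_000
    dt: float = 0.002
    friction: float = 1.0
    stride: int = 100
    n_bins: int = 20
    persistence: int = 5
    master_seed: int = 0
    unfold_method: str = "dynamics"     # "dynamics" (high-T) | "randomize"
    save_frames: bool = False
    params: GoParameters = field(default_factory=GoParameters)

    def __post_init__(self):
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.unfold_method not in ("dynamics", "randomize"):
            raise ValueError("unfold_method must be 'dynamics' or 'randomize'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["t_unfold"] = list(self.t_unfold)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["t_unfold"] = tuple(d.get("t_unfold", (550.0, 700.0)))
        d["params"] = GoParameters(**d.get("params", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _check_paths(config: RunConfig) -> None:
    for p in (config.structure_path, config.domains_path):
        if not Path(p).exists():
            raise PipelineError(f"input path does not exist: {p}")


def run_pipeline(config: RunConfig, until: str = "report",
                 resume: bool = False) -> dict:
    """Run stages up to ``until``; return the report bundle (also on disk).

    Per system this produces: the (possibly modified) native structure and
    contact-map TSV, an unfolded ensemble, folding trajectories with their
    outcomes and Q series, F(Q), the Q_tsl×Q_dsl histogram, residue contact
    frequencies, the pathway summary, and a manifest with every seed.  A
    stage failure preserves earlier results and marks the stage failed in
    the manifest.  With ``resume`` a previously written unfolded ensemble in
    ``out_dir`` is reused instead of regenerated.
    """
    order = ["prepare", "unfold", "fold", "analyze", "report"]
    if until not in order:
        raise ValueError(f"until must be one of {order}")
    _check_paths(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "param_hash": config.params.hash(),
        "stages": {},
    }
    bundle: dict = {}

    def stage(name, fn):
        if order.index(name) > order.index(until):
            return
        t0 = time.time()
        try:
            fn()
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.time() - t0, 2),
            }
            logger.info("stage %s ok (%.1fs)", name, time.time() - t0)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(out, manifest)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    ctx: dict = {}

    # ---- prepare ----------------------------------------------------------
    def prepare():
        structure = read_structure(config.structure_path)
        if config.modification is not None:
            # fail fast (before any simulation) on a non-G residue
            structure = apply_m22g(structure, config.modification)
        partition = assign_domains(
            structure, parse_domain_config(config.domains_path)
        )
        cmap = build_native_contacts(structure, cutoff=config.params.cutoff)
        if cmap.n_contacts == 0:
            raise StructureError("native structure yields no contacts")
        system = GoSystem(structure, cmap, config.params)
        write_frame(structure, structure.coordinates(), out / "native.pdb")
        write_contact_tsv(cmap, out / "contacts.tsv")
        ctx.update(structure=structure, partition=partition, cmap=cmap,
                   system=system)

    stage("prepare", prepare)

    # ---- unfold -----------------------------------------------------------
    def unfold():
        structure, cmap = ctx["structure"], ctx["cmap"]
        seeds = spawn_seeds(config.master_seed, config.n_trajectories + 1)
        manifest["unfold_seeds"] = seeds[:-1]
        ensemble_file = out / "unfolded_ensemble.pdb"
        if resume and ensemble_file.exists():
            from .structures import read_trajectory_pdb

            frames = read_trajectory_pdb(ensemble_file)
            if len(frames) == config.n_trajectories:
                ctx["starts"] = list(frames)
                return
        if config.unfold_method == "dynamics":
            starts = generate_unfolded_ensemble(
                structure, cmap, config.params, config.n_trajectories,
                T_range=config.t_unfold, seed=config.master_seed,
                max_steps=config.max_steps_unfold, dt=config.dt,
                friction=config.friction, stride=config.stride,
            )
            coords = [s.positions for s in starts]
        else:
            coords = [
                randomize_unfolded(structure, seed=sd, cmap=cmap,
                                   lambda_formed=config.params.lambda_formed)
                for sd in seeds[:-1]
            ]
        write_trajectory_pdb(structure, np.array(coords),
                             out / "unfolded_ensemble.pdb")
        ctx["starts"] = coords

    stage("unfold", unfold)

    # ---- fold -------------------------------------------------------------
    def fold():
        system = ctx["system"]
        fold_seeds = spawn_seeds(config.master_seed + 1, config.n_trajectories)
        manifest["fold_seeds"] = fold_seeds
        trajectories = []
        for k, (x0, sd) in enumerate(zip(ctx["starts"], fold_seeds)):
            traj = run_folding(
                SimulationState(np.asarray(x0), np.zeros_like(x0)),
                system, T=config.t_fold, q_stop=config.q_stop,
                max_steps=config.max_steps_fold, seed=sd, dt=config.dt,
                friction=config.friction, stride=config.stride,
            )
            trajectories.append(traj)
            if config.save_frames:
                write_trajectory_pdb(ctx["structure"], traj.frames,
                                     out / f"trajectory_{k:03d}.pdb")
        ctx["trajectories"] = trajectories

    stage("fold", fold)

    # ---- analyze ----------------------------------------------------------
    def analyze():
        cmap, partition = ctx["cmap"], ctx["partition"]
        lam = config.params.lambda_formed
        # domains without intra-domain contacts cannot carry a Q series
        with_contacts = [
            n for n in partition.names()
            if any(a in partition[n] and b in partition[n]
                   for a, b in cmap.residue_pairs())
        ]
        sub = {n: partition[n] for n in with_contacts}
        from .structures import DomainPartition
        part_q = DomainPartition(domains=sub)

        series, labels, rows = [], [], []
        for k, traj in enumerate(ctx["trajectories"]):
            ser = trajectory_order_parameters(
                traj.frames, traj.times, cmap, part_q, lam
            )
            series.append(ser)
            lab = classify_pathway(ser, q_fold=config.q_stop,
                                   persistence=config.persistence)
            labels.append(lab)
            df = pd.DataFrame({"time_ps": ser.times, "q": ser.q_global})
            for n, qd in ser.q_domain.items():
                df[f"q_{n}"] = qd
            df.to_csv(out / f"q_series_{k:03d}.tsv", sep="\t", index=False,
                      float_format="%.6f")
            rows.append({"trajectory": k, "outcome": traj.outcome,
                         "seed": traj.metadata["seed"],
                         "n_steps": traj.metadata["n_steps"],
                         "label": lab.label})
        pd.DataFrame(rows).to_csv(out / "outcomes.tsv", sep="\t", index=False)

        pooled = np.concatenate([s.q_global for s in series])
        prof = free_energy_profile(pooled, T=config.t_fold,
                                   n_bins=config.n_bins)
        pd.DataFrame({
            "q_center": prof.bin_centers, "F_kcal_mol": prof.F,
            "count": prof.occupancy,
        }).to_csv(out / "free_energy.tsv", sep="\t", index=False,
                  float_format="%.6f")

        if "tsl" in part_q and "dsl" in part_q:
            hist, edges = q2d_histogram(series, "tsl", "dsl", n_bins=10)
            np.savetxt(out / "q2d_tsl_dsl.tsv", hist, delimiter="\t",
                       fmt="%.1f")
            corner, diag = corner_vs_diagonal(hist, edges)
            bundle["q2d_corner_mass"] = corner
            bundle["q2d_diagonal_mass"] = diag

        freq = sum(
            contact_frequency_map(t.frames, cmap, ctx["structure"].n_residues,
                                  lam)
            for t in ctx["trajectories"]
        ) / len(ctx["trajectories"])
        np.savetxt(out / "contact_frequency.tsv", freq, delimiter="\t",
                   fmt="%.4f")

        summary = pathway_fractions(labels)
        with open(out / "pathways.json", "w") as fh:
            json.dump(
                {
                    "fractions_pct": summary.fractions,
                    "counts": summary.counts,
                    "per_trajectory": [
                        {"label": p.label, "events": p.events, "tie": p.tie}
                        for p in summary.per_trajectory
                    ],
                },
                fh, indent=2,
            )
        bundle.update(
            pathway_fractions=summary.fractions,
            outcomes=[t.outcome for t in ctx["trajectories"]],
            free_energy=prof,
            series=series,
            trajectories=ctx["trajectories"],
            structure=ctx["structure"],
            partition=ctx["partition"],
            cmap=cmap,
        )

    stage("analyze", analyze)

    # ---- report -----------------------------------------------------------
    def report():
        n_folded = sum(1 for t in ctx["trajectories"] if t.outcome == "folded")
        bundle["n_folded"] = n_folded
        manifest["n_folded"] = n_folded
        _write_manifest(out, manifest)

    stage("report", report)
    bundle["manifest"] = manifest
    return bundle


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def compare_systems(
    bundle_modified: dict,
    bundle_unmodified: dict,
    focus_residue: int,
    neighbors: list[int],
    gate: dict[str, float] | None = None,
    hb_partner: int | None = None,
    out_path=None,
) -> pd.DataFrame:
    """Δd (base center-of-mass shifts) and N_HB between two pipeline runs.

    ``bundle_modified``/``bundle_unmodified`` are :func:`run_pipeline` return
    values for the m2,2G and plain systems.  For every neighbor residue the
    table reports d_modified, d_unmodified and Δd = d_mod − d_unmod, averaged
    over all frames passing the per-domain Q ``gate``; negative Δd means the
    neighbor sits closer to the focus residue in the modified system.  With
    ``hb_partner`` set, the mean heavy-atom hydrogen-bond count between focus
    and partner bases is appended for both systems.
    """
    from .analysis import base_com_delta, hbond_count

    rows = []
    ens = tuple(
        [t.frames for t in b["trajectories"]]
        for b in (bundle_modified, bundle_unmodified)
    )
    structures = (bundle_modified["structure"], bundle_unmodified["structure"])
    cmaps = (bundle_modified["cmap"], bundle_unmodified["cmap"])
    partitions = (bundle_modified["partition"], bundle_unmodified["partition"])
    for nb in neighbors:
        res = base_com_delta(ens, structures, focus_residue, nb, gate=gate,
                             cmaps=cmaps, partitions=partitions)
        rows.append({"neighbor": nb, "d_modified_A": res["modified"],
                     "d_unmodified_A": res["unmodified"],
                     "delta_d_A": res["delta"]})
    df = pd.DataFrame(rows)
    if hb_partner is not None:
        means = []
        for b in (bundle_modified, bundle_unmodified):
            counts = [
                hbond_count(frame, b["structure"], focus_residue, hb_partner)
                for t in b["trajectories"] for frame in t.frames
            ]
            means.append(float(np.mean(counts)))
        df.attrs["nhb_modified"] = means[0]
        df.attrs["nhb_unmodified"] = means[1]
    if out_path is not None:
        with open(out_path, "w") as fh:
            if hb_partner is not None:
                fh.write(f"# focus={focus_residue} hb_partner={hb_partner} "
                         f"NHB_modified={df.attrs['nhb_modified']:.4f} "
                         f"NHB_unmodified={df.attrs['nhb_unmodified']:.4f}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    return df


def run_from_manifest(manifest_path, out_dir) -> dict:
    """Reproduce a run from its manifest alone (same platform ⇒ same bytes)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    config.out_dir = str(out_dir)
    return run_pipeline(config)
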