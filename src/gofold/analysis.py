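"""Folding analysis: Q, free-energy profiles, pathway classification and
local-interaction measures.

Q is the fraction of native contacts formed (a contact counts as formed when
r_ij < λ·σ_ij, λ = 1.2 by default).  The free-energy profile along Q is
F(Q) = −kB·T·ln P(Q) from the pooled Q histogram.  A trajectory's folding
pathway is the order in which the structural domains first keep their
intra-domain Q above a threshold persistently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import HB_ACCEPTORS, HB_DONORS, KB
from .contacts import ContactMap
from .structures import DomainPartition, NativeStructure

logger = logging.getLogger(__name__)

__all__ = [
    "OrderParameterSeries",
    "FreeEnergyProfile",
    "PathwayLabel",
    "EnsembleSummary",
    "compute_q",
    "trajectory_order_parameters",
    "free_energy_profile",
    "classify_pathway",
    "pathway_fractions",
    "contact_frequency_map",
    "q2d_histogram",
    "corner_vs_diagonal",
    "base_com_delta",
    "hbond_count",
]


@dataclass
class OrderParameterSeries:
    """Q(t): global plus per-domain, all in [0, 1]."""

    times: np.ndarray
    q_global: np.ndarray
    q_domain: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class FreeEnergyProfile:
    """F(Q) = −kB·T·ln P(Q); empty bins are NaN; global minimum shifted to 0."""

    bin_edges: np.ndarray
    F: np.ndarray
    occupancy: np.ndarray
    temperature: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class PathwayLabel:
    """Ordered domain folding events and the arrow-joined label string."""

    events: list[tuple[str, float]]
    label: str
    tie: bool = False


@dataclass
class EnsembleSummary:
    """Pathway composition of a trajectory ensemble (percentages and counts)."""

    per_trajectory: list[PathwayLabel]
    fractions: dict[str, float]
    counts: dict[str, int]


# ---------------------------------------------------------------------------
# Q
# ---------------------------------------------------------------------------

def _contact_mask_for_domain(cmap: ContactMap, domain: set[int] | None,
                             name: str = "") -> np.ndarray:
    if domain is None:
        return np.ones(cmap.n_contacts, dtype=bool)
    mask = np.array(
        [(a in domain and b in domain) for a, b in cmap.residue_pairs()],
        dtype=bool,
    )
    if not mask.any():
        raise ValueError(
            f"domain {name or sorted(domain)} has no intra-domain native contacts"
        )
    return mask


def compute_q(
    frame: np.ndarray,
    cmap: ContactMap,
    lambda_formed: float = 1.2,
    domain: set[int] | None = None,
    domain_name: str = "",
) -> float:
    """Fraction of native contacts with r < λ·σ in ``frame``.

    With ``domain`` given (a set of residue indices), only contacts whose two
    residues both lie in the domain are counted.
    """
    if cmap.n_contacts == 0:
        raise ValueError("contact map is empty")
    mask = _contact_mask_for_domain(cmap, domain, domain_name)
    frame = np.asarray(frame, dtype=float)
    d = np.linalg.norm(frame[cmap.i_idx[mask]] - frame[cmap.j_idx[mask]], axis=1)
    return float(np.mean(d < lambda_formed * cmap.sigma[mask]))


def trajectory_order_parameters(
    frames: np.ndarray,
    times: np.ndarray,
    cmap: ContactMap,
    partition: DomainPartition | None = None,
    lambda_formed: float = 1.2,
) -> OrderParameterSeries:
    """Vectorised Q(t), global and per domain, over a stack of frames."""
    frames = np.asarray(frames, dtype=float)
    d = np.linalg.norm(
        frames[:, cmap.i_idx, :] - frames[:, cmap.j_idx, :], axis=2
    )  # (F, C)
    formed = d < lambda_formed * cmap.sigma[None, :]
    q_global = formed.mean(axis=1)
    q_domain: dict[str, np.ndarray] = {}
    if partition is not None:
        for name in partition.names():
            mask = _contact_mask_for_domain(cmap, partition[name], name)
            q_domain[name] = formed[:, mask].mean(axis=1)
    return OrderParameterSeries(
        times=np.asarray(times, dtype=float), q_global=q_global,
        q_domain=q_domain,
    )


# ---------------------------------------------------------------------------
# Free energy
# ---------------------------------------------------------------------------

def free_energy_profile(
    q_samples, T: float, n_bins: int = 20
) -> FreeEnergyProfile:
    """F(Q) = −kB·T·ln P(Q) from the pooled Q histogram, minimum at 0.

    Empty bins are masked (NaN) rather than smoothed.
    """
    q = np.asarray(list(q_samples), dtype=float)
    if q.size == 0:
        raise ValueError("q_samples is empty")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("Q samples must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(q, bins=edges)
    p = counts / counts.sum()
    F = np.full(n_bins, np.nan)
    occ = counts > 0
    F[occ] = -KB * T * np.log(p[occ])
    F -= np.nanmin(F)
    return FreeEnergyProfile(bin_edges=edges, F=F, occupancy=counts,
                             temperature=T)


# ---------------------------------------------------------------------------
# Pathways
# ---------------------------------------------------------------------------

def classify_pathway(
    series: OrderParameterSeries,
    q_fold: float = 0.8,
    persistence: int = 5,
) -> PathwayLabel:
    """Order of domain folding events in one trajectory.

    A domain folds at the first frame where its Q exceeds ``q_fold`` and stays
    above it for ``persistence`` consecutive frames (suppressing transient
    spikes).  Domains that never fold are absent; if none folds the label is
    "none".  Exact ties in folding time are broken by domain name order and
    flagged.
    """
    n_frames = len(series.times)
    if n_frames < persistence:
        raise ValueError(
            f"series has {n_frames} frames, fewer than persistence={persistence}"
        )
    events: list[tuple[str, float]] = []
    for name in sorted(series.q_domain):
        above = series.q_domain[name] > q_fold
        fold_frame = None
        run = 0
        for idx, ok in enumerate(above):
            run = run + 1 if ok else 0
            if run == persistence:
                fold_frame = idx - persistence + 1
                break
        if fold_frame is not None:
            events.append((name, float(series.times[fold_frame])))
    events.sort(key=lambda e: (e[1], e[0]))
    tie = len({t for _, t in events}) < len(events)
    label = "→".join(name for name, _ in events) if events else "none"
    return PathwayLabel(events=events, label=label, tie=tie)


def pathway_fractions(ensemble: list[PathwayLabel]) -> EnsembleSummary:
    """Percentage of trajectories per distinct pathway label."""
    if not ensemble:
        raise ValueError("ensemble is empty")
    counts: dict[str, int] = {}
    for p in ensemble:
        counts[p.label] = counts.get(p.label, 0) + 1
    total = len(ensemble)
    fractions = {k: 100.0 * v / total for k, v in counts.items()}
    return EnsembleSummary(per_trajectory=list(ensemble), fractions=fractions,
                           counts=counts)


# ---------------------------------------------------------------------------
# Residue-residue interactions
# ---------------------------------------------------------------------------

def contact_frequency_map(
    frames: np.ndarray,
    cmap: ContactMap,
    n_residues: int,
    lambda_formed: float = 1.2,
) -> np.ndarray:
    """Symmetric (R, R) matrix of residue-pair contact formation frequencies.

    Entry (a, b) is the fraction of frames in which at least one native atom
    contact between residues a and b is formed.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    rp = np.array(cmap.residue_pairs(), dtype=np.int64)  # 1-based
    d = np.linalg.norm(frames[:, cmap.i_idx, :] - frames[:, cmap.j_idx, :],
                       axis=2)
    formed = d < lambda_formed * cmap.sigma[None, :]
    freq = np.zeros((n_residues, n_residues))
    # unique residue pairs and contact membership
    pair_ids = (rp[:, 0] - 1) * n_residues + (rp[:, 1] - 1)
    uniq, inverse = np.unique(pair_ids, return_inverse=True)
    for f in range(len(frames)):
        any_formed = np.zeros(len(uniq), dtype=bool)
        np.logical_or.at(any_formed, inverse, formed[f])
        a = uniq[any_formed] // n_residues
        b = uniq[any_formed] % n_residues
        freq[a, b] += 1.0
    freq /= len(frames)
    freq = np.maximum(freq, freq.T)
    return freq


def q2d_histogram(
    series_list: list[OrderParameterSeries],
    dom_x: str = "tsl",
    dom_y: str = "dsl",
    n_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled 2-D histogram of (Q_domx, Q_domy) over an ensemble."""
    qx = np.concatenate([s.q_domain[dom_x] for s in series_list])
    qy = np.concatenate([s.q_domain[dom_y] for s in series_list])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _, _ = np.histogram2d(qx, qy, bins=(edges, edges))
    return hist, edges


def corner_vs_diagonal(hist: np.ndarray, edges: np.ndarray) -> tuple[float, float]:
    """Mass in the one-domain-folded corners vs the concerted diagonal band.

    Corners: (Qx > 0.8, Qy < 0.2) and (Qx < 0.2, Qy > 0.8) — one stem loop
    folded while the other is not.  Diagonal: |Qx − Qy| < 0.2 with both in
    (0.2, 0.8) — the signature of concomitant folding.  Sequential folding
    puts more mass in the corners than on the diagonal.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    corner = ((cx > 0.8) & (cy < 0.2)) | ((cx < 0.2) & (cy > 0.8))
    diagonal = (np.abs(cx - cy) < 0.2) & (cx > 0.2) & (cx < 0.8) \
        & (cy > 0.2) & (cy < 0.8)
    return float(hist[corner].sum()), float(hist[diagonal].sum())


# ---------------------------------------------------------------------------
# Local structure around a focus residue
# ---------------------------------------------------------------------------

def _base_com(frame: np.ndarray, structure: NativeStructure,
              residue_index: int) -> np.ndarray:
    res = structure.residue(residue_index)
    base = res.base_atoms
    if not base:
        raise ValueError(f"residue {residue_index} has no base atoms")
    idx = np.array([a.index - 1 for a in base])
    m = np.array([a.mass for a in base])
    return (frame[idx] * m[:, None]).sum(axis=0) / m.sum()


def _gated_frames(frames, cmap, partition, gate, lambda_formed):
    if not gate:
        return np.asarray(frames, dtype=float)
    series = trajectory_order_parameters(
        frames, np.arange(len(frames)), cmap, partition, lambda_formed
    )
    keep = np.ones(len(frames), dtype=bool)
    for name, qmin in gate.items():
        keep &= series.q_domain[name] > qmin
    return np.asarray(frames, dtype=float)[keep]


def base_com_delta(
    ensembles: tuple[list[np.ndarray], list[np.ndarray]],
    structures: tuple[NativeStructure, NativeStructure],
    focus_residue: int,
    neighbor: int,
    gate: dict[str, float] | None = None,
    cmaps: tuple[ContactMap, ContactMap] | None = None,
    partitions: tuple[DomainPartition, DomainPartition] | None = None,
    lambda_formed: float = 1.2,
) -> dict[str, float]:
    """Δd = d_modified − d_unmodified of base center-of-mass distances.

    ``ensembles`` is (modified frame stacks, unmodified frame stacks); ``d``
    is averaged over all frames passing the per-domain Q ``gate`` (e.g.
    ``{"asl": 0.8}`` keeps frames recorded after the anticodon stem loop has
    folded).  Negative Δd means the neighbor sits closer to the focus residue
    in the modified system.
    """
    labels = ("modified", "unmodified")
    means = {}
    for which, (frame_stacks, structure) in enumerate(zip(ensembles, structures)):
        dists = []
        for frames in frame_stacks:
            frames = np.asarray(frames, dtype=float)
            if frames.ndim == 2:
                frames = frames[None]
            if gate:
                frames = _gated_frames(
                    frames, cmaps[which], partitions[which], gate, lambda_formed
                )
            for frame in frames:
                a = _base_com(frame, structure, focus_residue)
                b = _base_com(frame, structure, neighbor)
                dists.append(float(np.linalg.norm(a - b)))
        if not dists:
            raise ValueError(
                f"no frames satisfy the gate {gate} in the {labels[which]} ensemble"
            )
        means[labels[which]] = float(np.mean(dists))
    means["delta"] = means["modified"] - means["unmodified"]
    return means


def hbond_count(
    frame: np.ndarray,
    structure: NativeStructure,
    res_a: int,
    res_b: int,
    threshold: float = 3.5,
) -> int:
    """Base-base hydrogen bonds between two residues (heavy-atom criterion).

    Counts unique donor/acceptor heavy-atom pairs closer than ``threshold``
    (3.5 Å default), in either direction, using fixed per-base donor and
    acceptor lists.  Symmetric in (res_a, res_b).
    """
    frame = np.asarray(frame, dtype=float)
    ra = structure.residue(res_a)
    rb = structure.residue(res_b)
    pairs: set[tuple[int, int]] = set()
    found_chemistry = False
    for r1, r2 in ((ra, rb), (rb, ra)):
        donors = [a for a in r1.base_atoms if a.name in HB_DONORS.get(r1.base, set())]
        acceptors = [a for a in r2.base_atoms
                     if a.name in HB_ACCEPTORS.get(r2.base, set())]
        if donors and acceptors:
            found_chemistry = True
        for d in donors:
            for acc in acceptors:
                r = np.linalg.norm(frame[d.index - 1] - frame[acc.index - 1])
                if r < threshold:
                    pairs.add((min(d.index, acc.index), max(d.index, acc.index)))
    if not found_chemistry:
        logger.info(
            "residues %d/%d have no donor/acceptor atoms; H-bond count is 0",
            res_a, res_b,
        )
    return len(pairs)
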