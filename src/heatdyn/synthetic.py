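"""Synthetic conformational ensembles with planted statistical structure.

Three generators provide ground truth for every analysis stage without
any molecular-dynamics data:

* Gaussian ensembles whose bead displacements follow a prescribed
  block correlation matrix (tests the DCCM / correlation-score path);
* two-rigid-segment hinge motions with an immobile pivot (tests RMSF
  minima, PC1 amplitude minima and switch-region detection);
* donor–H–acceptor geometry series with a prescribed hydrogen-bond
  occupancy (tests the occupancy analysis, frame-exactly).

All generators are deterministic given their seed; the seed and the
planted parameters are recorded in the returned ensemble's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import AtomTable, Ensemble

__all__ = [
    "BlockCovarianceSpec", "HingeSpec", "HBondSeriesSpec",
    "build_correlation_matrix", "sample_gaussian_ensemble",
    "make_hinge_ensemble", "make_hbond_ensemble", "make_bead_table",
]

#: Cα–Cα spacing used for generated bead chains, Å.
BEAD_SPACING = 3.8

_PSD_TOL = 1e-8


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockCovarianceSpec:
    """Block correlation structure: named blocks of beads, one intra-block
    correlation per block, and an inter-block correlation per block pair."""

    blocks: tuple[tuple[str, int], ...]          # (name, size in beads)
    intra: tuple[float, ...]                     # per block, in [-1, 1]
    inter: tuple[tuple[float, ...], ...]         # symmetric, per block pair
    per_bead_stddev: float = 1.0                 # Å

    def __post_init__(self) -> None:
        k = len(self.blocks)
        if len(self.intra) != k:
            raise ValueError("need one intra-block correlation per block")
        if len(self.inter) != k or any(len(r) != k for r in self.inter):
            raise ValueError("inter must be a KxK matrix over blocks")
        inter = np.asarray(self.inter, dtype=float)
        if not np.allclose(inter, inter.T):
            raise ValueError("inter-block correlation matrix must be symmetric")
        vals = np.concatenate([np.asarray(self.intra, float), inter.ravel()])
        if (np.abs(vals) > 1).any():
            raise ValueError("correlations must lie in [-1, 1]")
        if any(s < 1 for _, s in self.blocks):
            raise ValueError("block sizes must be >= 1")
        if self.per_bead_stddev < 0:
            raise ValueError("per_bead_stddev must be >= 0")

    @property
    def n_beads(self) -> int:
        return sum(s for _, s in self.blocks)


@dataclass(frozen=True)
class HingeSpec:
    """Two straight rigid segments of beads joined at a pivot, opening and
    closing in a plane: angle(t) = amplitude * sin(phase_t), phases uniform.

    Bead layout: beads ``0 .. n1-1`` form segment 1 (outermost bead first),
    bead ``n1`` is the pivot, beads ``n1 .. n1+n2-1`` form segment 2. The
    pivot bead sits at the joint and never moves in the generated frames.
    """

    segment_lengths: tuple[int, int]
    opening_amplitude: float          # degrees, peak-to-centre
    n_frames: int
    seed: int
    hinge_index: int | None = None    # defaults to n1 (first bead of segment 2)
    rest_angle: float = 30.0          # equilibrium inter-segment angle, degrees

    def __post_init__(self) -> None:
        n1, n2 = self.segment_lengths
        if n1 < 3 or n2 < 3:
            raise ValueError("each segment needs at least 3 beads")
        if not 0 <= self.opening_amplitude < 180:
            raise ValueError("opening amplitude must be in [0, 180) degrees")
        if self.hinge_index is not None and self.hinge_index != n1:
            raise ValueError(
                f"hinge_index must equal segment 1 length ({n1}); "
                "the pivot is the first bead of segment 2")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def pivot(self) -> int:
        return self.segment_lengths[0]

    @property
    def n_beads(self) -> int:
        return sum(self.segment_lengths)


@dataclass(frozen=True)
class HBondSeriesSpec:
    """Donor–hydrogen–acceptor geometry series with planted occupancy.

    Each frame is independently in the bound geometry with probability
    ``target_occupancy``, otherwise in the unbound geometry. The bound
    geometry must satisfy the default detection criterion (heavy-atom
    distance <= 3.3 Å, D–H···A angle >= 145°) and the unbound geometry
    must violate it; both are validated at construction.
    """

    target_occupancy: float
    n_frames: int
    seed: int
    bound_geometry: tuple[float, float] = (2.9, 165.0)    # (d_DA Å, DHA °)
    unbound_geometry: tuple[float, float] = (4.5, 120.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target occupancy must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def make_bead_table(n_beads: int, chain_id: str = "A",
                    residue_name: str = "ALA") -> AtomTable:
    """Atom table of ``n_beads`` Cα-only pseudo-residues on one chain."""
    return AtomTable.from_records(
        atom_names=["CA"] * n_beads,
        residue_numbers=list(range(1, n_beads + 1)),
        residue_names=[residue_name] * n_beads,
        chain_ids=[chain_id] * n_beads,
        elements=["C"] * n_beads,
    )


def _straight_chain(n_beads: int, spacing: float = BEAD_SPACING) -> np.ndarray:
    """Bead coordinates along x, one bead per residue."""
    coords = np.zeros((n_beads, 3))
    coords[:, 0] = spacing * np.arange(n_beads)
    return coords


# ---------------------------------------------------------------------------
# block-correlated Gaussian ensembles
# ---------------------------------------------------------------------------

def build_correlation_matrix(spec: BlockCovarianceSpec) -> np.ndarray:
    """Expand a block spec into the full bead-level correlation matrix.

    The matrix is symmetric with unit diagonal and entries exactly as
    specified per block pair. Feasibility is verified: the smallest
    eigenvalue must be >= -1e-8, otherwise the spec is rejected.
    """
    sizes = [s for _, s in spec.blocks]
    n = sum(sizes)
    bounds = np.cumsum([0] + sizes)
    corr = np.empty((n, n))
    for a in range(len(sizes)):
        sa = slice(bounds[a], bounds[a + 1])
        corr[sa, sa] = spec.intra[a]
        for b in range(a + 1, len(sizes)):
            sb = slice(bounds[b], bounds[b + 1])
            corr[sa, sb] = spec.inter[a][b]
            corr[sb, sa] = spec.inter[a][b]
    np.fill_diagonal(corr, 1.0)
    w = np.linalg.eigvalsh(corr)
    if w[0] < -_PSD_TOL:
        raise ValueError(
            "infeasible correlation spec: smallest eigenvalue "
            f"{w[0]:.6g} < 0 (matrix not positive semidefinite)")
    return corr


def sample_gaussian_ensemble(mean_coords: np.ndarray,
                             correlation: np.ndarray,
                             stddev: float,
                             n_frames: int,
                             seed: int,
                             atom_table: AtomTable | None = None,
                             direction: str = "shared") -> Ensemble:
    """Draw i.i.d. frames whose bead displacements follow ``correlation``.

    Displacements are scalar Gaussians (stddev Å, correlation as given)
    applied along a fixed random unit direction. With the default
    ``direction="shared"`` every bead uses the same direction, so the
    vector dot-product cross-correlation of the ensemble equals the
    planted scalar correlation exactly in expectation. With
    ``direction="per_bead"`` each bead gets its own random direction and
    the observable correlation is attenuated by the direction cosines.
    """
    mean_coords = np.asarray(mean_coords, dtype=float)
    n = mean_coords.shape[0]
    if correlation.shape != (n, n):
        raise ValueError("correlation matrix must be n_beads x n_beads")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2 (covariance undefined below)")
    if direction not in ("shared", "per_bead"):
        raise ValueError("direction must be 'shared' or 'per_bead'")
    w, V = np.linalg.eigh(np.asarray(correlation, dtype=float))
    if w[0] < -_PSD_TOL:
        raise ValueError(
            f"correlation matrix not PSD (smallest eigenvalue {w[0]:.6g})")
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    if direction == "shared":
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        dirs = np.tile(u, (n, 1))
    else:
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    z = rng.standard_normal((n_frames, n)) @ L.T     # correlated scalars
    coords = mean_coords[None, :, :] + stddev * z[:, :, None] * dirs[None, :, :]
    table = atom_table if atom_table is not None else make_bead_table(n)
    return Ensemble(table, coords, metadata={
        "generator": "gaussian_block",
        "seed": seed,
        "stddev": stddev,
        "direction_mode": direction,
        "directions": dirs.tolist(),
    })


# ---------------------------------------------------------------------------
# hinge ensembles
# ---------------------------------------------------------------------------

def make_hinge_ensemble(spec: HingeSpec) -> tuple[Ensemble, int]:
    """Generate a two-segment hinge-opening ensemble.

    Returns ``(ensemble, pivot_bead_index)``. Segment 1 and segment 2 are
    straight rigid rods meeting at the pivot; per frame both rotate
    symmetrically about the pivot in the xy-plane by ±delta/2 where
    ``delta = opening_amplitude * sin(phase)`` and phases are sampled
    uniformly on [0, 2π). Intra-segment distances are exactly constant
    and the pivot bead never moves in the generated coordinates.
    """
    n1, n2 = spec.segment_lengths
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_frames)
    deltas = np.deg2rad(spec.opening_amplitude) * np.sin(phases)
    half_rest = 0.5 * np.deg2rad(spec.rest_angle)

    # template distances from the pivot (pivot itself at distance 0)
    d1 = BEAD_SPACING * np.arange(n1, 0, -1)       # beads 0..n1-1
    d2 = BEAD_SPACING * np.arange(0, n2)           # beads n1..n1+n2-1

    coords = np.empty((spec.n_frames, n1 + n2, 3))
    for t, delta in enumerate(deltas):
        a1 = half_rest + 0.5 * delta    # segment 1 direction angle
        a2 = -half_rest - 0.5 * delta   # segment 2 direction angle
        u1 = np.array([np.cos(a1), np.sin(a1), 0.0])
        u2 = np.array([np.cos(a2), np.sin(a2), 0.0])
        coords[t, :n1] = d1[:, None] * u1[None, :]
        coords[t, n1:] = d2[:, None] * u2[None, :]
    table = make_bead_table(n1 + n2)
    ens = Ensemble(table, coords, metadata={
        "generator": "hinge",
        "seed": spec.seed,
        "pivot_index": spec.pivot,
        "opening_amplitude_deg": spec.opening_amplitude,
    })
    return ens, spec.pivot


# ---------------------------------------------------------------------------
# hydrogen-bond geometry series
# ---------------------------------------------------------------------------

def _dha_coordinates(d_da: float, angle_dha: float) -> np.ndarray:
    """Coordinates (donor N, hydrogen, acceptor O) realising the given
    donor–acceptor distance (Å) and donor–H···acceptor angle (degrees).

    Donor at origin, hydrogen at (1, 0, 0) (1.0 Å N–H bond); the acceptor
    is placed in the xy-plane at the prescribed angle at the hydrogen and
    heavy-atom distance from the donor.
    """
    r_dh = 1.0
    donor = np.zeros(3)
    hyd = np.array([r_dh, 0.0, 0.0])
    theta = np.deg2rad(angle_dha)
    # direction of H->A makes angle theta with H->D (= -x)
    direction = np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
    # |hyd + L*direction| = d_da  ->  L^2 + 2 L (hyd.dir) + r_dh^2 - d_da^2 = 0
    b = float(hyd @ direction)
    disc = b * b - (r_dh ** 2 - d_da ** 2)
    if disc < 0:
        raise ValueError(
            f"geometry infeasible: d(D,A)={d_da} Å with DHA={angle_dha}°")
    L = -b + np.sqrt(disc)
    acc = hyd + L * direction
    return np.stack([donor, hyd, acc])


def make_hbond_ensemble(spec: HBondSeriesSpec) -> Ensemble:
    """Three-atom (donor, hydrogen, acceptor) ensemble whose frames flip
    between a bound and an unbound geometry with the planted occupancy.

    The realized bound-frame count is recorded in
    ``metadata["bound_frames"]`` so occupancy recovery can be checked
    frame-exactly.
    """
    from .hbonds import HBondCriterion, _geometry_satisfies

    crit = HBondCriterion()
    bound = _dha_coordinates(*spec.bound_geometry)
    unbound = _dha_coordinates(*spec.unbound_geometry)
    if not _geometry_satisfies(bound[0], bound[1], bound[2], crit):
        raise ValueError("bound geometry fails the default H-bond criterion")
    if _geometry_satisfies(unbound[0], unbound[1], unbound[2], crit):
        raise ValueError("unbound geometry passes the default H-bond criterion")
    rng = np.random.default_rng(spec.seed)
    is_bound = rng.random(spec.n_frames) < spec.target_occupancy
    coords = np.where(is_bound[:, None, None], bound[None], unbound[None])
    table = AtomTable.from_records(
        atom_names=["N", "H1", "O"],
        residue_numbers=[1, 1, 2],
        residue_names=["DON", "DON", "ACC"],
        chain_ids=["A", "A", "A"],
        elements=["N", "H", "O"],
    )
    return Ensemble(table, coords, metadata={
        "generator": "hbond_series",
        "seed": spec.seed,
        "target_occupancy": spec.target_occupancy,
        "bound_frames": int(is_bound.sum()),
        "realized_occupancy": float(is_bound.mean()),
    })
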