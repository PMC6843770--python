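"""Hydrogen-bond detection and occupancy analysis.

A donor–acceptor pair counts as hydrogen-bonded in a frame when the
heavy-atom distance is at most 3.3 Å and the best donor–H···acceptor
angle over the donor's hydrogens is at least 145° (the linearity
convention of the common trajectory-analysis tools; both thresholds
configurable). Occupancy is the fraction of window frames satisfying
the criterion. A distance-only mode (no angle test) supports
structures without hydrogens and salt-bridge-style contacts.

Donors and acceptors are assigned from the atom table: acceptors are
all N/O heavy atoms; donors are N/O atoms with at least one hydrogen
within 1.2 Å in the reference frame (coordinate files carry no bond
table, so covalent hydrogens are inferred geometrically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Ensemble
from .superpose import resolve_window

__all__ = ["HBondCriterion", "HBondOccupancy", "assign_donors_acceptors",
           "hbond_occupancy", "compare_occupancies", "occupancy_frame"]

_HEAVY = ("N", "O")
_H_BOND_MAX = 1.2  # Å, covalent D–H inference cutoff


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    ``angle_threshold=None`` selects distance-only mode. The angle
    convention is DHA_min: the donor–H···acceptor angle must be at
    least the threshold (near-linear bonds pass).
    """

    max_heavy_distance: float = 3.3       # Å, donor–acceptor heavy atoms
    angle_threshold: float | None = 145.0  # degrees, D–H···A minimum
    angle_convention: str = "DHA_min"

    def __post_init__(self) -> None:
        if self.max_heavy_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if self.angle_threshold is not None and not \
                0 < self.angle_threshold <= 180:
            raise ValueError("angle threshold must be in (0, 180]")
        if self.angle_convention != "DHA_min":
            raise ValueError("only the DHA_min angle convention is supported")

    @property
    def distance_only(self) -> bool:
        return self.angle_threshold is None


@dataclass
class HBondOccupancy:
    """Occupancy of one donor–acceptor pair over the analysis window."""

    donor: tuple[str, int, str]       # (chain, residue, atom name)
    acceptor: tuple[str, int, str]
    occupancy: float
    n_frames: int
    count: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.occupancy <= 1.0
        assert self.count == round(self.occupancy * self.n_frames)


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle at b (degrees) for broadcastable point arrays."""
    v1 = a - b
    v2 = c - b
    cos = (v1 * v2).sum(axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1))
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def _geometry_satisfies(donor: np.ndarray, hydrogen: np.ndarray,
                        acceptor: np.ndarray,
                        criterion: HBondCriterion) -> bool:
    """Single-geometry check used by the synthetic generator."""
    d = float(np.linalg.norm(acceptor - donor))
    if d > criterion.max_heavy_distance:
        return False
    if criterion.distance_only:
        return True
    ang = float(_angle_deg(donor, hydrogen, acceptor))
    return ang >= criterion.angle_threshold


def assign_donors_acceptors(ensemble: Ensemble, reference_index: int = 0
                            ) -> tuple[dict[int, list[int]], list[int]]:
    """Donor and acceptor assignment from the atom table.

    Returns ``(donors, acceptors)`` where ``donors`` maps the atom index
    of each donor heavy atom to the indices of its covalent hydrogens
    (name starts with H after stripping digits, within 1.2 Å in the
    reference frame) and ``acceptors`` lists all N/O heavy atoms.
    """
    tbl = ensemble.atom_table.frame
    elements = tbl["element"].str.upper().to_numpy()
    heavy_idx = np.where(np.isin(elements, _HEAVY))[0]
    h_idx = np.where(elements == "H")[0]
    if len(heavy_idx) == 0:
        raise ValueError("no N/O heavy atoms: nothing to analyse")
    if len(h_idx) == 0:
        raise ValueError(
            "structure contains no hydrogens; use a distance-only "
            "criterion (HBondCriterion(angle_threshold=None))")
    ref = ensemble.coords[reference_index]
    donors: dict[int, list[int]] = {}
    for i in heavy_idx:
        d = np.linalg.norm(ref[h_idx] - ref[i], axis=1)
        bonded = h_idx[d <= _H_BOND_MAX]
        if len(bonded):
            donors[int(i)] = [int(j) for j in bonded]
    return donors, [int(i) for i in heavy_idx]


def hbond_occupancy(ensemble: Ensemble,
                    criterion: HBondCriterion = HBondCriterion(),
                    window=None,
                    pair_filter=None,
                    include_zero: bool = False) -> list[HBondOccupancy]:
    """Per-pair hydrogen-bond occupancy over the analysis window.

    A frame counts for a (donor, acceptor) pair when the heavy-atom
    distance is within the cutoff and — unless in distance-only mode —
    the best D–H···A angle over the donor's hydrogens meets the
    threshold. ``pair_filter`` optionally restricts pairs to
    ``(component_a, component_b)`` given a per-atom component lookup
    callable ``pair_filter=(components, (name_a, name_b))`` where
    ``components`` maps atom index to a label.

    Pairs never observed bonded are omitted unless ``include_zero``.
    """
    start, stop = resolve_window(window, ensemble.n_frames)
    tbl = ensemble.atom_table.frame
    elements = tbl["element"].str.upper().to_numpy()
    if criterion.distance_only:
        heavy_idx = np.where(np.isin(elements, _HEAVY))[0]
        if len(heavy_idx) == 0:
            raise ValueError("no N/O heavy atoms: empty donor/acceptor sets")
        donors = {int(i): [] for i in heavy_idx}
        acceptors = [int(i) for i in heavy_idx]
    else:
        donors, acceptors = assign_donors_acceptors(ensemble)
    if not donors:
        raise ValueError("empty donor set: no N/O atom has a covalent H")

    if pair_filter is not None:
        comp_of, (name_a, name_b) = pair_filter
        wanted = {frozenset((name_a, name_b))}
    X = ensemble.coords[start:stop]
    T = stop - start
    results: list[HBondOccupancy] = []
    ids = list(zip(tbl["chain_id"], tbl["residue_number"], tbl["atom_name"]))
    for d_idx, hydrogens in donors.items():
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            if pair_filter is not None and \
                    frozenset((comp_of[d_idx], comp_of[a_idx])) not in wanted:
                continue
            dist = np.linalg.norm(X[:, a_idx] - X[:, d_idx], axis=1)
            ok = dist <= criterion.max_heavy_distance
            if not criterion.distance_only and ok.any():
                best = np.zeros(T)
                for h in hydrogens:
                    ang = _angle_deg(X[:, d_idx], X[:, h], X[:, a_idx])
                    best = np.maximum(best, ang)
                ok = ok & (best >= criterion.angle_threshold)
            count = int(ok.sum())
            if count == 0 and not include_zero:
                continue
            results.append(HBondOccupancy(
                donor=ids[d_idx], acceptor=ids[a_idx],
                occupancy=count / T, n_frames=T, count=count))
    results.sort(key=lambda r: -r.occupancy)
    return results


def occupancy_frame(table: list[HBondOccupancy]) -> pd.DataFrame:
    """Occupancy list as a flat table (one row per donor–acceptor pair)."""
    return pd.DataFrame([{
        "donor_chain": r.donor[0], "donor_res": r.donor[1],
        "donor_atom": r.donor[2],
        "acceptor_chain": r.acceptor[0], "acceptor_res": r.acceptor[1],
        "acceptor_atom": r.acceptor[2],
        "occupancy": r.occupancy,
    } for r in table], columns=[
        "donor_chain", "donor_res", "donor_atom", "acceptor_chain",
        "acceptor_res", "acceptor_atom", "occupancy"])


def compare_occupancies(tables: list[tuple[str, list[HBondOccupancy]]],
                        min_delta: float = 0.0) -> pd.DataFrame:
    """Cross-model occupancy deltas.

    Takes ``(label, occupancy table)`` pairs; the union of donor–
    acceptor pairs is formed, a pair missing from a model counts as
    occupancy 0, and rows whose max–min range reaches ``min_delta`` are
    returned sorted by range, descending.
    """
    if len(tables) < 2:
        raise ValueError("need at least two occupancy tables to compare")
    labels = [lbl for lbl, _ in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate model labels: {labels}")
    rows: dict[tuple, dict[str, float]] = {}
    for lbl, tab in tables:
        for r in tab:
            rows.setdefault((r.donor, r.acceptor), {})[lbl] = r.occupancy
    records = []
    for (don, acc), occ in rows.items():
        vals = [occ.get(lbl, 0.0) for lbl in labels]
        delta = max(vals) - min(vals)
        if delta >= min_delta:
            rec = {"donor": "/".join(map(str, don)),
                   "acceptor": "/".join(map(str, acc)),
                   **{lbl: v for lbl, v in zip(labels, vals)},
                   "delta": delta}
            records.append(rec)
    df = pd.DataFrame(records,
                      columns=["donor", "acceptor", *labels, "delta"])
    if len(df):
        df = df.sort_values("delta", ascending=False,
                            kind="stable").reset_index(drop=True)
    return df
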