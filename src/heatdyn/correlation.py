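"""Covariance, cross-correlation (DCCM), correlation scores and
switch-region detection.

The mass-weighted positional covariance matrix C (3N x 3N, amu·Å²) of
the analysis beads is the common root of this module and of the PCA in
:mod:`heatdyn.pca`. The per-bead Pearson cross-correlation

    CC_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>)

is the trace of the 3x3 inter-bead covariance block normalised by the
bead variances; bead masses cancel exactly, so the DCCM is identical
for the weighted and unweighted covariance. Correlation scores coarsen
the DCCM to component pairs:

    CS(A, B) = Σ_{i∈A, j∈B} CC_ij / (|A| · |B|)

i.e. the block mean of the DCCM over the two components' beads — a
correlation density, with no cutoff applied on the CC values entering
the sum. Switch regions — the pivots of accordion-like inter-domain
motions, where correlation against a probe block flips sign and the
first principal mode carries almost no displacement — are detected by
combining both signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BeadSelection, UNASSIGNED
from .superpose import SuperposedEnsemble, resolve_window

__all__ = ["CovarianceMatrix", "CrossCorrelationMatrix",
           "CorrelationScoreMatrix", "SwitchRegion", "covariance",
           "cross_correlation", "correlation_scores",
           "detect_switch_regions", "switch_regions_frame"]


@dataclass
class CovarianceMatrix:
    """3N x 3N positional covariance of the bead selection.

    Entries are sqrt(m_i m_j) <Δr_iα Δr_jβ> (amu·Å²) when mass-weighted,
    plain <Δr_iα Δr_jβ> (Å²) otherwise; displacements are about the
    window mean and normalised by the number of frames (population
    convention).
    """

    matrix: np.ndarray            # (3N, 3N)
    beads: BeadSelection
    window: tuple[int, int]
    mass_weighted: bool
    mean_coords: np.ndarray       # (N, 3) window mean of bead coordinates

    @property
    def n_beads(self) -> int:
        return len(self.beads.indices)

    def bead_block(self, i: int, j: int) -> np.ndarray:
        return self.matrix[3 * i:3 * i + 3, 3 * j:3 * j + 3]

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))


@dataclass
class CrossCorrelationMatrix:
    """N x N per-bead Pearson cross-correlation (DCCM), entries in [-1, 1]."""

    matrix: np.ndarray
    beads: BeadSelection
    window: tuple[int, int]

    def as_frame(self) -> pd.DataFrame:
        labels = self.beads.labels()
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


@dataclass
class CorrelationScoreMatrix:
    """K x K correlation-score (CS) matrix over named components.

    CS(A,B) is the mean CC over the A x B bead block (correlation
    density); the diagonal includes the i = j self terms, so CS(A,A) is
    inflated by 1/|A| relative to the off-diagonal mean. Stored values
    are never clipped; clipping (e.g. to ±0.6 for display) is a
    rendering choice left to callers.
    """

    matrix: np.ndarray
    component_names: list[str]
    component_sizes: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.component_names,
                            columns=self.component_names)

    def clipped(self, limit: float = 0.6) -> np.ndarray:
        """Display-clipped copy of the CS matrix (stored values untouched)."""
        return np.clip(self.matrix, -limit, limit)


@dataclass
class SwitchRegion:
    """A contiguous stretch of residues where correlation to the probe
    block flips sign and the first principal mode is near-silent."""

    chain_id: str
    residue_start: int
    residue_end: int
    bead_start: int
    bead_stop: int               # half-open bead index range
    flanking_before: str
    flanking_after: str
    flip_magnitude: float
    amplitude_percentile: float  # percentile threshold used for PC1 silence


def covariance(superposed: SuperposedEnsemble,
               window=None,
               mass_weighted: bool = True) -> CovarianceMatrix:
    """Mass-weighted covariance matrix of bead displacements.

    Requires a superposed ensemble (global rotation/translation
    removed); displacements are taken about the window mean.
    """
    if not isinstance(superposed, SuperposedEnsemble):
        raise TypeError(
            "covariance requires a SuperposedEnsemble; superpose the "
            "ensemble first (or mark it already-aligned with fit='none')")
    beads = superposed.beads
    start, stop = resolve_window(window, superposed.n_frames)
    if stop - start < 2:
        raise ValueError("covariance needs at least 2 frames in the window")
    X = superposed.coords[start:stop][:, beads.indices]    # (T, N, 3)
    T, N, _ = X.shape
    mean = X.mean(axis=0)
    D = (X - mean).reshape(T, 3 * N)
    C = D.T @ D / T
    if mass_weighted:
        sm = np.sqrt(np.repeat(beads.masses, 3))
        C = C * np.outer(sm, sm)
    return CovarianceMatrix(C, beads, (start, stop), mass_weighted, mean)


def cross_correlation(cov: CovarianceMatrix) -> CrossCorrelationMatrix:
    """Pearson cross-correlation matrix (DCCM) from the covariance.

    CC_ij = tr(C_ij) / sqrt(tr(C_ii) tr(C_jj)); the sqrt(m_i m_j) mass
    factors cancel between numerator and denominator.
    """
    N = cov.n_beads
    C = cov.matrix
    # trace of every 3x3 block: sum over the coordinate axis pairs
    blocks = C.reshape(N, 3, N, 3)
    tr = np.einsum("iaja->ij", blocks)
    var = np.diag(tr)
    zero = np.where(var <= 0)[0]
    if len(zero):
        i = int(zero[0])
        lbl = cov.beads.labels()[i]
        raise ValueError(
            f"zero-variance bead {i} ({lbl}): cross-correlation undefined "
            "for an immobile bead")
    denom = np.sqrt(np.outer(var, var))
    cc = tr / denom
    return CrossCorrelationMatrix(cc, cov.beads, cov.window)


def correlation_scores(cc: CrossCorrelationMatrix,
                       components: np.ndarray | None = None
                       ) -> CorrelationScoreMatrix:
    """Component-pair correlation scores: block means of the DCCM.

    Beads labelled "unassigned" are excluded; components that end up
    with zero beads are dropped. Diagonal blocks include the i = j
    terms (CC_ii = 1).
    """
    labels = np.asarray(components if components is not None
                        else cc.beads.components, dtype=object)
    names = [n for n in dict.fromkeys(labels) if n != UNASSIGNED]
    if not names:
        raise ValueError("no named components with beads: cannot compute CS")
    groups = {n: np.where(labels == n)[0] for n in names}
    K = len(names)
    cs = np.empty((K, K))
    sizes = np.array([len(groups[n]) for n in names])
    for a, na in enumerate(names):
        ia = groups[na]
        for b, nb in enumerate(names):
            ib = groups[nb]
            cs[a, b] = cc.matrix[np.ix_(ia, ib)].mean()
    return CorrelationScoreMatrix(cs, names, sizes)


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where mask is True."""
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def detect_switch_regions(cc: CrossCorrelationMatrix,
                          pca,
                          probe_block: str,
                          amplitude_percentile: float = 20.0,
                          min_flip: float = 0.2,
                          flank: int = 5) -> list[SwitchRegion]:
    """Locate switch regions: sign flips of probe-block correlation that
    coincide with near-zero first-principal-mode amplitude.

    Procedure: (1) per bead compute the mean CC against the probe
    block's beads; (2) candidate boundaries are adjacent bead pairs
    where this profile changes sign and the flanking ``flank``-bead
    means differ by at least ``min_flip``; (3) per-bead PC1 amplitudes
    (norm of the bead's 3-vector in the first eigenvector) are
    thresholded at the given percentile; (4) each region is the maximal
    contiguous run of low-amplitude beads around a candidate boundary.
    Candidates landing in the same run are merged. Regions are sorted
    by flip magnitude, descending. An empty list (no sign change) is a
    valid result, not an error.
    """
    beads = cc.beads
    labels = np.asarray(beads.components, dtype=object)
    probe_idx = np.where(labels == probe_block)[0]
    if len(probe_idx) == 0:
        raise ValueError(f"unknown probe block {probe_block!r}")
    N = cc.matrix.shape[0]
    s = cc.matrix[:, probe_idx].mean(axis=1)

    amps = pca.mode_amplitudes(0)
    if len(amps) != N:
        raise ValueError("PCA and CC matrix computed over different beads")
    thresh = np.percentile(amps, amplitude_percentile)
    low = amps <= thresh
    runs = _runs_of(low)

    candidates: list[tuple[int, float]] = []   # (boundary bead b, flip)
    for b in range(N - 1):
        if np.sign(s[b]) == np.sign(s[b + 1]) or s[b] == s[b + 1]:
            continue
        left = s[max(0, b - flank + 1):b + 1].mean()
        right = s[b + 1:b + 1 + flank].mean()
        flip = abs(left - right)
        if np.sign(left) != np.sign(right) and flip >= min_flip:
            candidates.append((b, flip))

    regions: dict[tuple[int, int], SwitchRegion] = {}
    for b, flip in candidates:
        run = next((r for r in runs if r[0] <= b + 1 and r[1] > b), None)
        if run is None:
            # nearest low-amplitude run within the flank distance
            near = [r for r in runs
                    if r[0] - (b + 1) <= flank and b - (r[1] - 1) <= flank]
            if not near:
                continue
            run = min(near, key=lambda r: min(abs(r[0] - b - 1),
                                              abs(b - r[1] + 1)))
        key = run
        if key in regions and regions[key].flip_magnitude >= flip:
            continue
        lo, hi = run
        before = labels[lo - 1] if lo > 0 else UNASSIGNED
        after = labels[hi] if hi < N else UNASSIGNED
        regions[key] = SwitchRegion(
            chain_id=str(beads.chain_ids[lo]),
            residue_start=int(beads.residue_numbers[lo]),
            residue_end=int(beads.residue_numbers[hi - 1]),
            bead_start=lo, bead_stop=hi,
            flanking_before=str(before), flanking_after=str(after),
            flip_magnitude=float(flip),
            amplitude_percentile=float(amplitude_percentile))
    return sorted(regions.values(), key=lambda r: -r.flip_magnitude)


def switch_regions_frame(regions: list[SwitchRegion]) -> pd.DataFrame:
    """BED-like table of switch regions (inclusive residue coordinates)."""
    return pd.DataFrame([{
        "chain": r.chain_id,
        "start_residue": r.residue_start,
        "end_residue": r.residue_end,
        "flip": r.flip_magnitude,
        "amplitude_pct": r.amplitude_percentile,
    } for r in regions],
        columns=["chain", "start_residue", "end_residue", "flip",
                 "amplitude_pct"])
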