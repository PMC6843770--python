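"""Essential dynamics: eigendecomposition of the positional covariance,
trajectory projections, and NMD export for mode visualisation.

The eigenvectors of the (mass-weighted) covariance with the largest
eigenvalues are the principal components — the directions of the most
relevant collective motions sampled by the ensemble. Cumulative
variance is always reported against the full 3N spectrum. Mode signs
are fixed (largest-magnitude component positive) so repeated runs are
bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import CovarianceMatrix
from .io import BeadSelection
from .superpose import SuperposedEnsemble

__all__ = ["PCAResult", "pca_modes", "project", "export_nmd", "read_nmd"]

#: Above this many covariance rows (3N) a partial iterative
#: eigendecomposition is used instead of the full symmetric solver.
FULL_EIGH_LIMIT = 6000


@dataclass
class PCAResult:
    """Principal modes of a covariance matrix.

    ``eigenvalues`` holds the full descending spectrum when the dense
    solver was used (3N values), otherwise the top ``n_modes``;
    ``eigenvectors`` has one orthonormal 3N-column per retained mode.
    """

    eigenvalues: np.ndarray          # descending, amu·Å² (or Å² unweighted)
    eigenvectors: np.ndarray         # (3N, n_modes)
    cumulative_variance: np.ndarray  # per retained mode, vs. total variance
    total_variance: float            # trace of the covariance
    cov: CovarianceMatrix

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    def mode_vectors(self, mode: int) -> np.ndarray:
        """Per-bead 3-vectors of one eigenvector, shape (N, 3)."""
        if not 0 <= mode < self.n_modes:
            raise IndexError(f"mode {mode} out of range (have {self.n_modes})")
        return self.eigenvectors[:, mode].reshape(-1, 3)

    def mode_amplitudes(self, mode: int) -> np.ndarray:
        """Per-bead amplitude (vector norm) in one eigenvector."""
        return np.linalg.norm(self.mode_vectors(mode), axis=1)

    def spectrum_frame(self) -> pd.DataFrame:
        k = len(self.eigenvalues)
        cum = np.cumsum(self.eigenvalues) / self.total_variance
        return pd.DataFrame({
            "mode": np.arange(1, k + 1),
            "eigenvalue": self.eigenvalues,
            "cumulative_variance": cum,
        })


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-magnitude component is positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def pca_modes(cov: CovarianceMatrix, n_modes: int | None = None,
              full_limit: int = FULL_EIGH_LIMIT) -> PCAResult:
    """Eigendecompose a covariance matrix into principal modes.

    Modes are sorted by eigenvalue, descending. For 3N <= ``full_limit``
    the full symmetric spectrum is computed (scipy ``eigh``); above it a
    partial Lanczos decomposition returns only the requested modes,
    with cumulative variance still normalised by the full trace.
    """
    from scipy.linalg import eigh

    C = cov.matrix
    dim = C.shape[0]
    if not np.allclose(C, C.T, atol=1e-8 * max(1.0, np.abs(C).max())):
        raise ValueError("covariance matrix must be symmetric")
    if n_modes is None:
        n_modes = min(dim, 20)
    if not 1 <= n_modes <= dim:
        raise ValueError(f"n_modes must be in [1, {dim}]")
    total = float(np.trace(C))
    if dim <= full_limit:
        w, V = eigh(C)
        w, V = w[::-1], V[:, ::-1]
        evals = w
        vecs = V[:, :n_modes]
    else:
        from scipy.sparse.linalg import eigsh
        w, V = eigsh(C, k=n_modes, which="LA")
        order = np.argsort(w)[::-1]
        evals, vecs = w[order], V[:, order]
    vecs = _fix_signs(np.ascontiguousarray(vecs))
    cum = np.cumsum(evals[:n_modes]) / total if total > 0 else \
        np.zeros(n_modes)
    return PCAResult(evals, vecs, cum, total, cov)


def project(superposed: SuperposedEnsemble, pca: PCAResult,
            mode: int) -> np.ndarray:
    """Per-frame scalar projections of the displacement onto one mode.

    Displacements are about the covariance's window mean and carry the
    same mass weighting as the covariance, so the population variance
    of the projections onto mode k equals eigenvalue k.
    """
    if not 0 <= mode < pca.n_modes:
        raise IndexError(f"mode {mode} out of range (have {pca.n_modes})")
    cov = pca.cov
    start, stop = cov.window
    X = superposed.coords[start:stop][:, cov.beads.indices]
    D = (X - cov.mean_coords).reshape(X.shape[0], -1)
    if cov.mass_weighted:
        D = D * np.sqrt(np.repeat(cov.beads.masses, 3))[None, :]
    return D @ pca.eigenvectors[:, mode]


# ---------------------------------------------------------------------------
# NMD (Normal Mode Wizard) export
# ---------------------------------------------------------------------------

def export_nmd(pca: PCAResult, beads: BeadSelection,
               reference_coords: np.ndarray, path: str | Path,
               modes: list[int] | None = None, scale: float = 1.0,
               title: str = "heatdyn essential dynamics") -> None:
    """Write principal modes as an NMWiz-compatible NMD file.

    ``reference_coords`` are the (N, 3) bead coordinates the arrows are
    drawn from; ``scale`` multiplies the mode vector components only.
    """
    modes = modes if modes is not None else list(range(pca.n_modes))
    ref = np.asarray(reference_coords, dtype=float).reshape(-1, 3)
    if ref.shape[0] != beads.n_beads:
        raise ValueError("reference coordinates must cover every bead")
    from ._elements import NUCLEOTIDES

    bead_atoms = ["P" if str(rn).strip().upper() in NUCLEOTIDES else "CA"
                  for rn in beads.residue_names]
    lines = [f"title {title}"]
    lines.append("names " + " ".join(bead_atoms))
    lines.append("resnames " + " ".join(str(r) for r in beads.residue_names))
    lines.append("resids " + " ".join(str(int(r))
                                      for r in beads.residue_numbers))
    lines.append("chainids " + " ".join(str(c) for c in beads.chain_ids))
    lines.append("coordinates " + " ".join(f"{x:.3f}" for x in ref.ravel()))
    for m in modes:
        if not 0 <= m < pca.n_modes:
            raise IndexError(f"mode {m} not computed")
        comps = scale * pca.eigenvectors[:, m]
        lines.append(f"mode {m + 1} " + " ".join(f"{x:.6e}" for x in comps))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_nmd(path: str | Path) -> dict:
    """Parse an NMD file back into a dict (coordinates, modes, labels).

    Returns keys: ``title``, ``names``, ``resids``, ``chainids``,
    ``coordinates`` (N, 3) and ``modes`` — a dict mode_number ->
    component array (3N).
    """
    out: dict = {"modes": {}}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        key, _, rest = line.partition(" ")
        if key == "title":
            out["title"] = rest
        elif key in ("names", "resnames", "chainids"):
            out[key] = rest.split()
        elif key == "resids":
            out["resids"] = [int(x) for x in rest.split()]
        elif key == "coordinates":
            out["coordinates"] = np.array(
                [float(x) for x in rest.split()]).reshape(-1, 3)
        elif key == "mode":
            toks = rest.split()
            out["modes"][int(toks[0])] = np.array(
                [float(x) for x in toks[1:]])
    return out
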