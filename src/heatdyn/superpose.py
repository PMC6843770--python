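"""Least-squares superposition and fluctuation profiles.

Frames are superposed onto a reference frame with the optimal
rotation/translation (Kabsch), computed over the analysis bead
selection but applied to all atoms, so that downstream analyses —
covariance matrices as well as all-atom hydrogen-bond geometry — share
one common frame. RMSF is computed about the window mean structure
(the standard convention); RMSD is measured to the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import BeadSelection, ComponentMap, Ensemble, UNASSIGNED

__all__ = ["SuperposedEnsemble", "FluctuationProfile", "superpose",
           "fluctuation_profile", "resolve_window"]


@dataclass
class SuperposedEnsemble:
    """An ensemble with global rotation/translation removed.

    ``fit_mode="none"`` marks an ensemble that is already expressed in a
    common frame (e.g. a synthetic ensemble generated without rigid-body
    motion), for which the identity fit is exact.
    """

    ensemble: Ensemble
    beads: BeadSelection
    reference_index: int = 0
    fit_weights: str = "uniform"
    fit_mode: str = "kabsch"

    @property
    def coords(self) -> np.ndarray:
        return self.ensemble.coords

    @property
    def n_frames(self) -> int:
        return self.ensemble.n_frames


@dataclass
class FluctuationProfile:
    """Per-bead RMSF, per-frame RMSD and radius of gyration (all Å),
    plus bead-count-weighted per-component mean RMSF."""

    rmsf: np.ndarray                 # (n_beads,)
    rmsd: np.ndarray                 # (n_window_frames,)
    radius_of_gyration: np.ndarray   # (n_window_frames,)
    per_component: pd.DataFrame      # component, n_beads, mean_rmsf
    window: tuple[int, int]

    def as_frame(self, beads: BeadSelection) -> pd.DataFrame:
        """Per-bead RMSF table (bead, chain, residue, component, rmsf_A)."""
        return pd.DataFrame({
            "bead": np.arange(beads.n_beads),
            "chain": beads.chain_ids,
            "residue": beads.residue_numbers,
            "component": beads.components,
            "rmsf_A": self.rmsf,
        })


def resolve_window(window, n_frames: int) -> tuple[int, int]:
    """Normalise a window spec to a half-open frame range ``(start, stop)``.

    Accepts ``None``/``"all"``, ``"last P%"``, or an explicit
    ``(start, stop)`` pair. ``"last P%"`` keeps the final
    ``floor(n * P/100)`` frames.
    """
    if window is None or window == "all":
        return (0, n_frames)
    if isinstance(window, str):
        s = window.strip().lower()
        if s.startswith("last") and s.endswith("%"):
            pct = float(s[4:-1].strip())
            if not 0 < pct <= 100:
                raise ValueError(f"percentage out of range in {window!r}")
            keep = int(np.floor(n_frames * pct / 100.0))
            start = n_frames - keep
            if keep < 1:
                raise ValueError(f"window {window!r} resolves to zero frames")
            return (start, n_frames)
        raise ValueError(f"unrecognised window spec {window!r}")
    start, stop = int(window[0]), int(window[1])
    if start < 0 or stop > n_frames or start >= stop:
        raise ValueError(
            f"empty or invalid frame range [{start}, {stop}) for "
            f"{n_frames} frames")
    return (start, stop)


def _check_degenerate(ref_beads: np.ndarray) -> None:
    if ref_beads.shape[0] < 3:
        raise ValueError("degenerate fit: need at least 3 beads")
    centered = ref_beads - ref_beads.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate fit: beads are collinear")


def superpose(ensemble: Ensemble, beads: BeadSelection,
              reference_index: int = 0,
              weights: str = "uniform",
              fit: str = "kabsch") -> SuperposedEnsemble:
    """Remove global rotation/translation from every frame.

    Each frame receives the rigid transform minimising the (optionally
    mass-) weighted RMSD of its beads to the reference frame's beads;
    the transform is applied to all atoms of the frame. ``fit="none"``
    skips the transformation and merely tags the ensemble as being in a
    common frame already.
    """
    if not 0 <= reference_index < ensemble.n_frames:
        raise IndexError(f"reference index {reference_index} out of range")
    if weights not in ("uniform", "mass"):
        raise ValueError("weights must be 'uniform' or 'mass'")
    if fit not in ("kabsch", "none"):
        raise ValueError("fit must be 'kabsch' or 'none'")
    if fit == "none":
        return SuperposedEnsemble(ensemble, beads, reference_index,
                                  weights, fit_mode="none")

    idx = beads.indices
    w = beads.masses if weights == "mass" else np.ones(beads.n_beads)
    w = w / w.sum()
    coords = ensemble.coords
    ref = coords[reference_index, idx]
    _check_degenerate(ref)
    ref_centroid = (w[:, None] * ref).sum(axis=0)
    ref_c = ref - ref_centroid

    # batched Kabsch: H_t = mob_cᵀ W ref_c, R_t = V diag(1,1,d) Uᵀ
    mob = coords[:, idx]                                   # (T, N, 3)
    mob_centroid = np.einsum("n,tnk->tk", w, mob)
    mob_c = mob - mob_centroid[:, None, :]
    H = np.einsum("tni,n,nj->tij", mob_c, w, ref_c)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("tij,tjk->tik",
                                        np.transpose(Vt, (0, 2, 1)),
                                        np.transpose(U, (0, 2, 1)))))
    D = np.zeros((len(d), 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("tij,tjk,tkl->til", np.transpose(Vt, (0, 2, 1)), D,
                  np.transpose(U, (0, 2, 1)))
    out = np.einsum("tij,tnj->tni",
                    R, coords - mob_centroid[:, None, :]) + ref_centroid
    fitted = ensemble.with_coords(out)
    return SuperposedEnsemble(fitted, beads, reference_index, weights,
                              fit_mode="kabsch")


def fluctuation_profile(superposed: SuperposedEnsemble,
                        cmap: ComponentMap | None = None,
                        window=None) -> FluctuationProfile:
    """RMSF per bead, RMSD and radius of gyration per frame.

    RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>) about the window mean structure;
    RMSD is to the reference frame over the bead selection (uniform
    weights); Rg is mass-weighted over the beads. Component means are
    bead-count-weighted means over named components only.
    """
    beads = superposed.beads
    start, stop = resolve_window(window, superposed.n_frames)
    if stop - start < 2:
        raise ValueError("RMSF undefined on a window of fewer than 2 frames")
    X = superposed.coords[start:stop][:, beads.indices]   # (T, N, 3)

    mean = X.mean(axis=0)
    rmsf = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))

    ref = superposed.coords[superposed.reference_index, beads.indices]
    rmsd = np.sqrt(((X - ref) ** 2).sum(axis=2).mean(axis=1))

    m = beads.masses
    com = (m[None, :, None] * X).sum(axis=1) / m.sum()
    rg = np.sqrt((m[None, :] * ((X - com[:, None, :]) ** 2).sum(axis=2)
                  ).sum(axis=1) / m.sum())

    comp = pd.DataFrame({"component": beads.components, "rmsf": rmsf})
    comp = comp[comp.component != UNASSIGNED]
    if len(comp):
        agg = comp.groupby("component", sort=False).agg(
            n_beads=("rmsf", "size"), mean_rmsf=("rmsf", "mean"))
        agg = agg.reset_index()
    else:
        agg = pd.DataFrame(columns=["component", "n_beads", "mean_rmsf"])
    return FluctuationProfile(rmsf, rmsd, rg, agg, (start, stop))
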