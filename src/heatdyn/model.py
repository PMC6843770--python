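"""Model/Results interface over the analysis pipeline.

:class:`EnsembleDynamics` fits a Gaussian fluctuation model — mean
structure plus (mass-weighted) positional covariance of the analysis
beads — to a conformational ensemble. The returned
:class:`EnsembleDynamicsResults` carries the fluctuation profiles, the
cross-correlation and correlation-score matrices, the principal modes,
and diagnostics, with a ``summary()`` table in the statsmodels style.

:class:`HBondAnalysis` does the same for hydrogen-bond occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import correlation as _corr
from . import hbonds as _hb
from . import pca as _pca
from .io import BeadSelection, ComponentMap, Ensemble, select_beads
from .superpose import (FluctuationProfile, SuperposedEnsemble,
                        fluctuation_profile, resolve_window, superpose)

__all__ = ["EnsembleDynamics", "EnsembleDynamicsResults",
           "HBondAnalysis", "HBondResults"]


class EnsembleDynamics:
    """Gaussian fluctuation model of a conformational ensemble.

    Parameters
    ----------
    ensemble:
        The conformational ensemble (frames in Å over a fixed atom table).
    component_map:
        Optional residue-to-component assignment; needed for correlation
        scores and per-component RMSF.
    window:
        Analysis window: ``"all"``, ``"last P%"`` or a ``(start, stop)``
        half-open frame range. Production-run analyses typically discard
        an initial equilibration stretch this way.
    fit:
        ``"kabsch"`` superposes every frame onto the reference frame
        before estimation; ``"none"`` declares the ensemble already
        expressed in a common frame (exact for synthetic ensembles
        generated without rigid-body motion).
    mass_weighted:
        Weight the covariance by sqrt(m_i m_j). The cross-correlation
        matrix is unaffected (masses cancel); eigenvalues are amu·Å².
    """

    def __init__(self, ensemble: Ensemble,
                 component_map: ComponentMap | None = None,
                 beads: BeadSelection | None = None,
                 window="all",
                 fit: str = "kabsch",
                 fit_weights: str = "uniform",
                 reference_index: int = 0,
                 mass_weighted: bool = True):
        self.ensemble = ensemble
        self.component_map = component_map
        self.beads = beads if beads is not None else \
            select_beads(ensemble, component_map)
        self.window = window
        self.fit_mode = fit
        self.fit_weights = fit_weights
        self.reference_index = reference_index
        self.mass_weighted = mass_weighted

    @classmethod
    def from_files(cls, topology, trajectory=None, component_map=None,
                   **kwargs) -> "EnsembleDynamics":
        """Build the model from structure/trajectory/component-map files."""
        from . import io as _io
        if trajectory is None:
            ens = _io.read_structure(topology)
        else:
            ens = _io.read_trajectory(topology, trajectory)
        cmap = _io.load_component_map(component_map) \
            if component_map is not None else None
        return cls(ens, component_map=cmap, **kwargs)

    def fit(self, n_modes: int | None = None) -> "EnsembleDynamicsResults":
        """Estimate the model: superpose, covariance, DCCM, CS, PCA."""
        sup = superpose(self.ensemble, self.beads,
                        reference_index=self.reference_index,
                        weights=self.fit_weights, fit=self.fit_mode)
        win = resolve_window(self.window, sup.n_frames)
        profile = fluctuation_profile(sup, self.component_map, window=win)
        cov = covariance = _corr.covariance(
            sup, window=win, mass_weighted=self.mass_weighted)
        cc = _corr.cross_correlation(cov)
        cs = None
        if self.component_map is not None and \
                len(self.component_map.entries):
            cs = _corr.correlation_scores(cc)
        pca = _pca.pca_modes(covariance, n_modes=n_modes)
        return EnsembleDynamicsResults(self, sup, win, profile, covariance,
                                       cc, cs, pca)


@dataclass
class EnsembleDynamicsResults:
    """Fitted fluctuation model: profiles, matrices, principal modes."""

    model: EnsembleDynamics
    superposed: SuperposedEnsemble
    window: tuple[int, int]
    profile: FluctuationProfile
    covariance: _corr.CovarianceMatrix
    cross_correlation: _corr.CrossCorrelationMatrix
    correlation_scores: _corr.CorrelationScoreMatrix | None
    pca: _pca.PCAResult

    # -- derived quantities -------------------------------------------------

    @property
    def rmsf(self) -> np.ndarray:
        return self.profile.rmsf

    @property
    def rmsd(self) -> np.ndarray:
        return self.profile.rmsd

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.pca.eigenvalues

    def project(self, mode: int) -> np.ndarray:
        """Per-frame projection of the trajectory onto one principal mode."""
        return _pca.project(self.superposed, self.pca, mode)

    def switch_regions(self, probe_block: str,
                       amplitude_percentile: float = 20.0,
                       min_flip: float = 0.2,
                       flank: int = 5) -> list[_corr.SwitchRegion]:
        """Detect switch regions against a probe component."""
        return _corr.detect_switch_regions(
            self.cross_correlation, self.pca, probe_block,
            amplitude_percentile=amplitude_percentile,
            min_flip=min_flip, flank=flank)

    def export_nmd(self, path, modes=None, scale: float = 1.0) -> None:
        """Write principal modes as an NMWiz-compatible NMD file."""
        _pca.export_nmd(self.pca, self.superposed.beads,
                        self.covariance.mean_coords, path,
                        modes=modes, scale=scale)

    def plot_correlation_scores(self, ax=None, clip: float | None = 0.6):
        """Heatmap of the CS matrix (display clipped to ±clip by default)."""
        import matplotlib.pyplot as plt
        if self.correlation_scores is None:
            raise ValueError("no component map: correlation scores absent")
        if ax is None:
            _fig, ax = plt.subplots()
        cs = self.correlation_scores
        data = cs.clipped(clip) if clip is not None else cs.matrix
        lim = clip if clip is not None else 1.0
        im = ax.imshow(data, cmap="RdBu", vmin=-lim, vmax=lim)
        ax.set_xticks(range(len(cs.component_names)), cs.component_names,
                      rotation=90)
        ax.set_yticks(range(len(cs.component_names)), cs.component_names)
        ax.figure.colorbar(im, ax=ax, label="correlation score")
        return ax

    def summary(self, n_modes: int = 5) -> str:
        """Plain-text fit summary."""
        beads = self.superposed.beads
        start, stop = self.window
        lines = [
            "Ensemble dynamics fit",
            "=" * 52,
            f"frames (window):        {stop - start} [{start}, {stop})",
            f"beads:                  {beads.n_beads}",
            f"superposition:          {self.superposed.fit_mode} "
            f"({self.superposed.fit_weights} weights)",
            f"covariance weighting:   "
            f"{'mass' if self.covariance.mass_weighted else 'uniform'}",
            f"mean RMSD to reference: {self.rmsd.mean():.3f} A",
            f"mean RMSF:              {self.rmsf.mean():.3f} A",
            f"covariance trace:       {self.covariance.trace:.4g}",
            "",
            "Principal modes",
            "-" * 52,
        ]
        spec = self.pca.spectrum_frame().head(n_modes)
        for _, row in spec.iterrows():
            lines.append(f"  PC{int(row['mode']):<3d} eigenvalue "
                         f"{row.eigenvalue:12.4g}   cumulative variance "
                         f"{row.cumulative_variance:6.3f}")
        if self.correlation_scores is not None:
            lines += ["", "Correlation scores (component pairs)", "-" * 52,
                      self.correlation_scores.as_frame().round(3).to_string()]
        return "\n".join(lines)


class HBondAnalysis:
    """Hydrogen-bond occupancy model over an analysis window."""

    def __init__(self, ensemble: Ensemble,
                 criterion: _hb.HBondCriterion | None = None,
                 window="all"):
        self.ensemble = ensemble
        self.criterion = criterion if criterion is not None \
            else _hb.HBondCriterion()
        self.window = window

    def fit(self, pair_filter=None) -> "HBondResults":
        occ = _hb.hbond_occupancy(self.ensemble, self.criterion,
                                  window=self.window,
                                  pair_filter=pair_filter)
        return HBondResults(self, occ)


@dataclass
class HBondResults:
    model: HBondAnalysis
    occupancies: list[_hb.HBondOccupancy]

    def as_frame(self) -> pd.DataFrame:
        return _hb.occupancy_frame(self.occupancies)

    def summary(self, top: int = 10) -> str:
        crit = self.model.criterion
        lines = [
            "Hydrogen-bond occupancy",
            "=" * 52,
            f"criterion: d(D,A) <= {crit.max_heavy_distance} A"
            + ("" if crit.distance_only
               else f", D-H...A >= {crit.angle_threshold} deg"),
            f"pairs observed bonded: {len(self.occupancies)}",
            "",
        ]
        df = self.as_frame().head(top)
        lines.append(df.to_string(index=False) if len(df) else "(none)")
        return "\n".join(lines)
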