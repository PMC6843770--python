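"""Multi-model comparison workflow: manifest-driven runs and reports.

A YAML manifest lists labelled models (topology + optional trajectory),
a shared component map, the analysis window and criterion overrides.
``run_manifest`` executes the full pipeline per model — superposition,
fluctuation profiles, covariance, DCCM, correlation scores, PCA, switch
regions, hydrogen bonds — writes every per-model artifact as CSV/TSV/NMD
under the output directory, and assembles cross-model comparisons:
CS difference matrices against a designated reference model and the
hydrogen-bond occupancy delta table. Outputs are deterministic given
identical inputs and seed (fixed float formatting, no timestamps in
numeric files); a provenance block records config hash, input checksums
and versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as _io
from . import hbonds as _hb
from .correlation import switch_regions_frame
from .model import EnsembleDynamics, EnsembleDynamicsResults, HBondAnalysis
from .superpose import resolve_window

logger = logging.getLogger("heatdyn")

__all__ = ["ModelInput", "AnalysisManifest", "ComparisonReport",
           "run_manifest", "window_resolve", "site_distance"]

_FLOAT_FMT = "%.10g"

#: alias matching the operation name used by the CLI layer
window_resolve = resolve_window


@dataclass(frozen=True)
class ModelInput:
    label: str
    topology: str
    trajectory: str | None = None


@dataclass
class AnalysisManifest:
    """Validated description of a multi-model comparison run."""

    models: list[ModelInput]
    output_dir: str
    component_map: str | None = None
    window: object = "all"
    reference_label: str | None = None     # default: first model
    seed: int = 0
    fit: str = "kabsch"
    mass_weighted: bool = True
    n_modes: int | None = None
    probe_block: str | None = None
    switch_params: dict = field(default_factory=dict)
    hbonds: bool = False
    hbond_criterion: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("manifest lists no models")
        labels = [m.label for m in self.models]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate model labels: {labels}")
        if self.reference_label is None:
            self.reference_label = self.models[0].label
        elif self.reference_label not in labels:
            raise ValueError(
                f"reference label {self.reference_label!r} not in {labels}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisManifest":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        models = [ModelInput(label=m["label"], topology=m["topology"],
                             trajectory=m.get("trajectory"))
                  for m in raw.pop("models")]
        window = raw.pop("window", "all")
        if isinstance(window, list):
            window = tuple(window)
        return cls(models=models, window=window, **raw)


@dataclass
class ComparisonReport:
    """Cross-model report: per-model results plus difference tables."""

    reference_label: str
    results: dict[str, EnsembleDynamicsResults]
    cs_matrices: dict[str, pd.DataFrame]
    cs_differences: dict[str, pd.DataFrame]     # model - reference
    switch_regions: dict[str, pd.DataFrame]
    rmsf_per_component: dict[str, pd.DataFrame]
    hbond_deltas: pd.DataFrame | None
    provenance: dict
    output_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=_FLOAT_FMT, index=index,
              lineterminator="\n")


def _load_model(spec: ModelInput) -> _io.Ensemble:
    if spec.trajectory is None:
        return _io.read_structure(spec.topology)
    return _io.read_trajectory(spec.topology, spec.trajectory)


def run_manifest(manifest: AnalysisManifest) -> ComparisonReport:
    """Execute the comparison workflow described by a manifest.

    Any stage failure aborts with the stage and model label in the
    exception message; artifacts written before the failure are kept
    alongside a ``FAILED`` marker file.
    """
    out_root = Path(manifest.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    cmap = _io.load_component_map(manifest.component_map) \
        if manifest.component_map else None

    provenance: dict = {
        "heatdyn_version": __version__,
        "seed": manifest.seed,
        "reference": manifest.reference_label,
        "inputs": {},
    }
    stage = "validate"
    results: dict[str, EnsembleDynamicsResults] = {}
    cs_matrices: dict[str, pd.DataFrame] = {}
    switch_tables: dict[str, pd.DataFrame] = {}
    rmsf_tables: dict[str, pd.DataFrame] = {}
    hbond_tables: list[tuple[str, list]] = []
    try:
        for spec in manifest.models:
            label = spec.label
            model_dir = out_root / label
            stage = f"read[{label}]"
            ens = _load_model(spec)
            for p in filter(None, (spec.topology, spec.trajectory)):
                provenance["inputs"][str(p)] = _sha256(Path(p))

            stage = f"fit[{label}]"
            md = EnsembleDynamics(
                ens, component_map=cmap, window=manifest.window,
                fit=manifest.fit, mass_weighted=manifest.mass_weighted)
            res = md.fit(n_modes=manifest.n_modes)
            results[label] = res

            stage = f"write[{label}]"
            beads = res.superposed.beads
            _write_csv(res.profile.as_frame(beads),
                       model_dir / "rmsf_per_bead.csv")
            _write_csv(pd.DataFrame({
                "frame": np.arange(*res.window),
                "rmsd_A": res.rmsd,
                "rg_A": res.profile.radius_of_gyration,
            }), model_dir / "rmsd_rg.csv")
            _write_csv(res.cross_correlation.as_frame(),
                       model_dir / "cross_correlation.csv", index=True)
            _write_csv(res.pca.spectrum_frame(),
                       model_dir / "pca_spectrum.csv")
            res.export_nmd(model_dir / "modes.nmd",
                           modes=list(range(min(3, res.pca.n_modes))))
            if res.correlation_scores is not None:
                df = res.correlation_scores.as_frame()
                cs_matrices[label] = df
                _write_csv(df, model_dir / "correlation_scores.csv",
                           index=True)
            rmsf_tables[label] = res.profile.per_component
            _write_csv(res.profile.per_component,
                       model_dir / "rmsf_per_component.csv")

            if manifest.probe_block is not None:
                stage = f"switch[{label}]"
                regions = res.switch_regions(manifest.probe_block,
                                             **manifest.switch_params)
                tab = switch_regions_frame(regions)
                switch_tables[label] = tab
                tab.to_csv(model_dir / "switch_regions.tsv", sep="\t",
                           index=False, float_format=_FLOAT_FMT,
                           lineterminator="\n")

            if manifest.hbonds:
                stage = f"hbonds[{label}]"
                crit = _hb.HBondCriterion(**manifest.hbond_criterion)
                hres = HBondAnalysis(ens, criterion=crit,
                                     window=manifest.window).fit()
                hbond_tables.append((label, hres.occupancies))
                _write_csv(hres.as_frame(),
                           model_dir / "hbond_occupancy.csv")
    except Exception as exc:
        (out_root / "FAILED").write_text(
            f"stage {stage}: {exc}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    ref = manifest.reference_label
    cs_diffs: dict[str, pd.DataFrame] = {}
    if ref in cs_matrices:
        ref_cs = cs_matrices[ref]
        for label, df in cs_matrices.items():
            if label == ref:
                continue
            if list(df.index) != list(ref_cs.index):
                raise RuntimeError(
                    "component ordering differs between models "
                    f"{label!r} and {ref!r}; use one shared component map")
            diff = df - ref_cs
            cs_diffs[label] = diff
            _write_csv(diff, out_root / f"cs_diff_{label}_vs_{ref}.csv",
                       index=True)

    hbond_delta = None
    if len(hbond_tables) >= 2:
        hbond_delta = _hb.compare_occupancies(hbond_tables, min_delta=0.0)
        _write_csv(hbond_delta, out_root / "hbond_deltas.csv")

    cfg = {
        "models": [(m.label, m.topology, m.trajectory)
                   for m in manifest.models],
        "window": str(manifest.window), "fit": manifest.fit,
        "mass_weighted": manifest.mass_weighted,
        "component_map": manifest.component_map,
        "probe_block": manifest.probe_block, "seed": manifest.seed,
    }
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()
    (out_root / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")

    return ComparisonReport(
        reference_label=ref, results=results, cs_matrices=cs_matrices,
        cs_differences=cs_diffs, switch_regions=switch_tables,
        rmsf_per_component=rmsf_tables, hbond_deltas=hbond_delta,
        provenance=provenance, output_dir=out_root)


def site_distance(ensemble: _io.Ensemble,
                  site_a: tuple[str, int], site_b: tuple[str, int],
                  atom_a: str | None = None, atom_b: str | None = None,
                  frame: int = 0) -> float:
    """Distance (Å) between two residues' reference atoms in one frame.

    Used for worked-example measurements such as the separation between
    a branch-point adenosine and the 5' splice-site scissile phosphate.
    By default the first atom record of each residue is used; pass
    ``atom_a``/``atom_b`` to pick specific atoms (e.g. ``"P"``, ``"C1'"``).
    """
    tbl = ensemble.atom_table.frame

    def _pick(chain: str, resnum: int, atom: str | None) -> int:
        sel = tbl[(tbl.chain_id == chain) & (tbl.residue_number == resnum)]
        if atom is not None:
            sel = sel[sel.atom_name.str.strip() == atom]
        if len(sel) == 0:
            raise KeyError(f"no atom for chain {chain!r} residue {resnum}"
                           + (f" atom {atom!r}" if atom else ""))
        return int(sel.index[0])

    ia = _pick(*site_a, atom_a)
    ib = _pick(*site_b, atom_b)
    return float(np.linalg.norm(ensemble.coords[frame, ia]
                                - ensemble.coords[frame, ib]))
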