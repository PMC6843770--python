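"""Reading and writing structures, ensembles and component maps.

Conformational ensembles are held as an :class:`Ensemble`: an immutable
atom table plus a ``(n_frames, n_atoms, 3)`` coordinate array in Å.
Multi-model PDB and GRO files are read through MDAnalysis (GRO's nm are
converted to Å on read); DCD trajectories need a topology file for the
atom table. Masses are always assigned from the element, since
coordinate files carry none.

The analysis bead selection — one bead per residue, Cα for amino acids
and P for nucleotides — lives here too, because every downstream matrix
(RMSF, covariance, cross-correlation) is indexed by it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._elements import AMINO_ACIDS, NUCLEOTIDES, element_from_name, mass_of

logger = logging.getLogger("heatdyn")

__all__ = [
    "AtomTable", "Ensemble", "ComponentMap", "BeadSelection",
    "read_structure", "read_trajectory", "write_structure",
    "write_trajectory", "load_component_map", "write_component_map",
    "select_beads", "TrajectoryError",
]

UNASSIGNED = "unassigned"


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent structure/trajectory input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomTable:
    """Per-atom records of an ensemble: name, element, residue, chain, mass."""

    frame: pd.DataFrame  # columns: atom_name, element, residue_number, residue_name, chain_id, mass

    COLUMNS = ("atom_name", "element", "residue_number", "residue_name",
               "chain_id", "mass")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        if len(self.frame) == 0:
            raise TrajectoryError("empty input: structure contains zero atoms")
        key = self.frame[["chain_id", "residue_number", "atom_name"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate atom record "
                f"(chain {dup.chain_id!r}, residue {dup.residue_number}, "
                f"atom {dup.atom_name!r})")
        if (self.frame["mass"] <= 0).any():
            raise ValueError("all atomic masses must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def masses(self) -> np.ndarray:
        return self.frame["mass"].to_numpy(dtype=float)

    def residues(self) -> Iterator[tuple[tuple[str, int, str], np.ndarray]]:
        """Iterate ``((chain_id, residue_number, residue_name), row_indices)``
        in first-appearance order."""
        keys = list(zip(self.frame["chain_id"], self.frame["residue_number"],
                        self.frame["residue_name"]))
        seen: dict[tuple, list[int]] = {}
        for i, k in enumerate(keys):
            seen.setdefault(k, []).append(i)
        for k, rows in seen.items():
            yield k, np.asarray(rows, dtype=int)

    @classmethod
    def from_records(cls, atom_names: Sequence[str],
                     residue_numbers: Sequence[int],
                     residue_names: Sequence[str],
                     chain_ids: Sequence[str],
                     elements: Sequence[str] | None = None) -> "AtomTable":
        """Build a table, inferring elements from names where not given."""
        atom_names = [str(a) for a in atom_names]
        residue_names = [str(r) for r in residue_names]
        if elements is None:
            elements = [element_from_name(a, r)
                        for a, r in zip(atom_names, residue_names)]
        masses = [mass_of(e) for e in elements]
        return cls(pd.DataFrame({
            "atom_name": atom_names,
            "element": list(elements),
            "residue_number": np.asarray(residue_numbers, dtype=int),
            "residue_name": residue_names,
            "chain_id": [str(c) for c in chain_ids],
            "mass": masses,
        }))


@dataclass
class Ensemble:
    """Ordered frames of coordinates (Å) over a fixed atom table."""

    atom_table: AtomTable
    coords: np.ndarray                 # (n_frames, n_atoms, 3), Å
    frame_labels: np.ndarray | None = None   # optional time stamps (ns)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), "
                             f"got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise TrajectoryError("ensemble must contain at least one frame")
        if self.coords.shape[1] != len(self.atom_table):
            raise TrajectoryError(
                f"dimension error: {self.coords.shape[1]} coordinates per "
                f"frame but {len(self.atom_table)} atoms in table")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.frame_labels is not None:
            self.frame_labels = np.asarray(self.frame_labels, dtype=float)
            if self.frame_labels.shape != (self.coords.shape[0],):
                raise ValueError("frame_labels must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray) -> "Ensemble":
        """A copy of this ensemble with new coordinates, same atom table."""
        return Ensemble(self.atom_table, coords,
                        frame_labels=self.frame_labels,
                        metadata=dict(self.metadata))


@dataclass(frozen=True)
class ComponentMap:
    """Residue-range assignment to named components (domains, repeats, RNAs).

    Ranges are 1-based and inclusive on both ends, matching how domain
    boundaries are cited in structural biology (e.g. HEAT repeats H1–H20).
    """

    entries: pd.DataFrame  # component_name, chain_id, residue_start, residue_end

    COLUMNS = ("component_name", "chain_id", "residue_start", "residue_end")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"component map missing columns: {sorted(missing)}")
        bad = self.entries[self.entries.residue_start > self.entries.residue_end]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(
                f"invalid range for component {r.component_name!r}: "
                f"residue_start {r.residue_start} > residue_end {r.residue_end}")
        for chain, grp in self.entries.groupby("chain_id"):
            g = grp.sort_values("residue_start")
            prev = None
            for _, row in g.iterrows():
                if prev is not None and row.residue_start <= prev.residue_end:
                    raise ValueError(
                        "overlapping component ranges on chain "
                        f"{chain!r}: {prev.component_name!r} "
                        f"[{prev.residue_start}, {prev.residue_end}] and "
                        f"{row.component_name!r} "
                        f"[{row.residue_start}, {row.residue_end}]")
                prev = row

    @classmethod
    def from_entries(cls, entries: Sequence[tuple[str, str, int, int]]
                     ) -> "ComponentMap":
        return cls(pd.DataFrame(list(entries), columns=list(cls.COLUMNS)))

    @property
    def component_names(self) -> list[str]:
        """Component names in first-appearance order."""
        return list(dict.fromkeys(self.entries["component_name"]))

    def component_of(self, chain_id: str, residue_number: int) -> str:
        """Component label for a residue, or ``"unassigned"``."""
        m = self.entries[(self.entries.chain_id == chain_id)
                         & (self.entries.residue_start <= residue_number)
                         & (self.entries.residue_end >= residue_number)]
        if len(m) == 0:
            return UNASSIGNED
        return str(m.iloc[0].component_name)

    @classmethod
    def empty(cls) -> "ComponentMap":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)))


@dataclass(frozen=True)
class BeadSelection:
    """One analysis bead per residue: Cα for amino acids, P for nucleotides."""

    indices: np.ndarray          # atom-table row indices, strictly increasing
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    components: np.ndarray       # component label per bead, or "unassigned"
    masses: np.ndarray           # amu

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise TrajectoryError(
                "empty selection: no Cα or P bead atoms found")
        if not (np.diff(self.indices) > 0).all():
            raise ValueError("bead indices must be strictly increasing")

    @property
    def n_beads(self) -> int:
        return len(self.indices)

    def labels(self) -> list[str]:
        """Human-readable per-bead labels ``chain:resname resnum``."""
        return [f"{c}:{rn}{num}" for c, rn, num in
                zip(self.chain_ids, self.residue_names, self.residue_numbers)]


# ---------------------------------------------------------------------------
# readers / writers (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _scan_pdb_models(path: Path) -> None:
    """Pre-scan a PDB for per-MODEL atom counts; raise on inconsistency."""
    counts: list[int] = []
    in_model = False
    loose = 0  # ATOM records outside any MODEL block
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                counts.append(0)
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise TrajectoryError(
                        f"{path}: malformed {rec} record at line {lineno} "
                        "(truncated coordinate fields)")
                if in_model:
                    counts[-1] += 1
                else:
                    loose += 1
            elif rec == "ENDMDL":
                in_model = False
    if loose:
        counts.append(loose)
    if len(set(counts)) > 1:
        raise TrajectoryError(
            f"{path}: inconsistent atom count across models "
            f"({sorted(set(counts))})")


def _universe_to_ensemble(u, frame_labels=None) -> Ensemble:
    import MDAnalysis as mda  # noqa: F401  (deferred; heavy import)

    atoms = u.atoms
    if len(atoms) == 0:
        raise TrajectoryError("empty input: structure contains zero atoms")
    names = [a.strip() for a in atoms.names]
    resnames = [r.strip() for r in atoms.resnames]
    try:
        elements = [e.strip().capitalize() if e.strip() else None
                    for e in atoms.elements]
    except Exception:
        elements = [None] * len(atoms)
    elements = [e if e else element_from_name(n, r)
                for e, n, r in zip(elements, names, resnames)]
    try:
        chains = [c if str(c).strip() else "A" for c in atoms.chainIDs]
    except Exception:
        chains = [str(s).strip() or "A" for s in atoms.segids]
    table = AtomTable.from_records(names, atoms.resids, resnames, chains,
                                   elements=[e.upper() for e in elements])
    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(atoms), 3), dtype=float)
    for i, _ts in enumerate(u.trajectory):
        coords[i] = atoms.positions  # MDAnalysis positions are in Å
    return Ensemble(table, coords, frame_labels=frame_labels)


def _drop_altlocs(u):
    """Keep altloc '' or 'A' only, enforcing one record per atom."""
    try:
        alts = u.atoms.altLocs
    except Exception:
        return u.atoms
    keep = np.array([a.strip() in ("", "A") for a in alts])
    return u.atoms[keep]


def read_structure(path: str | Path, format: str | None = None) -> Ensemble:
    """Read a (possibly multi-model) PDB or GRO file into an :class:`Ensemble`.

    Each MODEL record of a multi-model PDB becomes one frame. GRO
    coordinates (nm) are converted to Å. Masses come from standard
    atomic weights of the inferred elements.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    if fmt == "pdb":
        _scan_pdb_models(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # normalise MDAnalysis parse failures
        raise TrajectoryError(f"failed to parse {path}: {exc}") from exc
    ag = _drop_altlocs(u)
    if len(ag) != len(u.atoms):
        u = mda.Merge(ag)
    return _universe_to_ensemble(u)


def read_trajectory(topology: str | Path, coords: str | Path,
                    format: str | None = None) -> Ensemble:
    """Read a trajectory (DCD or multi-model PDB) over a topology file."""
    import MDAnalysis as mda

    topology, coords = Path(topology), Path(coords)
    fmt = (format or coords.suffix.lstrip(".")).lower()
    if fmt in ("multi_model_pdb", "pdb"):
        ens = read_structure(coords, format="pdb")
        top = read_structure(topology)
        if ens.n_atoms != top.n_atoms:
            raise TrajectoryError(
                f"dimension error: topology has {top.n_atoms} atoms but "
                f"trajectory frames have {ens.n_atoms}")
        return Ensemble(top.atom_table, ens.coords, ens.frame_labels)
    if fmt != "dcd":
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology), str(coords))
    except Exception as exc:
        msg = str(exc)
        if "atoms" in msg.lower() and ("match" in msg.lower()
                                       or "number" in msg.lower()):
            raise TrajectoryError(f"dimension error: {msg}") from exc
        raise TrajectoryError(
            f"failed to read trajectory {coords}: {msg}") from exc
    if u.trajectory.n_atoms != len(u.atoms):
        raise TrajectoryError(
            f"dimension error: topology has {len(u.atoms)} atoms but "
            f"trajectory has {u.trajectory.n_atoms}")
    return _universe_to_ensemble(u)


def _to_universe(ensemble: Ensemble):
    """Build an in-memory MDAnalysis Universe mirroring an Ensemble."""
    import MDAnalysis as mda

    tbl = ensemble.atom_table.frame
    res_keys = list(zip(tbl.chain_id, tbl.residue_number, tbl.residue_name))
    res_index: dict[tuple, int] = {}
    atom_resindex = np.empty(len(tbl), dtype=int)
    for i, k in enumerate(res_keys):
        atom_resindex[i] = res_index.setdefault(k, len(res_index))
    residues = list(res_index)
    chains = list(dict.fromkeys(k[0] for k in residues))
    seg_of = {c: i for i, c in enumerate(chains)}
    residue_segindex = np.array([seg_of[k[0]] for k in residues], dtype=int)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=len(tbl), n_residues=len(residues),
            n_segments=len(chains), atom_resindex=atom_resindex,
            residue_segindex=residue_segindex, trajectory=True)
        u.add_TopologyAttr("names", tbl.atom_name.tolist())
        u.add_TopologyAttr("resids", [k[1] for k in residues])
        u.add_TopologyAttr("resnames", [k[2] for k in residues])
        u.add_TopologyAttr("segids", chains)
        u.add_TopologyAttr("chainIDs", tbl.chain_id.tolist())
        u.add_TopologyAttr("elements",
                           [e.capitalize() for e in tbl.element])
        u.add_TopologyAttr("masses", tbl.mass.to_numpy())
        u.add_TopologyAttr("occupancies", np.ones(len(tbl)))
        u.add_TopologyAttr("tempfactors", np.zeros(len(tbl)))
        u.load_new(np.asarray(ensemble.coords, dtype=np.float32), order="fac")
    return u


def write_structure(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame)."""
    import MDAnalysis as mda

    u = _to_universe(ensemble)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True,
                        n_atoms=ensemble.n_atoms) as w:
            for _ts in u.trajectory:
                w.write(u.atoms)


def write_trajectory(ensemble: Ensemble, topology_path: str | Path,
                     dcd_path: str | Path) -> None:
    """Write topology (single-frame PDB) plus a DCD coordinate trajectory."""
    import MDAnalysis as mda

    first = ensemble.with_coords(ensemble.coords[:1])
    write_structure(first, topology_path)
    u = _to_universe(ensemble)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(dcd_path), n_atoms=ensemble.n_atoms) as w:
            for _ts in u.trajectory:
                w.write(u.atoms)


def load_component_map(path: str | Path) -> ComponentMap:
    """Load a 4-column TSV (component_name, chain_id, residue_start,
    residue_end; header required) into a validated :class:`ComponentMap`."""
    df = pd.read_csv(path, sep="\t", dtype={"component_name": str,
                                            "chain_id": str})
    missing = set(ComponentMap.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"component map {path} missing columns: {sorted(missing)}")
    if len(df):
        df["residue_start"] = df["residue_start"].astype(int)
        df["residue_end"] = df["residue_end"].astype(int)
    return ComponentMap(df[list(ComponentMap.COLUMNS)])


def write_component_map(cmap: ComponentMap, path: str | Path) -> None:
    cmap.entries.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bead selection
# ---------------------------------------------------------------------------

def select_beads(ensemble: Ensemble,
                 cmap: ComponentMap | None = None) -> BeadSelection:
    """Select one analysis bead per residue: the Cα atom for amino-acid
    residues, the P atom for nucleotides.

    Residues lacking their bead atom (e.g. the 5'-terminal nucleotide,
    which has no phosphate) are skipped with a logged warning; other
    residues (ligands, ions, water) are ignored silently. Bead order
    follows atom-table order, so downstream matrix indices are stable.
    """
    cmap = cmap if cmap is not None else ComponentMap.empty()
    tbl = ensemble.atom_table
    rows, resnums, resnames, chains = [], [], [], []
    for (chain, resnum, resname), idx in tbl.residues():
        upname = resname.strip().upper()
        if upname in AMINO_ACIDS:
            bead_name = "CA"
        elif upname in NUCLEOTIDES:
            bead_name = "P"
        else:
            continue
        names = tbl.frame["atom_name"].to_numpy()[idx]
        hit = idx[np.array([n.strip().upper() == bead_name for n in names])]
        if len(hit) == 0:
            logger.warning("residue %s %s%d lacks bead atom %s; skipped",
                           resname, chain, resnum, bead_name)
            continue
        rows.append(int(hit[0]))
        resnums.append(resnum)
        resnames.append(resname)
        chains.append(chain)
    order = np.argsort(rows, kind="stable")
    rows_a = np.asarray(rows, dtype=int)[order]
    resnums_a = np.asarray(resnums, dtype=int)[order]
    resnames_a = np.asarray(resnames, dtype=object)[order]
    chains_a = np.asarray(chains, dtype=object)[order]
    comps = np.asarray([cmap.component_of(c, int(r))
                        for c, r in zip(chains_a, resnums_a)], dtype=object)
    if len(rows_a) == 0:
        raise TrajectoryError("empty selection: no Cα or P bead atoms found")
    masses = tbl.masses[rows_a]
    return BeadSelection(rows_a, resnums_a, resnames_a, chains_a,
                         comps, masses)
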