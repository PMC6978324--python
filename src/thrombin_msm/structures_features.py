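"""Structural ensembles and the activation-state descriptors.

Lightweight topology/trajectory containers for serine-protease loop
analysis in chymotrypsin numbering (insertion codes preserved verbatim:
residue ``221a`` is distinct from ``221``), multi-model PDB round-tripping,
Kabsch superposition/RMSD, dihedrals, and the four activation descriptors:

* ``WCT`` — distance from the W215 heavy-atom centre to the centre of the
  catalytic-triad Calpha atoms (probes occlusion of the binding cleft),
* ``RCT`` — distance from the R221a guanidinium carbon to the triad centre,
* ``GG``  — G193--G216 Calpha distance (S1-pocket accessibility),
* ``PhiD`` — backbone phi dihedral of D221 (the slow loop torsion),

plus the binary sodium-coordination coordinate (a Na+ ion simultaneously
within a cutoff of the R221a and K224 backbone oxygens) and the residue-wise
centres of mass of the sodium-binding loop V213--T229 used as input features
for time-lagged independent component analysis.

Distances are in Angstrom, dihedrals in degrees on (-180, 180].
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "TrajectoryEnsemble",
    "FeatureMatrix",
    "read_structure_ensemble",
    "write_structure_ensemble",
    "kabsch_rmsd",
    "superpose",
    "dihedral_angle",
    "compute_activation_features",
    "na_bound_indicator",
    "residue_com_features",
    "ATOMIC_MASSES",
]

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "NA": 22.990}

_LABEL_RE = re.compile(r"^(\d+)([A-Za-z]?)$")


def parse_residue_label(label: str) -> tuple[int, str]:
    m = _LABEL_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"malformed residue label {label!r} (expected e.g. '215' or '221a')")
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    is_heavy: bool = True


@dataclass(frozen=True)
class Residue:
    name: str
    number: int
    icode: str = ""
    chain: str = "A"

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}"


@dataclass
class Topology:
    atoms: list[Atom]
    residues: list[Residue]
    atom_residue: np.ndarray  # atom index -> residue index

    def __post_init__(self) -> None:
        self.atom_residue = np.asarray(self.atom_residue, dtype=np.int64)
        if len(self.atom_residue) != len(self.atoms):
            raise ValueError("atom_residue must map every atom")
        seen = set()
        for r in self.residues:
            key = (r.chain, r.label)
            if key in seen:
                raise ValueError(f"duplicate residue {r.label} in chain {r.chain}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_index(self, label: str, chain: str | None = None) -> int:
        number, icode = parse_residue_label(label)
        for i, r in enumerate(self.residues):
            if r.number == number and r.icode == icode and (chain is None or r.chain == chain):
                return i
        raise KeyError(f"residue {label!r} not found in topology")

    def atoms_of(self, residue_index: int, heavy_only: bool = False) -> np.ndarray:
        idx = np.flatnonzero(self.atom_residue == residue_index)
        if heavy_only:
            idx = idx[[self.atoms[i].is_heavy for i in idx]]
        return idx

    def atom_index(self, residue_label: str, atom_name: str) -> int:
        ri = self.residue_index(residue_label)
        for i in self.atoms_of(ri):
            if self.atoms[i].name == atom_name:
                return int(i)
        raise KeyError(f"atom {atom_name!r} not found in residue {residue_label!r}")

    def ca_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.name == "CA"], dtype=np.int64)

    def element_indices(self, element: str) -> np.ndarray:
        element = element.upper()
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element.upper() == element],
            dtype=np.int64,
        )


@dataclass
class TrajectoryEnsemble:
    topology: Topology
    frames: np.ndarray  # (n_frames, n_atoms, 3) in Angstrom
    timestep_ps: float = 1.0
    condition: str = "without_Na"
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.timestep_ps <= 0:
            raise ValueError("timestep must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class FeatureMatrix:
    """Per-frame feature vectors with named columns and per-column units."""

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    provenance: pd.DataFrame | None = None  # columns: trajectory, frame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("FeatureMatrix must not contain missing values")
        if self.provenance is not None and len(self.provenance) != len(self.data):
            raise ValueError("provenance must have one row per frame")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(float)

    @staticmethod
    def hstack(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        data = pd.concat([p.data.reset_index(drop=True) for p in parts], axis=1)
        units: dict[str, str] = {}
        for p in parts:
            units.update(p.units)
        prov = next((p.provenance for p in parts if p.provenance is not None), None)
        return FeatureMatrix(data, units, prov)

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False, float_format="%.8g")
        meta = {"units": self.units}
        if self.provenance is not None:
            meta["provenance"] = {c: self.provenance[c].tolist() for c in self.provenance}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        data = pd.read_csv(path, sep="\t")
        units, prov = {}, None
        side = path.with_suffix(path.suffix + ".json")
        if side.exists():
            meta = json.loads(side.read_text())
            units = meta.get("units", {})
            if "provenance" in meta:
                prov = pd.DataFrame(meta["provenance"])
        return cls(data, units, prov)


# ---------------------------------------------------------------------------
# PDB input/output (wwPDB 3.3 fixed columns, MODEL/ENDMDL for multi-frame)


def _format_atom_name(name: str) -> str:
    # element-aligned: 1-3 character names start in column 14
    return name.ljust(4) if len(name) >= 4 else f" {name}".ljust(4)


def write_structure_ensemble(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    top = ensemble.topology
    lines: list[str] = []
    for m, frame in enumerate(ensemble.frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 0
        for i, atom in enumerate(top.atoms):
            res = top.residues[top.atom_residue[i]]
            serial += 1
            record = "HETATM" if atom.element.upper() == "NA" else "ATOM  "
            x, y, z = frame[i]
            icode = res.icode if res.icode else " "
            lines.append(
                f"{record}{serial:5d} {_format_atom_name(atom.name)} "
                f"{res.name:>3s} {res.chain}{res.number:4d}{icode}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{atom.element.upper():>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _prescan_pdb(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"malformed PDB record at line {lineno}: too short")
            try:
                for s in (line[30:38], line[38:46], line[46:54]):
                    float(s)
            except ValueError as exc:
                raise ValueError(
                    f"malformed PDB record at line {lineno}: bad coordinate field"
                ) from exc


def _read_pdb(path: Path) -> tuple[Topology, np.ndarray]:
    from Bio.PDB import PDBParser

    _prescan_pdb(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models found in {path}")

    atoms: list[Atom] = []
    residues: list[Residue] = []
    atom_residue: list[int] = []
    order: list[tuple] = []
    for chain in models[0]:
        for res in chain:
            icode = res.id[2].strip().lower() if res.id[2] != " " else ""
            residues.append(Residue(res.resname.strip(), res.id[1], icode, chain.id))
            ri = len(residues) - 1
            for at in res:
                el = (at.element or at.get_name()[0]).upper()
                atoms.append(Atom(at.get_name(), el, is_heavy=el != "H"))
                atom_residue.append(ri)
                order.append((chain.id, res.id, at.get_name()))
    top = Topology(atoms, residues, np.asarray(atom_residue))

    frames = np.empty((len(models), top.n_atoms, 3))
    for m, model in enumerate(models):
        coords = [at.coord for chain in model for res in chain for at in res]
        if len(coords) != top.n_atoms:
            raise ValueError(f"model {m + 1} has {len(coords)} atoms, expected {top.n_atoms}")
        frames[m] = np.asarray(coords, float)
    return top, frames


def read_structure_ensemble(
    path: str | Path,
    format: str = "pdb",
    topology_pdb: str | Path | None = None,
    required_residues: Sequence[str] | None = None,
    timestep_ps: float = 1.0,
    condition: str = "without_Na",
) -> TrajectoryEnsemble:
    """Read a multi-model PDB, or a frames TSV paired with a topology PDB.

    ``required_residues`` (labels such as ``"221a"``) are checked up front and
    reported together if absent.
    """
    path = Path(path)
    if format == "pdb":
        top, frames = _read_pdb(path)
    elif format == "tsv":
        if topology_pdb is None:
            raise ValueError("frames TSV format requires topology_pdb")
        top, _ = _read_pdb(Path(topology_pdb))
        arr = np.loadtxt(path, delimiter="\t", skiprows=1)
        arr = np.atleast_2d(arr)[:, 1:]
        if arr.shape[1] != 3 * top.n_atoms:
            raise ValueError(
                f"frames TSV has {arr.shape[1]} coordinate columns, expected {3 * top.n_atoms}"
            )
        frames = arr.reshape(len(arr), top.n_atoms, 3)
    else:
        raise ValueError(f"unknown format {format!r}")

    if required_residues:
        missing = []
        for label in required_residues:
            try:
                top.residue_index(label)
            except KeyError:
                missing.append(label)
        if missing:
            raise KeyError(f"required residues missing from {path.name}: {', '.join(missing)}")
    return TrajectoryEnsemble(top, frames, timestep_ps=timestep_ps, condition=condition)


def write_frames_tsv(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    n = len(ensemble)
    flat = ensemble.frames.reshape(n, -1)
    header = "frame\t" + "\t".join(
        f"a{i}_{ax}" for i in range(ensemble.topology.n_atoms) for ax in "xyz"
    )
    np.savetxt(
        path,
        np.column_stack([np.arange(n), flat]),
        delimiter="\t",
        header=header,
        comments="",
        fmt="%.6f",
    )


# ---------------------------------------------------------------------------
# Geometry


def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing |R p - q| for centred point sets."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
    rmsd_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose ``mobile`` onto ``reference`` and report the RMSD.

    The rotation/translation minimize the deviation over ``fit_selection``;
    the RMSD is then measured over ``rmsd_selection`` (defaults: all atoms /
    the fit selection).  Returns (rotation, translation, rmsd) with
    ``transformed = mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    fit = np.arange(len(mobile)) if fit_selection is None else np.asarray(fit_selection)
    rsel = fit if rmsd_selection is None else np.asarray(rmsd_selection)
    if len(fit) == 0 or len(rsel) == 0:
        raise ValueError("selections must be non-empty")
    if len(fit) < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    P = mobile[fit] - mobile[fit].mean(axis=0)
    Q = reference[fit] - reference[fit].mean(axis=0)
    if np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) fit selection")
    R = _kabsch_rotation(P, Q)
    t = reference[fit].mean(axis=0) - mobile[fit].mean(axis=0) @ R.T
    moved = mobile[rsel] @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference[rsel]) ** 2, axis=1))))
    return R, t, rmsd


def superpose(
    frames: np.ndarray, reference: np.ndarray, fit_selection: np.ndarray
) -> np.ndarray:
    """Rigid-align every frame onto ``reference`` using ``fit_selection``."""
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        R, t, _ = kabsch_rmsd(frame, reference, fit_selection)
        out[i] = frame @ R.T + t
    return out


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Dihedral in degrees on (-180, 180], IUPAC sign convention."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-10 or np.linalg.norm(b0) < 1e-10 or np.linalg.norm(b2) < 1e-10:
        raise ValueError("degenerate dihedral geometry: coincident consecutive points")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise ValueError("degenerate dihedral geometry: collinear points")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


# ---------------------------------------------------------------------------
# Activation descriptors


def _com(frames: np.ndarray, idx: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    sub = frames[:, idx, :]
    if weights is None:
        return sub.mean(axis=1)
    w = weights / weights.sum()
    return np.einsum("fij,i->fj", sub, w)


def compute_activation_features(
    ensemble: TrajectoryEnsemble,
    triad: Sequence[str] = ("57", "102", "195"),
) -> FeatureMatrix:
    """WCT, RCT, GG and PhiD for every frame.

    The catalytic-triad centre is the unweighted mean of the triad Calpha
    positions (H57, D102, S195 by default); centres of mass are unweighted
    (geometric) means of heavy atoms.
    """
    top = ensemble.topology
    frames = ensemble.frames
    w215 = top.atoms_of(top.residue_index("215"), heavy_only=True)
    if len(w215) == 0:
        raise KeyError("residue 215 has no heavy atoms")
    triad_ca = np.array([top.atom_index(label, "CA") for label in triad])
    cz = top.atom_index("221a", "CZ")
    g193 = top.atom_index("193", "CA")
    g216 = top.atom_index("216", "CA")

    ri_221 = top.residue_index("221")
    if ri_221 == 0:
        raise KeyError("residue 221 has no preceding residue for the phi dihedral")
    prev_atoms = top.atoms_of(ri_221 - 1)
    prev_c = next((i for i in prev_atoms if top.atoms[i].name == "C"), None)
    if prev_c is None:
        raise KeyError(
            f"atom 'C' not found in residue {top.residues[ri_221 - 1].label!r} "
            "(needed for the D221 phi dihedral)"
        )
    n221 = top.atom_index("221", "N")
    ca221 = top.atom_index("221", "CA")
    c221 = top.atom_index("221", "C")

    triad_center = frames[:, triad_ca, :].mean(axis=1)
    wct = np.linalg.norm(_com(frames, w215) - triad_center, axis=1)
    rct = np.linalg.norm(frames[:, cz, :] - triad_center, axis=1)
    gg = np.linalg.norm(frames[:, g193, :] - frames[:, g216, :], axis=1)
    phid = np.array(
        [
            dihedral_angle(f[prev_c], f[n221], f[ca221], f[c221])
            for f in frames
        ]
    )
    data = pd.DataFrame({"WCT": wct, "RCT": rct, "GG": gg, "PhiD": phid})
    units = {"WCT": "Angstrom", "RCT": "Angstrom", "GG": "Angstrom", "PhiD": "degrees"}
    return FeatureMatrix(data, units)


def na_bound_indicator(ensemble: TrajectoryEnsemble, cutoff: float = 3.8) -> FeatureMatrix:
    """Binary column: 1 iff some Na+ is within ``cutoff`` Angstrom of both the
    R221a and the K224 backbone oxygen simultaneously.  No sodium particles
    in the topology gives all zeros."""
    top = ensemble.topology
    na_idx = top.element_indices("NA")
    flag = np.zeros(len(ensemble))
    if len(na_idx) > 0:
        o221a = top.atom_index("221a", "O")
        o224 = top.atom_index("224", "O")
        d1 = np.linalg.norm(
            ensemble.frames[:, na_idx, :] - ensemble.frames[:, [o221a], :], axis=2
        )
        d2 = np.linalg.norm(
            ensemble.frames[:, na_idx, :] - ensemble.frames[:, [o224], :], axis=2
        )
        flag = (((d1 <= cutoff) & (d2 <= cutoff)).any(axis=1)).astype(float)
    return FeatureMatrix(pd.DataFrame({"NaBound": flag}), {"NaBound": "binary"})


def residue_com_features(
    ensemble: TrajectoryEnsemble,
    first: str = "213",
    last: str = "229",
    align: bool = True,
    reference_frame: np.ndarray | None = None,
    mass_weighted: bool = False,
) -> FeatureMatrix:
    """Residue-wise centres of mass of the loop ``first``..``last``.

    Residues are taken in topology order between the two labels (insertion
    codes included).  Frames are first superposed on the reference via all
    Calpha atoms — raw Cartesian features are meaningless under rigid-body
    diffusion.  Centres are unweighted means of heavy atoms by default; the
    mass-weighted variant is provided for comparison.
    """
    top = ensemble.topology
    i0 = top.residue_index(first)
    i1 = top.residue_index(last)
    if i1 < i0:
        raise ValueError("residue range is reversed in topology order")
    frames = ensemble.frames
    if align:
        ref = frames[0] if reference_frame is None else reference_frame
        frames = superpose(frames, ref, top.ca_indices())
    cols: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    for ri in range(i0, i1 + 1):
        res = top.residues[ri]
        idx = top.atoms_of(ri, heavy_only=True)
        if len(idx) == 0:
            raise KeyError(f"residue {res.label!r} has no heavy atoms")
        weights = None
        if mass_weighted:
            weights = np.array([ATOMIC_MASSES[top.atoms[i].element.upper()] for i in idx])
        com = _com(frames, idx, weights)
        for k, ax in enumerate("xyz"):
            name = f"COM_{res.label}_{ax}"
            cols[name] = com[:, k]
            units[name] = "Angstrom"
    return FeatureMatrix(pd.DataFrame(cols), units)
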