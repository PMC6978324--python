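"""Deterministic embedding of latent double-well states into toy loop structures.

Bridges the 2-D synthetic dynamics to the geometric featurization: a smooth
map places a minimal serine-protease-like topology (catalytic triad, W215,
the V213--T229 sodium-binding loop with the 221a insertion, anchor backbone
oxygens and an optional Na+ particle) so that

* latent coordinate 1 monotonically drives PhiD through its E/E* sign
  change (E well at positive PhiD) and the R221a orientation (RCT),
* latent coordinate 2 drives WCT and GG,
* sodium_state = 1 parks the Na+ ion in coordination distance of both the
  R221a and K224 backbone oxygens; sodium_state = 0 places it far away.

Every loop-residue centre of mass also shifts smoothly with both latent
coordinates so the TICA input features embed the full 2-D latent manifold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures_features import Atom, Residue, Topology, TrajectoryEnsemble

__all__ = ["ToyTemplate", "toy_template", "embed_latent_to_structures"]

# chymotrypsin-numbered loop V213-T229 (17 residues incl. insertion 221a,
# no residue 218, as in the thrombin sodium-binding loop)
_LOOP = [
    ("VAL", 213, ""), ("SER", 214, ""), ("TRP", 215, ""), ("GLY", 216, ""),
    ("GLU", 217, ""), ("GLY", 219, ""), ("ALA", 220, ""), ("ASP", 221, ""),
    ("ARG", 221, "a"), ("GLY", 222, ""), ("CYS", 223, ""), ("LYS", 224, ""),
    ("PRO", 225, ""), ("GLY", 226, ""), ("PHE", 227, ""), ("TYR", 228, ""),
    ("THR", 229, ""),
]

# W215 sidechain offsets about the residue centre (sum to zero so the
# heavy-atom centre equals the placed centre)
_W215_OFFSETS = np.array([[0.8, 0.4, 0.0], [-0.6, 0.5, 0.1], [-0.2, -0.9, -0.1]])

_PHI_QUARTET_BASE = {
    "A220_C": np.array([12.0, -6.0, 0.0]),
    "D221_N": np.array([13.33, -6.0, 0.0]),
    "D221_CA": np.array([14.08, -4.75, 0.0]),
}


@dataclass
class ToyTemplate:
    topology: Topology
    base: np.ndarray  # (n_atoms, 3) baseline coordinates
    special: dict[str, int]  # named anchor atoms -> atom index
    loop_ca: np.ndarray  # atom indices receiving generic latent displacement
    disp1: np.ndarray  # per-loop-CA displacement for tanh(z1)
    disp2: np.ndarray  # per-loop-CA displacement for tanh(z2)


def toy_template() -> ToyTemplate:
    atoms: list[Atom] = []
    residues: list[Residue] = []
    atom_res: list[int] = []
    coords: list[np.ndarray] = []
    special: dict[str, int] = {}

    def add_residue(name: str, number: int, icode: str = "") -> int:
        residues.append(Residue(name, number, icode))
        return len(residues) - 1

    def add_atom(ri: int, name: str, element: str, pos, tag: str | None = None) -> int:
        atoms.append(Atom(name, element, is_heavy=element != "H"))
        atom_res.append(ri)
        coords.append(np.asarray(pos, float))
        if tag:
            special[tag] = len(atoms) - 1
        return len(atoms) - 1

    # catalytic triad and G193 scaffold
    add_atom(add_residue("HIS", 57), "CA", "C", (0.0, 8.0, 0.0), "H57_CA")
    add_atom(add_residue("ASP", 102), "CA", "C", (2.0, 10.0, 0.0), "D102_CA")
    add_atom(add_residue("SER", 195), "CA", "C", (-2.0, 10.0, 1.0), "S195_CA")
    add_atom(add_residue("GLY", 193), "CA", "C", (-5.0, 2.0, 0.0), "G193_CA")

    # loop CAs along an arc around the triad
    loop_ca: list[int] = []
    arc = np.linspace(-0.9 * np.pi, 0.1 * np.pi, len(_LOOP))
    for (name, number, icode), ang in zip(_LOOP, arc):
        ri = add_residue(name, number, icode)
        base_ca = np.array([9.0 * np.cos(ang), 9.0 * np.sin(ang), 1.0 + np.sin(2 * ang)])
        ca = add_atom(ri, "CA", "C", base_ca, f"{number}{icode}_CA")
        loop_ca.append(ca)
        if (number, icode) == (215, ""):
            add_atom(ri, "CG", "C", base_ca + (1.5, 0.0, 0.2))
            add_atom(ri, "CZ2", "C", base_ca + (-1.5, 0.4, -0.2))
        elif (number, icode) == (220, ""):
            add_atom(ri, "C", "C", _PHI_QUARTET_BASE["A220_C"], "A220_C")
        elif (number, icode) == (221, ""):
            add_atom(ri, "N", "N", _PHI_QUARTET_BASE["D221_N"], "D221_N")
            add_atom(ri, "C", "C", (14.5, -3.4, 0.9), "D221_C")
        elif (number, icode) == (221, "a"):
            add_atom(ri, "CZ", "C", (5.0, 2.0, 0.0), "R221a_CZ")
            add_atom(ri, "O", "O", (6.0, -2.0, 0.0), "R221a_O")
        elif (number, icode) == (224, ""):
            add_atom(ri, "O", "O", (6.0, 1.6, 0.0), "K224_O")

    # D221 CA is part of the phi quartet: pin it (remove from generic drift)
    d221_ca = special["221_CA"]
    special["D221_CA"] = d221_ca

    na = add_residue("NA", 301)
    add_atom(na, "NA", "NA", (40.0, 40.0, 40.0), "NA")

    top = Topology(atoms, residues, np.asarray(atom_res))
    base = np.vstack(coords)
    base[special["D221_N"]] = _PHI_QUARTET_BASE["D221_N"]
    base[special["A220_C"]] = _PHI_QUARTET_BASE["A220_C"]
    base[d221_ca] = _PHI_QUARTET_BASE["D221_CA"]

    drift_ca = np.array(
        [special[f"{n}{i}_CA"] for (_, n, i) in _LOOP if (n, i) not in ((221, ""),)],
        dtype=np.int64,
    )
    rng = np.random.default_rng(12345)  # fixed template geometry, not a run seed
    disp1 = rng.normal(scale=0.8, size=(len(drift_ca), 3))
    disp2 = rng.normal(scale=0.8, size=(len(drift_ca), 3))
    return ToyTemplate(top, base, special, drift_ca, disp1, disp2)


_REQUIRED = [
    ("57", "CA"), ("102", "CA"), ("195", "CA"), ("193", "CA"), ("216", "CA"),
    ("221a", "CZ"), ("221a", "O"), ("224", "O"),
    ("221", "N"), ("221", "CA"), ("221", "C"), ("220", "C"),
]


def _place_dihedral(
    q0: np.ndarray, q1: np.ndarray, q2: np.ndarray,
    bond: float, angle_deg: float, phi_deg: np.ndarray,
) -> np.ndarray:
    """Fourth-atom placement so dihedral(q0, q1, q2, out) = phi (vectorized)."""
    b1 = q1 - q0
    b2 = q2 - q1
    b2h = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    nh = n / np.linalg.norm(n)
    mh = np.cross(nh, b2h)
    theta = np.radians(angle_deg)
    phi = np.radians(np.asarray(phi_deg, float))
    d = np.empty((len(phi), 3))
    d[:, 0] = -bond * np.cos(theta)
    d[:, 1] = bond * np.sin(theta) * np.cos(phi)
    d[:, 2] = bond * np.sin(theta) * np.sin(phi)
    return q2 + d[:, 0:1] * b2h + d[:, 1:2] * mh + d[:, 2:3] * nh


def embed_latent_to_structures(latent, template: ToyTemplate | None = None) -> TrajectoryEnsemble:
    """Map a latent trajectory to a toy structural ensemble (one model per frame)."""
    if template is None:
        template = toy_template()
    top = template.topology
    for res_label, atom_name in _REQUIRED:
        try:
            top.atom_index(res_label, atom_name)
        except KeyError as exc:
            raise KeyError(f"template missing required atom: {exc}") from exc
    if len(top.atoms_of(top.residue_index("215"), heavy_only=True)) < 1:
        raise KeyError("template missing required atom: W215 heavy atoms")

    z = np.asarray(latent.positions, float)
    a = np.tanh(z[:, 0])
    b = np.tanh(z[:, 1])
    n = len(z)
    frames = np.broadcast_to(template.base, (n, *template.base.shape)).copy()

    # generic smooth drift of loop CAs (embeds the latent manifold in the COMs)
    frames[:, template.loop_ca, :] += (
        a[:, None, None] * template.disp1 + b[:, None, None] * template.disp2
    )

    sp = template.special
    triad = (
        template.base[sp["H57_CA"]] + template.base[sp["D102_CA"]] + template.base[sp["S195_CA"]]
    ) / 3.0

    # W215 centre at distance WCT below the triad centre; offsets sum to zero
    wct = 9.0 + 2.5 * b
    w215_idx = top.atoms_of(top.residue_index("215"), heavy_only=True)
    w_com = triad + np.outer(wct, [0.0, -1.0, 0.0])
    frames[:, w215_idx, :] = w_com[:, None, :] + _W215_OFFSETS[: len(w215_idx)]

    # G216 CA at distance GG from G193 CA
    gg = 7.0 + 2.0 * b
    frames[:, sp["216_CA"], :] = template.base[sp["G193_CA"]] + np.outer(gg, [1.0, 0.0, 0.0])

    # R221a guanidinium C at distance RCT from the triad centre
    rct = 8.0 + 2.0 * a
    frames[:, sp["R221a_CZ"], :] = triad + np.outer(rct, [0.6, -0.8, 0.0])

    # D221 phi from latent coordinate 1 (E well at z1 > 0 -> PhiD > 0)
    phi = 100.0 * a
    frames[:, sp["D221_C"], :] = _place_dihedral(
        _PHI_QUARTET_BASE["A220_C"], _PHI_QUARTET_BASE["D221_N"],
        _PHI_QUARTET_BASE["D221_CA"], bond=1.52, angle_deg=111.0, phi_deg=phi,
    )

    # sodium: coordinated by both anchor oxygens when the sodium state is on
    o1 = template.base[sp["R221a_O"]]
    o2 = template.base[sp["K224_O"]]
    mid = 0.5 * (o1 + o2)
    site = mid + np.array([1.4, 0.0, 0.0])  # ~2.3 A from each oxygen
    frames[:, sp["NA"], :] = site if latent.sodium_state else np.array([40.0, 40.0, 40.0])

    return TrajectoryEnsemble(
        top,
        frames,
        timestep_ps=latent.dt,
        condition="with_Na" if latent.sodium_state else "without_Na",
        source=f"embedded latent trajectory (seed={latent.seed})",
    )
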