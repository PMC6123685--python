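"""Coordinate-model comparison of RyR ligand states.

Cryo-EM models of RyR1 in different ligand states (EGTA, Ca2+, caffeine+ATP)
differ by small rigid-body motions of the domains flanking the Ca2+-binding
site: the C-terminal domain (CTD) and core solenoid (CSol) each move by about
2 A when activating ligands bind, closing the Ca2+-binding pocket.  This
module measures such motions from coordinate files: Kabsch superposition on a
reference frame, per-domain Ca displacement, residue-pair contact distances
(the tryptophan-phenylalanine and tryptophan-isoleucine pairs of the caffeine
site), and a planar-polygon proxy for the Ca2+-binding pocket size.

Default RyR1 domain ranges: shell 1-3666, CSol 3667-4253, TM+S6c 4540-4956,
CTD 4957-5037 (overridable for other isoforms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

RYR1_DOMAINS: dict[str, tuple[int, int]] = {
    "shell": (1, 3666),
    "CSol": (3667, 4253),
    "TM+S6c": (4540, 4956),
    "CTD": (4957, 5037),
}

#: residue correspondence between rabbit RyR1 and mouse RyR2 at the analyzed
#: sites.  The RyR1 isoleucine is stored as 4996; primary literature also
#: prints 4966 for the same residue in places — flagged here once.
RYR1_TO_RYR2: dict[int, int] = {
    4716: 4644,  # Trp, caffeine site
    4996: 4925,  # Ile, CTD (also printed as I4966 in some passages)
    3753: 3713,  # Phe, CSol
    3893: 3847,  # Glu, Ca2+ coordination
    3967: 3921,  # Glu, Ca2+ coordination
    3970: 3924,  # Gln, indirect Ca2+ coordination
    5001: 4932,  # Thr / His carbonyl partner region in CTD
    4238: 4192,  # Cys, TaF (disease site)
    4678: 4606,  # Ala, S2S3 (disease site)
}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


class StructureParseError(ValueError):
    """The coordinate file could not be read or lacks the requested chain."""


class SelectionError(ValueError):
    """A residue/atom selection matched too little of the model."""


@dataclass
class StructureModel:
    """Heavy-atom coordinates of one protomer chain, as a flat atom table.

    `atoms` columns: resnum, icode, resname, atom, x, y, z.  Alternate
    locations are resolved to the highest-occupancy conformer; residue
    numbering is preserved from the source file.
    """

    atoms: pd.DataFrame
    source: str
    chain: str
    domains: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(RYR1_DOMAINS)
    )

    def ca_coords(self, residues: set[int] | None = None) -> pd.DataFrame:
        ca = self.atoms[self.atoms["atom"] == "CA"]
        if residues is not None:
            ca = ca[ca["resnum"].isin(residues)]
        return ca.set_index("resnum")[["x", "y", "z"]]

    def residue_atoms(self, resnum: int, heavy_only: bool = True) -> pd.DataFrame:
        sel = self.atoms[self.atoms["resnum"] == resnum]
        if heavy_only:
            sel = sel[~sel["atom"].str.startswith("H")]
        if sel.empty:
            raise SelectionError(f"residue {resnum} absent from chain {self.chain}")
        return sel

    def domain_residues(self, name_or_range) -> set[int]:
        if isinstance(name_or_range, str):
            lo, hi = self.domains[name_or_range]
        else:
            lo, hi = name_or_range
        present = set(self.atoms["resnum"].unique())
        return {r for r in present if lo <= r <= hi}


def load_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    """Parse a PDB or mmCIF file and extract one protomer chain.

    With ``chain=None`` the first chain alphabetically is used (a documented
    convention: the channel is a homotetramer).  Alternate locations keep the
    highest-occupancy conformer.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on bad input
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    structure.setup_entities()
    if len(structure) == 0:
        raise StructureParseError(f"{path}: no models")
    model = structure[0]
    names = sorted(ch.name for ch in model)
    if not names:
        raise StructureParseError(f"{path}: no chains")
    if chain is None:
        chain = names[0]
    if chain not in names:
        raise StructureParseError(f"{path}: chain {chain!r} not in {names}")

    rows = []
    for residue in model[chain]:
        # highest-occupancy altloc per atom name
        best: dict[str, gemmi.Atom] = {}
        for atom in residue:
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        for atom in best.values():
            rows.append(
                {
                    "resnum": residue.seqid.num,
                    "icode": residue.seqid.icode.strip(),
                    "resname": residue.name,
                    "atom": atom.name,
                    "x": atom.pos.x,
                    "y": atom.pos.y,
                    "z": atom.pos.z,
                }
            )
    if not rows:
        raise StructureParseError(f"{path}: chain {chain} has no atoms")
    return StructureModel(atoms=pd.DataFrame(rows), source=str(path), chain=chain)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns (R, t, rmsd) such that ``mobile @ R.T + t`` best matches
    ``reference`` in the least-squares sense (proper rotation enforced).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise SelectionError("superposition needs >= 3 paired atoms")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def _resolve_selection(selection, *models: StructureModel) -> set[int] | None:
    """Residue numbers named by a selection: domain name, (lo, hi) inclusive
    range, or an explicit iterable of residue numbers (None = all common)."""
    if selection is None:
        return None
    if isinstance(selection, str) or (
        isinstance(selection, tuple) and len(selection) == 2
    ):
        out = models[0].domain_residues(selection)
        for m in models[1:]:
            out &= m.domain_residues(selection)
        return out
    return set(selection)


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition on the common Ca atoms of a residue selection.

    ``selection`` is a domain name, an inclusive (first, last) residue-number
    range, an explicit residue-number iterable, or None (all common
    residues).  Residues missing from either model are dropped pairwise.
    """
    residues = _resolve_selection(selection, mobile, reference)
    ca_m = mobile.ca_coords(residues)
    ca_r = reference.ca_coords(residues)
    common = ca_m.index.intersection(ca_r.index)
    if len(common) < 3:
        raise SelectionError(f"only {len(common)} common Ca atoms in selection")
    return kabsch(ca_m.loc[common].to_numpy(), ca_r.loc[common].to_numpy())


def domain_displacement(
    state_a: StructureModel,
    state_b: StructureModel,
    reference_selection,
    target_domain,
) -> dict[str, object]:
    """Domain motion between two ligand states, in the frame of a reference.

    State B is superposed onto state A using the Ca atoms of
    ``reference_selection``; the mean per-Ca displacement and the centroid
    shift vector of ``target_domain`` are then measured in that frame.
    """
    R, t, ref_rmsd = superpose(state_b, state_a, reference_selection)
    residues = _resolve_selection(target_domain, state_a, state_b)
    ca_a = state_a.ca_coords(residues)
    ca_b = state_b.ca_coords(residues)
    common = ca_a.index.intersection(ca_b.index)
    if len(common) == 0:
        raise SelectionError("target domain has no common Ca atoms")
    A = ca_a.loc[common].to_numpy()
    B = ca_b.loc[common].to_numpy() @ R.T + t
    per_atom = np.linalg.norm(B - A, axis=1)
    centroid_shift = B.mean(axis=0) - A.mean(axis=0)
    return {
        "mean_displacement_A": float(per_atom.mean()),
        "centroid_shift_A": centroid_shift,
        "centroid_shift_norm_A": float(np.linalg.norm(centroid_shift)),
        "n_residues": int(len(common)),
        "reference_rmsd_A": ref_rmsd,
    }


def residue_pair_distance(
    model: StructureModel, res_a: int, res_b: int, mode: str = "min-heavy-atom"
) -> float:
    """Distance between two residues: closest heavy atoms or side-chain centroids."""
    atoms_a = model.residue_atoms(res_a)
    atoms_b = model.residue_atoms(res_b)
    if mode == "min-heavy-atom":
        xa = atoms_a[["x", "y", "z"]].to_numpy()
        xb = atoms_b[["x", "y", "z"]].to_numpy()
        diff = xa[:, None, :] - xb[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2)).min())
    if mode == "centroid":
        side_a = atoms_a[~atoms_a["atom"].isin(_BACKBONE)]
        side_b = atoms_b[~atoms_b["atom"].isin(_BACKBONE)]
        if side_a.empty or side_b.empty:
            raise SelectionError("side-chain atoms absent for centroid mode")
        ca = side_a[["x", "y", "z"]].to_numpy().mean(axis=0)
        cb = side_b[["x", "y", "z"]].to_numpy().mean(axis=0)
        return float(np.linalg.norm(ca - cb))
    raise ValueError(f"unknown mode {mode!r}")


#: default gauge atoms per residue type for the Ca2+-coordination set:
#: carboxylate oxygens of Glu, the amide oxygen of Gln, and the backbone
#: carbonyl oxygen of Thr (which coordinates Ca2+ via its main chain).
_GAUGE_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2"),
                "GLN": ("OE1",), "ASN": ("OD1",), "THR": ("O",)}


def pocket_gauge(
    model: StructureModel,
    residues: dict[int, tuple[str, ...]] | list[int],
) -> dict[str, object]:
    """Planar-polygon proxy for the Ca2+-binding pocket size.

    Gauge atoms (the metal-coordinating oxygens by default) are projected onto
    their best-fit plane; the convex-hull area of the projection is the size
    proxy, returned with the full pairwise-distance table.  This is a
    documented geometric proxy, not a cavity-volume algorithm: it is intended
    for comparing the same site across ligand states.
    """
    if isinstance(residues, dict):
        wanted = residues
    else:
        wanted = {}
        for resnum in residues:
            resname = model.residue_atoms(resnum)["resname"].iloc[0]
            wanted[resnum] = _GAUGE_ATOMS.get(resname, ("CA",))
    points, labels = [], []
    for resnum, atom_names in wanted.items():
        sel = model.residue_atoms(resnum)
        for name in atom_names:
            hit = sel[sel["atom"] == name]
            if hit.empty:
                continue
            points.append(hit[["x", "y", "z"]].to_numpy()[0])
            labels.append(f"{resnum}:{name}")
    if len(points) < 3:
        raise SelectionError(f"only {len(points)} gauge atoms found (need >= 3)")
    X = np.asarray(points)
    centroid = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - centroid)
    projected = (X - centroid) @ Vt[:2].T  # in-plane 2D coordinates
    hull = ConvexHull(projected)
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    table = pd.DataFrame(dist, index=labels, columns=labels)
    return {"area_A2": float(hull.volume), "pairwise_A": table,
            "n_atoms": len(points)}
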