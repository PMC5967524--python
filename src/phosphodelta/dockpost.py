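"""Post-processing of rigid-body docking pose ensembles.

A pose is a two-chain structure (receptor + ligand).  The analyses here are
the standard desk steps downstream of a docking run: least-squares
superposition, filtering poses by a catalytic-geometry distance (ligand
phosphosite proxy to receptor proton donor, within 10 A), interface
fingerprinting (residue pairs with any-atom distance strictly below 5 A),
contact-overlap pose clustering, per-residue interface propensities over the
filtered ensemble, Shrake-Rupley solvent accessibility, and selection of
solvent-accessible restraint residues around a seed patch (relative
accessibility of main- or side-chain atoms >= 15%, within a 10 A radius).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import biotite.structure as bst
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

MAINCHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}


def _load_reference() -> dict:
    with resources.files("phosphodelta.data").joinpath("sasa_reference.json").open() as fh:
        return json.load(fh)


_REF = _load_reference()


@dataclass
class Structure:
    """A light two-chain coordinate container (one docking pose).

    Parallel arrays, one entry per atom.  Radii are assigned per element
    from the configured radius table at read time.
    """

    chains: np.ndarray        # chain id per atom
    res_ids: np.ndarray       # integer residue id per atom
    res_names: np.ndarray     # 3-letter residue name per atom
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray        # (n_atoms, 3) float, Angstrom
    radii: np.ndarray         # (n_atoms,) float, Angstrom
    label: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not np.all(self.radii > 0):
            raise ValueError("atom radii must be positive")

    def __len__(self) -> int:
        return len(self.res_ids)

    def mask(self, chain: str | None = None, atom_names: Iterable[str] | None = None) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chains == chain
        if atom_names is not None:
            m &= np.isin(self.atom_names, list(atom_names))
        return m

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            chains=self.chains[mask],
            res_ids=self.res_ids[mask],
            res_names=self.res_names[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            coords=self.coords[mask],
            radii=self.radii[mask],
            label=self.label,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.subset(np.ones(len(self), dtype=bool))
        out.coords = self.coords @ rotation.T + translation
        return out

    def atom(self, chain: str, res_id: int, atom_name: str) -> np.ndarray | None:
        m = (self.chains == chain) & (self.res_ids == res_id) & (self.atom_names == atom_name)
        idx = np.flatnonzero(m)
        return self.coords[idx[0]] if idx.size else None

    def residue_ids(self, chain: str) -> list[int]:
        ids = self.res_ids[self.chains == chain]
        return sorted(set(int(i) for i in ids))


@dataclass(frozen=True)
class ContactSet:
    """Interface fingerprint: (receptor residue, ligand residue) pairs."""

    contacts: frozenset[tuple[int, int]]
    receptor_residues: frozenset[int] = frozenset()
    ligand_residues: frozenset[int] = frozenset()

    def __len__(self) -> int:
        return len(self.contacts)


def element_radius(element: str, radii: Mapping[str, float] | None = None) -> float:
    radii = radii or _REF["radii"]
    return float(radii.get(element.upper(), radii["default"]))


def read_pose(
    path: str | Path,
    receptor_chain: str,
    ligand_chain: str,
    include_hetatm: bool = False,
) -> Structure:
    """Read one two-chain PDB pose; missing chains are an error."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chains, res_ids, res_names, atom_names, elements, coords = [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for residue in chain:
            if not include_hetatm and residue.het_flag == "H":
                continue
            for atom in residue:
                chains.append(chain.name)
                res_ids.append(residue.seqid.num)
                res_names.append(residue.name)
                atom_names.append(atom.name)
                elements.append(atom.element.name.upper())
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ValueError(f"no ATOM records read from {path}")
    structure = Structure(
        chains=np.array(chains),
        res_ids=np.array(res_ids, dtype=int),
        res_names=np.array(res_names),
        atom_names=np.array(atom_names),
        elements=np.array(elements),
        coords=np.array(coords, dtype=float),
        radii=np.array([element_radius(e) for e in elements], dtype=float),
        label=Path(path).name,
    )
    for required in (receptor_chain, ligand_chain):
        if not np.any(structure.chains == required):
            raise ValueError(f"chain {required!r} missing from {path}")
    return structure


def read_poses(
    paths: Sequence[str | Path], receptor_chain: str, ligand_chain: str
) -> list[Structure]:
    return [read_pose(p, receptor_chain, ligand_chain) for p in paths]


def superpose(
    mobile: Structure,
    reference: Structure,
    chain: str | None = None,
    atom_names: Iterable[str] | None = ("CA",),
) -> tuple[Structure, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    The fit (Kabsch, via SVD with a proper-rotation determinant correction)
    uses the selected atoms, matched by order; the whole mobile structure is
    transformed.  Returns (transformed structure, RMSD over the selection).
    """
    sel_m = mobile.coords[mobile.mask(chain, atom_names)]
    sel_r = reference.coords[reference.mask(chain, atom_names)]
    if len(sel_m) != len(sel_r):
        raise ValueError("selections differ in atom count")
    if len(sel_m) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    cm, cr = sel_m.mean(axis=0), sel_r.mean(axis=0)
    H = (sel_m - cm).T @ (sel_r - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    moved = mobile.transformed(R, t)
    fitted = moved.coords[moved.mask(chain, atom_names)]
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - sel_r) ** 2, axis=1))))
    return moved, rmsd


def center_of_mass(structure: Structure, chain: str) -> np.ndarray:
    """Unweighted mean of the chain's atom coordinates."""
    coords = structure.coords[structure.mask(chain)]
    if len(coords) == 0:
        raise ValueError(f"no atoms in chain {chain!r}")
    return coords.mean(axis=0)


def pose_distance(
    pose: Structure,
    ligand_spec: tuple[str, int, str],
    receptor_spec: tuple[str, int, str],
    fallback_centroid: bool = False,
) -> float:
    """Distance between two specified atoms (chain, residue id, atom name)."""
    points = []
    for chain, res_id, atom_name in (ligand_spec, receptor_spec):
        p = pose.atom(chain, res_id, atom_name)
        if p is None:
            res_mask = (pose.chains == chain) & (pose.res_ids == res_id)
            if fallback_centroid and np.any(res_mask):
                log.warning(
                    "%s: atom %s/%d/%s absent, using residue centroid",
                    pose.label, chain, res_id, atom_name,
                )
                p = pose.coords[res_mask].mean(axis=0)
            else:
                raise ValueError(
                    f"atom {chain}/{res_id}/{atom_name} missing from {pose.label}"
                )
        points.append(p)
    return float(np.linalg.norm(points[0] - points[1]))


def distance_filter(
    poses: Sequence[Structure],
    ligand_spec: tuple[str, int, str],
    receptor_spec: tuple[str, int, str],
    cutoff: float = 10.0,
    fallback_centroid: bool = False,
) -> tuple[list[Structure], np.ndarray]:
    """Keep poses whose spec-atom distance is <= cutoff (inclusive).

    Distances for all poses are returned alongside the kept subset.
    """
    distances = np.array(
        [pose_distance(p, ligand_spec, receptor_spec, fallback_centroid) for p in poses]
    )
    kept = [p for p, d in zip(poses, distances) if d <= cutoff]
    return kept, distances


def interface(
    pose: Structure,
    receptor_chain: str,
    ligand_chain: str,
    cutoff: float = 5.0,
) -> ContactSet:
    """Residue-residue contacts with any-atom distance strictly below cutoff."""
    rec = pose.subset(pose.mask(receptor_chain))
    lig = pose.subset(pose.mask(ligand_chain))
    if len(rec) == 0 or len(lig) == 0:
        raise ValueError("both chains must contain atoms")
    tree = cKDTree(lig.coords)
    pairs: set[tuple[int, int]] = set()
    neighbour_lists = tree.query_ball_point(rec.coords, r=cutoff)
    for i, neighbours in enumerate(neighbour_lists):
        for j in neighbours:
            if np.linalg.norm(rec.coords[i] - lig.coords[j]) < cutoff:
                pairs.add((int(rec.res_ids[i]), int(lig.res_ids[j])))
    return ContactSet(
        contacts=frozenset(pairs),
        receptor_residues=frozenset(r for r, _ in pairs),
        ligand_residues=frozenset(l for _, l in pairs),
    )


def contact_similarity(a: ContactSet, b: ContactSet) -> float:
    """Symmetrized fraction of common contacts, min(|a&b|/|a|, |a&b|/|b|).

    Two empty fingerprints are identical (1); empty versus non-empty is 0.
    """
    if len(a) == 0 and len(b) == 0:
        return 1.0
    if len(a) == 0 or len(b) == 0:
        return 0.0
    common = len(a.contacts & b.contacts)
    return min(common / len(a), common / len(b))


def cluster_poses(
    contact_sets: Sequence[ContactSet],
    similarity_threshold: float = 0.75,
    min_cluster_size: int = 1,
) -> np.ndarray:
    """Leader-style clustering on contact-set similarity.

    Repeatedly select the unassigned pose with the most unassigned
    neighbours (similarity >= threshold; ties broken by lowest pose index)
    and form a cluster from it and those neighbours.  Every pose ends up in
    exactly one cluster; clusters smaller than ``min_cluster_size`` are
    labelled as singleton clusters of their own.  Deterministic for a given
    input order.
    """
    if len(contact_sets) == 0:
        raise ValueError("no poses to cluster")
    n = len(contact_sets)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = contact_similarity(contact_sets[i], contact_sets[j])
    labels = np.full(n, -1, dtype=int)
    next_label = 0
    unassigned = set(range(n))
    while unassigned:
        best, best_size = None, -1
        for i in sorted(unassigned):
            size = sum(1 for j in unassigned if sim[i, j] >= similarity_threshold)
            if size > best_size:
                best, best_size = i, size
        members = [j for j in sorted(unassigned) if sim[best, j] >= similarity_threshold]
        if len(members) < min_cluster_size:
            members = [best]
        for j in members:
            labels[j] = next_label
        next_label += 1
        unassigned.difference_update(members)
    return labels


def propensity(
    interface_residue_sets: Sequence[Iterable[int]],
    residues: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per-residue interface propensities over a pose ensemble.

    ``count`` is the number of poses where the residue is in the interface,
    ``frequency`` = count / ensemble size, and ``propensity`` =
    log2((count + 1) / (N * fbar + 1)) with fbar the mean frequency over
    residues observed in at least one interface -- a pseudocount-smoothed
    log2 enrichment over the ensemble-average interface residue.  The raw
    log2 frequency is emitted alongside.
    """
    sets = [set(int(r) for r in s) for s in interface_residue_sets]
    n = len(sets)
    if n == 0:
        raise ValueError("empty ensemble")
    universe = sorted(set(residues) if residues is not None else set().union(*sets))
    counts = {r: sum(1 for s in sets if r in s) for r in universe}
    observed = [c for c in counts.values() if c > 0]
    fbar = (sum(observed) / len(observed) / n) if observed else 0.0
    rows = []
    for r in universe:
        c = counts[r]
        freq = c / n
        rows.append(
            {
                "residue": r,
                "count": c,
                "frequency": freq,
                "propensity": math.log2((c + 1) / (n * fbar + 1)),
                "log2_frequency": math.log2(freq) if freq > 0 else -math.inf,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SASAResult:
    """Per-residue absolute and relative solvent accessibilities."""

    table: pd.DataFrame  # chain, res_id, res_name, sasa, rel_total, rel_main, rel_side
    atom_areas: np.ndarray

    def residue(self, chain: str, res_id: int) -> pd.Series:
        t = self.table
        row = t[(t["chain"] == chain) & (t["res_id"] == res_id)]
        if row.empty:
            raise KeyError((chain, res_id))
        return row.iloc[0]


def sasa(structure: Structure, probe: float = 1.4, n_points: int = 960) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area.

    The sphere-point evaluation is delegated to biotite with this package's
    radius table; per-atom areas are summed per residue and normalized by
    per-residue-type reference maxima (main-chain and side-chain relative
    accessibilities use the backbone reference and its complement).
    """
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    n = len(structure)
    arr = bst.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = structure.chains.astype("U4")
    arr.res_id = structure.res_ids
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = structure.elements.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    areas = bst.sasa(
        arr,
        probe_radius=probe,
        point_number=n_points,
        vdw_radii=structure.radii.astype(np.float64),
    )
    areas = np.nan_to_num(np.asarray(areas, dtype=float))

    max_total = _REF["max_sasa_total"]
    main_ref = float(_REF["max_sasa_mainchain"])
    side_floor = float(_REF["min_sidechain_reference"])
    rows = []
    keys = list(zip(structure.chains, structure.res_ids))
    seen = []
    for key in keys:
        if key not in seen:
            seen.append(key)
    for chain, res_id in seen:
        m = (structure.chains == chain) & (structure.res_ids == res_id)
        res_name = str(structure.res_names[m][0])
        total_ref = float(max_total.get(res_name, max_total["default"]))
        main_mask = m & np.isin(structure.atom_names, list(MAINCHAIN_ATOMS))
        side_mask = m & ~np.isin(structure.atom_names, list(MAINCHAIN_ATOMS))
        abs_total = float(areas[m].sum())
        abs_main = float(areas[main_mask].sum())
        abs_side = float(areas[side_mask].sum())
        side_ref = max(total_ref - main_ref, side_floor)
        rows.append(
            {
                "chain": chain,
                "res_id": int(res_id),
                "res_name": res_name,
                "sasa": abs_total,
                "rel_total": abs_total / total_ref,
                "rel_main": abs_main / main_ref,
                "rel_side": abs_side / side_ref if side_mask.any() else 0.0,
            }
        )
    return SASAResult(table=pd.DataFrame(rows), atom_areas=areas)


def restraint_selection(
    structure: Structure,
    chain: str,
    seed_residues: Sequence[int],
    radius: float = 10.0,
    min_rel_sasa: float = 0.15,
    probe: float = 1.4,
    n_points: int = 960,
    sasa_result: SASAResult | None = None,
) -> list[int]:
    """Solvent-accessible residues within a radius of a seed patch.

    A residue is selected when (a) any of its atoms is within ``radius`` of
    any atom of a seed residue, and (b) the relative accessibility of its
    main-chain or side-chain atoms is at least ``min_rel_sasa``.
    """
    if len(seed_residues) == 0:
        raise ValueError("empty seed residue set")
    result = sasa_result or sasa(structure, probe=probe, n_points=n_points)
    chain_mask = structure.mask(chain)
    seed_mask = chain_mask & np.isin(structure.res_ids, list(seed_residues))
    if not seed_mask.any():
        raise ValueError("seed residues not present in structure")
    tree = cKDTree(structure.coords[seed_mask])
    selected = []
    for res_id in structure.residue_ids(chain):
        res_mask = chain_mask & (structure.res_ids == res_id)
        dmin = tree.query(structure.coords[res_mask])[0].min()
        if dmin > radius:
            continue
        row = result.residue(chain, res_id)
        if row["rel_main"] >= min_rel_sasa or row["rel_side"] >= min_rel_sasa:
            selected.append(res_id)
    return selected


def write_pose_pdb(structure: Structure, path: str | Path) -> None:
    """Write a pose as minimal PDB ATOM records."""
    with open(path, "w") as fh:
        serial = 1
        for i in range(len(structure)):
            name = structure.atom_names[i]
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = structure.coords[i]
            fh.write(
                f"ATOM  {serial:5d} {pad_name:<4s} {structure.res_names[i]:<3s} "
                f"{structure.chains[i]:1s}{structure.res_ids[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{structure.elements[i]:>2s}\n"
            )
            serial += 1
        fh.write("END\n")
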