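"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study design: a wild-type (heavy) versus
phosphatase-deletion (light) SILAC comparison quantified by three
phosphopeptide enrichment methods.  A yeast-like random proteome is
digested into tryptic peptides; a configured fraction of phosphopeptides is
planted as hyperphosphorylated-in-mutant (negative log2 H/L effect), each
method's observation is the true effect plus Gaussian log2 noise, and
methods drop out independently.  Planted sequence motifs, enriched
annotation terms, interaction hubs and toy docking-pose ensembles with known
interfaces give every downstream stage a recoverable truth.

Random streams are drawn per output family from a master seed, so e.g.
adding peptides does not perturb pose generation, and regeneration with the
same seed is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dockpost import Structure, element_radius, write_pose_pdb
from .io import (
    METHODS,
    AbundanceMeasurement,
    PhosphopeptideMeasurement,
    ProteinSequenceRecord,
    ProteinSite,
    write_fasta,
    write_quant_table,
)

# Approximate S. cerevisiae proteome residue frequencies.
YEAST_COMPOSITION = {
    "A": 0.055, "C": 0.013, "D": 0.058, "E": 0.065, "F": 0.045,
    "G": 0.050, "H": 0.022, "I": 0.066, "K": 0.073, "L": 0.096,
    "M": 0.021, "N": 0.061, "P": 0.044, "Q": 0.039, "R": 0.044,
    "S": 0.089, "T": 0.059, "V": 0.056, "W": 0.010, "Y": 0.034,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the study-condition defaults.

    ``method_dropout`` defaults to zero for every method: the reference
    recovery conditions are peptides quantified in all three methods
    (dropout is exercised explicitly where a test needs it).
    """

    seed: int = 0
    n_proteins: int = 200
    protein_length_range: tuple[int, int] = (250, 550)
    n_phosphopeptides: int = 500
    fraction_hyper: float = 0.10
    effect_log2_mean: float = -1.0
    effect_log2_sd: float = 0.0
    noise_log2_sd: float = 0.2
    method_dropout: dict[str, float] = field(
        default_factory=lambda: {m: 0.0 for m in METHODS}
    )
    planted_motif: tuple[int, str, float] = (1, "P", 0.4)
    fraction_abundance_reduced: float = 0.158
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    planted_term_fg_prob: float = 0.6
    planted_term_bg_prob: float = 0.05
    n_random_edges: int = 40
    hub_degree: int = 10
    n_poses: int = 30
    n_pose_families: int = 3
    fraction_near_site: float = 0.3
    pose_jitter: float = 0.1

    def __post_init__(self) -> None:
        for name in ("fraction_hyper", "fraction_abundance_reduced", "fraction_near_site"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for m, p in self.method_dropout.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout probability for {m} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("protein_length_range", "term_size_range", "planted_motif"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named random streams derived from the master seed."""
    names = ("proteome", "peptides", "ratios", "dropout", "annotation", "poses")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Proteome and peptides


def gen_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (250, 550),
    rng: np.random.Generator | None = None,
    composition: Mapping[str, float] | None = None,
    accession_prefix: str = "SYN",
) -> dict[str, ProteinSequenceRecord]:
    """I.i.d. random proteome with yeast-like residue composition."""
    rng = rng if rng is not None else np.random.default_rng(0)
    comp = composition or YEAST_COMPOSITION
    letters = np.array(list(comp.keys()))
    probs = np.array(list(comp.values()), dtype=float)
    probs = probs / probs.sum()
    proteins: dict[str, ProteinSequenceRecord] = {}
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        acc = f"{accession_prefix}{i + 1:05d}"
        proteins[acc] = ProteinSequenceRecord(accession=acc, sequence=seq)
    return proteins


def tryptic_peptides(
    sequence: str, min_len: int = 7, max_len: int = 35
) -> list[tuple[int, str]]:
    """(0-based offset, peptide) fragments: cleave after K/R, not before P."""
    cut_points = [0]
    for i, ch in enumerate(sequence[:-1]):
        if ch in "KR" and sequence[i + 1] != "P":
            cut_points.append(i + 1)
    cut_points.append(len(sequence))
    out = []
    for a, b in zip(cut_points, cut_points[1:]):
        if min_len <= b - a <= max_len:
            out.append((a, sequence[a:b]))
    return out


@dataclass
class SimPeptide:
    protein_acc: str
    offset: int              # 0-based within protein
    sequence: str
    site_positions: list[int]  # 1-based within peptide
    site_residues: list[str]
    is_hyper: bool
    true_log2: float
    observed: dict[str, float] = field(default_factory=dict)  # method -> log2
    motif_planted: list[bool] = field(default_factory=list)   # per site

    @property
    def peptide_id(self) -> str:
        sites = ",".join(str(p) for p in sorted(self.site_positions))
        return f"{self.sequence.upper()}|{sites}"


@dataclass
class Experiment:
    """A generated three-method SILAC phosphoproteomics experiment."""

    config: SimulationConfig
    proteome: dict[str, ProteinSequenceRecord]
    peptides: list[SimPeptide]
    records: list[PhosphopeptideMeasurement]
    abundance: list[AbundanceMeasurement]
    reduced_proteins: set[str]

    @property
    def truth_hyper_ids(self) -> set[str]:
        return {p.peptide_id for p in self.peptides if p.is_hyper}

    @property
    def truth_hyper_proteins(self) -> set[str]:
        return {p.protein_acc for p in self.peptides if p.is_hyper}

    def planted_sites(self) -> list[ProteinSite]:
        """Protein-coordinate sites of planted hyper peptides."""
        out = []
        for p in self.peptides:
            if not p.is_hyper:
                continue
            for pos, res in zip(p.site_positions, p.site_residues):
                out.append(
                    ProteinSite(
                        protein_acc=p.protein_acc, position=p.offset + pos, residue=res
                    )
                )
        return out

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide_id": [p.peptide_id for p in self.peptides],
                "protein": [p.protein_acc for p in self.peptides],
                "is_hyper": [p.is_hyper for p in self.peptides],
                "true_log2": [p.true_log2 for p in self.peptides],
                "n_methods": [len(p.observed) for p in self.peptides],
            }
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteome, outdir / "proteome.fasta")
        for method in METHODS:
            write_quant_table(
                [m for m in self.records if m.method == method],
                outdir / f"quant_{method.lower()}.tsv",
            )
        pd.DataFrame(
            {
                "peptide": [a.peptide_id for a in self.abundance],
                "protein": [a.protein_acc for a in self.abundance],
                "hl_ratio": [repr(a.hl_ratio) for a in self.abundance],
            }
        ).to_csv(outdir / "abundance.tsv", sep="\t", index=False)
        self.truth_table().to_csv(outdir / "truth_peptides.tsv", sep="\t", index=False)


def gen_phospho_experiment(
    config: SimulationConfig,
    proteome: dict[str, ProteinSequenceRecord] | None = None,
) -> Experiment:
    """Three-method quantification tables + abundance table + ground truth.

    Hyperphosphorylated peptides are planted with a negative log2 H/L effect
    (wild type heavy, mutant light); per-method observations add Gaussian
    log2 noise; the planted motif (+1 proline by default) is written into an
    exact fraction of the hyper serine sites, and residual background
    prolines at the planted offset of eligible hyper S sites are mutated
    away so the planted foreground fraction is exact.
    """
    streams = _streams(config.seed)
    if proteome is None:
        proteome = gen_proteome(
            config.n_proteins, config.protein_length_range, rng=streams["proteome"]
        )
    sequences = {acc: rec.sequence for acc, rec in proteome.items()}

    rng = streams["peptides"]
    candidates: list[tuple[str, int, str]] = []
    seen_seqs: set[str] = set()
    for acc in sequences:
        for off, pep in tryptic_peptides(sequences[acc]):
            if pep in seen_seqs or not any(c in "ST" for c in pep):
                continue
            seen_seqs.add(pep)
            candidates.append((acc, off, pep))
    if len(candidates) < config.n_phosphopeptides:
        raise ValueError(
            f"proteome yields only {len(candidates)} usable peptides; "
            f"{config.n_phosphopeptides} requested"
        )
    chosen_idx = rng.choice(len(candidates), size=config.n_phosphopeptides, replace=False)
    n_hyper = round(config.fraction_hyper * config.n_phosphopeptides)
    hyper_flags = np.zeros(config.n_phosphopeptides, dtype=bool)
    hyper_flags[rng.choice(config.n_phosphopeptides, size=n_hyper, replace=False)] = True

    peptides: list[SimPeptide] = []
    rng_ratio = streams["ratios"]
    for flag, idx in zip(hyper_flags, chosen_idx):
        acc, off, pep = candidates[idx]
        st_positions = [i + 1 for i, c in enumerate(pep) if c in "ST"]
        n_sites = 1 if len(st_positions) == 1 or rng.random() < 0.8 else 2
        positions = sorted(
            int(p) for p in rng.choice(st_positions, size=n_sites, replace=False)
        )
        true_log2 = 0.0
        if flag:
            true_log2 = config.effect_log2_mean + (
                rng_ratio.normal(0.0, config.effect_log2_sd)
                if config.effect_log2_sd > 0
                else 0.0
            )
        peptides.append(
            SimPeptide(
                protein_acc=acc,
                offset=off,
                sequence=pep,
                site_positions=positions,
                site_residues=[pep[p - 1] for p in positions],
                is_hyper=bool(flag),
                true_log2=true_log2,
            )
        )

    _plant_motif(peptides, sequences, config, rng)
    proteome = {
        acc: ProteinSequenceRecord(accession=acc, sequence=sequences[acc])
        for acc in sequences
    }

    # Per-method observations with dropout.
    rng_drop = streams["dropout"]
    records: list[PhosphopeptideMeasurement] = []
    for p in peptides:
        kept = [
            m for m in METHODS if rng_drop.random() >= config.method_dropout.get(m, 0.0)
        ]
        if not kept:
            kept = [METHODS[int(rng_drop.integers(len(METHODS)))]]
        for m in kept:
            log2 = p.true_log2 + rng_ratio.normal(0.0, config.noise_log2_sd)
            p.observed[m] = log2
            records.append(
                PhosphopeptideMeasurement(
                    sequence=p.sequence,
                    method=m,
                    hl_ratio=2.0**log2,
                    log2_ratio=log2,
                    site_positions=list(p.site_positions),
                    site_residues=list(p.site_residues),
                    localization_probs=[
                        float(rng_ratio.uniform(0.9, 1.0)) for _ in p.site_positions
                    ],
                    protein_acc=p.protein_acc,
                    q_value=float(rng_ratio.uniform(0.0005, 0.009)),
                )
            )

    # Non-enriched abundance table: a configured fraction of proteins reduced.
    accs = sorted(sequences)
    n_reduced = round(config.fraction_abundance_reduced * len(accs))
    reduced = set(
        np.array(accs)[rng_ratio.choice(len(accs), size=n_reduced, replace=False)]
    )
    abundance = []
    for acc in accs:
        base = -0.737 if acc in reduced else 0.0  # log2(0.6) vs log2(1.0)
        for j in range(2):
            hl = 2.0 ** (base + rng_ratio.normal(0.0, 0.05))
            abundance.append(
                AbundanceMeasurement(
                    peptide_id=f"{acc}_np{j}", protein_acc=acc, hl_ratio=hl
                )
            )
    return Experiment(
        config=config,
        proteome=proteome,
        peptides=peptides,
        records=records,
        abundance=abundance,
        reduced_proteins=reduced,
    )


def _plant_motif(
    peptides: list[SimPeptide],
    sequences: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Write the planted motif into an exact fraction of hyper serine sites."""
    offset, residue, fraction = config.planted_motif
    if fraction <= 0:
        for p in peptides:
            p.motif_planted = [False] * len(p.site_positions)
        return
    eligible: list[tuple[SimPeptide, int]] = []  # (peptide, site index)
    for p in peptides:
        p.motif_planted = [False] * len(p.site_positions)
        if not p.is_hyper:
            continue
        for si, (pos, res) in enumerate(zip(p.site_positions, p.site_residues)):
            target = pos + offset
            if res != "S" or not 1 <= target <= len(p.sequence):
                continue
            if target in p.site_positions:
                continue  # never overwrite another phosphosite
            eligible.append((p, si))
    if not eligible:
        return
    n_plant = round(fraction * len(eligible))
    order = rng.permutation(len(eligible))
    planted = set(order[:n_plant].tolist())
    for rank, ei in enumerate(order.tolist()):
        p, si = eligible[ei]
        target = p.site_positions[si] + offset  # 1-based within peptide
        new_char = residue if rank < n_plant else None
        cur = p.sequence[target - 1]
        if new_char is None:
            new_char = "A" if cur == residue else cur  # de-plant residual matches
        if new_char == cur:
            if ei in planted:
                p.motif_planted[si] = True
            continue
        seq = sequences[p.protein_acc]
        abs_pos = p.offset + target - 1  # 0-based in protein
        sequences[p.protein_acc] = seq[:abs_pos] + new_char + seq[abs_pos + 1 :]
        p.sequence = p.sequence[: target - 1] + new_char + p.sequence[target:]
        if ei in planted:
            p.motif_planted[si] = True


# ---------------------------------------------------------------------------
# Annotations and interaction edges


@dataclass
class AnnotationTruth:
    planted_term: str
    hub_node: str
    hub_degree: int


def gen_annotation_and_edges(
    universe: Sequence[str],
    fg_genes: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, set[str]], list[tuple[str, str]], AnnotationTruth]:
    """Random term annotation with one planted enriched term, plus an edge
    list with one planted hub."""
    rng = rng if rng is not None else _streams(config.seed)["annotation"]
    universe = sorted({g.upper() for g in universe})
    fg = sorted({g.upper() for g in fg_genes})
    non_fg = [g for g in universe if g not in set(fg)]

    annotations: dict[str, set[str]] = {}
    lo, hi = config.term_size_range
    for i in range(config.n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        annotations[f"TERM{i + 1:04d}"] = set(members.tolist())
    planted = "TERM_PLANTED"
    members = {g for g in fg if rng.random() < config.planted_term_fg_prob}
    members |= {g for g in non_fg if rng.random() < config.planted_term_bg_prob}
    annotations[planted] = members
    # every gene annotated at least once, so the default background is the universe
    annotations["TERM_ROOT"] = set(universe)

    hub = fg[0] if fg else universe[0]
    partners = [g for g in universe if g != hub]
    neighbours = rng.choice(partners, size=min(config.hub_degree, len(partners)), replace=False)
    edges = [(hub, str(n)) for n in neighbours]
    for _ in range(config.n_random_edges):
        a, b = rng.choice(universe, size=2, replace=False)
        if hub in (a, b):
            continue
        edges.append((str(a), str(b)))
    return annotations, edges, AnnotationTruth(
        planted_term=planted, hub_node=hub, hub_degree=len(neighbours)
    )


# ---------------------------------------------------------------------------
# Toy docking poses


@dataclass
class PoseTruth:
    families: list[int]             # per pose
    near_site: list[bool]           # per pose
    catalytic_residue: int
    phosphosite_residue: int
    family_receptor_residues: dict[int, set[int]]  # planted interface per family


def _ring_receptor(n_res: int = 24, radius: float = 15.0) -> Structure:
    """Receptor: a ring of CA pseudo-residues in the z = 0 plane."""
    angles = np.linspace(0.0, 2 * math.pi, n_res, endpoint=False)
    coords = np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n_res)], axis=1
    )
    return Structure(
        chains=np.array(["A"] * n_res),
        res_ids=np.arange(1, n_res + 1),
        res_names=np.array(["GLY"] * n_res),
        atom_names=np.array(["CA"] * n_res),
        elements=np.array(["C"] * n_res),
        coords=coords,
        radii=np.full(n_res, element_radius("C")),
    )


def _ligand_template(n_res: int = 6, spacing: float = 2.0) -> np.ndarray:
    """Ligand template: atoms along +x, residue 1 at the origin."""
    return np.stack(
        [np.arange(n_res) * spacing, np.zeros(n_res), np.zeros(n_res)], axis=1
    )


def gen_poses(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Structure], PoseTruth]:
    """Toy pose ensemble around a ring receptor with known interfaces.

    Family 0 places the ligand's phosphosite-proxy residue ~4.2 A outside
    the catalytic residue (well within the 10 A catalytic filter and the
    5 A contact cutoff); the other families sit at distant ring positions.
    Per-pose jitter is a small random translation that cannot flip either
    cutoff at its default scale.
    """
    rng = rng if rng is not None else _streams(config.seed)["poses"]
    n_rec, ring_radius, approach = 24, 15.0, 4.2
    receptor = _ring_receptor(n_rec, ring_radius)
    template = _ligand_template()
    n_lig = len(template)

    n_families = max(1, config.n_pose_families)
    family_angles = [2 * math.pi * f / n_families for f in range(n_families)]
    n_near = round(config.fraction_near_site * config.n_poses)
    families, near_flags = [], []
    far_cycle = 0
    for i in range(config.n_poses):
        if i < n_near:
            families.append(0)
            near_flags.append(True)
        else:
            fam = 1 + far_cycle % max(1, n_families - 1) if n_families > 1 else 0
            far_cycle += 1
            families.append(fam)
            near_flags.append(n_families == 1)

    # Receptor residue nearest each family anchor angle is the planted contact.
    rec_angles = np.linspace(0.0, 2 * math.pi, n_rec, endpoint=False)
    family_contacts: dict[int, set[int]] = {}
    poses: list[Structure] = []
    for i, fam in enumerate(families):
        theta = family_angles[fam]
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        anchor = np.array(
            [(ring_radius + approach) * c, (ring_radius + approach) * s, 0.0]
        )
        jitter = rng.normal(0.0, config.pose_jitter, size=3) if config.pose_jitter > 0 else 0.0
        lig_coords = template @ rot.T + anchor + jitter
        nearest = int(np.argmin(np.abs((rec_angles - theta + math.pi) % (2 * math.pi) - math.pi)))
        family_contacts.setdefault(fam, set()).add(nearest + 1)
        atoms = Structure(
            chains=np.array(["A"] * n_rec + ["B"] * n_lig),
            res_ids=np.concatenate([receptor.res_ids, np.arange(1, n_lig + 1)]),
            res_names=np.array(["GLY"] * (n_rec + n_lig)),
            atom_names=np.array(["CA"] * (n_rec + n_lig)),
            elements=np.array(["C"] * (n_rec + n_lig)),
            coords=np.vstack([receptor.coords, lig_coords]),
            radii=np.full(n_rec + n_lig, element_radius("C")),
            label=f"pose_{i:04d}.pdb",
        )
        poses.append(atoms)
    return poses, PoseTruth(
        families=families,
        near_site=near_flags,
        catalytic_residue=1,
        phosphosite_residue=1,
        family_receptor_residues=family_contacts,
    )


def write_poses(poses: Sequence[Structure], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in poses:
        path = outdir / (p.label or "pose.pdb")
        write_pose_pdb(p, path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Study-scale synthetic stand-ins
#
# The deposited supplementary peptide tables of the source study are not
# shipped here; the two generators below construct synthetic stand-ins whose
# ground truth is planted to the study's printed marginal counts, so the
# pipeline's filter cascade, classification, significance testing and motif
# analysis can be exercised at study scale and checked against a known truth.


_FILLER = "ACDEFGHIKLMNQRVWY"  # no P, S or T: keeps planted patterns exact


def _filler(length: int, phase: int) -> str:
    return "".join(_FILLER[(phase + i) % len(_FILLER)] for i in range(length))


@dataclass
class SignificantSetStandin:
    """Synthetic stand-in for the significant-peptide set.

    62 peptides carrying 76 phosphosites: 65 serine (33 with +1 proline) and
    11 threonine (6 with +1 proline), embedded in synthetic host proteins,
    plus a background proteome for motif extraction.
    """

    records: list[PhosphopeptideMeasurement]
    proteins: dict[str, ProteinSequenceRecord]
    background: dict[str, ProteinSequenceRecord]


def gen_significant_set_standin(seed: int = 0) -> SignificantSetStandin:
    # site plan: residue and +1-proline flag for each of the 76 sites
    site_plan = (
        [("S", True)] * 33 + [("S", False)] * 32 + [("T", True)] * 6 + [("T", False)] * 5
    )
    # peptide plan: 14 peptides x 2 sites + 48 x 1 site = 76
    pep_sites = [2] * 14 + [1] * 48
    assert sum(pep_sites) == len(site_plan) == 76

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    records: list[PhosphopeptideMeasurement] = []
    proteins: dict[str, ProteinSequenceRecord] = {}
    site_iter = iter(enumerate(site_plan))
    for pi, n_sites in enumerate(pep_sites):
        pep_len = 21
        # two-site peptides keep their sites > 6 apart so neither site (nor its
        # planted +1 residue) falls inside the other's 13-wide window
        positions = [4, 17] if n_sites == 2 else [11]
        chars = list(_filler(pep_len, phase=(pi * 5) % len(_FILLER)))
        residues = []
        for pos in positions:
            si, (res, plant_p) = next(site_iter)
            chars[pos - 1] = res
            residues.append(res)
            if plant_p:
                chars[pos] = "P"
        pep = "".join(chars)
        acc = f"STD{pi + 1:04d}"
        flank_l = _filler(20, phase=(pi * 7 + 3) % len(_FILLER))
        flank_r = _filler(20, phase=(pi * 11 + 6) % len(_FILLER))
        protein_seq = flank_l + pep + flank_r
        assert protein_seq.find(pep) == 20
        proteins[acc] = ProteinSequenceRecord(accession=acc, sequence=protein_seq)
        log2 = -1.0 + float(rng.normal(0.0, 0.05))
        records.append(
            PhosphopeptideMeasurement(
                sequence=pep,
                method="TiSH",
                hl_ratio=2.0**log2,
                log2_ratio=log2,
                site_positions=positions,
                site_residues=residues,
                localization_probs=[0.99] * n_sites,
                protein_acc=acc,
                q_value=0.005,
            )
        )
    background = gen_proteome(
        400,
        (250, 550),
        rng=np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1]),
        accession_prefix="BG",
    )
    return SignificantSetStandin(records=records, proteins=proteins, background=background)


@dataclass
class CascadeStandin:
    """Synthetic stand-in for the full quantified phosphopeptide list.

    4,467 phosphopeptides with planted classes: 1,260 hyperphosphorylated
    (mean H/L < 0.75) across exactly 628 proteins, of which 62 are planted
    as three-method statistically significant; 27 significant
    hypophosphorylated; the rest unchanged or mildly shifted.  Margins are
    wide relative to the observation jitter, so a correct pipeline recovers
    the planted counts exactly.
    """

    records: list[PhosphopeptideMeasurement]
    n_hyper: int = 1260
    n_hyper_proteins: int = 628
    n_sig_hyper: int = 62
    n_sig_hypo: int = 27


def _standin_measurement(
    index: int, acc: str, method: str, log2: float
) -> PhosphopeptideMeasurement:
    # unique 12-mer carrying the peptide index in filler letters, S at pos 6
    suffix = []
    v = index
    for _ in range(5):
        suffix.append(_FILLER[v % len(_FILLER)])
        v //= len(_FILLER)
    pep = "AGL" + "".join(suffix) + "S" + "VEK"
    return PhosphopeptideMeasurement(
        sequence=pep,
        method=method,
        hl_ratio=2.0**log2,
        log2_ratio=log2,
        site_positions=[9],
        site_residues=["S"],
        localization_probs=[0.99],
        protein_acc=acc,
        q_value=0.005,
    )


def gen_cascade_standin(seed: int = 0) -> CascadeStandin:
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    jit = lambda: float(rng.normal(0.0, 0.03))

    # peptide group -> (count, per-method base log2 ratios)
    hyper_groups = [
        (62, (-1.0, -1.0, -1.0)),          # significant hyper, 3 methods
        (198, (-0.5, -0.9, -1.6)),         # hyper, 3 methods, inconsistent
        (300, (-0.6, -1.2)),               # hyper, 2 methods
        (700, (-0.9,)),                    # hyper, single method
    ]
    assert sum(c for c, _ in hyper_groups) == 1260
    hyper_proteins = [f"HP{i + 1:04d}" for i in range(628)]

    records: list[PhosphopeptideMeasurement] = []
    index = 0
    protein_of: list[str] = []
    # 62 significant peptides on the first 55 proteins (7 carry two peptides)
    for i in range(62):
        protein_of.append(hyper_proteins[i if i < 55 else i - 55])
    # remaining 1,198 hyper: one peptide each on proteins 56..628, rest cycled
    rest = list(range(55, 628)) + [i % 628 for i in range(1260 - 62 - 573)]
    protein_of.extend(hyper_proteins[i] for i in rest)
    assert len(protein_of) == 1260
    assert len({p for p in protein_of}) == 628

    pi = 0
    for count, bases in hyper_groups:
        for _ in range(count):
            methods = list(METHODS[: len(bases)])
            if len(bases) < 3:  # rotate partial-method assignments
                start = index % 3
                methods = [METHODS[(start + k) % 3] for k in range(len(bases))]
            for m, b in zip(methods, bases):
                records.append(_standin_measurement(index, protein_of[pi], m, b + jit()))
            index += 1
            pi += 1

    other_groups = [
        (27, (0.7, 0.7, 0.7), "XP"),       # significant hypo, 3 methods
        (60, (0.35, 0.85), "XP"),          # hypo-shifted but not significant
        (1200, (0.0,), "NP"),              # null single method
        (960, (0.0, 0.0), "NP"),           # null 2 methods
        (960, (0.0, 0.0, 0.0), "NP"),      # null 3 methods
    ]
    assert 1260 + sum(c for c, _, _ in other_groups) == 4467
    for count, bases, prefix in other_groups:
        for j in range(count):
            acc = f"{prefix}{(index % 800) + 1:04d}"
            methods = list(METHODS[: len(bases)])
            if len(bases) < 3:
                start = index % 3
                methods = [METHODS[(start + k) % 3] for k in range(len(bases))]
            for m, b in zip(methods, bases):
                records.append(_standin_measurement(index, acc, m, b + jit()))
            index += 1
    return CascadeStandin(records=records)
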