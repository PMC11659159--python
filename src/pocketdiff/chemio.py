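"""Structure I/O, pocket extraction, dataset curation, postprocessing of
generated point clouds into RDKit molecules, and evaluation metrics.

Formats: PDB in (BioPython), SDF in/out (RDKit), CSV for tabular output.
Bond perception uses OpenBabel when importable and otherwise falls back to a
covalent-radius criterion (bond iff distance <= 1.25 x sum of radii), with
valence-aware trimming of the longest excess bonds.
"""

from __future__ import annotations

import logging
import os
import sys
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molsys import AMINO_ACIDS, LIGAND_ALPHABET, AtomPointCloud, featurize_pocket

logger = logging.getLogger(__name__)

__all__ = [
    "CurationRules",
    "CurationEntry",
    "MetricsReport",
    "PostprocessResult",
    "read_pdb_structure",
    "extract_pocket",
    "read_sdf",
    "write_sdf",
    "cloud_to_mol",
    "mol_to_cloud",
    "postprocess",
    "curate",
    "compute_metrics",
]

# covalent radii (Angstrom), Cordero et al. values for the ligand alphabet
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "B": 0.84,
    "Br": 1.20, "Cl": 1.02, "P": 1.07, "I": 1.39, "F": 0.57,
}
_RADIUS_TOLERANCE = 1.25

# maximum bond counts used to trim implausible perception results
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 6, "B": 3, "P": 5,
                "F": 1, "Cl": 1, "Br": 1, "I": 1, "H": 1}


@dataclass(frozen=True)
class CurationRules:
    min_qed: float = 0.3
    allowed_elements: frozenset = frozenset(LIGAND_ALPHABET)
    max_per_ccd: int = 50
    pocket_radius: float = 8.0
    require_standard_aa: bool = True

    def __post_init__(self):
        if self.pocket_radius <= 0:
            raise ValueError("pocket radius must be positive")
        if self.max_per_ccd < 1:
            raise ValueError("max_per_ccd must be >= 1")


@dataclass
class CurationEntry:
    """One (protein, ligand) record offered to the curation filter."""

    ligand: object  # rdkit Mol
    ccd: str = "LIG"
    protein_residues: tuple[str, ...] = ()  # residue names, may be empty
    db_valid: bool = True  # pass-through flag for external validity criteria
    entry_id: str = ""


@dataclass
class MetricsReport:
    per_molecule: pd.DataFrame  # columns: qed, sa, logp, lipinski, target
    diversity: dict  # target -> mean pairwise (1 - Tanimoto), NaN if undefined
    n_failed: int = 0


@dataclass
class PostprocessResult:
    ok: bool
    mol: object = None
    stage: str = ""  # failure stage tag when not ok
    n_atoms_in: int = 0
    n_atoms_kept: int = 0


# ---------------------------------------------------------------------------
# PDB / pocket
# ---------------------------------------------------------------------------

def read_pdb_structure(path):
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PDBParser(QUIET=True).get_structure("s", str(path))


def _protein_residues(structure):
    """Standard-ordered (chain, resseq, residue) triples, hetero records skipped."""
    out = []
    for model in structure:
        for chain in model:
            for res in chain:
                if res.id[0] != " ":
                    continue
                out.append((chain.id, res.id[1], res))
        break  # first model only
    out.sort(key=lambda r: (r[0], r[1]))
    return out


def extract_pocket(structure, ligand_coords, radius: float = 8.0,
                   mode: str = "c_alpha"):
    """Keep every residue with at least one heavy atom within ``radius`` of any
    ligand atom. Returns ``(residue_keys, cloud)`` where ``residue_keys`` are
    ``(chain, resseq, resname)`` triples in deterministic order; ``cloud`` is
    the featurized pocket (or None for an empty pocket, with a warning)."""
    ligand_coords = np.atleast_2d(np.asarray(ligand_coords, dtype=np.float64))
    if radius <= 0:
        raise ValueError("radius must be positive")
    kept_keys, kept_residue_atoms = [], []
    for chain_id, resseq, res in _protein_residues(structure):
        atoms = []
        for atom in res:
            el = (atom.element or atom.get_name()[0]).capitalize()
            if el == "H":
                continue
            atoms.append((el, atom.get_name(), np.asarray(atom.coord, dtype=np.float64)))
        if not atoms:
            continue
        coords = np.array([a[2] for a in atoms])
        dmin = np.sqrt(((coords[:, None, :] - ligand_coords[None, :, :]) ** 2)
                       .sum(axis=-1)).min()
        if dmin <= radius:
            kept_keys.append((chain_id, resseq, res.get_resname()))
            kept_residue_atoms.append((res.get_resname(), atoms))
    if not kept_keys:
        warnings.warn("no protein residues within radius of the ligand: empty pocket")
        return [], None
    cloud = featurize_pocket(kept_residue_atoms, mode=mode)
    return kept_keys, cloud


# ---------------------------------------------------------------------------
# SDF / molecule conversion
# ---------------------------------------------------------------------------

def read_sdf(path, sanitize: bool = True):
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=sanitize, removeHs=False)
    return [m for m in supplier if m is not None]


def cloud_to_mol(cloud: AtomPointCloud, bonds=None):
    """Build an (unsanitized) RDKit molecule from a decoded point cloud."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    if not cloud.labels:
        raise ValueError("cloud has no decoded atom identities")
    mol = Chem.RWMol()
    for el in cloud.labels:
        mol.AddAtom(Chem.Atom(el))
    conf = Chem.Conformer(cloud.n_atoms)
    for i, xyz in enumerate(cloud.coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    if bonds:
        for i, j in bonds:
            mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    return mol.GetMol()


def mol_to_cloud(mol, alphabet=LIGAND_ALPHABET) -> AtomPointCloud:
    """Featurize an RDKit molecule with a 3D conformer (heavy atoms only)."""
    from .molsys import featurize_ligand

    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H":
            continue
        pos = conf.GetAtomPosition(atom.GetIdx())
        atoms.append((atom.GetSymbol(), (pos.x, pos.y, pos.z)))
    return featurize_ligand(atoms, alphabet=alphabet)


def write_sdf(items, path) -> None:
    """Write clouds (bonds perceived first) and/or RDKit mols as multi-record SDF."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for item in items:
            if isinstance(item, AtomPointCloud):
                bonds = perceive_bonds(item.labels, item.coords)
                mol = cloud_to_mol(item, bonds=bonds)
            else:
                mol = item
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# bond perception + postprocessing
# ---------------------------------------------------------------------------

def perceive_bonds(labels, coords) -> list[tuple[int, int]]:
    """Covalent-radius fallback: bond iff d <= 1.25 * (r_i + r_j); bonds beyond
    an element's typical valence are dropped longest-first."""
    coords = np.asarray(coords, dtype=np.float64)
    n = len(labels)
    cand = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            cutoff = _RADIUS_TOLERANCE * (COVALENT_RADII[labels[i]] + COVALENT_RADII[labels[j]])
            if d <= cutoff:
                cand.append((d, i, j))
    cand.sort()  # shortest first so excess valence drops the longest bonds
    degree = np.zeros(n, dtype=int)
    bonds = []
    for d, i, j in cand:
        if degree[i] < _MAX_VALENCE[labels[i]] and degree[j] < _MAX_VALENCE[labels[j]]:
            bonds.append((i, j))
            degree[i] += 1
            degree[j] += 1
    return bonds


def _perceive_with_openbabel(cloud: AtomPointCloud):
    from openbabel import openbabel as ob  # optional backend

    obmol = ob.OBMol()
    for el, xyz in zip(cloud.labels, cloud.coords):
        atom = obmol.NewAtom()
        atom.SetAtomicNum(ob.GetAtomicNum(el))
        atom.SetVector(*map(float, xyz))
    obmol.ConnectTheDots()
    obmol.PerceiveBondOrders()
    bonds = []
    for bond in ob.OBMolBondIter(obmol):
        bonds.append((bond.GetBeginAtomIdx() - 1, bond.GetEndAtomIdx() - 1))
    return bonds


def postprocess(cloud: AtomPointCloud) -> PostprocessResult:
    """Turn a decoded point cloud into a sanitized RDKit molecule.

    Never raises on garbage geometry: failures come back as typed records with
    a stage tag. The largest connected fragment (by heavy-atom count) is kept.
    """
    from rdkit import Chem

    n_in = cloud.n_atoms
    try:
        if not cloud.labels:
            return PostprocessResult(False, stage="decode", n_atoms_in=n_in)
        try:
            bonds = _perceive_with_openbabel(cloud)
        except ImportError:
            bonds = perceive_bonds(cloud.labels, cloud.coords)
        mol = cloud_to_mol(cloud, bonds=bonds)
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        mol = max(frags, key=lambda m: m.GetNumAtoms())
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return PostprocessResult(False, mol=None, stage="sanitize",
                                     n_atoms_in=n_in, n_atoms_kept=mol.GetNumAtoms())
        return PostprocessResult(True, mol=mol, stage="",
                                 n_atoms_in=n_in, n_atoms_kept=mol.GetNumAtoms())
    except Exception as exc:  # pragma: no cover - catch-all guard
        logger.warning("postprocess failed unexpectedly: %s", exc)
        return PostprocessResult(False, stage="unexpected", n_atoms_in=n_in)


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def curate(entries, rules: CurationRules | None = None, rng=0):
    """Apply the curation filters; returns (kept_entries, rejection_log).

    Filters: database validity pass-through, QED threshold, element alphabet,
    standard amino acids in the pocket, then a seeded random cap of
    ``max_per_ccd`` entries per chemical component identifier. Each rejection
    is logged as ``(entry_id, reason)``.
    """
    from rdkit.Chem import QED

    rules = rules or CurationRules()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(int(rng))
    log: list[tuple[str, str]] = []
    stage_pass: list[CurationEntry] = []
    standard = set(AMINO_ACIDS)
    for k, entry in enumerate(entries):
        eid = entry.entry_id or f"entry{k}"
        if entry.ligand is None:
            log.append((eid, "unparseable"))
            continue
        if not entry.db_valid:
            log.append((eid, "db_validity"))
            continue
        try:
            qed = QED.qed(entry.ligand)
        except Exception:
            log.append((eid, "unparseable"))
            continue
        if qed <= rules.min_qed:
            log.append((eid, "qed"))
            continue
        elements = {a.GetSymbol() for a in entry.ligand.GetAtoms() if a.GetSymbol() != "H"}
        bad = elements - set(rules.allowed_elements)
        if bad:
            log.append((eid, "element"))
            continue
        if rules.require_standard_aa and entry.protein_residues:
            if any(r not in standard for r in entry.protein_residues):
                log.append((eid, "nonstandard_aa"))
                continue
        stage_pass.append(entry)
    # seeded per-CCD cap, order-independent apart from the seeded sampling
    by_ccd: dict[str, list[CurationEntry]] = {}
    for entry in stage_pass:
        by_ccd.setdefault(entry.ccd, []).append(entry)
    kept: list[CurationEntry] = []
    for ccd in sorted(by_ccd):
        group = by_ccd[ccd]
        if len(group) > rules.max_per_ccd:
            idx = rng.choice(len(group), size=rules.max_per_ccd, replace=False)
            chosen = set(int(i) for i in idx)
            for k, entry in enumerate(group):
                if k in chosen:
                    kept.append(entry)
                else:
                    log.append((entry.entry_id or "?", "ccd_cap"))
        else:
            kept.extend(group)
    return kept, log


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _sa_score(mol) -> float:
    from rdkit import RDConfig

    sa_path = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if sa_path not in sys.path:
        sys.path.append(sa_path)
    import sascorer

    return float(sascorer.calculateScore(mol))


def lipinski_count(mol) -> int:
    """Number of satisfied rules among MW<=500, logP<=5, HBD<=5, HBA<=10 and
    at most ten rotatable bonds."""
    from rdkit.Chem import Crippen, Descriptors, Lipinski

    checks = [
        Descriptors.MolWt(mol) <= 500,
        Crippen.MolLogP(mol) <= 5,
        Lipinski.NumHDonors(mol) <= 5,
        Lipinski.NumHAcceptors(mol) <= 10,
        Descriptors.NumRotatableBonds(mol) <= 10,
    ]
    return int(sum(checks))


def _fingerprint(mol):
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    return gen.GetFingerprint(mol)


def tanimoto_diversity(mols) -> float:
    """Mean pairwise (1 - Tanimoto similarity); NaN for fewer than 2 molecules."""
    from rdkit import DataStructs

    if len(mols) < 2:
        return float("nan")
    fps = [_fingerprint(m) for m in mols]
    dis = []
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            dis.append(1.0 - DataStructs.TanimotoSimilarity(fps[i], fps[j]))
    return float(np.mean(dis))


def compute_metrics(molecules, per_target_grouping=None) -> MetricsReport:
    """QED/SA/logP/Lipinski per molecule and per-target diversity.

    ``per_target_grouping`` assigns a target label to each molecule (defaults
    to one group). Unsanitizable inputs count toward ``n_failed``.
    """
    from rdkit import Chem
    from rdkit.Chem import QED, Crippen

    groups = (list(per_target_grouping) if per_target_grouping is not None
              else ["target"] * len(molecules))
    if len(groups) != len(molecules):
        raise ValueError("grouping length must match molecule count")
    rows, ok_mols, ok_groups, n_failed = [], [], [], 0
    for mol, target in zip(molecules, groups):
        try:
            Chem.SanitizeMol(mol)
            rows.append({
                "qed": QED.qed(mol),
                "sa": _sa_score(mol),
                "logp": Crippen.MolLogP(mol),
                "lipinski": lipinski_count(mol),
                "target": target,
            })
            ok_mols.append(mol)
            ok_groups.append(target)
        except Exception:
            n_failed += 1
    per_molecule = pd.DataFrame(rows, columns=["qed", "sa", "logp", "lipinski", "target"])
    diversity = {}
    for target in dict.fromkeys(ok_groups):
        diversity[target] = tanimoto_diversity(
            [m for m, g in zip(ok_mols, ok_groups) if g == target])
    return MetricsReport(per_molecule=per_molecule, diversity=diversity, n_failed=n_failed)
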