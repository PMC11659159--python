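"""Atomic point clouds, featurization and typed graph construction.

Ligands and pockets are plain coordinate/feature matrices. Graphs connect
nodes whose Euclidean distance falls below a per-edge-type cut-off
(ligand-ligand ``LL``, ligand-pocket ``LP``, pocket-pocket ``PP``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "LIGAND_ALPHABET",
    "AMINO_ACIDS",
    "EDGE_TYPES",
    "AtomPointCloud",
    "ComplexSystem",
    "FeatureScaling",
    "featurize_ligand",
    "featurize_pocket",
    "build_graph",
    "apply_scaling",
    "decode_labels",
]

#: element vocabulary used for ligand atoms (and full-atom pockets)
LIGAND_ALPHABET: tuple[str, ...] = ("C", "N", "O", "S", "B", "Br", "Cl", "P", "I", "F")

#: the 20 standard amino acids, three-letter codes, fixed order
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

EDGE_TYPES: tuple[str, ...] = ("LL", "LP", "PP")

DEFAULT_CUTOFFS: dict[str, float] = {"LL": 5.0, "LP": 5.0, "PP": 5.0}


@dataclass
class AtomPointCloud:
    """Atoms as coordinates plus (possibly noised/scaled) categorical features."""

    coords: np.ndarray  # N x 3, Angstrom unless scaled
    feats: np.ndarray  # N x d
    labels: tuple[str, ...] = ()  # decoded categorical identities, may be empty

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.float64))
        self.feats = np.atleast_2d(np.asarray(self.feats, dtype=np.float64))
        if self.coords.shape[0] < 1:
            raise ValueError("point cloud must contain at least one atom")
        if self.coords.shape[1] != 3:
            raise ValueError("coords must be N x 3")
        if self.feats.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"coords ({self.coords.shape[0]}) and feats ({self.feats.shape[0]}) "
                "row counts differ"
            )
        if self.labels and len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels length must match atom count")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_feats(self) -> int:
        return self.feats.shape[1]

    def is_one_hot(self, atol: float = 1e-9) -> bool:
        """True when every feature row is a valid one-hot vector."""
        f = self.feats
        ones = np.isclose(f, 1.0, atol=atol)
        zeros = np.isclose(f, 0.0, atol=atol)
        return bool(np.all(ones.sum(axis=1) == 1) and np.all(ones | zeros))

    def copy(self) -> "AtomPointCloud":
        return AtomPointCloud(self.coords.copy(), self.feats.copy(), self.labels)


@dataclass
class ComplexSystem:
    """A ligand/pocket pair with the typed edge graph between them.

    Edges are stored as directed arcs (both directions present) so that
    message passing can iterate over ``j != i`` naturally.
    """

    ligand: AtomPointCloud
    pocket: AtomPointCloud
    edges: list[tuple[int, int, str]] = field(default_factory=list)
    edge_feats: np.ndarray | None = None  # per-edge one-hot of edge type
    cutoffs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def validate(self) -> None:
        n_l = self.ligand.n_atoms
        coords = np.vstack([self.ligand.coords, self.pocket.coords])
        for i, j, etype in self.edges:
            if i == j:
                raise ValueError(f"self edge at node {i}")
            roles = {"L" if i < n_l else "P", "L" if j < n_l else "P"}
            expected = "LL" if roles == {"L"} else ("PP" if roles == {"P"} else "LP")
            if etype != expected:
                raise ValueError(f"edge ({i},{j}) typed {etype}, endpoints say {expected}")
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d > self.cutoffs[etype] + 1e-9:
                raise ValueError(f"edge ({i},{j}) length {d:.3f} exceeds {etype} cut-off")


@dataclass(frozen=True)
class FeatureScaling:
    """Multiplicative scaling applied at model boundaries.

    Features are shrunk relative to coordinates; all-atom joint models
    additionally shrink the coordinates (and distance cut-offs) themselves.
    """

    feat_factor: float = 0.25
    coord_factor: float = 1.0

    def __post_init__(self):
        if self.feat_factor <= 0 or self.coord_factor <= 0:
            raise ValueError("scaling factors must be positive")

    def scale_cutoffs(self, cutoffs: dict[str, float]) -> dict[str, float]:
        return {k: v * self.coord_factor for k, v in cutoffs.items()}


def _one_hot(index: int, size: int) -> np.ndarray:
    row = np.zeros(size)
    row[index] = 1.0
    return row


def featurize_ligand(
    atom_list,
    alphabet=LIGAND_ALPHABET,
    scaling: FeatureScaling | None = None,
) -> AtomPointCloud:
    """Encode ``(element, xyz)`` pairs as a one-hot featured point cloud.

    When ``scaling`` is given, features/coordinates are multiplied by the
    respective factors (model frame); otherwise they are left unscaled.
    """
    atom_list = list(atom_list)
    if not atom_list:
        raise ValueError("atom list is empty (N >= 1 required)")
    alphabet = tuple(alphabet)
    index = {el: k for k, el in enumerate(alphabet)}
    coords, feats, labels = [], [], []
    for element, xyz in atom_list:
        if element not in index:
            raise ValueError(f"element {element!r} not in alphabet {alphabet}")
        coords.append(np.asarray(xyz, dtype=np.float64))
        feats.append(_one_hot(index[element], len(alphabet)))
        labels.append(element)
    cloud = AtomPointCloud(np.array(coords), np.array(feats), tuple(labels))
    if scaling is not None:
        cloud = apply_scaling(cloud, scaling, "forward")
    return cloud


def featurize_pocket(
    residue_atoms,
    mode: str = "full_atom",
    alphabet=LIGAND_ALPHABET,
    scaling: FeatureScaling | None = None,
) -> AtomPointCloud:
    """Featurize pocket residues.

    ``residue_atoms`` is a sequence of ``(residue_name, [(element, xyz), ...])``
    tuples, one per residue. ``full_atom`` yields one node per heavy atom with
    element one-hots; ``c_alpha`` yields one node per residue, located at the
    CA atom, with a 20-dim amino-acid one-hot.
    """
    residue_atoms = list(residue_atoms)
    if not residue_atoms:
        raise ValueError("no residues given")
    if mode == "full_atom":
        atoms = []
        for _resname, atom_entries in residue_atoms:
            for entry in atom_entries:
                element, xyz = entry[0], entry[-1]
                atoms.append((element, xyz))
        return featurize_ligand(atoms, alphabet=alphabet, scaling=scaling)
    if mode == "c_alpha":
        aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
        coords, feats, labels = [], [], []
        for resname, atom_entries in residue_atoms:
            if resname not in aa_index:
                raise ValueError(f"non-standard residue {resname!r} in c_alpha mode")
            ca = None
            for entry in atom_entries:
                if len(entry) == 3 and entry[1] == "CA":
                    ca = entry[-1]
            if ca is None and len(atom_entries) == 1:
                ca = atom_entries[0][-1]
            if ca is None:
                raise ValueError(f"residue {resname} has no CA atom")
            coords.append(np.asarray(ca, dtype=np.float64))
            feats.append(_one_hot(aa_index[resname], len(AMINO_ACIDS)))
            labels.append(resname)
        cloud = AtomPointCloud(np.array(coords), np.array(feats), tuple(labels))
        if scaling is not None:
            cloud = apply_scaling(cloud, scaling, "forward")
        return cloud
    raise ValueError(f"unknown pocket mode {mode!r}")


def build_graph(
    ligand: AtomPointCloud,
    pocket: AtomPointCloud | None,
    cutoffs: dict[str, float] | None = None,
    include_pp: bool = True,
) -> ComplexSystem:
    """Connect nodes whose distance is within the per-type cut-off.

    Ligand nodes occupy indices ``0..N_L-1``, pocket nodes follow. Both
    directed arcs of each undirected edge are stored. ``cutoffs`` must live in
    the same (possibly scaled) frame as the coordinates.
    """
    if pocket is None:
        raise ValueError("pocket is required")
    cutoffs = dict(DEFAULT_CUTOFFS) if cutoffs is None else dict(cutoffs)
    for k, v in cutoffs.items():
        if v <= 0:
            raise ValueError(f"cut-off {k} must be positive")
    n_l = ligand.n_atoms
    coords = np.vstack([ligand.coords, pocket.coords])
    n = coords.shape[0]
    dmat = cdist(coords, coords)
    edges: list[tuple[int, int, str]] = []
    type_onehot = {t: _one_hot(k, len(EDGE_TYPES)) for k, t in enumerate(EDGE_TYPES)}
    feats = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            etype = (
                "LL" if (i < n_l and j < n_l)
                else "PP" if (i >= n_l and j >= n_l)
                else "LP"
            )
            if etype == "PP" and not include_pp:
                continue
            if dmat[i, j] <= cutoffs[etype]:
                edges.append((i, j, etype))
                feats.append(type_onehot[etype])
    edge_feats = np.array(feats) if feats else np.zeros((0, len(EDGE_TYPES)))
    return ComplexSystem(ligand, pocket, edges, edge_feats, cutoffs)


def apply_scaling(
    cloud: AtomPointCloud, scaling: FeatureScaling, direction: str = "forward"
) -> AtomPointCloud:
    """Scale features/coordinates into (forward) or out of (inverse) the model frame."""
    if direction == "forward":
        ff, cf = scaling.feat_factor, scaling.coord_factor
    elif direction == "inverse":
        ff, cf = 1.0 / scaling.feat_factor, 1.0 / scaling.coord_factor
    else:
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    return AtomPointCloud(cloud.coords * cf, cloud.feats * ff, cloud.labels)


def decode_labels(feats: np.ndarray, alphabet=LIGAND_ALPHABET) -> tuple[str, ...]:
    """Arg-max decode of categorical channels; ties broken by lowest index."""
    idx = np.argmax(feats, axis=1)
    return tuple(alphabet[i] for i in idx)
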