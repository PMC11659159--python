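"""Deterministic toy ligand-pocket complexes and chiral point-set pairs.

Rigid ligand templates with known geometry are randomly rotated (proper
rotations only), jittered and placed at the center of a procedurally generated
shell of pocket pseudo-residues (written as glycine C-alpha records so both
pocket featurization modes parse). Everything is reproducible from a seed and
round-trips through plain-text PDB/SDF.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molsys import ComplexSystem, build_graph, featurize_ligand, featurize_pocket

__all__ = [
    "ToyTemplate",
    "TEMPLATES",
    "random_rotation",
    "make_toy_complexes",
    "make_chiral_pair",
    "kabsch_rmsd",
    "write_pocket_pdb",
]


@dataclass(frozen=True)
class ToyTemplate:
    name: str
    elements: tuple[str, ...]
    coords: np.ndarray  # canonical rigid-body coordinates, Angstrom
    pocket_radius: float = 6.0

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def mean_edge_length(self, cutoff: float = 2.0) -> float:
        """Mean length of intra-template edges shorter than ``cutoff`` (bonds)."""
        d = np.linalg.norm(self.coords[:, None] - self.coords[None, :], axis=-1)
        mask = (d > 0) & (d <= cutoff)
        return float(d[mask].mean())

    def mean_nn_distance(self) -> float:
        d = np.linalg.norm(self.coords[:, None] - self.coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return float(d.min(axis=1).mean())


def _tetrahedron(bond: float = 1.5) -> np.ndarray:
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    verts *= bond / np.sqrt(3.0)
    return np.vstack([[0.0, 0.0, 0.0], verts])


def _hex_ring_with_methyl(side: float = 1.39, sub: float = 1.5) -> np.ndarray:
    ang = np.arange(6) * np.pi / 3.0
    r = side  # hexagon circumradius equals its side
    ring = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(6)], axis=1)
    methyl = ring[0] + np.array([sub, 0.0, 0.0])
    return np.vstack([ring, methyl])


def _dumbbell(bond: float = 1.5, gap: float = 3.0) -> np.ndarray:
    tet = _tetrahedron(bond)
    left = tet + np.array([-(gap / 2 + 2 * bond), 0.0, 0.0])
    right = -tet + np.array([gap / 2 + 2 * bond, 0.0, 0.0])
    linker = np.array([[-gap / 2 + bond / 2, 0.0, 0.0], [gap / 2 - bond / 2, 0.0, 0.0]])
    return np.vstack([left, right, linker])


#: tetrahedral (chiral, >=3 non-collinear atoms), ringed (scaffold extraction)
#: and two-fragment dumbbell (linker design) templates
TEMPLATES: tuple[ToyTemplate, ...] = (
    ToyTemplate("tetra", ("C", "N", "O", "F", "C"), _tetrahedron(), 6.0),
    ToyTemplate("ring", ("C",) * 6 + ("N",), _hex_ring_with_methyl(), 7.0),
    ToyTemplate("dumbbell", ("C", "N", "O", "F", "C") * 2 + ("C", "C"), _dumbbell(), 9.0),
)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation (det = +1) via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _sphere_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius


def make_toy_complexes(
    n: int,
    templates=TEMPLATES,
    pocket_points_range: tuple[int, int] = (8, 16),
    jitter_sd: float = 0.1,
    seed: int = 0,
    out_dir=None,
    pocket_mode: str = "c_alpha",
    cutoffs=None,
):
    """Generate ``n`` reproducible toy complexes.

    Returns ``(systems, meta)`` where ``systems`` are :class:`ComplexSystem`
    objects (unscaled frame) and ``meta`` a DataFrame manifest. When
    ``out_dir`` is given, each complex is also written as a PDB/SDF pair plus
    a ``manifest.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    templates = tuple(templates)
    if not templates:
        raise ValueError("template list is empty")
    rng = np.random.default_rng(seed)
    systems, rows = [], []
    for k in range(n):
        tpl = templates[int(rng.integers(len(templates)))]
        rot = random_rotation(rng)
        lig_coords = tpl.coords @ rot.T
        if jitter_sd > 0:
            lig_coords = lig_coords + rng.normal(0.0, jitter_sd, lig_coords.shape)
        n_pocket = int(rng.integers(pocket_points_range[0], pocket_points_range[1] + 1))
        pocket_coords = _sphere_points(rng, n_pocket, tpl.pocket_radius)
        if jitter_sd > 0:
            pocket_coords = pocket_coords + rng.normal(0.0, jitter_sd, pocket_coords.shape)
        ligand = featurize_ligand(list(zip(tpl.elements, lig_coords)))
        residues = [("GLY", [("C", "CA", xyz)]) for xyz in pocket_coords]
        pocket = featurize_pocket(residues, mode=pocket_mode)
        systems.append(build_graph(ligand, pocket, cutoffs=cutoffs))
        rows.append({"index": k, "template": tpl.name, "n_ligand": ligand.n_atoms,
                     "n_pocket": pocket.n_atoms})
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            write_pocket_pdb(pocket_coords, os.path.join(out_dir, f"complex_{k:05d}.pdb"))
            from .chemio import write_sdf

            write_sdf([ligand], os.path.join(out_dir, f"complex_{k:05d}.sdf"))
    meta = pd.DataFrame(rows)
    if out_dir is not None:
        meta.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return systems, meta


def write_pocket_pdb(coords: np.ndarray, path) -> None:
    """Write pocket pseudo-residues as glycine C-alpha ATOM records."""
    lines = []
    for i, (x, y, z) in enumerate(np.atleast_2d(coords), start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def make_chiral_pair(seed: int = 0, n_points: int = 5):
    """A random non-planar point cloud and its mirror image.

    The pair shares its pairwise-distance multiset but cannot be superposed by
    any proper rotation (checked at generation time via Kabsch alignment).
    """
    if n_points < 4:
        raise ValueError("need >= 4 points for a non-planar cloud")
    rng = np.random.default_rng(seed)
    while True:
        pts = rng.uniform(-2.0, 2.0, (n_points, 3))
        pts -= pts.mean(axis=0)
        span = np.abs(np.linalg.det(pts[1:4] - pts[0]))
        mirror = pts.copy()
        mirror[:, 2] = -mirror[:, 2]
        if span > 0.5 and kabsch_rmsd(pts, mirror) > 0.1:
            break
    elements = tuple("C" for _ in range(n_points))
    a = featurize_ligand(list(zip(elements, pts)))
    b = featurize_ligand(list(zip(elements, mirror)))
    return a, b


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal proper-rotation (det = +1) superposition of the
    centered point sets, matching rows by index."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = a @ rot.T - b
    return float(np.sqrt((diff**2).sum() / len(a)))
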