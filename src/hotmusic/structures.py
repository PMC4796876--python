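"""Protein structures and residue-level descriptors.

Everything downstream of this module sees a protein only through three
structure elements computed here for every residue of a single chain:

* relative solvent accessibility ``a`` (percent of a per-amino-acid
  maximal area, Shrake-Rupley ASA),
* backbone torsion-angle domain ``t`` (a coarse partition of the
  Ramachandran plane),
* binned spatial distance ``d`` between side-chain geometric centroids.

The binning and reference tables are held in :class:`DescriptorConfig`; a
stable hash of the configuration travels with every derived potential so
that train-time and predict-time descriptor conventions can be checked for
identity.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (
    AA_INDEX,
    MAX_ASA_THEORETICAL,
    ONE_TO_THREE,
    THREE_TO_ONE,
)

UNDEFINED = "undefined"

#: Rectangles (label, phi_lo, phi_hi, psi_lo, psi_hi) in degrees, first
#: match wins; anything unmatched is "other".  The partition is a package
#: default, chosen to separate the classical right-handed helical,
#: extended-beta, polyproline-II, left-handed helical and epsilon regions.
DEFAULT_TORSION_DOMAINS: tuple[tuple[str, float, float, float, float], ...] = (
    ("helical", -160.0, -20.0, -120.0, 50.0),
    ("extended", -180.5, -90.0, 90.0, 180.5),
    ("extended", -180.5, -90.0, -180.5, -150.0),
    ("ppII", -90.0, -20.0, 50.0, 180.5),
    ("helical-L", 20.0, 125.0, -45.0, 90.0),
    ("epsilon", 60.0, 180.5, 90.0, 180.5),
)

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


@dataclass(frozen=True)
class DescriptorConfig:
    """Conventions used to turn coordinates into binned descriptors."""

    probe_radius: float = 1.4
    sasa_points: int = 960
    d_min: float = 3.0
    d_max: float = 8.0
    d_bin_width: float = 0.2
    min_seq_sep: int = 1
    acc_bin_edges: tuple[float, ...] = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0)
    torsion_domains: tuple[tuple[str, float, float, float, float], ...] = (
        DEFAULT_TORSION_DOMAINS
    )
    max_asa: Mapping[str, float] = field(
        default_factory=lambda: dict(MAX_ASA_THEORETICAL)
    )

    @property
    def n_distance_bins(self) -> int:
        return int(round((self.d_max - self.d_min) / self.d_bin_width))

    @property
    def torsion_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for label, *_ in self.torsion_domains:
            if label not in seen:
                seen.append(label)
        seen.append("other")
        return tuple(seen)

    @property
    def n_acc_bins(self) -> int:
        return len(self.acc_bin_edges) - 1

    def distance_bin(self, d: float) -> int:
        """Half-open uniform binning; -1 for out-of-range distances."""
        if not (self.d_min <= d < self.d_max):
            return -1
        return int((d - self.d_min) / self.d_bin_width)

    def acc_bin(self, rsa: float) -> int:
        inner = np.asarray(self.acc_bin_edges[1:-1])
        return int(np.searchsorted(inner, min(rsa, self.acc_bin_edges[-1]),
                                   side="right"))

    def torsion_domain(self, phi: float | None, psi: float | None) -> str:
        if phi is None or psi is None:
            return UNDEFINED
        for label, plo, phi_hi, slo, shi in self.torsion_domains:
            if plo <= phi < phi_hi and slo <= psi < shi:
                return label
        return "other"

    def config_hash(self) -> str:
        payload = {
            "probe_radius": self.probe_radius,
            "sasa_points": self.sasa_points,
            "d": [self.d_min, self.d_max, self.d_bin_width],
            "min_seq_sep": self.min_seq_sep,
            "acc": list(self.acc_bin_edges),
            "torsion": [list(r) for r in self.torsion_domains],
            "max_asa": {k: self.max_asa[k] for k in sorted(self.max_asa)},
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.md5(blob).hexdigest()

    def with_max_asa(self, table: Mapping[str, float]) -> "DescriptorConfig":
        return replace(self, max_asa=dict(table))


@dataclass
class Residue:
    """One standard amino-acid residue of a parsed chain."""

    aa: str
    author_number: str
    atoms: dict[str, np.ndarray]

    @property
    def backbone_complete(self) -> bool:
        return all(name in self.atoms for name in ("N", "CA", "C"))


@dataclass
class ProteinStructure:
    id: str
    chain: str
    residues: list[Residue]
    resolution: float | None = None
    tm: float | None = None

    @property
    def n_res(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def index_of_author_position(self, position: str | int) -> int:
        key = str(position).strip()
        for i, res in enumerate(self.residues):
            if res.author_number == key:
                return i
        raise KeyError(
            f"author position {key!r} not found in {self.id} chain {self.chain}"
        )


@dataclass
class ResidueDescriptor:
    index: int
    author_number: str
    aa: str
    rsa: float
    torsion_domain: str
    sidechain_centroid: np.ndarray


@dataclass
class ResiduePair:
    i: int
    j: int
    distance: float
    distance_bin: int


def _infer_element(name: str) -> str:
    head = name.strip()[0]
    return head if head in "CNOS" else "C"


def read_pdb(path: str | Path, chain: str) -> ProteinStructure:
    """Parse one chain of a PDB file into a :class:`ProteinStructure`.

    Only the 20 canonical amino acids are kept; waters, hetero groups and
    hydrogens are dropped.  For disordered atoms Biopython's selected
    (highest-occupancy) conformer is used.  A residue is retained as long
    as it has a CA atom; missing N/CA/C atoms are visible downstream as an
    ``undefined`` torsion domain.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        entity = parser.get_structure(path.stem, str(path))
        header = entity.header or {}
    model = next(entity.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(
            f"chain {chain!r} not present in {path.name}; "
            f"available: {[c.id for c in model]}"
        )
    residues: list[Residue] = []
    for res in model[chain]:
        hetflag, resseq, icode = res.id
        if hetflag != " " or res.resname not in THREE_TO_ONE:
            continue
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if (atom.element or "").upper() == "H" or atom.name.startswith("H"):
                continue
            atoms[atom.name] = np.asarray(atom.coord, dtype=float)
        if "CA" not in atoms:
            continue
        residues.append(
            Residue(
                aa=THREE_TO_ONE[res.resname],
                author_number=f"{resseq}{icode.strip()}",
                atoms=atoms,
            )
        )
    if not residues:
        raise ValueError(f"no standard residues parsed for chain {chain!r} of {path.name}")
    resolution = header.get("resolution")
    return ProteinStructure(
        id=path.stem, chain=chain, residues=residues,
        resolution=float(resolution) if resolution else None,
    )


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a minimal but syntactically valid single-chain PDB file."""
    path = Path(path)
    lines: list[str] = []
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS."
        )
    serial = 1
    chain = (structure.chain or "A")[0]
    for res in structure.residues:
        num = res.author_number
        icode = num[-1] if num and num[-1].isalpha() else " "
        resseq = int(num[:-1]) if icode != " " else int(num)
        for name, xyz in res.atoms.items():
            pad = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pad}{'':1s}{ONE_TO_THREE[res.aa]:>3s} "
                f"{chain}{resseq:4d}{icode}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {_infer_element(name):>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _to_biopdb(structure: ProteinStructure):
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure(structure.id)
    builder.init_model(0)
    builder.init_chain((structure.chain or "A")[0])
    builder.init_seg(" ")
    for i, res in enumerate(structure.residues):
        builder.init_residue(ONE_TO_THREE[res.aa], " ", i + 1, " ")
        for name, coord in res.atoms.items():
            builder.init_atom(
                name,
                np.asarray(coord, dtype=float),
                0.0,
                1.0,
                " ",
                name if len(name) == 4 else f" {name:<3s}",
                element=_infer_element(name),
            )
    return builder.get_structure()


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (Fibonacci golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * k / golden
    z = 1.0 - (2.0 * k + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Vectorised implementation of the classic rolling-probe point-counting
    algorithm: each atom's expanded sphere (van der Waals + probe radius)
    is sampled on a deterministic Fibonacci lattice and a sample point is
    accessible when it lies outside every neighbouring expanded sphere.
    """
    from scipy.spatial import cKDTree

    coords = np.ascontiguousarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n = len(coords)
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2.0 * radii.max(), output_type="ndarray")
    if len(pairs):
        sep = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[sep < radii[pairs[:, 0]] + radii[pairs[:, 1]]]
    both = np.concatenate([pairs, pairs[:, ::-1]]) if len(pairs) else pairs
    order = np.argsort(both[:, 0], kind="stable") if len(both) else []
    adjacency: list[np.ndarray] = [np.empty(0, dtype=int)] * n
    if len(both):
        sorted_pairs = both[order]
        starts = np.searchsorted(sorted_pairs[:, 0], np.arange(n + 1))
        adjacency = [
            sorted_pairs[starts[i]:starts[i + 1], 1] for i in range(n)
        ]
    areas = np.empty(n)
    for i in range(n):
        close = adjacency[i]
        if len(close):
            pts = coords[i] + radii[i] * sphere
            d2 = cdist(pts, coords[close], "sqeuclidean")
            buried = (d2 < (radii[close] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return areas


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(y, x)))


def _residue_sasa(structure: ProteinStructure, config: DescriptorConfig) -> np.ndarray:
    from Bio.PDB.SASA import ATOMIC_RADII

    coords: list[np.ndarray] = []
    radii: list[float] = []
    owner: list[int] = []
    for i, res in enumerate(structure.residues):
        for name, xyz in res.atoms.items():
            coords.append(xyz)
            radii.append(ATOMIC_RADII[_infer_element(name)])
            owner.append(i)
    atom_areas = shrake_rupley_sasa(
        np.asarray(coords), np.asarray(radii),
        probe_radius=config.probe_radius, n_points=config.sasa_points,
    )
    out = np.zeros(structure.n_res)
    np.add.at(out, np.asarray(owner), atom_areas)
    return out


def _phi_psi(structure: ProteinStructure, i: int) -> tuple[float | None, float | None]:
    res = structure.residues[i]
    if not res.backbone_complete:
        return None, None
    phi = psi = None
    max_peptide_bond = 2.5  # angstrom; larger C-N gaps are chain breaks
    if i > 0:
        prev = structure.residues[i - 1]
        if "C" in prev.atoms and (
            np.linalg.norm(prev.atoms["C"] - res.atoms["N"]) < max_peptide_bond
        ):
            phi = dihedral(prev.atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"])
    if i < structure.n_res - 1:
        nxt = structure.residues[i + 1]
        if "N" in nxt.atoms and (
            np.linalg.norm(res.atoms["C"] - nxt.atoms["N"]) < max_peptide_bond
        ):
            psi = dihedral(res.atoms["N"], res.atoms["CA"], res.atoms["C"], nxt.atoms["N"])
    return phi, psi


def _centroid(res: Residue) -> np.ndarray:
    side = [xyz for name, xyz in res.atoms.items() if name not in BACKBONE_ATOMS]
    if not side:
        return np.asarray(res.atoms["CA"], dtype=float)
    return np.mean(np.asarray(side, dtype=float), axis=0)


def compute_descriptors(
    structure: ProteinStructure, config: DescriptorConfig | None = None
) -> list[ResidueDescriptor]:
    """Per-residue (aa, rsa, torsion domain, side-chain centroid) descriptors.

    Chain termini and residues with incomplete backbones get torsion domain
    ``"undefined"``; geometry edge cases never raise.
    """
    config = config or DescriptorConfig()
    sasa = _residue_sasa(structure, config)
    out: list[ResidueDescriptor] = []
    for i, res in enumerate(structure.residues):
        phi, psi = _phi_psi(structure, i)
        domain = config.torsion_domain(phi, psi)
        rsa = 100.0 * sasa[i] / config.max_asa[res.aa]
        out.append(
            ResidueDescriptor(
                index=i,
                author_number=res.author_number,
                aa=res.aa,
                rsa=float(np.clip(rsa, 0.0, 100.0)),
                torsion_domain=domain,
                sidechain_centroid=_centroid(res),
            )
        )
    return out


def pair_distances(
    descriptors: Sequence[ResidueDescriptor], config: DescriptorConfig | None = None
) -> list[ResiduePair]:
    """All residue pairs with centroid distance inside the configured range."""
    config = config or DescriptorConfig()
    if len(descriptors) < 2:
        return []
    pts = np.asarray([d.sidechain_centroid for d in descriptors])
    dmat = cdist(pts, pts)
    pairs: list[ResiduePair] = []
    n = len(descriptors)
    for i in range(n):
        for j in range(i + config.min_seq_sep if config.min_seq_sep > 0 else i + 1, n):
            if j - i < config.min_seq_sep:
                continue
            b = config.distance_bin(dmat[i, j])
            if b >= 0:
                pairs.append(ResiduePair(i=i, j=j, distance=float(dmat[i, j]), distance_bin=b))
    return pairs


@dataclass
class StructureData:
    """Vectorised descriptor view consumed by counting and featurisation."""

    structure: ProteinStructure
    aa_idx: np.ndarray        # (n,) int
    acc_bin: np.ndarray       # (n,) int
    tor_idx: np.ndarray       # (n,) int, -1 for undefined
    rsa: np.ndarray           # (n,) float, percent
    pairs: np.ndarray         # (m, 3) int: i, j, distance bin
    config_hash: str

    @property
    def n_res(self) -> int:
        return len(self.aa_idx)


def structure_arrays(
    structure: ProteinStructure, config: DescriptorConfig | None = None
) -> StructureData:
    config = config or DescriptorConfig()
    desc = compute_descriptors(structure, config)
    labels = {lab: k for k, lab in enumerate(config.torsion_labels)}
    aa_idx = np.array([AA_INDEX[d.aa] for d in desc], dtype=np.int64)
    acc = np.array([config.acc_bin(d.rsa) for d in desc], dtype=np.int64)
    tor = np.array(
        [labels.get(d.torsion_domain, -1) for d in desc], dtype=np.int64
    )
    rsa = np.array([d.rsa for d in desc], dtype=float)
    prs = pair_distances(desc, config)
    pairs = (
        np.array([[p.i, p.j, p.distance_bin] for p in prs], dtype=np.int64)
        if prs
        else np.empty((0, 3), dtype=np.int64)
    )
    return StructureData(
        structure=structure,
        aa_idx=aa_idx,
        acc_bin=acc,
        tor_idx=tor,
        rsa=rsa,
        pairs=pairs,
        config_hash=config.config_hash(),
    )


def descriptors_to_tsv(
    descriptors: Iterable[ResidueDescriptor], path: str | Path
) -> None:
    import pandas as pd

    rows = [
        {
            "index": d.index,
            "author_number": d.author_number,
            "aa": d.aa,
            "rsa": round(d.rsa, 3),
            "torsion_domain": d.torsion_domain,
            "x": round(float(d.sidechain_centroid[0]), 3),
            "y": round(float(d.sidechain_centroid[1]), 3),
            "z": round(float(d.sidechain_centroid[2]), 3),
        }
        for d in descriptors
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
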