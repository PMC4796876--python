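"""Synthetic inputs for every stage of the pipeline.

Structures are ideal-geometry backbones (helical / extended / polyproline
segments with small torsional jitter) carrying a pseudo side-chain CB
atom; amino-acid types are drawn either independently of the local
structure (``coupling = 0``, which makes every mean-force potential vanish
in expectation) or biased by burial and torsion domain (``coupling > 0``).
Mutation datasets are generated from a known ("planted") parameter set:
the experimental dTm of each record is the planted model's prediction plus
Gaussian noise, so training can be validated against a known truth.

Because the residue type never feeds back into the geometry, sequence and
structure elements are exactly independent at ``coupling = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import AMINO_ACIDS, HELIX_PREFERENCE, HYDROPATHY
from .features import (
    FeatureVector,
    MutationRecord,
    featurize,
)
from .models import (
    HotParams,
    PolyFactor,
    SigmoidWeight,
    TmHotParams,
    predict_hot,
    predict_tm_hot,
)
from .potentials import PotentialSet
from .structures import (
    DescriptorConfig,
    ProteinStructure,
    Residue,
    StructureData,
    structure_arrays,
    write_pdb,
)

# ideal backbone geometry (bond lengths in angstrom, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7

#: (phi, psi) of the secondary-structure segment types used by the builder.
SEGMENT_TORSIONS: dict[str, tuple[float, float]] = {
    "helix": (-60.0, -45.0),
    "strand": (-120.0, 130.0),
    "ppII": (-75.0, 150.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic study; the same spec always reproduces the
    same corpus and dataset byte for byte."""

    n_structures: int = 20
    chain_length_range: tuple[int, int] = (50, 150)
    coupling: float = 0.5
    tm_range: tuple[float, float] | None = (40.0, 90.0)
    noise_sd: float = 2.0
    n_mutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.chain_length_range[0] > self.chain_length_range[1]:
            raise ValueError("chain_length_range must be ordered")
        if self.chain_length_range[0] < 3:
            raise ValueError("chains need at least 3 residues")
        if self.tm_range is not None and self.tm_range[0] > self.tm_range[1]:
            raise ValueError("tm_range must be ordered")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a fourth atom from three reference atoms (NeRF construction)."""
    ang = np.radians(angle)
    dih = np.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(dih),
         -bond * np.sin(ang) * np.sin(dih)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(torsions: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone atoms (N, CA, C, O) for a chain with the given (phi, psi)."""
    n_res = len(torsions)
    atoms: list[dict[str, np.ndarray]] = []
    N = np.zeros(3)
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    C = CA + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    atoms.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_res):
        psi_prev = torsions[i - 1][1]
        phi = torsions[i][0]
        prev = atoms[i - 1]
        N = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        CA = place_atom(prev["CA"], prev["C"], N, _B_N_CA, _A_C_N_CA, 180.0)
        C = place_atom(prev["C"], N, CA, _B_CA_C, _A_N_CA_C, phi)
        atoms.append({"N": N, "CA": CA, "C": C})
    for i in range(n_res):
        psi = torsions[i][1] if i < n_res - 1 else 180.0
        res = atoms[i]
        res["O"] = place_atom(res["N"], res["CA"], res["C"], 1.231, 120.5, psi + 180.0)
    return atoms


def _pseudo_cb(res: dict[str, np.ndarray]) -> np.ndarray:
    return place_atom(res["N"], res["C"], res["CA"], 1.53, 110.5, 122.5)


def _sample_torsions(n_res: int, rng: np.random.Generator) -> tuple[list, list]:
    torsions: list[tuple[float, float]] = []
    kinds: list[str] = []
    names = list(SEGMENT_TORSIONS)
    probs = np.array([0.45, 0.35, 0.20])
    while len(torsions) < n_res:
        kind = names[rng.choice(len(names), p=probs)]
        phi0, psi0 = SEGMENT_TORSIONS[kind]
        length = int(rng.integers(4, 13))
        for _ in range(min(length, n_res - len(torsions))):
            torsions.append(
                (phi0 + rng.normal(0.0, 8.0), psi0 + rng.normal(0.0, 8.0))
            )
            kinds.append(kind)
    return torsions, kinds


def _sample_sequence(
    torsions: list[tuple[float, float]],
    ca_coords: np.ndarray,
    coupling: float,
    rng: np.random.Generator,
) -> list[str]:
    n = len(torsions)
    if coupling == 0.0:
        return [AMINO_ACIDS[k] for k in rng.integers(0, len(AMINO_ACIDS), n)]
    # burial proxy: CA contact number, standardised over the chain
    d = np.linalg.norm(ca_coords[:, None, :] - ca_coords[None, :, :], axis=-1)
    contacts = ((d < 8.0).sum(axis=1) - 1).astype(float)
    z = (contacts - contacts.mean()) / (contacts.std() + 1e-9)
    cfg = DescriptorConfig()
    hydro = np.array([HYDROPATHY[aa] for aa in AMINO_ACIDS])
    helix = np.array([HELIX_PREFERENCE[aa] for aa in AMINO_ACIDS])
    seq: list[str] = []
    for i in range(n):
        is_helical = cfg.torsion_domain(*torsions[i]) == "helical"
        logw = coupling * (2.0 * hydro * z[i] + 1.5 * helix * float(is_helical))
        w = np.exp(logw - logw.max())
        w /= w.sum()
        seq.append(AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=w)])
    return seq


def generate_structures(spec: SyntheticSpec) -> list[ProteinStructure]:
    """A reproducible corpus of single-chain synthetic structures."""
    rng = np.random.default_rng([spec.seed, 0])
    out: list[ProteinStructure] = []
    lo, hi = spec.chain_length_range
    for k in range(spec.n_structures):
        n_res = int(rng.integers(lo, hi + 1))
        torsions, _ = _sample_torsions(n_res, rng)
        backbone = build_backbone(torsions)
        ca = np.array([r["CA"] for r in backbone])
        seq = _sample_sequence(torsions, ca, spec.coupling, rng)
        residues = []
        for i, (aa, atoms) in enumerate(zip(seq, backbone)):
            atom_dict = {k2: v.copy() for k2, v in atoms.items()}
            # every residue type (glycine included) carries the same pseudo
            # side-chain atom, so structure elements cannot leak residue
            # identity: at coupling 0, sequence and structure are exactly
            # independent
            atom_dict["CB"] = _pseudo_cb(atoms)
            residues.append(Residue(aa=aa, author_number=str(i + 1), atoms=atom_dict))
        tm = (
            float(rng.uniform(*spec.tm_range)) if spec.tm_range is not None else None
        )
        out.append(
            ProteinStructure(
                id=f"SYN{k:04d}", chain="A", residues=residues,
                resolution=1.8, tm=tm,
            )
        )
    return out


def extended_tripeptide_max_asa(
    config: DescriptorConfig | None = None,
) -> dict[str, float]:
    """Per-amino-acid maximal ASA computed on the package's own extended
    Gly-X-Gly reference conformation (with the pseudo-CB side chain).

    Useful as a self-consistent RSA reference for synthetic structures,
    whose residues carry no full side chains.
    """
    from .structures import _residue_sasa

    config = config or DescriptorConfig()
    backbone = build_backbone([(-120.0, 140.0)] * 3)
    out: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        residues = []
        for i, res_aa in enumerate(("G", aa, "G")):
            atoms = {k: v.copy() for k, v in backbone[i].items()}
            atoms["CB"] = _pseudo_cb(backbone[i])
            residues.append(Residue(aa=res_aa, author_number=str(i + 1), atoms=atoms))
        st = ProteinStructure(id=f"REF_{aa}", chain="A", residues=residues)
        out[aa] = float(_residue_sasa(st, config)[1])
    return out


_SYNTH_CONFIG: DescriptorConfig | None = None


def synthetic_descriptor_config() -> DescriptorConfig:
    """Descriptor configuration matched to the synthetic structures.

    Identical to the default except that the RSA reference areas are
    computed on the generator's own extended Gly-X-Gly conformation (with
    the pseudo side chain), so a fully exposed synthetic residue scores
    100% regardless of residue type.  With this reference the relative
    accessibility of a synthetic residue is exactly independent of its
    amino acid, which the coupling = 0 independence checks rely on.
    """
    global _SYNTH_CONFIG
    if _SYNTH_CONFIG is None:
        base = DescriptorConfig()
        _SYNTH_CONFIG = base.with_max_asa(extended_tripeptide_max_asa(base))
    return _SYNTH_CONFIG


def default_truth_hot() -> HotParams:
    """A fixed, plausible planted parameter set for the Tm-free model."""
    phis = [1.2, -0.8, 0.9, -0.5, 1.5, -1.0, 0.7, -0.6, 0.8]
    rs = [-0.8, 0.5, -0.6, 0.4, -1.2, 0.7, -0.5, 0.3, -0.4]
    weights = [SigmoidWeight(p, r, 0.1, 40.0) for p, r in zip(phis, rs)]
    weights.append(SigmoidWeight(-0.015, -0.020, 0.08, 30.0))  # dv_plus
    weights.append(SigmoidWeight(-0.020, 0.015, 0.08, 40.0))   # dv_minus
    weights.append(SigmoidWeight(-1.0, 1.2, 0.1, 50.0))        # independent
    return HotParams(weights=weights, a=60.0, c=-0.5)


def flat_truth_hot() -> HotParams:
    """A planted Tm-free parameter set with accessibility-independent
    (flat) weights; the resulting targets are linear in the features, so
    noiseless training can recover them essentially exactly."""
    phis = [1.2, -0.8, 0.9, -0.5, 1.5, -1.0, 0.7, -0.6, 0.8,
            -0.020, -0.025, -0.8]
    weights = [SigmoidWeight(p, 0.0, 0.0, 50.0) for p in phis]
    return HotParams(weights=weights, a=60.0, c=-0.5)


def default_truth_tmhot() -> TmHotParams:
    """A fixed planted parameter set for the Tm-aware model: mesostable
    terms dominate at low wild-type Tm, thermostable terms at high Tm."""
    meso = [SigmoidWeight(p, r, 0.1, 40.0)
            for p, r in zip([1.0, -0.7, 0.8, -0.9, 0.6], [-0.5, 0.4, -0.3, 0.5, -0.4])]
    thermo = [SigmoidWeight(p, r, 0.1, 40.0)
              for p, r in zip([-0.6, 0.9, -0.5, 0.7, -0.8], [0.3, -0.4, 0.5, -0.3, 0.4])]
    vol_ind = [
        SigmoidWeight(-0.9, -1.2, 0.08, 30.0),
        SigmoidWeight(-1.2, 0.9, 0.08, 40.0),
        SigmoidWeight(-40.0, 48.0, 0.1, 50.0),
    ]
    return TmHotParams(
        meso_weights=meso, thermo_weights=thermo, vol_ind_weights=vol_ind,
        f_meso=PolyFactor((2.0, -0.02, 0.0, 0.0, 0.0)),
        f_thermo=PolyFactor((-0.5, 0.02, 0.0, 0.0, 0.0)),
        f_vol=PolyFactor((0.02, 0.0, 0.0, 1.5, 0.0)),
    )


def generate_mutation_dataset(
    structures: list[ProteinStructure | StructureData],
    truth: HotParams | TmHotParams,
    standard: PotentialSet,
    meso: PotentialSet | None = None,
    thermo: PotentialSet | None = None,
    spec: SyntheticSpec | None = None,
    config: DescriptorConfig | None = None,
    n_dtm_outliers: int = 0,
) -> list[tuple[MutationRecord, FeatureVector]]:
    """Planted-model mutation dataset over a structure corpus.

    Each record's experimental dTm is the planted model's prediction on
    the true features plus Gaussian noise of sd ``spec.noise_sd``; metadata
    flags are set so that the curation filters keep every record, except
    for ``n_dtm_outliers`` extra records whose |dTm| is forced to 25 deg C.
    """
    spec = spec or SyntheticSpec()
    config = config or DescriptorConfig()
    rng = np.random.default_rng([spec.seed, 1])
    data = [
        s if isinstance(s, StructureData) else structure_arrays(s, config)
        for s in structures
    ]
    needs_tm = isinstance(truth, TmHotParams)
    out: list[tuple[MutationRecord, FeatureVector]] = []
    total = spec.n_mutations + n_dtm_outliers
    for k in range(total):
        sd = data[int(rng.integers(0, len(data)))]
        pos = int(rng.integers(0, sd.n_res))
        wt = sd.structure.residues[pos].aa
        mut = AMINO_ACIDS[int(rng.integers(0, len(AMINO_ACIDS)))]
        while mut == wt:
            mut = AMINO_ACIDS[int(rng.integers(0, len(AMINO_ACIDS)))]
        record = MutationRecord(
            protein_id=sd.structure.id,
            chain=sd.structure.chain,
            position=sd.structure.residues[pos].author_number,
            wt_aa=wt,
            mut_aa=mut,
            tm_wild=sd.structure.tm,
            ph=7.0,
            resolution=sd.structure.resolution,
        )
        vec = featurize(sd, record, standard, meso=meso, thermo=thermo, config=config)
        if needs_tm:
            clean = predict_tm_hot(truth, vec)
        else:
            clean = predict_hot(truth, vec)
        noisy = clean + float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else clean
        if k >= spec.n_mutations:
            noisy = 25.0 * float(rng.choice([-1.0, 1.0]))
        record.dtm_exp = float(noisy)
        out.append((record, vec))
    return out


def write_corpus(
    structures: list[ProteinStructure], out_dir: str | Path
) -> None:
    """Write a corpus as PDB files plus a Tm annotation table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for st in structures:
        write_pdb(st, out_dir / f"{st.id}.pdb")
        rows.append((st.id, st.chain, st.tm))
    with open(out_dir / "tm_table.tsv", "w") as fh:
        fh.write("protein_id\tchain\ttm\n")
        for pid, chain, tm in rows:
            fh.write(f"{pid}\t{chain}\t{'' if tm is None else round(tm, 2)}\n")
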