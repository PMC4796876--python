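"""From one point mutation on a wild-type structure to a model input vector.

The mutant structure is assumed identical to the wild type: a mutation
only changes the sequence element at the mutated position, so the change
in a statistical-potential energy, ddW = W(mut) - W(wild), reduces to the
few table lookups whose sequence-element tuple touches that position.
Packing effects of the substitution are carried separately by the
Heaviside-split residue volume difference (dV+, dV-).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import AA_INDEX, AMINO_ACIDS, RESIDUE_VOLUME
from .potentials import ELEMENT_SPECS, Potential, PotentialSet, STANDARD_FORMS, TDEP_ORDER
from .structures import DescriptorConfig, ProteinStructure, StructureData, structure_arrays

#: Canonical column order of the full per-mutation feature frame.
FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(f"ddw_{f}" for f in STANDARD_FORMS)
    + tuple(f"ddw_meso_{g}" for g in TDEP_ORDER)
    + tuple(f"ddw_thermo_{g}" for g in TDEP_ORDER)
    + ("dv_plus", "dv_minus", "rsa", "n_res", "tm_wild")
)

HOT_FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(f"ddw_{f}" for f in STANDARD_FORMS)
    + ("dv_plus", "dv_minus", "rsa", "n_res")
)

TMHOT_FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(f"ddw_meso_{g}" for g in TDEP_ORDER)
    + tuple(f"ddw_thermo_{g}" for g in TDEP_ORDER)
    + ("dv_plus", "dv_minus", "rsa", "n_res", "tm_wild")
)


@dataclass
class MutationRecord:
    """One single-point mutation with its experimental context."""

    protein_id: str
    chain: str
    position: str
    wt_aa: str
    mut_aa: str
    dtm_exp: float | None = None
    tm_wild: float | None = None
    ph: float | None = None
    resolution: float | None = None
    monomeric: bool = True
    no_denaturants: bool = True
    two_state: bool = True
    n_substitutions: int = 1
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position = str(self.position).strip()
        for aa, label in ((self.wt_aa, "wild-type"), (self.mut_aa, "mutant")):
            if aa not in AA_INDEX:
                raise ValueError(f"unknown {label} amino acid {aa!r}")
        if self.dtm_exp is not None and not np.isfinite(self.dtm_exp):
            raise ValueError("experimental dTm must be finite")

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (self.protein_id, self.chain, self.position, self.wt_aa, self.mut_aa)


@dataclass
class FeatureVector:
    """Model inputs for one mutation (ddW in kT, volumes in A^3, A in %)."""

    ddw_std: np.ndarray                  # 9 values, STANDARD_FORMS order
    dv_plus: float
    dv_minus: float
    rsa: float
    n_res: int
    ddw_meso: np.ndarray | None = None   # 5 values, TDEP_ORDER
    ddw_thermo: np.ndarray | None = None
    tm_wild: float | None = None

    def to_series(self) -> pd.Series:
        vals: dict[str, float] = {}
        for name, v in zip((f"ddw_{f}" for f in STANDARD_FORMS), self.ddw_std):
            vals[name] = float(v)
        meso = self.ddw_meso if self.ddw_meso is not None else [np.nan] * 5
        thermo = self.ddw_thermo if self.ddw_thermo is not None else [np.nan] * 5
        for name, v in zip((f"ddw_meso_{g}" for g in TDEP_ORDER), meso):
            vals[name] = float(v)
        for name, v in zip((f"ddw_thermo_{g}" for g in TDEP_ORDER), thermo):
            vals[name] = float(v)
        vals["dv_plus"] = self.dv_plus
        vals["dv_minus"] = self.dv_minus
        vals["rsa"] = self.rsa
        vals["n_res"] = float(self.n_res)
        vals["tm_wild"] = np.nan if self.tm_wild is None else float(self.tm_wild)
        return pd.Series(vals, index=list(FEATURE_COLUMNS))


def feature_table(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame([v.to_series() for v in vectors])


def volume_terms(wt_aa: str, mut_aa: str) -> tuple[float, float]:
    """Heaviside-split residue volume difference dV = V(mut) - V(wt).

    Returns (dv_plus, dv_minus), both non-negative, exactly one of them
    nonzero unless dV = 0: dv_plus carries added packing stress, dv_minus
    the created cavity volume.
    """
    for aa in (wt_aa, mut_aa):
        if aa not in RESIDUE_VOLUME:
            raise ValueError(f"unknown amino acid {aa!r}")
    dv = RESIDUE_VOLUME[mut_aa] - RESIDUE_VOLUME[wt_aa]
    return (max(dv, 0.0), max(-dv, 0.0))


def _delta_component(
    pot: Potential, sd: StructureData, p: int, wt: int, mut: int
) -> float:
    spec = ELEMENT_SPECS[pot.form]
    E = pot.energy
    if spec.mode == "residue":
        idx_wt: list[int] = []
        idx_mut: list[int] = []
        for e in spec.elements:
            if e.kind == "aa":
                idx_wt.append(wt)
                idx_mut.append(mut)
            else:
                v = int(sd.acc_bin[p] if e.kind == "acc" else sd.tor_idx[p])
                if v < 0:
                    return 0.0
                idx_wt.append(v)
                idx_mut.append(v)
        return float(E[tuple(idx_mut)] - E[tuple(idx_wt)])

    if len(sd.pairs) == 0:
        return 0.0
    mask = (sd.pairs[:, 0] == p) | (sd.pairs[:, 1] == p)
    total = 0.0
    for i, j, db in sd.pairs[mask]:
        for first, second in ((i, j), (j, i)):
            idx_wt, idx_mut = [], []
            changed = False
            ok = True
            for e in spec.elements:
                if e.kind == "dist":
                    idx_wt.append(int(db))
                    idx_mut.append(int(db))
                    continue
                who = first if e.role == "self" else second
                if e.kind == "aa":
                    if who == p:
                        idx_wt.append(wt)
                        idx_mut.append(mut)
                        changed = True
                    else:
                        v = int(sd.aa_idx[who])
                        idx_wt.append(v)
                        idx_mut.append(v)
                else:
                    v = int(sd.acc_bin[who] if e.kind == "acc" else sd.tor_idx[who])
                    if v < 0:
                        ok = False
                        break
                    idx_wt.append(v)
                    idx_mut.append(v)
            if ok and changed:
                total += float(E[tuple(idx_mut)] - E[tuple(idx_wt)])
    return total


def mutation_delta_energy(
    potentials: PotentialSet,
    sd: StructureData,
    index: int,
    wt_aa: str,
    mut_aa: str,
) -> dict[str, float]:
    """Per-potential ddW for substituting ``mut_aa`` at residue ``index``.

    Structure elements are those of the wild-type structure; grouped
    (temperature-dependent) potentials sum the deltas of their components.
    """
    wt = AA_INDEX[wt_aa]
    mut = AA_INDEX[mut_aa]
    if sd.aa_idx[index] != wt:
        raise ValueError(
            f"wild-type mismatch at position "
            f"{sd.structure.residues[index].author_number}: structure has "
            f"{AMINO_ACIDS[sd.aa_idx[index]]}, mutation says {wt_aa}"
        )
    return {
        pid: sum(_delta_component(pot, sd, index, wt, mut) for pot in comps)
        for pid, comps in potentials.potentials.items()
    }


def total_energy(potentials: PotentialSet, sd: StructureData,
                 aa_override: tuple[int, int] | None = None) -> dict[str, float]:
    """Sum of all counted contributions per potential; brute-force path used
    to verify the cancellation property of :func:`mutation_delta_energy`."""
    aa = sd.aa_idx.copy()
    if aa_override is not None:
        aa[aa_override[0]] = aa_override[1]
    out: dict[str, float] = {}
    for pid, comps in potentials.potentials.items():
        acc = 0.0
        for pot in comps:
            spec = ELEMENT_SPECS[pot.form]
            E = pot.energy
            if spec.mode == "residue":
                for p in range(sd.n_res):
                    idx = []
                    ok = True
                    for e in spec.elements:
                        v = {
                            "aa": int(aa[p]),
                            "acc": int(sd.acc_bin[p]),
                            "tor": int(sd.tor_idx[p]),
                        }[e.kind]
                        if v < 0:
                            ok = False
                            break
                        idx.append(v)
                    if ok:
                        acc += float(E[tuple(idx)])
            else:
                for i, j, db in sd.pairs:
                    for first, second in ((i, j), (j, i)):
                        idx = []
                        ok = True
                        for e in spec.elements:
                            if e.kind == "dist":
                                idx.append(int(db))
                                continue
                            who = first if e.role == "self" else second
                            v = {
                                "aa": int(aa[who]),
                                "acc": int(sd.acc_bin[who]),
                                "tor": int(sd.tor_idx[who]),
                            }[e.kind]
                            if v < 0:
                                ok = False
                                break
                            idx.append(v)
                        if ok:
                            acc += float(E[tuple(idx)])
        out[pid] = acc
    return out


def featurize(
    structure: ProteinStructure | StructureData,
    mutation: MutationRecord,
    standard: PotentialSet,
    meso: PotentialSet | None = None,
    thermo: PotentialSet | None = None,
    config: DescriptorConfig | None = None,
) -> FeatureVector:
    """Assemble the full feature vector for one mutation.

    All supplied potential sets must have been derived under the same
    descriptor configuration as the structure view.
    """
    config = config or DescriptorConfig()
    sd = (
        structure
        if isinstance(structure, StructureData)
        else structure_arrays(structure, config)
    )
    for potset in (standard, meso, thermo):
        if potset is not None and potset.config_hash != sd.config_hash:
            raise ValueError(
                f"potential set {potset.name!r} was derived under a different "
                "descriptor configuration than the structure"
            )
    p = sd.structure.index_of_author_position(mutation.position)
    ddw_std = mutation_delta_energy(standard, sd, p, mutation.wt_aa, mutation.mut_aa)
    dv_plus, dv_minus = volume_terms(mutation.wt_aa, mutation.mut_aa)
    vec = FeatureVector(
        ddw_std=np.array([ddw_std[f] for f in STANDARD_FORMS]),
        dv_plus=dv_plus,
        dv_minus=dv_minus,
        rsa=float(sd.rsa[p]),
        n_res=sd.n_res,
        tm_wild=mutation.tm_wild,
    )
    if meso is not None:
        d = mutation_delta_energy(meso, sd, p, mutation.wt_aa, mutation.mut_aa)
        vec.ddw_meso = np.array([d[g] for g in TDEP_ORDER])
    if thermo is not None:
        d = mutation_delta_energy(thermo, sd, p, mutation.wt_aa, mutation.mut_aa)
        vec.ddw_thermo = np.array([d[g] for g in TDEP_ORDER])
    return vec


_TSV_COLUMNS = (
    "protein_id", "chain", "position", "wt", "mut",
    "dtm_exp", "tm_wild", "ph", "resolution",
    "monomeric", "no_denaturants", "two_state", "n_substitutions",
)


def mutations_to_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            "protein_id": r.protein_id, "chain": r.chain, "position": r.position,
            "wt": r.wt_aa, "mut": r.mut_aa, "dtm_exp": r.dtm_exp,
            "tm_wild": r.tm_wild, "ph": r.ph, "resolution": r.resolution,
            "monomeric": int(r.monomeric), "no_denaturants": int(r.no_denaturants),
            "two_state": int(r.two_state), "n_substitutions": r.n_substitutions,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"position": str})
    records = []
    for _, row in df.iterrows():
        def _opt(name: str) -> float | None:
            v = row.get(name)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        records.append(
            MutationRecord(
                protein_id=str(row["protein_id"]),
                chain=str(row["chain"]),
                position=str(row["position"]),
                wt_aa=str(row["wt"]),
                mut_aa=str(row["mut"]),
                dtm_exp=_opt("dtm_exp"),
                tm_wild=_opt("tm_wild"),
                ph=_opt("ph"),
                resolution=_opt("resolution"),
                monomeric=bool(int(row.get("monomeric", 1))),
                no_denaturants=bool(int(row.get("no_denaturants", 1))),
                two_state=bool(int(row.get("two_state", 1))),
                n_substitutions=int(row.get("n_substitutions", 1)),
            )
        )
    return records
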