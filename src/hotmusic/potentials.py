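"""Knowledge-based mean-force potentials from structure corpora.

A statistical potential assigns an effective energy (in kT units, with
kT = 1) to an association of sequence elements ``s`` (amino-acid types)
and structure elements ``c`` (binned centroid distance ``d``, accessibility
bin ``a``, torsion domain ``t``), from the log-ratio of its observed to
expected frequency in a set of X-ray structures:

    two elements     W(x, y)    = -ln[ F(x,y) / (F(x) F(y)) ]
    three elements   W(x, y, z) = -ln[ F(x,y,z) F(x) F(y) F(z)
                                       / (F(x,y) F(x,z) F(y,z)) ]

Frequencies are shrunk toward independence with a pseudocount before the
log is taken, and distance-resolved potentials are smoothed along the
distance axis with an edge-renormalised triangular window.

Nine standard forms are extracted (sd, sds, sad, std, sa, saa, st, stt,
sst).  Temperature-dependent sets are derived by splitting a Tm-annotated
corpus at a mesostable/thermostable threshold and grouping the forms into
five potentials per subset ({sd}, {sds}, {sad}, {sa+saa}, {st+stt+sst});
the std form carries no temperature-dependent counterpart.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import reduce
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .constants import AMINO_ACIDS
from .structures import DescriptorConfig, ProteinStructure, StructureData, structure_arrays

#: The nine temperature-independent potential forms, fixed order.
STANDARD_FORMS: tuple[str, ...] = (
    "sd", "sds", "sad", "std", "sa", "saa", "st", "stt", "sst",
)

#: Grouping of forms into the five temperature-dependent potentials.
TDEP_GROUPS: dict[str, tuple[str, ...]] = {
    "sd": ("sd",),
    "sds": ("sds",),
    "sad": ("sad",),
    "acc": ("sa", "saa"),
    "tor": ("st", "stt", "sst"),
}

TDEP_ORDER: tuple[str, ...] = ("sd", "sds", "sad", "acc", "tor")

DEFAULT_PSEUDOCOUNT = 10.0
DEFAULT_SMOOTH_HALF_WIDTH = 2


@dataclass(frozen=True)
class Element:
    kind: str   # "aa" | "acc" | "tor" | "dist"
    role: str   # "self" | "partner" | "pair"


@dataclass(frozen=True)
class ElementSpec:
    """What gets counted for one potential form.

    ``mode == "residue"`` iterates single residues; ``mode == "pair"``
    iterates every in-range residue pair in both ordered directions, so a
    pair-type form contributes two counts per geometric pair.
    """

    form: str
    mode: str
    elements: tuple[Element, ...]

    def axis_kinds(self) -> tuple[str, ...]:
        return tuple(e.kind for e in self.elements)


ELEMENT_SPECS: dict[str, ElementSpec] = {
    "sd": ElementSpec("sd", "pair", (Element("aa", "self"), Element("dist", "pair"))),
    "sds": ElementSpec(
        "sds", "pair",
        (Element("aa", "self"), Element("dist", "pair"), Element("aa", "partner")),
    ),
    "sad": ElementSpec(
        "sad", "pair",
        (Element("aa", "self"), Element("acc", "self"), Element("dist", "pair")),
    ),
    "std": ElementSpec(
        "std", "pair",
        (Element("aa", "self"), Element("tor", "self"), Element("dist", "pair")),
    ),
    "sa": ElementSpec("sa", "residue", (Element("aa", "self"), Element("acc", "self"))),
    "saa": ElementSpec(
        "saa", "pair",
        (Element("aa", "self"), Element("acc", "self"), Element("acc", "partner")),
    ),
    "st": ElementSpec("st", "residue", (Element("aa", "self"), Element("tor", "self"))),
    "stt": ElementSpec(
        "stt", "pair",
        (Element("aa", "self"), Element("tor", "self"), Element("tor", "partner")),
    ),
    "sst": ElementSpec(
        "sst", "pair",
        (Element("aa", "self"), Element("aa", "partner"), Element("tor", "partner")),
    ),
}


def axis_size(kind: str, config: DescriptorConfig) -> int:
    if kind == "aa":
        return len(AMINO_ACIDS)
    if kind == "acc":
        return config.n_acc_bins
    if kind == "tor":
        return len(config.torsion_labels)
    if kind == "dist":
        return config.n_distance_bins
    raise ValueError(f"unknown element kind {kind!r}")


@dataclass
class FrequencyTable:
    """Joint occurrence counts over the binned element tuple of one form."""

    spec: ElementSpec
    counts: np.ndarray

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def marginal(self, axes: Sequence[int]) -> np.ndarray:
        """Marginal counts keeping ``axes`` (in their original order)."""
        drop = tuple(a for a in range(self.counts.ndim) if a not in axes)
        return self.counts.sum(axis=drop) if drop else self.counts

    def check_marginal_consistency(self) -> None:
        total = self.total
        for k in range(self.counts.ndim):
            assert np.isclose(self.marginal([k]).sum(), total)


def _element_values(
    sd: StructureData,
    element: Element,
    first: np.ndarray,
    second: np.ndarray,
    dbin: np.ndarray,
) -> np.ndarray:
    who = first if element.role == "self" else second
    if element.kind == "aa":
        return sd.aa_idx[who]
    if element.kind == "acc":
        return sd.acc_bin[who]
    if element.kind == "tor":
        return sd.tor_idx[who]
    if element.kind == "dist":
        return dbin
    raise ValueError(element.kind)


def count_frequencies(
    structures: Iterable[ProteinStructure | StructureData],
    spec: ElementSpec | str,
    config: DescriptorConfig | None = None,
) -> FrequencyTable:
    """Accumulate joint counts of one element spec over a structure set.

    Residues with an undefined element (e.g. terminal torsions) are skipped
    for the specs that need them.  Accepts parsed structures or
    pre-computed :class:`StructureData` views.
    """
    config = config or DescriptorConfig()
    if isinstance(spec, str):
        spec = ELEMENT_SPECS[spec]
    data = [
        s if isinstance(s, StructureData) else structure_arrays(s, config)
        for s in structures
    ]
    if not data:
        raise ValueError("empty structure list")
    shape = tuple(axis_size(k, config) for k in spec.axis_kinds())
    counts = np.zeros(shape, dtype=float)
    for sd in data:
        if spec.mode == "residue":
            n = sd.n_res
            first = np.arange(n)
            second = first
            dbin = np.zeros(n, dtype=np.int64)
            _accumulate(counts, sd, spec, first, second, dbin)
        else:
            if len(sd.pairs) == 0:
                continue
            i, j, db = sd.pairs[:, 0], sd.pairs[:, 1], sd.pairs[:, 2]
            # both ordered directions of every geometric pair
            _accumulate(counts, sd, spec, i, j, db)
            _accumulate(counts, sd, spec, j, i, db)
    return FrequencyTable(spec=spec, counts=counts)


def _accumulate(
    counts: np.ndarray,
    sd: StructureData,
    spec: ElementSpec,
    first: np.ndarray,
    second: np.ndarray,
    dbin: np.ndarray,
) -> None:
    idx = [_element_values(sd, e, first, second, dbin) for e in spec.elements]
    valid = reduce(np.logical_and, (v >= 0 for v in idx))
    if not valid.all():
        idx = [v[valid] for v in idx]
    np.add.at(counts, tuple(idx), 1.0)


def sparse_correct(raw_ratio: float | np.ndarray, n_eff: float | np.ndarray,
                   n0: float = DEFAULT_PSEUDOCOUNT):
    """Shrink a frequency ratio toward 1 when observations are few.

    ``(n_eff * raw_ratio + n0) / (n_eff + n0)``: with no data the corrected
    ratio is exactly 1 (zero energy); with abundant data it approaches the
    raw ratio.
    """
    return (n_eff * raw_ratio + n0) / (n_eff + n0)


def expected_counts(freq: FrequencyTable) -> np.ndarray:
    """Per-cell expected counts under the no-association null.

    Two elements: m(x) m(y) / N.  Three elements: the no-three-way-
    interaction expectation P(xy) P(xz) P(yz) N / (m(x) m(y) m(z)).
    Cells whose single marginals vanish get expectation zero.
    """
    J = freq.counts
    N = freq.total
    if N <= 0:
        raise ValueError("frequency table is empty")
    k = J.ndim
    if k == 2:
        m0 = freq.marginal([0])
        m1 = freq.marginal([1])
        return m0[:, None] * m1[None, :] / N
    if k == 3:
        m = [freq.marginal([a]) for a in range(3)]
        p01 = freq.marginal([0, 1])
        p02 = freq.marginal([0, 2])
        p12 = freq.marginal([1, 2])
        num = p01[:, :, None] * p02[:, None, :] * p12[None, :, :] * N
        den = (
            m[0][:, None, None]
            * m[1][None, :, None]
            * m[2][None, None, :]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return lam
    raise ValueError("only 2- and 3-element potentials are supported")


def energy_table(freq: FrequencyTable, n0: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Mean-force energies (kT) for every cell of a frequency table.

    The observed/expected ratio is shrunk toward 1 by ``sparse_correct``
    with the expected count as the effective observation number, so
    ``n_eff * raw_ratio`` is simply the observed count:
    corrected ratio = (n + n0) / (lambda + n0).
    """
    J = freq.counts
    lam = expected_counts(freq)
    if n0 > 0:
        corrected = (J + n0) / (lam + n0)
    else:
        # plain log-ratio; cells without data carry zero energy
        corrected = np.ones_like(J)
        pos = J > 0
        corrected[pos] = J[pos] / lam[pos]
    assert np.isfinite(corrected).all() and (corrected > 0).all()
    return -np.log(corrected)


def pmf_pair(freq: FrequencyTable, c_value: int, s_value: int,
             n0: float = 0.0) -> float:
    """Energy of one (element, element) cell; ``n0 = 0`` disables shrinkage."""
    if freq.counts.ndim != 2:
        raise ValueError("pmf_pair needs a 2-element frequency table")
    return float(energy_table(freq, n0=n0)[c_value, s_value])


def pmf_higher(freq: FrequencyTable, *values: int, n0: float = 0.0) -> float:
    """Energy of one 3-element cell (joint x singles / pairs factorisation)."""
    if freq.counts.ndim != 3:
        raise ValueError("pmf_higher needs a 3-element frequency table")
    return float(energy_table(freq, n0=n0)[tuple(values)])


def smooth_distance_axis(
    energies: np.ndarray,
    axis: int,
    half_width: int = DEFAULT_SMOOTH_HALF_WIDTH,
) -> np.ndarray:
    """Edge-renormalised triangular smoothing along one axis."""
    if half_width <= 0:
        return energies
    w = np.array(
        [half_width + 1 - abs(k) for k in range(-half_width, half_width + 1)],
        dtype=float,
    )
    w /= w.sum()
    num = convolve1d(energies, w, axis=axis, mode="constant", cval=0.0)
    den = convolve1d(np.ones_like(energies), w, axis=axis, mode="constant", cval=0.0)
    return num / den


@dataclass
class Potential:
    form: str
    axes: tuple[str, ...]
    energy: np.ndarray
    n_observations: float


@dataclass
class PotentialSet:
    """A named bundle of derived potentials.

    ``potentials`` maps a potential id to the tuple of component tables it
    groups; standard sets have one component per id, temperature-dependent
    sets group up to three forms whose mutation energies are summed.
    """

    name: str
    potentials: dict[str, tuple[Potential, ...]]
    config_hash: str
    provenance: dict

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.potentials)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "config_hash": self.config_hash,
            "provenance": self.provenance,
            "potentials": {
                pid: [
                    {
                        "form": p.form,
                        "axes": list(p.axes),
                        "shape": list(p.energy.shape),
                        "energy": p.energy.ravel().tolist(),
                        "n_observations": p.n_observations,
                    }
                    for p in comps
                ]
                for pid, comps in self.potentials.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PotentialSet":
        payload = json.loads(Path(path).read_text())
        pots = {
            pid: tuple(
                Potential(
                    form=d["form"],
                    axes=tuple(d["axes"]),
                    energy=np.asarray(d["energy"], dtype=float).reshape(d["shape"]),
                    n_observations=d["n_observations"],
                )
                for d in comps
            )
            for pid, comps in payload["potentials"].items()
        }
        return cls(
            name=payload["name"],
            potentials=pots,
            config_hash=payload["config_hash"],
            provenance=payload["provenance"],
        )


def _structure_fingerprint(structures: Sequence[ProteinStructure | StructureData]) -> str:
    parts = []
    for s in structures:
        st = s.structure if isinstance(s, StructureData) else s
        parts.append(f"{st.id}:{st.chain}:{st.n_res}")
    return hashlib.md5("|".join(parts).encode()).hexdigest()


def _derive_forms(
    data: Sequence[StructureData],
    forms: Sequence[str],
    config: DescriptorConfig,
    n0: float,
    smooth_half_width: int,
) -> dict[str, Potential]:
    out: dict[str, Potential] = {}
    for form in forms:
        spec = ELEMENT_SPECS[form]
        freq = count_frequencies(data, spec, config)
        freq.check_marginal_consistency()
        energy = energy_table(freq, n0=n0)
        kinds = spec.axis_kinds()
        if "dist" in kinds:
            energy = smooth_distance_axis(
                energy, axis=kinds.index("dist"), half_width=smooth_half_width
            )
        out[form] = Potential(
            form=form, axes=kinds, energy=energy, n_observations=freq.total
        )
    return out


def _as_data(
    structures: Sequence[ProteinStructure | StructureData], config: DescriptorConfig
) -> list[StructureData]:
    return [
        s if isinstance(s, StructureData) else structure_arrays(s, config)
        for s in structures
    ]


def derive_standard_potentials(
    structures: Sequence[ProteinStructure | StructureData],
    config: DescriptorConfig | None = None,
    n0: float = DEFAULT_PSEUDOCOUNT,
    smooth_half_width: int = DEFAULT_SMOOTH_HALF_WIDTH,
) -> PotentialSet:
    """Derive the nine temperature-independent potentials from a corpus."""
    config = config or DescriptorConfig()
    if not structures:
        raise ValueError("empty structure list")
    data = _as_data(structures, config)
    forms = _derive_forms(data, STANDARD_FORMS, config, n0, smooth_half_width)
    return PotentialSet(
        name="standard",
        potentials={form: (forms[form],) for form in STANDARD_FORMS},
        config_hash=config.config_hash(),
        provenance={
            "structures": _structure_fingerprint(data),
            "n_structures": len(data),
            "n0": n0,
            "smooth_half_width": smooth_half_width,
        },
    )


def _derive_grouped(
    data: Sequence[StructureData],
    name: str,
    config: DescriptorConfig,
    n0: float,
    smooth_half_width: int,
) -> PotentialSet:
    needed = sorted({f for forms in TDEP_GROUPS.values() for f in forms})
    forms = _derive_forms(data, needed, config, n0, smooth_half_width)
    return PotentialSet(
        name=name,
        potentials={
            gid: tuple(forms[f] for f in TDEP_GROUPS[gid]) for gid in TDEP_ORDER
        },
        config_hash=config.config_hash(),
        provenance={
            "structures": _structure_fingerprint(data),
            "n_structures": len(data),
            "n0": n0,
            "smooth_half_width": smooth_half_width,
        },
    )


def derive_t_dependent_potentials(
    structures: Sequence[ProteinStructure | StructureData],
    tm_threshold: float = 65.0,
    config: DescriptorConfig | None = None,
    n0: float = DEFAULT_PSEUDOCOUNT,
    smooth_half_width: int = DEFAULT_SMOOTH_HALF_WIDTH,
) -> tuple[PotentialSet, PotentialSet]:
    """Split a Tm-annotated corpus at ``tm_threshold`` (deg C) and derive the
    five mesostable and five thermostable grouped potentials."""
    config = config or DescriptorConfig()
    data = _as_data(structures, config)
    for sd in data:
        if sd.structure.tm is None:
            raise ValueError(
                f"structure {sd.structure.id} has no Tm annotation; "
                "temperature-dependent potentials need one for every structure"
            )
    meso = [sd for sd in data if sd.structure.tm < tm_threshold]
    thermo = [sd for sd in data if sd.structure.tm >= tm_threshold]
    if not meso:
        raise ValueError(f"mesostable subset empty (no structure with Tm < {tm_threshold})")
    if not thermo:
        raise ValueError(f"thermostable subset empty (no structure with Tm >= {tm_threshold})")
    return (
        _derive_grouped(meso, "meso", config, n0, smooth_half_width),
        _derive_grouped(thermo, "thermo", config, n0, smooth_half_width),
    )


def max_abs_energy(potset: PotentialSet) -> float:
    """Largest |energy| over every cell of every table in a set."""
    return max(
        float(np.abs(p.energy).max())
        for comps in potset.potentials.values()
        for p in comps
    )
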