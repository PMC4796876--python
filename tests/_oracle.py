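"""Brute-force mean-force-potential oracle, independent of the package's
counting and energy machinery: plain Python dict counting over explicitly
enumerated element tuples, and direct -ln frequency ratios."""

from __future__ import annotations

import math
from collections import Counter

from hotmusic.structures import (
    DescriptorConfig,
    ProteinStructure,
    compute_descriptors,
    pair_distances,
)


def observations(structures: list[ProteinStructure], form: str,
                 config: DescriptorConfig) -> list[tuple]:
    """Element tuples counted for one potential form, enumerated by hand."""
    labels = {lab: k for k, lab in enumerate(config.torsion_labels)}
    obs: list[tuple] = []
    for st in structures:
        desc = compute_descriptors(st, config)
        pairs = pair_distances(desc, config)
        aa = [d.aa for d in desc]
        acc = [config.acc_bin(d.rsa) for d in desc]
        tor = [labels.get(d.torsion_domain, -1) for d in desc]
        if form == "sa":
            obs.extend((aa[i], acc[i]) for i in range(len(desc)))
        elif form == "st":
            obs.extend((aa[i], tor[i]) for i in range(len(desc)) if tor[i] >= 0)
        else:
            for p in pairs:
                for i, j in ((p.i, p.j), (p.j, p.i)):
                    d = p.distance_bin
                    if form == "sd":
                        obs.append((aa[i], d))
                    elif form == "sds":
                        obs.append((aa[i], d, aa[j]))
                    elif form == "sad":
                        obs.append((aa[i], acc[i], d))
                    elif form == "std":
                        if tor[i] >= 0:
                            obs.append((aa[i], tor[i], d))
                    elif form == "saa":
                        obs.append((aa[i], acc[i], acc[j]))
                    elif form == "stt":
                        if tor[i] >= 0 and tor[j] >= 0:
                            obs.append((aa[i], tor[i], tor[j]))
                    elif form == "sst":
                        if tor[j] >= 0:
                            obs.append((aa[i], aa[j], tor[j]))
                    else:
                        raise ValueError(form)
    return obs


def pmf_energy(obs: list[tuple], cell: tuple) -> float:
    """-ln frequency ratio for one cell, 2 or 3 elements, no correction."""
    n = len(obs)
    joint = Counter(obs)
    if joint[cell] == 0:
        return 0.0
    k = len(cell)
    singles = [Counter(o[a] for o in obs) for a in range(k)]
    if k == 2:
        ratio = joint[cell] * n / (singles[0][cell[0]] * singles[1][cell[1]])
    else:
        p01 = Counter((o[0], o[1]) for o in obs)
        p02 = Counter((o[0], o[2]) for o in obs)
        p12 = Counter((o[1], o[2]) for o in obs)
        num = (
            joint[cell]
            * singles[0][cell[0]]
            * singles[1][cell[1]]
            * singles[2][cell[2]]
        )
        den = (
            p01[(cell[0], cell[1])]
            * p02[(cell[0], cell[2])]
            * p12[(cell[1], cell[2])]
            * n
        )
        ratio = num / den
    return -math.log(ratio)
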