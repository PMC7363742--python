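"""Monte-Carlo gene dropping with Bernoulli-autozygous founder alleles.

Every replicate assigns each founder a pair of allele labels: with
probability equal to its assigned inbreeding coefficient ``f`` the founder
is *autozygous* and receives two copies of one fresh label, otherwise two
distinct fresh labels.  Labels are globally unique per replicate across
founders (founders mutually unrelated), and each nonfounder inherits one
uniformly chosen label from each parent.  IBD is label equality.  This is
the single-locus sampling model under which all exact coefficients in this
package are defined, so the simulator serves as an independent oracle for
every one of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .karigl import canonicalize_pattern
from .pedigree import Pedigree, PedigreeError, generation_index

__all__ = [
    "StateFrequencies",
    "GeneralizedEstimate",
    "drop_genes",
    "estimate_identity",
    "estimate_generalized",
]


def _simulate(ped: Pedigree, replicates: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorised gene drop: member id -> (replicates, 2) integer label array."""
    ped.check()
    if replicates < 1:
        raise ValueError("need at least one replicate")
    gen = generation_index(ped)
    order = sorted(ped.ids, key=lambda i: gen[i])
    alleles: dict[str, np.ndarray] = {}
    next_label = 0
    for mid in order:
        parents = ped.parents(mid)
        if parents is None:
            f = float(ped.founder_f(mid))
            pair = np.empty((replicates, 2), dtype=np.int64)
            pair[:, 0] = next_label
            if f == 0:
                pair[:, 1] = next_label + 1
            else:
                auto = rng.random(replicates) < f
                pair[:, 1] = np.where(auto, next_label, next_label + 1)
            next_label += 2
            alleles[mid] = pair
        else:
            father, mother = parents
            rows = np.arange(replicates)
            pat = alleles[father][rows, rng.integers(0, 2, replicates)]
            mat = alleles[mother][rows, rng.integers(0, 2, replicates)]
            alleles[mid] = np.column_stack([pat, mat])
    return alleles


def drop_genes(ped: Pedigree, replicates: int, seed: int) -> list[dict[str, tuple[int, int]]]:
    """Per-replicate allele assignments (member id -> ordered label pair)."""
    alleles = _simulate(ped, replicates, np.random.default_rng(seed))
    return [
        {mid: (int(arr[r, 0]), int(arr[r, 1])) for mid, arr in alleles.items()}
        for r in range(replicates)
    ]


@dataclass(frozen=True)
class StateFrequencies:
    """Observed condensed-state counts for a pair, over many replicates."""

    counts: np.ndarray  # shape (9,), Jacquard's state order
    replicates: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.replicates

    @property
    def standard_errors(self) -> np.ndarray:
        p = self.frequencies
        return np.sqrt(p * (1 - p) / self.replicates)


@dataclass(frozen=True)
class GeneralizedEstimate:
    estimate: float
    replicates: int

    @property
    def standard_error(self) -> float:
        p = self.estimate
        return float(np.sqrt(p * (1 - p) / self.replicates))


def _classify_states(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Condensed state (0-based) per replicate from the two label pairs."""
    a1, a2 = a[:, 0], a[:, 1]
    b1, b2 = b[:, 0], b[:, 1]
    aa = a1 == a2
    bb = b1 == b2
    m11, m12 = a1 == b1, a1 == b2
    m21, m22 = a2 == b1, a2 == b2
    share_any = m11 | m12 | m21 | m22
    two_pairs = (m11 & m22) | (m12 & m21)
    conditions = [
        aa & bb & m11,                      # 1: all four IBD
        aa & bb & ~m11,                     # 2
        aa & ~bb & share_any,               # 3
        aa & ~bb & ~share_any,              # 4
        ~aa & bb & share_any,               # 5
        ~aa & bb & ~share_any,              # 6
        ~aa & ~bb & two_pairs,              # 7
        ~aa & ~bb & share_any & ~two_pairs,  # 8
    ]
    return np.select(conditions, np.arange(8), default=8)


def estimate_identity(
    ped: Pedigree, a: str, b: str, replicates: int, seed: int
) -> StateFrequencies:
    """Estimate Delta_1..Delta_9 for (a, b) by gene dropping."""
    ped.member(a), ped.member(b)
    alleles = _simulate(ped, replicates, np.random.default_rng(seed))
    states = _classify_states(alleles[a], alleles[b])
    counts = np.bincount(states, minlength=9)
    return StateFrequencies(counts=counts, replicates=replicates)


def estimate_generalized(
    ped: Pedigree, pattern, replicates: int, seed: int
) -> GeneralizedEstimate:
    """Estimate a generalized kinship coefficient by gene dropping.

    One allele is sampled per pattern slot (with replacement within an
    individual); a replicate scores 1 when every group is label-constant.
    """
    groups = canonicalize_pattern(pattern)
    for g in groups:
        for mid in g:
            ped.member(mid)
    rng = np.random.default_rng(seed)
    alleles = _simulate(ped, replicates, rng)
    rows = np.arange(replicates)
    ok = np.ones(replicates, dtype=bool)
    for g in groups:
        first = None
        for mid in g:
            draw = alleles[mid][rows, rng.integers(0, 2, replicates)]
            if first is None:
                first = draw
            else:
                ok &= draw == first
    return GeneralizedEstimate(estimate=float(ok.mean()), replicates=replicates)
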