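"""Synthetic genotype tables with known allele frequencies.

The generator emulates the statistical structure the fingerprinting analysis
assumes: independent loci, Hardy-Weinberg random mating (allele copies drawn
i.i.d. from the locus frequency vector), and an optional small fraction of
triploid individuals drawing three copies instead of two.  Because the true
frequencies are known, every analytic quantity (PID, PIC, spectra) has a
Monte-Carlo counterpart to converge to, which makes the generator the oracle
for the formula implementations.

``empirical_match_probability`` is that oracle for PID: the exact fraction of
unordered individual pairs sharing a canonical genotype at all named loci.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import CultivarRecord, GenotypeCall, GenotypeTable

__all__ = ["PopulationSpec", "simulate_table", "empirical_match_probability"]


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a synthetic population.

    ``loci`` maps locus names to allele-frequency vectors keyed by allele
    size (bp); each vector must sum to 1.  ``triploid_fraction`` is the
    probability that an individual's call at a locus carries three allele
    copies (tea's rare triploid cultivars are the motivating case).
    """

    n_individuals: int
    loci: tuple[tuple[str, tuple[tuple[int, float], ...]], ...]
    triploid_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not 0.0 <= self.triploid_fraction < 1.0:
            raise ValueError("triploid_fraction must lie in [0, 1)")
        if not self.loci:
            raise ValueError("at least one locus is required")
        for name, freqs in self.loci:
            p = np.array([f for _, f in freqs], dtype=float)
            if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"locus {name}: frequencies must be positive and sum to 1")

    @classmethod
    def from_dict(
        cls,
        loci: dict[str, dict[int, float]],
        n_individuals: int,
        triploid_fraction: float = 0.0,
        seed: int = 0,
    ) -> "PopulationSpec":
        frozen = tuple(
            (name, tuple(sorted(freqs.items()))) for name, freqs in loci.items()
        )
        return cls(n_individuals, frozen, triploid_fraction, seed)

    @classmethod
    def from_json(cls, text: str) -> "PopulationSpec":
        """Load from the documented config schema::

            {"n_individuals": 100, "triploid_fraction": 0.03, "seed": 1,
             "loci": {"L1": {"100": 0.5, "104": 0.5}}}
        """
        obj = json.loads(text)
        loci = {
            name: {int(a): float(f) for a, f in freqs.items()}
            for name, freqs in obj["loci"].items()
        }
        return cls.from_dict(
            loci,
            int(obj["n_individuals"]),
            float(obj.get("triploid_fraction", 0.0)),
            int(obj.get("seed", 0)),
        )


def simulate_table(spec: PopulationSpec) -> GenotypeTable:
    """Draw a genotype table from ``spec``; reproducible for a fixed seed.

    Individuals are assigned codes 1..n and synthetic names; loci are drawn
    independently of each other, and triploid calls draw three independent
    allele copies from the same frequency vector (no meiotic model).
    """
    rng = np.random.default_rng(spec.seed)
    markers = [name for name, _ in spec.loci]
    calls: dict[tuple[int, str], GenotypeCall] = {}
    cultivars = [
        CultivarRecord(code=i, name=f"SYN{i:05d}", origin="synthetic")
        for i in range(1, spec.n_individuals + 1)
    ]
    for name, freq_items in spec.loci:
        alleles = np.array([a for a, _ in freq_items])
        p = np.array([f for _, f in freq_items], dtype=float)
        p = p / p.sum()
        ploidy = np.where(
            rng.random(spec.n_individuals) < spec.triploid_fraction, 3, 2
        )
        draws = rng.choice(alleles, size=(spec.n_individuals, 3), p=p)
        for i in range(spec.n_individuals):
            calls[(i + 1, name)] = GenotypeCall(tuple(int(a) for a in draws[i, : ploidy[i]]))
    return GenotypeTable(cultivars, markers, calls)


def empirical_match_probability(table: GenotypeTable, loci: Sequence[str]) -> float:
    """Fraction of unordered individual pairs with identical genotypes at all ``loci``.

    Equivalent to the exhaustive O(n^2) pair scan, computed by grouping
    identical multilocus genotypes and summing C(k, 2) per group.  This is the
    direct empirical estimator of the panel's probability of identity.
    """
    if table.n_cultivars < 2:
        raise ValueError("need at least two individuals")
    for locus in loci:
        if locus not in table.markers:
            raise KeyError(f"unknown locus {locus!r}")
    keys = Counter(
        tuple(table.calls[(code, m)] for m in loci) for code in table.codes
    )
    n = table.n_cultivars
    matching = sum(k * (k - 1) // 2 for k in keys.values())
    return matching / (n * (n - 1) // 2)
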