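"""Per-locus marker statistics and probability-of-identity math.

For a locus with allele frequencies :math:`p_i`:

* probability of identity
  :math:`\\mathrm{PID} = 2\\bigl(\\sum_i p_i^2\\bigr)^2 - \\sum_i p_i^4`,
  the probability that two random individuals drawn from a Hardy-Weinberg
  population share a (diploid) genotype at the locus;
* polymorphism information content
  :math:`\\mathrm{PIC} = 1 - \\sum_i p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2`
  (the Botstein form, as computed by PowerMarker).

All frequency math is ploidy-aware at the counting stage: a triploid call
contributes three allele observations, a diploid call two.  The PID and PIC
formulas themselves are functions of the frequency spectrum only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeCall, GenotypeTable

__all__ = [
    "AlleleFrequencySpectrum",
    "allele_frequency_spectrum",
    "pid",
    "pic",
    "observed_heterozygosity",
    "genotype_classes",
    "summarize_markers",
    "combined_pid",
    "compare_with_reference",
    "write_stats_csv",
]

STAT_COLUMNS = ["marker", "maf", "ng", "na", "ho", "pic", "pid"]


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Allele frequencies at one locus, with the observation count behind them."""

    marker: str
    freqs: Mapping[int, float]
    n_allele_observations: int

    def __post_init__(self) -> None:
        p = np.asarray(list(self.freqs.values()), dtype=float)
        if p.size == 0:
            raise ValueError(f"{self.marker}: empty frequency spectrum")
        if (p <= 0).any():
            raise ValueError(f"{self.marker}: every allele frequency must be > 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"{self.marker}: frequencies sum to {p.sum()!r}, not 1")

    @property
    def p(self) -> np.ndarray:
        return np.asarray(list(self.freqs.values()), dtype=float)

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)

    @property
    def major_allele_frequency(self) -> float:
        return float(self.p.max())


def allele_frequency_spectrum(table: GenotypeTable, marker: str) -> AlleleFrequencySpectrum:
    """Empirical spectrum at ``marker``: each call contributes each allele copy once.

    The denominator is the total number of allele copies observed (2 per
    diploid, 3 per triploid call), so mixed-ploidy tables are handled without
    discarding data.
    """
    counts: dict[int, int] = {}
    total = 0
    for call in table.marker_calls(marker):
        for a in call.alleles:
            counts[a] = counts.get(a, 0) + 1
        total += call.ploidy
    freqs = {a: counts[a] / total for a in sorted(counts)}
    return AlleleFrequencySpectrum(marker, freqs, total)


def pid(spectrum: AlleleFrequencySpectrum | Iterable[float]) -> float:
    """Probability of identity at one locus, ``2(sum p^2)^2 - sum p^4``."""
    p = spectrum.p if isinstance(spectrum, AlleleFrequencySpectrum) else np.asarray(
        list(spectrum), dtype=float
    )
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 2.0 * s2**2 - s4


def pic(spectrum: AlleleFrequencySpectrum | Iterable[float]) -> float:
    """Polymorphism information content, ``1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2``."""
    p = spectrum.p if isinstance(spectrum, AlleleFrequencySpectrum) else np.asarray(
        list(spectrum), dtype=float
    )
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 == (sum p^2)^2 - sum p^4
    return 1.0 - s2 - (s2**2 - s4)


def observed_heterozygosity(table: GenotypeTable, marker: str) -> float:
    """Fraction of cultivars carrying >= 2 distinct alleles at ``marker``."""
    calls = table.marker_calls(marker)
    return sum(c.is_heterozygous for c in calls) / len(calls)


def genotype_classes(table: GenotypeTable, marker: str) -> dict[GenotypeCall, list[int]]:
    """Partition of cultivar codes by canonical genotype at ``marker``.

    The number of keys is NG, the number of distinct genotypes; two cultivars
    fall in the same class iff their calls are multiset-equal.
    """
    classes: dict[GenotypeCall, list[int]] = {}
    for record in table.cultivars:
        classes.setdefault(table.calls[(record.code, marker)], []).append(record.code)
    return classes


def summarize_markers(table: GenotypeTable) -> pd.DataFrame:
    """Per-marker statistics table: MAF, NG, NA, Ho, PIC, PID (one row per marker)."""
    if table.n_cultivars == 0:
        raise ValueError("cannot summarise an empty table")
    rows = []
    for marker in table.markers:
        spec = allele_frequency_spectrum(table, marker)
        rows.append(
            {
                "marker": marker,
                "maf": spec.major_allele_frequency,
                "ng": len(genotype_classes(table, marker)),
                "na": spec.n_alleles,
                "ho": observed_heterozygosity(table, marker),
                "pic": pic(spec),
                "pid": pid(spec),
            }
        )
    return pd.DataFrame(rows, columns=STAT_COLUMNS)


def combined_pid(per_locus_pids: Sequence[float]) -> float:
    """Panel-wide probability of identity: the product over independently
    segregating loci of their per-locus PIDs."""
    values = np.asarray(list(per_locus_pids), dtype=float)
    if values.size == 0:
        raise ValueError("combined_pid requires at least one locus")
    if ((values <= 0) | (values > 1)).any():
        bad = values[(values <= 0) | (values > 1)]
        raise ValueError(f"per-locus PID values must lie in (0, 1]: {bad.tolist()}")
    return float(np.prod(values))


def compare_with_reference(table: GenotypeTable, reference: pd.DataFrame) -> pd.DataFrame:
    """Diagnostic: recomputed statistics vs a published reference table.

    ``reference`` needs columns ``marker, maf, ng, na, ho, pic, pid``; only
    markers present in ``table`` are compared.  Returns a long-format frame
    with recomputed and reference values and their difference — published
    survey tables do not always reproduce exactly from the printed genotypes,
    and this surfaces where they do not.
    """
    computed = summarize_markers(table).set_index("marker")
    ref = reference.set_index("marker")
    rows = []
    for marker in computed.index:
        if marker not in ref.index:
            continue
        for col in ["maf", "ng", "na", "ho", "pic", "pid"]:
            c, r = float(computed.loc[marker, col]), float(ref.loc[marker, col])
            rows.append(
                {"marker": marker, "statistic": col, "computed": c, "reference": r,
                 "delta": c - r}
            )
    return pd.DataFrame(rows, columns=["marker", "statistic", "computed", "reference", "delta"])


def write_stats_csv(stats: pd.DataFrame, dest: io.TextIOBase | None = None) -> str:
    """Serialise a statistics table with a trailing ``Mean`` row, values to 3 dp."""
    out = stats.copy()
    mean_row = {"marker": "Mean"}
    for col in ["maf", "ng", "na", "ho", "pic", "pid"]:
        mean_row[col] = out[col].mean()
    out = pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)
    for col in ["maf", "ho", "pic", "pid"]:
        out[col] = out[col].map(lambda v: f"{v:.3g}" if v < 1e-3 else f"{v:.3f}")
    for col in ["ng", "na"]:
        out[col] = out[col].map(lambda v: f"{v:g}")
    buf = io.StringIO()
    out.to_csv(buf, index=False)
    text = buf.getvalue()
    if dest is not None:
        dest.write(text)
    return text
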