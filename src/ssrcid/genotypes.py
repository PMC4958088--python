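"""Data model and I/O for co-dominant SSR genotype tables.

An SSR (microsatellite) allele is scored as a fragment length in base pairs.
A genotype call at one locus for one cultivar is an unordered multiset of two
alleles (diploid) or, rarely in tea, three (triploid).  Tables are stored wide:
one row per cultivar, one column per marker, each cell ``a/b`` or ``a/b/c``.

Calls are canonicalised to ascending allele order so that equality is multiset
equality regardless of scoring order.  Missing cells are an error, never a NA
state: a complete survey table is assumed and an empty cell almost always
means a transcription mistake.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenotypeCall",
    "MarkerDef",
    "CultivarRecord",
    "GenotypeTable",
    "GenotypeParseError",
    "TableFormatError",
    "parse_genotype_string",
    "format_genotype_string",
    "read_genotype_table",
    "write_genotype_table",
]


class GenotypeParseError(ValueError):
    """A genotype cell could not be interpreted as a 2- or 3-allele call."""


class TableFormatError(ValueError):
    """A genotype table violates its structural invariants."""


@dataclass(frozen=True, order=True)
class GenotypeCall:
    """Canonical (ascending-sorted) multiset of 2 or 3 allele sizes in bp."""

    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) not in (2, 3):
            raise GenotypeParseError(
                f"a call must carry 2 or 3 alleles, got {len(self.alleles)}: {self.alleles}"
            )
        if any((not isinstance(a, int)) or a <= 0 for a in self.alleles):
            raise GenotypeParseError(f"allele sizes must be positive integers: {self.alleles}")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def is_heterozygous(self) -> bool:
        """True if the call carries at least two distinct alleles."""
        return len(set(self.alleles)) >= 2

    def allele_shares(self) -> dict[int, float]:
        """Within-individual allele frequencies (1/2 or 1/3 per copy)."""
        shares: dict[int, float] = {}
        w = 1.0 / len(self.alleles)
        for a in self.alleles:
            shares[a] = shares.get(a, 0.0) + w
        return shares

    def __str__(self) -> str:
        return format_genotype_string(self)


def parse_genotype_string(text: str) -> GenotypeCall:
    """Parse a slash-delimited size string such as ``"268/292"``.

    Inverse of :func:`format_genotype_string`; the result is canonical, so
    ``"292/268"`` and ``"268/292"`` parse to equal calls.
    """
    tokens = text.strip().split("/")
    if len(tokens) not in (2, 3):
        raise GenotypeParseError(
            f"expected 2 or 3 '/'-separated allele sizes, got {len(tokens)} in {text!r}"
        )
    try:
        alleles = tuple(int(t) for t in tokens)
    except ValueError as exc:
        raise GenotypeParseError(f"non-integer allele size in {text!r}") from exc
    if any(a <= 0 for a in alleles):
        raise GenotypeParseError(f"non-positive allele size in {text!r}")
    return GenotypeCall(alleles)


def format_genotype_string(call: GenotypeCall) -> str:
    return "/".join(str(a) for a in call.alleles)


@dataclass(frozen=True)
class MarkerDef:
    """An SSR marker: identity, repeat motif and assay metadata.

    ``motif`` is written ``(UNIT)count``; only long-core motifs (repeat unit of
    3-6 bp) are admitted, the di-nucleotide repeats being excluded for their
    stutter-prone electropherograms.
    """

    name: str
    motif: str | None = None
    linkage_group: str | None = None
    forward_primer: str | None = None
    reverse_primer: str | None = None
    tm: float | None = None
    dye: str | None = None
    core: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise TableFormatError("marker name must be non-empty")
        if self.motif:
            unit = self.motif.split(")")[0].lstrip("(")
            if not 3 <= len(unit) <= 6:
                raise TableFormatError(
                    f"{self.name}: repeat unit {unit!r} is not a long-core motif (3-6 bp)"
                )


_CPP_LABELS = frozenset({"O", "G", "B"})


@dataclass(frozen=True)
class CultivarRecord:
    """A clonal cultivar: code, name, origin and processing property.

    ``processing_property`` is the subset of tea types the cultivar is bred
    for: O oolong, G green, B black.
    """

    code: int
    name: str
    origin: str | None = None
    processing_property: frozenset[str] = frozenset({"G"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "processing_property", frozenset(self.processing_property))
        if not self.processing_property:
            raise TableFormatError(f"cultivar {self.code}: processing property must be non-empty")
        if not self.processing_property <= _CPP_LABELS:
            raise TableFormatError(
                f"cultivar {self.code}: unknown processing property "
                f"{sorted(self.processing_property - _CPP_LABELS)}"
            )


@dataclass
class GenotypeTable:
    """Cultivars x markers matrix of genotype calls.

    Every (cultivar, marker) pair must hold exactly one call.  Row and column
    order are preserved as given.
    """

    cultivars: list[CultivarRecord]
    markers: list[str]
    calls: dict[tuple[int, str], GenotypeCall]
    marker_defs: dict[str, MarkerDef] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = [c.code for c in self.cultivars]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise TableFormatError(f"duplicate cultivar codes: {dupes}")
        if len(set(self.markers)) != len(self.markers):
            dupes = sorted({m for m in self.markers if self.markers.count(m) > 1})
            raise TableFormatError(f"duplicate marker names: {dupes}")
        for code in codes:
            for marker in self.markers:
                if (code, marker) not in self.calls:
                    raise TableFormatError(f"missing call for cultivar {code}, marker {marker}")
        expected = len(codes) * len(self.markers)
        if len(self.calls) != expected:
            extra = set(self.calls) - {(c, m) for c in codes for m in self.markers}
            raise TableFormatError(f"calls outside the table grid: {sorted(extra)[:5]}")

    @property
    def codes(self) -> list[int]:
        return [c.code for c in self.cultivars]

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivars)

    def record(self, code: int) -> CultivarRecord:
        for c in self.cultivars:
            if c.code == code:
                return c
        raise KeyError(f"unknown cultivar code {code}")

    def call(self, code: int, marker: str) -> GenotypeCall:
        try:
            return self.calls[(code, marker)]
        except KeyError:
            if marker not in self.markers:
                raise KeyError(f"unknown marker {marker!r}") from None
            raise KeyError(f"unknown cultivar code {code}") from None

    def marker_calls(self, marker: str) -> list[GenotypeCall]:
        """Calls at one marker, in cultivar (row) order."""
        if marker not in self.markers:
            raise KeyError(f"unknown marker {marker!r}")
        return [self.calls[(c.code, marker)] for c in self.cultivars]

    def profile(self, code: int) -> dict[str, GenotypeCall]:
        """The cultivar's multilocus genotype, keyed by marker."""
        if code not in self.codes:
            raise KeyError(f"unknown cultivar code {code}")
        return {m: self.calls[(code, m)] for m in self.markers}

    def subset_markers(self, markers: Sequence[str]) -> "GenotypeTable":
        for m in markers:
            if m not in self.markers:
                raise KeyError(f"unknown marker {m!r}")
        calls = {(c.code, m): self.calls[(c.code, m)] for c in self.cultivars for m in markers}
        defs = {m: self.marker_defs[m] for m in markers if m in self.marker_defs}
        return GenotypeTable(list(self.cultivars), list(markers), calls, defs)

    def with_cultivar(
        self, record: CultivarRecord, genotypes: Mapping[str, GenotypeCall | str]
    ) -> "GenotypeTable":
        """Extended copy with one additional cultivar (all markers required)."""
        if record.code in self.codes:
            raise TableFormatError(f"duplicate cultivar code {record.code}")
        calls = dict(self.calls)
        for m in self.markers:
            if m not in genotypes:
                raise TableFormatError(f"new cultivar {record.code} lacks a call at {m}")
            g = genotypes[m]
            calls[(record.code, m)] = g if isinstance(g, GenotypeCall) else parse_genotype_string(g)
        return GenotypeTable(
            list(self.cultivars) + [record], list(self.markers), calls, dict(self.marker_defs)
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame with genotype strings, indexed like the CSV layout."""
        rows = []
        for c in self.cultivars:
            row: dict[str, object] = {"code": c.code, "name": c.name}
            for m in self.markers:
                row[m] = format_genotype_string(self.calls[(c.code, m)])
            rows.append(row)
        return pd.DataFrame(rows, columns=["code", "name", *self.markers])

    def __eq__(self, other: object) -> bool:
        """Genotype-table identity: same rows (code, name), columns and calls.

        Side metadata (origin, processing property, marker definitions) is not
        part of the serialised table and is ignored here.
        """
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            [(c.code, c.name) for c in self.cultivars]
            == [(c.code, c.name) for c in other.cultivars]
            and self.markers == other.markers
            and self.calls == other.calls
        )


def read_genotype_table(source: str | io.TextIOBase) -> GenotypeTable:
    """Read a wide-layout genotype CSV.

    Layout: header ``code,name,<marker...>``; one row per cultivar; cells are
    slash-delimited size strings.  ``#`` lines are comments.  Empty cells and
    malformed calls are reported with their (cultivar, marker) location.
    """
    df = pd.read_csv(source, comment="#", dtype=str)
    if list(df.columns[:2]) != ["code", "name"]:
        raise TableFormatError(
            f"first two columns must be 'code,name', got {list(df.columns[:2])}"
        )
    markers = list(df.columns[2:])
    if not markers:
        raise TableFormatError("no marker columns found")
    cultivars: list[CultivarRecord] = []
    calls: dict[tuple[int, str], GenotypeCall] = {}
    for _, row in df.iterrows():
        try:
            code = int(row["code"])
        except (TypeError, ValueError):
            raise TableFormatError(f"non-integer cultivar code {row['code']!r}") from None
        name = row["name"] if isinstance(row["name"], str) else str(code)
        cultivars.append(CultivarRecord(code=code, name=name))
        for m in markers:
            cell = row[m]
            if not isinstance(cell, str) or not cell.strip():
                raise TableFormatError(f"empty genotype cell at cultivar {code}, marker {m}")
            try:
                calls[(code, m)] = parse_genotype_string(cell)
            except GenotypeParseError as exc:
                raise GenotypeParseError(f"cultivar {code}, marker {m}: {exc}") from None
    return GenotypeTable(cultivars, markers, calls)


def write_genotype_table(table: GenotypeTable, dest: io.TextIOBase | None = None) -> str:
    """Serialise a table to the wide CSV dialect read by :func:`read_genotype_table`."""
    buf = io.StringIO()
    table.to_frame().to_csv(buf, index=False)
    text = buf.getvalue()
    if dest is not None:
        dest.write(text)
    return text
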