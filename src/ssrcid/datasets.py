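"""Packaged study data: the tea-cultivar fingerprinting survey tables.

Four plain-text fixtures ship with the package, hand-transcribed from the
printed survey of 66 Chinese clonal tea cultivars genotyped with long-core
motif SSR markers:

* ``table1_cultivars.csv``   - the 66 cultivars (code, name, origin, CPP);
* ``table2_marker_panel.csv`` - the 33-marker panel with motif/assay metadata;
* ``table3_marker_stats.csv`` - per-locus statistics of the 33 markers,
  exactly as printed (including the anomalous TM369 PID ``8.58E-07``, which
  is kept verbatim because downstream panel products depend on it);
* ``table4_genotypes.csv``   - genotypes of the 66 cultivars at the 6 core
  markers (396 calls, 5 of them triploid).

Loaders validate shape and a few spot values so that transcription damage
fails loudly rather than propagating.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genotypes import (
    CultivarRecord,
    GenotypeTable,
    MarkerDef,
    read_genotype_table,
)

__all__ = [
    "CORE_MARKER_ORDER",
    "FixtureError",
    "load_cultivars",
    "load_marker_panel",
    "load_marker_stats",
    "load_genotype_table",
    "load_fixtures",
]

#: The six core fingerprinting markers in descending printed-PID order — the
#: order in which the identification diagram consumes them.
CORE_MARKER_ORDER = ["TM442", "TM324", "TM351", "TM569", "TM581", "TM461"]


class FixtureError(RuntimeError):
    """A packaged fixture failed its integrity checks."""


def _open(name: str):
    return resources.files("ssrcid.fixtures").joinpath(name).open("r", encoding="utf-8")


def load_cultivars() -> list[CultivarRecord]:
    """The 66 surveyed cultivars with origin and processing property."""
    with _open("table1_cultivars.csv") as fh:
        df = pd.read_csv(fh, comment="#")
    records = [
        CultivarRecord(
            code=int(r.code),
            name=str(r.name),
            origin=str(r.origin),
            processing_property=frozenset(str(r.processing_property).split("/")),
        )
        for r in df.itertuples(index=False)
    ]
    if len(records) != 66 or [r.code for r in records] != list(range(1, 67)):
        raise FixtureError("cultivar fixture must hold codes 1-66 in order")
    return records


def load_marker_panel() -> list[MarkerDef]:
    """The 33-marker SSR panel; the 6 core markers carry ``core=True``."""
    with _open("table2_marker_panel.csv") as fh:
        df = pd.read_csv(fh, comment="#")
    panel = [
        MarkerDef(
            name=str(r.marker),
            motif=str(r.motif),
            linkage_group=str(r.linkage_group),
            forward_primer=None if pd.isna(r.forward_primer) else str(r.forward_primer),
            reverse_primer=None if pd.isna(r.reverse_primer) else str(r.reverse_primer),
            tm=float(r.tm),
            dye=str(r.dye),
            core=bool(r.core),
        )
        for r in df.itertuples(index=False)
    ]
    if len(panel) != 33:
        raise FixtureError(f"marker panel must hold 33 rows, found {len(panel)}")
    core = [m.name for m in panel if m.core]
    if sorted(core) != sorted(CORE_MARKER_ORDER):
        raise FixtureError(f"core flags {core} do not match the expected six markers")
    return panel


def load_marker_stats() -> pd.DataFrame:
    """Printed per-locus statistics of the 33 markers.

    Columns: ``linkage_group, marker, maf, ng, na, ho, pic, pid, core``.
    Values are as printed (3 decimals); they are treated as inputs for panel
    arithmetic, not re-derived, because the printed genotype table does not
    reproduce them exactly.
    """
    with _open("table3_marker_stats.csv") as fh:
        df = pd.read_csv(fh, comment="#")
    if len(df) != 33:
        raise FixtureError(f"statistics fixture must hold 33 rows, found {len(df)}")
    if int(df.core.sum()) != 6:
        raise FixtureError("statistics fixture must flag exactly 6 core markers")
    tm442 = df.loc[df.marker == "TM442", "pid"]
    if len(tm442) != 1 or abs(float(tm442.iloc[0]) - 0.192) > 1e-12:
        raise FixtureError("statistics fixture spot check failed: TM442 PID should be 0.192")
    return df


def load_genotype_table() -> GenotypeTable:
    """The 66-cultivar x 6-core-marker genotype table, with cultivar metadata merged."""
    with _open("table4_genotypes.csv") as fh:
        table = read_genotype_table(fh)
    meta = {r.code: r for r in load_cultivars()}
    table.cultivars = [meta[c.code] for c in table.cultivars]
    table.marker_defs = {m.name: m for m in load_marker_panel() if m.name in table.markers}
    if table.n_cultivars != 66 or table.markers != CORE_MARKER_ORDER:
        raise FixtureError("genotype fixture must be 66 cultivars x the 6 core markers")
    if len(table.calls) != 396:
        raise FixtureError(f"genotype fixture must hold 396 calls, found {len(table.calls)}")
    triploid = sorted({code for (code, _), call in table.calls.items() if call.ploidy == 3})
    if triploid != [4, 18]:
        raise FixtureError(f"triploid-bearing cultivars should be [4, 18], found {triploid}")
    return table


def load_fixtures() -> tuple[GenotypeTable, list[MarkerDef], pd.DataFrame]:
    """All study inputs: (genotype table, 33-marker panel, printed statistics)."""
    return load_genotype_table(), load_marker_panel(), load_marker_stats()
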