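"""Accession × locus allele calls and their binary band expansion.

Genotypes are fragment sizes (bp) called per accession and SSR marker.
Because the strains are dikaryotic each cell holds an unordered set of
up to two allele sizes; an empty set means missing data.  For
fingerprinting and similarity analysis the matrix is expanded to a
binary *band matrix*: one 0/1 column per (marker, allele size) pair,
columns ordered by marker display order then ascending size — the
"presence of a band is 1, absence 0" scoring used with capillary
electrophoresis profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ManifestError(ValueError):
    """Genotype table refers to a marker absent from the manifest."""


class PloidyError(ValueError):
    """A cell carries more than two alleles (impossible for a dikaryon)."""


@dataclass(frozen=True)
class Marker:
    name: str
    forward_primer: str = ""
    reverse_primer: str = ""
    display_order: int = 0


@dataclass
class GenotypeMatrix:
    """Ordered accessions × markers with 0–2 allele sizes per cell."""

    accessions: list[str]
    markers: list[Marker]
    calls: dict[tuple[str, str], frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ManifestError("marker names must be unique")
        self.markers = sorted(self.markers, key=lambda m: m.display_order)
        for (acc, marker), alleles in self.calls.items():
            if len(alleles) > 2:
                raise PloidyError(
                    f"cell ({acc}, {marker}) has {len(alleles)} alleles; max 2"
                )
            if any(a <= 0 for a in alleles):
                raise ValueError(f"cell ({acc}, {marker}) has non-positive size")

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def call(self, accession: str, marker: str) -> frozenset[int]:
        return self.calls.get((accession, marker), frozenset())

    def is_missing(self, accession: str, marker: str) -> bool:
        return len(self.call(accession, marker)) == 0

    def alleles_at(self, marker: str) -> list[int]:
        """Sorted distinct allele sizes observed at ``marker``."""
        sizes: set[int] = set()
        for acc in self.accessions:
            sizes |= self.call(acc, marker)
        return sorted(sizes)


@dataclass
class BandMatrix:
    """Binary presence/absence expansion of a :class:`GenotypeMatrix`.

    ``data`` has one row per accession and one ``"marker:size"`` column
    per observed (marker, allele size) pair; ``missing`` flags whole
    (accession, marker) cells with no data, whose band columns are zero
    but carry no evidence of absence.
    """

    data: pd.DataFrame
    missing: pd.DataFrame
    marker_of_column: list[str]

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, accession: str) -> np.ndarray:
        return self.data.loc[accession].to_numpy()


def to_band_matrix(g: GenotypeMatrix) -> BandMatrix:
    """Expand calls to 0/1 bands; column count equals total distinct alleles."""
    columns: list[str] = []
    marker_of_column: list[str] = []
    col_index: dict[tuple[str, int], int] = {}
    for m in g.markers:
        for size in g.alleles_at(m.name):
            col_index[(m.name, size)] = len(columns)
            columns.append(f"{m.name}:{size}")
            marker_of_column.append(m.name)
    data = np.zeros((len(g.accessions), len(columns)), dtype=np.int8)
    missing = np.zeros((len(g.accessions), len(g.markers)), dtype=bool)
    for i, acc in enumerate(g.accessions):
        for j, m in enumerate(g.markers):
            alleles = g.call(acc, m.name)
            if not alleles:
                missing[i, j] = True
                continue
            for size in alleles:
                data[i, col_index[(m.name, size)]] = 1
    return BandMatrix(
        data=pd.DataFrame(data, index=list(g.accessions), columns=columns),
        missing=pd.DataFrame(
            missing, index=list(g.accessions), columns=g.marker_names
        ),
        marker_of_column=marker_of_column,
    )


def collapse_bands(b: BandMatrix) -> dict[tuple[str, str], frozenset[int]]:
    """Invert :func:`to_band_matrix` back to call sets (non-missing cells)."""
    calls: dict[tuple[str, str], frozenset[int]] = {}
    sizes = [int(c.split(":")[1]) for c in b.data.columns]
    for acc in b.accessions:
        row = b.data.loc[acc].to_numpy()
        per_marker: dict[str, set[int]] = {}
        for val, marker, size in zip(row, b.marker_of_column, sizes):
            if val:
                per_marker.setdefault(marker, set()).add(size)
        for marker in set(b.marker_of_column):
            if b.missing.loc[acc, marker]:
                continue
            calls[(acc, marker)] = frozenset(per_marker.get(marker, set()))
    return calls


def read_marker_manifest(path: str | Path) -> list[Marker]:
    """Delimited manifest with name, primers and display order columns."""
    df = pd.read_csv(path)
    required = {"name", "display_order"}
    if not required <= set(df.columns):
        raise ManifestError(f"manifest needs columns {sorted(required)}")
    return [
        Marker(
            name=str(r["name"]),
            forward_primer=str(r.get("forward_primer", "") or ""),
            reverse_primer=str(r.get("reverse_primer", "") or ""),
            display_order=int(r["display_order"]),
        )
        for _, r in df.iterrows()
    ]


def write_marker_manifest(markers: list[Marker], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": m.name,
                "forward_primer": m.forward_primer,
                "reverse_primer": m.reverse_primer,
                "display_order": m.display_order,
            }
            for m in markers
        ]
    ).to_csv(path, index=False)


def read_genotypes(path: str | Path, markers: list[Marker]) -> GenotypeMatrix:
    """Read an ``accession,SSR3_a,SSR3_b,...`` table of fragment sizes.

    Each marker owns one or two size columns (``_a``/``_b`` suffixes, or
    the bare marker name for single-column tables).  Empty cells are
    missing data and stay missing through a write/read round trip.
    """
    df = pd.read_csv(path, dtype=str).set_index("accession")
    known = {m.name for m in markers}
    col_marker: dict[str, str] = {}
    for col in df.columns:
        base = col.rsplit("_", 1)[0] if col.rsplit("_", 1)[-1] in ("a", "b") else col
        if base not in known:
            raise ManifestError(f"column {col!r} names unknown marker {base!r}")
        col_marker[col] = base
    calls: dict[tuple[str, str], frozenset[int]] = {}
    for acc, row in df.iterrows():
        per_marker: dict[str, set[int]] = {m.name: set() for m in markers}
        for col, val in row.items():
            if pd.isna(val) or str(val).strip() == "":
                continue
            per_marker[col_marker[col]].add(int(float(val)))
        for name, sizes in per_marker.items():
            if len(sizes) > 2:
                raise PloidyError(
                    f"cell ({acc}, {name}) has {len(sizes)} alleles; max 2"
                )
            if sizes:
                calls[(str(acc), name)] = frozenset(sizes)
    return GenotypeMatrix(
        accessions=[str(a) for a in df.index], markers=list(markers), calls=calls
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    records = []
    for acc in g.accessions:
        rec: dict[str, object] = {"accession": acc}
        for m in g.markers:
            alleles = sorted(g.call(acc, m.name))
            rec[f"{m.name}_a"] = alleles[0] if len(alleles) > 0 else ""
            rec[f"{m.name}_b"] = alleles[1] if len(alleles) > 1 else ""
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False)


def write_band_matrix(b: BandMatrix, path: str | Path) -> None:
    b.data.rename_axis("accession").to_csv(path)
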