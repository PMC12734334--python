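"""Molecular identity codes for germplasm accessions.

Each accession gets a three-part identity: a *fingerprint code* (the
accession's band row written as a "0"/"1" string in fixed marker order),
a *trait code* (single-character codes for phenotype fields such as cap
color) and a *supplementary code* (origin region, cultivation type).
The parts are joined with ``-`` into a payload suitable for 2D-barcode
encoding; a 2-character base-36 checksum can be appended so scanned IDs
are self-validating while the raw payload stays recoverable.

The code book (field → level → code mapping) is user-supplied
configuration with a shipped default, loadable from YAML.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .genotypes import BandMatrix

_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
# QR capacity for byte-mode content at the largest symbol version
DEFAULT_CAPACITY = 2953
SEPARATOR = "-"
CHECKSUM_SEPARATOR = "~"


class EncodingError(ValueError):
    """Metadata level missing from the code book (names the field)."""


class CapacityError(ValueError):
    """Payload too long for the configured barcode capacity."""


@dataclass
class IDCodeBook:
    """Ordered categorical → code mappings for trait and supplementary fields."""

    trait_fields: dict[str, dict[str, str]]
    supplementary_fields: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for fields in (self.trait_fields, self.supplementary_fields):
            for name, levels in fields.items():
                codes = list(levels.values())
                if len(set(codes)) != len(codes):
                    raise ValueError(f"ambiguous codes in field {name!r}")
                if any(SEPARATOR in c or CHECKSUM_SEPARATOR in c for c in codes):
                    raise ValueError(
                        f"codes in field {name!r} must not contain separators"
                    )

    def encode(self, fields: dict[str, dict[str, str]], metadata: dict) -> str:
        parts = []
        for name, levels in fields.items():
            if name not in metadata:
                raise EncodingError(f"metadata missing field {name!r}")
            level = str(metadata[name])
            if level not in levels:
                raise EncodingError(
                    f"level {level!r} of field {name!r} not in code book"
                )
            parts.append(levels[level])
        return "".join(parts)

    @classmethod
    def from_dict(cls, d: dict) -> "IDCodeBook":
        return cls(
            trait_fields={k: dict(v) for k, v in d.get("trait_fields", {}).items()},
            supplementary_fields={
                k: dict(v) for k, v in d.get("supplementary_fields", {}).items()
            },
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IDCodeBook":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "trait_fields": self.trait_fields,
                    "supplementary_fields": self.supplementary_fields,
                },
                fh,
                sort_keys=False,
            )


def default_codebook() -> IDCodeBook:
    """Shipped default: fruiting-body color, origin region, cultivation type."""
    return IDCodeBook(
        trait_fields={"color": {"brown": "B", "white": "W"}},
        supplementary_fields={
            "origin": {
                "China": "CN",
                "Japan": "JP",
                "Malaysia": "MY",
                "other": "XX",
            },
            "cultivation": {"industrial": "I", "artificial": "A"},
        },
    )


@dataclass
class MolecularID:
    accession: str
    fingerprint: str
    trait_code: str
    supplementary_code: str
    low_confidence: bool = False

    @property
    def payload(self) -> str:
        return SEPARATOR.join(
            (self.fingerprint, self.trait_code, self.supplementary_code)
        )


def fingerprint_code(b: BandMatrix, accession: str) -> str:
    """Band row of ``accession`` as a 0/1 string in fixed column order."""
    if accession not in b.data.index:
        raise KeyError(f"accession {accession!r} not in band matrix")
    return "".join(str(int(v)) for v in b.data.loc[accession])


def build_molecular_id(
    accession: str,
    fingerprint: str,
    metadata: dict,
    codebook: IDCodeBook,
    low_confidence: bool = False,
) -> MolecularID:
    return MolecularID(
        accession=accession,
        fingerprint=fingerprint,
        trait_code=codebook.encode(codebook.trait_fields, metadata),
        supplementary_code=codebook.encode(codebook.supplementary_fields, metadata),
        low_confidence=low_confidence,
    )


def molecular_ids(
    b: BandMatrix, metadata: pd.DataFrame, codebook: IDCodeBook
) -> list[MolecularID]:
    """One :class:`MolecularID` per accession; all-missing accessions are
    flagged low-confidence (their fingerprint is all zeros)."""
    ids = []
    for acc in b.accessions:
        fp = fingerprint_code(b, acc)
        all_missing = bool(b.missing.loc[acc].all())
        ids.append(
            build_molecular_id(
                acc, fp, metadata.loc[acc].to_dict(), codebook,
                low_confidence=all_missing,
            )
        )
    return ids


_PAYLOAD_RE = re.compile(r"^([01]+)-([^-]*)-([^-]*)$")


def parse_payload(payload: str) -> tuple[str, str, str]:
    """Split a payload back into (fingerprint, trait code, supplementary code)."""
    m = _PAYLOAD_RE.match(payload)
    if not m:
        raise ValueError(f"unparseable payload {payload!r}")
    return m.group(1), m.group(2), m.group(3)


@dataclass
class DuplicateGroup:
    members: list[str]
    key: str
    metadata_distinct: bool = False


def detect_duplicates(
    ids: list[MolecularID], on: str = "fingerprint"
) -> list[DuplicateGroup]:
    """Maximal groups of accessions with identical keys (singletons omitted).

    With ``on="fingerprint"`` a group whose members still differ in their
    trait/supplementary codes is flagged ``metadata_distinct`` — such
    accessions can only be told apart through the added metadata.
    """
    if len(ids) < 2:
        raise ValueError("need at least two ids")
    if on not in ("fingerprint", "payload"):
        raise ValueError("on must be 'fingerprint' or 'payload'")
    groups: dict[str, list[MolecularID]] = {}
    for mid in ids:
        key = mid.fingerprint if on == "fingerprint" else mid.payload
        groups.setdefault(key, []).append(mid)
    out = []
    for key, members in groups.items():  # insertion order = first occurrence
        if len(members) < 2:
            continue
        distinct = len({m.payload for m in members}) > 1
        out.append(
            DuplicateGroup(
                members=[m.accession for m in members],
                key=key,
                metadata_distinct=distinct and on == "fingerprint",
            )
        )
    return out


def checksum(payload: str) -> str:
    """Two base-36 characters: character-sum of the payload modulo 36²."""
    total = sum(ord(ch) for ch in payload) % (36 * 36)
    return _B36[total // 36] + _B36[total % 36]


def qr_payload(mid: MolecularID, capacity: int = DEFAULT_CAPACITY) -> str:
    """Payload plus ``~XX`` checksum, ready for 2D-barcode encoding.

    Raises :class:`CapacityError` for payloads beyond ``capacity``,
    suggesting base-36 compaction of the fingerprint.
    """
    payload = mid.payload
    if not mid.fingerprint:
        raise ValueError("empty payload")
    full = payload + CHECKSUM_SEPARATOR + checksum(payload)
    if len(full) > capacity:
        raise CapacityError(
            f"payload of {len(full)} characters exceeds capacity {capacity}; "
            "consider compress_fingerprint() for base-36 compaction"
        )
    return full


def verify_qr_payload(text: str) -> tuple[str, str, str]:
    """Check the checksum of a scanned payload and parse its components."""
    payload, _, ck = text.rpartition(CHECKSUM_SEPARATOR)
    if not payload or checksum(payload) != ck:
        raise ValueError("checksum mismatch")
    return parse_payload(payload)


def compress_fingerprint(bits: str) -> str:
    """Base-36 compaction of a 0/1 fingerprint (length prefix kept)."""
    value = int(bits, 2)
    digits = ""
    while value:
        value, rem = divmod(value, 36)
        digits = _B36[rem] + digits
    return f"{len(bits)}Z{digits or '0'}"


def decompress_fingerprint(text: str) -> str:
    length, _, digits = text.partition("Z")
    value = 0
    for ch in digits:
        value = value * 36 + _B36.index(ch)
    return format(value, f"0{int(length)}b")


def write_id_table(ids: list[MolecularID], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "accession": m.accession,
                "fingerprint": m.fingerprint,
                "trait_code": m.trait_code,
                "supplementary_code": m.supplementary_code,
                "payload": m.payload,
                "checksum": checksum(m.payload),
                "low_confidence": m.low_confidence,
            }
            for m in ids
        ]
    ).to_csv(path, sep="\t", index=False)
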