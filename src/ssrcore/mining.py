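"""Perfect microsatellite (SSR) detection in genome assemblies.

A simple sequence repeat (SSR) is a perfect tandem repeat of a primitive
1–6 bp unit.  The scanner reports every *maximal* perfect tract whose
repeat count reaches the per-unit-length threshold — by default 10 for
mononucleotide, 6 for dinucleotide and 5 for tri- through hexanucleotide
units, the thresholds conventionally used with MISA-style mining.

Repeat units are collapsed into strand- and rotation-independent *motif
classes* written ``"X/Y"`` (e.g. ``AG/CT``): ``X`` is the lexicographic
minimum over all cyclic rotations of the unit and of its reverse
complement, and ``Y`` its reverse complement.  A pure power such as
``AGAGAG`` is therefore only ever reported at its shortest primitive
unit (``AG``).

Coordinates are 0-based half-open in memory and 1-based inclusive in the
exported tables (GFF-style).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord


class MotifError(ValueError):
    """Raised for repeat units that are not valid primitive DNA motifs."""


class FastaFormatError(ValueError):
    """Raised for empty input or non-nucleotide sequence content."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not itself a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Collapse a repeat unit to its motif-class label, e.g. ``"TC"`` → ``"AG/CT"``.

    The label is invariant under cyclic rotation and reverse complement,
    so all 2·u variants of a u-bp unit share one class.  Palindromic
    classes such as ``"AT/AT"`` are legal.
    """
    motif = motif.upper()
    if not motif or len(motif) > 6:
        raise MotifError(f"motif length must be 1-6, got {motif!r}")
    if not set(motif) <= set("ACGT"):
        raise MotifError(f"motif {motif!r} contains non-ACGT characters")
    if not is_primitive(motif):
        raise MotifError(f"motif {motif!r} is not primitive")
    rc = reverse_complement(motif)
    n = len(motif)
    variants = [motif[i:] + motif[:i] for i in range(n)]
    variants += [rc[i:] + rc[:i] for i in range(n)]
    x = min(variants)
    return f"{x}/{reverse_complement(x)}"


@dataclass(frozen=True)
class MotifRules:
    """Minimum repeat counts per unit length for a tract to be reported."""

    min_repeats_by_unit_length: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )
    max_unit_length: int = 6

    def __post_init__(self) -> None:
        expected = set(range(1, self.max_unit_length + 1))
        if set(self.min_repeats_by_unit_length) != expected:
            raise ValueError(
                f"thresholds must cover unit lengths {sorted(expected)}"
            )
        if any(v < 2 for v in self.min_repeats_by_unit_length.values()):
            raise ValueError("all repeat thresholds must be >= 2")


DEFAULT_RULES = MotifRules()


@dataclass(frozen=True, order=True)
class SSRLocus:
    """One perfect tandem repeat tract (0-based, half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    motif: str
    motif_class: str
    unit_length: int
    repeat_count: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.unit_length * self.repeat_count:
            raise ValueError("span must equal unit_length * repeat_count")


@dataclass
class SSRCatalog:
    """Ordered set of detected SSR loci plus genome-level tallies."""

    loci: list[SSRLocus]
    genome_length: int

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.seq_id, l.start))

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def counts_by_unit_length(self) -> dict[int, int]:
        return dict(Counter(l.unit_length for l in self.loci))

    @property
    def counts_by_motif_class(self) -> dict[str, int]:
        return dict(Counter(l.motif_class for l in self.loci))

    @property
    def mean_interlocus_distance(self) -> float:
        """Assembly length divided by locus count (bp per locus)."""
        if not self.loci:
            raise ValueError("undefined for an empty catalog")
        return self.genome_length / len(self.loci)


def _segments_without_n(seq: str) -> Iterable[tuple[int, str]]:
    """Yield (offset, segment) for maximal N-free stretches of ``seq``."""
    start = None
    for i, base in enumerate(seq):
        if base == "N":
            if start is not None:
                yield start, seq[start:i]
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, seq[start:]


def _scan_segment(seq_id: str, offset: int, seg: str, rules: MotifRules) -> list[SSRLocus]:
    loci: list[SSRLocus] = []
    n = len(seg)
    for u in range(1, rules.max_unit_length + 1):
        threshold = rules.min_repeats_by_unit_length[u]
        if n < u * threshold:
            continue
        i = 0
        limit = n - u - 1  # last index where seg[i + u] exists
        while i <= limit:
            if seg[i] != seg[i + u]:
                i += 1
                continue
            # extend the period-u run; i is left-maximal because the
            # previous position failed (or i == 0 after a recorded run)
            j = i
            while j <= limit and seg[j] == seg[j + u]:
                j += 1
            run_len = (j - i) + u
            repeats = run_len // u
            unit = seg[i : i + u]
            if repeats >= threshold and is_primitive(unit):
                start = offset + i
                loci.append(
                    SSRLocus(
                        seq_id=seq_id,
                        start=start,
                        end=start + u * repeats,
                        motif=unit,
                        motif_class=canonical_motif(unit),
                        unit_length=u,
                        repeat_count=repeats,
                    )
                )
            i = j + 1
    return loci


def find_ssrs(
    sequences: Iterable[SeqRecord] | Sequence[tuple[str, str]],
    rules: MotifRules = DEFAULT_RULES,
) -> SSRCatalog:
    """Detect every threshold-passing perfect SSR tract in ``sequences``.

    Accepts Biopython ``SeqRecord`` iterables or plain ``(id, sequence)``
    pairs.  Soft-masked (lowercase) bases are uppercased; ``N`` breaks
    tracts; any other non-ACGT character is a format error.  Each tract
    is reported exactly once, at its shortest primitive unit.
    """
    loci: list[SSRLocus] = []
    total_length = 0
    n_records = 0
    for rec in sequences:
        if isinstance(rec, tuple):
            seq_id, seq = rec
        else:
            seq_id, seq = rec.id, str(rec.seq)
        seq = seq.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FastaFormatError(
                f"sequence {seq_id!r} contains non-nucleotide characters {sorted(bad)}"
            )
        n_records += 1
        total_length += len(seq)
        for offset, seg in _segments_without_n(seq):
            loci.extend(_scan_segment(seq_id, offset, seg, rules))
    if n_records == 0:
        raise FastaFormatError("no sequences supplied")
    return SSRCatalog(loci=loci, genome_length=total_length)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly gzip-compressed) multi-record FASTA file."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as handle:
            return list(SeqIO.parse(handle, "fasta"))
    return list(SeqIO.parse(str(path), "fasta"))


def composition_percentages(counts: dict) -> dict:
    """Percentage share of each key in a count tally (two decimals)."""
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


@dataclass
class CompositionReport:
    """Motif-composition summary of an SSR catalog."""

    n_loci: int
    genome_length: int
    counts_by_unit_length: dict[int, int]
    pct_by_unit_length: dict[int, float]
    counts_by_motif_class: dict[str, int]
    pct_by_motif_class: dict[str, float]
    pct_by_motif_class_within_unit: dict[int, dict[str, float]]
    mean_interlocus_distance: float | None


def summarize_catalog(catalog: SSRCatalog) -> CompositionReport:
    """Counts and percentage shares by unit length and motif class.

    Percentages within each grouping sum to 100 up to rounding.  Mean
    interlocus distance is assembly length over locus count; it is
    ``None`` (flagged undefined) for an empty catalog.
    """
    by_unit = catalog.counts_by_unit_length
    by_class = catalog.counts_by_motif_class
    within: dict[int, dict[str, float]] = {}
    for u in sorted(by_unit):
        cls_counts = Counter(
            l.motif_class for l in catalog.loci if l.unit_length == u
        )
        within[u] = composition_percentages(dict(cls_counts))
    return CompositionReport(
        n_loci=len(catalog),
        genome_length=catalog.genome_length,
        counts_by_unit_length=by_unit,
        pct_by_unit_length=composition_percentages(by_unit),
        counts_by_motif_class=by_class,
        pct_by_motif_class=composition_percentages(by_class),
        pct_by_motif_class_within_unit=within,
        mean_interlocus_distance=(
            catalog.mean_interlocus_distance if catalog.loci else None
        ),
    )


def write_locus_table(catalog: SSRCatalog, path: str | Path) -> None:
    """Tab-delimited locus table with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tmotif\tmotif_class\tunit_length\trepeats\n")
        for l in catalog.loci:
            fh.write(
                f"{l.seq_id}\t{l.start + 1}\t{l.end}\t{l.motif}\t"
                f"{l.motif_class}\t{l.unit_length}\t{l.repeat_count}\n"
            )


def write_gff3(catalog: SSRCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, l in enumerate(catalog.loci, start=1):
            attrs = (
                f"ID=ssr{i};motif={l.motif};motif_class={l.motif_class};"
                f"repeats={l.repeat_count}"
            )
            fh.write(
                f"{l.seq_id}\tssrcore\tmicrosatellite\t{l.start + 1}\t{l.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )


def write_composition_report(report: CompositionReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("section\tkey\tcount\tpercent\n")
        for u in sorted(report.counts_by_unit_length):
            fh.write(
                f"unit_length\t{u}\t{report.counts_by_unit_length[u]}\t"
                f"{report.pct_by_unit_length[u]}\n"
            )
        for cls in sorted(report.counts_by_motif_class):
            fh.write(
                f"motif_class\t{cls}\t{report.counts_by_motif_class[cls]}\t"
                f"{report.pct_by_motif_class[cls]}\n"
            )
        dist = (
            "" if report.mean_interlocus_distance is None
            else f"{report.mean_interlocus_distance:.2f}"
        )
        fh.write(f"summary\tmean_interlocus_distance_bp\t{report.n_loci}\t{dist}\n")
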