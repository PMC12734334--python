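"""One-command orchestration: mine → stats → cluster → core → id.

The historical tool chain for this kind of survey (a repeat miner, a
population-genetics package, a clustering package and a core-collection
selector, each with its own formats) is replaced by one auditable run:
a single config drives every stage, outputs land in one directory, and
a JSON manifest records parameters, package version and SHA-256
checksums so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .clustering import (
    cut_at_similarity,
    simple_matching,
    upgma_from_similarity,
    write_groups,
    write_newick,
    write_similarity,
)
from .coreset import select_core, write_core
from .diversity import diversity_table, write_diversity_table
from .genotypes import read_genotypes, read_marker_manifest, to_band_matrix
from .mining import (
    MotifRules,
    find_ssrs,
    read_fasta,
    summarize_catalog,
    write_composition_report,
    write_gff3,
    write_locus_table,
)
from .molecular_id import IDCodeBook, default_codebook, molecular_ids, write_id_table

import pandas as pd


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str
    fasta: str | None = None
    genotypes: str | None = None
    markers: str | None = None
    metadata: str | None = None
    codebook: str | None = None
    min_repeats: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )
    similarity_cut: float = 0.76
    core_target: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_cut <= 1.0:
            raise ConfigError("similarity_cut must be in [0, 1]")
        self.min_repeats = {int(k): int(v) for k, v in self.min_repeats.items()}
        for name in ("fasta", "genotypes", "markers", "metadata", "codebook"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns (and writes) a manifest: parameter echo, per-stage output
    files with checksums, and the package version.  A failing stage
    aborts the run with a :class:`StageError` naming it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, list[str]] = {}

    if config.fasta:
        try:
            rules = MotifRules(min_repeats_by_unit_length=dict(config.min_repeats))
            catalog = find_ssrs(read_fasta(config.fasta), rules)
            write_locus_table(catalog, out / "loci.tsv")
            write_gff3(catalog, out / "loci.gff3")
            write_composition_report(summarize_catalog(catalog), out / "composition.tsv")
            stages["mine"] = ["loci.tsv", "loci.gff3", "composition.tsv"]
        except Exception as exc:  # noqa: BLE001 - reported per stage
            raise StageError("mine", exc) from exc

    if config.genotypes:
        if not config.markers:
            raise ConfigError("genotypes given without a marker manifest")
        try:
            markers = read_marker_manifest(config.markers)
            g = read_genotypes(config.genotypes, markers)
            bands = to_band_matrix(g)
        except Exception as exc:
            raise StageError("stats", exc) from exc

        try:
            write_diversity_table(diversity_table(g), out / "diversity.tsv")
            stages["stats"] = ["diversity.tsv"]
        except Exception as exc:
            raise StageError("stats", exc) from exc

        try:
            sim = simple_matching(bands)
            tree = upgma_from_similarity(sim)
            groups = cut_at_similarity(tree, config.similarity_cut)
            write_similarity(sim, out / "similarity.tsv")
            write_newick(tree, out / "tree.nwk")
            write_groups(groups, out / "groups.tsv")
            stages["cluster"] = ["similarity.tsv", "tree.nwk", "groups.tsv"]
        except Exception as exc:
            raise StageError("cluster", exc) from exc

        try:
            core = select_core(bands, target_size=config.core_target)
            write_core(core, out / "core.tsv")
            stages["core"] = ["core.tsv"]
        except Exception as exc:
            raise StageError("core", exc) from exc

        if config.metadata:
            try:
                meta = pd.read_csv(config.metadata).set_index("accession")
                codebook = (
                    IDCodeBook.from_yaml(config.codebook)
                    if config.codebook
                    else default_codebook()
                )
                ids = molecular_ids(bands, meta, codebook)
                write_id_table(ids, out / "ids.tsv")
                stages["id"] = ["ids.tsv"]
            except Exception as exc:
                raise StageError("id", exc) from exc

    manifest = {
        "version": __version__,
        "parameters": {
            **asdict(config),
            "min_repeats": {str(k): v for k, v in config.min_repeats.items()},
        },
        "stages": {
            stage: {name: _sha256(out / name) for name in files}
            for stage, files in stages.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
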