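"""End-to-end pipeline driver.

The analysis decomposes into seven stages ("widgets") that communicate only
through files stored under the output directory, so any stage can be re-run
independently or replaced by the user's own intermediate files:

1. ``filter-otus`` — keep 16S sequences of networked OTUs.
2. ``match-genomes`` — best-hit genome assignment with percent identity.
3. ``get-models`` — resolve genome ids to local SBML model files (the
   reconstruction step itself is delegated to an external service or the
   user; a provider hook is defined below).
4. ``merge-pairs`` — build two-species community models.
5. ``simulate-growth`` — four growth rates per pair under the chosen diet.
6. ``classify`` — interaction types and the polarity summary.
7. ``draw-network`` — JSON/GraphML/HTML interaction network.

For a fixed configuration and seed every stage is deterministic, so a full
run and widget-by-widget runs produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable

from . import community_build, diet_fba, interactions, network_out, otu_prep
from .errors import DependencyError, PairmintError
from .model_core import MetabolicModel, read_sbml, write_sbml

__all__ = ["RunConfig", "run_widget", "run_all", "LocalModelProvider"]

logger = logging.getLogger(__name__)

WIDGET_NAMES = {
    1: "filter-otus",
    2: "match-genomes",
    3: "get-models",
    4: "merge-pairs",
    5: "simulate-growth",
    6: "classify",
    7: "draw-network",
}


@dataclass
class RunConfig:
    """Paths and options for a pipeline run.

    Can be loaded from a ``key = value`` config file; explicit keyword
    overrides win over file values.
    """

    associations: Path | None = None
    sequences: Path | None = None
    reference: Path | None = None
    models_dir: Path | None = None
    diet: Path | None = None
    diet_scale: float = 1.0
    out: Path = Path("pairmint_out")
    degeneracy: str = "fair"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("diet_scale", "seed", "degeneracy", "log_level") or v is None:
                continue
            setattr(self, f.name, Path(v))
        self.diet_scale = float(self.diet_scale)
        self.seed = int(self.seed)
        if not self.diet_scale > 0:
            raise ValueError(f"diet_scale must be > 0, got {self.diet_scale}")
        if self.degeneracy not in ("fair", "vertex"):
            raise ValueError(f"degeneracy must be 'fair' or 'vertex', got {self.degeneracy!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        values: dict[str, str] = {}
        for lineno, line in enumerate(open(path), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PairmintError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise PairmintError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def widget_dir(self, n: int) -> Path:
        return Path(self.out) / f"widget{n}"


class LocalModelProvider:
    """Resolve genome ids to SBML files in a local directory.

    The interface (``get(genome_id) -> MetabolicModel``) is the extension
    point for a remote-reconstruction backend; this implementation expects a
    pre-reconstructed ``<models_dir>/<genome_id>.xml`` per genome.
    """

    def __init__(self, models_dir: Path):
        self.models_dir = Path(models_dir)

    def path_for(self, genome_id: str) -> Path:
        return self.models_dir / f"{genome_id}.xml"

    def get(self, genome_id: str) -> MetabolicModel:
        path = self.path_for(genome_id)
        if not path.exists():
            raise DependencyError(
                f"local model provider: no SBML model for genome {genome_id!r} "
                f"(expected {path})"
            )
        return read_sbml(path)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _setup_logging(config: RunConfig) -> None:
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("pairmint")
    root.setLevel(config.log_level.upper())
    logfile = out / "run.log"
    for h in list(root.handlers):
        target = getattr(h, "_pairmint_target", None)
        if target is not None and target != str(logfile):
            root.removeHandler(h)
            h.close()
    have = {getattr(h, "_pairmint_target", None) for h in root.handlers}
    if str(logfile) not in have:
        fh = logging.FileHandler(logfile)
        fh._pairmint_target = str(logfile)  # type: ignore[attr-defined]
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(fh)


def _require(path: Path | None, what: str, produced_by: int | None = None) -> Path:
    if path is not None and Path(path).exists():
        return Path(path)
    if produced_by is not None:
        raise DependencyError(
            f"missing {what} ({path}); run widget {produced_by} "
            f"({WIDGET_NAMES[produced_by]}) first"
        )
    raise DependencyError(f"missing required input: {what} ({path})")


def _log_files(widget: int, paths: list[Path]) -> None:
    for p in paths:
        logger.info("widget %d output %s sha256=%s", widget, p, _digest(p))


# ---------------------------------------------------------------------------
# Widget implementations
# ---------------------------------------------------------------------------


def _widget1(config: RunConfig) -> list[Path]:
    assoc = otu_prep.read_associations(_require(config.associations, "association table"))
    seqs = otu_prep.read_fasta(_require(config.sequences, "16S sequence FASTA"))
    wdir = config.widget_dir(1)
    wdir.mkdir(parents=True, exist_ok=True)
    filtered = otu_prep.filter_sequences(seqs, assoc)
    out_fasta = otu_prep.write_fasta(filtered, wdir / "filtered.fasta")
    out_assoc = wdir / "associations.tsv"
    with open(out_assoc, "w") as handle:
        handle.write("otu_a\totu_b\tweight\n")
        for a, b, w in assoc:
            handle.write(f"{a}\t{b}\t{w:.9g}\n")
    return [out_fasta, out_assoc]


def _widget2(config: RunConfig) -> list[Path]:
    queries = otu_prep.read_fasta(
        _require(config.widget_dir(1) / "filtered.fasta", "filtered FASTA", produced_by=1)
    )
    reference = otu_prep.read_fasta(_require(config.reference, "reference genome 16S FASTA"))
    matches = otu_prep.match_genomes(queries, reference)
    wdir = config.widget_dir(2)
    wdir.mkdir(parents=True, exist_ok=True)
    return [otu_prep.write_matches(matches, wdir / "similarity.tsv")]


def _widget3(config: RunConfig) -> list[Path]:
    matches = otu_prep.read_matches(
        _require(config.widget_dir(2) / "similarity.tsv", "similarity table", produced_by=2)
    )
    if config.models_dir is None or not Path(config.models_dir).exists():
        raise DependencyError(
            f"local model provider: models directory not found ({config.models_dir})"
        )
    provider = LocalModelProvider(config.models_dir)
    wdir = config.widget_dir(3) / "models"
    wdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for genome_id in dict.fromkeys(m.genome_id for m in matches):
        src = provider.path_for(genome_id)
        if not src.exists():
            raise DependencyError(
                f"local model provider: no SBML model for genome {genome_id!r} "
                f"(expected {src})"
            )
        dst = wdir / src.name
        shutil.copyfile(src, dst)
        written.append(dst)
    return written


def _widget4(config: RunConfig) -> list[Path]:
    assoc = otu_prep.read_associations(
        _require(config.widget_dir(1) / "associations.tsv", "association table", produced_by=1)
    )
    matches = otu_prep.read_matches(
        _require(config.widget_dir(2) / "similarity.tsv", "similarity table", produced_by=2)
    )
    models_dir = _require(config.widget_dir(3) / "models", "local model copies", produced_by=3)
    pairs = community_build.pair_list(assoc, matches)
    wdir = config.widget_dir(4)
    wdir.mkdir(parents=True, exist_ok=True)
    manifest = wdir / "pairs.tsv"
    written = [manifest]
    provider = LocalModelProvider(models_dir)
    with open(manifest, "w") as handle:
        handle.write("genome_a\tgenome_b\ttag_a\ttag_b\tbiomass_a\tbiomass_b\tsbml\n")
        for ga, gb in pairs:
            community = community_build.build_community(
                provider.get(ga), provider.get(gb), tag_a="A", tag_b="B"
            )
            sbml = wdir / f"community__{ga}__{gb}.xml"
            write_sbml(community.base, sbml)
            written.append(sbml)
            handle.write(
                f"{ga}\t{gb}\tA\tB\t{community.biomass_ids['A']}"
                f"\t{community.biomass_ids['B']}\t{sbml.name}\n"
            )
    return written


def _load_communities(config: RunConfig) -> list[community_build.CommunityModel]:
    manifest = _require(config.widget_dir(4) / "pairs.tsv", "community pair manifest", produced_by=4)
    out: list[community_build.CommunityModel] = []
    with open(manifest) as handle:
        handle.readline()
        for line in handle:
            if not line.strip():
                continue
            ga, gb, tag_a, tag_b, bio_a, bio_b, sbml = line.rstrip("\n").split("\t")
            base = read_sbml(config.widget_dir(4) / sbml, require_biomass=False)
            out.append(
                community_build.CommunityModel(
                    base=base,
                    tags=(tag_a, tag_b),
                    biomass_ids={tag_a: bio_a, tag_b: bio_b},
                    pair=(ga, gb),
                )
            )
    return out


def _widget5(config: RunConfig) -> list[Path]:
    communities = _load_communities(config)
    diet = diet_fba.read_diet(_require(config.diet, "diet file"))
    if config.diet_scale != 1.0:
        diet = diet_fba.scale_diet(diet, config.diet_scale)
    results = [
        diet_fba.community_growth(c, diet, degeneracy=config.degeneracy)
        for c in communities
    ]
    wdir = config.widget_dir(5)
    wdir.mkdir(parents=True, exist_ok=True)
    return [diet_fba.write_growth_results(results, wdir / "growth.tsv")]


def _widget6(config: RunConfig) -> list[Path]:
    growth = diet_fba.read_growth_results(
        _require(config.widget_dir(5) / "growth.tsv", "growth table", produced_by=5)
    )
    records = [interactions.classify(g) for g in growth]
    wdir = config.widget_dir(6)
    wdir.mkdir(parents=True, exist_ok=True)
    table = interactions.write_interactions(records, wdir / "interactions.tsv")
    summary = interactions.summarize(records) if records else None
    summary_path = wdir / "summary.json"
    payload = (
        {
            "total": summary.total,
            "counts": summary.counts,
            "polarity_counts": summary.polarity_counts,
            "polarity_percent": summary.polarity_percent,
        }
        if summary
        else {"total": 0}
    )
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return [table, summary_path]


def _widget7(config: RunConfig) -> list[Path]:
    assoc = otu_prep.read_associations(
        _require(config.widget_dir(1) / "associations.tsv", "association table", produced_by=1)
    )
    matches = otu_prep.read_matches(
        _require(config.widget_dir(2) / "similarity.tsv", "similarity table", produced_by=2)
    )
    records = interactions.read_interactions(
        _require(config.widget_dir(6) / "interactions.tsv", "interaction table", produced_by=6)
    )
    # Interaction records are keyed by genome pair; map through the matches.
    net = network_out.build_network(assoc, matches, records)
    paths = network_out.write_network(net, ("json", "graphml", "html"), config.widget_dir(7))
    return list(paths.values())


_WIDGETS: dict[int, Callable[[RunConfig], list[Path]]] = {
    1: _widget1,
    2: _widget2,
    3: _widget3,
    4: _widget4,
    5: _widget5,
    6: _widget6,
    7: _widget7,
}


def run_widget(n: int, config: RunConfig) -> list[Path]:
    """Run one widget; returns the files written into ``out/widgetN/``.

    Idempotent for fixed inputs and seed.  Missing upstream intermediates
    raise :class:`DependencyError` naming the widget that produces them.
    """
    if n not in _WIDGETS:
        raise ValueError(f"widget number must be 1..7, got {n}")
    _setup_logging(config)
    logger.info("running widget %d (%s)", n, WIDGET_NAMES[n])
    written = _WIDGETS[n](config)
    _log_files(n, written)
    return written


def run_all(config: RunConfig) -> Path:
    """Run widgets 1–7 in order; intermediates are stored per widget.

    On failure the run aborts with the failing widget's error; outputs of the
    widgets already completed are retained.
    """
    _setup_logging(config)
    for n in sorted(_WIDGETS):
        run_widget(n, config)
    return Path(config.out)
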