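"""End-to-end orchestration: records -> curation -> matrix -> pattern ->
enrichment -> inference, with every stage's artifact written to disk.

Artifacts are plain text (TSV / newick / JSON) and contain no timestamps, so
rerunning the same configuration on the same input reproduces every file
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .association import (
    AssociationMatrix,
    GroupScheme,
    build_association_matrix,
    default_group_scheme,
    select_genera,
    validate_group_scheme,
)
from .curation import DEFAULT_MIN_TAXA, curation_funnel, report_frequency_ecd
from .enrichment import (
    DEFAULT_FOLD,
    class_lookup_from_records,
    export_heatmap_table,
    group_proportions,
    order_rows,
    per_plastic_table,
)
from .inference import run_group_tests
from .pattern import (
    cosine_distance_matrix,
    cut_tree,
    dendrogram_to_newick,
    hierarchical_cluster,
    nmds_embed,
)
from .records import read_records, write_records
from .simulate import SimParams, generate_corpus

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` / ``simulate`` must be set. The defaults
    are the analysis' standard thresholds: plastics kept at >= 10 distinct
    taxonomy ids, genera selected at >= 4 plastic types, average linkage,
    twofold tendency rule.
    """

    outdir: str | Path
    input_path: Optional[str | Path] = None
    simulate: Optional[SimParams] = None
    min_taxa: int = DEFAULT_MIN_TAXA
    min_plastics: int = 4
    linkage: str = "average"
    fold: float = DEFAULT_FOLD
    strict_fold: bool = False
    seed: int = 0
    scheme_path: Optional[str | Path] = None
    tree_path: Optional[str | Path] = None
    allow_unmapped: bool = False
    per_plastic: bool = False
    nmds_restarts: int = 8

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("set exactly one of input_path or simulate")


@dataclass
class ReportBundle:
    """Paths of every artifact a run produced, plus the in-memory results."""

    outdir: Path
    paths: dict[str, Path]
    funnel: "pd.DataFrame"
    matrix: AssociationMatrix
    tests: dict

    def __getitem__(self, key: str) -> Path:
        return self.paths[key]


def run_full(config: RunConfig) -> ReportBundle:
    """Run every stage and write its artifact; returns the bundle of paths."""
    import pandas as pd  # local: only needed for the funnel frame type

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    # --- input
    if config.simulate is not None:
        records, truth = _stage("simulate", lambda: generate_corpus(config.simulate))
        paths["corpus"] = out / "corpus.tsv"
        write_records(records, paths["corpus"])
        paths["truth"] = out / "truth.json"
        truth.write(paths["truth"])
    else:
        dialect = "csv" if str(config.input_path).endswith(".csv") else "tsv"
        records = _stage(
            "read", lambda: read_records(config.input_path, dialect=dialect)
        )

    # --- curation
    table = _stage("curation", lambda: curation_funnel(records, min_taxa=config.min_taxa))
    paths["funnel"] = out / "funnel.tsv"
    table.write_funnel(paths["funnel"])
    for stage in table.funnel:
        logger.info(
            "%s: %d records in, %d dropped, %d out",
            stage.name, stage.n_in, stage.n_dropped, stage.n_out,
        )
    for level in ("species", "genus"):
        curve = _stage("ecd", lambda lv=level: report_frequency_ecd(table.records, lv))
        paths[f"ecd_{level}"] = out / f"ecd_{level}.tsv"
        curve.write(paths[f"ecd_{level}"])

    # --- association
    matrix = _stage("association", lambda: build_association_matrix(table))
    paths["matrix"] = out / "matrix.tsv"
    matrix.to_tsv(paths["matrix"])
    scheme = (
        GroupScheme.from_tsv(config.scheme_path)
        if config.scheme_path
        else default_group_scheme()
    )
    report = validate_group_scheme(scheme, matrix)
    if not report.ok and not config.allow_unmapped:
        raise RuntimeError(
            "pipeline stage 'scheme' failed: unmapped plastic columns "
            f"{', '.join(report.unmapped_plastics)} (use allow_unmapped to proceed)"
        )
    if report.unmapped_plastics:
        logger.warning("excluding unmapped plastics: %s", report.unmapped_plastics)

    # --- pattern
    dist = _stage("distance", lambda: cosine_distance_matrix(matrix))
    paths["distance"] = out / "distance.tsv"
    dist.to_tsv(paths["distance"])
    dendro = _stage("cluster", lambda: hierarchical_cluster(dist, linkage=config.linkage))
    paths["dendrogram"] = out / "dendrogram.nwk"
    paths["dendrogram"].write_text(dendrogram_to_newick(dendro) + "\n")
    if len(dist.labels) >= 3:
        emb = _stage(
            "nmds",
            lambda: nmds_embed(dist, seed=config.seed, n_restarts=config.nmds_restarts),
        )
        paths["embedding"] = out / "embedding.tsv"
        emb.to_tsv(paths["embedding"])
        paths["embedding_stress"] = out / "embedding_stress.json"
        paths["embedding_stress"].write_text(
            json.dumps({"stress_1": emb.stress, "seed": emb.seed,
                        "n_restarts": emb.n_restarts}, indent=2)
        )

    # --- enrichment
    selected = _stage("select", lambda: select_genera(matrix, config.min_plastics))
    rows = _stage(
        "enrichment",
        lambda: group_proportions(
            selected,
            scheme,
            class_lookup=class_lookup_from_records(table.records),
            fold=config.fold,
            strict=config.strict_fold,
            allow_unmapped=config.allow_unmapped,
        ),
    )
    tree_text = Path(config.tree_path).read_text() if config.tree_path else None
    rows = _stage("order", lambda: order_rows(rows, tree_text))
    paths["heatmap"] = out / "heatmap.tsv"
    export_heatmap_table(rows, paths["heatmap"])
    if config.per_plastic:
        paths["per_plastic"] = out / "heatmap_per_plastic.tsv"
        per_plastic_table(selected, scheme, rows).to_csv(
            paths["per_plastic"], sep="\t", index=False
        )

    # --- inference
    tests = _stage("tests", lambda: run_group_tests(rows))
    paths["tests"] = out / "tests.json"
    paths["tests"].write_text(json.dumps(tests.to_dict(), indent=2))

    # --- manifest
    cfg = dataclasses.asdict(config)
    cfg["outdir"] = str(cfg["outdir"])
    for key in ("input_path", "scheme_path", "tree_path"):
        if cfg[key] is not None:
            cfg[key] = str(cfg[key])
    manifest = {
        "package": "plastdeg",
        "version": __version__,
        "config": cfg,
        "stage_counts": [
            {"stage": s.name, "n_in": s.n_in, "n_dropped": s.n_dropped, "n_out": s.n_out}
            for s in table.funnel
        ],
        "n_genera": len(matrix.genera),
        "n_plastics": len(matrix.plastics),
        "n_selected_genera": len(selected.genera),
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))

    return ReportBundle(
        outdir=out,
        paths=paths,
        funnel=table.funnel_frame(),
        matrix=matrix,
        tests=tests.to_dict(),
    )
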