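"""End-to-end orchestration: filter → DE → signature → predict → pairs →
cluster → enrich, from files or from a synthetic spec, with a manifest of
every artifact produced."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .io import (
    TREATMENTS,
    ContrastTable,
    read_counts,
    read_gene_sets,
    write_network,
)
from .diffexpr import filter_expressed, nb_contrast_test
from .enrichment import enrichment_table, ora_enrich
from .network import build_pairs, eagle_cluster, pairs_to_graph, select_top_clusters
from .signature import icd_signature
from .synthetic import IMMUNE_TERM, SyntheticSpec, generate_dataset, write_dataset
from .targets import export_predictions, predict_targets

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One structured configuration for a full run.

    Exactly one input mode: either all four file inputs (counts + metadata +
    FASTA + GMT) or a synthetic spec.
    """

    outdir: str | Path = "icdmir_run"
    # file mode
    mirna_counts: str | None = None
    mrna_counts: str | None = None
    metadata: str | None = None
    mirna_fasta: str | None = None
    transcript_fasta: str | None = None
    gene_sets: str | None = None
    # synthetic mode
    synthetic: SyntheticSpec | None = None
    # thresholds
    fc_min: float = 1.3
    alpha: float = 0.05
    mirna_floor: int = 3
    mrna_floor: int = 10
    score_threshold: float = 0.9
    go_term: str = IMMUNE_TERM
    min_clique_size: int | None = None
    inducer_rule: str = "any"
    use_adjusted: bool = True
    #: (cell line, treatment) whose mRNA contrast drives pair construction.
    pair_contrast: tuple[str, str] = ("Mino", "RA_IFNa")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        file_inputs = [self.mirna_counts, self.mrna_counts, self.metadata,
                       self.mirna_fasta, self.transcript_fasta, self.gene_sets]
        has_files = any(v is not None for v in file_inputs)
        if has_files and self.synthetic is not None:
            raise ConfigurationError(
                "exactly one input mode: give file paths OR a synthetic spec"
            )
        if has_files and any(v is None for v in file_inputs):
            raise ConfigurationError(
                "file mode needs counts, metadata, both FASTA files and a GMT"
            )
        if not has_files and self.synthetic is None:
            self.synthetic = SyntheticSpec(rng_seed=self.rng_seed)

    def config_hash(self) -> str:
        def encode(value):
            if dataclasses.is_dataclass(value):
                return dataclasses.asdict(value)
            if isinstance(value, Path):
                return str(value)
            return value

        payload = {
            k: encode(v)
            for k, v in dataclasses.asdict(self).items()
            if k != "outdir"  # the hash identifies the analysis, not its location
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_log(manifest: dict, stage: str, **counts) -> None:
    manifest["stages"].append({"stage": stage, **counts})
    log.info("stage %-10s %s", stage, counts)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written as JSON).

    The manifest records the config hash, package version, per-stage feature
    accounting, and the output file list; identical config and seed give
    identical outputs and manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": [],
        "outputs": [],
    }

    def register(path: Path) -> Path:
        manifest["outputs"].append(str(path))
        return path

    # ---- input stage -----------------------------------------------------
    if config.synthetic is not None:
        dataset = generate_dataset(config.synthetic)
        paths = write_dataset(dataset, out / "inputs")
        for p in paths.values():
            register(p)
        mirna_counts, mrna_counts = dataset.mirna_counts, dataset.mrna_counts
        samples = dataset.samples
        mirna_fasta = dataset.mirna_fasta
        transcript_fasta = dataset.transcript_fasta
        gene_sets = dataset.gene_sets
        cell_lines = config.synthetic.cell_lines
    else:
        mirna_counts, samples = read_counts(config.mirna_counts, config.metadata)
        mrna_counts, _ = read_counts(config.mrna_counts, config.metadata)
        from .targets import read_fasta

        mirna_fasta = read_fasta(config.mirna_fasta)
        transcript_fasta = read_fasta(config.transcript_fasta)
        gene_sets = read_gene_sets(config.gene_sets)
        cell_lines = tuple(sorted({s.cell_line for s in samples}))
    _stage_log(
        manifest, "input",
        mirnas=len(mirna_counts), mrnas=len(mrna_counts), samples=len(samples),
    )

    # ---- expression filter ----------------------------------------------
    mirna_expr = filter_expressed(mirna_counts, config.mirna_floor, "miRNA")
    mrna_expr = filter_expressed(mrna_counts, config.mrna_floor, "mRNA")
    _stage_log(
        manifest, "filter",
        mirnas_in=len(mirna_counts), mirnas_out=len(mirna_expr),
        mrnas_in=len(mrna_counts), mrnas_out=len(mrna_expr),
    )

    # ---- differential expression ----------------------------------------
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    records: dict[str, dict[tuple[str, str], pd.DataFrame]] = {
        "mirna": {}, "mrna": {}
    }
    for kind, matrix in (("mirna", mirna_expr), ("mrna", mrna_expr)):
        for line in cell_lines:
            for treatment in TREATMENTS:
                res = nb_contrast_test(matrix, samples, line, treatment)
                records[kind][(line, treatment)] = res
                res.to_csv(
                    register(de_dir / f"{kind}_{line}_{treatment}.tsv"), sep="\t"
                )
    _stage_log(manifest, "de", contrasts=len(records["mirna"]) + len(records["mrna"]))

    # ---- ICD signatures --------------------------------------------------
    tables = {
        kind: ContrastTable.from_records(recs, use_adjusted=config.use_adjusted)
        for kind, recs in records.items()
    }
    signatures = {
        kind: icd_signature(
            tables[kind], fc_min=config.fc_min, alpha=config.alpha,
            inducer_rule=config.inducer_rule, cell_lines=tuple(cell_lines),
        )
        for kind in tables
    }
    for kind, sig in signatures.items():
        rows = [{"feature_id": f, "direction": sig.direction_of(f)}
                for f in sorted(sig.members)]
        pd.DataFrame(rows, columns=["feature_id", "direction"]).to_csv(
            register(out / f"{kind}_signature.tsv"), sep="\t", index=False
        )
    _stage_log(
        manifest, "signature",
        mirnas_up=len(signatures["mirna"].up),
        mirnas_down=len(signatures["mirna"].down),
        mrnas_up=len(signatures["mrna"].up),
        mrnas_down=len(signatures["mrna"].down),
    )

    # ---- target prediction ----------------------------------------------
    sig_mirnas = {
        m: mirna_fasta[m]
        for m in sorted(signatures["mirna"].members)
        if m in mirna_fasta
    }
    predictions = predict_targets(
        sig_mirnas or {"_none_": "A" * 22}, transcript_fasta,
        threshold=config.score_threshold,
    ) if sig_mirnas else []
    export_predictions(predictions, register(out / "predictions.tsv"))
    _stage_log(manifest, "predict", mirnas=len(sig_mirnas),
               predictions=len(predictions))

    # ---- immunogenic pairs ----------------------------------------------
    go_genes = gene_sets.get(config.go_term, set())
    if not go_genes:
        raise ConfigurationError(
            f"gene set {config.go_term!r} is absent or empty in the GMT input"
        )
    line, treatment = config.pair_contrast
    pairs = build_pairs(
        signatures["mirna"], records["mrna"][(line, treatment)], predictions,
        go_genes, fc_min=config.fc_min, alpha=config.alpha,
        score_threshold=config.score_threshold,
        use_adjusted=config.use_adjusted,
    )
    graph = pairs_to_graph(pairs)
    write_network(graph, register(out / "pair_network.tsv"))
    _stage_log(manifest, "pairs", pairs=len(pairs),
               nodes=graph.number_of_nodes(), edges=graph.number_of_edges())

    # ---- clustering ------------------------------------------------------
    _, cover = eagle_cluster(graph, min_clique_size=config.min_clique_size)
    clusters = select_top_clusters(cover, graph)
    clusters.to_csv(register(out / "clusters.tsv"), sep="\t", index=False)
    _stage_log(manifest, "cluster", communities=len(cover.communities),
               eq=round(cover.eq, 6))

    # ---- enrichment of the top cluster's genes ---------------------------
    if len(clusters):
        top_members = set(
            clusters.iloc[0]["genes"].split(";")
        ) if clusters.iloc[0]["genes"] else set()
    else:
        top_members = set()
    enrich_rows = ora_enrich(top_members, gene_sets) if top_members else []
    enrichment_table(enrich_rows).to_csv(
        register(out / "top_cluster_enrichment.tsv"), sep="\t", index=False
    )
    _stage_log(manifest, "enrich", query=len(top_members), terms=len(enrich_rows))

    manifest_path = out / "manifest.json"
    manifest["outputs"].append(str(manifest_path))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
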