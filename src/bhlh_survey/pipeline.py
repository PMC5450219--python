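"""End-to-end orchestration: run every configured stage, write TSV outputs
and a YAML manifest.

A run executes, in order: profile build -> domain scan -> binding
classification -> conservation profiling -> phylogeny with subfamily
assignment -> redundancy clustering and ortholog calling -> expression
analysis.  Stages whose inputs are not configured are skipped with a
logged reason.  Identical config + inputs + seed give byte-identical TSV
outputs; the manifest (timestamps, checksums) is the only file allowed to
differ between re-runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from bhlh_survey import __version__
from bhlh_survey.classification import (
    ClassifierRule, category_counts, classify, conservation_profile,
    conserved_positions, count_basic_residues,
)
from bhlh_survey.domain_profile import build_profile, default_regions, scan_collection
from bhlh_survey.expression import cluster_subgroups, detect_blocks, normalize, qpcr_agreement
from bhlh_survey.homology import call_orthologs, cluster_redundant, ortholog_summary
from bhlh_survey.io_formats import (
    ExpressionMatrix, RunConfig, ValidationError, read_expression, read_fasta,
    write_newick,
)
from bhlh_survey.phylogeny import (
    aligned_from_hits, assign_subfamilies, bootstrap, p_distance,
)

logger = logging.getLogger("bhlh_survey")


@dataclass
class PipelineInputs:
    """Paths to the external inputs; unset paths skip their stage."""

    proteins_fasta: Path | None = None
    seed_alignment_fasta: Path | None = None
    reference_domains_fasta: Path | None = None   # labeled references for subfamilies
    reference_labels_tsv: Path | None = None      # id <tab> subfamily
    ortholog_references: dict[str, Path] = field(default_factory=dict)  # species -> fasta
    expression_tsv: Path | None = None
    expression_meta_tsv: Path | None = None
    reference_genes_txt: Path | None = None
    qpcr_tsv: Path | None = None


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    started: str
    finished: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def to_yaml(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str) -> None:
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_survey(config: RunConfig, inputs: PipelineInputs, out_dir: Path) -> RunManifest:
    """Execute every stage that has inputs configured; see module docstring."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config), seed=config.seed, version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    for name, path in (
        ("proteins_fasta", inputs.proteins_fasta),
        ("seed_alignment_fasta", inputs.seed_alignment_fasta),
        ("reference_domains_fasta", inputs.reference_domains_fasta),
        ("reference_labels_tsv", inputs.reference_labels_tsv),
        ("expression_tsv", inputs.expression_tsv),
        ("expression_meta_tsv", inputs.expression_meta_tsv),
        ("reference_genes_txt", inputs.reference_genes_txt),
        ("qpcr_tsv", inputs.qpcr_tsv),
    ):
        if path is not None:
            manifest.input_checksums[name] = _checksum(Path(path))
    for species, path in inputs.ortholog_references.items():
        manifest.input_checksums[f"ortholog_{species}"] = _checksum(Path(path))

    def emit(name: str, frame: pd.DataFrame, **kwargs) -> Path:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)
        manifest.outputs[name] = _checksum(path)
        return path

    hits = None
    regions = None
    rule = ClassifierRule(min_basic_residues=config.min_basic_residues)

    # --- sequence stages -------------------------------------------------
    if inputs.proteins_fasta and inputs.seed_alignment_fasta:
        try:
            proteins = read_fasta(inputs.proteins_fasta)
            seed_aln = read_fasta(inputs.seed_alignment_fasta)
            profile = build_profile(seed_aln, pseudocount=config.pseudocount)
            regions = default_regions(profile, config)
            hits, missing = scan_collection(
                profile, proteins, min_score=config.min_score,
                gap_open=config.gap_open, gap_extend=config.gap_extend,
            )
        except ValidationError as exc:
            raise StageError("scan", str(exc)) from exc
        emit("domain_hits.tsv", pd.DataFrame(
            [(h.protein_id, h.start + 1, h.end, round(h.score, 4)) for h in hits],
            columns=["protein_id", "start", "end", "score"],
        ))
        emit("proteins_without_hit.tsv",
             pd.DataFrame({"protein_id": missing}))

        try:
            cats = {h.protein_id: classify(h, regions, rule) for h in hits}
        except ValidationError as exc:
            raise StageError("classify", str(exc)) from exc
        emit("classification.tsv", pd.DataFrame(
            [(h.protein_id, cats[h.protein_id].value,
              count_basic_residues(h, regions, rule)) for h in hits],
            columns=["protein_id", "category", "n_basic_residues"],
        ))

        cons = conservation_profile(
            hits, conserved_min_fraction=config.conserved_min_fraction,
            high_min_fraction=config.high_min_fraction,
        )
        conserved, highly = conserved_positions(cons)
        emit("conservation.tsv", pd.DataFrame(
            [(j + 1, cons.modal_residues[j], cons.counts[j],
              round(cons.fractions[j], 6),
              "high" if j + 1 in highly else
              ("conserved" if j + 1 in conserved else ""))
             for j in range(cons.length)],
            columns=["column", "modal_residue", "count", "fraction", "tier"],
        ))

        # phylogeny + subfamily assignment
        aligned = aligned_from_hits(hits)
        if inputs.reference_domains_fasta and inputs.reference_labels_tsv:
            refs = read_fasta(inputs.reference_domains_fasta)
            labels_df = pd.read_csv(inputs.reference_labels_tsv, sep="\t",
                                    dtype=str)
            labels = dict(zip(labels_df["id"], labels_df["subfamily"]))
            for r in refs:
                if len(r.sequence) != len(next(iter(aligned.values()))):
                    raise StageError(
                        "tree", f"reference domain {r.id} not in profile coordinates")
                aligned[r.id] = r.sequence
        else:
            labels = {}
            manifest.skipped["subfamily_assignment"] = "no labeled reference domains"
        if len(aligned) >= 3:
            tree = bootstrap(aligned, replicates=config.bootstrap_replicates,
                             seed=config.seed, model=config.distance_model)
            write_newick(tree, out_dir / "tree.nwk")
            manifest.outputs["tree.nwk"] = _checksum(out_dir / "tree.nwk")
            if labels:
                assignment = assign_subfamilies(
                    tree, labels, distance_ceiling=config.assignment_distance_ceiling)
                rows = [(q, sf, ref, round(dist, 6), True)
                        for q, (sf, ref, dist) in sorted(assignment.assignments.items())]
                rows += [(q, "", "", "", False) for q in sorted(assignment.unplaced)]
                emit("subfamilies.tsv", pd.DataFrame(
                    rows, columns=["query_id", "subfamily", "reference_id",
                                   "distance", "placed"]))
        else:
            manifest.skipped["tree"] = "fewer than 3 domains"

        # redundancy clustering
        representatives, membership = cluster_redundant(
            proteins, identity_threshold=config.redundancy_threshold,
            gap_open=config.sw_gap_open, gap_extend=config.sw_gap_extend)
        emit("redundancy.tsv", pd.DataFrame(
            sorted(membership.items()), columns=["member", "representative"]))

        # orthologs
        if inputs.ortholog_references:
            all_refs = []
            for species, path in inputs.ortholog_references.items():
                all_refs.extend(read_fasta(path, species=species))
            table = call_orthologs(
                proteins, all_refs,
                min_length=config.ortholog_min_length,
                min_identity=config.ortholog_min_identity,
                gap_open=config.sw_gap_open, gap_extend=config.sw_gap_extend,
                reciprocal=config.reciprocal_orthologs)
            emit("orthologs.tsv", table)
        else:
            manifest.skipped["orthologs"] = "no reference proteomes configured"
    else:
        manifest.skipped["sequence_stages"] = "proteins or seed alignment not configured"

    # --- expression stages ----------------------------------------------
    if inputs.expression_tsv and inputs.expression_meta_tsv and inputs.reference_genes_txt:
        try:
            matrix = read_expression(inputs.expression_tsv, inputs.expression_meta_tsv)
            ref_ids = [l.strip() for l in
                       Path(inputs.reference_genes_txt).read_text().splitlines()
                       if l.strip()]
            nm = normalize(matrix, ref_ids)
        except ValidationError as exc:
            raise StageError("expression", str(exc)) from exc
        emit("normalized.tsv", nm.values.round(6), index=True, index_label="gene")
        clustering = cluster_subgroups(
            nm, k=config.cluster_k, linkage=config.linkage, metric=config.metric)
        emit("subgroups.tsv", pd.DataFrame(
            sorted(clustering.assignments.items()), columns=["gene", "subgroup"]))
        blocks = detect_blocks(clustering, nm,
                               margin_threshold=config.block_margin_threshold)
        emit("blocks.tsv", pd.DataFrame(
            [(b.subgroup, b.dominant_tissue, round(b.margin, 6), b.specific)
             for b in blocks],
            columns=["subgroup", "dominant_tissue", "margin", "specific"]))
        if inputs.qpcr_tsv:
            qpcr = read_expression(inputs.qpcr_tsv, inputs.expression_meta_tsv)
            agreement = qpcr_agreement(matrix, qpcr, scale=config.correlation_scale)
            agreement["r"] = agreement["r"].round(6)
            agreement["p"] = agreement["p"].map(lambda p: f"{p:.4g}")
            emit("qpcr_agreement.tsv", agreement)
        else:
            manifest.skipped["qpcr"] = "no qPCR table configured"
    else:
        manifest.skipped["expression_stages"] = "expression inputs not configured"

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_yaml(out_dir / "manifest.yaml")
    return manifest


def summarize(manifest: RunManifest, out_dir: Path) -> pd.DataFrame:
    """One-table summary of a finished run's headline counts."""
    out_dir = Path(out_dir)
    rows: list[tuple[str, object]] = []

    def read(name: str) -> pd.DataFrame | None:
        path = out_dir / name
        return pd.read_csv(path, sep="\t") if path.exists() else None

    hits = read("domain_hits.tsv")
    missing = read("proteins_without_hit.tsv")
    if hits is not None:
        n_missing = 0 if missing is None else len(missing)
        rows.append(("n_proteins", len(hits) + n_missing))
        rows.append(("n_with_domain_hit", len(hits)))
    classification = read("classification.tsv")
    if classification is not None:
        for cat, count in classification["category"].value_counts().items():
            rows.append((f"n_{cat.lower()}", int(count)))
    conservation = read("conservation.tsv")
    if conservation is not None:
        tiers = conservation["tier"].fillna("")
        rows.append(("n_conserved_positions", int((tiers != "").sum())))
        rows.append(("n_highly_conserved_positions", int((tiers == "high").sum())))
    subfamilies = read("subfamilies.tsv")
    if subfamilies is not None:
        placed = subfamilies[subfamilies["placed"] == True]  # noqa: E712
        rows.append(("n_subfamilies_used", placed["subfamily"].nunique()))
        rows.append(("n_unplaced", int((subfamilies["placed"] == False).sum())))  # noqa: E712
    orthologs = read("orthologs.tsv")
    if orthologs is not None and len(orthologs):
        for key, val in ortholog_summary(orthologs).items():
            rows.append((f"orthologs_{key}", val))
    elif "orthologs.tsv" in manifest.outputs:
        rows.append(("orthologs_total", "NA"))
    redundancy = read("redundancy.tsv")
    if redundancy is not None:
        rows.append(("n_redundancy_clusters", redundancy["representative"].nunique()))
    blocks = read("blocks.tsv")
    if blocks is not None:
        rows.append(("n_subgroups", len(blocks)))
        rows.append(("n_tissue_specific_blocks", int(blocks["specific"].sum())))
    summary = pd.DataFrame(rows, columns=["quantity", "value"])
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    return summary
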