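"""Readers and writers for the external formats the survey touches.

Protein sequences travel as FASTA, expression data as TSV matrices with a
sample-metadata TSV, trees as Newick with bootstrap counts as internal-node
labels, and run configuration as YAML.  All parsing validates the
invariants of the in-memory types; errors name the offending line, record
or sample.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("bhlh_survey")

#: the 20 standard amino acids, alphabetical one-letter codes
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_LETTERS = set(AMINO_ACIDS) | {"X", "-"}  # '-' only in aligned records


class FastaParseError(ValueError):
    """Malformed FASTA input (bad header, empty sequence, duplicate id)."""


class ValidationError(ValueError):
    """Input violates a documented invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified protein sequence with an optional source tag.

    Sequences are uppercased on construction; letters outside the 20
    standard amino acids are replaced with ``X`` (ambiguity codes are
    expected in translated-assembly input) and the substitution is logged.
    """

    id: str
    sequence: str
    species: str = ""
    subfamily_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record id must be non-empty")
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if not set(seq) <= _VALID_LETTERS:
            bad = sorted(set(seq) - _VALID_LETTERS)
            logger.warning(
                "record %s: non-standard residue(s) %s replaced with X",
                self.id, ",".join(bad),
            )
            seq = "".join(c if c in _VALID_LETTERS else "X" for c in seq)
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ExpressionMatrix:
    """A gene x sample FPKM table with a tissue label per sample.

    ``values`` is a pandas DataFrame indexed by gene id with sample-id
    columns; entries are non-negative reals.  Row and column order is
    preserved exactly as parsed.
    """

    values: pd.DataFrame
    sample_tissue: dict[str, str]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.sample_tissue]
        if missing:
            raise ValidationError(
                f"samples missing from tissue metadata: {', '.join(map(str, missing))}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], dict(self.sample_tissue))


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with documented defaults.

    Thresholds mirror the survey conventions: a ~14-column basic region
    holding at least 6 basic residues for DNA binding, conservation tiers
    at "more than 100 of 225" (fraction 0.4445, strict) and 75%
    (inclusive), ortholog filters at aligned length > 60 and identity
    > 80%, redundancy clustering at 0.95 identity.
    """

    # domain profile / scan
    pseudocount: float = 1.0
    min_score: float = 15.0         # bits; acceptance threshold for a domain hit
    gap_open: float = -4.0          # bits, profile scan
    gap_extend: float = -1.0
    # region partition, 1-based inclusive profile columns
    basic_span: tuple[int, int] = (1, 14)
    helix1_span: tuple[int, int] = (15, 29)
    loop_span: tuple[int, int] = (30, 36)
    helix2_span: tuple[int, int] = (37, 50)
    # classifier
    min_basic_residues: int = 6
    # conservation tiers
    conserved_min_fraction: float = 0.4445
    high_min_fraction: float = 0.75
    # phylogeny
    bootstrap_replicates: int = 1000
    distance_model: str = "p"       # "p" or "poisson"
    assignment_distance_ceiling: float = 0.8
    # homology
    ortholog_min_length: int = 61   # aligned length must be >= this (i.e. > 60)
    ortholog_min_identity: float = 80.0  # percent, exclusive
    redundancy_threshold: float = 0.95
    sw_gap_open: float = 11.0
    sw_gap_extend: float = 1.0
    reciprocal_orthologs: bool = False
    # expression
    cluster_k: int = 14
    linkage: str = "complete"
    metric: str = "euclidean"
    block_margin_threshold: float = 0.5
    correlation_scale: str = "log2"  # "log2" or "raw"
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValidationError("seed must be an integer")
        checks = [
            (0 <= self.conserved_min_fraction <= 1, "conserved_min_fraction in [0,1]"),
            (0 <= self.high_min_fraction <= 1, "high_min_fraction in [0,1]"),
            (0 < self.redundancy_threshold <= 1, "redundancy_threshold in (0,1]"),
            (self.min_basic_residues >= 0, "min_basic_residues >= 0"),
            (self.bootstrap_replicates >= 1, "bootstrap_replicates >= 1"),
            (self.cluster_k >= 1, "cluster_k >= 1"),
            (0 <= self.ortholog_min_identity <= 100, "ortholog_min_identity in [0,100]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(f"config: {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {', '.join(sorted(unknown))}")
        for key in ("basic_span", "helix1_span", "loop_span", "helix2_span"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("basic_span", "helix1_span", "loop_span", "helix2_span"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Duplicate ids are rejected; sequences are uppercased.  An entry with an
    empty sequence or a bare ``>`` header raises :class:`FastaParseError`
    naming the line.
    """
    path = Path(path)
    # pre-scan for structural errors with line numbers (SeqIO is permissive)
    seen: set[str] = set()
    with open(path) as fh:
        current_id: str | None = None
        current_len = 0
        header_line = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if current_id is not None and current_len == 0:
                    raise FastaParseError(
                        f"{path}:{header_line}: record {current_id!r} has an empty sequence"
                    )
                current_id = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
                header_line = lineno
                if not current_id:
                    raise FastaParseError(f"{path}:{lineno}: malformed header {line!r}")
                if current_id in seen:
                    raise FastaParseError(
                        f"{path}:{lineno}: duplicate record id {current_id!r}"
                    )
                seen.add(current_id)
                current_len = 0
            elif line.strip():
                if current_id is None:
                    raise FastaParseError(f"{path}:{lineno}: sequence data before any header")
                current_len += len(line.strip())
        if current_id is not None and current_len == 0:
            raise FastaParseError(
                f"{path}:{header_line}: record {current_id!r} has an empty sequence"
            )
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq), species=species)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA.  Empty input is an error."""
    records = list(records)
    if not records:
        raise ValidationError("write_fasta: no records to write")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_expression(matrix_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV plus a sample->tissue metadata TSV.

    The matrix has a header row of sample ids and gene ids in the first
    column.  The metadata TSV has columns ``sample`` and ``tissue``.
    Negative values and samples without tissue labels are validation errors.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if not {"sample", "tissue"} <= set(meta.columns):
        raise ValidationError(
            f"{meta_path}: metadata must have 'sample' and 'tissue' columns"
        )
    sample_tissue = dict(zip(meta["sample"], meta["tissue"]))
    return ExpressionMatrix(values=values, sample_tissue=sample_tissue)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     meta_path: str | Path | None = None) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene")
    if meta_path is not None:
        pd.DataFrame(
            {"sample": list(matrix.sample_tissue),
             "tissue": [matrix.sample_tissue[s] for s in matrix.sample_tissue]}
        ).to_csv(meta_path, sep="\t", index=False)


def write_newick(tree: "PhyloTree", path: str | Path) -> None:  # noqa: F821
    """Serialize a tree as Newick with branch lengths and integer bootstrap
    labels on internal nodes."""
    from bhlh_survey.phylogeny import PhyloTree  # local import avoids a cycle

    if not isinstance(tree, PhyloTree):
        raise TypeError("write_newick expects a PhyloTree")
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path: str | Path) -> "PhyloTree":  # noqa: F821
    """Parse a Newick file (via dendropy) into a :class:`PhyloTree`."""
    from bhlh_survey.phylogeny import PhyloTree, TreeNode

    dtree = dendropy.Tree.get(path=str(path), schema="newick",
                              suppress_internal_node_taxa=False)

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise ValidationError("newick leaf without a label")
            node = TreeNode(name=dnode.taxon.label)
        else:
            support = None
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is not None:
                try:
                    support = int(float(label))
                except ValueError:
                    support = None
            node = TreeNode(name=None, support=support)
        node.length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    return PhyloTree(root=root)
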