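"""Pairwise local alignment, ortholog calling, redundancy clustering and
chromosome-distribution summaries.

Ortholog calling follows a best-hit protocol with hard filters: the local
alignment must cover more than 60 aligned amino-acid columns (roughly the
conserved domain length) and exceed 80% identity.  Redundancy clustering
reproduces greedy longest-first dereplication semantics (the cd-hit
approach) at a configurable identity threshold, where identity is
identical positions divided by the shorter sequence's length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from bhlh_survey.io_formats import ProteinRecord, ValidationError

logger = logging.getLogger("bhlh_survey")


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    aligned_length: int   # aligned (non-gap) columns
    identities: int
    score: float

    def __post_init__(self) -> None:
        if self.identities > self.aligned_length:
            raise ValidationError("identities cannot exceed aligned length")

    @property
    def percent_identity(self) -> float:
        if self.aligned_length == 0:
            return 0.0
        return 100.0 * self.identities / self.aligned_length


def _make_aligner(gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _identity_stats(alignment) -> tuple[int, int]:
    """(aligned_length, identities) over non-gap columns of an alignment."""
    aligned_length = 0
    identities = 0
    qseq, sseq = alignment.sequences
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        aligned_length += qe - qs
        for a, b in zip(qseq[qs:qe], sseq[ss:se]):
            if a == b:
                identities += 1
    return aligned_length, identities


def smith_waterman(
    a: ProteinRecord,
    b: ProteinRecord,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal local alignment under BLOSUM62 with affine gaps.

    Identities are counted over aligned columns only (gap columns
    excluded).  A best score <= 0 is reported as an empty alignment.
    """
    if not a.sequence or not b.sequence:
        raise ValidationError("cannot align empty sequences")
    aligner = _make_aligner(gap_open, gap_extend, "local")
    score = float(aligner.score(a.sequence, b.sequence))
    if score <= 0:
        return AlignmentResult(a.id, b.id, 0, 0, 0.0)
    alignment = next(iter(aligner.align(a.sequence, b.sequence)))
    aligned_length, identities = _identity_stats(alignment)
    return AlignmentResult(a.id, b.id, aligned_length, identities, score)


#: columns of an ortholog table
ORTHOLOG_COLUMNS = ["wheat_id", "partner_species", "partner_id",
                    "percent_identity", "aligned_length"]


def call_orthologs(
    wheat: Sequence[ProteinRecord],
    references: Sequence[ProteinRecord],
    min_length: int = 61,
    min_identity: float = 80.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    reciprocal: bool = False,
) -> pd.DataFrame:
    """Best cross-species hits passing the aligned-length/identity filters.

    For each wheat protein and each reference species, the best-scoring
    partner is retained iff ``aligned_length >= min_length`` (default 61,
    i.e. strictly more than 60 columns) and ``percent_identity >
    min_identity`` (default 80, exclusive).  With ``reciprocal=True`` the
    wheat protein must also be its partner's best wheat hit.
    """
    if not wheat or not references:
        raise ValidationError("both sequence collections must be non-empty")
    by_species: dict[str, list[ProteinRecord]] = {}
    for ref in references:
        by_species.setdefault(ref.species or "reference", []).append(ref)

    rows = []
    best_back: dict[str, str] = {}
    if reciprocal:
        for ref in references:
            hits = [smith_waterman(ref, w, gap_open, gap_extend) for w in wheat]
            best = max(hits, key=lambda h: (h.score, h.subject_id))
            best_back[ref.id] = best.subject_id
    for w in wheat:
        for species, refs in by_species.items():
            hits = [smith_waterman(w, r, gap_open, gap_extend) for r in refs]
            best = max(hits, key=lambda h: (h.score, h.subject_id))
            if best.aligned_length < min_length:
                continue
            if best.percent_identity <= min_identity:
                continue
            if reciprocal and best_back.get(best.subject_id) != w.id:
                continue
            rows.append((w.id, species, best.subject_id,
                         best.percent_identity, best.aligned_length))
    return pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)


def ortholog_summary(table: pd.DataFrame) -> dict[str, int]:
    """Counts of wheat genes with partners in one species only, or several.

    Returns ``{"<species>_only": ..., "both": ..., "total": ...}`` — the
    survey's headline "orthologs in A only / B only / both" partition.
    """
    species = sorted(table["partner_species"].unique())
    per_gene = table.groupby("wheat_id")["partner_species"].agg(set)
    out: dict[str, int] = {}
    for sp in species:
        out[f"{sp}_only"] = int(sum(s == {sp} for s in per_gene))
    out["both"] = int(sum(len(s) > 1 for s in per_gene))
    out["total"] = int(len(per_gene))
    return out


def cluster_redundant(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.95,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Greedy longest-first dereplication.

    Sequences are processed by decreasing length (ties by id); each joins
    the first existing representative with global identity >= threshold
    (identity = identical aligned positions / shorter sequence length),
    otherwise it founds a new cluster.  Returns (representatives,
    member_id -> representative_id).
    """
    if not records:
        raise ValidationError("no records to cluster")
    aligner = _make_aligner(gap_open, gap_extend, "global")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    representatives: list[ProteinRecord] = []
    membership: dict[str, str] = {}
    for rec in order:
        assigned = False
        for rep in representatives:
            alignment = next(iter(aligner.align(rec.sequence, rep.sequence)))
            _, identities = _identity_stats(alignment)
            identity = identities / min(len(rec), len(rep))
            if identity >= identity_threshold:
                membership[rec.id] = rep.id
                assigned = True
                break
        if not assigned:
            representatives.append(rec)
            membership[rec.id] = rec.id
    return representatives, membership


#: the 21 chromosomes of hexaploid bread wheat
WHEAT_CHROMOSOMES = tuple(
    f"{num}{sub}" for num in range(1, 8) for sub in "ABD"
)


def read_locations(path) -> pd.DataFrame:
    """Gene locations TSV: columns gene, chromosome, start, end (1-based)."""
    loc = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    required = {"gene", "chromosome", "start", "end"}
    if not required <= set(loc.columns):
        raise ValidationError(f"location table must have columns {sorted(required)}")
    if (loc["start"] >= loc["end"]).any():
        raise ValidationError("location table: start must be < end")
    return loc.set_index("gene")


def chromosome_distribution(
    locations: pd.DataFrame,
    genes: Iterable[str],
    universe: Sequence[str] = WHEAT_CHROMOSOMES,
) -> tuple[dict[str, int], list[str]]:
    """Per-chromosome gene counts plus the list of unmapped genes.

    Chromosomes outside ``universe`` are binned under "scaffold"; genes
    absent from the location table are returned unmapped, so
    ``sum(counts) + len(unmapped) == len(genes)``.
    """
    counts = {chrom: 0 for chrom in universe}
    counts["scaffold"] = 0
    unmapped = []
    for gene in genes:
        if gene not in locations.index:
            unmapped.append(gene)
            continue
        chrom = str(locations.loc[gene, "chromosome"])
        counts[chrom if chrom in counts else "scaffold"] += 1
    return counts, unmapped
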