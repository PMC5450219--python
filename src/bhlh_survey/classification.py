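"""DNA-binding classification of the basic region and family conservation.

bHLH factors bind E-box DNA elements (5'-CANNTG-3'), with the G-box
(CACGTG) as the best-studied special case, through the basic region at
the domain's N-terminus.  Binding competence requires a minimum number of
basic residues (Lys/Arg/His) there — typically six — and recognition of
the E-box/G-box depends on specific residues at conserved basic-region
positions (Glu and Arg for the E-box core; an additional His/Arg pair for
G-box discrimination).  This module applies that rule to classify each
domain into one of four categories, and computes per-column conservation
of the family in profile coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from bhlh_survey.domain_profile import GAP, DomainHit, RegionPartition
from bhlh_survey.io_formats import ProteinRecord, ValidationError


class BindingCategory(str, Enum):
    """Four DNA-binding classes of a bHLH basic region."""

    EG_BOX = "EG_BOX"              # binds both E-box and G-box
    E_BOX_ONLY = "E_BOX_ONLY"
    OTHER_BINDING = "OTHER_BINDING"  # binding-competent, fails E-box requirements
    NON_BINDING = "NON_BINDING"      # too few basic residues to contact DNA


class ConfigurationError(ValueError):
    """Classifier rule incompatible with the region partition."""


BASIC_RESIDUES = frozenset("KRH")


@dataclass(frozen=True)
class ClassifierRule:
    """Residue requirements on the basic region, in 1-based profile columns.

    ``ebox_requirements`` must all hold for E-box recognition;
    ``gbox_extra_requirements`` additionally for G-box.  A gap at a
    required column counts as unmet (conservative: a deleted position
    cannot make the DNA contact).
    """

    min_basic_residues: int = 6
    basic_residue_set: frozenset[str] = BASIC_RESIDUES
    ebox_requirements: tuple[tuple[int, str], ...] = ((7, "E"), (10, "R"))
    gbox_extra_requirements: tuple[tuple[int, str], ...] = ((2, "H"), (11, "R"))


def classify(hit: DomainHit, regions: RegionPartition,
             rule: ClassifierRule | None = None) -> BindingCategory:
    """Assign one of the four binding categories to a domain hit.

    Order of evaluation: fewer than ``min_basic_residues`` basic residues
    in the basic region -> NON_BINDING; all E-box and all G-box
    requirements met -> EG_BOX; E-box only -> E_BOX_ONLY; otherwise
    OTHER_BINDING.
    """
    rule = rule or ClassifierRule()
    lo, hi = regions.basic
    required_cols = [c for c, _ in rule.ebox_requirements + rule.gbox_extra_requirements]
    for col in required_cols:
        if not (lo + 1 <= col <= hi):
            raise ConfigurationError(
                f"rule column {col} outside basic region {lo + 1}..{hi}"
            )
    basic_residues = sum(
        1 for c in range(lo, hi) if hit.residues[c] in rule.basic_residue_set
    )
    if basic_residues < rule.min_basic_residues:
        return BindingCategory.NON_BINDING
    ebox = all(hit.residue_at(col) == aa for col, aa in rule.ebox_requirements)
    gbox = all(hit.residue_at(col) == aa for col, aa in rule.gbox_extra_requirements)
    if ebox and gbox:
        return BindingCategory.EG_BOX
    if ebox:
        return BindingCategory.E_BOX_ONLY
    return BindingCategory.OTHER_BINDING


def count_basic_residues(hit: DomainHit, regions: RegionPartition,
                         rule: ClassifierRule | None = None) -> int:
    rule = rule or ClassifierRule()
    lo, hi = regions.basic
    return sum(1 for c in range(lo, hi) if hit.residues[c] in rule.basic_residue_set)


def classify_collection(
    hits: Iterable[DomainHit], regions: RegionPartition,
    rule: ClassifierRule | None = None,
) -> dict[str, BindingCategory]:
    return {h.protein_id: classify(h, regions, rule) for h in hits}


def category_counts(categories: Iterable[BindingCategory]) -> dict[BindingCategory, int]:
    counts = Counter(categories)
    return {cat: counts.get(cat, 0) for cat in BindingCategory}


@dataclass
class ConservationProfile:
    """Modal residue and its frequency at each profile column.

    ``fraction`` uses the total number of sequences as denominator, so a
    column that is often deleted cannot appear conserved.  Tier
    thresholds: ``conserved`` requires the modal count to exceed
    ``conserved_min_fraction * n`` strictly (the "more than 100 of 225"
    convention); ``highly_conserved`` requires fraction >=
    ``high_min_fraction`` (inclusive).
    """

    modal_residues: list[str]
    counts: list[int]
    n_sequences: int
    conserved_min_fraction: float = 0.4445
    high_min_fraction: float = 0.75

    @property
    def fractions(self) -> list[float]:
        return [c / self.n_sequences for c in self.counts]

    @property
    def length(self) -> int:
        return len(self.modal_residues)


def conservation_profile(
    hits: Sequence[DomainHit],
    records: Sequence[ProteinRecord] | None = None,
    conserved_min_fraction: float = 0.4445,
    high_min_fraction: float = 0.75,
) -> ConservationProfile:
    """Per-column modal residue, count and fraction over a set of hits.

    Gaps and ambiguity (X) are excluded from the modal tally but retained
    in the denominator.  Modal ties break alphabetically.
    """
    if len(hits) < 2:
        raise ValidationError("conservation profile needs at least 2 hits")
    ncol = len(hits[0].residues)
    if any(len(h.residues) != ncol for h in hits):
        raise ValidationError("hits must share profile coordinates")
    modal, counts = [], []
    for j in range(ncol):
        tally = Counter(
            h.residues[j] for h in hits if h.residues[j] not in (GAP, "X")
        )
        if tally:
            top = max(tally.items(), key=lambda kv: (kv[1], -ord(kv[0])))
            # alphabetical tie-break: among max counts pick smallest letter
            best_count = top[1]
            residue = min(r for r, c in tally.items() if c == best_count)
            modal.append(residue)
            counts.append(best_count)
        else:
            modal.append(GAP)
            counts.append(0)
    return ConservationProfile(
        modal_residues=modal, counts=counts, n_sequences=len(hits),
        conserved_min_fraction=conserved_min_fraction,
        high_min_fraction=high_min_fraction,
    )


def conserved_positions(profile: ConservationProfile) -> tuple[list[int], list[int]]:
    """(conserved, highly_conserved) 1-based profile columns.

    ``conserved``: modal count strictly greater than
    ``conserved_min_fraction * n``.  ``highly_conserved``: modal fraction
    at least ``high_min_fraction``.
    """
    threshold = profile.conserved_min_fraction * profile.n_sequences
    conserved = [j + 1 for j, c in enumerate(profile.counts) if c > threshold]
    highly = [
        j + 1 for j, f in enumerate(profile.fractions)
        if f >= profile.high_min_fraction
    ]
    return conserved, highly


def mutation_report(
    hits: Sequence[DomainHit],
    column_1based: int,
    reference_residue: str,
) -> list[tuple[str, str]]:
    """Proteins whose residue at a profile column differs from the reference.

    A deleted column is reported as ``"lost"`` — e.g. surveying which
    family members replaced or lost an otherwise invariant Leu.
    """
    if not hits:
        return []
    ncol = len(hits[0].residues)
    if not (1 <= column_1based <= ncol):
        raise ValidationError(f"column {column_1based} outside profile 1..{ncol}")
    report = []
    for h in hits:
        observed = h.residue_at(column_1based)
        if observed == reference_residue:
            continue
        report.append((h.protein_id, "lost" if observed == GAP else observed))
    return report
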