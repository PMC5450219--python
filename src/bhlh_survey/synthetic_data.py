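"""Synthetic inputs with the statistical structure the survey assumes.

Two generators, both pure functions of their seed:

``generate_family``
    Subfamily-structured protein families.  Each subfamily derives from a
    random ~60-residue archetype domain; members mutate it at a
    per-position substitution rate, then the basic-region columns that
    determine the DNA-binding category are overwritten *last*, so the
    planted category always holds under the default classifier rule.
    Domains are embedded in random flanking sequence.  The default
    conditions mirror a hexaploid-wheat-scale survey: 23 subfamilies,
    ~10 members each, category mix proportional to 133:45:28:19
    (E/G-box : E-box-only : other-binding : non-binding).

``generate_expression``
    Block-structured tissue-specific FPKM matrices.  Gene baselines are
    log-normal (meanlog 1, sdlog 1); a gene assigned to a tissue block is
    elevated ``block_effect``-fold in that tissue's samples; reference
    genes have constant mean across tissues; qPCR values for a small
    endosperm-block panel are the FPKM values under multiplicative
    log-normal noise.  Defaults mirror the surveyed tissue panel: seven
    tissues (endosperm, aleurone, seedling, spike, flag leaf, shoot,
    root), 225 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from bhlh_survey.classification import BindingCategory, ClassifierRule
from bhlh_survey.io_formats import AMINO_ACIDS, ExpressionMatrix, ProteinRecord, ValidationError

#: amino acids that are not basic (no K, R or H)
_NON_BASIC = "".join(a for a in AMINO_ACIDS if a not in "KRH")
_BASIC = "KR"  # planted basic residues (H reserved for the G-box contact)

DEFAULT_CATEGORY_MIX = (133 / 225, 45 / 225, 28 / 225, 19 / 225)
CATEGORY_ORDER = (
    BindingCategory.EG_BOX,
    BindingCategory.E_BOX_ONLY,
    BindingCategory.OTHER_BINDING,
    BindingCategory.NON_BINDING,
)


@dataclass(frozen=True)
class FamilySpec:
    n_subfamilies: int = 23
    members_per_subfamily: int = 10
    domain_length: int = 60
    per_position_substitution_rate: float = 0.05
    flank_length_range: tuple[int, int] = (10, 50)
    category_mix: tuple[float, float, float, float] = DEFAULT_CATEGORY_MIX
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValidationError("category_mix must sum to 1")
        if not (0.0 <= self.per_position_substitution_rate <= 1.0):
            raise ValidationError("substitution rate must be in [0,1]")
        if self.n_subfamilies < 1 or self.members_per_subfamily < 1:
            raise ValidationError("counts must be positive")
        if self.domain_length < 50:
            raise ValidationError("domain_length must be >= 50")
        lo, hi = self.flank_length_range
        if not (0 <= lo <= hi):
            raise ValidationError("bad flank_length_range")


@dataclass(frozen=True)
class FamilyTruth:
    subfamily: str
    category: BindingCategory
    domain_start: int  # 0-based half-open protein coordinates
    domain_end: int


def _allocate_counts(n: int, mix: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n items to proportions."""
    raw = [n * p for p in mix]
    counts = [int(np.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _force_category(domain: list[str], category: BindingCategory,
                    rng: np.random.Generator, rule: ClassifierRule) -> None:
    """Overwrite basic-region columns so the planted category holds.

    Works in 0-based domain coordinates against the default rule geometry
    (basic region = first 14 columns).  Written last, after mutation, so
    the category truth always wins.
    """
    ebox = {col - 1: aa for col, aa in rule.ebox_requirements}
    gbox = {col - 1: aa for col, aa in rule.gbox_extra_requirements}
    rule_cols = set(ebox) | set(gbox)
    basic_span = range(0, 14)
    free_cols = [c for c in basic_span if c not in rule_cols]

    if category is BindingCategory.NON_BINDING:
        # strip every basic residue but keep the archetype elsewhere, so
        # the member still aligns to its subfamily and the truth label
        # sits well below the threshold rather than boundary-ambiguous
        for c in basic_span:
            if domain[c] in rule.basic_residue_set:
                domain[c] = _NON_BASIC[rng.integers(len(_NON_BASIC))]
        return

    # binding-competent: guarantee >= min_basic_residues basic residues
    for col, aa in ebox.items():
        domain[col] = aa
    if category is BindingCategory.EG_BOX:
        for col, aa in gbox.items():
            domain[col] = aa
    elif category is BindingCategory.E_BOX_ONLY:
        for col in gbox:  # break every G-box requirement, stay basic
            domain[col] = "K"
    else:  # OTHER_BINDING: break every E-box requirement
        for col in ebox:
            domain[col] = "Q"
        for col in gbox:
            domain[col] = "K"
    # real binding-competent basic regions are Lys/Arg-rich well beyond the
    # minimum; plant two residues above the threshold for the same reason
    present = sum(1 for c in basic_span if domain[c] in rule.basic_residue_set)
    deficit = rule.min_basic_residues + 2 - present
    if deficit > 0:
        non_basic_free = [c for c in free_cols
                          if domain[c] not in rule.basic_residue_set]
        chosen = rng.choice(len(non_basic_free), size=deficit, replace=False)
        for c in chosen:
            domain[non_basic_free[c]] = _BASIC[rng.integers(2)]


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def generate_family(
    spec: FamilySpec, rule: ClassifierRule | None = None
) -> tuple[list[ProteinRecord], dict[str, FamilyTruth]]:
    """Generate a subfamily-structured protein family with planted truth.

    Returns (records, truth) where truth maps each id to its subfamily,
    binding category and true domain span.  Deterministic in the seed.
    """
    rule = rule or ClassifierRule()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_subfamilies * spec.members_per_subfamily
    counts = _allocate_counts(n_total, spec.category_mix)
    labels = [cat for cat, c in zip(CATEGORY_ORDER, counts) for _ in range(c)]
    labels = [labels[i] for i in rng.permutation(n_total)]

    records: list[ProteinRecord] = []
    truth: dict[str, FamilyTruth] = {}
    member = 0
    for sf in range(spec.n_subfamilies):
        archetype = _random_sequence(spec.domain_length, rng)
        subfamily = f"SF{sf + 1:02d}"
        for _ in range(spec.members_per_subfamily):
            domain = list(archetype)
            mutate = rng.random(spec.domain_length) < spec.per_position_substitution_rate
            for pos in np.flatnonzero(mutate):
                alternatives = AMINO_ACIDS.replace(domain[pos], "")
                domain[pos] = alternatives[rng.integers(len(alternatives))]
            category = labels[member]
            _force_category(domain, category, rng, rule)
            lo, hi = spec.flank_length_range
            left = _random_sequence(int(rng.integers(lo, hi + 1)), rng)
            right = _random_sequence(int(rng.integers(lo, hi + 1)), rng)
            pid = f"syn{member + 1:03d}"
            seq = left + "".join(domain) + right
            records.append(ProteinRecord(id=pid, sequence=seq, species="synthetic"))
            truth[pid] = FamilyTruth(
                subfamily=subfamily, category=category,
                domain_start=len(left), domain_end=len(left) + spec.domain_length,
            )
            member += 1
    return records, truth


def true_domain_alignment(
    records: list[ProteinRecord], truth: Mapping[str, FamilyTruth]
) -> list[ProteinRecord]:
    """Extract the true (gapless, equal-length) domain alignment."""
    return [
        ProteinRecord(
            id=r.id,
            sequence=r.sequence[truth[r.id].domain_start:truth[r.id].domain_end],
            species=r.species,
        )
        for r in records
    ]


DEFAULT_TISSUES = ("endosperm", "aleurone", "seedling", "spike",
                   "flag_leaf", "shoot", "root")


@dataclass(frozen=True)
class ExpressionSpec:
    n_genes: int = 225
    n_tissues: int = 7
    samples_per_tissue: int = 4
    block_assignments: Mapping[str, str] | None = None  # default: round-robin
    block_effect: float = 4.0
    noise_sd: float = 0.5       # sd of log-normal multiplicative noise
    n_reference_genes: int = 5
    qpcr_noise_sd: float = 0.7  # pilot-tuned: log2-scale Pearson r ~ 0.7
    n_qpcr_genes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tissues, self.samples_per_tissue,
               self.n_reference_genes) < 1:
            raise ValidationError("counts must be positive")
        if self.block_effect <= 1:
            raise ValidationError("block_effect must be > 1")
        if self.noise_sd < 0 or self.qpcr_noise_sd < 0:
            raise ValidationError("noise sds must be >= 0")


def _tissue_names(n: int) -> list[str]:
    if n <= len(DEFAULT_TISSUES):
        return list(DEFAULT_TISSUES[:n])
    return list(DEFAULT_TISSUES) + [
        f"tissue{i:02d}" for i in range(len(DEFAULT_TISSUES) + 1, n + 1)
    ]


def generate_expression(
    spec: ExpressionSpec,
) -> tuple[ExpressionMatrix, list[str], ExpressionMatrix, dict[str, str]]:
    """Generate a block-structured FPKM matrix with references and qPCR panel.

    Returns (matrix, reference_ids, qpcr, truth_blocks).  The matrix
    includes the reference genes as extra rows; ``truth_blocks`` maps each
    non-reference gene to the tissue where it is elevated.  The qPCR panel
    covers ``n_qpcr_genes`` genes from the first tissue's block with
    multiplicative log-normal noise of sd ``qpcr_noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    tissues = _tissue_names(spec.n_tissues)
    samples = [f"{t}_r{k + 1}" for t in tissues
               for k in range(spec.samples_per_tissue)]
    sample_tissue = {s: s.rsplit("_r", 1)[0] for s in samples}

    gene_ids = [f"g{i + 1:03d}" for i in range(spec.n_genes)]
    if spec.block_assignments is None:
        truth_blocks = {g: tissues[i % spec.n_tissues]
                        for i, g in enumerate(gene_ids)}
    else:
        unknown = set(spec.block_assignments.values()) - set(tissues)
        if unknown:
            raise ValidationError(f"block tissues not in panel: {sorted(unknown)}")
        truth_blocks = {g: spec.block_assignments.get(g) for g in gene_ids}

    base = rng.lognormal(mean=1.0, sigma=1.0, size=spec.n_genes)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, len(samples)))
    values = base[:, None] * np.exp(noise)
    for i, g in enumerate(gene_ids):
        tissue = truth_blocks.get(g)
        if tissue is None:
            continue
        for j, s in enumerate(samples):
            if sample_tissue[s] == tissue:
                values[i, j] *= spec.block_effect

    ref_ids = [f"ref{i + 1}" for i in range(spec.n_reference_genes)]
    ref_base = rng.lognormal(mean=1.0, sigma=1.0, size=spec.n_reference_genes)
    ref_noise = rng.normal(0.0, spec.noise_sd,
                           size=(spec.n_reference_genes, len(samples)))
    ref_values = ref_base[:, None] * np.exp(ref_noise)

    frame = pd.DataFrame(
        np.vstack([values, ref_values]),
        index=gene_ids + ref_ids, columns=samples,
    )
    matrix = ExpressionMatrix(values=frame, sample_tissue=dict(sample_tissue))

    first_block_genes = [g for g in gene_ids if truth_blocks.get(g) == tissues[0]]
    panel = first_block_genes[:spec.n_qpcr_genes]
    qpcr_noise = rng.normal(0.0, spec.qpcr_noise_sd,
                            size=(len(panel), len(samples)))
    qpcr_values = frame.loc[panel].to_numpy() * np.exp(qpcr_noise)
    qpcr = ExpressionMatrix(
        values=pd.DataFrame(qpcr_values, index=panel, columns=samples),
        sample_tissue=dict(sample_tissue),
    )
    return matrix, ref_ids, qpcr, {g: t for g, t in truth_blocks.items() if t}
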