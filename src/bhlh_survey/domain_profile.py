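"""Position-weight profile construction and glocal domain scanning.

The bHLH domain is a ~60-residue unit (basic region, helix 1, loop,
helix 2).  A :class:`DomainProfile` is built from a seed alignment of
known domains: per-column residue probabilities with a pseudocount, turned
into log-odds scores (bits) against a background distribution.  A protein
is scanned by glocal (global-in-profile, local-in-protein) dynamic
programming with affine gap costs: every profile column must be matched or
deleted, while the protein contributes an arbitrary substring; flanks are
free.  The loop region varies in length across family members, so gaps
must be affordable — the defaults (open -4, extend -1 bits) let a scan
absorb loop-length differences without losing the domain anchor.

Residues ``X`` (ambiguity) score 0 bits everywhere: they neither support
nor contradict a placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from bhlh_survey.io_formats import AMINO_ACIDS, ProteinRecord, RunConfig, ValidationError

logger = logging.getLogger("bhlh_survey")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP = "-"


@dataclass
class DomainProfile:
    """Log-odds profile over the 20 amino acids.

    ``probs[j, a]`` is the pseudocounted probability of amino acid ``a``
    at column ``j``; ``weights`` holds ``log2(probs / background)``.
    """

    probs: np.ndarray                 # (length, 20)
    background: np.ndarray            # (20,)
    pseudocount: float = 1.0
    dropped_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("profile column probabilities must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """Per-column log-odds scores in bits, shape (length, 20)."""
        return np.log2(self.probs / self.background[None, :])

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[a] for a in np.argmax(self.weights, axis=1))

    def max_score(self) -> float:
        """Sum of per-column maximum log-odds (gapless consensus score)."""
        return float(self.weights.max(axis=1).sum())


@dataclass(frozen=True)
class DomainHit:
    """A located domain: protein coordinates plus a per-column mapping.

    ``column_map[j]`` gives the 0-based protein index aligned to profile
    column ``j``, or ``None`` for a deleted column.  ``residues`` is the
    domain as a profile-coordinate string ('-' at deleted columns;
    protein insertions between columns are not represented — the profile
    coordinate system is what downstream classification and conservation
    index into).
    """

    protein_id: str
    start: int
    end: int
    score: float
    column_map: tuple[int | None, ...]
    residues: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"hit {self.protein_id}: bad span {self.start}..{self.end}")
        if len(self.column_map) != len(self.residues):
            raise ValidationError("column_map and residues length mismatch")
        if not np.isfinite(self.score):
            raise ValidationError("hit score must be finite")

    def residue_at(self, column_1based: int) -> str:
        """Residue at a 1-based profile column ('-' if the column is deleted)."""
        return self.residues[column_1based - 1]


@dataclass(frozen=True)
class RegionPartition:
    """Half-open profile-column spans for basic, helix1, loop and helix2."""

    basic: tuple[int, int]
    helix1: tuple[int, int]
    loop: tuple[int, int]
    helix2: tuple[int, int]

    def __post_init__(self) -> None:
        spans = [self.basic, self.helix1, self.loop, self.helix2]
        for lo, hi in spans:
            if not (0 <= lo < hi):
                raise ValidationError(f"bad region span {lo}..{hi}")
        for (prev, nxt) in zip(spans, spans[1:]):
            if prev[1] > nxt[0]:
                raise ValidationError("region spans must be disjoint and ordered")


def build_profile(
    aligned_domains: Sequence[ProteinRecord],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> DomainProfile:
    """Build a log-odds profile from an alignment of domain sequences.

    Column probabilities are ``(count + pseudocount) / (n + 20*pseudocount)``
    with ``n`` the non-gap observations in the column; ``X`` counts as no
    observation.  Columns with more than 50% gaps are dropped (logged).
    """
    if len(aligned_domains) < 2:
        raise ValidationError("profile needs at least 2 aligned sequences")
    lengths = {len(r.sequence) for r in aligned_domains}
    if len(lengths) != 1:
        raise ValidationError(f"ragged alignment: lengths {sorted(lengths)}")
    ncol = lengths.pop()
    nseq = len(aligned_domains)
    if background is None:
        background = np.full(20, 1 / 20)

    counts = np.zeros((ncol, 20))
    gaps = np.zeros(ncol, dtype=int)
    for rec in aligned_domains:
        for j, aa in enumerate(rec.sequence):
            if aa == GAP or aa == "X":
                gaps[j] += aa == GAP
            else:
                counts[j, _AA_INDEX[aa]] += 1

    keep = gaps <= nseq / 2
    dropped = [int(j) for j in np.flatnonzero(~keep)]
    if dropped:
        logger.info("build_profile: dropped %d gap-heavy column(s): %s",
                    len(dropped), dropped)
    counts = counts[keep]
    if counts.shape[0] < 30:
        raise ValidationError(
            f"seed alignment yields only {counts.shape[0]} usable columns (< 30)")
    nobs = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount) / (nobs + 20 * pseudocount)
    if pseudocount == 0:
        # avoid 0/0 on columns with no observations
        empty = nobs[:, 0] == 0
        probs[empty] = 1 / 20
    return DomainProfile(probs=probs, background=background,
                         pseudocount=pseudocount, dropped_columns=dropped)


def _score_matrix(profile: DomainProfile, sequence: str) -> np.ndarray:
    """(length x len(sequence)) log-odds of each residue at each column; X -> 0."""
    W = profile.weights
    S = np.zeros((profile.length, len(sequence)))
    for i, aa in enumerate(sequence):
        if aa != "X":
            S[:, i] = W[:, _AA_INDEX[aa]]
    return S


def scan_protein(
    profile: DomainProfile,
    protein: ProteinRecord,
    min_score: float = 15.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> DomainHit | None:
    """Locate the best glocal placement of the profile in a protein.

    Returns the maximum-scoring :class:`DomainHit` if its score reaches
    ``min_score`` bits, else ``None``.  Ties in score are broken by the
    smallest start coordinate.  A gap of length g costs
    ``gap_open + (g-1)*gap_extend`` (both negative, in bits).
    """
    n = len(protein.sequence)
    if n < 10:
        raise ValidationError(f"protein {protein.id} too short to scan ({n} aa)")
    L = profile.length
    S = _score_matrix(profile, protein.sequence)
    NEG = -1e30

    # DP over profile columns j=1..L; i indexes protein prefix length 0..n.
    # M[j,i]: column j matched to protein residue i-1.
    # D[j,i]: column j deleted, i residues consumed so far.
    # I[j,i]: protein residue i-1 inserted after column j.
    M = np.full((L + 1, n + 1), NEG)
    D = np.full((L + 1, n + 1), NEG)
    I = np.full((L + 1, n + 1), NEG)
    D[0, :] = 0.0  # free start anywhere in the protein
    idx = np.arange(n + 1)

    for j in range(1, L + 1):
        prev = np.maximum(np.maximum(M[j - 1], D[j - 1]), I[j - 1])
        M[j, 1:] = S[j - 1, :] + prev[:-1]
        open_from = np.maximum(M[j - 1], I[j - 1]) + gap_open
        # D[0] row holds 0 before any column: deletion at column 1 opens a gap
        if j == 1:
            open_from = np.maximum(open_from, D[0] + gap_open)
            D[j] = open_from
        else:
            D[j] = np.maximum(open_from, D[j - 1] + gap_extend)
        # I[j,i] = max over i'<i of base[i'] + gap_open + (i-i'-1)*gap_extend
        base = np.maximum(M[j], D[j])
        run = np.maximum.accumulate(base - gap_extend * idx)
        I[j, 1:] = run[:-1] + gap_open + gap_extend * (idx[1:] - 1)

    final = np.maximum(M[L], D[L])
    best = float(final.max())
    if best < min_score:
        return None

    tol = 1e-9
    candidate_ends = [int(i) for i in np.flatnonzero(final >= best - tol)]

    def traceback(end_i: int) -> tuple[int, list[int | None]]:
        col_map: list[int | None] = [None] * L
        j, i = L, end_i
        state = "M" if M[L, end_i] >= D[L, end_i] - tol else "D"
        while j > 0:
            if state == "M":
                col_map[j - 1] = i - 1
                prev_vals = (M[j - 1, i - 1], D[j - 1, i - 1], I[j - 1, i - 1])
                target = M[j, i] - S[j - 1, i - 1]
                state = "MDI"[int(np.argmax([v if abs(v - target) <= tol else NEG
                                             for v in prev_vals]))]
                j, i = j - 1, i - 1
            elif state == "D":
                opts = [
                    ("M", j - 1, M[j - 1, i] + gap_open),
                    ("I", j - 1, I[j - 1, i] + gap_open),
                ]
                if j > 1:
                    opts.append(("D", j - 1, D[j - 1, i] + gap_extend))
                else:
                    opts.append(("D", j - 1, D[0, i] + gap_open))
                for st, nj, val in opts:
                    if abs(val - D[j, i]) <= tol:
                        state, j = st, nj
                        if state == "D" and j == 0:
                            return i, col_map
                        break
                else:  # pragma: no cover - defensive
                    raise RuntimeError("traceback failed in D state")
            else:  # I: protein residue inserted
                opts = [
                    ("M", M[j, i - 1] + gap_open),
                    ("D", D[j, i - 1] + gap_open),
                    ("I", I[j, i - 1] + gap_extend),
                ]
                for st, val in opts:
                    if abs(val - I[j, i]) <= tol:
                        state, i = st, i - 1
                        break
                else:  # pragma: no cover - defensive
                    raise RuntimeError("traceback failed in I state")
        return i, col_map

    results = []
    for end_i in candidate_ends:
        start_i, col_map = traceback(end_i)
        matched = [c for c in col_map if c is not None]
        if not matched:
            continue
        results.append((start_i, end_i, col_map))
    if not results:
        return None
    start_i, end_i, col_map = min(results, key=lambda t: (t[0], t[1]))
    matched = [c for c in col_map if c is not None]
    start, end = min(matched), max(matched) + 1
    residues = "".join(
        protein.sequence[c] if c is not None else GAP for c in col_map
    )
    return DomainHit(
        protein_id=protein.id, start=start, end=end, score=best,
        column_map=tuple(col_map), residues=residues,
    )


def default_regions(
    profile: DomainProfile, config: RunConfig | None = None
) -> RegionPartition:
    """Partition the profile into basic/helix1/loop/helix2 spans.

    Default spans (1-based inclusive columns): basic 1-14, helix1 15-29,
    loop 30-36, helix2 37 to min(50, profile length); overridable through
    :class:`RunConfig`.  Profiles shorter than 50 columns need overrides.
    """
    cfg = config or RunConfig()
    overridden = config is not None and (
        cfg.basic_span, cfg.helix1_span, cfg.loop_span, cfg.helix2_span
    ) != (RunConfig().basic_span, RunConfig().helix1_span,
          RunConfig().loop_span, RunConfig().helix2_span)
    if profile.length < 50 and not overridden:
        raise ValidationError(
            f"profile has {profile.length} columns (< 50); supply region overrides"
        )

    def half_open(span: tuple[int, int], clamp: bool = False) -> tuple[int, int]:
        lo, hi = span
        if clamp:
            hi = min(hi, profile.length)
        if not (1 <= lo <= hi <= profile.length):
            raise ValidationError(f"region span {span} outside profile (1..{profile.length})")
        return (lo - 1, hi)

    return RegionPartition(
        basic=half_open(cfg.basic_span),
        helix1=half_open(cfg.helix1_span),
        loop=half_open(cfg.loop_span),
        helix2=half_open(cfg.helix2_span, clamp=True),
    )


def scan_collection(
    profile: DomainProfile,
    records: Iterable[ProteinRecord],
    min_score: float = 15.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> tuple[list[DomainHit], list[str]]:
    """Scan many proteins; returns (hits, ids_without_hit).

    Proteins lacking a hit are reported, never silently dropped — a family
    survey keeps track of members missing the domain signature.
    """
    hits, missing = [], []
    for rec in records:
        hit = scan_protein(profile, rec, min_score=min_score,
                           gap_open=gap_open, gap_extend=gap_extend)
        if hit is None:
            missing.append(rec.id)
        else:
            hits.append(hit)
    return hits, missing
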