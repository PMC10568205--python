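"""Scoring and assembly of CRISPR editing-cassette designs.

Each design introduces one amino-acid change (to A, W, Q, D or P) into an
essential gene via a 200-nt oligo that carries both the homology-directed
repair template and the sgRNA spacer, so the repair template doubles as a
strain barcode. Designs are ranked by a scoring table that rewards a short
distance between the silent PAM mutation and the target codon and a clean
off-target profile of the protospacer, with penalties when fewer than five
substitutions are possible at a site. Designs scoring below 3 are excluded.

Off-target classes of a protospacer (NGG PAMs only, both strands):

=====  ==============================  ===========================
class  11-nt PAM-proximal exact match  off-target with <=4 mismatches
=====  ==============================  ===========================
1      no                              no
2      no                              yes
3      yes                             no
4      yes                             yes
=====  ==============================  ===========================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from ._sequences import (
    CODON_TABLE,
    HOMOLOGY_ARM_LEN,
    OLIGO_MAX_LEN,
    PREFERRED_CODON,
    PROMOTER_J23119,
    PROTOSPACER_LEN,
    SGRNA_HANDLE,
    SPACER_MID,
    SPACER5,
    revcomp,
    translate,
)

__all__ = [
    "DesignCandidate",
    "OffTargetEvidence",
    "CassetteOligo",
    "DesignInfeasibleError",
    "CandidateOutOfRangeError",
    "classify_offtarget",
    "base_score",
    "score_design",
    "select_designs",
    "assemble_oligo",
]

#: Allowed destination amino acids for designed changes.
ALLOWED_MUT_AA = frozenset("AWQDP")

#: Base score at distance 0 for off-target classes 1-4.
CLASS_ANCHOR = {1: 5.0, 2: 4.41, 3: 3.9, 4: 2.0}

#: Score penalty by number of possible substitutions at the site.
SUBSTITUTION_PENALTY = {5: 0.0, 4: -0.95, 3: -1.25, 2: -3.0}

#: Designs below this score are excluded.
MIN_SCORE = 3.0

MAX_PAM_DISTANCE = 30


class DesignInfeasibleError(Exception):
    """No silent PAM-destroying edit is possible for this candidate."""


class CandidateOutOfRangeError(ValueError):
    """PAM distance exceeds the 30-nt design window."""


@dataclass
class DesignCandidate:
    """One proposed amino-acid change with its cassette-design context."""

    gene_id: str
    protein_pos: int  # 1-based
    wt_aa: str
    mut_aa: str
    pam_distance_nt: int
    offtarget_class: int
    n_substitutions_at_site: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.mut_aa not in ALLOWED_MUT_AA:
            raise ValueError(
                f"mut_aa must be one of A,W,Q,D,P; got {self.mut_aa!r}"
            )
        if self.offtarget_class not in CLASS_ANCHOR:
            raise ValueError(f"offtarget_class must be 1-4, got {self.offtarget_class}")
        if self.protein_pos < 1:
            raise ValueError("protein_pos is 1-based and must be >= 1")


@dataclass(frozen=True)
class OffTargetEvidence:
    """Genome-scan evidence for a protospacer's off-target liability."""

    has_proximal_match: bool
    has_mm4_offtarget: bool

    @property
    def offtarget_class(self) -> int:
        return {
            (False, False): 1,
            (False, True): 2,
            (True, False): 3,
            (True, True): 4,
        }[(self.has_proximal_match, self.has_mm4_offtarget)]


@dataclass(frozen=True)
class CassetteOligo:
    """Assembled 200-nt editing oligo (fixed segments + design-specific parts)."""

    gene_id: str
    spacer5: str
    homology_arm: str
    spacer_mid: str
    promoter: str
    protospacer: str
    handle: str
    pam_distance_nt: int = 0

    @property
    def full_sequence(self) -> str:
        return (
            self.spacer5
            + self.homology_arm
            + self.spacer_mid
            + self.promoter
            + self.protospacer
            + self.handle
        )


def _iter_pam_sites(seq: str):
    """Yield (protospacer, pam_pos, strand) for every NGG site on both strands.

    ``pam_pos`` is the 0-based position of the PAM's first base on the plus
    strand (for minus-strand sites, of the CCN triplet).
    """
    n = len(seq)
    for p in range(n - 2):
        if seq[p + 1 : p + 3] == "GG" and p >= PROTOSPACER_LEN:
            yield seq[p - PROTOSPACER_LEN : p], p, "+"
        if seq[p : p + 2] == "CC" and p + 3 + PROTOSPACER_LEN <= n:
            yield revcomp(seq[p + 3 : p + 3 + PROTOSPACER_LEN]), p, "-"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_offtarget(
    protospacer: str, genome: Mapping[str, str] | Iterable[str]
) -> OffTargetEvidence:
    """Exhaustively scan a genome for off-target sites of a protospacer.

    The scan enumerates every NGG-adjacent 20-mer on both strands of every
    sequence. The first site identical to the protospacer is taken to be the
    on-target site and excluded; any *other* site contributes evidence:
    an exact match of the 11 PAM-proximal nucleotides sets
    ``has_proximal_match``, a full-length match with at most 4 mismatches
    sets ``has_mm4_offtarget``.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt")
    if set(protospacer) - set("ACGT"):
        raise ValueError("protospacer contains ambiguous (non-ACGT) bases")
    seqs = genome.values() if isinstance(genome, Mapping) else list(genome)
    seqs = [s.upper() for s in seqs]
    if not seqs or not any(seqs):
        raise ValueError("genome is empty")

    proximal_q = protospacer[-11:]  # the 11 nt adjacent to the PAM
    on_target_skipped = False
    has_proximal = False
    has_mm4 = False
    for seq in seqs:
        for site, _pos, _strand in _iter_pam_sites(seq):
            if site == protospacer and not on_target_skipped:
                on_target_skipped = True
                continue
            if site[-11:] == proximal_q:
                has_proximal = True
            if _hamming(site, protospacer) <= 4:
                has_mm4 = True
            if has_proximal and has_mm4:
                return OffTargetEvidence(True, True)
    return OffTargetEvidence(has_proximal, has_mm4)


def base_score(offtarget_class: int, pam_distance_nt: int) -> float:
    """Distance/class score of a cassette design.

    Anchored at 5, 4.41, 3.9 and 2 for classes 1-4 at distance 0, dropping
    0.2 per 3-nt step; distances that are not multiples of 3 interpolate
    linearly (0.2/3 per nt). Distances beyond 30 nt are not designable.
    """
    if offtarget_class not in CLASS_ANCHOR:
        raise ValueError(f"offtarget_class must be 1-4, got {offtarget_class}")
    if pam_distance_nt < 0:
        raise ValueError("pam_distance_nt must be >= 0")
    if pam_distance_nt > MAX_PAM_DISTANCE:
        raise CandidateOutOfRangeError(
            f"PAM distance {pam_distance_nt} nt exceeds {MAX_PAM_DISTANCE} nt"
        )
    return CLASS_ANCHOR[offtarget_class] - 0.2 * pam_distance_nt / 3.0


def score_design(candidate: DesignCandidate) -> float | None:
    """Score a candidate; ``None`` means excluded (score < 3).

    score = base_score(class, distance) + substitution penalty
    (0 for 5 possible substitutions at the site, -0.95 for 4, -1.25 for 3,
    -3 for 2).
    """
    n_subs = candidate.n_substitutions_at_site
    if n_subs < 2 or n_subs > 5:
        raise ValueError(f"n_substitutions_at_site must be in 2..5, got {n_subs}")
    score = base_score(candidate.offtarget_class, candidate.pam_distance_nt)
    score += SUBSTITUTION_PENALTY[n_subs]
    if score < MIN_SCORE:
        return None
    return score


def select_designs(
    candidates: Sequence[DesignCandidate],
    max_sites: int = 10,
    max_subs_per_site: int = 5,
) -> list[DesignCandidate]:
    """Select up to ``max_sites`` sites per gene, each with up to
    ``max_subs_per_site`` substitutions, from scored candidates.

    Excluded candidates (score < 3) are dropped. Sites are ranked by their
    best candidate's score; ties break by smaller PAM distance, then lower
    protein position. The result is deterministic and invariant to input
    order.
    """
    scored: list[DesignCandidate] = []
    for cand in candidates:
        s = cand.score if cand.score is not None else score_design(cand)
        if s is not None:
            scored.append(replace(cand, score=s))

    out: list[DesignCandidate] = []
    genes = sorted({c.gene_id for c in scored})
    for gene in genes:
        sites: dict[int, list[DesignCandidate]] = {}
        for c in scored:
            if c.gene_id == gene:
                sites.setdefault(c.protein_pos, []).append(c)
        ranked_sites = sorted(
            sites.items(),
            key=lambda kv: (
                -max(c.score for c in kv[1]),
                min(c.pam_distance_nt for c in kv[1]),
                kv[0],
            ),
        )
        for pos, cands in ranked_sites[:max_sites]:
            cands = sorted(
                cands, key=lambda c: (-c.score, c.pam_distance_nt, c.mut_aa)
            )
            out.extend(cands[:max_subs_per_site])
    return out


def _pam_destroyed(seq: str, pam_pos: int, strand: str) -> bool:
    if strand == "+":
        return seq[pam_pos + 1 : pam_pos + 3] != "GG"
    return seq[pam_pos : pam_pos + 2] != "CC"


def _codon_bounds(pam_pos: int, strand: str) -> range:
    # positions whose edit can destroy the PAM (the two G/C bases; the N is free)
    if strand == "+":
        return range(pam_pos + 1, pam_pos + 3)
    return range(pam_pos, pam_pos + 2)


def assemble_oligo(
    candidate: DesignCandidate,
    cds: str,
    upstream: str = "",
    downstream: str = "",
) -> CassetteOligo:
    """Assemble the 200-nt editing oligo for a design candidate.

    The homology arm is an 85-nt window of the genomic context carrying the
    designed mutation (most-used synonymous codon for ``mut_aa``) plus one
    silent PAM-destroying edit, centered on the mutation codon and shifted
    when needed so both edits stay >=10 nt from the arm edges. The
    protospacer is the wild-type 20-mer adjacent to the chosen PAM. PAMs are
    searched within 30 nt of the target codon; the nearest feasible one is
    used. When the PAM overlaps the mutated codon and the mutation itself
    destroys it, no extra silent edit is made.
    """
    cds = cds.upper()
    context = upstream.upper() + cds + downstream.upper()
    cds_start = len(upstream)
    codon_start = cds_start + (candidate.protein_pos - 1) * 3
    codon_end = codon_start + 3
    if codon_end > cds_start + len(cds):
        raise ValueError("protein_pos outside the CDS")
    wt_codon = context[codon_start:codon_end]
    if CODON_TABLE.get(wt_codon) != candidate.wt_aa:
        raise ValueError(
            f"CDS codon {wt_codon} encodes {CODON_TABLE.get(wt_codon)}, "
            f"not the stated wild-type {candidate.wt_aa}"
        )
    mut_codon = PREFERRED_CODON[candidate.mut_aa]
    mutated = context[:codon_start] + mut_codon + context[codon_end:]

    def pam_distance(pam_pos: int) -> int:
        # nt between nearest edges of the 3-nt PAM and the target codon
        if pam_pos + 3 <= codon_start:
            return codon_start - (pam_pos + 3)
        if pam_pos >= codon_end:
            return pam_pos - codon_end
        return 0

    pams = sorted(
        (
            (pam_distance(pos), pos, strand, proto)
            for proto, pos, strand in _iter_pam_sites(context)
            if pam_distance(pos) <= MAX_PAM_DISTANCE
        ),
        key=lambda t: (t[0], t[1]),
    )
    if not pams:
        raise DesignInfeasibleError(
            f"no NGG PAM within {MAX_PAM_DISTANCE} nt of codon {candidate.protein_pos}"
        )

    for dist, pam_pos, strand, protospacer in pams:
        edited, edit_pos = _try_silent_pam_edit(
            mutated, pam_pos, strand, cds_start, cds_start + len(cds),
            codon_start, codon_end,
        )
        if edited is None:
            continue
        arm = _homology_arm(edited, codon_start, edit_pos)
        oligo = CassetteOligo(
            gene_id=candidate.gene_id,
            spacer5=SPACER5,
            homology_arm=arm,
            spacer_mid=SPACER_MID,
            promoter=PROMOTER_J23119,
            protospacer=protospacer,
            handle=SGRNA_HANDLE,
            pam_distance_nt=dist,
        )
        assert len(oligo.full_sequence) <= OLIGO_MAX_LEN
        return oligo
    raise DesignInfeasibleError(
        f"no silent PAM edit possible for {candidate.gene_id} "
        f"pos {candidate.protein_pos}"
    )


def _try_silent_pam_edit(
    mutated: str,
    pam_pos: int,
    strand: str,
    cds_start: int,
    cds_end: int,
    codon_start: int,
    codon_end: int,
):
    """Return (edited context, edit position) or (None, None).

    The edit position is ``None`` (with a valid context) when the designed
    mutation itself already destroyed the PAM.
    """
    if _pam_destroyed(mutated, pam_pos, strand):
        overlaps = pam_pos < codon_end and pam_pos + 3 > codon_start
        if overlaps:
            return mutated, None
        # PAM broken outside the codon without an edit: cannot happen for a
        # site enumerated on the wild type unless the codon overlapped it.
        return mutated, None
    for pos in _codon_bounds(pam_pos, strand):
        current = mutated[pos]
        for base in "ACGT":
            if base == current:
                continue
            trial = mutated[:pos] + base + mutated[pos + 1 :]
            if not _pam_destroyed(trial, pam_pos, strand):
                continue
            if cds_start <= pos < cds_end:
                frame = (pos - cds_start) % 3
                cstart = pos - frame
                if CODON_TABLE.get(trial[cstart : cstart + 3]) != CODON_TABLE.get(
                    mutated[cstart : cstart + 3]
                ):
                    continue
            return trial, pos
    return None, None


def _homology_arm(edited: str, codon_start: int, edit_pos: int | None) -> str:
    """Cut the 85-nt homology arm, keeping both edits >=10 nt from the edges."""
    margin = 10
    center = codon_start + 1
    start = center - HOMOLOGY_ARM_LEN // 2
    lo_anchor = codon_start if edit_pos is None else min(codon_start, edit_pos)
    hi_anchor = codon_start + 2 if edit_pos is None else max(codon_start + 2, edit_pos)
    start = min(start, lo_anchor - margin)
    start = max(start, hi_anchor + margin + 1 - HOMOLOGY_ARM_LEN)
    start = max(0, min(start, len(edited) - HOMOLOGY_ARM_LEN))
    if len(edited) < HOMOLOGY_ARM_LEN:
        raise ValueError("genomic context shorter than the homology arm")
    return edited[start : start + HOMOLOGY_ARM_LEN]
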