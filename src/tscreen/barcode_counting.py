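"""Paired-end barcode counting for the pooled competition assay.

Reads covering the editing cassette are merged from their overlap, trimmed
to the variable region between the constant cassette flanks, and counted
against the designed sequences. Only reads identical to a design are
counted: a mismatch may indicate faulty editing rather than sequencing
error, so there is no edit-distance rescue.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from ._sequences import SGRNA_HANDLE, SPACER5, revcomp

__all__ = [
    "SampleMeta",
    "CountMatrix",
    "MergedRead",
    "merge_pairs",
    "extract_region",
    "count_matches",
    "count_sample",
    "read_fastq",
]


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing sample in the competition assay."""

    sample_id: str
    temperature: float  # degC, 30 or 42
    time_h: float
    replicate: str


@dataclass
class CountMatrix:
    """Integer barcode counts, strains x samples, with sample metadata."""

    counts: pd.DataFrame  # index: strain_id, columns: sample_id
    samples: pd.DataFrame  # index: sample_id; temperature, time_h, replicate

    @property
    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample_ids(self, temperature=None, replicate=None, time_h=None) -> list[str]:
        sel = self.samples
        if temperature is not None:
            sel = sel[sel["temperature"] == temperature]
        if replicate is not None:
            sel = sel[sel["replicate"] == replicate]
        if time_h is not None:
            sel = sel[sel["time_h"] == time_h]
        return list(sel.index)


@dataclass(frozen=True)
class MergedRead:
    sequence: str
    quality: tuple[int, ...]


def merge_pairs(
    seq1: str,
    qual1: Iterable[int],
    seq2: str,
    qual2: Iterable[int],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Merge a read pair by its best ungapped overlap, or ``None``.

    Read 2 is reverse-complemented, then every ungapped alignment with an
    overlap of at least ``min_overlap`` bases and a mismatch fraction of at
    most ``max_mismatch_frac`` is considered; the alignment with the most
    matching bases wins (ties: longer overlap). Overlap mismatches resolve
    to the base with the higher quality score.
    """
    if not seq1 or not seq2:
        raise ValueError("empty read")
    seq1 = seq1.upper()
    q1 = list(qual1)
    rc2 = revcomp(seq2.upper())
    q2 = list(qual2)[::-1]
    if len(q1) != len(seq1) or len(q2) != len(rc2):
        raise ValueError("quality length does not match sequence length")

    best = None  # (matches, overlap_len, offset)
    # offset = start of rc2 relative to seq1; negative offsets let rc2
    # overhang the 5' end of read 1.
    for offset in range(-(len(rc2) - min_overlap), len(seq1) - min_overlap + 1):
        lo = max(0, offset)
        hi = min(len(seq1), offset + len(rc2))
        ov = hi - lo
        if ov < min_overlap:
            continue
        mism = sum(
            1 for i in range(lo, hi) if seq1[i] != rc2[i - offset]
        )
        if mism > max_mismatch_frac * ov:
            continue
        key = (ov - mism, ov, -abs(offset))
        if best is None or key > best[0]:
            best = (key, offset, lo, hi)
    if best is None:
        return None

    _, offset, lo, hi = best
    seq_out: list[str] = []
    qual_out: list[int] = []
    # 5' overhang
    if offset >= 0:
        seq_out.extend(seq1[:lo])
        qual_out.extend(q1[:lo])
    else:
        seq_out.extend(rc2[: -offset])
        qual_out.extend(q2[: -offset])
    # overlap: quality-argmax base call
    for i in range(lo, hi):
        b1, b2 = seq1[i], rc2[i - offset]
        p1, p2 = q1[i], q2[i - offset]
        if b1 == b2:
            seq_out.append(b1)
            qual_out.append(max(p1, p2))
        elif p1 >= p2:
            seq_out.append(b1)
            qual_out.append(p1)
        else:
            seq_out.append(b2)
            qual_out.append(p2)
    # 3' overhang
    if offset + len(rc2) >= len(seq1):
        seq_out.extend(rc2[hi - offset :])
        qual_out.extend(q2[hi - offset :])
    else:
        seq_out.extend(seq1[hi:])
        qual_out.extend(q1[hi:])
    return MergedRead("".join(seq_out), tuple(qual_out))


def extract_region(
    merged: str, anchor5: str = SPACER5, anchor3: str = SGRNA_HANDLE
) -> str | None:
    """Trim a merged read to the region between exact anchor hits.

    Returns ``None`` when either anchor is absent, hits more than once, or
    the anchors are out of order. Anchoring is exact by design: a mutated
    flank is as suspect as a mutated barcode.
    """
    if merged.count(anchor5) != 1 or merged.count(anchor3) != 1:
        return None
    start = merged.index(anchor5) + len(anchor5)
    end = merged.index(anchor3)
    if end < start:
        return None
    return merged[start:end]


def count_matches(
    regions: Iterable[str | None],
    designs: Mapping[str, str],
    meta: SampleMeta | None = None,
) -> tuple[pd.Series, dict]:
    """Count extracted regions against designed variable regions (exact match).

    Returns a per-strain count series (index ordered like ``designs``) and a
    QC dict with ``counted`` / ``discarded`` totals. Duplicate design
    sequences are a barcode collision and raise.
    """
    lookup: dict[str, str] = {}
    for strain, seq in designs.items():
        if seq in lookup:
            raise ValueError(
                f"duplicate design sequence shared by {lookup[seq]} and {strain}"
            )
        lookup[seq] = strain
    counts = pd.Series(0, index=pd.Index(designs.keys(), name="strain_id"), dtype=int)
    n_in = counted = 0
    for region in regions:
        n_in += 1
        strain = lookup.get(region) if region is not None else None
        if strain is None:
            continue
        counts[strain] += 1
        counted += 1
    name = meta.sample_id if meta is not None else None
    counts.name = name
    return counts, {"input": n_in, "counted": counted, "discarded": n_in - counted}


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (read id, sequence, phred qualities) from a FASTQ(.gz) file."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]


def count_sample(
    fastq1: str | Path,
    fastq2: str | Path,
    designs: Mapping[str, str],
    meta: SampleMeta,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[pd.Series, dict]:
    """Full per-sample pipeline: merge pairs, trim to region, count."""
    merged_n = unmerged_n = 0

    def regions():
        nonlocal merged_n, unmerged_n
        for (_, s1, q1), (_, s2, q2) in zip(read_fastq(fastq1), read_fastq(fastq2)):
            m = merge_pairs(s1, q1, s2, q2, min_overlap, max_mismatch_frac)
            if m is None:
                unmerged_n += 1
                yield None
            else:
                merged_n += 1
                yield extract_region(m.sequence)

    counts, qc = count_matches(regions(), designs, meta)
    qc.update(merged=merged_n, unmerged=unmerged_n)
    return counts, qc
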