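"""Seed-region extraction and seed-complement scanning of 3'UTR sets.

The siRNA guide strand recognizes off-target mRNAs miRNA-like: nucleotides
2-8 from its 5' end (the seed region) pair with a complementary site in the
transcript's 3'UTR.  A transcript is *seed-matched* (SM) when its 3'UTR
contains at least one exact occurrence of the reverse complement of the seed.
This module extracts seeds, scans UTR FASTA sets, and designs the two
luciferase reporter inserts used to read out on-target (fully complementary,
CM) and seed-only off-target (tandem seed-matched, SM) activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO

__all__ = [
    "GuideStrand",
    "SeedMotif",
    "SeedClassification",
    "ReporterInserts",
    "extract_seed",
    "reverse_complement",
    "scan_sequence",
    "classify_utr_set",
    "design_reporter_inserts",
]

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class GuideStrand:
    """An siRNA guide strand, 5'->3', with optional modification tags.

    ``seq`` is normalized to the RNA alphabet (T accepted and mapped to U).
    ``mod_positions`` maps 1-based positions to modification tags, e.g.
    ``{6: "FA"}`` for a 2'-formamido sugar at position 6.
    """

    name: str
    seq: str
    mod_positions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = _normalize_rna(self.seq)
        if set(norm) - set("ACGU"):
            raise ValueError(f"invalid characters in guide sequence {self.seq!r}")
        if not 15 <= len(norm) <= 30:
            raise ValueError(f"guide strand length {len(norm)} outside 15-30 nt")
        for pos in self.mod_positions:
            if not 1 <= pos <= len(norm):
                raise ValueError(f"modification position {pos} outside guide")
        object.__setattr__(self, "seq", norm)


@dataclass(frozen=True)
class SeedMotif:
    """A guide-strand seed and its target-side complement.

    ``guide_subseq`` is the seed read off the guide (5'->3'); ``target_match``
    is its reverse complement — the sequence actually sought in mRNA 3'UTRs,
    also written 5'->3'.
    """

    guide_start: int
    guide_end: int
    guide_subseq: str
    target_match: str

    def __post_init__(self) -> None:
        width = self.guide_end - self.guide_start + 1
        if width not in (7, 8):
            raise ValueError("seed width must be 7 or 8 nt")
        if len(self.guide_subseq) != width or len(self.target_match) != width:
            raise ValueError("seed sequences inconsistent with positions")
        if self.target_match != reverse_complement(self.guide_subseq):
            raise ValueError("target_match is not the reverse complement of the seed")


@dataclass(frozen=True)
class SeedClassification:
    """Per-transcript seed-match verdict."""

    transcript_id: str
    is_sm: bool
    match_count: int
    match_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.is_sm != (self.match_count >= 1):
            raise ValueError("is_sm inconsistent with match_count")
        if len(self.match_offsets) != self.match_count:
            raise ValueError("match_offsets inconsistent with match_count")


@dataclass(frozen=True)
class ReporterInserts:
    """Luciferase reporter 3'UTR inserts for on- and off-target readouts."""

    cm_insert: str
    sm_insert: str
    n_repeats: int


def reverse_complement(seq: str, alphabet: Literal["RNA", "DNA"] = "RNA") -> str:
    """Watson-Crick reverse complement (U<->A, G<->C; DNA mode maps T<->A)."""
    seq = seq.upper()
    if alphabet == "RNA":
        valid, table = set("ACGU"), _RNA_COMPLEMENT
    elif alphabet == "DNA":
        valid, table = set("ACGT"), _DNA_COMPLEMENT
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    bad = set(seq) - valid
    if bad:
        raise ValueError(f"invalid {alphabet} characters: {sorted(bad)}")
    return seq.translate(table)[::-1]


def extract_seed(guide: GuideStrand | str, start: int = 2, end: int = 8) -> SeedMotif:
    """Extract the seed region of a guide strand (1-based inclusive positions).

    The default window 2-8 is the canonical 7-nt seed; ``start=1, end=8``
    selects the 8-mer mode matching octamer reporter sites.
    """
    seq = guide.seq if isinstance(guide, GuideStrand) else _normalize_rna(str(guide))
    if set(seq) - set("ACGU"):
        raise ValueError("invalid characters in guide sequence")
    if start < 1 or end > len(seq):
        raise ValueError(f"seed positions {start}-{end} outside guide of {len(seq)} nt")
    if end - start + 1 not in (7, 8):
        raise ValueError("seed width must be 7 or 8 nt")
    sub = seq[start - 1 : end]
    return SeedMotif(
        guide_start=start,
        guide_end=end,
        guide_subseq=sub,
        target_match=reverse_complement(sub),
    )


def scan_sequence(utr_seq: str, motif: SeedMotif | str) -> list[int]:
    """All 0-based offsets of the seed-complement motif in a UTR sequence.

    Overlapping occurrences are reported.  The UTR is normalized (uppercase,
    T -> U) before matching; ambiguity codes such as N never match.  An empty
    sequence yields an empty list.
    """
    pattern = motif.target_match if isinstance(motif, SeedMotif) else _normalize_rna(motif)
    if not pattern:
        raise ValueError("empty motif")
    seq = _normalize_rna(utr_seq)
    offsets: list[int] = []
    i = seq.find(pattern)
    while i != -1:
        offsets.append(i)
        i = seq.find(pattern, i + 1)
    return offsets


def _iter_fasta(fasta) -> Iterable[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA path, handle, or (id, seq) iterable."""
    if isinstance(fasta, (str, Path)):
        path = Path(fasta)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    if not line.startswith(">"):
                        raise ValueError(
                            f"{path}: line {lineno}: expected FASTA header '>'"
                        )
                    break
        for rec in SeqIO.parse(str(path), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        for item in fasta:
            if hasattr(item, "id") and hasattr(item, "seq"):
                yield item.id, str(item.seq)
            else:
                yield item


def classify_utr_set(
    fasta,
    guide: GuideStrand | str,
    mode: Literal["7mer", "8mer"] = "7mer",
) -> tuple[list[SeedClassification], dict[str, int]]:
    """Classify every 3'UTR in a FASTA set as seed-matched or not.

    Parameters
    ----------
    fasta
        Path to a FASTA file, an iterable of Bio.SeqRecord objects, or an
        iterable of ``(id, sequence)`` pairs.  Record ids must be unique.
    guide
        The siRNA guide strand (5'->3').
    mode
        ``7mer`` scans for the complement of guide positions 2-8 (default);
        ``8mer`` for positions 1-8.

    Returns
    -------
    (classifications, summary)
        One :class:`SeedClassification` per record, in input order, and a
        summary dict with keys ``n_sm`` and ``n_non_sm``.
    """
    if mode == "7mer":
        motif = extract_seed(guide, 2, 8)
    elif mode == "8mer":
        motif = extract_seed(guide, 1, 8)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    seen: set[str] = set()
    results: list[SeedClassification] = []
    for rec_id, seq in _iter_fasta(fasta):
        if rec_id in seen:
            raise ValueError(f"duplicate transcript id {rec_id!r}")
        seen.add(rec_id)
        offsets = scan_sequence(seq, motif)
        results.append(
            SeedClassification(
                transcript_id=rec_id,
                is_sm=bool(offsets),
                match_count=len(offsets),
                match_offsets=tuple(offsets),
            )
        )
    n_sm = sum(r.is_sm for r in results)
    return results, {"n_sm": n_sm, "n_non_sm": len(results) - n_sm}


def design_reporter_inserts(
    guide: GuideStrand | str,
    n_repeats: int = 3,
    filler_rng_seed: int = 0,
    spacer_length: int = 4,
) -> ReporterInserts:
    """Design CM and SM reporter 3'UTR inserts for a guide strand.

    The CM (completely matched) insert is the full reverse complement of the
    guide — a perfect on-target site.  The SM (seed-matched) insert is
    ``n_repeats`` tandem copies of the complement of the 8-nt seed-containing
    region (guide positions 1-8) separated by random spacers; spacers are
    rejection-sampled so the insert shares no complementary run of 6 nt or
    more with the guide outside the seed, and so the 7-mer seed complement
    occurs exactly ``n_repeats`` times.
    """
    seq = guide.seq if isinstance(guide, GuideStrand) else _normalize_rna(str(guide))
    if set(seq) - set("ACGU"):
        raise ValueError("invalid characters in guide sequence")
    if len(seq) < 8:
        raise ValueError("guide too short for an 8-nt seed-containing region")
    cm_insert = reverse_complement(seq)
    octamer_site = reverse_complement(seq[:8])
    seed7 = extract_seed(seq, 2, 8)

    # 6-mers complementary to the guide but absent from the seed site are
    # forbidden in the final insert.
    allowed = {octamer_site[i : i + 6] for i in range(len(octamer_site) - 5)}
    forbidden = {
        cm_insert[i : i + 6] for i in range(len(cm_insert) - 5)
    } - allowed

    rng = np.random.default_rng(filler_rng_seed)
    bases = np.array(list("ACGU"))
    for _ in range(10_000):
        parts = []
        for _ in range(n_repeats):
            parts.append(octamer_site)
            parts.append("".join(rng.choice(bases, size=spacer_length)))
        sm_insert = "".join(parts)
        kmer_clash = any(
            sm_insert[i : i + 6] in forbidden for i in range(len(sm_insert) - 5)
        )
        if not kmer_clash and len(scan_sequence(sm_insert, seed7)) == n_repeats:
            return ReporterInserts(
                cm_insert=cm_insert, sm_insert=sm_insert, n_repeats=n_repeats
            )
    raise RuntimeError("could not sample compliant spacers in 10000 attempts")
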