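"""Fast tag-based 16S community profiling from the V6 hypervariable region.

Each sequencing read is scanned for a universal degenerate primer site
upstream of the 16S V6 region; the 33 nucleotides immediately downstream
of a primer match define the V6 tag used as a taxon proxy. Two artefact
filters are applied to the aggregated tags:

* tags covered by fewer than two reads are removed (sequencing-error
  artefacts), and
* tags for which any single read type (distinct full-read sequence)
  accounts for >= 50% of the covering reads are removed (PCR/optical
  duplication artefacts).

Filtered tags are assembled into a per-sample abundance table from which
the top-N most dominant tags are selected.
"""
from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Universal V6 primer for the 16S rRNA hypervariable region.
V6_PRIMER = "CGACRRCCATGCANCACCT"

#: Length of the V6 tag downstream of the primer site.
TAG_LENGTH = 33

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_READ_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class SequencingRead:
    """A single read: identifier, sequence over {A,C,G,T,N}, optional quality string."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        bad = set(self.sequence) - _READ_ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id}: invalid bases {sorted(bad)}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.read_id}: quality length mismatch")


@dataclass(frozen=True)
class DegeneratePrimer:
    """A primer over the IUPAC nucleotide alphabet, default the universal V6 primer."""

    iupac_sequence: str = V6_PRIMER

    def __post_init__(self) -> None:
        bad = set(self.iupac_sequence) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC codes in primer: {sorted(bad)}")
        if not self.iupac_sequence:
            raise ValueError("primer must be non-empty")

    def __len__(self) -> int:
        return len(self.iupac_sequence)

    def reverse_complement(self) -> "DegeneratePrimer":
        return DegeneratePrimer(self.iupac_sequence.translate(_COMPLEMENT)[::-1])


@dataclass
class V6Tag:
    """An aggregated 33-nt V6 tag with its covering-read support.

    ``read_type_counts`` maps each distinct full-read sequence ("read
    type") to the number of reads of that type covering the tag.
    """

    tag_sequence: str
    read_type_counts: Counter = field(default_factory=Counter)

    @property
    def total_reads(self) -> int:
        return sum(self.read_type_counts.values())

    @property
    def max_type_fraction(self) -> float:
        total = self.total_reads
        if total == 0:
            return 0.0
        return max(self.read_type_counts.values()) / total


@dataclass
class TagTable:
    """Per-sample tag abundance: integer counts and row-normalised relative abundance.

    ``zero_samples`` flags samples with no filtered reads; their
    relative-abundance rows are NaN.
    """

    counts: pd.DataFrame  # samples x tags, nonnegative integers
    relative_abundance: pd.DataFrame  # same shape, rows sum to 1 (or NaN)
    zero_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tags(self) -> list[str]:
        return list(self.counts.columns)


def match_degenerate(primer: DegeneratePrimer | str, sequence: str) -> list[int]:
    """Return ascending 0-based start positions of exact degenerate-primer matches.

    A position matches iff every read base lies in the IUPAC expansion of
    the corresponding primer code. An ``N`` in the read matches only
    primer code ``N``: an ambiguous base is not evidence of a match. A
    sequence shorter than the primer yields an empty list.
    """
    if isinstance(primer, str):
        primer = DegeneratePrimer(primer)
    psets = []
    for code in primer.iupac_sequence:
        allowed = set(IUPAC_CODES[code])
        if code == "N":
            allowed.add("N")
        psets.append(allowed)
    plen = len(psets)
    hits = []
    for p in range(len(sequence) - plen + 1):
        if all(sequence[p + i] in psets[i] for i in range(plen)):
            hits.append(p)
    return hits


def extract_v6_tags(
    reads: Iterable[SequencingRead],
    primer: DegeneratePrimer | str = V6_PRIMER,
    tag_length: int = TAG_LENGTH,
    scan_reverse_complement: bool = False,
) -> dict[str, V6Tag]:
    """Extract all V6 tags downstream of primer matches, aggregated over reads.

    Every primer match with at least ``tag_length`` nt remaining after the
    match end yields one tag occurrence, attributed to the read's full
    sequence (its read type). Matches too close to the read end yield
    nothing. Reads are scanned on the given strand only unless
    ``scan_reverse_complement`` is set, in which case the reverse
    complement of each read is scanned as well.
    """
    if isinstance(primer, str):
        primer = DegeneratePrimer(primer)
    reads = list(reads)
    if not reads:
        raise ValueError("no reads supplied")
    plen = len(primer)
    tags: dict[str, V6Tag] = {}

    def _scan(seq: str, read_type: str) -> None:
        for p in match_degenerate(primer, seq):
            start = p + plen
            if start + tag_length > len(seq):
                continue
            tag_seq = seq[start : start + tag_length]
            tag = tags.setdefault(tag_seq, V6Tag(tag_sequence=tag_seq))
            tag.read_type_counts[read_type] += 1

    for read in reads:
        _scan(read.sequence, read.sequence)
        if scan_reverse_complement:
            rc = read.sequence.translate(_COMPLEMENT)[::-1]
            _scan(rc, read.sequence)
    return tags


def filter_tags(
    raw_tags: Mapping[str, V6Tag],
    min_reads: int = 2,
    max_type_fraction: float = 0.5,
) -> dict[str, V6Tag]:
    """Apply the two artefact filters literally.

    A tag is kept iff its total covering reads >= ``min_reads`` AND the
    most frequent read type accounts for strictly less than
    ``max_type_fraction`` of covering reads.
    """
    kept = {}
    for seq, tag in raw_tags.items():
        if tag.total_reads >= min_reads and tag.max_type_fraction < max_type_fraction:
            kept[seq] = tag
    return kept


def tag_support_report(
    raw_tags: Mapping[str, V6Tag],
    min_reads: int = 2,
    max_type_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-tag support and keep/remove decision with the reason."""
    rows = []
    for seq, tag in sorted(raw_tags.items()):
        reasons = []
        if tag.total_reads < min_reads:
            reasons.append(f"fewer than {min_reads} covering reads")
        if tag.max_type_fraction >= max_type_fraction:
            reasons.append(
                f"single read type >= {max_type_fraction:.0%} of covering reads"
            )
        rows.append(
            {
                "tag": seq,
                "total_reads": tag.total_reads,
                "max_type_fraction": tag.max_type_fraction,
                "kept": not reasons,
                "reason": "; ".join(reasons) if reasons else "",
            }
        )
    return pd.DataFrame(rows, columns=["tag", "total_reads", "max_type_fraction", "kept", "reason"])


def build_tag_table(per_sample_tags: Mapping[str, Mapping[str, V6Tag]]) -> TagTable:
    """Assemble filtered per-sample tags into a counts + relative-abundance table.

    Columns are the union of tags across samples; a tag absent from a
    sample gets count 0. Samples with zero total filtered reads are
    flagged and get NaN relative abundances.
    """
    if not per_sample_tags:
        raise ValueError("at least one sample required")
    samples = list(per_sample_tags)
    all_tags = sorted({t for tags in per_sample_tags.values() for t in tags})
    counts = pd.DataFrame(0, index=samples, columns=all_tags, dtype=int)
    for sample, tags in per_sample_tags.items():
        for seq, tag in tags.items():
            counts.loc[sample, seq] = tag.total_reads
    totals = counts.sum(axis=1)
    zero_samples = list(totals.index[totals == 0])
    if zero_samples:
        logger.warning("samples with zero filtered reads: %s", zero_samples)
    rel = counts.div(totals.where(totals > 0), axis=0).astype(float)
    return TagTable(counts=counts, relative_abundance=rel, zero_samples=zero_samples)


def top_n_tags(table: TagTable, n: int = 50) -> TagTable:
    """Restrict the table to the n most dominant tags.

    Tags are ranked by mean relative abundance across samples
    (descending); ties break lexicographically by tag sequence so the
    selection is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    means = table.relative_abundance.mean(axis=0, skipna=True).fillna(0.0)
    if n > len(means):
        logger.info("requested top %d tags but only %d present; returning all", n, len(means))
        n = len(means)
    order = sorted(means.index, key=lambda t: (-means[t], t))
    chosen = order[:n]
    return TagTable(
        counts=table.counts[chosen].copy(),
        relative_abundance=table.relative_abundance[chosen].copy(),
        zero_samples=list(table.zero_samples),
    )


def read_sequences(path: str | Path) -> list[SequencingRead]:
    """Load reads from FASTQ or FASTA, plain or gzip-compressed."""
    path = Path(path)
    name = path.name.lower()
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    reads = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            reads.append(SequencingRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def profile_samples(
    sample_files: Mapping[str, Sequence[str | Path]],
    primer: DegeneratePrimer | str = V6_PRIMER,
    tag_length: int = TAG_LENGTH,
    min_reads: int = 2,
    max_type_fraction: float = 0.5,
    top_n: int | None = 50,
    scan_reverse_complement: bool = False,
) -> TagTable:
    """End-to-end profiling: read files -> extract -> filter -> table -> top-N."""
    per_sample = {}
    for sample, files in sample_files.items():
        reads: list[SequencingRead] = []
        for f in files:
            reads.extend(read_sequences(f))
        raw = extract_v6_tags(
            reads, primer, tag_length, scan_reverse_complement=scan_reverse_complement
        )
        per_sample[sample] = filter_tags(raw, min_reads, max_type_fraction)
    table = build_tag_table(per_sample)
    if top_n is not None:
        table = top_n_tags(table, top_n)
    return table
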