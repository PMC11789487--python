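"""Sequential four-pass adapter trimming with header metadata preservation.

The passes, in order, mirror the library architecture:

1. remove the 3' adapter (the primer-duplex Read2 sequence) and everything
   downstream, tolerating partial occurrences at the read 3' end;
2. cut the first X bases (the UMI) and record them;
3. cut the final base (the primer-duplex +1 position, "PD") and record it;
4. quality-trim the 3' end and drop reads shorter than the minimum length.

The sequences removed in passes 2 and 3 are retained verbatim in the read
header as ``{id}_UMI={umi}_PD={base}`` so downstream stages can recover them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .references import DEFAULT_READ2_ADAPTER


@dataclass
class TrimScheme:
    adapter: str = DEFAULT_READ2_ADAPTER
    umi_length: int = 7
    quality_cutoff: int = 10
    min_length: int = 15
    max_error_rate: float = 0.1
    min_overlap: int = 3

    def __post_init__(self):
        if self.umi_length < 0 or self.quality_cutoff < 0 or self.min_length < 1:
            raise ValueError("invalid trim scheme parameters")
        if not self.adapter:
            raise ValueError("adapter must be nonempty")


@dataclass
class TrimStats:
    reads_in: int = 0
    reads_out: int = 0
    adapter_found: int = 0
    discarded_short_prefix: int = 0  # nothing left after UMI + PD cuts
    discarded_min_length: int = 0

    @property
    def discards(self) -> int:
        return self.discarded_short_prefix + self.discarded_min_length

    def as_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_out": self.reads_out,
            "adapter_found": self.adapter_found,
            "adapter_found_fraction": (
                self.adapter_found / self.reads_in if self.reads_in else 0.0
            ),
            "discarded_short_prefix": self.discarded_short_prefix,
            "discarded_min_length": self.discarded_min_length,
        }


@dataclass
class TrimmedRead:
    read_id: str
    insert_sequence: str
    insert_qualities: str
    umi: str
    plus_one_base: str
    adapter_found: bool

    @property
    def header(self) -> str:
        return f"{self.read_id}_UMI={self.umi}_PD={self.plus_one_base}"


_HEADER_RE = re.compile(r"^(?P<id>.*)_UMI=(?P<umi>[A-Z]*)_PD=(?P<pd>[A-Z]?)$")


def parse_trimmed_header(header: str) -> tuple[str, str, str]:
    """Recover ``(original_id, umi, pd)`` from a trimmed-read header."""
    m = _HEADER_RE.match(header)
    if not m:
        raise ValueError(f"not a trimmed-read header: {header!r}")
    return m.group("id"), m.group("umi"), m.group("pd")


def trim_adapter_3p(
    seq: str,
    qual: str,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> tuple[str, str, bool]:
    """Remove the best occurrence of ``adapter`` and everything 3' of it.

    An occurrence may be internal (full adapter, up to
    ``floor(max_error_rate * len)`` mismatches) or a partial prefix of the
    adapter at the read 3' end with at least ``min_overlap`` bases. The
    best-scoring (most matching bases, ties to the leftmost) occurrence wins.
    Returns ``(seq, qual, found)`` unchanged when nothing qualifies.
    """
    n, m = len(seq), len(adapter)
    # fast path: an exact full occurrence always attains the maximum score,
    # and find() is leftmost, which is also the tie-break of the full scan
    pos = seq.find(adapter)
    if pos >= 0:
        return seq[:pos], qual[:pos], True
    # scan all offsets left to right (overlap shrinks to a 3'-end partial);
    # best score = matching bases, first-seen wins ties
    best_pos, best_score = None, -1
    for i in range(0, n - min_overlap + 1):
        overlap = min(m, n - i)
        allowed = int(max_error_rate * overlap)
        mismatches = 0
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            score = overlap - mismatches
            if score > best_score:
                best_pos, best_score = i, score
    if best_pos is None:
        return seq, qual, False
    return seq[:best_pos], qual[:best_pos], True


def extract_fixed_positions(
    seq: str, qual: str, umi_length: int
) -> tuple[str, str, str, str] | None:
    """Cut the UMI prefix and PD suffix; ``None`` when nothing would remain.

    Returns ``(insert_seq, insert_qual, umi, pd)``.
    """
    if len(seq) <= umi_length + 1:
        return None
    umi = seq[:umi_length]
    pd = seq[-1]
    return seq[umi_length:-1], qual[umi_length:-1], umi, pd


def quality_trim_3p(seq: str, qual: str, cutoff: int) -> tuple[str, str]:
    """BWA-style 3' quality trimming at the given phred cutoff.

    Scanning from the 3' end, accumulate ``cutoff - Q_i`` and cut at the
    position minimising the running sum; all-high-quality reads pass
    unchanged.
    """
    if cutoff <= 0 or not seq:
        return seq, qual
    s = 0
    max_s = 0
    cut = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        s += cutoff - (ord(qual[i]) - 33)
        if s < 0:
            break
        if s > max_s:
            max_s = s
            cut = i
    if max_s > 0:
        return seq[:cut], qual[:cut]
    return seq, qual


def run_trim_pipeline(
    records: Iterable[tuple[str, str, str]],
    scheme: TrimScheme | None = None,
) -> tuple[list[TrimmedRead], TrimStats]:
    """Apply the four passes in order to ``(id, seq, qual)`` records."""
    scheme = scheme or TrimScheme()
    stats = TrimStats()
    out: list[TrimmedRead] = []
    for read_id, seq, qual in records:
        stats.reads_in += 1
        if len(seq) != len(qual):
            raise ValueError(
                f"malformed FASTQ record {stats.reads_in} ({read_id!r}): "
                "sequence/quality length mismatch"
            )
        seq, qual, found = trim_adapter_3p(
            seq, qual, scheme.adapter, scheme.max_error_rate, scheme.min_overlap
        )
        if found:
            stats.adapter_found += 1
        fixed = extract_fixed_positions(seq, qual, scheme.umi_length)
        if fixed is None:
            stats.discarded_short_prefix += 1
            continue
        seq, qual, umi, pd = fixed
        seq, qual = quality_trim_3p(seq, qual, scheme.quality_cutoff)
        if len(seq) < scheme.min_length:
            stats.discarded_min_length += 1
            continue
        stats.reads_out += 1
        out.append(TrimmedRead(read_id, seq, qual, umi, pd, found))
    return out, stats


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(id, seq, qual)`` from a phred+33 FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_trimmed_fastq(reads: Iterable[TrimmedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.header}\n{r.insert_sequence}\n+\n{r.insert_qualities}\n")


def read_trimmed_fastq(path) -> list[TrimmedRead]:
    out = []
    for header, seq, qual in read_fastq(path):
        rid, umi, pd = parse_trimmed_header(header)
        out.append(TrimmedRead(rid, seq, qual, umi, pd, True))
    return out
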