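"""Reference sequence sets consumed by every pipeline stage.

Three kinds of reference live here:

* the miRNA pool — a named collection of short RNA sequences (stored in the
  DNA alphabet, as a sequencer reports them) standing in for an equimolar
  benchmarking pool;
* the oligonucleotide scheme — the adapter/UMI/primer-duplex architecture
  that shapes every raw read;
* contaminant references — surrogate sequences for enzyme-borne nucleic
  acids (expression plasmid, host genome with tRNA/rRNA annotation) plus the
  adapter oligos themselves.

A deterministic generator builds a synthetic pool + contaminant set whose
category boundaries are unambiguous (no shared 15-mers), so downstream
classification can be validated against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
PURINES = frozenset("AG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNAEntry:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def terminal_3p(self) -> str:
        return self.sequence[-1]

    @property
    def terminal_5p(self) -> str:
        return self.sequence[0]

    @property
    def is_3p_purine(self) -> bool:
        return self.terminal_3p in PURINES


class MiRNAReference:
    """Ordered collection of uniquely named small-RNA sequences (DNA alphabet)."""

    def __init__(self, entries: Iterable[MiRNAEntry]):
        self.entries: list[MiRNAEntry] = list(entries)
        ids = [e.id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate reference ids: {sorted(dupes)}")
        for e in self.entries:
            if not e.sequence:
                raise ValueError(f"empty sequence for record {e.id!r}")
            bad = set(e.sequence) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"non-IUPAC/ambiguous character(s) {sorted(bad)} in record {e.id!r}"
                )
        self._by_id = {e.id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self._by_id

    def __getitem__(self, mirna_id: str) -> MiRNAEntry:
        return self._by_id[mirna_id]

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def sequences(self) -> dict[str, str]:
        return {e.id: e.sequence for e in self.entries}

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.id}\n")
                for i in range(0, len(e.sequence), 80):
                    fh.write(e.sequence[i : i + 80] + "\n")


# Duplexed-portion sequence of the +1 primer duplex as it appears at the read
# 3' end after the insert; this is the string removed in the first trimming pass.
DEFAULT_READ2_ADAPTER = "GATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
# Constant 5' portion of the complementary Read1 primer sequence; its complete
# presence in an adapter-dimer cDNA determines Read1 detectability.
DEFAULT_CREAD1_PREFIX = "AGATCGG"


@dataclass
class OligoScheme:
    """Adapter/UMI architecture of a library.

    ``umi_pattern`` is an IUPAC string read as the UMI prefix of each read
    (e.g. ``NNNNNRC`` for the 7-nt UMI design); ``plus_one_weights`` gives the
    molar mix of primer-duplex +1 overhang bases (T reports a ddA label, C a
    ddG label).
    """

    read2_adapter: str = DEFAULT_READ2_ADAPTER
    umi_pattern: str = "NNNNNRC"
    cread1_constant_prefix: str = DEFAULT_CREAD1_PREFIX
    plus_one_weights: Mapping[str, float] = field(
        default_factory=lambda: {"T": 4.0, "C": 1.0}
    )

    def __post_init__(self):
        for base, w in self.plus_one_weights.items():
            if base not in DNA_ALPHABET:
                raise ValueError(f"invalid +1 base {base!r}")
            if w <= 0:
                raise ValueError("+1 mix weights must be positive")
        for c in self.umi_pattern:
            if c not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code {c!r} in UMI pattern")

    @property
    def umi_length(self) -> int:
        return len(self.umi_pattern)

    def draw_umi(self, rng: np.random.Generator) -> str:
        return "".join(
            IUPAC_CODES[c][rng.integers(len(IUPAC_CODES[c]))] for c in self.umi_pattern
        )

    def draw_plus_one(self, rng: np.random.Generator) -> str:
        bases = list(self.plus_one_weights)
        w = np.array([self.plus_one_weights[b] for b in bases], dtype=float)
        return bases[rng.choice(len(bases), p=w / w.sum())]


@dataclass(frozen=True)
class AnnotationInterval:
    """Half-open interval [start, end) on a contaminant sequence."""

    reference_id: str
    start: int
    end: int
    feature: str  # "tRNA" | "rRNA"


class ContaminantReference:
    """Ordered contaminant categories; order defines cascade mapping priority."""

    def __init__(
        self,
        categories: Sequence[tuple[str, dict[str, str]]],
        annotations: Sequence[AnnotationInterval] = (),
    ):
        names = [name for name, _ in categories]
        if len(set(names)) != len(names):
            raise ValueError("contaminant category names must be unique")
        self.categories: list[tuple[str, dict[str, str]]] = [
            (name, dict(seqs)) for name, seqs in categories
        ]
        self.annotations: list[AnnotationInterval] = list(annotations)

    def category(self, name: str) -> dict[str, str]:
        for cat, seqs in self.categories:
            if cat == name:
                return seqs
        raise KeyError(name)

    @property
    def category_names(self) -> list[str]:
        return [name for name, _ in self.categories]


# ---------------------------------------------------------------------------
# loading / filtering


def load_fasta_reference(path) -> MiRNAReference:
    """Load a FASTA file into a :class:`MiRNAReference`.

    U is normalised to T so that all downstream comparison happens in the DNA
    alphabet the sequencer reports. Ids are the header token up to the first
    whitespace. Duplicate ids, empty sequences and non-IUPAC characters are
    hard errors naming the offending record.
    """
    entries = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"non-IUPAC character(s) {sorted(bad)} in record {rec.id!r} in {path}"
            )
        entries.append(MiRNAEntry(rec.id, seq))
    return MiRNAReference(entries)


def length_filter(ref: MiRNAReference, min_len: int, max_len: int) -> MiRNAReference:
    """Retain entries with ``min_len <= L <= max_len``, preserving order."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return MiRNAReference(e for e in ref if min_len <= e.length <= max_len)


def reliable_subset(
    ref: MiRNAReference, end_trim: int = 3, max_mismatches: int = 2
) -> set[str]:
    """Ids of entries that cannot misalign when both ends are trimmed.

    Each entry's core (sequence minus ``end_trim`` nt from each end) is
    aligned against the full reference with the pipeline's ungapped aligner;
    an entry is reliable iff the core's unique best placement is on itself.
    Entries too short to trim are excluded with a warning rather than an
    error.
    """
    from .mapping import WindowIndex  # local import to avoid a cycle

    index = WindowIndex(ref.sequences(), both_strands=False)
    reliable: set[str] = set()
    for e in ref:
        if e.length <= 2 * end_trim:
            logger.warning(
                "entry %s (length %d) too short for %d+%d end trim; excluded "
                "from reliable subset",
                e.id, e.length, end_trim, end_trim,
            )
            continue
        core = e.sequence[end_trim : e.length - end_trim]
        placements = index.align(core, max_mismatches=max_mismatches)
        if len(placements) == 1 and placements[0].reference_id == e.id:
            reliable.add(e.id)
    return reliable


# ---------------------------------------------------------------------------
# synthetic generation

# Length histogram of the default synthetic pool: 962 entries spanning
# 16-28 nt with 943 in the 19-24 nt mapping range, matching the composition of
# the commercial equimolar benchmarking pool the metrics are defined around.
DEFAULT_LENGTH_COUNTS: dict[int, int] = {
    16: 3, 17: 3, 18: 3,
    19: 157, 20: 157, 21: 157, 22: 158, 23: 157, 24: 157,
    25: 3, 26: 3, 27: 2, 28: 2,
}


@dataclass
class ReferenceConfig:
    """Parameters of the synthetic reference generator."""

    length_counts: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_COUNTS)
    )
    # 3'-terminal nucleotide composition; entries are assigned terminal bases
    # round-robin in these proportions so exact compositions are achievable.
    terminal_3p_composition: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    plasmid_length: int = 2500
    genome_length: int = 6000
    kmer_guard: int = 15

    @property
    def pool_size(self) -> int:
        return sum(self.length_counts.values())


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = revcomp(seq)
    n = len(seq)
    return {min(seq[i : i + k], rc[n - i - k : n - i]) for i in range(n - k + 1)}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_synthetic_references(
    config: ReferenceConfig | None = None,
    seed: int = 0,
    scheme: OligoScheme | None = None,
) -> tuple[MiRNAReference, ContaminantReference]:
    """Deterministically build a synthetic miRNA pool plus contaminant set.

    Contaminant sequences are generated first; pool candidates sharing any
    canonical ``kmer_guard``-mer with them (or with each other) are rejected,
    so category assignment by alignment is unambiguous at pool scale.
    """
    config = config or ReferenceConfig()
    scheme = scheme or OligoScheme()
    rng = np.random.default_rng(seed)

    plasmid = _random_seq(rng, config.plasmid_length)
    genome = _random_seq(rng, config.genome_length)
    adapters = {
        "read2_adapter": scheme.read2_adapter,
        "cread1": scheme.cread1_constant_prefix + revcomp(scheme.read2_adapter)[:20],
    }

    k = config.kmer_guard
    guard: set[str] = set()
    for s in (plasmid, genome, *adapters.values()):
        if len(s) >= k:
            guard |= _canonical_kmers(s, k)

    # annotation intervals on the genome surrogate (tRNA/rRNA loci)
    g = config.genome_length
    annotations = [
        AnnotationInterval("genome", int(0.08 * g), int(0.08 * g) + 76, "tRNA"),
        AnnotationInterval("genome", int(0.25 * g), int(0.25 * g) + 90, "tRNA"),
        AnnotationInterval("genome", int(0.50 * g), int(0.50 * g) + 120, "rRNA"),
        AnnotationInterval("genome", int(0.70 * g), int(0.70 * g) + 150, "rRNA"),
    ]

    comp = config.terminal_3p_composition
    bases = sorted(comp)
    weights = np.array([comp[b] for b in bases], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("terminal composition weights must sum to > 0")
    weights /= weights.sum()

    pool_size = config.pool_size
    # round-robin assignment of terminal bases in requested proportions:
    # exact counts for divisible pool sizes, largest-remainder otherwise
    counts = np.floor(weights * pool_size).astype(int)
    remainder = pool_size - counts.sum()
    if remainder:
        order = np.argsort(-(weights * pool_size - counts))
        for i in order[:remainder]:
            counts[i] += 1
    terminal_cycle = [b for b, c in zip(bases, counts) for _ in range(c)]
    rng.shuffle(terminal_cycle)

    lengths = [L for L, c in sorted(config.length_counts.items()) for _ in range(c)]
    if len(lengths) != pool_size:
        raise ValueError("length_counts inconsistent with pool size")
    max_distinct = min(4 ** (min(lengths) - 1), 2**62)
    if pool_size > max_distinct:
        raise ValueError("pool size exceeds distinct sequences available")

    entries: list[MiRNAEntry] = []
    seen: set[str] = set()
    for idx, (L, t3) in enumerate(zip(lengths, terminal_cycle)):
        for _attempt in range(1000):
            seq = _random_seq(rng, L - 1) + t3
            if seq in seen:
                continue
            if len(seq) >= k and _canonical_kmers(seq, k) & guard:
                continue
            break
        else:
            raise RuntimeError("could not generate a guard-clean pool sequence")
        seen.add(seq)
        guard |= _canonical_kmers(seq, k) if len(seq) >= k else set()
        entries.append(MiRNAEntry(f"syn-mir-{idx + 1:04d}", seq))

    pool = MiRNAReference(entries)
    contaminants = ContaminantReference(
        [
            ("adapters", adapters),
            ("expression_plasmid", {"plasmid": plasmid}),
            ("genome", {"genome": genome}),
        ],
        annotations,
    )
    return pool, contaminants
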