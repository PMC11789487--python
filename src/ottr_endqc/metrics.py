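"""Quantitative evaluation surfaces for OTTR libraries.

Count/CPM tables and the library-wide coefficient of variation quantify how
far a library strays from equimolar representation of the input pool; the
end-precision estimators quantify how faithfully read ends reflect molecule
ends; coverage profiles, composition summaries and terminal-nucleotide
stratification localise the bias; and the mechanism/junction classifiers
interpret individual alignments and adapter-dimer cDNA junctions.

End precision (for either end) is the mean over miRNAs of the per-miRNA
fraction of alignments that include the terminal reference nucleotide:

    precision = (1/m) * sum_j b_j / T_j

with ``T_j`` the total alignments to miRNA j, ``b_j`` those covering the
first (5') or last (3') position, and ``m`` the number of miRNAs evaluated.
A literal double-normalisation variant ``(1/T)(1/m) sum_j b_j`` (with ``T``
the grand total) is available for comparison via ``per_mirna=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .references import MiRNAReference, OligoScheme, PURINES

logger = logging.getLogger(__name__)

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# counts / CV


def mirna_counts_cpm(
    alignments: pd.DataFrame,
    ref: MiRNAReference,
    single_mapping_only: bool = True,
    library_id: str = "library",
) -> pd.DataFrame:
    """Per-miRNA counts and CPM from miRNA-category alignment records.

    Zero-count miRNAs are present with count 0. With zero total counts the
    CPM column is NaN (undefined) and a warning is logged.
    """
    sub = alignments[alignments["category"] == "mirna"]
    if single_mapping_only and "multi_mapping" in sub:
        sub = sub[~sub["multi_mapping"].astype(bool)]
    counts = sub["reference_id"].value_counts()
    table = pd.DataFrame(
        {"count": [int(counts.get(i, 0)) for i in ref.ids]}, index=pd.Index(ref.ids, name="mirna_id")
    )
    total = table["count"].sum()
    if total == 0:
        logger.warning("library %s has zero mapped miRNA reads; CPM undefined", library_id)
        table["cpm"] = np.nan
    else:
        table["cpm"] = table["count"] * 1e6 / total
    table.attrs["library_id"] = library_id
    return table


def apply_median_filter(
    count_tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
    threshold: int = 50,
) -> set[str]:
    """MiRNAs whose median raw count across libraries is >= ``threshold``."""
    if isinstance(count_tables, pd.DataFrame):
        counts = count_tables
    else:
        if not count_tables:
            raise ValueError("at least one library required")
        counts = pd.DataFrame({k: t["count"] for k, t in count_tables.items()})
    med = counts.median(axis=1)
    return set(med.index[med >= threshold])


def coefficient_of_variation(counts: Sequence[float] | pd.Series) -> float:
    """Library-wide CV: sample standard deviation / mean of per-miRNA counts."""
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least two values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# end precision


@dataclass
class PrecisionSummary:
    end: str  # "5p" | "3p"
    per_mirna: pd.DataFrame  # columns: T, covered, fraction
    mean_precision: float
    m: int


def end_precision(
    alignments: pd.DataFrame,
    ref: MiRNAReference,
    reliable_ids: Iterable[str] | None = None,
    end: str = "3p",
    single_mapping_only: bool = True,
    per_mirna: bool = True,
) -> PrecisionSummary:
    """Mean 5'/3' end precision over (reliable) miRNAs with >= 1 alignment.

    An alignment includes a position iff its [start, end) interval covers it
    on the reference: the first nucleotide is covered iff start == 0, the
    final nucleotide iff end == L_j (alignments are end-to-end and ungapped).
    """
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")
    sub = alignments[alignments["category"] == "mirna"]
    if single_mapping_only and "multi_mapping" in sub:
        sub = sub[~sub["multi_mapping"].astype(bool)]
    if reliable_ids is not None:
        reliable = set(reliable_ids)
        sub = sub[sub["reference_id"].isin(reliable)]
    lengths = {e.id: e.length for e in ref}
    rows = []
    for mirna_id, grp in sub.groupby("reference_id"):
        t = len(grp)
        if end == "5p":
            covered = int((grp["start"] == 0).sum())
        else:
            covered = int((grp["end"] == lengths[mirna_id]).sum())
        rows.append((mirna_id, t, covered, covered / t))
    if not rows:
        raise ValueError("no miRNAs with alignments to evaluate")
    table = pd.DataFrame(
        rows, columns=["mirna_id", "T", "covered", "fraction"]
    ).set_index("mirna_id")
    m = len(table)
    if per_mirna:
        mean = float(table["fraction"].mean())
    else:  # literal double normalisation: (1/T)(1/m) sum_j b_j
        mean = float(table["covered"].sum() / (table["T"].sum() * m))
    return PrecisionSummary(end, table, mean, m)


def end_coverage_profile(
    alignments: pd.DataFrame,
    ref: MiRNAReference,
    mirna_id: str,
    anchor: str = "3p",
) -> pd.Series:
    """Histogram of alignment endpoints in end-anchored offset coordinates.

    For the 3' anchor, offset 0 is the miRNA 3' end, -1 the penultimate
    nucleotide, and so on; the mirrored 5'-anchored profile uses alignment
    start offsets (0 = first nucleotide, -1 = one nucleotide in).
    """
    if mirna_id not in ref:
        raise KeyError(mirna_id)
    L = ref[mirna_id].length
    sub = alignments[
        (alignments["category"] == "mirna") & (alignments["reference_id"] == mirna_id)
    ]
    if anchor == "3p":
        offsets = sub["end"].astype(int) - L
    elif anchor == "5p":
        offsets = -sub["start"].astype(int)
    else:
        raise ValueError("anchor must be '5p' or '3p'")
    profile = offsets.value_counts().sort_index()
    profile.name = f"{mirna_id}:{anchor}"
    return profile


# ---------------------------------------------------------------------------
# composition


def composition_summary(
    records: pd.DataFrame, min_len: int = 17
) -> tuple[pd.Series, dict[str, pd.Series]]:
    """Category fractions of the library, excluding reads <= ``min_len`` nt.

    Returns ``(fractions, length_histograms)`` where fractions are over reads
    strictly longer than ``min_len`` (e.g. 18 nt and longer for the default
    17) and sum to 1 over the categories present.
    """
    kept = records[records["read_length"] > min_len]
    order = ["mirna", "adapter", "plasmid", "genome", "unmapped"]
    counts = kept["category"].value_counts()
    cats = [c for c in order if c in counts.index] + [
        c for c in counts.index if c not in order
    ]
    fractions = pd.Series(
        {c: counts.get(c, 0) / len(kept) for c in cats}, name="fraction"
    )
    hists = {
        c: grp["read_length"].value_counts().sort_index()
        for c, grp in kept.groupby("category")
    }
    return fractions, hists


def terminal_nt_stratification(
    count_table: pd.DataFrame,
    ref: MiRNAReference,
    group_by: str = "purine",
) -> pd.DataFrame:
    """log2 CPM of each miRNA grouped by its 3'-terminal nucleotide.

    Zero-count entries get a CPM recomputed from count + 0.5 (flagged in the
    ``zero_imputed`` column) so the logarithm is defined. ``group_by`` is
    ``"purine"`` (purine vs pyrimidine) or ``"base"`` (four groups).
    """
    total = count_table["count"].sum()
    if total == 0:
        raise ValueError("no miRNA counts")
    rows = []
    for e in ref:
        if e.id not in count_table.index:
            continue
        count = count_table.loc[e.id, "count"]
        zero = count == 0
        cpm = (count + 0.5) * 1e6 / total if zero else count_table.loc[e.id, "cpm"]
        group = (
            ("purine" if e.is_3p_purine else "pyrimidine")
            if group_by == "purine"
            else e.terminal_3p
        )
        rows.append((e.id, e.terminal_3p, group, float(np.log2(cpm)), bool(zero)))
    df = pd.DataFrame(
        rows, columns=["mirna_id", "terminal_3p", "group", "log2_cpm", "zero_imputed"]
    ).set_index("mirna_id")
    return df


def stratification_medians(strat: pd.DataFrame) -> pd.Series:
    return strat.groupby("group")["log2_cpm"].median()


# ---------------------------------------------------------------------------
# mechanism / junction classification


def classify_alignment_mechanism(
    three_prime_offset: int,
    terminal_3p: str,
    plus_one_base: str | None = None,
    penultimate_nt: str | None = None,
) -> set[str]:
    """Compatible 3'-end capture mechanisms for an observed alignment offset.

    Observed offsets do not uniquely identify mechanisms (a +2 overhang
    capture of the terminal base is indistinguishable from precise capture),
    so a set is returned, never a guess. The primer-duplex +1 base, when
    given, filters direct-pairing mechanisms by Watson-Crick compatibility.
    """
    if three_prime_offset == 0:
        out = {"I_precise"}
        if terminal_3p not in PURINES:
            out.add("III_plus2_apparent_precise")
        return out
    if three_prime_offset == 1:
        out = {"IV_plus2_internal"}
        if terminal_3p in PURINES and (
            plus_one_base is None or (plus_one_base, terminal_3p) in _WC
        ):
            out.add("II_overcapture")
        return out
    if three_prime_offset == 2:
        if penultimate_nt is None or penultimate_nt in PURINES:
            return {"V_plus1_penultimate"}
        return {"OTHER"}
    return {"OTHER"}


@dataclass
class JunctionCall:
    junction: str
    plus_one: str
    offset: int
    first_cdna_base: str
    first_base_paired_position: int
    pd_dependent: bool
    nta_dependent: bool
    read1_detectable: bool


_DASHES = str.maketrans({"‐": "-", "‑": "-", "–": "-", "−": "-"})


def classify_junction(
    junction: str,
    plus_one: str | None = None,
    scheme: OligoScheme | None = None,
    umi_read_length: int | None = None,
) -> JunctionCall:
    """Classify an adapter-dimer cDNA junction string (``<PD>|<prefix>``).

    The observed adapter-derived prefix is compared against the expected full
    cDNA prefix ``G + N*(X-1) + <constant cRead1 prefix>`` (X = number of
    UMI-derived read bases; X = 1 for a UMI-less adapter template). Leading
    ``-`` characters mark adapter-template sequence excluded by internal
    initiation; their count is the offset. The dimer is detectable by Read1
    sequencing iff the constant prefix is completely present.

    For UMI-less schemes the primer-duplex and NTA dependence flags follow
    from Watson-Crick pairing of the +1 base at the initiation-adjacent
    template position; internal initiation within a degenerate UMI segment is
    assigned both dependencies by rule.
    """
    scheme = scheme or OligoScheme()
    x = umi_read_length if umi_read_length is not None else max(scheme.umi_length, 1)
    norm = junction.translate(_DASHES)
    if "|" not in norm:
        raise ValueError(f"junction not parseable: {junction!r}")
    pd_base, observed = norm.split("|", 1)
    pd_base = (plus_one or pd_base).strip().upper()
    observed = observed.strip()
    core = observed.lstrip("-")
    if not core:
        raise ValueError(f"junction has no observed sequence: {junction!r}")
    offset = len(observed) - len(core)
    constant = scheme.cread1_constant_prefix
    expected = "G" + "N" * (x - 1) + constant
    detectable = constant in core
    has_umi = x > 1
    if offset == 0:
        pd_dep, nta_dep = False, True
    elif has_umi:
        # internal initiation within/adjacent to the degenerate UMI segment:
        # both a paired +1 base and an NTA are required (rule, not derived)
        pd_dep, nta_dep = True, True
    else:
        if offset > len(expected):
            raise ValueError(f"offset {offset} exceeds adapter cDNA length")
        template_adjacent = _COMPLEMENT[expected[offset - 1]]
        pd_dep = (pd_base, template_adjacent) in _WC
        nta_dep = not pd_dep
    return JunctionCall(
        junction=junction,
        plus_one=pd_base,
        offset=offset,
        first_cdna_base=core[0],
        first_base_paired_position=-offset,
        pd_dependent=pd_dep,
        nta_dependent=nta_dep,
        read1_detectable=detectable,
    )


#: Sanger-sequenced adapter-dimer cDNA junction observations (printed
#: ``<PD base>|<observed adapter-derived prefix>``), with the scheme class
#: ("no_umi" or "umi"), the number of clones, and the curated primer-duplex
#: dependence / NTA dependence / Read1 detectability calls. Input data for the
#: junction classifier's validation, not part of its rules.
OBSERVED_ADAPTER_DIMER_JUNCTIONS: list[dict] = [
    {"scheme": "no_umi", "junction": "C|GAGATCGG", "plus_one": "C", "n": 2,
     "pd_dependent": False, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "no_umi", "junction": "T|GAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": False, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "no_umi", "junction": "C|-AGATCGG", "plus_one": "C", "n": 2,
     "pd_dependent": False, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "no_umi", "junction": "T|-AGATCGG", "plus_one": "T", "n": 13,
     "pd_dependent": False, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "no_umi", "junction": "C|------GG", "plus_one": "C", "n": 4,
     "pd_dependent": True, "nta_dependent": False, "read1_detectable": False},
    {"scheme": "no_umi", "junction": "T|------GG", "plus_one": "T", "n": 1,
     "pd_dependent": False, "nta_dependent": True, "read1_detectable": False},
    {"scheme": "no_umi", "junction": "T|-------G", "plus_one": "T", "n": 8,
     "pd_dependent": False, "nta_dependent": True, "read1_detectable": False},
    {"scheme": "umi", "junction": "T|GTTTTCTAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": False, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "C|GCGGCCCAGATCGG", "plus_one": "C", "n": 1,
     "pd_dependent": False, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "T|--AGCTTAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "T|--AACTTAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "C|--GGCTAAGATCGG", "plus_one": "C", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "T|--GGGCTAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "C|--GGTACAGATCGG", "plus_one": "C", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "T|--GTCATAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "T|--GCGTAAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "T|--GAGAAAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "T|--GGGTTAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
    {"scheme": "umi", "junction": "T|---GGTTAGATCGG", "plus_one": "T", "n": 1,
     "pd_dependent": True, "nta_dependent": True, "read1_detectable": True},
]


# ---------------------------------------------------------------------------
# truth-table helpers (simulator cross-checks)


def mechanism_frequencies(truth: pd.DataFrame) -> pd.Series:
    """Observed mechanism frequencies from a simulator truth table."""
    return truth["mechanism"].value_counts(normalize=True)
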