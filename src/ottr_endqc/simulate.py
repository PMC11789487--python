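"""Generative model of OTTR read capture with per-read ground truth.

OTTR (ordered two-template relay) builds a sequencing-ready cDNA in a single
reaction: the input RNA first receives a 3' dideoxypurine label (ddA or ddG,
collectively "ddR"), a primer duplex with a single pyrimidine (+1 Y) overhang
pairs that label to prime reverse transcription, and after copying the input
the enzyme jumps to an adapter template, appending the second adapter.

The raw read architecture is therefore::

    [UMI prefix][insert][+1 base][Read2 adapter] ...

Capture is not always precise. The model distinguishes five read-level
mechanisms at the 3' end:

* ``I_precise`` — labeled molecule, primed on the ddR; full-length insert.
* ``II_overcapture`` — unlabeled 3'-purine molecule captured by direct +1 Y
  pairing on its terminal base, which trimming then removes: apparent 1-nt
  3' truncation.
* ``III_plus2_apparent_precise`` — unlabeled 3'-pyrimidine molecule captured
  via a nontemplated purine addition (+2 YR overhang) pairing the terminal
  base; indistinguishable from precise capture.
* ``IV_plus2_internal`` — the same +2 YR capture initiating on the
  penultimate nucleotide: apparent 1-nt truncation.
* ``V_plus1_penultimate`` — +1 Y pairing of an internal (penultimate) purine:
  apparent 2-nt truncation.

Independently, the second template jump may lose the input 5'-terminal
nucleotide (1-nt 5' truncation). Adapter dimers (no insert) and enzyme-borne
contaminant molecules competing with the input at a fixed molar load complete
the model. Unlabeled, uncaptured molecules drop out implicitly: read count,
not molecule count, is the observable, so sampling is renormalised over
emitted reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .references import (
    AnnotationInterval,
    ContaminantReference,
    MiRNAReference,
    OligoScheme,
    PURINES,
    revcomp,
)

MECHANISM_OFFSETS = {
    "I_precise": 0,
    "II_overcapture": 1,
    "III_plus2_apparent_precise": 0,
    "IV_plus2_internal": 1,
    "V_plus1_penultimate": 2,
}


@dataclass(frozen=True)
class MechanismLabel:
    code: str
    three_prime_offset: int
    five_prime_offset: int

    def __post_init__(self):
        expected = MECHANISM_OFFSETS.get(self.code)
        if expected is not None and self.three_prime_offset != expected:
            raise ValueError(
                f"{self.code} implies 3' offset {expected}, got {self.three_prime_offset}"
            )


DROPOUT = MechanismLabel("DROPOUT", 0, 0)


@dataclass
class CaptureModel:
    """Read-level capture chemistry parameters.

    ``p_label`` may be a scalar or a per-3'-nucleotide mapping. All
    probabilities are per-molecule; ``p_overcapture_R`` and ``p_nta`` act as
    relative capture weights of unlabeled molecules (uncaptured molecules
    drop out). ``capture_dispersion`` is the standard deviation of per-miRNA
    log capture efficiency (lognormal bias); ``contaminant_molar_load`` is a
    fixed per-reaction contaminant quantity in the same arbitrary molar units
    as ``input_pg * capture_efficiency_per_pg``.
    """

    p_label: float | Mapping[str, float] = 0.85
    p_nta: float = 0.3
    p_overcapture_R: float = 0.5
    p_internal_minus1: float = 0.25
    p_penultimate_plus1: float = 0.05
    p_5p_truncation: float = 0.05
    capture_dispersion: float = 0.55
    dimer_rate: float = 0.05
    contaminant_molar_load: float = 0.0
    capture_efficiency_per_pg: float = 1.0
    sequencing_error_rate: float = 0.0

    def __post_init__(self):
        probs = [self.p_nta, self.p_overcapture_R, self.p_internal_minus1,
                 self.p_penultimate_plus1, self.p_5p_truncation, self.dimer_rate,
                 self.sequencing_error_rate]
        if isinstance(self.p_label, Mapping):
            probs.extend(self.p_label.values())
        else:
            probs.append(self.p_label)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.capture_dispersion < 0:
            raise ValueError("capture_dispersion must be >= 0")
        if self.contaminant_molar_load < 0:
            raise ValueError("contaminant_molar_load must be >= 0")

    def label_prob(self, base: str) -> float:
        if isinstance(self.p_label, Mapping):
            return float(self.p_label.get(base, 0.0))
        return float(self.p_label)


@dataclass
class TruthRead:
    read_id: str
    raw_sequence: str
    raw_qualities: str
    source_id: str
    mechanism: MechanismLabel
    umi: str
    plus_one_base: str
    insert: str


def draw_capture_outcome(
    source_3p_nt: str,
    model: CaptureModel,
    rng: np.random.Generator,
    penultimate_nt: str | None = None,
    p_5p_truncation: float | None = None,
) -> MechanismLabel:
    """Draw the capture mechanism for one molecule (DROPOUT if uncaptured).

    The 5' truncation is drawn independently of the 3' mechanism; mechanism V
    requires an eligible internal purine (penultimate base), which callers
    supply via ``penultimate_nt``.
    """
    p5 = model.p_5p_truncation if p_5p_truncation is None else p_5p_truncation

    def with_5p(code: str, off3: int) -> MechanismLabel:
        off5 = 1 if rng.random() < p5 else 0
        return MechanismLabel(code, off3, off5)

    if rng.random() < model.label_prob(source_3p_nt):
        return with_5p("I_precise", 0)
    penultimate_ok = penultimate_nt is not None and penultimate_nt in PURINES
    if source_3p_nt in PURINES:
        if rng.random() < model.p_overcapture_R:
            return with_5p("II_overcapture", 1)
    else:
        if rng.random() < model.p_nta:
            if rng.random() < model.p_internal_minus1:
                return with_5p("IV_plus2_internal", 1)
            return with_5p("III_plus2_apparent_precise", 0)
    if penultimate_ok and rng.random() < model.p_penultimate_plus1:
        return with_5p("V_plus1_penultimate", 2)
    return DROPOUT


def assemble_raw_read(
    source_seq: str,
    mechanism: MechanismLabel,
    scheme: OligoScheme,
    read_len: int,
    rng: np.random.Generator,
    read_id: str = "read",
    source_id: str = "source",
    quality_char: str = "F",  # phred+33 Q37
) -> TruthRead:
    """Assemble a raw read: UMI + truncated insert + (+1 base) + Read2 adapter.

    The +1 base reports the labeling chemistry (T for ddA, C for ddG) and is
    drawn from the scheme's primer-duplex mix; a DIMER mechanism omits the
    insert entirely. The assembled sequence is truncated to ``read_len``.
    """
    off3, off5 = mechanism.three_prime_offset, mechanism.five_prime_offset
    if mechanism.code == "DIMER":
        insert = ""
    else:
        if off3 + off5 >= len(source_seq):
            raise ValueError(
                f"mechanism offsets ({off5}+{off3}) exceed source length "
                f"{len(source_seq)}"
            )
        insert = source_seq[off5 : len(source_seq) - off3]
    umi = scheme.draw_umi(rng)
    if mechanism.code == "II_overcapture":
        # direct +1 Y pairing of the unlabeled terminal purine: A pairs T, G pairs C
        plus_one = "T" if source_seq[-1] == "A" else "C"
    elif mechanism.code == "V_plus1_penultimate":
        plus_one = "T" if source_seq[-2] == "A" else "C"
    else:
        plus_one = scheme.draw_plus_one(rng)
    raw = (umi + insert + plus_one + scheme.read2_adapter)[:read_len]
    return TruthRead(
        read_id=read_id,
        raw_sequence=raw,
        raw_qualities=quality_char * len(raw),
        source_id=source_id,
        mechanism=mechanism,
        umi=umi,
        plus_one_base=plus_one,
        insert=insert,
    )


def _apply_sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < rate):
        chars[i] = "ACGT"[(("ACGT".index(chars[i])) + rng.integers(1, 4)) % 4]
    return "".join(chars)


@dataclass
class ContaminantLoadModel:
    """How contaminant reads are drawn once a read is assigned to a category."""

    category_weights: Mapping[str, float] = field(
        default_factory=lambda: {"expression_plasmid": 0.35, "genome": 0.65}
    )
    genome_feature_weights: Mapping[str, float] = field(
        default_factory=lambda: {"tRNA": 0.45, "rRNA": 0.30, "other": 0.25}
    )
    insert_length_range: tuple[int, int] = (18, 40)


@dataclass
class SimulatedLibrary:
    reads: list[TruthRead]
    truth: pd.DataFrame
    library_id: str = "library"

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.raw_sequence}\n+\n{r.raw_qualities}\n")

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.reads)


def _contaminant_insert(
    contaminants: ContaminantReference,
    load_model: ContaminantLoadModel,
    rng: np.random.Generator,
) -> tuple[str, str, str]:
    """Draw (category_label, source_id, insert) for one contaminant read."""
    cats = list(load_model.category_weights)
    w = np.array([load_model.category_weights[c] for c in cats], dtype=float)
    cat = cats[rng.choice(len(cats), p=w / w.sum())]
    seqs = contaminants.category(cat)
    lo, hi = load_model.insert_length_range
    length = int(rng.integers(lo, hi + 1))

    if cat == "genome":
        feats = list(load_model.genome_feature_weights)
        fw = np.array([load_model.genome_feature_weights[f] for f in feats], float)
        feat = feats[rng.choice(len(feats), p=fw / fw.sum())]
        intervals = [iv for iv in contaminants.annotations if iv.feature == feat]
        if feat != "other" and intervals:
            iv: AnnotationInterval = intervals[rng.integers(len(intervals))]
            seq = seqs[iv.reference_id]
            length = min(length, iv.end - iv.start)
            start = int(rng.integers(iv.start, iv.end - length + 1))
            source = iv.reference_id
        else:
            source = list(seqs)[rng.integers(len(seqs))]
            seq = seqs[source]
            length = min(length, len(seq))
            start = int(rng.integers(0, len(seq) - length + 1))
    else:
        source = list(seqs)[rng.integers(len(seqs))]
        seq = seqs[source]
        length = min(length, len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))

    insert = seq[start : start + length]
    if rng.random() < 0.5:  # contaminating DNA enters in either orientation
        insert = revcomp(insert)
    return cat, source, insert


def simulate_library(
    ref: MiRNAReference,
    contaminants: ContaminantReference | None,
    model: CaptureModel,
    input_amount_pg: float,
    n_reads: int,
    seed: int,
    scheme: OligoScheme | None = None,
    read_len: int = 75,
    library_id: str = "library",
    load_model: ContaminantLoadModel | None = None,
) -> SimulatedLibrary:
    """Simulate a library of ``n_reads`` reads with a truth row per read.

    The expected contaminant read fraction is
    ``load / (load + input_pg * capture_efficiency_per_pg)``, so the
    miRNA:contaminant read ratio is proportional to the input amount.
    Per-miRNA expected counts carry multiplicative lognormal(0, sigma^2)
    capture-efficiency weights. Deterministic given ``seed``.
    """
    if len(ref) == 0:
        raise ValueError("empty miRNA reference")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    scheme = scheme or OligoScheme()
    load_model = load_model or ContaminantLoadModel()
    rng = np.random.default_rng(seed)

    load = model.contaminant_molar_load
    signal = input_amount_pg * model.capture_efficiency_per_pg
    f_contaminant = load / (load + signal) if load > 0 else 0.0
    if load > 0 and contaminants is None:
        raise ValueError("contaminant_molar_load > 0 but no contaminant reference")

    # per-miRNA lognormal capture-efficiency weights (the equimolar-pool bias)
    sigma = model.capture_dispersion
    weights = (
        rng.lognormal(0.0, sigma, size=len(ref)) if sigma > 0 else np.ones(len(ref))
    )
    # mechanism-dependent capture probability renormalises the per-miRNA weights:
    # under incomplete labeling, molecules that drop out produce no read at all
    entries = list(ref)
    capture_p = np.array(
        [_expected_capture_probability(e.sequence, model) for e in entries]
    )
    weights = weights * capture_p
    if weights.sum() <= 0 and f_contaminant < 1 and model.dimer_rate < 1:
        raise ValueError("capture model leaves no capturable miRNA molecules")

    reads: list[TruthRead] = []
    rows: list[dict] = []
    p_mirna = weights / weights.sum() if weights.sum() > 0 else weights
    for i in range(n_reads):
        read_id = f"{library_id}:{i + 1}"
        u = rng.random()
        if u < model.dimer_rate:
            mech = MechanismLabel("DIMER", 0, 0)
            tr = assemble_raw_read(
                "", mech, scheme, read_len, rng, read_id=read_id, source_id="DIMER"
            )
        elif u < model.dimer_rate + (1 - model.dimer_rate) * f_contaminant:
            cat, source, insert = _contaminant_insert(contaminants, load_model, rng)
            mech = MechanismLabel(f"CONTAMINANT_{cat}", 0, 0)
            tr = assemble_raw_read(
                insert, mech, scheme, read_len, rng, read_id=read_id, source_id=source
            )
        else:
            j = rng.choice(len(entries), p=p_mirna)
            e = entries[j]
            mech = _draw_emitted_mechanism(e.sequence, model, rng)
            tr = assemble_raw_read(
                e.sequence, mech, scheme, read_len, rng,
                read_id=read_id, source_id=e.id,
            )
        if model.sequencing_error_rate > 0:
            tr.raw_sequence = _apply_sequencing_errors(
                tr.raw_sequence, model.sequencing_error_rate, rng
            )
        reads.append(tr)
        rows.append(
            {
                "read_id": tr.read_id,
                "source_id": tr.source_id,
                "mechanism": tr.mechanism.code,
                "three_prime_offset": tr.mechanism.three_prime_offset,
                "five_prime_offset": tr.mechanism.five_prime_offset,
                "umi": tr.umi,
                "plus_one_base": tr.plus_one_base,
                "insert": tr.insert,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["read_id", "source_id", "mechanism", "three_prime_offset",
                 "five_prime_offset", "umi", "plus_one_base", "insert"],
    )
    return SimulatedLibrary(reads, truth, library_id)


def _mechanism_probabilities(seq: str, model: CaptureModel) -> dict[str, float]:
    """Per-molecule probability of each capture mechanism (incl. DROPOUT)."""
    t3 = seq[-1]
    pen = seq[-2] if len(seq) >= 2 else None
    p_lab = model.label_prob(t3)
    pen_ok = pen is not None and pen in PURINES
    probs = {"I_precise": p_lab}
    rest = 1.0 - p_lab
    if t3 in PURINES:
        probs["II_overcapture"] = rest * model.p_overcapture_R
        rest *= 1 - model.p_overcapture_R
    else:
        probs["IV_plus2_internal"] = rest * model.p_nta * model.p_internal_minus1
        probs["III_plus2_apparent_precise"] = (
            rest * model.p_nta * (1 - model.p_internal_minus1)
        )
        rest *= 1 - model.p_nta
    if pen_ok:
        probs["V_plus1_penultimate"] = rest * model.p_penultimate_plus1
        rest *= 1 - model.p_penultimate_plus1
    probs["DROPOUT"] = rest
    return probs


def _expected_capture_probability(seq: str, model: CaptureModel) -> float:
    return 1.0 - _mechanism_probabilities(seq, model)["DROPOUT"]


def _draw_emitted_mechanism(
    seq: str, model: CaptureModel, rng: np.random.Generator
) -> MechanismLabel:
    """Draw a mechanism conditional on the molecule producing a read."""
    probs = _mechanism_probabilities(seq, model)
    probs.pop("DROPOUT")
    codes = list(probs)
    w = np.array([probs[c] for c in codes])
    code = codes[rng.choice(len(codes), p=w / w.sum())]
    off5 = 1 if rng.random() < model.p_5p_truncation else 0
    return MechanismLabel(code, MECHANISM_OFFSETS[code], off5)


def implied_end_precision(
    ref: MiRNAReference, model: CaptureModel, end: str = "3p"
) -> float:
    """Model-implied mean end precision over the pool.

    For each miRNA the probability that an emitted read retains the terminal
    nucleotide (3': mechanisms with zero 3' offset; 5': no 5' truncation),
    averaged over miRNAs — the same estimand the empirical estimator targets.
    """
    vals = []
    for e in ref:
        probs = _mechanism_probabilities(e.sequence, model)
        p_cap = 1.0 - probs.pop("DROPOUT")
        if p_cap <= 0:
            continue
        if end == "3p":
            p_precise = sum(
                p for c, p in probs.items() if MECHANISM_OFFSETS[c] == 0
            )
            vals.append(p_precise / p_cap)
        elif end == "5p":
            vals.append(1.0 - model.p_5p_truncation)
        else:
            raise ValueError("end must be '3p' or '5p'")
    if not vals:
        raise ValueError("no capturable miRNAs under this model")
    return float(np.mean(vals))
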