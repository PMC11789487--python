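"""Statistical comparison of libraries and input-titration extrapolation.

Libraries are compared on per-miRNA end-precision fractions with a paired
two-sided Student's t-test restricted to miRNAs with enough alignments in
both libraries, Bonferroni-adjusted; the contamination analysis fits a
through-origin line to the miRNA:contaminant read ratio across an input
titration and extrapolates the input amount at which the ratio reaches a
target (9:1, i.e. 90% of reads from the input pool).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

AVOGADRO = 6.02214076e23
#: average mass of one nucleotide residue in single-stranded RNA (Da)
RNA_RESIDUE_MASS_DA = 321.5


@dataclass
class ComparisonResult:
    n_mirnas: int
    mean_difference_pct: float  # mean per-miRNA difference (B - A), percent
    ci95_pct: tuple[float, float]
    t_statistic: float
    p_value: float
    adjusted_p: float
    direction: str  # "B>A" | "B<A" | "none"


def bonferroni_adjust(p: float, k: int) -> float:
    """min(1, p * k); monotone in p and capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if k < 1:
        raise ValueError("correction factor must be >= 1")
    return min(1.0, p * k)


def paired_precision_comparison(
    fractions_a: pd.DataFrame,
    fractions_b: pd.DataFrame,
    min_alignments: int = 30,
    correction_factor: int | None = None,
) -> ComparisonResult:
    """Paired two-sided t-test on per-miRNA precision fractions (B vs A).

    Inputs are per-miRNA tables with columns ``T`` (alignments) and
    ``fraction`` (as produced by the end-precision estimator). Pairs are
    restricted to miRNAs with at least ``min_alignments`` alignments in BOTH
    libraries. The mean difference (B - A) and its 95% CI from the t
    distribution are reported in percent. By default the Bonferroni factor is
    the number of paired miRNAs; pass ``correction_factor`` to adjust by the
    number of simultaneous comparisons instead.
    """
    common = fractions_a.index.intersection(fractions_b.index)
    qual = [
        i
        for i in common
        if fractions_a.loc[i, "T"] >= min_alignments
        and fractions_b.loc[i, "T"] >= min_alignments
    ]
    if len(qual) < 3:
        raise ValueError(
            f"only {len(qual)} miRNA pairs with >= {min_alignments} alignments"
        )
    a = fractions_a.loc[qual, "fraction"].to_numpy(dtype=float)
    b = fractions_b.loc[qual, "fraction"].to_numpy(dtype=float)
    d = b - a
    n = len(d)
    mean_d = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        t_stat, p = 0.0, 1.0
        half = 0.0
    else:
        t_stat, p = sps.ttest_rel(b, a)
        t_stat, p = float(t_stat), float(p)
        half = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    k = correction_factor if correction_factor is not None else n
    adj = bonferroni_adjust(p, k)
    direction = "B>A" if mean_d > 0 else ("B<A" if mean_d < 0 else "none")
    return ComparisonResult(
        n_mirnas=n,
        mean_difference_pct=100 * mean_d,
        ci95_pct=(100 * (mean_d - half), 100 * (mean_d + half)),
        t_statistic=t_stat,
        p_value=p,
        adjusted_p=adj,
        direction=direction,
    )


def one_sided_unpaired_test(
    fractions_a: Sequence[float], fractions_b: Sequence[float]
) -> float:
    """Welch one-sided p-value for mean(B) > mean(A).

    With zero variance in both groups and equal means the test is degenerate
    and p = 0.5 is returned (no evidence of a shift in either direction).
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if b.mean() == a.mean():
            return 0.5
        return 0.0 if b.mean() > a.mean() else 1.0
    res = sps.ttest_ind(b, a, equal_var=False, alternative="greater")
    return float(res.pvalue)


def spearman_rank_correlation(
    cpm_a: Sequence[float], cpm_b: Sequence[float]
) -> float:
    """Spearman's rho with average ranks for ties; NaN flagged as undefined."""
    a = np.asarray(cpm_a, dtype=float)
    b = np.asarray(cpm_b, dtype=float)
    if a.size != b.size:
        raise ValueError("vectors must have the same miRNA universe")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, _ = sps.spearmanr(a, b)
    return float(rho)


@dataclass
class TitrationSeries:
    """Observed (input_pg, miRNA:contaminant read ratio) points."""

    points: list[tuple[float, float]]

    def __post_init__(self):
        for x, y in self.points:
            if x <= 0:
                raise ValueError("input amounts must be positive")
            if y < 0:
                raise ValueError("ratios must be >= 0")


@dataclass
class ExtrapolationResult:
    slope_per_pg: float
    extrapolated_input_pg: float
    r_squared: float


def extrapolate_minimum_input(
    series: TitrationSeries, target_ratio: float = 9.0
) -> ExtrapolationResult:
    """Through-origin fit of ratio vs input; input at which ratio hits target.

    The model (a fixed contaminant load competing with the input) forces the
    ratio to zero at zero input, so the least-squares slope through the
    origin ``k = sum(x*y)/sum(x^2)`` is used and the extrapolated minimum
    input is ``target_ratio / k``. With a single point this reduces to
    ``x * target / y``.
    """
    x = np.array([p[0] for p in series.points], dtype=float)
    y = np.array([p[1] for p in series.points], dtype=float)
    if np.all(y == 0):
        raise ValueError("all ratios are zero; slope undefined")
    k = float((x * y).sum() / (x * x).sum())
    resid = y - k * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return ExtrapolationResult(k, target_ratio / k, r2)


def molecules_from_mass(
    mass_g: float,
    mean_length_nt: float = 22.0,
    residue_mass_da: float = RNA_RESIDUE_MASS_DA,
) -> float:
    """Number of RNA molecules in ``mass_g`` grams at the given mean length."""
    if mass_g < 0 or mean_length_nt <= 0 or residue_mass_da <= 0:
        raise ValueError("inputs must be positive (mass may be zero)")
    return mass_g / (mean_length_nt * residue_mass_da / AVOGADRO)
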