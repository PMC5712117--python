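"""Coding vs noncoding transcript comparison statistics.

lncRNAs are expected to fold into less stable secondary structures than
protein-coding mRNAs. The comparison works on four per-transcript
metrics — length (nt), GC fraction, minimum free energy (MFE, kcal/mol)
and length-corrected MFE (kcal/mol/nt, MFE divided by length) — and for
each metric reports:

* Welch's two-sample t statistic with Welch–Satterthwaite degrees of
  freedom (unequal variances, two-sided p),
* the effect size computed from the t statistic as d = 2·|t|/√df, and
* the two-sample Kolmogorov–Smirnov statistic D = sup|ECDF₁ − ECDF₂|
  with its asymptotic p-value at effective n = n₁n₂/(n₁+n₂).

Because lncRNAs are unevenly distributed along the genome, the
protein-coding control set is drawn by chromosome-stratified random
sampling (``stratified_sample``) so both groups share the same
chromosomal occurrence pattern.

``nussinov_fold`` is a maximum base-pairing folder (Watson–Crick plus
G·U wobble, minimum hairpin loop, no pseudoknots) used to fold the
small synthetic fixtures; real thermodynamic MFE values are parsed from
RNAfold output by :mod:`vinenc.formats_io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats

from .errors import DataError
from .types import FoldResult, GeneModel, TranscriptRecord


@dataclass(frozen=True)
class MetricSample:
    group_label: str
    values: tuple[float, ...]


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison report for one metric."""

    metric: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    t: float
    df: float
    p_t: float
    d: float
    ks_D: float
    p_ks: float


@dataclass(frozen=True)
class StratifiedPlan:
    """Per-chromosome sample counts with a reproducibility seed."""

    counts: dict[str, int]
    seed: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# elementary metrics


def gc_content(sequence: str) -> float:
    """GC fraction: (#G + #C) / length; N counts in the denominator only."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


def length_corrected_mfe(fold: FoldResult, length: int) -> float:
    """MFE normalized by transcript length, kcal/mol/nt."""
    if length <= 0:
        raise ValueError("length must be positive")
    return fold.mfe / length


# ---------------------------------------------------------------------------
# two-sample statistics


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch's t and Welch–Satterthwaite df from group summaries.

    t = (m₁ − m₂) / √(s₁²/n₁ + s₂²/n₂);
    df = (s₁²/n₁ + s₂²/n₂)² / [ (s₁²/n₁)²/(n₁−1) + (s₂²/n₂)²/(n₂−1) ].
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0:
        raise DataError("degenerate variance: both groups have zero spread")
    t = (mean1 - mean2) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df


def welch_t(values1, values2) -> tuple[float, float, float]:
    """Welch's t, df and two-sided p computed from raw samples."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    t, df = welch_t_from_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def cohens_d_from_t(t: float, df: float) -> float:
    """Effect size from the t statistic: d = 2·|t| / √df.

    Reported as a magnitude; conventional interpretation calls
    d >= 0.8 a 'large' effect.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    return 2.0 * abs(t) / math.sqrt(df)


def ks_two_sample(values1, values2) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    D = sup|ECDF₁ − ECDF₂|; p is the Kolmogorov survival function
    evaluated at √(n₁n₂/(n₁+n₂))·D. Exact small-sample p-values are out
    of scope; at the sample sizes the comparison targets (thousands per
    group) the asymptotic distribution is accurate.
    """
    a = np.sort(np.asarray(values1, dtype=float))
    b = np.sort(np.asarray(values2, dtype=float))
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf1 = np.searchsorted(a, pooled, side="right") / n1
    cdf2 = np.searchsorted(b, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf1 - cdf2)))
    en = n1 * n2 / (n1 + n2)
    p = float(special.kolmogorov(math.sqrt(en) * d))
    return d, min(1.0, max(0.0, p))


# ---------------------------------------------------------------------------
# chromosome-stratified control sampling


def stratified_sample(pool: list[GeneModel], plan: StratifiedPlan) -> list[str]:
    """Sample gene ids per chromosome to match the plan counts exactly.

    Sampling is uniform without replacement within each chromosome and
    fully reproducible from the plan's seed.
    """
    rng = np.random.default_rng(plan.seed)
    by_chrom: dict[str, list[str]] = {}
    for g in pool:
        by_chrom.setdefault(g.chromosome, []).append(g.gene_id)
    out: list[str] = []
    for chrom in sorted(plan.counts):
        k = plan.counts[chrom]
        if k < 0:
            raise ValueError(f"negative count for {chrom}")
        candidates = sorted(by_chrom.get(chrom, []))
        if len(candidates) < k:
            raise DataError(
                f"chromosome '{chrom}': plan requests {k} genes, pool has {len(candidates)}"
            )
        out.extend(rng.choice(candidates, size=k, replace=False))
    return out


# ---------------------------------------------------------------------------
# maximum base-pairing folding stand-in

_PAIRABLE = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}


def nussinov_fold(sequence: str, min_loop: int = 3) -> tuple[int, str, float]:
    """Maximum base-pair fold with a hairpin-loop constraint.

    Pairs are Watson–Crick plus G·U wobble; a pair (i, j) requires
    j − i > ``min_loop`` unpaired-equivalent separation; structures are
    nested (no pseudoknots). Returns ``(n_pairs, dot_bracket,
    pseudo_mfe)`` where the pseudo energy is −1.0 per pair. The
    traceback is deterministic: at each interval the last position is
    left unpaired only when pairing it gains nothing, and its partner is
    the smallest qualifying index.
    """
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - {"A", "C", "G", "U"}
    if bad:
        raise ValueError(f"invalid characters for folding: {sorted(bad)}")
    n = len(seq)

    def pairable(i: int, j: int) -> bool:
        return (seq[i], seq[j]) in _PAIRABLE and j - i > min_loop

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        score = best(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if pairable(k, j):
                score = max(score, best(i, k - 1) + best(k + 1, j - 1) + 1)
        return score

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        if j - i <= min_loop:
            return
        target = best(i, j)
        for k in range(i, j - min_loop):  # prefer pairing j, smallest partner k
            if pairable(k, j) and best(i, k - 1) + best(k + 1, j - 1) + 1 == target:
                structure[k], structure[j] = "(", ")"
                traceback(i, k - 1)
                traceback(k + 1, j - 1)
                return
        traceback(i, j - 1)

    pairs = 0
    if n:
        pairs = best(0, n - 1)
        traceback(0, n - 1)
    best.cache_clear()
    return pairs, "".join(structure), -1.0 * pairs


# ---------------------------------------------------------------------------
# group comparison report


def _compare_metric(metric: str, v1, v2) -> GroupComparison:
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError(f"metric '{metric}': both groups need at least 2 values")
    t, df, p_t = welch_t(a, b)
    d = cohens_d_from_t(t, df)
    ks_d, p_ks = ks_two_sample(a, b)
    return GroupComparison(
        metric=metric,
        n1=len(a), n2=len(b),
        mean1=float(a.mean()), sd1=float(a.std(ddof=1)),
        mean2=float(b.mean()), sd2=float(b.std(ddof=1)),
        t=t, df=df, p_t=p_t, d=d, ks_D=ks_d, p_ks=p_ks,
    )


METRICS = ("length", "gc", "mfe", "mfe_per_nt")


def compare_groups(
    lnc: list[TranscriptRecord],
    lnc_folds: dict[str, FoldResult],
    coding: list[TranscriptRecord],
    coding_folds: dict[str, FoldResult],
) -> list[GroupComparison]:
    """Compare the two transcript groups on all four metrics.

    Group 1 is the lncRNA set, group 2 the protein-coding set; each
    transcript must have a fold result keyed by its id.
    """

    def metric_values(transcripts, folds):
        vals = {m: [] for m in METRICS}
        for t in transcripts:
            if t.id not in folds:
                raise DataError(f"no fold result for transcript '{t.id}'")
            fold = folds[t.id]
            vals["length"].append(float(t.length))
            vals["gc"].append(t.gc)
            vals["mfe"].append(fold.mfe)
            vals["mfe_per_nt"].append(length_corrected_mfe(fold, t.length))
        return vals

    v_lnc = metric_values(lnc, lnc_folds)
    v_cod = metric_values(coding, coding_folds)
    return [_compare_metric(m, v_lnc[m], v_cod[m]) for m in METRICS]


def render_report(comparisons: list[GroupComparison]) -> str:
    """Plain-text table of all group comparisons."""
    header = (
        f"{'metric':<12}{'n1':>6}{'n2':>6}{'mean1':>12}{'sd1':>10}"
        f"{'mean2':>12}{'sd2':>10}{'t':>10}{'df':>10}{'p_t':>10}"
        f"{'d':>8}{'ks_D':>8}{'p_ks':>10}"
    )
    lines = [header]
    for c in comparisons:
        lines.append(
            f"{c.metric:<12}{c.n1:>6}{c.n2:>6}{c.mean1:>12.4g}{c.sd1:>10.3g}"
            f"{c.mean2:>12.4g}{c.sd2:>10.3g}{c.t:>10.3f}{c.df:>10.1f}{c.p_t:>10.3g}"
            f"{c.d:>8.3f}{c.ks_D:>8.3f}{c.p_ks:>10.3g}"
        )
    return "\n".join(lines)
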