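"""Allele-specific TF-binding (ASB) calling and training-set assembly.

ASB SNVs — heterozygous sites where ChIP-seq reads support one allele
significantly more than the other — are the high-confidence positives for
the generic scoring model.  The allelic null is a beta-binomial with mean
0.5 and overdispersion ``rho``; ``rho = 0`` reduces to the exact binomial.
Tests are restricted to sites whose reads fall inside the same dataset's
TF-binding peaks, sites inside copy-number-variable regions (read-depth
ratio outside [0.5, 1.5]) are excluded, and significance is controlled by
Benjamini-Hochberg FDR across all in-peak tests.

The negative set combines three sources with equal total weight:
(i) non-allelic binding SNVs (exactly balanced read counts),
(ii) for each positive, its nearest variant outside all peaks, and
(iii) a random sample of variants with no functional-annotation hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic import GenomicInterval, IntervalIndex, Variant

log = logging.getLogger(__name__)

#: Read-depth ratio bounds outside which a region is treated as copy-number
#: variable and its sites excluded from allelic testing.
CNV_RATIO_BOUNDS = (0.5, 1.5)


@dataclass(frozen=True)
class AllelicSite:
    """Allelic read counts for one variant in one ChIP-seq dataset."""

    variant: Variant
    dataset: str
    ref_count: int
    alt_count: int
    in_peak: bool

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref_count + self.alt_count < 1:
            raise ValueError("total read count must be >= 1")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class CnvRegion:
    """A copy-number-variation call with its read-depth ratio."""

    interval: GenomicInterval
    read_depth_ratio: float

    def __post_init__(self) -> None:
        if self.read_depth_ratio <= 0:
            raise ValueError("read depth ratio must be positive")

    @property
    def excluded(self) -> bool:
        lo, hi = CNV_RATIO_BOUNDS
        return self.read_depth_ratio < lo or self.read_depth_ratio > hi


@dataclass
class TrainingSet:
    """Positives plus the three equally-weighted negative sublists.

    Per-example weights: each positive gets ``1/len(positives)`` and each
    negative sublist totals one third of the total negative weight (1.0),
    so the two classes carry equal total weight overall.
    """

    positives: list[Variant]
    non_allelic: list[Variant]
    nearest_outside_peak: list[Variant]
    random_no_hit: list[Variant]
    weights: dict[str, float] = field(default_factory=dict)

    def negative_sublists(self) -> dict[str, list[Variant]]:
        return {
            "non_allelic": self.non_allelic,
            "nearest_outside_peak": self.nearest_outside_peak,
            "random_no_hit": self.random_no_hit,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.positives:
            rows.append((v.key, v.chrom, v.pos, v.ref, v.alt, 1, "positive", self.weights[v.key]))
        for name, sub in self.negative_sublists().items():
            for v in sub:
                rows.append((v.key, v.chrom, v.pos, v.ref, v.alt, 0, name, self.weights[v.key]))
        return pd.DataFrame(
            rows, columns=["id", "chrom", "pos", "ref", "alt", "label", "source", "weight"]
        )


def _betabinom_params(rho: float) -> float:
    """Shared alpha = beta for a symmetric beta-binomial with overdispersion rho.

    rho is the standard intraclass correlation 1/(alpha+beta+1), so
    alpha = beta = (1/rho - 1)/2.
    """
    return (1.0 / rho - 1.0) / 2.0


def beta_binomial_pvalue(ref_count: int, alt_count: int, rho: float = 0.0) -> float:
    """Two-sided p-value for allelic imbalance under a symmetric null.

    The null allelic ratio is fixed at 0.5; ``rho`` in [0, 1) is the
    beta-binomial overdispersion.  Two-sided p is
    ``min(1, 2 * min(lower tail, upper tail))``; at ``rho = 0`` this equals
    the exact binomial two-sided p-value at p = 0.5.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    k = int(ref_count)
    n = k + int(alt_count)
    if n < 1:
        raise ValueError("total read count must be >= 1")
    if rho == 0.0:
        dist = stats.binom(n, 0.5)
    else:
        a = _betabinom_params(rho)
        dist = stats.betabinom(n, a, a)
    lower = dist.cdf(k)
    upper = dist.sf(k - 1)  # P(X >= k)
    return float(min(1.0, 2.0 * min(lower, upper)))


def estimate_overdispersion(sites: Sequence[AllelicSite], min_total: int = 6) -> float:
    """Method-of-moments estimate of the null overdispersion rho.

    Under BetaBinomial(n, 0.5, rho) the allelic ratio r = k/n satisfies
    ``E[(r - 0.5)^2] = (0.25/n) * (1 + (n-1) rho)``.  Pooling over sites
    and solving for rho gives the moment estimator, clamped to [0, 0.99].
    Requires at least 50 sites with total count >= ``min_total``.
    """
    usable = [s for s in sites if s.total >= min_total]
    if len(usable) < 50:
        raise ValueError(
            f"need >= 50 sites with total count >= {min_total} to estimate rho "
            f"(got {len(usable)}); supply a default rho via configuration instead"
        )
    n = np.array([s.total for s in usable], dtype=float)
    r = np.array([s.ref_count for s in usable], dtype=float) / n
    excess = np.sum((r - 0.5) ** 2 - 0.25 / n)
    scale = np.sum(0.25 * (n - 1.0) / n)
    rho = excess / scale if scale > 0 else 0.0
    return float(np.clip(rho, 0.0, 0.99))


def call_asb(
    sites: Sequence[AllelicSite],
    cnv: Sequence[CnvRegion] = (),
    fdr: float = 0.05,
    rho: float = 0.0,
    min_total: int = 6,
) -> pd.DataFrame:
    """Call ASB SNVs from allelic counts.

    Sites inside excluded CNV regions are removed before testing; only
    in-peak sites with total count >= ``min_total`` are tested.  P-values
    are corrected by Benjamini-Hochberg at level ``fdr`` across all tests.
    A variant is ASB-positive when significant in at least one dataset;
    tested sites with exactly equal counts are the non-allelic pool.

    Returns a per-site frame with columns ``variant`` (key), ``chrom``,
    ``pos``, ``dataset``, counts, ``tested``, ``pvalue``, ``qvalue``,
    ``significant`` and ``non_allelic``.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    cnv_index = IntervalIndex(c.interval for c in cnv if c.excluded)
    kept = [s for s in sites if not cnv_index.contains_variant(s.variant)]
    rows = []
    for s in kept:
        tested = s.in_peak and s.total >= min_total
        rows.append(
            {
                "variant": s.variant.key,
                "chrom": s.variant.chrom,
                "pos": s.variant.pos,
                "ref": s.variant.ref,
                "alt": s.variant.alt,
                "dataset": s.dataset,
                "ref_count": s.ref_count,
                "alt_count": s.alt_count,
                "tested": tested,
                "pvalue": beta_binomial_pvalue(s.ref_count, s.alt_count, rho) if tested else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or not df["tested"].any():
        log.warning("call_asb: no in-peak sites to test")
        df["qvalue"] = np.nan
        df["significant"] = False
        df["non_allelic"] = False
        return df
    df["qvalue"] = np.nan
    df["significant"] = False
    mask = df["tested"].to_numpy()
    reject, qvals, _, _ = multipletests(df.loc[mask, "pvalue"], alpha=fdr, method="fdr_bh")
    df.loc[mask, "qvalue"] = qvals
    df.loc[mask, "significant"] = reject
    df["non_allelic"] = df["tested"] & (df["ref_count"] == df["alt_count"])
    return df


def asb_positives(results: pd.DataFrame) -> list[Variant]:
    """Unique variants significant in >= 1 dataset, in genomic order."""
    return _unique_variants(results[results.get("significant", False) == True])  # noqa: E712


def asb_non_allelic(results: pd.DataFrame) -> list[Variant]:
    """Unique non-allelic (exactly balanced) tested variants, excluding positives."""
    if results.empty:
        return []
    pos_keys = set(results.loc[results["significant"] == True, "variant"])  # noqa: E712
    sub = results[(results["non_allelic"] == True) & ~results["variant"].isin(pos_keys)]  # noqa: E712
    return _unique_variants(sub)


def _unique_variants(df: pd.DataFrame) -> list[Variant]:
    seen: dict[str, Variant] = {}
    for _, row in df.iterrows():
        v = Variant(row["chrom"], int(row["pos"]), row["ref"], row["alt"],
                    None if ":" in str(row["variant"]) else str(row["variant"]))
        seen.setdefault(v.key, v)
    return sorted(seen.values())


def build_negative_set(
    positives: Sequence[Variant],
    non_allelic: Sequence[Variant],
    all_variants: Sequence[Variant],
    peaks: IntervalIndex,
    has_annotation: Callable[[Variant], bool],
    n_random: int = 1000,
    seed: int = 0,
) -> TrainingSet:
    """Assemble the three-source negative set and per-example weights.

    Sublist (ii) takes, for every positive, the nearest variant on the same
    chromosome that lies outside all peaks (deduplicated; a positive with
    no peak-free neighbour contributes nothing, logged).  Sublist (iii) is
    a seeded sample of ``n_random`` variants with no annotation hits.
    """
    pos_keys = {p.key for p in positives}
    by_chrom: dict[str, list[Variant]] = {}
    for v in sorted(all_variants):
        if v.key not in pos_keys:
            by_chrom.setdefault(v.chrom, []).append(v)

    nearest: dict[str, Variant] = {}
    orphans = 0
    for p in positives:
        candidates = by_chrom.get(p.chrom, [])
        best: Variant | None = None
        best_d = None
        for c in candidates:
            if peaks.contains_variant(c):
                continue
            d = abs(c.pos - p.pos)
            if best is None or d < best_d or (d == best_d and c < best):
                best, best_d = c, d
        if best is None:
            orphans += 1
        else:
            nearest[best.key] = best
    if orphans:
        log.info("build_negative_set: %d positive(s) had no peak-free neighbour", orphans)

    rng = np.random.default_rng(seed)
    taken = pos_keys | set(nearest)
    pool = [v for v in sorted(all_variants)
            if v.key not in taken and not has_annotation(v)]
    if len(pool) > n_random:
        idx = rng.choice(len(pool), size=n_random, replace=False)
        random_sub = sorted(pool[i] for i in idx)
    else:
        random_sub = pool

    non_allelic_sub = sorted({v.key: v for v in non_allelic if v.key not in pos_keys}.values())
    ts = TrainingSet(
        positives=sorted(positives),
        non_allelic=non_allelic_sub,
        nearest_outside_peak=sorted(nearest.values()),
        random_no_hit=random_sub,
    )
    weights: dict[str, float] = {}
    n_pos = len(ts.positives)
    for v in ts.positives:
        weights[v.key] = 1.0 / n_pos if n_pos else 0.0
    for sub in ts.negative_sublists().values():
        w = (1.0 / 3.0) / len(sub) if sub else 0.0
        for v in sub:
            weights[v.key] = w
    ts.weights = weights
    return ts
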