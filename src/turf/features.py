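"""Feature extraction: variant + annotation bundle -> model feature vectors.

Two feature schemas feed the two random forests:

* **generic** (15 features, across all biosamples pooled): 7 binaries —
  eQTL membership, TF ChIP-seq peak, matched TF motif (motif hit for a TF
  whose peak also covers the variant), matched DNase footprint (footprint
  plus DNase peak co-occurrence), DNase peak, any TF motif, any DNase
  footprint — and 8 numerics — maximum motif information-content change,
  median / 95th-percentile / standard deviation of per-dataset TF ChIP-seq
  signal, the same three for DNase signal, and an externally supplied
  functional-significance score (an input column, never computed here).
* **tissue** (7 binaries, one biosample at a time): DNase peak, DNase
  footprint, H3K27ac, H3K4me1, H3K4me3, H3K36me3, H3K27me3.  Per-cell-line
  models may add H3K4me2 as an optional eighth column; the cross-tissue
  ensemble is restricted to the five widely-assayed marks above.

Quantiles use linear interpolation; the spread is the sample standard
deviation (0 with fewer than two tracks).  A missing assay in a biosample
reads as 0 and is recorded in the bundle's missingness report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic import IntervalIndex, Pwm, SignalTrack, Variant, signal_at

GENERIC_BINARY = (
    "eqtl",
    "tf_peak",
    "matched_tf_motif",
    "matched_dnase_footprint",
    "dnase_peak",
    "any_tf_motif",
    "any_dnase_footprint",
)
GENERIC_NUMERIC = (
    "max_ic_change",
    "chip_signal_q50",
    "chip_signal_q95",
    "chip_signal_sd",
    "dnase_signal_q50",
    "dnase_signal_q95",
    "dnase_signal_sd",
    "deepsea_score",
)

TISSUE_MARKS = ("h3k27ac", "h3k4me1", "h3k4me3", "h3k36me3", "h3k27me3")
OPTIONAL_TISSUE_MARKS = ("h3k4me2",)


@dataclass(frozen=True)
class FeatureSchema:
    """Named, ordered feature roster; persisted beside every feature matrix."""

    name: str
    columns: tuple[str, ...]


GENERIC_SCHEMA = FeatureSchema("generic-v1", GENERIC_BINARY + GENERIC_NUMERIC)
TISSUE_SCHEMA = FeatureSchema("tissue-v1", ("dnase_peak", "dnase_footprint") + TISSUE_MARKS)
TISSUE_SCHEMA_8 = FeatureSchema(
    "tissue-v1+h3k4me2", ("dnase_peak", "dnase_footprint") + TISSUE_MARKS + OPTIONAL_TISSUE_MARKS
)


@dataclass
class AnnotationBundle:
    """Per-biosample annotation tracks used for feature extraction.

    ``tf_peaks`` maps TF name -> peak index; ``histone_peaks`` maps
    lower-case mark name -> peak index.  ``sequence`` holds chromosome
    sequences for motif scanning and may be absent (motif features then 0).
    """

    biosample: str
    tf_peaks: dict[str, IntervalIndex] = field(default_factory=dict)
    dnase_peaks: IntervalIndex = field(default_factory=IntervalIndex)
    footprints: IntervalIndex = field(default_factory=IntervalIndex)
    histone_peaks: dict[str, IntervalIndex] = field(default_factory=dict)
    chip_signals: list[SignalTrack] = field(default_factory=list)
    dnase_signals: list[SignalTrack] = field(default_factory=list)
    eqtl_ids: set[str] = field(default_factory=set)
    pwms: list[Pwm] = field(default_factory=list)
    sequence: dict[str, str] | None = None

    def missing_assays(self, schema: FeatureSchema = TISSUE_SCHEMA) -> list[str]:
        """Tissue-schema assays with no data in this biosample."""
        missing = []
        for col in schema.columns:
            if col == "dnase_peak" and len(self.dnase_peaks) == 0:
                missing.append(col)
            elif col == "dnase_footprint" and len(self.footprints) == 0:
                missing.append(col)
            elif col in TISSUE_MARKS + OPTIONAL_TISSUE_MARKS and len(
                self.histone_peaks.get(col, IntervalIndex())
            ) == 0:
                missing.append(col)
        return missing


def union_bundles(bundles: Sequence[AnnotationBundle], name: str = "union") -> AnnotationBundle:
    """Pool annotations across biosamples (set union of every track type)."""
    out = AnnotationBundle(biosample=name)
    seq: dict[str, str] = {}
    for b in bundles:
        for tf, idx in b.tf_peaks.items():
            tgt = out.tf_peaks.setdefault(tf, IntervalIndex())
            for iv in idx:
                tgt.add(iv)
        for iv in b.dnase_peaks:
            out.dnase_peaks.add(iv)
        for iv in b.footprints:
            out.footprints.add(iv)
        for mark, idx in b.histone_peaks.items():
            tgt = out.histone_peaks.setdefault(mark, IntervalIndex())
            for iv in idx:
                tgt.add(iv)
        out.chip_signals.extend(b.chip_signals)
        out.dnase_signals.extend(b.dnase_signals)
        out.eqtl_ids |= b.eqtl_ids
        out.pwms.extend(p for p in b.pwms if p.id not in {q.id for q in out.pwms})
        if b.sequence:
            seq.update(b.sequence)
    out.sequence = seq or None
    return out


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_COL = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MotifHit:
    """A PWM window covering the variant that passes the score threshold."""

    pwm: Pwm
    chrom: str
    start: int  # 0-based window start
    strand: str
    variant_offset: int  # motif position index covering the variant

    def __post_init__(self) -> None:
        if not 0 <= self.variant_offset < len(self.pwm):
            raise ValueError("variant must lie inside the motif window")


def _window_score(pwm_lo: np.ndarray, window: str) -> float | None:
    score = 0.0
    for j, base in enumerate(window):
        col = _BASE_COL.get(base)
        if col is None:
            return None
        score += pwm_lo[j, col]
    return score


def scan_motifs(
    v: Variant,
    context_sequence: str,
    context_start: int,
    pwms: Sequence[Pwm],
    score_fraction: float = 0.8,
) -> list[MotifHit]:
    """Scan both strands for PWM windows covering the variant.

    ``context_sequence`` is the reference sequence beginning at 1-based
    genomic position ``context_start``; it must span the variant plus the
    longest motif on both sides.  A window is a hit when its log-odds score
    (uniform 0.25 background) reaches ``score_fraction`` of the motif's
    maximum attainable score.  Forward and reverse hits on the same window
    are deduplicated to one hit per (pwm, window).
    """
    if not 0.0 < score_fraction <= 1.0:
        raise ValueError("score_fraction must be in (0, 1]")
    seq = context_sequence.upper()
    var_idx = v.pos - context_start  # index of variant base in seq
    if var_idx < 0 or var_idx >= len(seq):
        raise ValueError("context sequence does not cover the variant")
    hits: dict[tuple[str, int], MotifHit] = {}
    for pwm in pwms:
        L = len(pwm)
        if var_idx - (L - 1) < 0 or var_idx + L > len(seq):
            raise ValueError(
                f"context sequence too short for motif {pwm.id} (length {L})"
            )
        lo = pwm.log_odds()
        max_score = float(lo.max(axis=1).sum())
        threshold = score_fraction * max_score
        for off in range(L):  # off = motif position covering the variant
            w0 = var_idx - off
            window = seq[w0 : w0 + L]
            fwd = _window_score(lo, window)
            rc = window.translate(_COMPLEMENT)[::-1]
            rev = _window_score(lo, rc)
            best = None
            if fwd is not None and fwd >= threshold:
                best = ("+", off)
            if rev is not None and rev >= threshold and (best is None or rev > fwd):
                best = ("-", L - 1 - off)
            if best is not None:
                key = (pwm.id, w0)
                if key not in hits:
                    strand, motif_off = best
                    hits[key] = MotifHit(
                        pwm=pwm,
                        chrom=v.chrom,
                        start=context_start - 1 + w0,
                        strand=strand,
                        variant_offset=motif_off,
                    )
    return sorted(hits.values(), key=lambda h: (h.pwm.id, h.start))


def ic_change(hit: MotifHit, ref: str, alt: str) -> float:
    """Signed information-content change when ref is replaced by alt.

    ``IC(pos) * (f(ref, pos) - f(alt, pos))`` where IC is the smoothed
    column information content in bits.  On the minus strand the alleles
    are complemented before the frequency lookup.
    """
    j = hit.variant_offset
    if hit.strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    f = hit.pwm.matrix
    ic = float(hit.pwm.information_content()[j])
    return ic * float(f[j, _BASE_COL[ref]] - f[j, _BASE_COL[alt]])


# ---------------------------------------------------------------------------
# Feature vectors
# ---------------------------------------------------------------------------


def _signal_stats(values: Sequence[float]) -> tuple[float, float, float]:
    if len(values) == 0:
        return 0.0, 0.0, 0.0
    arr = np.asarray(values, dtype=float)
    q50 = float(np.quantile(arr, 0.50))
    q95 = float(np.quantile(arr, 0.95))
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return q50, q95, sd


def _motif_hits_for(v: Variant, bundle: AnnotationBundle) -> list[MotifHit]:
    if not bundle.pwms or not bundle.sequence:
        return []
    seq = bundle.sequence.get(v.chrom)
    if seq is None:
        return []
    max_len = max(len(p) for p in bundle.pwms)
    lo = max(0, v.pos - 1 - max_len)
    hi = min(len(seq), v.pos + max_len)
    window = seq[lo:hi]
    if v.pos - 1 - lo < max_len - 1 or hi - v.pos < max_len - 1:
        return []  # variant too close to the contig edge for the longest motif
    try:
        return scan_motifs(v, window, lo + 1, bundle.pwms)
    except ValueError:
        return []


def extract_generic(
    v: Variant,
    bundle: AnnotationBundle,
    deepsea_score: float | None = None,
) -> pd.Series:
    """15-feature generic vector from the all-biosample union bundle."""
    hits = _motif_hits_for(v, bundle)
    tf_hit_names = {h.pwm.tf for h in hits}
    tf_peak_names = {tf for tf, idx in bundle.tf_peaks.items() if idx.contains_variant(v)}
    in_dnase = bundle.dnase_peaks.contains_variant(v)
    in_footprint = bundle.footprints.contains_variant(v)

    values = {
        "eqtl": float(v.key in bundle.eqtl_ids or (v.id or "") in bundle.eqtl_ids),
        "tf_peak": float(bool(tf_peak_names)),
        "matched_tf_motif": float(bool(tf_hit_names & tf_peak_names)),
        "matched_dnase_footprint": float(in_footprint and in_dnase),
        "dnase_peak": float(in_dnase),
        "any_tf_motif": float(bool(hits)),
        "any_dnase_footprint": float(in_footprint),
    }
    values["max_ic_change"] = (
        max(abs(ic_change(h, v.ref, v.alt)) for h in hits) if hits else 0.0
    )
    chip_vals = signal_at(v, bundle.chip_signals)
    dnase_vals = signal_at(v, bundle.dnase_signals)
    (
        values["chip_signal_q50"],
        values["chip_signal_q95"],
        values["chip_signal_sd"],
    ) = _signal_stats(chip_vals)
    (
        values["dnase_signal_q50"],
        values["dnase_signal_q95"],
        values["dnase_signal_sd"],
    ) = _signal_stats(dnase_vals)
    values["deepsea_score"] = float(deepsea_score) if deepsea_score is not None else 0.0
    return pd.Series([values[c] for c in GENERIC_SCHEMA.columns], index=GENERIC_SCHEMA.columns)


def extract_tissue(
    v: Variant,
    bundle: AnnotationBundle,
    schema: FeatureSchema = TISSUE_SCHEMA,
) -> pd.Series:
    """Binary tissue vector from a single biosample's bundle.

    A mark with no data in the biosample reads 0; consult
    :meth:`AnnotationBundle.missing_assays` for the missingness report.
    """
    values = {}
    for col in schema.columns:
        if col == "dnase_peak":
            values[col] = float(bundle.dnase_peaks.contains_variant(v))
        elif col == "dnase_footprint":
            values[col] = float(bundle.footprints.contains_variant(v))
        else:
            idx = bundle.histone_peaks.get(col)
            values[col] = float(idx.contains_variant(v)) if idx is not None else 0.0
    return pd.Series([values[c] for c in schema.columns], index=schema.columns)


def generic_feature_matrix(
    variants: Sequence[Variant],
    bundle: AnnotationBundle,
    deepsea: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Generic feature matrix indexed by variant key."""
    rows = [
        extract_generic(v, bundle, None if deepsea is None else deepsea.get(v.key))
        for v in variants
    ]
    return pd.DataFrame(rows, index=[v.key for v in variants])


def tissue_feature_matrix(
    variants: Sequence[Variant],
    bundle: AnnotationBundle,
    schema: FeatureSchema = TISSUE_SCHEMA,
) -> pd.DataFrame:
    rows = [extract_tissue(v, bundle, schema) for v in variants]
    return pd.DataFrame(rows, index=[v.key for v in variants])
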