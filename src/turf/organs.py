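"""Organ-level score aggregation and significance transformation.

An organ's annotation bundle is the union of the bundles of every
biosample mapped to it, so each binary tissue feature is 1 when any
member biosample has it.  The organ-specific score is the tissue-specific
score evaluated on that union bundle.  Scores are converted to
significance by ranking against a background of GWAS variants (after LD
expansion at R^2 >= 0.6):

    sigma = -log10(max(#{background > score} / N, 1/(N + 1)))

The comparison is strictly greater, so background ties favour the query;
the 1/(N+1) floor keeps the transform finite when the query tops the
whole background.  Only variants on chromosomes 1-22 and X are scored at
organ level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import AnnotationBundle, union_bundles
from .genomic import ORGAN_SCORING_CHROMS, BiosampleOrganMap, Variant
from .models import ScoreTable, TissueEnsemble, VariantFunctionResults, score_variants

log = logging.getLogger(__name__)

DEFAULT_BACKGROUND_R2 = 0.6


@dataclass
class OrganBundle:
    """Union-of-biosample annotation bundle for one organ."""

    organ: str
    bundle: AnnotationBundle
    biosamples: tuple[str, ...]

    @property
    def scoreable(self) -> bool:
        """An organ needs histone-mark and DNase data to be scored."""
        return len(self.bundle.dnase_peaks) > 0 and any(
            len(idx) > 0 for idx in self.bundle.histone_peaks.values()
        )


def build_organ_bundles(
    bundles: Mapping[str, AnnotationBundle],
    organ_map: BiosampleOrganMap,
) -> dict[str, OrganBundle]:
    """Union each organ's member-biosample bundles; report scoreable count."""
    out: dict[str, OrganBundle] = {}
    for organ in sorted(organ_map.organs()):
        members = [b for b in organ_map.biosamples_for(organ) if b in bundles]
        if not members:
            log.warning("organ %s has no biosample with annotation data", organ)
            continue
        merged = union_bundles([bundles[b] for b in members], name=organ)
        merged.biosample = organ
        out[organ] = OrganBundle(organ, merged, tuple(members))
    n_scoreable = sum(1 for ob in out.values() if ob.scoreable)
    log.info("organ bundles: %d of %d organs scoreable", n_scoreable, len(out))
    return out


def ld_expand(
    snv_ids: Sequence[str] | set[str],
    ld_table: pd.DataFrame,
    r2_threshold: float,
) -> set[str]:
    """Single-hop LD expansion of an SNV id set.

    The pair table (snp_a, snp_b, r2) is closed symmetrically on read.
    Partners with r2 >= threshold of any input SNV are added; no
    transitive hops.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError(f"r2 threshold must be in (0, 1], got {r2_threshold}")
    base = set(snv_ids)
    if ld_table.empty:
        return base
    keep = ld_table["r2"].to_numpy(dtype=float) >= r2_threshold
    a = ld_table["snp_a"].to_numpy()[keep]
    b = ld_table["snp_b"].to_numpy()[keep]
    partners = set(b[np.isin(a, list(base))]) | set(a[np.isin(b, list(base))])
    return base | partners


def organ_score_table(
    variants: Sequence[Variant],
    generic_results: VariantFunctionResults,
    ensemble: TissueEnsemble,
    generic_bundle: AnnotationBundle,
    organ_bundles: Mapping[str, OrganBundle],
    deepsea: Mapping[str, float] | None = None,
) -> ScoreTable:
    """Organ-specific scores for every scoreable organ.

    Variants off chromosomes 1-22/X are dropped with a log message;
    unscoreable organs (no histone or DNase data) raise by name so silent
    zero-score organs cannot leak into downstream enrichment.
    """
    eligible = [v for v in variants if v.chrom in ORGAN_SCORING_CHROMS]
    dropped = len(variants) - len(eligible)
    if dropped:
        log.info("organ scoring: dropped %d variant(s) off chr1-22/X", dropped)
    bad = [name for name, ob in organ_bundles.items() if not ob.scoreable]
    if bad:
        raise ValueError(
            f"organ(s) without histone+DNase data cannot be scored: {sorted(bad)}"
        )
    bundles = {name: ob.bundle for name, ob in organ_bundles.items()}
    return score_variants(
        eligible, generic_results, ensemble, generic_bundle, bundles, deepsea
    )


def organ_score(
    v: Variant,
    generic_results: VariantFunctionResults,
    ensemble: TissueEnsemble,
    generic_bundle: AnnotationBundle,
    organ_bundle: OrganBundle,
    deepsea_score: float | None = None,
) -> float:
    """Single-variant organ-specific score S = G * T(union features)."""
    deepsea = None if deepsea_score is None else {v.key: deepsea_score}
    table = organ_score_table(
        [v], generic_results, ensemble, generic_bundle,
        {organ_bundle.organ: organ_bundle}, deepsea,
    )
    return float(table.frame[f"{organ_bundle.organ}_score"].iloc[0])


class SignificanceBackground:
    """Sorted organ-score background used by the significance transform."""

    def __init__(self, scores: Sequence[float]) -> None:
        arr = np.sort(np.asarray(scores, dtype=float))
        if arr.size == 0:
            raise ValueError("significance background must be non-empty")
        self.scores = arr

    def __len__(self) -> int:
        return self.scores.size


def significance(score: float, background: SignificanceBackground) -> float:
    """-log10 of the background fraction with a strictly greater score.

    The fraction is floored at 1/(N+1) so a query above the whole
    background maps to log10(N+1) rather than infinity.
    """
    N = len(background)
    greater = N - int(np.searchsorted(background.scores, score, side="right"))
    portion = max(greater / N, 1.0 / (N + 1))
    return float(-np.log10(portion))


def significance_table(
    scores: ScoreTable,
    backgrounds: Mapping[str, SignificanceBackground],
) -> pd.DataFrame:
    """Long-format frame: variant, organ, score, significance."""
    rows = []
    for organ in scores.tissues:
        bg = backgrounds.get(organ)
        if bg is None:
            log.warning("no significance background for organ %s; skipped", organ)
            continue
        col = scores.frame[f"{organ}_score"]
        for key, s in col.items():
            rows.append((key, organ, float(s), significance(float(s), bg)))
    return pd.DataFrame(rows, columns=["variant", "organ", "score", "significance"])
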