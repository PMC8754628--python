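"""End-to-end composition of the scoring stages.

These helpers wire the synthetic generators, the two forest stages, organ
aggregation and the enrichment engine into the complete workflow, so the
command-line interface, the test suite and reproduction scripts all run
the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, TraitSet, eligible_traits, run_enrichment
from .features import AnnotationBundle, generic_feature_matrix, union_bundles
from .genomic import Variant
from .models import (
    ScoreTable,
    TissueEnsemble,
    TissueFunctionModel,
    VariantFunctionModel,
    VariantFunctionResults,
    score_variants,
)
from .organs import OrganBundle, build_organ_bundles, organ_score_table
from .simulate import (
    CellLineSim,
    GwasSim,
    SimulatedAnnotations,
    SimulationConfig,
    simulate_annotations,
    simulate_cell_lines,
    simulate_gwas,
    simulate_training_variants,
)


def train_generic_from_simulation(
    config: SimulationConfig,
    annotations: SimulatedAnnotations | None = None,
    n_trees: int = 500,
) -> tuple[VariantFunctionResults, AnnotationBundle, "np.ndarray", list[Variant]]:
    """Simulate training variants and fit the generic stage.

    Returns the fitted results, the pooled (all-biosample) bundle used for
    generic feature extraction, the truth labels and the variants.
    """
    ann = annotations or simulate_annotations(config)
    training = simulate_training_variants(config, ann)
    bundle = union_bundles(list(ann.bundles.values()))
    bundle.eqtl_ids |= training.eqtl_ids
    X = generic_feature_matrix(training.variants, bundle)
    model = VariantFunctionModel(X, training.labels)
    results = model.fit(n_trees=n_trees, seed=config.seed)
    return results, bundle, training.labels, training.variants


def train_ensemble_from_simulation(
    config: SimulationConfig,
    n_trees: int = 500,
    cells: CellLineSim | None = None,
) -> tuple[TissueEnsemble, CellLineSim]:
    """Simulate six cell lines and fit the averaged tissue ensemble."""
    cells = cells or simulate_cell_lines(config)
    members = []
    for line in config.cell_lines:
        model = TissueFunctionModel.from_cell_line(
            cells.asb_by_cell_line, line, cells.annotations.bundles
        )
        members.append(model.fit(n_trees=n_trees, seed=config.seed, holdout_fraction=0.0))
    return TissueEnsemble(members), cells


def planted_cell_line_recovery(
    config: SimulationConfig,
    n_trees: int = 500,
) -> tuple[float, ScoreTable, CellLineSim]:
    """Score planted per-cell-line ASB variants across all six cell lines.

    Both stages are trained inside the cell-line annotation universe: the
    generic stage on planted training variants over the union of the six
    bundles, the tissue stage on the per-line ASB sets.  Returns the
    fraction of ASB variants whose top tissue-specific score falls in
    their planted (functional) cell line, plus the full score table.
    """
    cells = simulate_cell_lines(config)
    ensemble, _ = train_ensemble_from_simulation(config, n_trees, cells=cells)
    training = simulate_training_variants(config, cells.annotations, stream="cells/training")
    bundle = union_bundles(list(cells.annotations.bundles.values()))
    bundle.eqtl_ids |= training.eqtl_ids
    X = generic_feature_matrix(training.variants, bundle)
    generic_results = VariantFunctionModel(X, training.labels).fit(
        n_trees=n_trees, seed=config.seed
    )
    variants = [v for line in config.cell_lines for v in cells.asb_by_cell_line[line]]
    planted_line = {
        v.key: line for line in config.cell_lines for v in cells.asb_by_cell_line[line]
    }
    table = score_variants(
        variants, generic_results, ensemble, bundle, cells.annotations.bundles
    )
    scores = table.tissue_scores()
    top = scores.idxmax(axis=1)
    frac = float(np.mean([top[k] == planted_line[k] for k in scores.index]))
    return frac, table, cells


@dataclass
class OrganScoringRun:
    """Everything needed to score variants at organ level."""

    generic_results: VariantFunctionResults
    ensemble: TissueEnsemble
    generic_bundle: AnnotationBundle
    organ_bundles: dict[str, OrganBundle]
    annotations: SimulatedAnnotations


def build_organ_scoring_run(
    config: SimulationConfig,
    n_trees: int = 500,
) -> OrganScoringRun:
    """Train both stages on simulated data and build the organ bundles."""
    ann = simulate_annotations(config)
    generic_results, bundle, _, _ = train_generic_from_simulation(config, ann, n_trees)
    ensemble, _ = train_ensemble_from_simulation(config, n_trees)
    organ_bundles = build_organ_bundles(ann.bundles, ann.organ_map)
    return OrganScoringRun(generic_results, ensemble, bundle, organ_bundles, ann)


def organ_scores_frame(run: OrganScoringRun, gwas: GwasSim) -> tuple[pd.DataFrame, ScoreTable]:
    """Score every simulated SNV per organ; frame is keyed for enrichment.

    Returns (organ_scores, score_table): the frame is indexed by variant
    id with columns chrom, pos and one column per organ.
    """
    variants = gwas.variants()
    table = organ_score_table(
        variants, run.generic_results, run.ensemble, run.generic_bundle, run.organ_bundles
    )
    frame = pd.DataFrame(index=[v.key for v in variants])
    pos = gwas.positions.set_index("variant_id")
    frame["chrom"] = pos["chrom"]
    frame["pos"] = pos["pos"].astype(int)
    for organ in table.tissues:
        frame[organ] = table.frame[f"{organ}_score"]
    return frame, table


def candidate_locus_experiment(
    config: SimulationConfig,
    organ: str = "liver",
    n_candidates: int = 20,
    n_trees: int = 500,
    run: OrganScoringRun | None = None,
) -> tuple[pd.DataFrame, str]:
    """Rank one planted organ-functional variant among background candidates.

    Plants a single variant inside the target organ's active regions and
    ``n_candidates - 1`` candidates in inactive background, scores all of
    them per organ, and converts scores to significance against the
    LD-expanded GWAS-catalog background.  Returns the long-format
    significance table and the planted variant's key.
    """
    from .organs import SignificanceBackground, ld_expand, significance_table
    from .simulate import substream, _random_alleles

    run = run or build_organ_scoring_run(config, n_trees)
    gwas = simulate_gwas(config, run.annotations)
    scores, _ = organ_scores_frame(run, gwas)
    expanded = ld_expand(set(gwas.catalog["variant_id"]), gwas.ld_table, 0.6)
    backgrounds = {
        o: SignificanceBackground(scores.loc[scores.index.isin(expanded), o])
        for o in run.organ_bundles
    }

    rng = substream(config.seed, "candidates")
    regions = [
        iv
        for b in run.annotations.organ_map.biosamples_for(organ)
        for iv in run.annotations.active_regions[b]
    ]
    reg = regions[int(rng.integers(len(regions)))]
    ref, alt = _random_alleles(rng)
    planted = Variant(
        reg.chrom, int(rng.integers(reg.start + 1, reg.end + 1)), ref, alt, "planted_candidate"
    )
    active_all = run.annotations.all_active_index()
    candidates = [planted]
    chrom_names = sorted(config.chroms)
    while len(candidates) < n_candidates:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(1, config.chroms[chrom] + 1))
        ref, alt = _random_alleles(rng)
        v = Variant(chrom, pos, ref, alt, f"candidate_{len(candidates)}")
        if not active_all.contains_variant(v):
            candidates.append(v)
    table = organ_score_table(
        candidates, run.generic_results, run.ensemble, run.generic_bundle, run.organ_bundles
    )
    return significance_table(table, backgrounds), planted.key


def enrichment_from_simulation(
    config: SimulationConfig,
    iterations: int = 100,
    apply_trait_filter: bool = False,
    n_trees: int = 500,
    run: OrganScoringRun | None = None,
) -> tuple[EnrichmentResult, GwasSim, OrganScoringRun]:
    """Full trait-organ enrichment on a simulated catalog.

    With ``apply_trait_filter`` the eligibility rule (>= 20 SNVs, >= 5%
    high generic score among LD-expanded members) gates the traits;
    otherwise every catalog trait except the background pool is tested —
    the mode used for null-calibration runs, where eligibility would
    remove exactly the traits under study.
    """
    run = run or build_organ_scoring_run(config, n_trees)
    gwas = simulate_gwas(config, run.annotations)
    scores, table = organ_scores_frame(run, gwas)
    catalog = gwas.catalog[gwas.catalog["trait"] != "background"]
    if apply_trait_filter:
        generic = table.frame["generic"].to_dict()
        traits = eligible_traits(catalog, gwas.ld_table, generic)
    else:
        traits = [
            TraitSet(t, tuple(sorted(set(g["variant_id"]))))
            for t, g in catalog.groupby("trait")
        ]
    result = run_enrichment(
        traits,
        gwas.catalog,
        gwas.ld_table,
        scores,
        iterations=iterations,
        seed=config.seed,
    )
    return result, gwas, run
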