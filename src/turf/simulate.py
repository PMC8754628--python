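"""Seeded synthetic-data generators with planted, recoverable effects.

Every input the pipeline consumes can be generated here: per-biosample
annotation bundles with planted active regions, allelic read-count tables
with planted imbalanced sites, training variants enriched for functional
annotations, and a GWAS catalog whose planted traits sit preferentially in
one organ's active regions.  The generators emulate the *structure* the
scoring method assumes (positives enriched in annotations, allelic
imbalance at heterozygous sites, trait SNVs concentrated in one organ) —
not the length or LD-decay distributions of real data.

All randomness flows from a single seed through named sub-streams
(:func:`substream`), so adding a generator never perturbs the outputs of
existing ones, and the same config produces byte-identical files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .asb import AllelicSite
from .features import TISSUE_MARKS, AnnotationBundle
from .genomic import (
    BiosampleOrganMap,
    GenomicInterval,
    IntervalIndex,
    SignalTrack,
    Variant,
    write_bed,
    write_bedgraph,
    write_organ_map,
    write_variants,
)

_BASES = np.array(list("ACGT"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named sub-stream of the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the conditions the package's own calibration and recovery
    checks run under: 2 000 training variants at a 4:1 annotation-enrichment
    odds for positives, 2 000 allelic sites with 200 planted at a 0.9
    allelic ratio and ~40x read depth, and a GWAS catalog with one trait
    planted into one organ.
    """

    seed: int
    # genome
    n_chroms: int = 8
    chrom_length: int = 4_000_000
    with_sequence: bool = False
    # annotations
    organs: tuple[str, ...] = ("liver", "heart", "brain", "lung")
    biosamples_per_organ: int = 2
    regions_per_biosample: int = 40
    region_width: int = 2_000
    background_peak_density: float = 5e-6  # peaks per bp per assay
    peak_width: int = 300
    assay_active_prob: float = 0.9
    tf_names: tuple[str, ...] = ("CTCF", "FOXA1")
    # training variants
    n_variants: int = 2_000
    positive_fraction: float = 0.5
    feature_enrichment_odds: float = 4.0
    eqtl_rate_negative: float = 0.05
    # allele-specific binding
    asb_n_sites: int = 2_000
    asb_n_planted: int = 200
    asb_rho: float = 0.0
    asb_effect_ratio: float = 0.9
    asb_mean_depth: int = 40
    # cell-line (tissue-model) simulation
    cell_lines: tuple[str, ...] = ("GM12878", "HepG2", "A549", "K562", "MCF7", "H1hESC")
    asb_per_cell_line: int = 120
    # GWAS
    gwas_n_snvs: int = 400
    gwas_trait_size: int = 30
    gwas_n_null_traits: int = 2
    planted_traits: dict = field(default_factory=lambda: {"planted_trait": "liver"})
    ld_block_size: int = 2
    ld_within_r2: float = 0.9

    def __post_init__(self) -> None:
        for p in (
            self.positive_fraction,
            self.assay_active_prob,
            self.asb_effect_ratio,
            self.eqtl_rate_negative,
            self.ld_within_r2,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability parameter out of [0, 1]: {p}")
        if not 0.0 <= self.asb_rho < 1.0:
            raise ValueError("asb_rho must be in [0, 1)")

    @property
    def chroms(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("organs", "tf_names", "cell_lines"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class SimulatedAnnotations:
    """Per-biosample bundles, the organ map and the planted active regions."""

    config: SimulationConfig
    bundles: dict[str, AnnotationBundle]
    organ_map: BiosampleOrganMap
    active_regions: dict[str, list[GenomicInterval]]  # per biosample

    def active_index(self, biosample: str) -> IntervalIndex:
        return IntervalIndex(self.active_regions[biosample])

    def all_active_index(self) -> IntervalIndex:
        return IntervalIndex(iv for ivs in self.active_regions.values() for iv in ivs)


def _draw_intervals(
    rng: np.random.Generator,
    chroms: Mapping[str, int],
    n: int,
    width: int,
    label: str | None = None,
) -> list[GenomicInterval]:
    names = sorted(chroms)
    out = []
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        start = int(rng.integers(0, max(1, chroms[chrom] - width)))
        out.append(GenomicInterval(chrom, start, start + width, label))
    return out


def _peaks_over_regions(
    rng: np.random.Generator,
    regions: Sequence[GenomicInterval],
    chroms: Mapping[str, int],
    active_prob: float,
    background_density: float,
    peak_width: int,
    label: str,
) -> IntervalIndex:
    idx = IntervalIndex()
    for reg in regions:
        if rng.random() < active_prob:
            idx.add(GenomicInterval(reg.chrom, reg.start, reg.end, label))
    genome = sum(chroms.values())
    n_bg = rng.poisson(background_density * genome)
    for iv in _draw_intervals(rng, chroms, int(n_bg), peak_width, label):
        idx.add(iv)
    return idx


def _merge_intervals(regions: Sequence[GenomicInterval]) -> list[tuple[str, int, int]]:
    """Union of possibly-overlapping intervals as sorted disjoint spans."""
    out: list[tuple[str, int, int]] = []
    for iv in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and out[-1][0] == iv.chrom and iv.start <= out[-1][2]:
            out[-1] = (iv.chrom, out[-1][1], max(out[-1][2], iv.end))
        else:
            out.append((iv.chrom, iv.start, iv.end))
    return out


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_annotations(
    config: SimulationConfig,
    biosamples: Sequence[str] | None = None,
    organ_of: Mapping[str, str] | None = None,
    disjoint_regions: bool = False,
    stream: str = "annotations",
) -> SimulatedAnnotations:
    """Generate per-biosample annotation bundles and the biosample-organ map.

    By default each organ contributes ``biosamples_per_organ`` biosamples
    named ``{organ}_bs{i}``; biosamples of one organ share the organ's
    planted active regions.  With ``disjoint_regions`` each biosample gets
    its own non-overlapping region set (used for cell-line simulations
    where recovery requires separable tissues).
    """
    cfg = config
    chroms = cfg.chroms
    if biosamples is None:
        biosamples = [
            f"{organ}_bs{i + 1}"
            for organ in cfg.organs
            for i in range(cfg.biosamples_per_organ)
        ]
        organ_of = {b: b.rsplit("_bs", 1)[0] for b in biosamples}
    elif organ_of is None:
        organ_of = {b: b for b in biosamples}

    region_rng = substream(cfg.seed, f"{stream}/regions")
    active: dict[str, list[GenomicInterval]] = {}
    if disjoint_regions:
        # carve non-overlapping slots so each biosample's regions never touch
        slot = cfg.chrom_length // (len(biosamples) * cfg.regions_per_biosample + 1)
        width = min(cfg.region_width, max(1, slot // 2))
        chrom_names = sorted(chroms)
        k = 0
        for b in biosamples:
            regs = []
            for _ in range(cfg.regions_per_biosample):
                chrom = chrom_names[k % len(chrom_names)]
                base = (k // len(chrom_names)) * slot * len(biosamples)
                start = (base + (k % len(biosamples)) * slot) % (cfg.chrom_length - width)
                regs.append(GenomicInterval(chrom, start, start + width, b))
                k += 1
            active[b] = regs
    else:
        organ_regions = {
            organ: _draw_intervals(
                substream(cfg.seed, f"{stream}/regions/{organ}"),
                chroms,
                cfg.regions_per_biosample,
                cfg.region_width,
                organ,
            )
            for organ in sorted(set(organ_of.values()))
        }
        for b in biosamples:
            active[b] = list(organ_regions[organ_of[b]])

    sequence = None
    if cfg.with_sequence:
        seq_rng = substream(cfg.seed, f"{stream}/sequence")
        sequence = {c: _random_sequence(seq_rng, L) for c, L in sorted(chroms.items())}

    bundles: dict[str, AnnotationBundle] = {}
    for b in biosamples:
        rng = substream(cfg.seed, f"{stream}/bundle/{b}")
        bundle = AnnotationBundle(biosample=b, sequence=sequence)
        for tf in cfg.tf_names:
            bundle.tf_peaks[tf] = _peaks_over_regions(
                rng, active[b], chroms, cfg.assay_active_prob,
                cfg.background_peak_density, cfg.peak_width, tf,
            )
        bundle.dnase_peaks = _peaks_over_regions(
            rng, active[b], chroms, cfg.assay_active_prob,
            cfg.background_peak_density, cfg.peak_width, "DNase",
        )
        bundle.footprints = _peaks_over_regions(
            rng, active[b], chroms, cfg.assay_active_prob * 0.8,
            cfg.background_peak_density / 2, max(20, cfg.peak_width // 10), "footprint",
        )
        for mark in TISSUE_MARKS:
            bundle.histone_peaks[mark] = _peaks_over_regions(
                rng, active[b], chroms, cfg.assay_active_prob,
                cfg.background_peak_density, cfg.peak_width, mark,
            )
        merged = _merge_intervals(active[b])
        chip_steps = [
            (chrom, s, e, float(rng.lognormal(1.5, 0.5))) for chrom, s, e in merged
        ]
        dnase_steps = [
            (chrom, s, e, float(rng.lognormal(1.0, 0.5))) for chrom, s, e in merged
        ]
        bundle.chip_signals = [SignalTrack(chip_steps, dataset=f"{b}_chip", biosample=b)]
        bundle.dnase_signals = [SignalTrack(dnase_steps, dataset=f"{b}_dnase", biosample=b)]
        bundles[b] = bundle

    mapping: dict[str, set[str]] = {}
    for b in biosamples:
        mapping.setdefault(b, set()).add(organ_of[b])
    return SimulatedAnnotations(cfg, bundles, BiosampleOrganMap(mapping), active)


def write_annotations(sim: SimulatedAnnotations, out_dir: str | Path) -> None:
    """Write the bundles to disk as BED / bedGraph / TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_organ_map(sim.organ_map, out / "organ_map.tsv")
    for b, bundle in sorted(sim.bundles.items()):
        bdir = out / b
        bdir.mkdir(exist_ok=True)
        for tf, idx in sorted(bundle.tf_peaks.items()):
            write_bed(sorted(idx, key=lambda iv: (iv.chrom, iv.start)), bdir / f"tf_{tf}.bed")
        write_bed(sorted(bundle.dnase_peaks, key=lambda iv: (iv.chrom, iv.start)), bdir / "dnase_peaks.bed")
        write_bed(sorted(bundle.footprints, key=lambda iv: (iv.chrom, iv.start)), bdir / "dnase_footprints.bed")
        for mark, idx in sorted(bundle.histone_peaks.items()):
            write_bed(sorted(idx, key=lambda iv: (iv.chrom, iv.start)), bdir / f"{mark}.bed")
        for track in bundle.chip_signals + bundle.dnase_signals:
            write_bedgraph(track, bdir / f"{track.dataset}.bedgraph")


# ---------------------------------------------------------------------------
# Training variants
# ---------------------------------------------------------------------------


@dataclass
class TrainingSim:
    """Planted-effect training variants with truth labels."""

    variants: list[Variant]
    labels: np.ndarray  # 1 = planted functional
    eqtl_ids: set[str]


def _random_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(0, 4))
    j = (i + 1 + int(rng.integers(0, 3))) % 4
    return str(_BASES[i]), str(_BASES[j])


def simulate_training_variants(
    config: SimulationConfig,
    annotations: SimulatedAnnotations,
    stream: str = "training",
) -> TrainingSim:
    """Positives planted inside active regions, negatives uniform background.

    Positives therefore hit peaks/footprints/signals at the active-region
    rate while negatives only hit scattered background peaks; eQTL
    membership is assigned at ``feature_enrichment_odds`` : 1 odds for
    positives over negatives.
    """
    cfg = config
    rng = substream(cfg.seed, stream)
    active_all = annotations.all_active_index()
    regions = [iv for ivs in annotations.active_regions.values() for iv in ivs]
    n_pos = int(round(cfg.n_variants * cfg.positive_fraction))
    n_neg = cfg.n_variants - n_pos
    chrom_names = sorted(cfg.chroms)

    seen: set[tuple[str, int]] = set()
    variants: list[Variant] = []
    labels: list[int] = []
    while sum(labels) < n_pos:
        reg = regions[int(rng.integers(len(regions)))]
        pos = int(rng.integers(reg.start + 1, reg.end + 1))  # 1-based inside region
        if (reg.chrom, pos) in seen:
            continue
        seen.add((reg.chrom, pos))
        ref, alt = _random_alleles(rng)
        variants.append(Variant(reg.chrom, pos, ref, alt, f"sim_pos_{len(variants)}"))
        labels.append(1)
    while len(labels) - n_pos < n_neg:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(1, cfg.chroms[chrom] + 1))
        if (chrom, pos) in seen:
            continue
        ref, alt = _random_alleles(rng)
        v = Variant(chrom, pos, ref, alt, f"sim_neg_{len(variants)}")
        if active_all.contains_variant(v):
            continue
        seen.add((chrom, pos))
        variants.append(v)
        labels.append(0)

    eq_pos = min(1.0, cfg.eqtl_rate_negative * cfg.feature_enrichment_odds)
    eqtl_ids = {
        v.key
        for v, lab in zip(variants, labels)
        if rng.random() < (eq_pos if lab else cfg.eqtl_rate_negative)
    }
    return TrainingSim(variants, np.asarray(labels), eqtl_ids)


# ---------------------------------------------------------------------------
# Allelic counts
# ---------------------------------------------------------------------------


def simulate_asb_counts(
    config: SimulationConfig,
    stream: str = "asb",
) -> tuple[list[AllelicSite], pd.DataFrame]:
    """Allelic read-count sites: beta-binomial nulls plus planted imbalance.

    Null sites draw ref counts from BetaBinomial(n, 0.5, rho); planted
    sites from Binomial(n, effect_ratio) with a random allele direction.
    Depths are ``6 + Poisson(mean_depth - 6)``.  Returns the sites and a
    truth frame (variant key, planted flag).
    """
    cfg = config
    rng = substream(cfg.seed, stream)
    chrom_names = sorted(cfg.chroms)
    sites: list[AllelicSite] = []
    truth_rows = []
    a = None if cfg.asb_rho == 0 else (1.0 / cfg.asb_rho - 1.0) / 2.0
    for i in range(cfg.asb_n_sites):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(1, cfg.chroms[chrom] + 1))
        ref, alt = _random_alleles(rng)
        n = 6 + int(rng.poisson(max(0, cfg.asb_mean_depth - 6)))
        planted = i < cfg.asb_n_planted
        if planted:
            ratio = cfg.asb_effect_ratio if rng.random() < 0.5 else 1.0 - cfg.asb_effect_ratio
            k = int(rng.binomial(n, ratio))
        elif a is None:
            k = int(rng.binomial(n, 0.5))
        else:
            p = rng.beta(a, a)
            k = int(rng.binomial(n, p))
        k = min(max(k, 0), n)
        if k == 0:
            k = 1  # a het site needs at least one read per allele to be listed
        if k == n:
            k = n - 1
        v = Variant(chrom, pos, ref, alt, f"asb_site_{i}")
        sites.append(AllelicSite(v, dataset=f"ds{i % 8}", ref_count=k, alt_count=n - k, in_peak=True))
        truth_rows.append({"variant": v.key, "planted": planted})
    return sites, pd.DataFrame(truth_rows)


def write_asb_counts(sites: Sequence[AllelicSite], truth: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        (s.variant.chrom, s.variant.pos, s.variant.ref, s.variant.alt,
         s.dataset, s.ref_count, s.alt_count)
        for s in sites
    ]
    pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "dataset", "ref_count", "alt_count"]
    ).to_csv(out / "allelic_counts.tsv", sep="\t", index=False)
    truth.to_csv(out / "asb_truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cell-line (tissue model) simulation
# ---------------------------------------------------------------------------


@dataclass
class CellLineSim:
    """Six cell-line bundles with per-line planted ASB variants."""

    annotations: SimulatedAnnotations
    asb_by_cell_line: dict[str, list[Variant]]


def simulate_cell_lines(config: SimulationConfig, stream: str = "cells") -> CellLineSim:
    """Disjoint-region cell-line bundles plus per-line planted ASB SNVs.

    Each cell line's ASB variants are placed inside that line's own active
    regions, so a variant's tissue features are on in its functional line
    and off elsewhere — the structure behind per-line score recovery.
    """
    cfg = config
    ann = simulate_annotations(
        cfg,
        biosamples=list(cfg.cell_lines),
        organ_of={c: c for c in cfg.cell_lines},
        disjoint_regions=True,
        stream=f"{stream}/annotations",
    )
    rng = substream(cfg.seed, f"{stream}/variants")
    asb: dict[str, list[Variant]] = {}
    seen: set[tuple[str, int]] = set()
    for line in cfg.cell_lines:
        regions = ann.active_regions[line]
        vs: list[Variant] = []
        while len(vs) < cfg.asb_per_cell_line:
            reg = regions[int(rng.integers(len(regions)))]
            pos = int(rng.integers(reg.start + 1, reg.end + 1))
            if (reg.chrom, pos) in seen:
                continue
            seen.add((reg.chrom, pos))
            ref, alt = _random_alleles(rng)
            vs.append(Variant(reg.chrom, pos, ref, alt, f"asb_{line}_{len(vs)}"))
        asb[line] = vs
    return CellLineSim(ann, asb)


# ---------------------------------------------------------------------------
# GWAS catalog
# ---------------------------------------------------------------------------


@dataclass
class GwasSim:
    """Synthetic GWAS catalog with LD blocks and a planted trait-organ map."""

    catalog: pd.DataFrame  # variant_id, chrom, pos, trait
    ld_table: pd.DataFrame  # snp_a, snp_b, r2
    positions: pd.DataFrame  # variant_id, chrom, pos, ref, alt (incl. LD partners)
    truth: dict[str, str]  # trait -> planted organ ("" for null traits)

    def variants(self) -> list[Variant]:
        return [
            Variant(r.chrom, int(r.pos), r.ref, r.alt, r.variant_id)
            for r in self.positions.itertuples()
        ]


def simulate_gwas(
    config: SimulationConfig,
    annotations: SimulatedAnnotations,
    stream: str = "gwas",
) -> GwasSim:
    """Catalog + LD table with planted trait-organ structure.

    Planted traits draw their SNVs from the planted organ's active
    regions; null traits and the unassigned background draw uniformly.
    Each catalog SNV heads an LD block of ``ld_block_size`` members at
    ``ld_within_r2``; partners sit within 5 kb of the head SNV (inheriting
    its active-region context) and appear in ``positions`` but not in the
    catalog.
    """
    cfg = config
    rng = substream(cfg.seed, stream)
    chrom_names = sorted(cfg.chroms)
    seen: set[tuple[str, int]] = set()
    pos_rows = []
    cat_rows = []
    ld_rows = []
    truth: dict[str, str] = {}

    def _uniform_site() -> tuple[str, int]:
        while True:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            p = int(rng.integers(1, cfg.chroms[chrom] + 1))
            if (chrom, p) not in seen:
                seen.add((chrom, p))
                return chrom, p

    def _active_site(organ: str) -> tuple[str, int]:
        regions = [
            iv
            for b in annotations.organ_map.biosamples_for(organ)
            for iv in annotations.active_regions[b]
        ]
        while True:
            reg = regions[int(rng.integers(len(regions)))]
            p = int(rng.integers(reg.start + 1, reg.end + 1))
            if (reg.chrom, p) not in seen:
                seen.add((reg.chrom, p))
                return reg.chrom, p

    def _add_snv(vid: str, chrom: str, p: int, trait: str | None) -> None:
        ref, alt = _random_alleles(rng)
        pos_rows.append((vid, chrom, p, ref, alt))
        if trait is not None:
            cat_rows.append((vid, chrom, p, trait))
        for j in range(cfg.ld_block_size - 1):
            while True:
                q = p + int(rng.integers(-5000, 5001))
                if q >= 1 and (chrom, q) not in seen:
                    seen.add((chrom, q))
                    break
            pid = f"{vid}_ld{j + 1}"
            r2, a2 = _random_alleles(rng)
            pos_rows.append((pid, chrom, q, r2, a2))
            ld_rows.append((vid, pid, cfg.ld_within_r2))

    k = 0
    for trait, organ in sorted(cfg.planted_traits.items()):
        truth[trait] = organ
        for _ in range(cfg.gwas_trait_size):
            chrom, p = _active_site(organ)
            _add_snv(f"rs{k}", chrom, p, trait)
            k += 1
    for t in range(cfg.gwas_n_null_traits):
        trait = f"null_trait_{t + 1}"
        truth[trait] = ""
        for _ in range(cfg.gwas_trait_size):
            chrom, p = _uniform_site()
            _add_snv(f"rs{k}", chrom, p, trait)
            k += 1
    n_bg = max(0, cfg.gwas_n_snvs - len(cat_rows))
    for _ in range(n_bg):
        chrom, p = _uniform_site()
        _add_snv(f"rs{k}", chrom, p, "background")
        k += 1

    catalog = pd.DataFrame(cat_rows, columns=["variant_id", "chrom", "pos", "trait"])
    ld = pd.DataFrame(ld_rows, columns=["snp_a", "snp_b", "r2"])
    positions = pd.DataFrame(pos_rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    return GwasSim(catalog, ld, positions, truth)


def write_gwas(sim: GwasSim, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.catalog.to_csv(out / "gwas_catalog.tsv", sep="\t", index=False)
    sim.ld_table.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
    sim.positions.to_csv(out / "snv_positions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t, o) for t, o in sorted(sim.truth.items())], columns=["trait", "planted_organ"]
    ).to_csv(out / "trait_truth.tsv", sep="\t", index=False)
    write_variants(sim.variants(), out / "snvs.vcf", format="vcf")
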