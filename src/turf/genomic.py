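"""Domain types and file I/O for the variant-scoring pipeline.

Coordinate conventions
----------------------
Variants are 1-based (VCF convention); intervals are 0-based half-open
(BED convention).  The single place where the two meet is
:meth:`IntervalIndex.contains_variant` / :meth:`SignalTrack.value_at`,
which convert ``pos`` to ``pos - 1`` before querying.

Chromosome names are normalized to the ``chr``-prefixed dialect on read,
so ENCODE-style (``chr1``) and dbSNP-style (``1``) inputs mix freely.
Strand is ignored throughout; motif scanning evaluates both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Chromosomes eligible for organ-specific scoring (autosomes + X).
ORGAN_SCORING_CHROMS = frozenset({f"chr{i}" for i in range(1, 23)} | {"chrX"})


def normalize_chrom(chrom: str) -> str:
    """Return the ``chr``-prefixed form of a chromosome name."""
    chrom = chrom.strip()
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


@dataclass(frozen=True, order=True)
class Variant:
    """A single-nucleotide variant, the unit being scored.

    ``pos`` is 1-based.  ``ref`` and ``alt`` are single upper-case bases
    and must differ.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref not in _BASE_INDEX or self.alt not in _BASE_INDEX:
            raise ValueError(f"alleles must be one of A/C/G/T, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref})")

    @property
    def key(self) -> str:
        """Stable identifier: the rsID when present, else ``chrom:pos:ref:alt``."""
        return self.id if self.id else f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` in 0-based coordinates."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.start < self.end:
            raise ValueError(f"interval start must be < end, got [{self.start}, {self.end})")


class IntervalIndex:
    """Chromosome-partitioned interval tree supporting point overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def __iter__(self) -> Iterator[GenomicInterval]:
        for tree in self._trees.values():
            for node in tree:
                yield node.data

    def contains_variant(self, v: Variant) -> bool:
        """True iff the variant's 0-based position falls inside any interval."""
        tree = self._trees.get(v.chrom)
        return bool(tree is not None and tree[v.pos - 1])

    def hits(self, v: Variant) -> list[GenomicInterval]:
        tree = self._trees.get(v.chrom)
        if tree is None:
            return []
        return [node.data for node in tree[v.pos - 1]]

    def nearest_gap(self, chrom: str, pos: int) -> int | None:
        """Distance from a 1-based position to the closest interval edge on ``chrom``."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None or len(tree) == 0:
            return None
        p = pos - 1
        if tree[p]:
            return 0
        return min(
            min(abs(p - node.begin), abs(p - (node.end - 1))) for node in tree
        )


def overlaps(v: Variant, intervals: IntervalIndex) -> bool:
    """Binary overlap of a variant with an interval set (half-open, 0-based)."""
    return intervals.contains_variant(v)


class SignalTrack:
    """Continuous signal over non-overlapping steps (bedGraph/wig semantics).

    Stores per-chromosome sorted arrays of (start, end, value); lookups use
    binary search.  Positions without coverage read as ``no coverage`` and
    the feature layer fills those with 0.0.
    """

    def __init__(
        self,
        steps: Iterable[tuple[str, int, int, float]],
        dataset: str = "",
        biosample: str = "",
    ) -> None:
        self.dataset = dataset
        self.biosample = biosample
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in steps:
            if not np.isfinite(value):
                raise ValueError(f"non-finite signal value {value!r} on {chrom}:{start}")
            per_chrom.setdefault(normalize_chrom(chrom), []).append((start, end, float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping steps in signal track on {chrom}")
            values = np.array([r[2] for r in rows], dtype=float)
            self._data[chrom] = (starts, ends, values)

    def value_at(self, v: Variant) -> float | None:
        """Signal value covering the variant, or None when uncovered."""
        entry = self._data.get(v.chrom)
        if entry is None:
            return None
        starts, ends, values = entry
        p = v.pos - 1
        i = int(np.searchsorted(starts, p, side="right")) - 1
        if i >= 0 and p < ends[i]:
            return float(values[i])
        return None

    def steps(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in sorted(self._data):
            starts, ends, values = self._data[chrom]
            for s, e, val in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(val)


def signal_at(v: Variant, tracks: Sequence[SignalTrack]) -> list[float]:
    """One value per track at the variant position; 0.0 where uncovered."""
    out = []
    for t in tracks:
        val = t.value_at(v)
        out.append(0.0 if val is None else val)
    return out


class Pwm:
    """Position frequency matrix with pseudocount smoothing.

    ``matrix`` rows are motif positions, columns A,C,G,T; rows sum to 1
    after adding ``pseudocount`` to each raw frequency and renormalizing.
    ``tf`` links the motif to a transcription factor name for matched-motif
    features; it defaults to the motif id.
    """

    def __init__(
        self,
        motif_id: str,
        matrix: np.ndarray | Sequence[Sequence[float]],
        pseudocount: float = 1e-3,
        tf: str | None = None,
    ) -> None:
        raw = np.asarray(matrix, dtype=float)
        if raw.ndim != 2 or raw.shape[1] != 4 or raw.shape[0] < 1:
            raise ValueError("PWM matrix must be (length >= 1) x 4")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        smoothed = raw + pseudocount
        self.matrix = smoothed / smoothed.sum(axis=1, keepdims=True)
        assert np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9)
        self.id = motif_id
        self.tf = tf if tf is not None else motif_id
        self.pseudocount = pseudocount

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits: ``2 + sum_b f log2 f`` (max 2 for DNA)."""
        f = self.matrix
        return 2.0 + np.sum(f * np.log2(f), axis=1)

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        return np.log2(self.matrix / background)


@dataclass
class BiosampleOrganMap:
    """Mapping from biosample id to the organ names it belongs to."""

    mapping: dict[str, set[str]]

    def organs(self) -> set[str]:
        out: set[str] = set()
        for orgs in self.mapping.values():
            out |= orgs
        return out

    def biosamples_for(self, organ: str) -> list[str]:
        return sorted(b for b, orgs in self.mapping.items() if organ in orgs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_variants(path: str | Path, format: str = "tsv") -> list[Variant]:
    """Read SNVs from a VCF or a 4-column TSV (chrom, pos, ref, alt[, id]).

    Multi-allelic VCF records are split into one variant per alternate
    allele; non-SNV records (indels, symbolic alleles) are skipped and the
    skip count logged.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_variant_tsv(path)
    raise ValueError(f"unknown variant format {format!r} (expected 'vcf' or 'tsv')")


def _read_vcf(path: Path) -> list[Variant]:
    from cyvcf2 import VCF

    out: list[Variant] = []
    skipped = 0
    try:
        reader = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"failed to open VCF {path}: {exc}") from exc
    for i, rec in enumerate(reader):
        try:
            ref = rec.REF.upper()
            for alt in rec.ALT:
                alt = alt.upper()
                if len(ref) == 1 and len(alt) == 1 and ref in _BASE_INDEX and alt in _BASE_INDEX:
                    out.append(Variant(rec.CHROM, rec.POS, ref, alt, rec.ID or None))
                else:
                    skipped += 1
        except Exception as exc:
            raise ValueError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    if skipped:
        log.info("read_variants: skipped %d non-SNV allele(s) in %s", skipped, path)
    return out


def _read_variant_tsv(path: Path) -> list[Variant]:
    out: list[Variant] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4:
            raise ValueError(f"{path}: variant TSV needs >= 4 tab-separated columns, line 1")
        has_id = len(header) >= 5
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: malformed line {lineno}: {line.rstrip()!r}")
            chrom, pos_s, ref, alt = fields[:4]
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASE_INDEX or alt not in _BASE_INDEX:
                skipped += 1
                continue
            try:
                pos = int(pos_s)
                vid = fields[4] if has_id and len(fields) > 4 and fields[4] else None
                out.append(Variant(chrom, pos, ref, alt, vid))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    if skipped:
        log.info("read_variants: skipped %d non-SNV row(s) in %s", skipped, path)
    return out


def write_variants(variants: Sequence[Variant], path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("chrom\tpos\tref\talt\tid\n")
            for v in variants:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.id or ''}\n")
    elif format == "vcf":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            chroms = sorted({v.chrom for v in variants})
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in variants:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\n")
    else:
        raise ValueError(f"unknown variant format {format!r}")


def read_bed(path: str | Path, label: str | None = None) -> list[GenomicInterval]:
    """Read BED3+ intervals; column 4 (name) becomes the label when present."""
    out: list[GenomicInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            try:
                name = fields[3] if len(fields) > 3 and fields[3] != "." else label
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\n")


def read_bedgraph(path: str | Path, dataset: str = "", biosample: str = "") -> SignalTrack:
    steps: list[tuple[str, int, int, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}")
            steps.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return SignalTrack(steps, dataset=dataset or Path(path).stem, biosample=biosample)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, value in track.steps():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_wig(path: str | Path, dataset: str = "", biosample: str = "") -> SignalTrack:
    """Read fixedStep / variableStep wiggle into a SignalTrack."""
    steps: list[tuple[str, int, int, float]] = []
    mode = None
    chrom = ""
    span = 1
    start = step = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode, chrom = "fixed", kv["chrom"]
                start = int(kv["start"]) - 1  # wig is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
            elif line.startswith("variableStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode, chrom = "variable", kv["chrom"]
                span = int(kv.get("span", 1))
            elif mode == "fixed":
                steps.append((chrom, start, start + span, float(line)))
                start += step
            elif mode == "variable":
                pos_s, val_s = line.split()
                p = int(pos_s) - 1
                steps.append((chrom, p, p + span, float(val_s)))
            else:
                raise ValueError(f"{path}: wig data before declaration line at {lineno}")
    return SignalTrack(steps, dataset=dataset or Path(path).stem, biosample=biosample)


def read_pwms(path: str | Path, format: str = "jaspar", pseudocount: float = 1e-3) -> list[Pwm]:
    """Read motif models via Bio.motifs (JASPAR PFM text or MEME minimal)."""
    from Bio import motifs as bio_motifs

    fmt = {"jaspar": "jaspar", "meme": "minimal"}.get(format)
    if fmt is None:
        raise ValueError(f"unknown motif format {format!r}")
    out: list[Pwm] = []
    with open(path, encoding="utf-8") as fh:
        for m in bio_motifs.parse(fh, fmt):
            counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)], dtype=float)
            totals = counts.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            name = m.name or getattr(m, "matrix_id", None) or f"motif_{len(out)}"
            out.append(Pwm(name, counts / totals, pseudocount=pseudocount))
    return out


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_organ_map(path: str | Path) -> BiosampleOrganMap:
    """TSV with columns ``biosample`` and ``organ`` (one row per pair)."""
    df = _read_table(path, ["biosample", "organ"])
    mapping: dict[str, set[str]] = {}
    for b, o in zip(df["biosample"], df["organ"]):
        mapping.setdefault(b, set()).add(o)
    return BiosampleOrganMap(mapping)


def write_organ_map(m: BiosampleOrganMap, path: str | Path) -> None:
    rows = [(b, o) for b in sorted(m.mapping) for o in sorted(m.mapping[b])]
    pd.DataFrame(rows, columns=["biosample", "organ"]).to_csv(path, sep="\t", index=False)


def read_ld_table(path: str | Path) -> pd.DataFrame:
    """LD pair TSV with columns ``snp_a``, ``snp_b``, ``r2``."""
    df = _read_table(path, ["snp_a", "snp_b", "r2"])
    df["r2"] = df["r2"].astype(float)
    return df


def read_gwas_catalog(path: str | Path) -> pd.DataFrame:
    """GWAS catalog TSV: ``variant_id``, ``chrom``, ``pos``, ``trait``."""
    df = _read_table(path, ["variant_id", "chrom", "pos", "trait"])
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(int)
    return df


def read_allelic_counts(path: str | Path) -> pd.DataFrame:
    """Allelic read-count TSV: chrom, pos, ref, alt, dataset, ref_count, alt_count."""
    df = _read_table(path, ["chrom", "pos", "ref", "alt", "dataset", "ref_count", "alt_count"])
    df["chrom"] = df["chrom"].map(normalize_chrom)
    for c in ("pos", "ref_count", "alt_count"):
        df[c] = df[c].astype(int)
    return df


def read_cnv_table(path: str | Path) -> pd.DataFrame:
    """CNV read-depth TSV: chrom, start, end, ratio (0-based half-open)."""
    df = _read_table(path, ["chrom", "start", "end", "ratio"])
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["ratio"] = df["ratio"].astype(float)
    return df
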