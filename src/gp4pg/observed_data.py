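"""Observed-data pipeline: from a multi-sample VCF to the observed 4jSFS.

The pipeline mirrors a conservative callable-genome workflow for
SFS-based demographic inference: site-level quality filters (depth,
QUAL, PASS, indel flanks, multiallelic exclusion), neutrality masks
(repeats, CNVs, genes with a 20-kb flank, CpG islands), a sliding-window
callable-density screen (10-kb windows, 2500-bp step, >90% density),
polarization of alleles against an ancestral annotation, and grouping of
surviving sites into genomic blocks for the block bootstrap.

Coordinates: VCF positions are 1-based; BED intervals and all internal
interval sets are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_depth: int = 5
    min_qual: float = 20.0
    require_pass: bool = True
    biallelic_only: bool = True
    indel_flank_bp: int = 6
    gene_flank_bp: int = 20_000
    window_bp: int = 10_000
    step_bp: int = 2_500
    min_density: float = 0.90

    def __post_init__(self):
        if self.step_bp > self.window_bp:
            raise ValueError("step must not exceed window")


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    filter_pass: bool
    depth: int | None
    gts: np.ndarray  # (n_samples, 2) allele indices, -1 = missing
    aa: str | None = None

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)

    @property
    def is_snp(self) -> bool:
        return not self.is_indel


def read_vcf(path, aa_field: str = "AA") -> tuple[list[VariantRecord], list[str]]:
    """Load VCF records (plain or bgzipped) with per-sample genotypes."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        depth = v.INFO.get("DP")
        if depth is None:
            try:
                fmt = v.format("DP")
            except KeyError:
                fmt = None
            if fmt is not None:
                d = np.asarray(fmt).ravel()
                d = d[d >= 0]
                depth = int(d.min()) if len(d) else None
        gts = np.array([g[:2] for g in v.genotypes], dtype=int) if samples else np.zeros((0, 2), int)
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=v.QUAL,
                filter_pass=(v.FILTER is None),  # cyvcf2: None means PASS
                depth=int(depth) if depth is not None else None,
                gts=gts,
                aa=v.INFO.get(aa_field),
            )
        )
    return records, samples


# ---- site-level quality filters ---------------------------------------------


def filter_variants(
    records: list[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the site-quality criteria in order; report per-criterion drops.

    Order: minimum depth, minimum QUAL, PASS flag, indel-flank exclusion
    (records within ``indel_flank_bp`` of any indel's affected interval),
    multiallelic exclusion.  Indel records themselves are removed (they
    only contribute flank intervals); records missing a required field
    drop as ``unscorable``.
    """
    config = config or FilterConfig()
    drops = {
        "depth": 0,
        "qual": 0,
        "not_pass": 0,
        "indel_flank": 0,
        "multiallelic": 0,
        "indel_record": 0,
        "unscorable": 0,
    }
    # Affected 0-based half-open intervals of all indels, per chromosome.
    indel_spans: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        if r.is_indel:
            span = max(len(r.ref), 1)
            indel_spans.setdefault(r.chrom, []).append((r.pos - 1, r.pos - 1 + span))

    survivors = []
    f = config.indel_flank_bp
    for r in records:
        if r.depth is None or r.qual is None:
            drops["unscorable"] += 1
            logger.debug("unscorable record %s:%d", r.chrom, r.pos)
            continue
        if r.depth < config.min_depth:
            drops["depth"] += 1
            continue
        if r.qual < config.min_qual:
            drops["qual"] += 1
            continue
        if config.require_pass and not r.filter_pass:
            drops["not_pass"] += 1
            continue
        if r.is_indel:
            drops["indel_record"] += 1
            continue
        p0 = r.pos - 1
        near_indel = any(
            a - f <= p0 < b + f for a, b in indel_spans.get(r.chrom, ())
        )
        if near_indel:
            drops["indel_flank"] += 1
            continue
        if config.biallelic_only and len(r.alts) != 1:
            drops["multiallelic"] += 1
            continue
        survivors.append(r)
    return survivors, drops


# ---- interval sets ----------------------------------------------------------


def read_bed(path) -> dict[str, np.ndarray]:
    """Parse a 3+ column BED into per-chromosome (k, 2) interval arrays."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                a, b = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from e
            if b < a:
                raise ValueError(f"{path}: inverted interval at line {lineno}")
            intervals.setdefault(parts[0], []).append((a, b))
    return {c: merge_intervals(np.array(iv, dtype=int)) for c, iv in intervals.items()}


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent sorted-or-not 0-based half-open intervals."""
    if len(intervals) == 0:
        return np.zeros((0, 2), dtype=int)
    iv = intervals[np.argsort(intervals[:, 0])]
    out = [list(iv[0])]
    for a, b in iv[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return np.array(out, dtype=int)


def _in_intervals(pos0: int, iv: np.ndarray) -> bool:
    if len(iv) == 0:
        return False
    i = np.searchsorted(iv[:, 0], pos0, side="right") - 1
    return i >= 0 and pos0 < iv[i, 1]


@dataclass
class CallableMask:
    """Disjoint sorted 0-based half-open intervals per chromosome."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def contains(self, chrom: str, pos0: int) -> bool:
        return _in_intervals(pos0, self.intervals.get(chrom, np.zeros((0, 2), int)))

    def total_length(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values())
        )

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for a, b in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{a}\t{b}\n")

    @classmethod
    def from_bed(cls, path) -> "CallableMask":
        return cls(intervals=read_bed(path))


def apply_masks(
    records: list[VariantRecord],
    masks: dict[str, "str | Path | dict[str, np.ndarray]"],
    gene_flank_bp: int = 20_000,
    gene_mask_names: tuple[str, ...] = ("genes",),
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Drop records inside any mask; gene masks get a strand-agnostic flank.

    ``masks`` maps a mask name to a BED path or a pre-parsed interval
    dict.  A record at a gene edge + flank is still masked (the flank is
    inclusive of its outer base); one base further it is retained.
    Idempotent: survivors re-masked are unchanged.
    """
    parsed: dict[str, dict[str, np.ndarray]] = {}
    for name, src in masks.items():
        iv = src if isinstance(src, dict) else read_bed(src)
        if name in gene_mask_names and gene_flank_bp:
            iv = {
                c: merge_intervals(
                    np.stack(
                        [np.maximum(arr[:, 0] - gene_flank_bp, 0), arr[:, 1] + gene_flank_bp],
                        axis=1,
                    )
                )
                for c, arr in iv.items()
            }
        parsed[name] = iv

    drops = {name: 0 for name in parsed}
    survivors = []
    for r in records:
        hit = None
        for name, iv in parsed.items():
            if _in_intervals(r.pos - 1, iv.get(r.chrom, np.zeros((0, 2), int))):
                hit = name
                break
        if hit is None:
            survivors.append(r)
        else:
            drops[hit] += 1
    return survivors, drops


def window_density_mask(
    callable_positions: dict[str, np.ndarray],
    window_bp: int = 10_000,
    step_bp: int = 2_500,
    min_density: float = 0.90,
) -> CallableMask:
    """Retain sliding windows whose callable-site density exceeds the cutoff.

    ``callable_positions`` maps chromosome to sorted 1-based positions of
    individually callable bases.  Windows of ``window_bp`` starting every
    ``step_bp`` from 0 are kept when the fraction of callable positions
    inside exceeds ``min_density`` (strictly); overlapping kept windows
    merge into maximal intervals.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, pos in callable_positions.items():
        pos = np.sort(np.asarray(pos))
        if len(pos) == 0:
            continue
        last = int(pos[-1])
        kept = []
        start = 0
        while start < last:
            # 1-based positions in (start, start + window]
            lo = np.searchsorted(pos, start, side="right")
            hi = np.searchsorted(pos, start + window_bp, side="right")
            if (hi - lo) / window_bp > min_density:
                kept.append((start, start + window_bp))
            start += step_bp
        if kept:
            out[chrom] = merge_intervals(np.array(kept, dtype=int))
    return CallableMask(intervals=out)


# ---- polarization -----------------------------------------------------------


def polarize(
    records: list[VariantRecord],
    pops: dict[str, str],
    samples: list[str],
    ancestral_fasta=None,
    aa_field_used: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Orient biallelic SNPs to derived-allele counts per population.

    The ancestral allele comes from each record's AA annotation, falling
    back to an ancestral FASTA lookup.  Sites whose ancestral allele
    matches neither REF nor ALT, or with missing genotypes, are dropped
    and counted.  Returns a frame with chrom, pos and one derived-count
    column per population.
    """
    fasta = None
    if ancestral_fasta is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(ancestral_fasta))
    pop_order = sorted(set(pops.values()))
    sample_idx: dict[str, list[int]] = {p: [] for p in pop_order}
    for i, s in enumerate(samples):
        if s in pops:
            sample_idx[pops[s]].append(i)

    drops = {"ancestral_mismatch": 0, "missing_ancestral": 0, "missing_genotype": 0}
    rows = []
    for r in records:
        if len(r.alts) != 1 or r.is_indel:
            continue
        aa = r.aa if (aa_field_used and r.aa) else None
        if aa is None and fasta is not None:
            aa = str(fasta[r.chrom][r.pos - 1 : r.pos]).upper()
        if not aa or aa in (".", "N", "-"):
            drops["missing_ancestral"] += 1
            continue
        aa = aa.upper()
        if aa == r.ref.upper():
            flip = False
        elif aa == r.alts[0].upper():
            flip = True
        else:
            drops["ancestral_mismatch"] += 1
            continue
        if (r.gts < 0).any():
            drops["missing_genotype"] += 1
            continue
        row = {"chrom": r.chrom, "pos": r.pos}
        for p in pop_order:
            alt = int((r.gts[sample_idx[p]] == 1).sum())
            total = 2 * len(sample_idx[p])
            row[p] = total - alt if flip else alt
        rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "pos"] + pop_order)
    return df, drops


# ---- blocking ---------------------------------------------------------------


def make_blocks(
    sites: pd.DataFrame,
    mask: CallableMask,
    scheme: str = "mask_intervals",
    tile_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Assign each surviving site to a genomic block for the bootstrap.

    ``mask_intervals``: each maximal callable interval is one block.
    ``fixed``: chromosomes are tiled into ``tile_bp`` windows and the
    intersecting mask intervals inherit the tile's id.  Sites outside the
    mask are excluded.
    """
    block_of = {}
    next_id = 0
    for chrom in sorted(mask.intervals):
        for a, b in mask.intervals[chrom]:
            if scheme == "mask_intervals":
                block_of[(chrom, int(a), int(b))] = next_id
                next_id += 1
    out_rows = []
    tile_ids: dict[tuple[str, int], int] = {}
    for row in sites.itertuples(index=False):
        p0 = row.pos - 1
        iv = mask.intervals.get(row.chrom)
        if iv is None or len(iv) == 0:
            continue
        i = np.searchsorted(iv[:, 0], p0, side="right") - 1
        if i < 0 or p0 >= iv[i, 1]:
            continue
        if scheme == "mask_intervals":
            block = block_of[(row.chrom, int(iv[i, 0]), int(iv[i, 1]))]
        elif scheme == "fixed":
            key = (row.chrom, p0 // tile_bp)
            if key not in tile_ids:
                tile_ids[key] = len(tile_ids)
            block = tile_ids[key]
        else:
            raise ValueError(f"unknown blocking scheme {scheme!r}")
        d = row._asdict()
        d["block"] = block
        out_rows.append(d)
    cols = list(sites.columns) + ["block"]
    return pd.DataFrame(out_rows, columns=cols)


# ---- end-to-end convenience --------------------------------------------------


def build_observed(
    vcf_path,
    pops: dict[str, str],
    masks: dict[str, "str | Path"] | None = None,
    ancestral_fasta=None,
    config: FilterConfig | None = None,
    callable_mask: CallableMask | None = None,
    aa_field: str = "AA",
):
    """VCF -> filtered, polarized, blocked site table plus a filter report.

    When no explicit callable mask is given, one is derived from the
    density screen over the positions surviving the quality filters and
    masks.  Returns (site table, report dict).
    """
    config = config or FilterConfig()
    records, samples = read_vcf(vcf_path, aa_field=aa_field)
    kept, drops = filter_variants(records, config)
    mask_drops: dict[str, int] = {}
    if masks:
        kept, mask_drops = apply_masks(kept, masks, config.gene_flank_bp)
    table, pol_drops = polarize(kept, pops, samples, ancestral_fasta, aa_field_used=True)
    if callable_mask is None:
        positions = {
            c: g["pos"].to_numpy() for c, g in table.groupby("chrom", sort=True)
        }
        callable_mask = window_density_mask(
            positions, config.window_bp, config.step_bp, config.min_density
        )
        if not callable_mask.intervals:
            # sparse toy data: fall back to one block per chromosome
            callable_mask = CallableMask(
                intervals={
                    c: np.array([[0, int(p.max())]], dtype=int)
                    for c, p in positions.items()
                    if len(p)
                }
            )
    blocked = make_blocks(table, callable_mask)
    report = {
        "filter_drops": drops,
        "mask_drops": mask_drops,
        "polarization_drops": pol_drops,
        "n_sites": int(len(blocked)),
        "callable_bp": callable_mask.total_length(),
    }
    return blocked, report


__all__ = [
    "FilterConfig",
    "VariantRecord",
    "CallableMask",
    "read_vcf",
    "filter_variants",
    "read_bed",
    "merge_intervals",
    "apply_masks",
    "window_density_mask",
    "polarize",
    "make_blocks",
    "build_observed",
]
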