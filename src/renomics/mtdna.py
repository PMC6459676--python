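"""Relative mitochondrial genome dosage from sequencing coverage, and mtRNA load.

mtDNA is highly multi-copy, so even exome or genome sequencing not
targeting the mitochondrial contig captures it off-target at depths
proportional to per-cell copy number.  With a diploid autosomal background,

    mt_cn = 2 * (mean mt coverage) / (mean autosomal coverage)

copies per diploid genome, and the tumor/normal ratio of mt_cn is the
relative copy-number factor (a factor of 0.1 = ten-fold depletion).  The
autosomal mean comes from fixed-width windows filtered by mapping quality
and optional exclusion masks.  Mitochondrial transcriptional output is
summarized as the per-sample sum of TPM over the 13 mtDNA-encoded
protein-coding genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

logger = logging.getLogger("renomics")

__all__ = [
    "CoveragePair",
    "RelativeCN",
    "MT_PROTEIN_GENES",
    "coverage_from_alignment",
    "coverage_from_windows",
    "relative_mtdna_cn",
    "mtrna_fraction",
    "rank_outliers",
]

#: The 13 protein-coding genes of the human mitochondrial genome.
MT_PROTEIN_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

MT_CONTIG_NAMES = ("MT", "chrM", "chrMT", "M")


@dataclass
class CoveragePair:
    """Mean mitochondrial and autosomal coverage for one sample."""

    sample_id: str
    mt_mean_coverage: float
    autosomal_mean_coverage: float
    n_windows_used: int

    def __post_init__(self):
        if self.mt_mean_coverage < 0 or self.autosomal_mean_coverage < 0:
            raise ValueError("coverages must be non-negative")

    @property
    def mt_cn(self) -> float:
        """mtDNA copies per diploid genome: 2 x mt/autosome coverage ratio."""
        if self.n_windows_used < 1 or self.autosomal_mean_coverage == 0:
            raise ValueError(f"sample {self.sample_id}: no usable autosomal coverage")
        return 2.0 * self.mt_mean_coverage / self.autosomal_mean_coverage


@dataclass
class RelativeCN:
    """Tumor vs matched-normal mtDNA copy-number comparison."""

    pair_id: str
    mt_cn_tumor: float
    mt_cn_normal: float

    @property
    def relative_factor(self) -> float:
        return self.mt_cn_tumor / self.mt_cn_normal


def _autosomal_contigs(contigs: Iterable[str]) -> list[str]:
    keep = []
    for c in contigs:
        base = c[3:] if c.startswith("chr") else c
        if base.isdigit():
            keep.append(c)
    return keep


def coverage_from_alignment(
    path,
    sample_id: str | None = None,
    mapq_min: int = 30,
    window_length: int = 10_000,
    exclude_masks: dict | None = None,
    mode: str | None = None,
) -> CoveragePair:
    """Mean mt and autosomal-window coverage from a SAM/BAM/CRAM alignment.

    Reads are streamed (no index required); duplicate-flagged, unmapped,
    secondary/supplementary and low-MAPQ reads are excluded.  Autosomal
    coverage is the mean per-base depth over fixed-width windows whose span
    does not intersect ``exclude_masks`` (contig -> list of 0-based
    half-open (start, end) intervals).  The default MAPQ cutoff suppresses
    reads cross-mapping between the mt genome and nuclear mt-like segments
    (NUMTs).
    """
    exclude_masks = exclude_masks or {}
    with pysam.AlignmentFile(str(path), mode) as af:
        lengths = dict(zip(af.references, af.lengths))
        mt_contig = next((c for c in MT_CONTIG_NAMES if c in lengths), None)
        if mt_contig is None:
            raise ValueError("no mitochondrial contig (MT/chrM) in alignment header")
        autosomes = _autosomal_contigs(lengths)
        depth = {c: np.zeros(lengths[c], dtype=np.int64) for c in [mt_contig, *autosomes]}
        n_used = 0
        for read in af.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_duplicate
                or read.is_secondary
                or read.is_supplementary
                or read.mapping_quality < mapq_min
            ):
                continue
            contig = read.reference_name
            if contig not in depth:
                continue
            for start, end in read.get_blocks():
                depth[contig][start:end] += 1
            n_used += 1
        if sample_id is None:
            sample_id = str(path)
    if n_used == 0:
        raise ValueError("no reads passed the MAPQ/duplicate filters; nothing to estimate")
    mt_mean = float(depth[mt_contig].mean())
    window_means = []
    for c in autosomes:
        masks = exclude_masks.get(c, [])
        n_win = lengths[c] // window_length
        for w in range(n_win):
            start, end = w * window_length, (w + 1) * window_length
            if any(ms < end and me > start for ms, me in masks):
                continue
            window_means.append(depth[c][start:end].mean())
    if not window_means:
        raise ValueError("no autosomal windows passed the masks/length filter")
    return CoveragePair(sample_id, mt_mean, float(np.mean(window_means)), len(window_means))


def coverage_from_windows(
    sample_id: str,
    mt_counts: Sequence[float],
    mt_window_length: int,
    autosomal_counts: Sequence[float],
    autosomal_window_length: int,
) -> CoveragePair:
    """Build a CoveragePair from precomputed per-window read counts.

    Counts are reads per window; coverage is counts / window length (reads
    treated as depth contributions, suitable for simulated count tables).
    """
    mt_counts = np.asarray(mt_counts, dtype=float)
    auto = np.asarray(autosomal_counts, dtype=float)
    if auto.size < 1:
        raise ValueError("at least one autosomal window required")
    return CoveragePair(
        sample_id,
        float(mt_counts.sum() / (mt_counts.size * mt_window_length)) if mt_counts.size else 0.0,
        float(auto.mean() / autosomal_window_length),
        int(auto.size),
    )


def relative_mtdna_cn(tumor: CoveragePair, normal: CoveragePair) -> RelativeCN:
    """Tumor-over-normal relative mtDNA copy number."""
    if tumor.autosomal_mean_coverage == 0 or normal.autosomal_mean_coverage == 0:
        raise ValueError("degenerate input: zero autosomal coverage")
    if normal.mt_mean_coverage == 0:
        raise ValueError("degenerate input: zero mitochondrial coverage in normal")
    return RelativeCN(
        f"{tumor.sample_id}/{normal.sample_id}",
        tumor.mt_cn,
        normal.mt_cn,
    )


def mtrna_fraction(
    expr: pd.DataFrame,
    mt_genes: Sequence[str] = MT_PROTEIN_GENES,
    tpm_tolerance: float = 0.01,
) -> pd.DataFrame:
    """Aggregate mitochondrial transcription per sample from a TPM table.

    ``expr`` is genes x samples in TPM (each column sums to 1e6 within the
    stated tolerance).  Returns per-sample ``tpm_sum`` over the mt gene list
    and ``fraction`` of total expression.  Missing genes are warned about
    and skipped; an empty effective list is an error.
    """
    mt_genes = list(mt_genes)
    if not mt_genes:
        raise ValueError("empty mitochondrial gene list")
    totals = expr.sum(axis=0)
    off = np.abs(totals - 1e6) / 1e6
    if (off > tpm_tolerance).any():
        bad = list(totals.index[off > tpm_tolerance])
        raise ValueError(f"columns do not sum to 1e6 within {tpm_tolerance:.0%}: {bad}")
    present = [g for g in mt_genes if g in expr.index]
    missing = [g for g in mt_genes if g not in expr.index]
    if missing:
        logger.warning("mt genes absent from expression table, skipped: %s", missing)
    if not present:
        raise ValueError("none of the mitochondrial genes are present")
    tpm_sum = expr.loc[present].sum(axis=0)
    return pd.DataFrame({"tpm_sum": tpm_sum, "fraction": tpm_sum / totals})


def rank_outliers(cn_values: pd.Series, flagged: Iterable[str]) -> tuple[pd.Series, float]:
    """Ascending mid-ranks of flagged samples and Mann-Whitney p vs the rest.

    Used to ask whether a labeled subset (e.g. re-reviewed tumors) sits at
    the low end of a cohort-wide copy-number distribution.
    """
    cn_values = pd.Series(cn_values, dtype=float)
    flagged = set(flagged)
    if len(cn_values) < 2:
        raise ValueError("need at least 2 samples")
    unknown = flagged - set(cn_values.index)
    if unknown:
        raise KeyError(f"flagged samples absent from values: {sorted(unknown)}")
    if not flagged or flagged == set(cn_values.index):
        raise ValueError("flagged subset must be non-empty and proper")
    ranks = pd.Series(
        stats.rankdata(cn_values.to_numpy()), index=cn_values.index
    )
    in_f = cn_values.index.isin(flagged)
    res = stats.mannwhitneyu(
        cn_values[in_f], cn_values[~in_f], alternative="two-sided"
    )
    return ranks[list(flagged)].sort_values(), float(res.pvalue)
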