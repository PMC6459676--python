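"""Somatic mtDNA variant scoring from duplex-consensus tables.

Duplex consensus sequencing suppresses sequencing error far below the
frequency of true low-level heteroplasmies, so somatic (non-inherited)
mtDNA variants can be separated from germline/clonal alleles purely by
allele fraction: positions where the variant exceeds 1% of duplex reads
are treated as inherited or clonally expanded and excluded, as are
positions with fewer than 100 duplex consensus reads.  Each mutation type
is scored only once per genomic position regardless of read multiplicity.
Coding consequences are annotated under the vertebrate mitochondrial
genetic code (translation table 2), extracting codons strand-aware; on the
human mitochondrial genome MT-ND6 is the one protein gene read off the
opposite strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "DuplexSite",
    "MtGeneModel",
    "SomaticCallSet",
    "call_somatic",
    "annotate_consequence",
    "summarize_per_sample",
    "read_duplex_table",
]

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]


@dataclass(frozen=True)
class DuplexSite:
    """One position/allele row of a duplex consensus variant table."""

    position: int  # 1-based on the mitochondrial reference
    ref: str
    alt: str
    depth: int
    variant_reads: int

    def __post_init__(self):
        if not (0 <= self.variant_reads <= self.depth):
            raise ValueError(
                f"position {self.position}: variant reads {self.variant_reads} "
                f"outside [0, depth={self.depth}]"
            )

    @property
    def vaf(self) -> float:
        return self.variant_reads / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class MtGeneModel:
    """Coding interval(s) of one mitochondrial gene, 1-based inclusive."""

    name: str
    strand: str  # '+' light-strand sense, '-' reverse (MT-ND6)
    intervals: tuple  # ((start, end), ...) 1-based inclusive
    allow_incomplete_stop: bool = False

    def __post_init__(self):
        ivs = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.name}: overlapping coding intervals")
        length = sum(e - s + 1 for s, e in self.intervals)
        if length % 3 and not self.allow_incomplete_stop:
            raise ValueError(f"{self.name}: coding length {length} not divisible by 3")

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)

    def coding_offset(self, position: int) -> int:
        """0-based offset of a genomic position within the spliced CDS."""
        off = 0
        for s, e in sorted(self.intervals):
            if s <= position <= e:
                return off + (position - s)
            off += e - s + 1
        raise ValueError(f"position {position} not in {self.name}")

    def coding_sequence(self, reference: str) -> str:
        seq = "".join(reference[s - 1 : e] for s, e in sorted(self.intervals))
        return seq


@dataclass
class SomaticCallSet:
    """Retained somatic calls and the surveyed-base denominator."""

    calls: list
    bases_surveyed: int
    excluded_clonal: int = 0
    excluded_depth: int = 0

    @property
    def mutation_frequency(self) -> float:
        """Somatic mutations per duplex base surveyed."""
        if self.bases_surveyed == 0:
            return 0.0
        return len(self.calls) / self.bases_surveyed


def call_somatic(
    sites: Iterable[DuplexSite],
    clonality_max: float = 0.01,
    depth_min: int = 100,
) -> SomaticCallSet:
    """Apply the clonality and depth cutoffs and de-duplicate mutation types.

    A site is retained iff its variant allele fraction does not exceed
    ``clonality_max`` (strictly greater is excluded as inherited/clonal),
    its depth is at least ``depth_min`` and it carries at least one variant
    read.  Among retained sites, each (position, ref, alt) mutation type
    counts once.  ``bases_surveyed`` sums depth over distinct positions
    meeting the depth cutoff (variant-free positions included when present
    in the input).
    """
    seen: set = set()
    calls: list[DuplexSite] = []
    surveyed: dict[int, int] = {}
    n_clonal = n_depth = 0
    for site in sites:
        if site.depth >= depth_min:
            surveyed.setdefault(site.position, site.depth)
        if site.variant_reads == 0:
            continue
        if site.depth < depth_min:
            n_depth += 1
            continue
        if site.vaf > clonality_max:
            n_clonal += 1
            continue
        key = (site.position, site.ref, site.alt)
        if key in seen:
            continue
        seen.add(key)
        calls.append(site)
    return SomaticCallSet(
        calls,
        bases_surveyed=int(sum(surveyed.values())),
        excluded_clonal=n_clonal,
        excluded_depth=n_depth,
    )


def annotate_consequence(
    call: DuplexSite,
    reference: str,
    genes: Sequence[MtGeneModel],
) -> dict:
    """Consequence of a single-base call under the mitochondrial code.

    Returns a dict with ``consequence`` in {missense, synonymous, nonsense,
    stop-lost, non-coding}, plus gene / codon-change detail for coding
    calls.  The reference base at the call position must match the call's
    ref allele.
    """
    pos = call.position
    if not (1 <= pos <= len(reference)):
        raise ValueError(f"position {pos} outside reference (length {len(reference)})")
    if reference[pos - 1].upper() != call.ref.upper():
        raise ValueError(
            f"reference mismatch at {pos}: reference has {reference[pos - 1]!r}, "
            f"call has {call.ref!r}"
        )
    gene = next((g for g in genes if g.contains(pos)), None)
    if gene is None:
        return {"consequence": "non-coding", "gene": None, "codon_change": None,
                "aa_change": None}
    cds = gene.coding_sequence(reference)
    offset = gene.coding_offset(pos)
    alt_cds = cds[:offset] + call.alt + cds[offset + 1 :]
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
        alt_cds = str(Seq(alt_cds).reverse_complement())
        offset = len(cds) - 1 - offset
    codon_i = offset // 3
    ref_codon = cds[3 * codon_i : 3 * codon_i + 3].upper()
    alt_codon = alt_cds[3 * codon_i : 3 * codon_i + 3].upper()
    if len(ref_codon) < 3:  # trailing incomplete (polyadenylation-completed) stop
        return {"consequence": "non-coding", "gene": gene.name,
                "codon_change": None, "aa_change": None}
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "nonsense"
    elif ref_aa == "*":
        consequence = "stop-lost"
    else:
        consequence = "missense"
    return {
        "consequence": consequence,
        "gene": gene.name,
        "codon_change": f"{ref_codon}>{alt_codon}",
        "aa_change": f"{ref_aa}{codon_i + 1}{alt_aa}",
    }


def _translate_codon(codon: str) -> str:
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


def summarize_per_sample(annotated_calls: Mapping[str, Sequence[dict]]) -> pd.DataFrame:
    """Tabulate non-synonymous / synonymous call counts per sample.

    ``annotated_calls`` maps sample id -> list of annotation dicts from
    :func:`annotate_consequence`.  Non-synonymous covers missense, nonsense
    and stop-lost.  The returned frame carries one row per sample plus the
    cohort mean frequency in ``DataFrame.attrs['mean_nonsyn_per_sample']``.
    """
    nonsyn = {"missense", "nonsense", "stop-lost"}
    rows = []
    for sample, calls in annotated_calls.items():
        kinds = [c["consequence"] for c in calls]
        rows.append(
            {
                "sample": sample,
                "n_calls": len(kinds),
                "n_nonsynonymous": sum(k in nonsyn for k in kinds),
                "n_synonymous": sum(k == "synonymous" for k in kinds),
                "n_noncoding": sum(k == "non-coding" for k in kinds),
            }
        )
    df = pd.DataFrame(
        rows, columns=["sample", "n_calls", "n_nonsynonymous", "n_synonymous", "n_noncoding"]
    ).set_index("sample")
    df.attrs["mean_nonsyn_per_sample"] = (
        float(df["n_nonsynonymous"].mean()) if len(df) else 0.0
    )
    return df


def read_duplex_table(path) -> list[DuplexSite]:
    """Read a duplex site TSV (position, ref, alt, depth, variant_reads)."""
    df = pd.read_csv(path, sep="\t")
    return [
        DuplexSite(
            int(r["position"]), str(r["ref"]), str(r["alt"]),
            int(r["depth"]), int(r["variant_reads"]),
        )
        for _, r in df.iterrows()
    ]
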