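"""Post-processing filter cascades for somatic substitutions and indels.

Upstream callers (an EM-based substitution caller, a split-read indel
caller) maximize sensitivity; specificity comes from published post-filters
evaluated here as pure predicates over read-level evidence.  Every rule is
evaluated for every record — no short-circuiting — so per-rule failure
counts are meaningful.  Substitution rules cover mutant base quality, read
position of the mutant base, matched-normal contamination, strand bias of
low-quality sites, repetitive/anomalous regions, and two unmatched
panel-of-normals screens; indel rules cover depth-dependent minimum allele
fraction, local short-repeat content, matched-normal/panel read evidence,
caller-support consistency, an anchor mapping-score sum, and a panel
recurrence screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "PanelSummary",
    "FilterVerdict",
    "SUBSTITUTION_RULES",
    "INDEL_RULES",
    "filter_substitution",
    "filter_indel",
    "apply_cascade",
]

#: Rule ids in evaluation order, substitution cascade.
SUBSTITUTION_RULES = (
    "base-quality-third",     # >=1/3 of mutant bases with BQ >= 25
    "middle-read-position",   # BQ>=20 mutant base in middle 3rd (cov>=10) / first 2/3
    "panel-read-support",     # <3 supporting reads in every unmatched-panel sample
    "normal-contamination",   # tumor VAF > 5x matched-normal VAF, or normal VAF == 0
    "strand-bias",            # if mean BQ < 20: <96% of mutant reads on one strand
    "region-mask",            # no simple-repeat/centromeric/excess-depth/low-mapq flag
    "panel-recurrence",       # not in >5% of panel samples at >=5% burden
)

#: Rule ids in evaluation order, indel cascade.
INDEL_RULES = (
    "min-allele-fraction",    # >=8% of reads (<200x) or >=4% (>=200x)
    "small-repeat-count",     # <=9 short (<4 nt) repeats in the region
    "normal-evidence",        # zero reads in matched normal and in the panel
    "caller-support",         # >4 indel-caller calls and BWA/strand consistency
    "anchor-mapping-score",   # sum of anchor mapping scores >= 150
    "panel-recurrence",       # not in >1% of panel samples at >=1% burden
)


@dataclass
class PanelSummary:
    """Unmatched normal panel context: how many samples were screened."""

    n_samples: int

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("panel must contain at least one sample")


@dataclass
class VariantRecord:
    """One candidate somatic variant with the evidence the filters consume.

    ``panel_hits`` lists, for each unmatched-panel sample where the site
    had any evidence, a (supporting_reads, allele_burden) tuple; samples
    without evidence are omitted.  Indel-specific fields default so that
    substitution records can leave them untouched.
    """

    record_id: str
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    mutant_coverage: int = 0
    total_depth: int = 0
    mutant_read_base_qualities: tuple = ()
    mutant_read_positions: tuple = ()  # fractional position in read, [0, 1]
    strand_counts: tuple = (0, 0)  # (forward, reverse) mutant reads
    mean_base_quality: float = 0.0
    matched_normal_vaf: float = 0.0
    region_flags: frozenset = frozenset()
    panel_hits: tuple = ()  # ((reads, burden), ...)
    # indel-specific evidence
    small_repeat_count: int = 0
    pindel_reads: tuple = (0, 0)  # (forward, reverse)
    bwa_mutant_reads: int = 0
    sum_ms: float = 0.0
    matched_normal_reads: int = 0
    pindel_call_count: int = 0

    def __post_init__(self):
        if self.mutant_coverage < 0 or self.total_depth < 0:
            raise ValueError(f"{self.record_id}: negative counts")
        if any(not (0.0 <= p <= 1.0) for p in self.mutant_read_positions):
            raise ValueError(f"{self.record_id}: read positions must lie in [0, 1]")
        if (
            self.mutant_read_positions
            and self.mutant_read_base_qualities
            and len(self.mutant_read_positions) != len(self.mutant_read_base_qualities)
        ):
            raise ValueError(
                f"{self.record_id}: base-quality and read-position lists must be parallel"
            )

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def vaf(self) -> float:
        return self.mutant_coverage / self.total_depth if self.total_depth else 0.0


@dataclass
class FilterVerdict:
    record_id: str
    failed_rules: tuple
    reasons: tuple = ()

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def filter_substitution(r: VariantRecord, panel: PanelSummary) -> FilterVerdict:
    """Evaluate the substitution post-filters; all rules, no short-circuit."""
    if not r.is_substitution:
        raise TypeError(f"{r.record_id}: indel record passed to the substitution cascade")
    failed, reasons = [], []

    def fail(rule, reason):
        failed.append(rule)
        reasons.append(reason)

    bqs = np.asarray(r.mutant_read_base_qualities, dtype=float)
    if bqs.size == 0 or (bqs >= 25).sum() * 3 < bqs.size:
        fail("base-quality-third",
             "fewer than a third of mutant bases have base quality >= 25")

    pos = np.asarray(r.mutant_read_positions, dtype=float)
    good = (bqs >= 20) if bqs.size == pos.size else np.ones(pos.size, dtype=bool)
    if r.mutant_coverage >= 10:
        ok = bool(np.any(good & (pos >= 1 / 3) & (pos <= 2 / 3)))
        window = "middle 3rd"
    else:
        ok = bool(np.any(good & (pos <= 2 / 3)))
        window = "first 2/3"
    if not ok:
        fail("middle-read-position",
             f"no mutant base of quality >= 20 in the {window} of a read")

    if any(reads >= 3 for reads, _ in r.panel_hits):
        fail("panel-read-support",
             "site marked by >=3 reads in an unmatched-panel sample")

    if not (r.matched_normal_vaf == 0 or r.vaf > 5 * r.matched_normal_vaf):
        fail("normal-contamination",
             "mutant allele proportion not >5x the matched normal (and normal nonzero)")

    fwd, rev = r.strand_counts
    total = fwd + rev
    if r.mean_base_quality < 20 and total > 0 and max(fwd, rev) / total >= 0.96:
        fail("strand-bias",
             "mean base quality < 20 and >=96% of mutant reads on one strand")

    if r.region_flags:
        fail("region-mask", f"record in masked region(s): {sorted(r.region_flags)}")

    if panel.n_samples > 0:
        hi = sum(1 for _, burden in r.panel_hits if burden >= 0.05)
        if hi / panel.n_samples > 0.05:
            fail("panel-recurrence",
                 "detected in >5% of the unmatched panel at >=5% allele burden")

    return FilterVerdict(r.record_id, tuple(failed), tuple(reasons))


def filter_indel(r: VariantRecord, panel: PanelSummary) -> FilterVerdict:
    """Evaluate the indel post-filters; all rules, no short-circuit."""
    if r.is_substitution:
        raise TypeError(f"{r.record_id}: substitution record passed to the indel cascade")
    failed, reasons = [], []

    def fail(rule, reason):
        failed.append(rule)
        reasons.append(reason)

    min_frac = 0.08 if r.total_depth < 200 else 0.04
    if r.vaf < min_frac:
        fail("min-allele-fraction",
             f"variant fraction {r.vaf:.3f} below {min_frac:.0%} at depth {r.total_depth}")

    if r.small_repeat_count > 9:
        fail("small-repeat-count",
             f"{r.small_repeat_count} short (<4 nt) repeats in the variant region (> 9)")

    panel_reads = sum(reads for reads, _ in r.panel_hits)
    if r.matched_normal_reads > 0 or panel_reads > 0:
        fail("normal-evidence",
             "variant seen in reads of the matched normal or the unmatched panel")

    pf, pr = r.pindel_reads
    support = r.pindel_call_count > 4 and (
        r.bwa_mutant_reads > 0
        or (r.bwa_mutant_reads == 0 and r.small_repeat_count == 0 and pf > 0 and pr > 0)
    )
    if not support:
        fail("caller-support",
             "needs >4 indel-caller calls and BWA-mapped mutant reads "
             "(or no repeats with split-read support on both strands)")

    if r.sum_ms < 150:
        fail("anchor-mapping-score", f"anchor mapping-score sum {r.sum_ms} < 150")

    hi = sum(1 for _, burden in r.panel_hits if burden >= 0.01)
    if hi / panel.n_samples > 0.01:
        fail("panel-recurrence",
             "detected in >1% of the unmatched panel at >=1% allele burden")

    return FilterVerdict(r.record_id, tuple(failed), tuple(reasons))


def _resolve_region_flags(r: VariantRecord, masks: dict | None) -> VariantRecord:
    """Fill region_flags by BED-interval intersection when flags are absent.

    ``masks`` maps flag-name -> {contig: [(start, end), ...]} with 0-based
    half-open BED semantics; the record's 1-based position is converted.
    """
    if r.region_flags or not masks:
        return r
    pos0 = r.position - 1
    flags = {
        name
        for name, by_contig in masks.items()
        if any(s <= pos0 < e for s, e in by_contig.get(r.contig, []))
    }
    if flags:
        import dataclasses

        r = dataclasses.replace(r, region_flags=frozenset(flags))
    return r


def apply_cascade(
    records: Iterable[VariantRecord],
    panel: PanelSummary,
    masks: dict | None = None,
) -> tuple[list[FilterVerdict], pd.DataFrame]:
    """Run the appropriate cascade on every record.

    Returns per-record verdicts (input order preserved) and a per-rule
    failure-count summary.  Malformed records yield a verdict failing the
    synthetic rule ``malformed`` so the cascade continues.
    """
    verdicts: list[FilterVerdict] = []
    counts: dict[str, int] = {}
    n_pass = 0
    for rec in records:
        try:
            rec = _resolve_region_flags(rec, masks)
            if rec.is_substitution:
                v = filter_substitution(rec, panel)
            else:
                v = filter_indel(rec, panel)
        except (TypeError, ValueError) as exc:
            v = FilterVerdict(getattr(rec, "record_id", "?"), ("malformed",), (str(exc),))
        verdicts.append(v)
        if v.passed:
            n_pass += 1
        for rule in v.failed_rules:
            counts[rule] = counts.get(rule, 0) + 1
    summary = pd.DataFrame(
        sorted(counts.items()), columns=["rule", "n_failed"]
    )
    summary.attrs["n_records"] = len(verdicts)
    summary.attrs["n_pass"] = n_pass
    return verdicts, summary


def read_records_tsv(path) -> list[VariantRecord]:
    """Read variant records from a flat TSV.

    List-valued evidence columns (``mutant_read_base_qualities``,
    ``mutant_read_positions``) are comma-separated; paired columns
    (``strand_counts``, ``pindel_reads``) are two comma-separated numbers;
    ``panel_hits`` is semicolon-separated ``reads:burden`` pairs;
    ``region_flags`` is comma-separated flag names.  Absent columns take
    the record defaults.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")

    def floats(v):
        return tuple(float(x) for x in v.split(",") if x != "")

    def pair(v, default=(0, 0)):
        return tuple(int(float(x)) for x in v.split(",")) if v else default

    records = []
    for _, row in df.iterrows():
        kwargs = dict(
            record_id=row["record_id"],
            contig=row["contig"],
            position=int(row["position"]),
            ref=row["ref"],
            alt=row["alt"],
        )
        get = lambda k: row[k] if k in row else ""
        for k in ("mutant_coverage", "total_depth", "small_repeat_count",
                  "bwa_mutant_reads", "matched_normal_reads", "pindel_call_count"):
            if get(k):
                kwargs[k] = int(float(row[k]))
        for k in ("mean_base_quality", "matched_normal_vaf", "sum_ms"):
            if get(k):
                kwargs[k] = float(row[k])
        if get("mutant_read_base_qualities"):
            kwargs["mutant_read_base_qualities"] = floats(row["mutant_read_base_qualities"])
        if get("mutant_read_positions"):
            kwargs["mutant_read_positions"] = floats(row["mutant_read_positions"])
        if get("strand_counts"):
            kwargs["strand_counts"] = pair(row["strand_counts"])
        if get("pindel_reads"):
            kwargs["pindel_reads"] = pair(row["pindel_reads"])
        if get("region_flags"):
            kwargs["region_flags"] = frozenset(row["region_flags"].split(","))
        if get("panel_hits"):
            kwargs["panel_hits"] = tuple(
                (int(float(h.split(":")[0])), float(h.split(":")[1]))
                for h in row["panel_hits"].split(";")
            )
        records.append(VariantRecord(**kwargs))
    return records
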