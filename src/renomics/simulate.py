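"""Synthetic inputs for every stage of the pipeline.

Each generator draws from a single :class:`numpy.random.Generator` stream
seeded by the spec's integer seed, so regeneration with the same spec is
bit-identical.

The metabolomics generator uses a log-normal abundance model with
multiplicative group effects and run-day batch factors — the model under
which median-ratio normalization and fold-change estimation are exact —
plus detection-limit censoring.  :func:`study_cohort_spec` instantiates it
at the study conditions of the three-group renal cohort this package
analyzes (9 CCPAP, 10 ccRCC of which 2 atypically high in sorbitol, 10
adjacent-normal; 548 measured compounds; polyol, glutathione and
NAD(H)-couple effects at their reported magnitudes).

Coverage, duplex-table, variant-record and mutation-catalog generators
emulate the sequencing-side inputs: Poisson window coverage with a
tumor-specific mtDNA depletion factor, binomial duplex allele counts at
clonal and subclonal fractions, filter-cascade records carrying
ground-truth rule-violation labels, and substitution catalogs drawn from a
96-channel trinucleotide spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .duplex import DuplexSite
from .filters import INDEL_RULES, SUBSTITUTION_RULES, VariantRecord
from .preprocess import MetaboliteMatrix
from .spectrum import CHANNELS

__all__ = [
    "MetaboCohortSpec",
    "CoverageSimSpec",
    "DuplexSimSpec",
    "simulate_metabolomics",
    "simulate_coverage",
    "simulate_duplex_table",
    "simulate_variant_records",
    "simulate_mutation_catalog",
    "random_reference",
    "study_cohort_spec",
    "STUDY_EFFECTS",
    "HIGH_SORBITOL_LABEL",
]

DEFAULT_GROUPS = ("CCPAP", "ccRCC", "NORMAL")


# ---------------------------------------------------------------------------
# Metabolomics cohorts

@dataclass
class MetaboCohortSpec:
    """Design of a multi-group metabolomics cohort.

    ``group_effects`` maps (compound, group) -> multiplicative effect on the
    compound's baseline abundance (absent entries default to 1).  Noise is
    log-normal with per-compound sigma on the natural-log scale; each run
    day multiplies all its samples by a shared log-normal batch factor with
    scale ``runday_sigma``.  Values below a compound's detection limit are
    censored (reported missing).
    """

    n_per_group: Mapping[str, int]
    baseline_log_mean: Mapping[str, float]
    group_effects: Mapping[tuple, float] = field(default_factory=dict)
    noise_sigma: Mapping[str, float] | float = 0.5
    rundays: int = 3
    runday_sigma: float = 0.2
    detection_limit: Mapping[str, float] | float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.n_per_group or any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")
        if self.rundays < 1:
            raise ValueError("rundays must be >= 1")
        if self.runday_sigma < 0:
            raise ValueError("runday_sigma must be >= 0")
        for c in self.compounds:
            if self.sigma_of(c) < 0:
                raise ValueError(f"negative noise_sigma for {c!r}")
            if any(e < 0 for (cc, _), e in self.group_effects.items() if cc == c):
                raise ValueError(f"negative effect for {c!r}")

    @property
    def compounds(self) -> list:
        return list(self.baseline_log_mean)

    def sigma_of(self, compound: str) -> float:
        if isinstance(self.noise_sigma, Mapping):
            return float(self.noise_sigma.get(compound, 0.5))
        return float(self.noise_sigma)

    def limit_of(self, compound: str) -> float:
        if isinstance(self.detection_limit, Mapping):
            return float(self.detection_limit.get(compound, 0.0))
        return float(self.detection_limit)

    def effect_of(self, compound: str, group: str) -> float:
        return float(self.group_effects.get((compound, group), 1.0))


def simulate_metabolomics(spec: MetaboCohortSpec) -> MetaboliteMatrix:
    """Draw a cohort matrix under the log-normal group/batch-effect model.

    abundance(s, c) = exp(baseline_c + N(0, sigma_c)) * effect(c, group(s))
    * batch(runday(s)); run days are assigned round-robin across samples
    (balanced blocks with well-defined medians); draws below the compound's
    detection limit are censored to missing.
    """
    rng = np.random.default_rng(spec.seed)
    samples, groups = [], []
    for g, n in spec.n_per_group.items():
        for i in range(n):
            samples.append(f"{g}-{i + 1}")
            groups.append(g)
    rundays = [i % spec.rundays + 1 for i in range(len(samples))]
    batch = np.exp(rng.normal(0.0, spec.runday_sigma, size=spec.rundays))
    compounds = spec.compounds
    data = np.empty((len(compounds), len(samples)))
    for ci, c in enumerate(compounds):
        noise = rng.normal(0.0, spec.sigma_of(c), size=len(samples))
        base = np.exp(spec.baseline_log_mean[c] + noise)
        eff = np.array([spec.effect_of(c, g) for g in groups])
        vals = base * eff * batch[np.array(rundays) - 1]
        vals[vals < spec.limit_of(c)] = np.nan
        data[ci] = vals
    ab = pd.DataFrame(data, index=compounds, columns=samples)
    return MetaboliteMatrix(
        ab,
        pd.Series(groups, index=samples),
        pd.Series(rundays, index=samples),
    )


# -- Study conditions -------------------------------------------------------

HIGH_SORBITOL_LABEL = "ccRCC-highsorbitol"

#: Multiplicative effects (relative to adjacent-normal tissue) that define
#: the emulated study cohort.  Polyol, glutathione and redox-couple effects
#: sit at their reported magnitudes: sorbitol 36x in tumor vs normal and
#: 8.5x vs the full ccRCC arm (64x vs typical ccRCC once the two atypical
#: high-sorbitol samples are excluded), fructose >30x vs normal and 5x vs
#: ccRCC, glutathione species 13x vs ccRCC, ophthalmate 4x vs ccRCC,
#: aspartate 3.5x and fumarate 4x DOWN vs normal.  The NAD(H)-couple
#: members are set so that four of the five measurable couples shift
#: toward their reduced member in tumor (fructose/sorbitol,
#: uracil/dihydrouracil, xanthine/hypoxanthine, dehydroascorbate/ascorbate)
#: while urate/xanthine does not.
STUDY_EFFECTS: dict = {
    "sorbitol": {"CCPAP": 36.0, "ccRCC": 0.5625, HIGH_SORBITOL_LABEL: 18.925},
    "fructose": {"CCPAP": 32.0, "ccRCC": 6.4, HIGH_SORBITOL_LABEL: 6.4},
    "glutathione": {"CCPAP": 13.0},
    "glutathione disulfide": {"CCPAP": 13.0},
    "ophthalmate": {"CCPAP": 6.0, "ccRCC": 1.5, HIGH_SORBITOL_LABEL: 1.5},
    "aspartate": {"CCPAP": 1 / 3.5},
    "fumarate": {"CCPAP": 0.25},
    "uracil": {"CCPAP": 1.2},
    "5,6-dihydrouracil": {"CCPAP": 3.0},
    "xanthine": {"CCPAP": 1.2},
    "hypoxanthine": {"CCPAP": 2.5},
    "urate": {"CCPAP": 1.5},
    "dehydroascorbate": {"CCPAP": 0.8},
    "ascorbate": {"CCPAP": 2.5},
}

_N_TUMOR_SPECIFIC_BG = 142  # background compounds shifted vs both comparators
_N_CCRCC_DRIVEN_BG = 48     # compounds where ccRCC, not CCPAP, departs from normal
_N_NULL_BG = 344            # unchanged compounds; universe totals 548


def study_cohort_spec(seed: int = 0, compounds: Sequence[str] | None = None) -> MetaboCohortSpec:
    """The cohort specification emulating the study's metabolomics arm.

    9 CCPAP, 8 typical ccRCC + 2 high-sorbitol ccRCC, 10 normal; 548
    compounds of which 14 are the named key metabolites, 142 background
    compounds are tumor-specifically shifted (differential vs both ccRCC
    and normal), 48 are ccRCC-driven (differential vs ccRCC only) and the
    rest are null.  ``compounds`` restricts the universe (e.g. to the
    redox-couple members) without changing any effect.
    """
    effects: dict = {}
    baselines: dict = {}
    for c, by_group in STUDY_EFFECTS.items():
        baselines[c] = 10.0
        for g, e in by_group.items():
            effects[(c, g)] = e
    up_down = [4.0, 6.0, 0.25, 1 / 6.0]
    for i in range(_N_TUMOR_SPECIFIC_BG):
        c = f"met-ts-{i + 1:03d}"
        baselines[c] = 10.0
        effects[(c, "CCPAP")] = up_down[i % len(up_down)]
    for i in range(_N_CCRCC_DRIVEN_BG):
        c = f"met-cc-{i + 1:03d}"
        baselines[c] = 10.0
        e = [5.0, 0.2][i % 2]
        effects[(c, "ccRCC")] = e
        effects[(c, HIGH_SORBITOL_LABEL)] = e
    for i in range(_N_NULL_BG):
        baselines[f"met-null-{i + 1:03d}"] = 10.0
    if compounds is not None:
        keep = set(compounds)
        baselines = {c: b for c, b in baselines.items() if c in keep}
        effects = {(c, g): e for (c, g), e in effects.items() if c in keep}
    return MetaboCohortSpec(
        n_per_group={"CCPAP": 9, "ccRCC": 8, HIGH_SORBITOL_LABEL: 2, "NORMAL": 10},
        baseline_log_mean=baselines,
        group_effects=effects,
        noise_sigma=0.5,
        rundays=3,
        runday_sigma=0.2,
        # 2.5 natural-log units below baseline: untargeted panels measure most
        # species well above detection; only the tails of strongly depleted
        # compounds (a few %) fall below and exercise the imputation path
        detection_limit={c: float(np.exp(10.0 - 2.5)) for c in baselines},
        seed=seed,
    )


def simulate_study_cohort(seed: int = 0, compounds: Sequence[str] | None = None):
    """Generate the study cohort; returns (matrix, high-sorbitol sample ids).

    The two atypical high-sorbitol samples are relabeled into the ccRCC
    group (they are ccRCC histologically) and their ids returned so
    analyses can optionally exclude them.
    """
    spec = study_cohort_spec(seed, compounds)
    m = simulate_metabolomics(spec)
    high = m.group_samples(HIGH_SORBITOL_LABEL)
    m.sample_groups = m.sample_groups.replace({HIGH_SORBITOL_LABEL: "ccRCC"})
    return m, high


# ---------------------------------------------------------------------------
# Tumor/normal coverage

@dataclass
class CoverageSimSpec:
    """Poisson coverage model for mitochondrial vs autosomal sequencing."""

    mt_genome_length: int = 16_569
    n_autosomal_windows: int = 200
    window_length: int = 10_000
    normal_mt_cn: float = 500.0
    depletion_factor: float = 0.1
    mean_autosomal_depth: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if min(self.mt_genome_length, self.n_autosomal_windows, self.window_length) <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.depletion_factor <= 0:
            raise ValueError("depletion_factor must be > 0")
        if self.normal_mt_cn < 0 or self.mean_autosomal_depth < 0:
            raise ValueError("copy number and depth must be >= 0")


def simulate_coverage(spec: CoverageSimSpec) -> tuple[dict, dict]:
    """Draw (tumor, normal) read-count tables under the Poisson model.

    Autosomal windows carry Poisson(depth * window_length) base counts; the
    mitochondrial contig carries Poisson(depth * mt_length * cn/2 * f) with
    f = 1 in the normal and f = depletion_factor in the tumor.  Each table
    maps 'mt' -> array of one count and 'autosomal' -> per-window counts.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for f in (spec.depletion_factor, 1.0):  # tumor first, then normal
        auto = rng.poisson(
            spec.mean_autosomal_depth * spec.window_length,
            size=spec.n_autosomal_windows,
        )
        mt_mean = (
            spec.mean_autosomal_depth
            * spec.mt_genome_length
            * spec.normal_mt_cn
            / 2.0
            * f
        )
        mt = rng.poisson(mt_mean, size=1)
        out.append({"mt": mt, "autosomal": auto})
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Duplex consensus variant tables

@dataclass
class DuplexSimSpec:
    """Mixture of clonal (germline) and subclonal (somatic) duplex alleles."""

    n_positions: int = 1000
    depth_mean: float = 5000.0
    germline_sites: Sequence[tuple] = ()  # (position, vaf near 0.5 or 1.0)
    somatic_sites: Sequence[tuple] = ()   # (position, vaf <= 0.01)
    seed: int = 0

    def __post_init__(self):
        if self.n_positions <= 0 or self.depth_mean <= 0:
            raise ValueError("n_positions and depth_mean must be positive")
        for _, vaf in (*self.germline_sites, *self.somatic_sites):
            if not (0.0 < vaf <= 1.0):
                raise ValueError("site VAFs must lie in (0, 1]")
        seen = set()
        for pos, _ in (*self.germline_sites, *self.somatic_sites):
            if pos in seen:
                raise ValueError(f"duplicate variant position {pos}")
            seen.add(pos)


def simulate_duplex_table(spec: DuplexSimSpec) -> list[DuplexSite]:
    """Emit one DuplexSite per position: Poisson depth, binomial alt reads.

    Variant-free positions are emitted with zero variant reads so the
    surveyed-base denominator downstream reflects the whole target.
    """
    rng = np.random.default_rng(spec.seed)
    vaf_at = {pos: vaf for pos, vaf in (*spec.germline_sites, *spec.somatic_sites)}
    bases = "ACGT"
    sites = []
    for pos in range(1, spec.n_positions + 1):
        depth = int(rng.poisson(spec.depth_mean))
        ref = bases[int(rng.integers(4))]
        vaf = vaf_at.get(pos, 0.0)
        var = int(rng.binomial(depth, vaf)) if vaf > 0 and depth > 0 else 0
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        sites.append(DuplexSite(pos, ref, alt, depth, var))
    return sites


# ---------------------------------------------------------------------------
# Filter-cascade variant records with ground-truth labels

_SUB_PREFIX, _INDEL_PREFIX = "sub:", "indel:"
KNOWN_RULE_IDS = tuple(
    [_SUB_PREFIX + r for r in SUBSTITUTION_RULES] + [_INDEL_PREFIX + r for r in INDEL_RULES]
)


def _make_substitution(i: int, rng: np.random.Generator, violated: frozenset) -> VariantRecord:
    """Substitution record violating exactly the named rules.

    Base-quality, read-position and strand evidence interact (the strand
    rule is only armed below mean BQ 20), so the record is assembled from
    the full violation set rather than by independent field edits.
    """
    want_bq = "base-quality-third" in violated
    want_strand = "strand-bias" in violated
    want_mid = "middle-read-position" in violated
    if want_bq:
        n_hi = 2  # 2/12 < a third at BQ >= 25
    elif want_strand:
        n_hi = 4  # exactly a third: passes the quality rule, mean still < 20
    else:
        n_hi = 12
    hi_q = 30 if n_hi == 12 else 26
    quals = (hi_q,) * n_hi + (10,) * (12 - n_hi)
    if want_mid:
        positions = tuple(0.05 if k % 2 else 0.95 for k in range(12))
    else:
        # the BQ >= 20 reads (the high-quality ones) sit mid-read
        positions = tuple(
            float(rng.uniform(0.36, 0.64)) if q >= 20 else float(rng.uniform(0.7, 0.95))
            for q in quals
        )
    hits: list = []
    if "panel-read-support" in violated:
        hits.append((5, 0.02))
    if "panel-recurrence" in violated:
        hits.extend((2, 0.06) for _ in range(6))
    if not hits:
        hits.append((1, 0.01))
    return VariantRecord(
        record_id=f"sub-{i}",
        contig="1",
        position=int(rng.integers(1, 10_000_000)),
        ref="C",
        alt="T",
        mutant_coverage=12,
        total_depth=100,
        mutant_read_base_qualities=quals,
        mutant_read_positions=positions,
        strand_counts=(12, 0) if want_strand else (6, 6),
        mean_base_quality=float(np.mean(quals)),
        matched_normal_vaf=0.05 if "normal-contamination" in violated else 0.0,
        region_flags=frozenset({"simple_repeat"}) if "region-mask" in violated else frozenset(),
        panel_hits=tuple(hits),
    )


def _make_indel(i: int, rng: np.random.Generator, violated: frozenset) -> VariantRecord:
    depth, cov = (150, 9) if "min-allele-fraction" in violated else (100, 12)
    return VariantRecord(
        record_id=f"indel-{i}",
        contig="1",
        position=int(rng.integers(1, 10_000_000)),
        ref="A",
        alt="AT",
        mutant_coverage=cov,
        total_depth=depth,
        matched_normal_vaf=0.0,
        panel_hits=(
            tuple((0, 0.02) for _ in range(5))
            if "panel-recurrence" in violated
            else ()
        ),
        small_repeat_count=10 if "small-repeat-count" in violated else 0,
        pindel_reads=(3, 3),
        bwa_mutant_reads=5,
        sum_ms=100.0 if "anchor-mapping-score" in violated else 300.0,
        matched_normal_reads=2 if "normal-evidence" in violated else 0,
        pindel_call_count=3 if "caller-support" in violated else 6,
    )


def simulate_variant_records(
    n: int,
    rule_mix: Mapping[str, float],
    seed: int = 0,
) -> list[tuple[VariantRecord, frozenset]]:
    """Records exercising the filter cascades, labeled with ground truth.

    ``rule_mix`` maps a namespaced rule id (``sub:<rule>`` or
    ``indel:<rule>``; see :data:`KNOWN_RULE_IDS`) to the fraction of
    records of that type that should violate the rule.  Returns
    (record, violated-rule-ids) pairs where the label set uses the filter
    cascade's unprefixed rule ids; clean records carry an empty label set
    (PASS).  Record type alternates substitution/indel unless the mix
    names rules of only one type.
    """
    for rule, frac in rule_mix.items():
        if rule not in KNOWN_RULE_IDS:
            raise KeyError(f"unknown rule id {rule!r}; known: {KNOWN_RULE_IDS}")
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"violation fraction for {rule!r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    sub_rules = {r[len(_SUB_PREFIX):]: f for r, f in rule_mix.items() if r.startswith(_SUB_PREFIX)}
    indel_rules = {r[len(_INDEL_PREFIX):]: f for r, f in rule_mix.items() if r.startswith(_INDEL_PREFIX)}
    if sub_rules and not indel_rules:
        kinds = ["sub"] * n
    elif indel_rules and not sub_rules:
        kinds = ["indel"] * n
    else:
        kinds = ["sub" if i % 2 == 0 else "indel" for i in range(n)]
    out = []
    for i, kind in enumerate(kinds):
        rules, make = (
            (sub_rules, _make_substitution) if kind == "sub" else (indel_rules, _make_indel)
        )
        violated = frozenset(rule for rule, frac in rules.items() if rng.random() < frac)
        out.append((make(i, rng, violated), violated))
    return out


# ---------------------------------------------------------------------------
# Mutation catalogs from trinucleotide spectra

def random_reference(length: int, seed: int = 0) -> str:
    """Uniform-composition random nucleotide sequence."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


_COMP = str.maketrans("ACGT", "TGCA")


def simulate_mutation_catalog(
    n: int,
    spectrum_weights: Sequence[float],
    reference: str,
    seed: int = 0,
) -> list[tuple]:
    """Draw ``n`` substitutions whose trinucleotide channels follow weights.

    Channels follow :data:`renomics.spectrum.CHANNELS`; weights are
    normalized to sum 1.  Each mutation is placed uniformly at random among
    reference positions whose pyrimidine-folded context matches the
    sampled channel (purine-reference positions get the complemented alt).
    Returns (contig, position, ref, alt) tuples on contig 'ref'.  A sampled
    channel with no matching context in the reference is an error naming
    the channel.
    """
    w = np.asarray(spectrum_weights, dtype=float)
    if w.shape != (96,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("spectrum_weights must be 96 non-negative values with positive sum")
    w = w / w.sum()
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    ref_upper = reference.upper()
    context_positions: dict[str, list[int]] = {}
    for i in range(1, len(ref_upper) - 1):
        tri = ref_upper[i - 1 : i + 2]
        if any(b not in "ACGT" for b in tri):
            continue
        folded = tri if tri[1] in "CT" else tri.translate(_COMP)[::-1]
        context_positions.setdefault(folded, []).append(i + 1)  # 1-based
    draws = rng.multinomial(n, w)
    catalog = []
    for ch_i, count in enumerate(draws):
        if count == 0:
            continue
        channel = CHANNELS[ch_i]
        five, cls, three = channel[0], channel[2:5], channel[6]
        folded = five + cls[0] + three
        positions = context_positions.get(folded)
        if not positions:
            raise ValueError(f"context for channel {channel} absent from reference")
        for pos in rng.choice(positions, size=count, replace=True):
            pos = int(pos)
            ref_base = ref_upper[pos - 1]
            alt = cls[2] if ref_base == cls[0] else cls[2].translate(_COMP)
            catalog.append(("ref", pos, ref_base, alt))
    return catalog
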