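"""96-channel trinucleotide mutation spectra and C:G>A:T enrichment.

Single-base substitutions are classified by the substituted pyrimidine
(variants with a purine reference are reverse-complemented onto the
pyrimidine strand) and its 5'/3' flanking bases: 6 substitution classes
x 16 contexts = 96 channels, in the conventional channel order.  The
oxidative-damage readout is the fraction of C>A (equivalently C:G>A:T)
mutations, tested against a baseline fraction with an exact binomial
test — guanine oxidation (8-oxo-dG) characteristically produces an excess
of these transversions, so a spectrum without C>A enrichment argues that
observed oxidative stress is not translating into mutational damage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

logger = logging.getLogger("renomics")

__all__ = [
    "Spectrum96",
    "CHANNELS",
    "build_spectrum",
    "ca_enrichment",
    "signature_nnls",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Canonical channel keys, e.g. ``A[C>A]A`` — class-major, then 5' and 3' flank.
CHANNELS = tuple(
    f"{five}[{cls}]{three}"
    for cls in _CLASSES
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {ch: i for i, ch in enumerate(CHANNELS)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_of(trinucleotide: str, alt: str) -> str:
    """Canonical channel of a substitution given its reference context.

    ``trinucleotide`` is the 5'-base, substituted base, 3'-base triplet on
    the sequenced strand; purine-centered contexts are folded onto the
    pyrimidine strand.
    """
    tri = trinucleotide.upper()
    alt = alt.upper()
    if len(tri) != 3 or any(b not in _BASES for b in tri + alt):
        raise ValueError(f"invalid context/alt: {trinucleotide!r} > {alt!r}")
    if tri[1] == alt:
        raise ValueError(f"ref equals alt at {trinucleotide!r}")
    if tri[1] in "GA":
        tri = _revcomp(tri)
        alt = alt.translate(_COMPLEMENT)
    return f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"


@dataclass
class Spectrum96:
    """Counts over the 96 canonical substitution channels."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    n_skipped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,) or (self.counts < 0).any():
            raise ValueError("spectrum must be 96 non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, channel: str) -> int:
        return int(self.counts[_CHANNEL_INDEX[channel]])

    def add(self, channel: str, n: int = 1) -> None:
        self.counts[_CHANNEL_INDEX[channel]] += n

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros(96)
        return self.counts / self.total

    def as_dict(self) -> dict:
        return dict(zip(CHANNELS, self.counts.tolist()))

    def class_fraction(self, substitution_class: str) -> float:
        """Fraction of mutations in one of the six classes (e.g. 'C>A')."""
        if substitution_class not in _CLASSES:
            raise ValueError(f"unknown class {substitution_class!r}")
        if self.total == 0:
            raise ValueError("empty spectrum")
        i = _CLASSES.index(substitution_class)
        return float(self.counts[16 * i : 16 * (i + 1)].sum() / self.total)


def build_spectrum(
    variants: Iterable[tuple],
    reference: str | Mapping[str, str],
) -> Spectrum96:
    """Accumulate a spectrum from (contig, position, ref, alt) substitutions.

    ``reference`` is either a single sequence (contig field then ignored)
    or a mapping contig -> sequence; positions are 1-based.  Indels and
    multi-base records are skipped with a warning, as are variants whose
    context would run off a sequence end; a ref-allele mismatch against the
    reference is an error.
    """
    spectrum = Spectrum96()
    single = isinstance(reference, str)
    for contig, position, ref, alt in variants:
        ref, alt = str(ref).upper(), str(alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            logger.warning("skipping non-SNV record at %s:%s (%s>%s)", contig, position, ref, alt)
            spectrum.n_skipped += 1
            continue
        seq = reference if single else reference[contig]
        if not (1 <= position <= len(seq)):
            raise ValueError(f"position {position} outside reference {contig}")
        if seq[position - 1].upper() != ref:
            raise ValueError(
                f"reference mismatch at {contig}:{position}: "
                f"reference {seq[position - 1]!r} vs variant ref {ref!r}"
            )
        if position == 1 or position == len(seq):
            logger.warning("skipping boundary variant at %s:%s (no flanking context)", contig, position)
            spectrum.n_skipped += 1
            continue
        tri = seq[position - 2 : position + 1].upper()
        spectrum.add(channel_of(tri, alt))
    return spectrum


def ca_enrichment(
    spectrum: Spectrum96,
    baseline: float | Spectrum96 = 1.0 / 6.0,
) -> tuple[float, float]:
    """Observed C>A fraction and two-sided exact binomial p vs a baseline.

    ``baseline`` is the expected C>A fraction under the null — by default
    the uniform 1/6 across substitution classes, or a cohort spectrum whose
    own C>A fraction is used.  Returns (fraction, p_value).
    """
    if spectrum.total < 1:
        raise ValueError("empty spectrum")
    if isinstance(baseline, Spectrum96):
        baseline = baseline.class_fraction("C>A")
    if not (0.0 < baseline < 1.0):
        raise ValueError("baseline fraction must lie in (0, 1)")
    ca = int(round(spectrum.class_fraction("C>A") * spectrum.total))
    res = stats.binomtest(ca, spectrum.total, baseline, alternative="two-sided")
    return ca / spectrum.total, float(res.pvalue)


def signature_nnls(spectrum: Spectrum96, signatures: np.ndarray) -> np.ndarray:
    """Non-negative least-squares exposure of a spectrum to signature columns.

    Hook for refitting against a user-supplied (96 x k) signature matrix;
    exposures are returned on the proportion scale.  Shipped as a
    convenience, not validated against any published signature catalog.
    """
    signatures = np.asarray(signatures, dtype=float)
    if signatures.shape[0] != 96:
        raise ValueError("signature matrix must have 96 rows")
    from scipy.optimize import nnls

    x, _ = nnls(signatures, spectrum.proportions())
    return x
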