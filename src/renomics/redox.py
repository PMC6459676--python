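"""NADH/NAD redox-shift inference from oxidized/reduced metabolite couples.

The cytosolic NADH/NAD ratio is hard to measure directly and the
metabolomic readout is artifact-prone, so the pipeline infers shifts
indirectly: among NAD(H)-coupled reactions in a metabolic reconstruction,
keep those whose non-cofactor substrates and products were all measured,
and for each form the per-sample ratio oxidized/reduced.  Near chemical
equilibrium an elevated NADH/NAD poise pushes each couple toward its
reduced member, so a coordinated drop of these ratios in the tumor group
is evidence of impaired NADH re-oxidation (e.g. a defective respiratory
chain).  Five couples survive the measurement filter in the reference
network: fructose/sorbitol, uracil/5,6-dihydrouracil, xanthine/
hypoxanthine, urate/xanthine and dehydroascorbate/ascorbate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffabund import bh_correct, mann_whitney
from .preprocess import MetaboliteMatrix

logger = logging.getLogger("renomics")

__all__ = [
    "RedoxReaction",
    "RedoxRatioResult",
    "COFACTORS",
    "filter_reactions",
    "ratio_per_sample",
    "ratio_shift_test",
    "load_reactions",
    "example_reactions",
]

#: Metabolites exempt from the "all members measured" requirement: the
#: cofactor couple itself plus ubiquitous small species.
COFACTORS = frozenset(
    {"nad", "nad+", "nadh", "h+", "h2o", "water", "phosphate", "pi", "o2", "co2"}
)


@dataclass(frozen=True)
class RedoxReaction:
    """One NAD(H)-coupled reaction with its oxidized/reduced couple."""

    reaction_id: str
    substrates: tuple
    products: tuple
    oxidized_metabolite: str
    reduced_metabolite: str
    cofactor_pair: str = "NADH/NAD"

    def __post_init__(self):
        if self.oxidized_metabolite == self.reduced_metabolite:
            raise ValueError("oxidized and reduced metabolites must differ")
        members = set(self.substrates) | set(self.products)
        for met in (self.oxidized_metabolite, self.reduced_metabolite):
            if met not in members:
                raise ValueError(f"{met!r} not among substrates/products of {self.reaction_id}")

    @property
    def pair_label(self) -> str:
        return f"{self.oxidized_metabolite}/{self.reduced_metabolite}"


@dataclass
class RedoxRatioResult:
    """Per-sample ratios and the group-shift verdict for one couple."""

    pair_label: str
    ratios: pd.Series  # per sample
    median_a: float
    median_b: float
    direction: str  # drop / rise / flat, A relative to B
    p_value: float
    q_value: float = np.nan


def _is_cofactor(met: str, cofactors: frozenset = COFACTORS) -> bool:
    return met.strip().lower() in cofactors


def filter_reactions(
    reactions: Iterable[RedoxReaction],
    measured: Iterable[str],
    cofactors: frozenset = COFACTORS,
) -> list[RedoxReaction]:
    """Retain reactions whose every non-cofactor member was measured."""
    measured = set(measured)
    kept = []
    for rxn in reactions:
        members = [
            m
            for m in (*rxn.substrates, *rxn.products)
            if not _is_cofactor(m, cofactors)
        ]
        if not members:
            logger.warning("reaction %s has only cofactor members; skipped", rxn.reaction_id)
            continue
        if all(m in measured for m in members):
            kept.append(rxn)
    return kept


def ratio_per_sample(m: MetaboliteMatrix, pair: RedoxReaction) -> pd.Series:
    """abundance(oxidized, s) / abundance(reduced, s) for every sample."""
    for met in (pair.oxidized_metabolite, pair.reduced_metabolite):
        if met not in m.abundances.index:
            raise KeyError(f"metabolite {met!r} of pair {pair.pair_label} absent from matrix")
    ox = m.abundances.loc[pair.oxidized_metabolite]
    red = m.abundances.loc[pair.reduced_metabolite]
    return (ox / red).rename(pair.pair_label)


def ratio_shift_test(
    m: MetaboliteMatrix,
    pairs: Sequence[RedoxReaction],
    contrast: tuple,
) -> list[RedoxRatioResult]:
    """Directional shift of each couple's ratio between two groups.

    Direction is decided on group medians (drop when median_A < median_B);
    significance is a two-sided Mann-Whitney test BH-corrected across the
    pair family.  The summary statistic of interest downstream is the count
    of pairs whose ratio drops in group A.
    """
    group_a, group_b = contrast
    sa = m.group_samples(group_a)
    sb = m.group_samples(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each contrast group needs at least 2 samples")
    results = []
    for pair in pairs:
        ratios = ratio_per_sample(m, pair)
        va = ratios[sa].dropna().to_numpy()
        vb = ratios[sb].dropna().to_numpy()
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        if med_a < med_b:
            direction = "drop"
        elif med_a > med_b:
            direction = "rise"
        else:
            direction = "flat"
        _, p = mann_whitney(va, vb)
        results.append(
            RedoxRatioResult(pair.pair_label, ratios, med_a, med_b, direction, p)
        )
    if results:
        qs = bh_correct([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


def drop_count(results: Sequence[RedoxRatioResult]) -> int:
    """Number of couples whose ratio drops in the first contrast group."""
    return sum(r.direction == "drop" for r in results)


# ---------------------------------------------------------------------------
# Flat-TSV reaction network I/O

def load_reactions(path) -> list[RedoxReaction]:
    """Read a reaction network TSV.

    Columns: reaction_id, substrates, products (semicolon-separated lists),
    oxidized, reduced.  Reactions whose oxidized/reduced annotation does not
    resolve to a member are skipped with a warning rather than dropped
    silently.
    """
    df = pd.read_csv(path, sep="\t")
    reactions = []
    for _, row in df.iterrows():
        try:
            reactions.append(
                RedoxReaction(
                    reaction_id=str(row["reaction_id"]),
                    substrates=tuple(str(row["substrates"]).split(";")),
                    products=tuple(str(row["products"]).split(";")),
                    oxidized_metabolite=str(row["oxidized"]),
                    reduced_metabolite=str(row["reduced"]),
                )
            )
        except (ValueError, KeyError) as exc:
            logger.warning("skipping unparseable reaction row: %s", exc)
    return reactions


def example_reactions() -> list[RedoxReaction]:
    """The bundled hand-curated NAD(H) reaction network.

    A synthetic stand-in for a genome-scale reconstruction lookup: the five
    canonical measurable couples plus canonical NAD-dependent reactions
    whose central members (pyruvate, alpha-ketoglutarate, oxaloacetate,
    DHAP) are typically not quantified and act as negative controls.
    """
    ref = resources.files("renomics.data").joinpath("nad_reactions_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_reactions(path)
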