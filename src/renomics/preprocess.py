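"""Metabolite-matrix container, run-day normalization and minimum imputation.

Untargeted metabolomics platforms report relative ion counts whose scale
drifts between instrument run days.  The pipeline removes that drift by
median registration: within each run-day block every compound's observed
values are divided by the block median (registering the block median to
1.00), and each compound is then divided by its median across all samples.
Values below the detection limit are reported missing and, after
normalization, imputed with the lowest measured (normalized) abundance of
that compound.  Because all downstream statistics are rank-based, the
normalization mainly serves fold-change interpretation and visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("renomics")

__all__ = [
    "MetaboliteMatrix",
    "runday_normalize",
    "median_scale",
    "impute_min",
    "normalize_pipeline",
    "read_matrix",
    "write_matrix",
]


@dataclass
class MetaboliteMatrix:
    """Compounds x samples abundance matrix with sample annotations.

    Parameters
    ----------
    abundances
        DataFrame indexed by compound id, columns are sample ids.
        Missing (below detection) entries are NaN; observed entries are
        non-negative relative ion counts.
    sample_groups
        Series mapping sample id -> group label (e.g. CCPAP, ccRCC, NORMAL).
    rundays
        Series mapping sample id -> run-day block id.
    normalized
        State flag: True once run-day and median normalization have run.
    flagged_compounds
        Compounds that could not be normalized in at least one block
        (fully missing there) or were dropped at imputation.
    """

    abundances: pd.DataFrame
    sample_groups: pd.Series
    rundays: pd.Series
    normalized: bool = False
    flagged_compounds: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.abundances = self.abundances.astype(float)
        self.sample_groups = pd.Series(self.sample_groups)
        self.rundays = pd.Series(self.rundays)
        if not self.abundances.index.is_unique:
            raise ValueError("compound ids must be unique")
        missing_ann = [
            s
            for s in self.abundances.columns
            if s not in self.sample_groups.index or s not in self.rundays.index
        ]
        if missing_ann:
            raise ValueError(f"samples lack group/run-day annotation: {missing_ann}")
        with np.errstate(invalid="ignore"):
            if (self.abundances.to_numpy() < 0).any():
                raise ValueError("negative abundances are not allowed")

    @property
    def samples(self) -> list:
        return list(self.abundances.columns)

    @property
    def compounds(self) -> list:
        return list(self.abundances.index)

    def group_samples(self, group: str) -> list:
        sel = self.sample_groups[self.sample_groups == group]
        return [s for s in self.abundances.columns if s in sel.index]

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.abundances.copy(),
            self.sample_groups.copy(),
            self.rundays.copy(),
            self.normalized,
            set(self.flagged_compounds),
        )


def runday_normalize(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Register each compound's median to 1.00 within every run-day block.

    Observed values of a compound within a block are divided by the block
    median of that compound; missing values are untouched.  A compound with
    no observed value in some block cannot be registered there: it is left
    undivided in that block and flagged.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    out = m.copy()
    ab = out.abundances
    for day in sorted(out.rundays.unique()):
        cols = [s for s in ab.columns if out.rundays[s] == day]
        block = ab[cols]
        med = block.median(axis=1, skipna=True)
        empty = med.isna() | (med == 0)
        if empty.any():
            for c in med.index[empty]:
                out.flagged_compounds.add(c)
            logger.warning(
                "run-day %s: %d compound(s) fully missing or zero-median; left unregistered",
                day,
                int(empty.sum()),
            )
        med = med.where(~empty, 1.0)
        ab.loc[:, cols] = block.div(med, axis=0)
    return out


def median_scale(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each compound by its median across all samples (median -> 1)."""
    out = m.copy()
    med = out.abundances.median(axis=1, skipna=True)
    empty = med.isna() | (med == 0)
    if empty.any():
        out.flagged_compounds.update(med.index[empty])
        logger.warning("%d compound(s) fully missing; left unscaled", int(empty.sum()))
    med = med.where(~empty, 1.0)
    out.abundances = out.abundances.div(med, axis=0)
    out.normalized = True
    return out


def impute_min(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace missing entries with the compound's lowest measured abundance.

    Compounds with no observed value at all cannot be imputed; they are
    dropped from the matrix and logged.
    """
    out = m.copy()
    ab = out.abundances
    row_min = ab.min(axis=1, skipna=True)
    dead = row_min.isna()
    if dead.any():
        dropped = list(ab.index[dead])
        logger.warning("dropping %d fully-missing compound(s): %s", len(dropped), dropped)
        out.flagged_compounds.update(dropped)
        ab = ab.loc[~dead]
        row_min = row_min.loc[~dead]
    out.abundances = ab.T.fillna(row_min).T
    return out


def normalize_pipeline(m: MetaboliteMatrix, already_normalized: bool = False) -> MetaboliteMatrix:
    """Full preprocessing: run-day registration, median scaling, imputation.

    ``already_normalized`` skips the two normalization steps for matrices
    published post-normalization, applying only minimum imputation.
    """
    if already_normalized:
        out = m.copy()
        out.normalized = True
        return impute_min(out)
    return impute_min(median_scale(runday_normalize(m)))


# ---------------------------------------------------------------------------
# TSV round-trip (matrix + sample-annotation sidecar)

def write_matrix(m: MetaboliteMatrix, matrix_path, annotations_path) -> None:
    m.abundances.rename_axis("compound").to_csv(matrix_path, sep="\t")
    ann = pd.DataFrame(
        {
            "sample": m.samples,
            "group": [m.sample_groups[s] for s in m.samples],
            "runday": [m.rundays[s] for s in m.samples],
        }
    )
    ann.to_csv(annotations_path, sep="\t", index=False)


def read_matrix(matrix_path, annotations_path, normalized: bool = False) -> MetaboliteMatrix:
    ab = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotations_path, sep="\t").set_index("sample")
    return MetaboliteMatrix(
        ab,
        ann["group"].astype(str),
        ann["runday"],
        normalized=normalized,
    )
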