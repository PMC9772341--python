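"""Positional association between alignment columns and activity labels.

For each alignment column a categories-by-2 contingency table (residue or
residue-class versus active/inactive) is tested with Pearson's chi-squared
test of independence, two-sided, without continuity correction.  Columns
gapped in more than 90% of sequences are removed beforehand.  Gaps at a
tested position form their own category by default (presence or absence of
an insertion is itself positional information); a drop-gaps mode is
available.  Raw p-values mirror the screening convention; a Bonferroni
column is reported alongside but never silently applied.

The residue-class grouping is the five-class scheme aliphatic
(AGVLIMCP), aromatic (FWYH), positive (RK), negative (DE), polar (NQST),
which partitions the 20 canonical residues exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .errors import ConfigError, EvaluationError
from .io import Alignment, CANONICAL_AA


def _load_chi2_classes() -> dict:
    with resources.files("petmine.data").joinpath("residue_classes.json").open() as fh:
        raw = json.load(fh)["chi2_classes"]
    classes = {name: set(members) for name, members in raw.items()}
    union = set().union(*classes.values())
    if union != set(CANONICAL_AA):
        raise ConfigError("chi-squared residue classes must cover the 20 residues")
    total = sum(len(v) for v in classes.values())
    if total != 20:
        raise ConfigError("chi-squared residue classes must be disjoint")
    return classes

CHI2_CLASSES = _load_chi2_classes()
_CLASS_OF = {aa: name for name, members in CHI2_CLASSES.items() for aa in members}


@dataclass
class PositionTestResult:
    column: int            # 1-based index in the filtered alignment
    original_column: int   # 1-based index in the unfiltered alignment
    table: dict            # category -> (active count, inactive count)
    chi2: float
    dof: int
    p: float
    grouping: str          # "amino_acid" | "residue_class"


@dataclass
class GapFilterResult:
    alignment: Alignment
    kept_columns: list     # 0-based original indices of retained columns
    n_removed: int
    n_retained: int


def filter_gap_columns(aln: Alignment, max_gap_fraction: float = 0.9) -> GapFilterResult:
    """Drop columns gapped in strictly more than ``max_gap_fraction`` of rows."""
    kept = []
    for j in range(aln.n_columns):
        gaps = aln.column(j).count("-")
        if gaps / aln.n_rows <= max_gap_fraction:
            kept.append(j)
    if not kept:
        warnings.warn("gap filtering removed every column")
        filtered = aln
    else:
        rows = ["".join(r[j] for j in kept) for r in aln.rows]
        filtered = Alignment(aln.ids, rows)
    return GapFilterResult(
        alignment=filtered if kept else None,
        kept_columns=kept,
        n_removed=aln.n_columns - len(kept),
        n_retained=len(kept),
    )


def _categorize(residue: str, grouping: str, drop_gaps: bool):
    if residue == "-":
        return None if drop_gaps else "gap"
    if grouping == "residue_class":
        return _CLASS_OF.get(residue, "other")
    return residue


def position_chi2(aln: Alignment, labels: dict, column: int,
                  grouping: str = "amino_acid", drop_gaps: bool = False,
                  min_expected: float = 0.0,
                  original_column: int | None = None) -> PositionTestResult:
    """Chi-squared independence test of one column against activity labels.

    ``labels`` maps every row id to "active"/"inactive" (or 1/0).  ``column``
    is 0-based.  Categories with zero total are dropped before computing the
    degrees of freedom; a single observed category yields statistic 0, p 1.
    When ``min_expected`` > 0 a warning is raised if any expected count
    falls below it (the test is still computed).
    """
    if grouping not in ("amino_acid", "residue_class"):
        raise ConfigError(f"unknown grouping {grouping!r}")
    missing = [i for i in aln.ids if i not in labels]
    if missing:
        raise EvaluationError(f"labels missing for rows: {missing[:5]}")
    counts: dict[str, list] = {}
    for i, row in zip(aln.ids, aln.rows):
        cat = _categorize(row[column], grouping, drop_gaps)
        if cat is None:
            continue
        lab = labels[i]
        active = lab in (1, "1", "active", True)
        if cat not in counts:
            counts[cat] = [0, 0]
        counts[cat][0 if active else 1] += 1

    table = {c: tuple(v) for c, v in sorted(counts.items())}
    obs = np.array([v for v in counts.values()], dtype=float)
    obs = obs[obs.sum(axis=1) > 0]
    col_tot = obs.sum(axis=0)
    obs = obs[:, col_tot > 0] if obs.size else obs
    n_rows_t = obs.shape[0]
    n_cols_t = obs.shape[1] if obs.size else 0
    if n_rows_t < 2 or n_cols_t < 2:
        chi2_stat, dof, p = 0.0, 0, 1.0
    else:
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        if min_expected > 0 and np.any(expected < min_expected):
            warnings.warn(
                f"column {column}: expected count below {min_expected}; "
                "chi-squared approximation may be poor"
            )
        chi2_stat = float(((obs - expected) ** 2 / expected).sum())
        dof = (n_rows_t - 1) * (n_cols_t - 1)
        p = float(chi2_dist.sf(chi2_stat, dof))
    return PositionTestResult(
        column=column + 1,
        original_column=(original_column if original_column is not None else column) + 1,
        table=table,
        chi2=chi2_stat,
        dof=dof,
        p=p,
        grouping=grouping,
    )


def scan_alignment(aln: Alignment, labels: dict, grouping: str = "amino_acid",
                   alpha: float = 0.01, max_gap_fraction: float = 0.9,
                   drop_gaps: bool = False):
    """Gap-filter then chi-squared test every column.

    Returns ``(results, significant)`` where results is the ordered list of
    :class:`PositionTestResult` (with a Bonferroni-adjusted p available as
    ``p * n_tests`` capped at 1 through :func:`bonferroni`) and significant
    is the list of filtered-alignment 1-based positions with raw p < alpha.
    """
    filt = filter_gap_columns(aln, max_gap_fraction)
    if filt.n_retained == 0:
        return [], []
    results = [
        position_chi2(filt.alignment, labels, j, grouping, drop_gaps,
                      original_column=filt.kept_columns[j])
        for j in range(filt.alignment.n_columns)
    ]
    significant = [r.column for r in results if r.p < alpha]
    return results, significant


def bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)
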