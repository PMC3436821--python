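"""Count matrices, pairing designs and per-feature 2x2 contingency tables.

A paired count experiment is a features x samples matrix of non-negative
integer counts together with a pairing design that links each subject's
"before" sample to its "after" sample.  For one feature and one subject the
data form a 2x2 contingency table: the feature's count before and after
treatment, against all remaining counts in each sample, with the per-sample
totals as column margins.  The statistical machinery consumes one
:class:`FeaturePairSet` (the N tables of a single feature) at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairedCountTable",
    "FeaturePairSet",
    "CountMatrix",
    "PairingDesign",
    "read_count_matrix",
    "read_design",
    "build_pair_sets",
    "normalize_for_display",
    "observed_fold_change",
    "write_results",
]

#: default pseudo-count applied when displaying ratios of possibly-zero counts
DEFAULT_CORRECTION = 0.5


@dataclass(frozen=True)
class PairedCountTable:
    """One feature's 2x2 contingency table for a single subject.

    ``before``/``after`` are the feature's counts in the two conditions;
    ``total_before``/``total_after`` are the total sample counts (the column
    margins).  The complementary cells (all other features) are derived.
    """

    before: int
    after: int
    total_before: int
    total_after: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.before < 0 or self.after < 0:
            raise ValueError("counts must be non-negative")
        if self.total_before <= 0 or self.total_after <= 0:
            raise ValueError("sample totals must be positive")
        if self.before > self.total_before or self.after > self.total_after:
            raise ValueError(
                f"count exceeds its sample total for subject {self.subject_id!r}"
            )

    @property
    def others_before(self) -> int:
        """Count of all other features in the before sample."""
        return self.total_before - self.before

    @property
    def others_after(self) -> int:
        """Count of all other features in the after sample."""
        return self.total_after - self.after

    def swapped(self) -> "PairedCountTable":
        """The same table with the two conditions exchanged."""
        return PairedCountTable(
            self.after, self.before, self.total_after, self.total_before, self.subject_id
        )


@dataclass(frozen=True)
class FeaturePairSet:
    """The N paired tables of one feature; the unit the test consumes."""

    feature_id: str
    pairs: tuple[PairedCountTable, ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("a FeaturePairSet needs at least one pair")
        object.__setattr__(self, "pairs", tuple(self.pairs))
        ids = [p.subject_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate subject ids in feature {self.feature_id!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Counts and totals as four aligned arrays (before, after, totals)."""
        a = np.array([p.before for p in self.pairs], dtype=float)
        b = np.array([p.after for p in self.pairs], dtype=float)
        ta = np.array([p.total_before for p in self.pairs], dtype=float)
        tb = np.array([p.total_after for p in self.pairs], dtype=float)
        return a, b, ta, tb

    def swapped(self) -> "FeaturePairSet":
        return FeaturePairSet(self.feature_id, tuple(p.swapped() for p in self.pairs))


@dataclass
class CountMatrix:
    """A features x samples grid of non-negative integer counts.

    ``totals`` defaults to the column sums; an externally supplied vector may
    exceed them (e.g. when the matrix was filtered after counting) but must
    cover every single cell.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    totals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match feature/sample ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.totals = np.asarray(self.totals, dtype=np.int64)
            if self.totals.shape != (len(self.sample_ids),):
                raise ValueError("totals must have one entry per sample")
            if np.any(self.totals <= 0):
                raise ValueError("sample totals must be positive")
            colmax = self.counts.max(axis=0, initial=0)
            if np.any(self.totals < colmax):
                raise ValueError("a supplied total is smaller than a cell count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


@dataclass
class PairingDesign:
    """Maps samples to (subject, condition) with condition in {before, after}."""

    rows: list[tuple[str, str, str]]

    CONDITIONS = ("before", "after")

    def __post_init__(self) -> None:
        for sample, subject, cond in self.rows:
            if cond not in self.CONDITIONS:
                raise ValueError(
                    f"condition {cond!r} for sample {sample!r} is not one of {self.CONDITIONS}"
                )
        per_subject: dict[str, dict[str, str]] = {}
        for sample, subject, cond in self.rows:
            slots = per_subject.setdefault(subject, {})
            if cond in slots:
                raise ValueError(f"subject {subject!r} has more than one {cond!r} sample")
            slots[cond] = sample
        for subject, slots in per_subject.items():
            missing = set(self.CONDITIONS) - set(slots)
            if missing:
                raise ValueError(f"subject {subject!r} is missing a {missing.pop()!r} sample")
        self._per_subject = per_subject

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for _, subject, _ in self.rows:
            if subject not in seen:
                seen.append(subject)
        return seen

    def samples_for(self, subject: str) -> tuple[str, str]:
        slots = self._per_subject[subject]
        return slots["before"], slots["after"]

    def validate_against(self, matrix: CountMatrix) -> None:
        known = set(matrix.sample_ids)
        for sample, subject, _ in self.rows:
            if sample not in known:
                raise ValueError(
                    f"design references sample {sample!r} absent from the count matrix"
                )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_count_matrix(path: str | Path, totals_path: str | Path | None = None) -> CountMatrix:
    """Read a TSV/CSV count matrix (header = sample ids, first column = feature ids).

    An optional two-column totals file (sample_id, total) overrides the
    default column-sum totals.
    """
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need a feature-id column plus at least one sample")
    feature_ids = raw.iloc[:, 0].astype(str).tolist()
    sample_ids = [str(c) for c in raw.columns[1:]]
    if len(set(feature_ids)) != len(feature_ids):
        dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
        raise ValueError(f"{path}: duplicate feature id(s) {dupes}")
    counts = np.empty((len(feature_ids), len(sample_ids)), dtype=np.int64)
    for j, col in enumerate(raw.columns[1:]):
        for i, cell in enumerate(raw[col]):
            try:
                value = int(str(cell))
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer count {cell!r} at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"{path}: negative count {value} at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                )
            counts[i, j] = value
    totals = None
    if totals_path is not None:
        tdf = _read_table(totals_path)
        mapping = dict(zip(tdf.iloc[:, 0].astype(str), tdf.iloc[:, 1]))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"{totals_path}: no total for sample(s) {missing}")
        totals = np.array([int(mapping[s]) for s in sample_ids], dtype=np.int64)
    return CountMatrix(feature_ids, sample_ids, counts, totals)


def read_design(path: str | Path) -> PairingDesign:
    """Read a 3-column TSV/CSV design file: sample_id, subject_id, condition."""
    raw = _read_table(path)
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: design needs columns sample_id, subject_id, condition")
    rows = [
        (str(s), str(g), str(c).strip().lower())
        for s, g, c in zip(raw.iloc[:, 0], raw.iloc[:, 1], raw.iloc[:, 2])
    ]
    return PairingDesign(rows)


def build_pair_sets(matrix: CountMatrix, design: PairingDesign) -> list[FeaturePairSet]:
    """One :class:`FeaturePairSet` per matrix feature, ordered as the matrix."""
    design.validate_against(matrix)
    subjects = design.subjects
    cols = [
        (matrix.column(b), matrix.column(a))
        for b, a in (design.samples_for(s) for s in subjects)
    ]
    out = []
    for i, fid in enumerate(matrix.feature_ids):
        pairs = tuple(
            PairedCountTable(
                before=int(matrix.counts[i, jb]),
                after=int(matrix.counts[i, ja]),
                total_before=int(matrix.totals[jb]),
                total_after=int(matrix.totals[ja]),
                subject_id=subject,
            )
            for subject, (jb, ja) in zip(subjects, cols)
        )
        out.append(FeaturePairSet(fid, pairs))
    return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_for_display(matrix: CountMatrix) -> CountMatrix:
    """Scale every column to the mean total count and round.

    Display convenience only: the test itself always works on raw counts and
    raw totals, so this function must never feed the inference path.
    """
    mean_total = float(matrix.totals.mean())
    scaled = matrix.counts * (mean_total / matrix.totals.astype(float))[None, :]
    rounded = _round_half_away(scaled).astype(np.int64)
    common = int(_round_half_away(np.array([mean_total]))[0])
    common = max(common, int(rounded.max(initial=0)))
    totals = np.full(len(matrix.sample_ids), common, dtype=np.int64)
    return CountMatrix(list(matrix.feature_ids), list(matrix.sample_ids), rounded, totals)


def observed_fold_change(table: PairedCountTable, correction: float = 0.0) -> float:
    """Observed fold change (before/after) of normalized fractions.

    ``correction`` is a pseudo-count added to both counts; with zero
    correction both counts must be positive.
    """
    if correction < 0:
        raise ValueError("correction must be non-negative")
    if correction == 0 and (table.before == 0 or table.after == 0):
        raise ZeroDivisionError(
            "fold change undefined for zero counts without a correction term"
        )
    num = (table.before + correction) / table.total_before
    den = (table.after + correction) / table.total_after
    return num / den


def write_results(results: Sequence, path: str | Path) -> None:
    """Write test results as a TSV, preserving input order.

    Columns: feature_id, fold_change, log2_fold_change, statistic_S, p_value,
    p_adjusted, alpha_hat, beta_hat, converged.
    """
    if len(results) == 0:
        raise ValueError("no results to write")
    rows = []
    for r in results:
        fc = r.fold_change
        rows.append(
            {
                "feature_id": r.feature_id,
                "fold_change": fc,
                "log2_fold_change": np.log2(fc) if fc > 0 else np.nan,
                "statistic_S": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "alpha_hat": r.alpha_hat,
                "beta_hat": r.beta_hat,
                "converged": r.converged,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
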