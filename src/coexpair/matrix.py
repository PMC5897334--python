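"""Expression-matrix container, delimited-table I/O and panel preprocessing.

The central object is :class:`ExpressionMatrix`: a features × samples table of
normalized log-scale expression values (for RT-qPCR panels these derive from Ct
values) together with an explicit boolean missingness mask.  Non-detections in
qPCR panels appear as missing cells, so missingness is carried as first-class
state rather than encoded in a magic value: a cell flagged missing carries no
interpretable payload and every operation in this package ignores it.

Preprocessing follows the conventions of paired RT-qPCR panel studies:

* ``filter_missing`` drops features with *more than* a threshold of missing
  cells (strictly more-than: a feature exactly at the threshold is retained);
* ``filter_detection`` keeps features detected in strictly more than a given
  fraction of samples;
* ``impute_feature_mean`` replaces each remaining missing cell with the mean
  of the feature's observed values.

Normalization and batch correction are out of scope: the matrix is assumed to
hold already-normalized values on some monotone log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "PreprocessConfig",
    "load_matrix",
    "write_matrix",
    "load_metadata",
    "write_metadata",
    "filter_missing",
    "filter_detection",
    "impute_feature_mean",
]

#: Fraction of samples that may be missing before a feature is dropped, in the
#: default paired-panel configuration: 12 missing out of 22 samples is the
#: largest count retained (strict "more than 12" removal at n = 22).
DEFAULT_MAX_MISSING_FRACTION = 12.0 / 22.0

#: Default detection filter: a feature must be detected (non-missing) in
#: strictly more than this fraction of samples.
DEFAULT_DETECTION_FRACTION = 0.6

_FLOAT_SLOP = 1e-9  # guards strict > comparisons on fraction * n products


@dataclass(frozen=True)
class ExpressionMatrix:
    """Features × samples expression values with an explicit missingness mask.

    Parameters
    ----------
    features
        Ordered, unique feature (miRNA) identifiers; length F.
    samples
        Ordered, unique sample identifiers; length S.
    values
        ``(F, S)`` float array of normalized log-scale expression.  Cells
        flagged in ``missing_mask`` carry no meaning (they are stored as NaN).
    missing_mask
        ``(F, S)`` boolean array, ``True`` where no value was detected.
    """

    features: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(str(f) for f in self.features))
        object.__setattr__(self, "samples", tuple(str(s) for s in self.samples))
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.missing_mask, dtype=bool)
        shape = (len(self.features), len(self.samples))
        if values.shape != shape:
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if mask.shape != shape:
            raise ValueError(
                f"missing_mask shape {mask.shape} does not match values shape {shape}"
            )
        for kind, ids in (("feature", self.features), ("sample", self.samples)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {kind} identifier(s): {sorted(dupes)}")
        # masked cells carry no payload; normalize them to NaN so accidental
        # use surfaces immediately
        values = values.copy()
        values[mask] = np.nan
        if np.isnan(values[~mask]).any():
            bad = np.argwhere(np.isnan(values) & ~mask)[0]
            raise ValueError(
                f"NaN value in unmasked cell (feature {self.features[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r}); mark it missing instead"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing_mask", mask.copy())
        self.values.setflags(write=False)
        self.missing_mask.setflags(write=False)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def missing_counts(self) -> np.ndarray:
        """Number of missing cells per feature, shape (F,)."""
        return self.missing_mask.sum(axis=1)

    def detection_counts(self) -> np.ndarray:
        """Number of detected (non-missing) cells per feature, shape (F,)."""
        return (~self.missing_mask).sum(axis=1)

    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def subset_features(self, keep: Sequence[bool] | np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep, dtype=bool)
        return ExpressionMatrix(
            features=tuple(f for f, k in zip(self.features, keep) if k),
            samples=self.samples,
            values=self.values[keep],
            missing_mask=self.missing_mask[keep],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            features=self.features,
            samples=tuple(sample_ids),
            values=self.values[:, cols],
            missing_mask=self.missing_mask[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame (missing cells as NaN)."""
        return pd.DataFrame(self.values, index=list(self.features), columns=list(self.samples))


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design information: subject membership and condition label.

    For a paired design every subject has exactly one sample per timepoint
    condition (e.g. ``baseline`` and ``week4``); for a cross-sectional design
    the condition is a group label (e.g. ``smoker`` / ``never-smoker``).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "condition")

    def __post_init__(self) -> None:
        table = pd.DataFrame(self.table)
        missing_cols = [c for c in self.REQUIRED if c not in table.columns]
        if missing_cols:
            raise ValueError(f"metadata missing required column(s): {missing_cols}")
        table = table.loc[:, list(self.REQUIRED)].astype(str).reset_index(drop=True)
        dupes = _duplicates(table["sample_id"])
        if dupes:
            raise ValueError(f"duplicate sample_id(s) in metadata: {sorted(dupes)}")
        object.__setattr__(self, "table", table)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table["sample_id"])

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted(self.table["condition"].unique()))

    def samples_for(self, condition: str) -> tuple[str, ...]:
        sub = self.table[self.table["condition"] == condition]
        return tuple(sub["sample_id"])

    def condition_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample id: {sample_id!r}")
        return str(row["condition"].iloc[0])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Require metadata samples and matrix samples to coincide exactly."""
        meta_ids = set(self.sample_ids)
        mat_ids = set(matrix.samples)
        only_meta = sorted(meta_ids - mat_ids)
        only_mat = sorted(mat_ids - meta_ids)
        if only_meta or only_mat:
            raise ValueError(
                "metadata and matrix sample sets differ: "
                f"only in metadata {only_meta}, only in matrix {only_mat}"
            )

    def paired_subjects(self, baseline: str, followup: str) -> list[tuple[str, str, str]]:
        """Return (subject, baseline_sample, followup_sample) for every subject.

        Raises ``ValueError`` listing any subject without exactly one sample at
        each of the two timepoints.
        """
        table = self.table[self.table["condition"].isin([baseline, followup])]
        bad: list[str] = []
        out: list[tuple[str, str, str]] = []
        for subject, grp in table.groupby("subject_id", sort=True):
            by_cond = {c: list(g["sample_id"]) for c, g in grp.groupby("condition")}
            b = by_cond.get(baseline, [])
            f = by_cond.get(followup, [])
            if len(b) == 1 and len(f) == 1:
                out.append((str(subject), b[0], f[0]))
            else:
                bad.append(str(subject))
        if bad:
            raise ValueError(
                f"subject(s) without exactly one sample per timepoint "
                f"({baseline!r}, {followup!r}): {bad}"
            )
        if not out:
            raise ValueError(f"no subjects with both conditions {baseline!r} and {followup!r}")
        return out


@dataclass(frozen=True)
class PreprocessConfig:
    """Thresholds for the missingness and detection filters.

    Exactly one of ``max_missing_count`` (absolute) and
    ``max_missing_fraction`` (relative) is active.  With neither given, the
    fraction mode defaults to 12/22 — which reproduces the absolute
    "more than 12 missing of 22 samples" rule on a 22-sample paired panel and
    scales proportionally to other sample counts.
    """

    max_missing_count: int | None = None
    max_missing_fraction: float | None = None
    detection_fraction: float = DEFAULT_DETECTION_FRACTION

    def __post_init__(self) -> None:
        if self.max_missing_count is not None and self.max_missing_fraction is not None:
            raise ValueError("give max_missing_count or max_missing_fraction, not both")
        if self.max_missing_count is None and self.max_missing_fraction is None:
            object.__setattr__(self, "max_missing_fraction", DEFAULT_MAX_MISSING_FRACTION)
        if self.max_missing_count is not None and self.max_missing_count < 0:
            raise ValueError("max_missing_count must be >= 0")
        if self.max_missing_fraction is not None and not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not 0.0 <= self.detection_fraction <= 1.0:
            raise ValueError("detection_fraction must be in [0, 1]")

    def missing_threshold(self, n_samples: int) -> float:
        """Largest missing count retained (features strictly above are removed)."""
        if self.max_missing_count is not None:
            return float(self.max_missing_count)
        return self.max_missing_fraction * n_samples + _FLOAT_SLOP


def _duplicates(ids) -> set:
    seen: set = set()
    dupes: set = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def load_matrix(
    path: str | Path,
    sep: str | None = None,
    missing_sentinels: Sequence[str] = ("", "NA"),
) -> ExpressionMatrix:
    """Read a features × samples expression table.

    The first column holds feature identifiers, the header row sample
    identifiers.  Empty cells or any of ``missing_sentinels`` denote missing
    values.  The delimiter is inferred from the extension (``.tsv``/``.tab``/
    ``.txt`` → tab, otherwise comma) unless ``sep`` is given.

    Raises
    ------
    ValueError
        On duplicate feature or sample identifiers (naming the duplicate) and
        on non-numeric, non-sentinel cells (with row/column coordinates).
    """
    path = Path(path)
    sep = _infer_sep(path, sep)
    raw = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    features = [str(f) for f in raw.index]
    samples = [str(s) for s in raw.columns]
    sentinels = {s.strip() for s in missing_sentinels}
    values = np.empty(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    cells = raw.to_numpy(dtype=object)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(cells[i, j]).strip()
            if cell in sentinels:
                mask[i, j] = True
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at feature {features[i]!r} "
                    f"(row {i + 2}), sample {samples[j]!r} (column {j + 2}) in {path}"
                ) from None
    return ExpressionMatrix(features=features, samples=samples, values=values, missing_mask=mask)


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    sep: str | None = None,
    missing_sentinel: str = "NA",
) -> None:
    """Write the matrix as a delimited table; missing cells as ``missing_sentinel``.

    Values are written with ``repr``-level precision so that a
    ``load_matrix(write_matrix(...))`` round trip reproduces values and mask
    bit-exactly.
    """
    path = Path(path)
    sep = _infer_sep(path, sep)
    with open(path, "w") as fh:
        fh.write("feature" + sep + sep.join(matrix.samples) + "\n")
        for i, feat in enumerate(matrix.features):
            cells = [
                missing_sentinel if matrix.missing_mask[i, j] else repr(float(matrix.values[i, j]))
                for j in range(matrix.n_samples)
            ]
            fh.write(feat + sep + sep.join(cells) + "\n")


def load_metadata(path: str | Path, sep: str | None = None) -> SampleMetadata:
    """Read a sample metadata table with columns sample_id, subject_id, condition."""
    path = Path(path)
    return SampleMetadata(pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str))


def write_metadata(meta: SampleMetadata, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    meta.table.to_csv(path, sep=_infer_sep(path, sep), index=False)


def filter_missing(matrix: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Drop features with strictly more missing cells than the threshold.

    A feature exactly at the threshold (e.g. 12 missing of 22 at the default)
    is retained.  Sample set and feature order are unchanged.  A threshold at
    or above the sample count makes the filter a no-op (warned).
    """
    cfg = cfg or PreprocessConfig()
    threshold = cfg.missing_threshold(matrix.n_samples)
    if threshold >= matrix.n_samples:
        warnings.warn(
            f"missingness threshold {threshold:g} >= sample count {matrix.n_samples}; "
            "filter is a no-op",
            stacklevel=2,
        )
        return matrix
    keep = matrix.missing_counts() <= threshold
    return matrix.subset_features(keep)


def filter_detection(matrix: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Keep features detected in strictly more than ``detection_fraction`` of samples."""
    cfg = cfg or PreprocessConfig()
    keep = matrix.detection_counts() > cfg.detection_fraction * matrix.n_samples + _FLOAT_SLOP
    return matrix.subset_features(keep)


def impute_feature_mean(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each missing cell with its feature's mean over observed cells.

    Observed cells are untouched (bit-exact); the output mask is all-false.

    Raises
    ------
    ValueError
        If any feature has no observed value at all — run ``filter_missing``
        (or drop such features) first.
    """
    if matrix.is_complete():
        return matrix
    detected = matrix.detection_counts()
    if (detected == 0).any():
        bad = [f for f, d in zip(matrix.features, detected) if d == 0]
        raise ValueError(
            f"feature(s) with all values missing: {bad}; run filter_missing first"
        )
    values = matrix.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(np.where(matrix.missing_mask, np.nan, values), axis=1)
    rows, cols = np.nonzero(matrix.missing_mask)
    values[rows, cols] = means[rows]
    return ExpressionMatrix(
        features=matrix.features,
        samples=matrix.samples,
        values=values,
        missing_mask=np.zeros_like(matrix.missing_mask),
    )
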