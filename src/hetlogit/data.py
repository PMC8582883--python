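"""Crash-record containers, validation and CSV I/O.

A crash dataset holds one row per crash: a four-level injury-severity
outcome and a set of binary (0/1) indicator covariates.  Severity is coded

====  ===========  ================================================
code  label        meaning
====  ===========  ================================================
1     no_injury    property damage only (the baseline category)
2     minor        visible but non-incapacitating injury
3     severe       incapacitating injury
4     fatal        injury leading to death
====  ===========  ================================================

CSV files are comma-separated UTF-8 with a mandatory header row.  The
outcome column may contain either the integer codes 1–4 or the canonical
labels above.  Missing values are rejected, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SEVERITY_CODES: tuple[int, ...] = (1, 2, 3, 4)
SEVERITY_LABELS: dict[int, str] = {
    1: "no_injury",
    2: "minor",
    3: "severe",
    4: "fatal",
}
LABEL_TO_CODE: dict[str, int] = {v: k for k, v in SEVERITY_LABELS.items()}


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A cell value violates the data contract (non-binary covariate,
    unknown outcome label, missing value)."""


def _parse_outcome(values: pd.Series) -> np.ndarray:
    """Map an outcome column (codes or labels) to integer codes 1–4."""
    out = np.empty(len(values), dtype=np.int64)
    for pos, (idx, v) in enumerate(values.items()):
        if pd.isna(v):
            raise ValidationError(f"missing outcome value in row {idx!r}")
        if isinstance(v, str):
            s = v.strip()
            if s in LABEL_TO_CODE:
                out[pos] = LABEL_TO_CODE[s]
                continue
            try:
                code = int(s)
            except ValueError:
                raise ValidationError(
                    f"unknown outcome label {v!r} in row {idx!r}"
                ) from None
        else:
            f = float(v)
            if not f.is_integer():
                raise ValidationError(f"unknown outcome value {v!r} in row {idx!r}")
            code = int(f)
        if code not in SEVERITY_CODES:
            raise ValidationError(f"unknown outcome code {code} in row {idx!r}")
        out[pos] = code
    return out


@dataclass(frozen=True)
class CrashDataset:
    """An estimation sample: outcomes plus a binary design matrix.

    Parameters
    ----------
    outcome : ndarray of int
        Severity codes in {1, 2, 3, 4}, one per crash, in file order.
    covariates : DataFrame
        Binary indicator columns, one row per crash.  All values 0/1.
    ids : ndarray of str
        Opaque per-crash identifiers (row numbers if the file has none).
    """

    outcome: np.ndarray
    covariates: pd.DataFrame
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if len(self.outcome) == 0:
            raise ValidationError("dataset must contain at least one crash")
        if len(self.outcome) != len(self.covariates):
            raise ValidationError("outcome and covariates differ in length")
        if self.ids is None:
            object.__setattr__(
                self, "ids", np.array([str(i) for i in range(len(self.outcome))])
            )
        bad = ~np.isin(self.outcome, SEVERITY_CODES)
        if bad.any():
            raise ValidationError(
                f"outcome codes outside 1–4 at rows {list(np.where(bad)[0][:5])}"
            )
        for name in self.covariates.columns:
            col = self.covariates[name]
            if col.isna().any():
                row = self.ids[int(np.where(col.isna())[0][0])]
                raise ValidationError(f"missing value in covariate {name!r}, row {row}")
            vals = col.to_numpy()
            ok = np.isin(vals, (0, 1))
            if not ok.all():
                row = self.ids[int(np.where(~ok)[0][0])]
                raise ValidationError(
                    f"non-binary value {vals[~ok][0]!r} in covariate {name!r}, row {row}"
                )

    @property
    def n(self) -> int:
        return len(self.outcome)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def severity_counts(self) -> dict[int, int]:
        """Crash count per severity code (all four codes always present)."""
        return {c: int(np.sum(self.outcome == c)) for c in SEVERITY_CODES}

    def covariate_array(self, name: str) -> np.ndarray:
        return self.covariates[name].to_numpy(dtype=np.float64)

    def subset(self, mask: np.ndarray) -> "CrashDataset":
        """Row subset (boolean mask or integer index), order preserved."""
        return CrashDataset(
            outcome=self.outcome[mask],
            covariates=self.covariates.iloc[mask].reset_index(drop=True),
            ids=self.ids[mask],
        )

    def with_covariate_set(self, name: str, value: int) -> "CrashDataset":
        """Counterfactual copy with covariate ``name`` set to ``value`` for
        every crash (used for discrete-change marginal effects)."""
        cov = self.covariates.copy()
        cov[name] = value
        return CrashDataset(outcome=self.outcome, covariates=cov, ids=self.ids)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: Sequence[str],
        outcome: str = "severity",
        id_column: str | None = None,
    ) -> "CrashDataset":
        missing = [c for c in [outcome, *covariates] if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {missing}")
        ids = (
            df[id_column].astype(str).to_numpy()
            if id_column is not None and id_column in df.columns
            else np.array([str(i) for i in df.index])
        )
        cov = df.loc[:, list(covariates)].copy()
        for name in cov.columns:
            if cov[name].isna().any():
                row = ids[int(np.where(cov[name].isna())[0][0])]
                raise ValidationError(f"missing value in covariate {name!r}, row {row}")
            try:
                as_float = cov[name].astype(float)
            except (TypeError, ValueError):
                bad = cov[name].iloc[0]
                raise ValidationError(
                    f"non-numeric value {bad!r} in covariate {name!r}"
                ) from None
            if not np.isin(as_float.to_numpy(), (0.0, 1.0)).all():
                bad_ix = int(np.where(~np.isin(as_float.to_numpy(), (0.0, 1.0)))[0][0])
                raise ValidationError(
                    f"non-binary value {cov[name].iloc[bad_ix]!r} in covariate "
                    f"{name!r}, row {ids[bad_ix]}"
                )
            cov[name] = as_float.astype(np.int64)
        return cls(
            outcome=_parse_outcome(df[outcome]),
            covariates=cov.reset_index(drop=True),
            ids=ids,
        )


def read_crash_csv(
    path: str | Path,
    covariates: Sequence[str],
    outcome: str = "severity",
    id_column: str | None = None,
) -> CrashDataset:
    """Read a crash CSV, keeping only the declared covariates.

    Raises :class:`SchemaError` when a declared column is absent and
    :class:`ValidationError` for non-binary covariate cells or unknown
    outcome labels, citing the offending row.
    """
    df = pd.read_csv(path)
    return CrashDataset.from_dataframe(df, covariates, outcome, id_column)


def write_crash_csv(dataset: CrashDataset, path: str | Path) -> None:
    """Write the dataset back to CSV (id, severity code, covariates)."""
    out = pd.DataFrame({"id": dataset.ids, "severity": dataset.outcome})
    for name in dataset.covariate_names:
        out[name] = dataset.covariates[name].to_numpy()
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class DescriptiveSummary:
    """Per-covariate proportions/SDs and per-severity counts.

    SDs use the population convention (divide by n): for a binary
    indicator this equals sqrt(p(1-p)), the convention under which a
    proportion of 0.91 pairs with an SD of 0.29.
    """

    covariate_stats: pd.DataFrame  # index covariate, columns mean, sd
    severity_counts: dict[int, int]
    n: int

    def to_csv(self, path: str | Path) -> None:
        out = self.covariate_stats.rename_axis("variable").reset_index()
        out.columns = ["variable", "mean", "sd"]
        out.to_csv(path, index=False)


def summarize(dataset: CrashDataset) -> DescriptiveSummary:
    """Descriptive statistics: covariate means/SDs and severity counts."""
    means = dataset.covariates.mean(axis=0)
    sds = dataset.covariates.std(axis=0, ddof=0)
    stats = pd.DataFrame({"mean": means, "sd": sds})
    return DescriptiveSummary(
        covariate_stats=stats,
        severity_counts=dataset.severity_counts(),
        n=dataset.n,
    )
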