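"""Core containers for qPCR cycle-threshold (Ct) data.

A :class:`CtMatrix` holds assay x sample Ct values in PCR cycles.  The
censored "Undetermined" state produced by the qPCR instrument (no
amplification within the run's cycle budget) is represented internally as
``NaN`` and round-trips through the on-disk tab-delimited format as the
token ``Undetermined``.  A :class:`SampleSheet` maps each sample to its
group (patient / control) and cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNDETERMINED_TOKEN = "Undetermined"

GROUP_PATIENT = "patient"
GROUP_CONTROL = "control"
VALID_GROUPS = (GROUP_PATIENT, GROUP_CONTROL)


class MirsigError(Exception):
    """Base error for this package."""


class ConfigurationError(MirsigError):
    """An invalid configuration was supplied."""


class ParseError(MirsigError):
    """A file could not be parsed."""


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ParseError(f"duplicate {what}: {dups}")


@dataclass
class CtMatrix:
    """Assays x samples matrix of Ct values (cycles); NaN = Undetermined."""

    values: pd.DataFrame
    spikein_assays: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (assays x samples)")
        _check_unique(self.values.index, "assay names")
        _check_unique(self.values.columns, "sample IDs")
        self.values = self.values.astype(float)
        finite = self.values.to_numpy()
        if np.any(finite[np.isfinite(finite)] < 0):
            raise ValueError("Ct values must be >= 0")
        if np.any(np.isinf(finite)):
            raise ValueError("Ct values must be finite or NaN (Undetermined)")
        self.spikein_assays = tuple(
            a for a in self.spikein_assays if a in self.values.index
        )

    @property
    def assay_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_undetermined(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy(), self.spikein_assays)

    def to_tsv(self, path) -> None:
        """Write the matrix with ``Undetermined`` tokens for censored cells."""
        out = self.values.map(
            lambda v: UNDETERMINED_TOKEN if pd.isna(v) else format(v, ".6g")
        )
        out.index.name = "assay"
        out.to_csv(path, sep="\t")


@dataclass
class SampleSheet:
    """Per-sample metadata: group, cohort and optional QC annotations."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        t = self.table
        if "sample_id" in t.columns:
            t = t.set_index("sample_id")
        _check_unique(t.index, "sample IDs")
        if "group" not in t.columns:
            raise ValueError("sample sheet requires a 'group' column")
        bad = set(t["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if "cohort" not in t.columns:
            t = t.assign(cohort="default")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def labels(self, sample_ids=None) -> np.ndarray:
        """Binary labels: patient = 1, control = 0."""
        g = self.groups if sample_ids is None else self.groups.loc[list(sample_ids)]
        return (g == GROUP_PATIENT).to_numpy(dtype=int)

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].copy())

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path)
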