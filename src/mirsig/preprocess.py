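"""Ct matrix ingestion, imputation, informativeness filtering and hemolysis QC.

The preprocessing conventions follow standard practice for TaqMan array-card
data: censored "Undetermined" wells are assigned Ct = 40 (the run's cycle
budget), assays with Ct above 33 cycles are treated as not expressed, and
sample-level hemolysis is screened with the miR-23a / miR-451 cycle
difference (miR-451 is red-blood-cell enriched, so hemolysis inflates the
difference).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CtMatrix, MirsigError, ParseError, SampleSheet, _check_unique

DEFAULT_UNDETERMINED_CT = 40.0
DEFAULT_CT_MAX = 33.0
HEMOLYSIS_DELTA_FAIL = 7.0
HEMOLYSIS_DELTA_WARN = 5.0

# Spike-in miRNAs carry non-human prefixes on TaqMan cards.
_SPIKEIN_PREFIXES = ("ath-", "cel-", "osa-")


@dataclass
class QcReport:
    """Per-sample and per-assay quality-control outcome."""

    sample_qc: pd.DataFrame | None = None
    n_imputed: int = 0
    assays_kept: list[str] = field(default_factory=list)
    assays_dropped: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "n_imputed": self.n_imputed,
            "n_assays_kept": len(self.assays_kept),
            "n_assays_dropped": len(self.assays_dropped),
            "assays_dropped": self.assays_dropped,
            "notes": self.notes,
        }
        if self.sample_qc is not None:
            payload["sample_qc"] = json.loads(
                self.sample_qc.to_json(orient="index")
            )
        Path(path).write_text(json.dumps(payload, indent=2))


def read_ct_matrix(path, sep: str = "\t", spikein_assays=None) -> CtMatrix:
    """Read a tab-delimited Ct matrix (first column assay names).

    Cells equal to ``Undetermined`` (case-insensitive) become the censored
    state; any other non-numeric token raises a :class:`ParseError` naming
    the offending assay and sample.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    _check_unique(raw.index, "assay names")
    _check_unique(raw.columns, "sample IDs")
    cleaned = raw.apply(lambda col: col.str.strip())
    undet = cleaned.apply(lambda col: col.str.lower() == "undetermined")
    numeric = cleaned.mask(undet).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~undet
    if bad.to_numpy().any():
        assay = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[assay]][0]
        raise ParseError(
            f"non-numeric Ct value {cleaned.loc[assay, sample]!r} "
            f"at assay {assay!r}, sample {sample!r}"
        )
    if spikein_assays is None:
        spikein_assays = tuple(
            a for a in numeric.index if str(a).lower().startswith(_SPIKEIN_PREFIXES)
        )
    return CtMatrix(numeric, tuple(spikein_assays))


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


def impute_undetermined(m: CtMatrix, value: float = DEFAULT_UNDETERMINED_CT) -> CtMatrix:
    """Replace every censored (Undetermined) entry with a fixed Ct value."""
    return CtMatrix(m.values.fillna(float(value)), m.spikein_assays)


def filter_informative(
    m: CtMatrix,
    ct_max: float = DEFAULT_CT_MAX,
    policy: str = "all",
    min_fraction: float = 0.5,
    per_group: bool = False,
    sheet: SampleSheet | None = None,
) -> tuple[CtMatrix, QcReport]:
    """Retain informative assays (Ct <= ct_max), drop the rest.

    policy "all" (default) keeps an assay only when every sample is at or
    below ``ct_max`` -- the "detected in all samples" convention.  policy
    "fraction" keeps assays detected in at least ``min_fraction`` of samples
    overall, or within at least one group when ``per_group`` is set.
    """
    ok = m.values.le(ct_max)  # NaN compares False: censored is uninformative
    if policy == "all":
        keep = ok.all(axis=1)
    elif policy == "fraction":
        if per_group:
            if sheet is None:
                raise ValueError("per_group fraction policy requires a sample sheet")
            frac = ok.T.groupby(sheet.groups.loc[ok.columns]).mean().T
            keep = frac.max(axis=1) >= min_fraction
        else:
            keep = ok.mean(axis=1) >= min_fraction
    else:
        raise ValueError(f"unknown informativeness policy {policy!r}")

    kept = m.values.index[keep]
    dropped = m.values.index[~keep]
    report = QcReport(
        assays_kept=list(kept),
        assays_dropped=list(dropped),
        notes=[f"informative filter: policy={policy}, ct_max={ct_max}"],
    )
    if len(kept) == 0:
        warnings.warn("informative filter removed every assay", stacklevel=2)
        report.notes.append("warning: no informative assays")
    filtered = CtMatrix(m.values.loc[keep].copy(), m.spikein_assays)
    return filtered, report


def hemolysis_qc(
    m: CtMatrix,
    marker_a: str = "miR-23a",
    marker_b: str = "miR-451",
    delta_max: float = HEMOLYSIS_DELTA_FAIL,
    delta_warn: float = HEMOLYSIS_DELTA_WARN,
) -> QcReport:
    """Per-sample hemolysis screen from the Ct(marker_a) - Ct(marker_b) delta.

    delta > delta_max fails the sample; delta in (delta_warn, delta_max] is
    flagged but passes.  A censored marker in a sample makes the delta
    undefined and the sample "inconclusive" (passes, surfaced in the report).
    """
    report = QcReport()
    if marker_a not in m.values.index or marker_b not in m.values.index:
        warnings.warn(
            f"hemolysis markers {marker_a!r}/{marker_b!r} not both present; "
            "skipping hemolysis QC",
            stacklevel=2,
        )
        report.notes.append("hemolysis QC skipped: markers missing")
        report.sample_qc = pd.DataFrame(
            {
                "hemolysis_delta": np.nan,
                "status": "not_assessed",
                "qc_pass": True,
            },
            index=m.values.columns,
        )
        return report

    delta = m.values.loc[marker_a] - m.values.loc[marker_b]
    status = pd.Series("pass", index=m.values.columns)
    status[delta > delta_warn] = "warn"
    status[delta > delta_max] = "fail"
    status[delta.isna()] = "inconclusive"
    report.sample_qc = pd.DataFrame(
        {
            "hemolysis_delta": delta,
            "status": status,
            "qc_pass": status != "fail",
        }
    )
    n_fail = int((status == "fail").sum())
    if n_fail:
        report.notes.append(f"hemolysis QC: {n_fail} sample(s) failed")
    return report


def apply_sample_qc(
    m: CtMatrix, sheet: SampleSheet, qc: QcReport
) -> tuple[CtMatrix, SampleSheet]:
    """Drop QC-failed samples from the matrix and sheet (column order kept)."""
    if qc.sample_qc is None:
        return m, sheet
    passing = [s for s in m.sample_ids if bool(qc.sample_qc.loc[s, "qc_pass"])]
    if not passing:
        raise MirsigError("every sample failed QC")
    return (
        CtMatrix(m.values[passing].copy(), m.spikein_assays),
        sheet.subset(passing),
    )
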