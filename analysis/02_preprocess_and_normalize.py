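#!/usr/bin/env python
"""Quality control and normalization-method selection on the discovery cohort.

Applies the hemolysis screen (miR-23a minus miR-451 cycle difference),
assigns Ct = 40 to Undetermined wells, keeps assays informative (Ct <= 33)
in every sample, then scores five candidate normalization methods (quantile,
scale/norm rank-invariant, geometric mean, delta-Ct against spike-ins) by
mean per-assay CV and SD and keeps the winner.  Writes the filtered and
normalized matrices plus QC and score reports under results/.
"""

import json
from dataclasses import asdict
from pathlib import Path

from mirsig import (
    filter_informative,
    hemolysis_qc,
    impute_undetermined,
    read_ct_matrix,
    read_sample_sheet,
    select_normalization,
)
from mirsig.preprocess import apply_sample_qc

ROOT = Path(__file__).resolve().parents[1] / "results"


def preprocess_cohort(name: str, methods=None) -> str:
    m = read_ct_matrix(ROOT / "data" / name / "ct_matrix.tsv")
    sheet = read_sample_sheet(ROOT / "data" / name / "samples.csv")
    qc = hemolysis_qc(m)
    m, sheet = apply_sample_qc(m, sheet, qc)
    qc.n_imputed = m.n_undetermined
    m = impute_undetermined(m)
    m, filt = filter_informative(m, sheet=sheet)
    qc.assays_kept, qc.assays_dropped = filt.assays_kept, filt.assays_dropped
    qc.to_json(ROOT / f"qc_{name}.json")
    nm, scores = select_normalization(m, methods=methods)
    nm.to_tsv(ROOT / f"normalized_{name}.tsv")
    sheet.to_csv(ROOT / f"samples_{name}.csv")
    (ROOT / f"normalization_scores_{name}.json").write_text(
        json.dumps({"selected": nm.method, "scores": [asdict(s) for s in scores]},
                   indent=2)
    )
    print(f"[{name}] {len(filt.assays_kept)} informative assays "
          f"({len(filt.assays_dropped)} dropped); "
          f"selected normalization: {nm.method}")
    for s in sorted(scores, key=lambda s: s.mean_cv):
        print(f"  {s.method:24s} mean CV {s.mean_cv:.5f}  mean SD {s.mean_sd:.4f}")
    return nm.method


def main() -> None:
    method = preprocess_cohort("discovery")
    # the validation cohort reuses the method selected on discovery
    preprocess_cohort("validation", methods=[method])


if __name__ == "__main__":
    main()
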