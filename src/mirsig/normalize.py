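"""Candidate normalization methods for qPCR Ct matrices and their selection.

Five methods are implemented on the Ct (log2) scale:

``quantile``
    Each sample's k-th order statistic is replaced by the mean k-th order
    statistic across samples; within-sample ties receive the mean of the
    replacement values they span.
``scale_rank_invariant``
    A constant per-sample shift computed over the set of assays whose rank
    is stable between every sample and a pseudo-reference (the per-assay
    mean Ct across samples).
``norm_rank_invariant``
    A locally weighted (lowess) curve mapping sample Ct to reference Ct,
    fitted over the sample's rank-invariant set and applied to all assays,
    with linear extrapolation beyond the fitted range.  Unlike the scale
    variant this removes intensity-dependent distortions.
``geometric_mean``
    Per-sample arithmetic-mean centering on the Ct scale (the geometric
    mean on the linear 2**(-Ct) scale), re-anchored at the grand mean.
``delta_ct``
    Subtraction of the mean Ct of designated control assays (defaults to
    spike-ins) per sample.

The best method is chosen by the smallest mean per-assay coefficient of
variation across samples, ties broken by mean per-assay SD and then by a
fixed method order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import CtMatrix, MirsigError

METHOD_ORDER = (
    "quantile",
    "scale_rank_invariant",
    "norm_rank_invariant",
    "geometric_mean",
    "delta_ct",
)

RANK_INVARIANT_FLOOR = 5


@dataclass
class NormalizedMatrix(CtMatrix):
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # normalized Ct values may legitimately be negative (e.g. delta-Ct),
        # so only the structural CtMatrix invariants are enforced
        from .data import _check_unique

        _check_unique(self.values.index, "assay names")
        _check_unique(self.values.columns, "sample IDs")
        self.values = self.values.astype(float)
        if np.any(np.isinf(self.values.to_numpy())):
            raise ValueError("normalized Ct values must be finite")


@dataclass
class NormalizationScore:
    method: str
    mean_cv: float
    mean_sd: float


def _require_complete(m: CtMatrix) -> pd.DataFrame:
    if m.values.isna().to_numpy().any():
        raise MirsigError("normalization requires an imputed (censoring-free) matrix")
    return m.values


def normalize_quantile(m: CtMatrix) -> NormalizedMatrix:
    V = _require_complete(m)
    arr = V.to_numpy()
    sorted_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        repl = np.empty_like(col)
        repl[order] = sorted_means
        # ties within a sample get the mean replacement over their span
        out[:, j] = pd.Series(repl).groupby(col).transform("mean").to_numpy()
    return NormalizedMatrix(
        pd.DataFrame(out, index=V.index, columns=V.columns),
        m.spikein_assays,
        method="quantile",
    )


def normalize_geometric_mean(m: CtMatrix) -> NormalizedMatrix:
    V = _require_complete(m)
    grand = float(V.to_numpy().mean())
    out = V - V.mean(axis=0) + grand
    return NormalizedMatrix(
        out, m.spikein_assays, method="geometric_mean", params={"grand_mean": grand}
    )


def normalize_delta_ct(m: CtMatrix, control_assays=None) -> NormalizedMatrix:
    V = _require_complete(m)
    if control_assays is None:
        control_assays = m.spikein_assays
    control_assays = list(control_assays)
    if not control_assays:
        raise MirsigError("delta_ct normalization needs at least one control assay")
    missing = [a for a in control_assays if a not in V.index]
    if missing:
        raise MirsigError(f"control assays missing from matrix: {missing}")
    out = V - V.loc[control_assays].mean(axis=0)
    return NormalizedMatrix(
        out,
        m.spikein_assays,
        method="delta_ct",
        params={"control_assays": control_assays},
    )


def rank_invariant_set(
    sample_cts: pd.Series,
    reference_cts: pd.Series,
    max_rank_shift: float = 0.05,
    exclude_extreme: float = 0.05,
) -> list:
    """Assays whose rank is stable between a sample and the reference.

    Keeps assays whose within-sample rank differs from the reference rank by
    at most ``max_rank_shift * N`` and whose reference rank lies outside the
    ``exclude_extreme`` tails.
    """
    if len(sample_cts) != len(reference_cts):
        raise ValueError("sample and reference must have equal length")
    n = len(sample_cts)
    rs = rankdata(np.asarray(sample_cts, dtype=float))
    rr = rankdata(np.asarray(reference_cts, dtype=float))
    keep = (
        (np.abs(rs - rr) <= max_rank_shift * n)
        & (rr > exclude_extreme * n)
        & (rr <= (1.0 - exclude_extreme) * n)
    )
    index = sample_cts.index if isinstance(sample_cts, pd.Series) else pd.RangeIndex(n)
    return list(index[keep])


def normalize_scale_rank_invariant(
    m: CtMatrix,
    max_rank_shift: float = 0.05,
    exclude_extreme: float = 0.05,
    floor: int = RANK_INVARIANT_FLOOR,
) -> NormalizedMatrix:
    """Per-sample constant shift over the common rank-invariant assay set."""
    V = _require_complete(m)
    if V.shape[1] < 2:
        return NormalizedMatrix(
            V.copy(), m.spikein_assays, method="scale_rank_invariant",
            params={"note": "single sample: identity"},
        )
    reference = V.mean(axis=1)
    common: set | None = None
    for s in V.columns:
        ri = set(rank_invariant_set(V[s], reference, max_rank_shift, exclude_extreme))
        common = ri if common is None else (common & ri)
    common_list = [a for a in V.index if a in (common or set())]
    if len(common_list) < floor:
        warnings.warn(
            "rank-invariant set degenerate "
            f"({len(common_list)} < {floor}); falling back to geometric-mean",
            stacklevel=2,
        )
        fallback = normalize_geometric_mean(m)
        fallback.params["fallback_from"] = "scale_rank_invariant"
        return fallback
    ref_mean = float(reference.loc[common_list].mean())
    shifts = ref_mean - V.loc[common_list].mean(axis=0)
    out = V + shifts
    return NormalizedMatrix(
        out,
        m.spikein_assays,
        method="scale_rank_invariant",
        params={"n_rank_invariant": len(common_list)},
    )


def normalize_norm_rank_invariant(
    m: CtMatrix,
    max_rank_shift: float = 0.05,
    exclude_extreme: float = 0.05,
    floor: int = RANK_INVARIANT_FLOOR,
    lowess_frac: float = 0.6,
) -> NormalizedMatrix:
    """Per-sample lowess curve through the rank-invariant set.

    Maps each sample's Ct values through a smooth sample->reference curve,
    extrapolating linearly beyond the rank-invariant range.
    """
    V = _require_complete(m)
    if V.shape[1] < 2:
        return NormalizedMatrix(
            V.copy(), m.spikein_assays, method="norm_rank_invariant",
            params={"note": "single sample: identity"},
        )
    reference = V.mean(axis=1)
    sets = {}
    for s in V.columns:
        ri = rank_invariant_set(V[s], reference, max_rank_shift, exclude_extreme)
        if len(ri) < floor:
            warnings.warn(
                f"rank-invariant set degenerate for sample {s!r}; "
                "falling back to scale rank-invariant",
                stacklevel=2,
            )
            fallback = normalize_scale_rank_invariant(
                m, max_rank_shift, exclude_extreme, floor
            )
            fallback.params["fallback_from"] = "norm_rank_invariant"
            return fallback
        sets[s] = ri

    out = {}
    for s in V.columns:
        ri = sets[s]
        x = V.loc[ri, s].to_numpy()
        y = reference.loc[ri].to_numpy()
        fitted = lowess(y, x, frac=lowess_frac, return_sorted=True)
        fx, fy = fitted[:, 0], fitted[:, 1]
        # collapse duplicate x for a strictly increasing interpolation grid
        ux, inv = np.unique(fx, return_inverse=True)
        uy = np.bincount(inv, weights=fy) / np.bincount(inv)
        if len(ux) < 2:
            out[s] = V[s] - float(x.mean()) + float(y.mean())
            continue
        curve = interp1d(ux, uy, kind="linear", fill_value="extrapolate",
                         assume_sorted=True)
        out[s] = pd.Series(curve(V[s].to_numpy()), index=V.index)
    out_df = pd.DataFrame(out)[V.columns]
    return NormalizedMatrix(
        out_df,
        m.spikein_assays,
        method="norm_rank_invariant",
        params={"lowess_frac": lowess_frac,
                "n_rank_invariant": {s: len(r) for s, r in sets.items()}},
    )


def score_normalization(nm: CtMatrix, per_assay: bool = True) -> NormalizationScore:
    """Mean per-assay SD across samples and CV = SD / mean on the Ct scale."""
    V = _require_complete(nm)
    sd = V.std(axis=1, ddof=1)
    mean = V.mean(axis=1)
    nonzero = mean != 0
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} zero-mean assay(s) excluded from CV",
            stacklevel=2,
        )
    cv = sd[nonzero] / mean[nonzero]
    method = getattr(nm, "method", "")
    if per_assay:
        return NormalizationScore(method, float(cv.mean()), float(sd.mean()))
    pooled_sd = float(np.sqrt((sd**2).mean()))
    pooled_cv = pooled_sd / float(V.to_numpy().mean())
    return NormalizationScore(method, pooled_cv, pooled_sd)


def select_normalization(
    m: CtMatrix,
    methods=None,
    control_assays=None,
    per_assay: bool = True,
) -> tuple[NormalizedMatrix, list[NormalizationScore]]:
    """Run candidate methods, score each, return the lowest-CV result.

    Ties are broken by mean SD and then by the fixed :data:`METHOD_ORDER`.
    ``delta_ct`` competes only when control assays (spike-ins) are available.
    """
    if methods is None:
        methods = list(METHOD_ORDER)
    if not methods:
        raise ValueError("no normalization methods requested")
    runners = {
        "quantile": normalize_quantile,
        "scale_rank_invariant": normalize_scale_rank_invariant,
        "norm_rank_invariant": normalize_norm_rank_invariant,
        "geometric_mean": normalize_geometric_mean,
        "delta_ct": lambda mm: normalize_delta_ct(mm, control_assays),
    }
    results: list[tuple[NormalizedMatrix, NormalizationScore]] = []
    for name in methods:
        if name not in runners:
            raise ValueError(f"unknown normalization method {name!r}")
        if name == "delta_ct" and not (control_assays or m.spikein_assays):
            warnings.warn(
                "delta_ct skipped: no control/spike-in assays available",
                stacklevel=2,
            )
            continue
        nm = runners[name](m)
        score = score_normalization(nm, per_assay=per_assay)
        score.method = name  # scored under the requested name even on fallback
        results.append((nm, score))
    if not results:
        raise MirsigError("no normalization method could be run")
    best = min(
        results,
        key=lambda r: (r[1].mean_cv, r[1].mean_sd, METHOD_ORDER.index(r[1].method)),
    )
    return best[0], [s for _, s in results]
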