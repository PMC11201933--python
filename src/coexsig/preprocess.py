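"""Low-expression filtering, TMM normalization factors, and log2-CPM.

The normalization follows the trimmed-mean-of-M-values (TMM) procedure of
Robinson & Oshlack with the conventional defaults (30% M-trim, 5% A-trim,
precision weighting), and the log-CPM transform uses the voom offsets
(+0.5 to counts, +1 to the effective library size).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import ExpressionMatrix, LOG_CPM, NormalizationResult, RAW_COUNTS


def filter_low_expression(m: ExpressionMatrix, min_count: float = 1.0,
                          max_frac: float = 0.30) -> ExpressionMatrix:
    """Drop genes whose count is below ``min_count`` in more than
    ``max_frac`` of samples.

    The boundary is strict: a gene failing in exactly ``max_frac`` of
    samples is kept. Raises if no gene survives.
    """
    m.require_stage(RAW_COUNTS)
    v = m.values
    frac_low = (v < min_count).sum(axis=1) / v.shape[1]
    keep = frac_low <= max_frac
    if not keep.any():
        raise ValueError(
            "no gene passes the low-expression filter; "
            "lower min_count or raise max_frac"
        )
    return ExpressionMatrix(values=v.loc[keep].copy(), stage=RAW_COUNTS)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, logratio_trim: float,
              sum_trim: float, a_cutoff: float, weighted: bool) -> float:
    """TMM factor of one sample against the reference column."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))          # M values
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0  # A values
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    f = 2.0 ** f
    return float(f) if np.isfinite(f) else 1.0


def tmm_factors(m: ExpressionMatrix, logratio_trim: float = 0.30,
                sum_trim: float = 0.05, a_cutoff: float = -1e10,
                weighted: bool = True,
                ref_sample: str | None = None) -> NormalizationResult:
    """Compute TMM normalization factors for each sample.

    The reference sample is the one whose 75th-percentile count (scaled by
    library size) is closest to the mean over samples. M-values (log2
    expression ratio vs. reference) are doubly trimmed — by M
    (``logratio_trim`` off each tail) and by A (``sum_trim``) — then
    averaged with inverse-delta-method-variance weights. Factors are
    rescaled to geometric mean 1.
    """
    m.require_stage(RAW_COUNTS)
    if m.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = m.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = m.samples[lib == 0].tolist()
        raise ValueError(f"sample(s) with zero total counts: {bad}")
    if ref_sample is None:
        f75 = np.array([np.quantile(counts[:, j], 0.75) for j in range(counts.shape[1])]) / lib
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = int(m.samples.get_loc(ref_sample))
    ref = counts[:, ref_idx]
    factors = np.array([
        _tmm_pair(counts[:, j], ref, logratio_trim, sum_trim, a_cutoff, weighted)
        for j in range(counts.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationResult(
        lib_sizes=pd.Series(lib, index=m.samples, name="lib_size"),
        tmm_factors=pd.Series(factors, index=m.samples, name="tmm_factor"),
    )


def log_cpm(m: ExpressionMatrix, norm: NormalizationResult | None = None,
            prior: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with voom offsets.

    value = log2( (count + prior) / (effective_lib + 1) * 1e6 ), where
    effective_lib = lib_size * TMM factor. With ``norm=None`` the raw
    library sizes are used (factors of 1).
    """
    m.require_stage(RAW_COUNTS)
    if norm is None:
        eff = m.values.sum(axis=0)
    else:
        eff = norm.effective_lib.reindex(m.samples)
        if eff.isna().any():
            missing = m.samples[eff.isna()].tolist()
            raise ValueError(f"normalization result lacks samples: {missing}")
    values = np.log2((m.values + prior) / (eff + 1.0) * 1e6)
    return ExpressionMatrix(values=values, stage=LOG_CPM)


def normalize_pipeline(m: ExpressionMatrix, min_count: float = 1.0,
                       max_frac: float = 0.30, prior: float = 0.5
                       ) -> tuple[ExpressionMatrix, NormalizationResult]:
    """Filter, TMM-normalize and log-CPM transform raw counts in one call."""
    filtered = filter_low_expression(m, min_count=min_count, max_frac=max_frac)
    norm = tmm_factors(filtered)
    return log_cpm(filtered, norm, prior=prior), norm
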