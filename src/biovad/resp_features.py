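"""Per-segment respiratory feature bank (21 features per band).

Speech respiration shows shorter inspiration, longer expiration, higher
inspiratory flow and larger breath-to-breath variability; the bank captures
these as timing ratios, amplitudes, flows and variability statistics of the
detected breath cycles.  Amplitudes are uncalibrated (arbitrary units), so
flow-like quantities are amplitude over time rather than volumetric flow.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .breath import BreathSeries

__all__ = [
    "RESP_FEATURE_NAMES",
    "META_COLUMNS",
    "resp_feature_vector",
    "missing_feature_vector",
    "dual_band_vector",
    "impute_within_subject",
]

logger = logging.getLogger(__name__)

RESP_FEATURE_NAMES: tuple[str, ...] = (
    "mean_ie", "sd_ie",
    "mean_te", "sd_te",
    "mean_ti", "sd_ti",
    "mean_duty",
    "mean_amp_insp", "sd_amp_insp",
    "mean_amp_exp", "sd_amp_exp",
    "mean_flow_insp", "sd_flow_insp",
    "mean_flow_exp", "sd_flow_exp",
    "rrv",
    "mean_first_diff_te",
    "rr",
    "minute_amp_insp", "minute_amp_exp",
    "pt_symmetry",
)

#: non-feature columns of a feature table
META_COLUMNS = ("subject_id", "segment_idx", "label")


def _sd(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0


def resp_feature_vector(breaths: BreathSeries, window_s: float = 30.0) -> dict[str, float]:
    """Compute the 21 respiratory features from a segment's breath series.

    Notable definitions: duty cycle = Ti / (Ti + Te); flows = amplitude over
    phase time; RRV is the RMSSD of breath-to-breath total durations; the
    first difference of expiration averages the *absolute* successive Te
    differences (the signed mean telescopes to an endpoint difference and
    carries no variability information); RR = 60 / mean cycle duration,
    robust to window truncation; minute amplitudes = mean amplitude x RR;
    peak-trough symmetry is the mean fraction of the cycle occupied by the
    trough-to-peak (rise) limb.

    Raises ``ValueError`` on fewer than two complete cycles; the caller is
    expected to emit a missing row for within-subject imputation.
    """
    if breaths.n_cycles < 2:
        raise ValueError("need at least 2 complete breath cycles")
    ti, te = breaths.ti, breaths.te
    d = breaths.duration
    a_in, a_ex = breaths.amp_insp, breaths.amp_exp
    ie = ti / te
    duty = ti / d
    flow_in = a_in / ti
    flow_ex = a_ex / te
    rr = 60.0 / float(np.mean(d))
    return {
        "mean_ie": float(np.mean(ie)),
        "sd_ie": _sd(ie),
        "mean_te": float(np.mean(te)),
        "sd_te": _sd(te),
        "mean_ti": float(np.mean(ti)),
        "sd_ti": _sd(ti),
        "mean_duty": float(np.mean(duty)),
        "mean_amp_insp": float(np.mean(a_in)),
        "sd_amp_insp": _sd(a_in),
        "mean_amp_exp": float(np.mean(a_ex)),
        "sd_amp_exp": _sd(a_ex),
        "mean_flow_insp": float(np.mean(flow_in)),
        "sd_flow_insp": _sd(flow_in),
        "mean_flow_exp": float(np.mean(flow_ex)),
        "sd_flow_exp": _sd(flow_ex),
        "rrv": float(np.sqrt(np.mean(np.diff(d) ** 2))),
        "mean_first_diff_te": float(np.mean(np.abs(np.diff(te)))),
        "rr": rr,
        "minute_amp_insp": float(np.mean(a_in)) * rr,
        "minute_amp_exp": float(np.mean(a_ex)) * rr,
        "pt_symmetry": float(np.mean(duty)),
    }


def missing_feature_vector() -> dict[str, float]:
    """Placeholder (all-NaN) row for an invalid segment, to be imputed."""
    return {name: np.nan for name in RESP_FEATURE_NAMES}


def dual_band_vector(
    thorax: dict[str, float],
    abdomen: dict[str, float],
    *,
    thorax_segment: int | None = None,
    abdomen_segment: int | None = None,
    prefixes: tuple[str, str] = ("thx_", "abd_"),
) -> dict[str, float]:
    """Concatenate thorax and abdomen band vectors into 42 prefixed features.

    No cross-band composites are formed.  If segment indices are supplied
    they must match (both bands must describe the same window).
    """
    if thorax_segment is not None and abdomen_segment is not None:
        if thorax_segment != abdomen_segment:
            raise ValueError(
                f"band segment mismatch: thorax {thorax_segment} vs abdomen {abdomen_segment}"
            )
    out = {prefixes[0] + k: v for k, v in thorax.items()}
    out.update({prefixes[1] + k: v for k, v in abdomen.items()})
    return out


def impute_within_subject(table: pd.DataFrame, subject_col: str = "subject_id") -> pd.DataFrame:
    """Replace missing feature cells with the subject's mean for that feature.

    Raises when a subject has no valid value at all for some feature (there
    is then nothing to impute from).  The imputed fraction is logged per
    feature that required any imputation.
    """
    feat_cols = [c for c in table.columns if c not in META_COLUMNS]
    out = table.copy()
    grouped = out.groupby(subject_col, sort=False)
    for col in feat_cols:
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        means = grouped[col].transform("mean")
        if means.isna().any():
            bad = out.loc[means.isna(), subject_col].unique()
            raise ValueError(
                f"subject(s) {list(bad)} have no valid value for feature '{col}'"
            )
        out[col] = out[col].fillna(means)
        logger.info(
            "imputed %.3f%% of segments for feature %s",
            100.0 * n_missing / len(out),
            col,
        )
    return out
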