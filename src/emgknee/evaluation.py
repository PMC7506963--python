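"""Evaluation metrics and cross-method summary arithmetic.

Per run the pipeline reports the root-mean-square error in degrees,

    RMSE = sqrt( (1/n) * sum_i (est_i - act_i)^2 ),

and the zero-lag Pearson correlation rho between estimated and actual
angle.  Across methods the summary arithmetic produces per-method column
means with their sample standard deviations, pairwise percent
reductions/increases of those means, and per-subject maxima of the
pairwise percent changes.

Two small per-subject reference tables (RMSE in degrees and rho for four
methods - BPNN/LSTM each with RMS-only and RRTAF features - from a
five-subject 1.0 m/s treadmill study) are bundled so the summary
arithmetic has a worked example that runs offline; see
:func:`load_example_results`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd


def rmse(estimated, actual) -> float:
    """Root-mean-square error; zero iff the vectors are identical."""
    est = np.asarray(estimated, dtype=float).ravel()
    act = np.asarray(actual, dtype=float).ravel()
    if est.size != act.size:
        raise ValueError(f"length mismatch: {est.size} vs {act.size}")
    if est.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((est - act) ** 2)))


def cross_corr_rho(estimated, actual) -> float:
    """Zero-lag Pearson correlation between estimate and truth.

    Raises on constant input rather than returning a silent 0.
    """
    est = np.asarray(estimated, dtype=float).ravel()
    act = np.asarray(actual, dtype=float).ravel()
    if est.size != act.size:
        raise ValueError(f"length mismatch: {est.size} vs {act.size}")
    if est.size < 2:
        raise ValueError("need at least two samples")
    de = est - est.mean()
    da = act - act.mean()
    se = np.sqrt(np.mean(de ** 2))
    sa = np.sqrt(np.mean(da ** 2))
    if se == 0.0 or sa == 0.0:
        raise ValueError("zero variance in input; rho undefined")
    r = float(np.mean(de * da) / (se * sa))
    return float(np.clip(r, -1.0, 1.0))


def percent_change(reference: float, new: float, direction: str = "reduction") -> float:
    """Percent reduction or increase of ``new`` relative to ``reference``.

    reduction = (reference - new) / reference * 100;
    increase  = (new - reference) / reference * 100.
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    if direction == "reduction":
        return (reference - new) / reference * 100.0
    if direction == "increase":
        return (new - reference) / reference * 100.0
    raise ValueError("direction must be 'reduction' or 'increase'")


@dataclass
class EvaluationReport:
    """Cross-method summary of a [subject x method] metric table.

    means/sds are per-method; percent-change entries are keyed
    ``"<method_a> vs <method_b>"`` and computed on the unrounded column
    means; subject_max_change holds the largest per-subject pairwise
    change for the same keys.  Standard deviations use the sample (n-1)
    convention, degrading to 0 for a single subject.
    """

    means: dict
    sds: dict
    percent_changes: dict = field(default_factory=dict)
    subject_max_changes: dict = field(default_factory=dict)
    n_subjects: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "sd": self.sds})


def summarize_methods(table: pd.DataFrame, direction: str = "reduction") -> EvaluationReport:
    """Column means/sds plus all pairwise percent changes of a complete
    [subject x method] table.

    ``direction="reduction"`` treats each later column as the improved
    method relative to each earlier one (RMSE-style); ``"increase"``
    likewise for a benefit metric (rho-style).  Missing cells are an error.
    """
    df = table.copy()
    if "subject" in df.columns:
        df = df.set_index("subject")
    if df.isna().any().any():
        raise ValueError("table has missing cells")
    n = len(df)
    means = {c: float(df[c].mean()) for c in df.columns}
    sds = {c: (float(df[c].std(ddof=1)) if n > 1 else 0.0) for c in df.columns}

    pct, submax = {}, {}
    cols = list(df.columns)
    for a_i, ref_col in enumerate(cols):
        for new_col in cols[a_i + 1:]:
            key = f"{new_col} vs {ref_col}"
            pct[key] = percent_change(means[ref_col], means[new_col], direction)
            per_subj = [percent_change(r, v, direction)
                        for r, v in zip(df[ref_col], df[new_col])]
            submax[key] = float(np.max(per_subj))
    return EvaluationReport(means=means, sds=sds, percent_changes=pct,
                            subject_max_changes=submax, n_subjects=n)


def load_example_results() -> dict:
    """Bundled five-subject reference tables: {'rmse_deg': df, 'rho': df}.

    Columns are ordered worst-to-best (BPNN_RMS, BPNN_RRTAF, LSTM_RMS,
    LSTM_RRTAF) so that ``summarize_methods`` percent changes read as
    later-method improvements over earlier ones.
    """
    out = {}
    pkg = resources.files("emgknee.data")
    out["rmse_deg"] = pd.read_csv(pkg / "example_rmse_deg.csv")
    out["rho"] = pd.read_csv(pkg / "example_rho.csv")
    return out
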