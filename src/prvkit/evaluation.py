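"""Agreement scoring between a reference (contact) and a test (camera) channel.

The contact channel is treated as ground truth.  For each subject the five
PRV indicators are computed on every data segment of both channels; the
per-subject mean absolute percentage error

    MAPE [%] = 100/n * sum_i |x_i - xhat_i| / x_i

(x = reference indicator, xhat = test indicator, i over the n segments)
fills one table row, and column means summarise each indicator across
subjects.  Tables built from raw PPI and from normalized NNI are compared
element-wise to quantify how much outlier replacement improves agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ParameterError
from .metrics import BandDefinition, SpectralConfig, compute_prv
from .ppi import NNISeries, PPISeries

INDICATORS = ["mean_nn", "sdnn", "lfnu", "hfnu", "lf_hf"]


@dataclass(frozen=True)
class MAPETable:
    """Per-subject MAPE (%) per indicator, with column means across subjects."""

    rows: pd.DataFrame  # index: subject, columns: indicators

    def __post_init__(self) -> None:
        if (self.rows.to_numpy() < 0).any():
            raise ParameterError("MAPE entries must be >= 0")

    @property
    def column_means(self) -> pd.Series:
        return self.rows.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Rows plus a trailing 'mean' row, as printed in reports."""
        out = self.rows.copy()
        out.loc["mean"] = self.column_means
        return out


def mape(reference: np.ndarray, test: np.ndarray) -> float:
    """Mean absolute percentage error of ``test`` against ``reference``."""
    x = np.asarray(reference, dtype=float)
    xhat = np.asarray(test, dtype=float)
    if x.shape != xhat.shape or x.ndim != 1 or x.size == 0:
        raise FormatError("reference and test must be equal-length 1-D, n >= 1")
    if np.any(x == 0):
        raise ParameterError("reference contains a zero value; MAPE undefined")
    return float(100.0 * np.mean(np.abs(x - xhat) / np.abs(x)))


def indicators_frame(
    per_subject: dict[str | int, list],
) -> pd.DataFrame:
    """Long-format indicator table from per-subject PRVIndices lists.

    ``per_subject`` maps subject id -> list of :class:`~prvkit.metrics.PRVIndices`
    (one per segment, in segment order).  Segment indices are 1-based.
    """
    records = []
    for subject, indices in per_subject.items():
        for seg, ind in enumerate(indices, start=1):
            rec = {"subject": subject, "segment": seg}
            rec.update({k: getattr(ind, k) for k in INDICATORS})
            records.append(rec)
    return pd.DataFrame.from_records(records)


def build_mape_table(ref: pd.DataFrame, test: pd.DataFrame) -> MAPETable:
    """One MAPE per (subject, indicator) from matched long-format frames.

    Both frames need columns ``subject``, ``segment`` and the five
    indicators; subjects and segment counts must match exactly.
    """
    for frame, name in ((ref, "ref"), (test, "test")):
        missing = {"subject", "segment", *INDICATORS} - set(frame.columns)
        if missing:
            raise FormatError(f"{name} frame missing columns {sorted(missing)}")
    ref_g = {s: g.sort_values("segment") for s, g in ref.groupby("subject")}
    test_g = {s: g.sort_values("segment") for s, g in test.groupby("subject")}
    if set(ref_g) != set(test_g):
        raise FormatError(
            f"subject mismatch: {sorted(set(ref_g) ^ set(test_g))}"
        )
    rows = {}
    for subject in ref_g:
        r, t = ref_g[subject], test_g[subject]
        if len(r) != len(t):
            raise FormatError(f"segment count mismatch for subject {subject}")
        rows[subject] = {
            k: mape(r[k].to_numpy(), t[k].to_numpy()) for k in INDICATORS
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[INDICATORS]
    return MAPETable(table.sort_index())


def improvement_delta(
    table_ppi: MAPETable, table_nni: MAPETable
) -> tuple[pd.DataFrame, pd.Series]:
    """Element-wise PPI - NNI MAPE differences (positive = NNI improved)."""
    if not table_ppi.rows.index.equals(table_nni.rows.index) or list(
        table_ppi.rows.columns
    ) != list(table_nni.rows.columns):
        raise FormatError("tables are not congruent")
    rows = table_ppi.rows - table_nni.rows
    return rows, table_ppi.column_means - table_nni.column_means


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise FormatError("need equal-length series with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def _paired_nni_correlation(
    ref: list[tuple[PPISeries, NNISeries]],
    test: list[tuple[PPISeries, NNISeries]],
) -> float:
    """Correlation of pooled NNI values paired by index (truncated)."""
    xs, ys = [], []
    for (_, ref_nni), (_, test_nni) in zip(ref, test):
        n = min(ref_nni.intervals_ms.size, test_nni.intervals_ms.size)
        xs.append(ref_nni.intervals_ms[:n])
        ys.append(test_nni.intervals_ms[:n])
    return pearson_correlation(np.concatenate(xs), np.concatenate(ys))


def agreement_report(
    ref_outputs: dict[str | int, list[tuple[PPISeries, NNISeries]]],
    test_outputs: dict[str | int, list[tuple[PPISeries, NNISeries]]],
    bands: BandDefinition | None = None,
    cfg: SpectralConfig | None = None,
) -> dict:
    """Full agreement report for paired per-subject pipeline outputs.

    Computes PRV indicators per segment on both the raw PPI and the
    normalized NNI of each channel, builds both MAPE tables, their
    improvement deltas, the pooled per-subject NNI correlations and the
    pooled per-indicator correlations, and returns a JSON-serializable
    dict (see :func:`render_report` for the text form).
    """
    if set(ref_outputs) != set(test_outputs):
        raise FormatError("reference and test subjects do not match")
    bands = bands or BandDefinition()
    cfg = cfg or SpectralConfig()

    def frame(outputs, which):
        per_subject = {
            s: [compute_prv(pair[which].intervals_ms, bands, cfg) for pair in segs]
            for s, segs in outputs.items()
        }
        return indicators_frame(per_subject)

    ref_ppi, ref_nni = frame(ref_outputs, 0), frame(ref_outputs, 1)
    test_ppi, test_nni = frame(test_outputs, 0), frame(test_outputs, 1)
    table_ppi = build_mape_table(ref_ppi, test_ppi)
    table_nni = build_mape_table(ref_nni, test_nni)
    delta_rows, delta_means = improvement_delta(table_ppi, table_nni)

    nni_corr = {
        str(s): _paired_nni_correlation(ref_outputs[s], test_outputs[s])
        for s in sorted(ref_outputs, key=str)
    }
    merged = ref_nni.merge(
        test_nni, on=["subject", "segment"], suffixes=("_ref", "_test")
    )
    indicator_corr = {
        k: pearson_correlation(
            merged[f"{k}_ref"].to_numpy(), merged[f"{k}_test"].to_numpy()
        )
        for k in INDICATORS
    }
    return {
        "schema_version": 1,
        "indicators": INDICATORS,
        "mape_ppi": _table_dict(table_ppi),
        "mape_nni": _table_dict(table_nni),
        "improvement_delta": {
            "rows": {str(s): _row_dict(delta_rows.loc[s]) for s in delta_rows.index},
            "column_means": _row_dict(delta_means),
        },
        "nni_correlation_per_subject": nni_corr,
        "nni_correlation_mean": float(np.mean(list(nni_corr.values()))),
        "indicator_correlation": indicator_corr,
    }


def _row_dict(row: pd.Series) -> dict[str, float]:
    return {str(k): float(v) for k, v in row.items()}


def _table_dict(table: MAPETable) -> dict:
    return {
        "rows": {str(s): _row_dict(table.rows.loc[s]) for s in table.rows.index},
        "column_means": _row_dict(table.column_means),
    }


def render_report(report: dict) -> str:
    """Human-readable text rendering of :func:`agreement_report` output."""
    lines = ["PRV agreement report", "===================="]
    for key, title in (("mape_ppi", "MAPE (%) from PPI"), ("mape_nni", "MAPE (%) from NNI")):
        lines.append("")
        lines.append(title)
        frame = pd.DataFrame.from_dict(report[key]["rows"], orient="index")
        frame.loc["mean"] = pd.Series(report[key]["column_means"])
        lines.append(frame.round(2).to_string())
    lines.append("")
    lines.append("PPI - NNI column-mean improvement (%)")
    lines.append(
        "  "
        + "  ".join(
            f"{k}={v:+.2f}" for k, v in report["improvement_delta"]["column_means"].items()
        )
    )
    lines.append("")
    lines.append(
        f"mean pooled NNI correlation: {report['nni_correlation_mean']:.3f}"
    )
    lines.append(
        "indicator correlations: "
        + "  ".join(f"{k}={v:.3f}" for k, v in report["indicator_correlation"].items())
    )
    return "\n".join(lines) + "\n"


def write_report(report: dict, path) -> None:
    """Write a report dict as pretty-printed JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
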