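"""IES retention scores (IRS), score tables, grouping, and correlation.

The retention score of an IES is the fraction of junction-informative
reads that support retention::

    IRS = IES+ / (IES+ + IES-)

where ``IES+`` counts reads matching a retention junction and ``IES-``
counts exact-excision reads.  Scores are undefined (``NaN``) below a
coverage floor; an undefined score is never collapsed to 0, because 0
means *confidently excised*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .junctions import EventCounts

__all__ = [
    "irs",
    "irs_table",
    "irs_summary",
    "irs_correlation",
    "group_by_retention",
    "IrsCorrelation",
    "read_irs_tsv",
    "write_irs_tsv",
]


def irs(n_plus: int, n_minus: int) -> float:
    """Retention score ``n_plus / (n_plus + n_minus)``; NaN if no coverage."""
    if n_plus < 0 or n_minus < 0:
        raise ValueError("counts must be non-negative")
    total = n_plus + n_minus
    if total == 0:
        return float("nan")
    return n_plus / total


def irs_table(
    counts: EventCounts, min_cov: int = 5, sample: str = ""
) -> pd.DataFrame:
    """Per-IES retention scores as a DataFrame indexed by ies_id.

    An IES has two retention junctions but a single excision junction,
    so the IES+ count entering the score is the boundary-averaged
    retention evidence ``(n_plus_left + n_plus_right) / 2`` (column
    ``n_plus``); the raw distinct-read total is kept in
    ``n_plus_reads``.  Rows with ``n_plus + n_minus < min_cov`` keep
    their counts but carry an undefined (NaN) score.  The coverage
    floor and sample label are recorded in ``DataFrame.attrs``.
    """
    rows = []
    for ies_id, cell in counts.per_ies.items():
        n_reads, nm = cell["n_plus"], cell["n_minus"]
        np_ = (
            cell.get("n_plus_left", n_reads) + cell.get("n_plus_right", n_reads)
        ) / 2.0
        score = irs(np_, nm) if np_ + nm >= min_cov else float("nan")
        rows.append((ies_id, np_, n_reads, nm, score))
    table = pd.DataFrame(
        rows, columns=["ies_id", "n_plus", "n_plus_reads", "n_minus", "irs"]
    ).set_index("ies_id")
    table.attrs["min_cov"] = min_cov
    table.attrs["sample"] = sample
    return table


def irs_summary(table: pd.DataFrame) -> dict[str, float]:
    """Distribution summary of the defined scores (histogram-style quantiles)."""
    defined = table["irs"].dropna()
    out = {
        "n_total": int(len(table)),
        "n_defined": int(len(defined)),
        "mean": float(defined.mean()) if len(defined) else float("nan"),
    }
    for q in (0.05, 0.25, 0.5, 0.75, 0.95):
        out[f"q{int(q * 100):02d}"] = (
            float(defined.quantile(q)) if len(defined) else float("nan")
        )
    return out


@dataclass(frozen=True)
class IrsCorrelation:
    pearson_r: float
    n_shared: int
    slope: float
    intercept: float


def irs_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> IrsCorrelation:
    """Pearson correlation and OLS fit of two score tables.

    Undefined scores are excluded pairwise; at least 3 shared defined
    IESs are required.  A constant table raises an error naming the
    offending sample.
    """
    joined = table_a[["irs"]].join(
        table_b[["irs"]], how="inner", lsuffix="_a", rsuffix="_b"
    ).dropna()
    if len(joined) < 3:
        raise ValueError(
            f"need >= 3 IESs with defined scores in both tables, got {len(joined)}"
        )
    x = joined["irs_a"].to_numpy()
    y = joined["irs_b"].to_numpy()
    for vals, table, which in ((x, table_a, "first"), (y, table_b, "second")):
        if np.ptp(vals) == 0.0:
            name = table.attrs.get("sample") or which
            raise ValueError(f"degenerate variance: {name} table is constant")
    r, _ = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return IrsCorrelation(
        pearson_r=float(r),
        n_shared=int(len(joined)),
        slope=float(slope),
        intercept=float(intercept),
    )


def group_by_retention(table: pd.DataFrame, threshold: float = 0.2) -> pd.DataFrame:
    """Label each defined IES "low" (IRS < threshold) or "high" (IRS >= threshold).

    The boundary value goes to "high".  Undefined IESs are excluded; the
    excluded count is recorded in ``attrs["n_undefined"]``.
    """
    defined = table.dropna(subset=["irs"]).copy()
    n_undefined = len(table) - len(defined)
    if len(defined) == 0:
        warnings.warn("all retention scores are undefined; groups are empty")
    defined["group"] = np.where(defined["irs"] >= threshold, "high", "low")
    defined.attrs["n_undefined"] = n_undefined
    defined.attrs["threshold"] = threshold
    return defined


def write_irs_tsv(table: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# min_cov={table.attrs.get('min_cov', '')}\n")
        table.to_csv(fh, sep="\t", na_rep="NA")


def read_irs_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA").set_index(
        "ies_id"
    )
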