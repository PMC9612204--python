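"""Cap-vs-cap comparison layer: channel reliability, agreement metrics
(Pearson r, RMSD), distributional tests (Lilliefors-type KS normality check,
Wilcoxon–Mann–Whitney U), impedance and metadata summaries, and the study
report bundle."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .preprocess import ChannelRating, InsufficientDataError, Verdict
from .synthdata import SubjectMetadata

__all__ = [
    "ReliabilityTable",
    "TestKind",
    "TestResult",
    "UndefinedCorrelationError",
    "IncompleteReportError",
    "channel_reliability",
    "pearson_r",
    "rmsd",
    "ks_normality",
    "mann_whitney_u",
    "impedance_summary",
    "metadata_summary",
    "prep_time_ratio",
    "build_report",
    "StudyReport",
]

ALPHA_LEVEL = 0.05


class UndefinedCorrelationError(ValueError):
    """Pearson r undefined for constant input."""


class IncompleteReportError(ValueError):
    """A pipeline stage output required for the report is missing."""


class TestKind(str, Enum):
    KS_NORMALITY = "ks_normality"
    MANN_WHITNEY_U = "mann_whitney_u"


@dataclass(frozen=True)
class TestResult:
    test: TestKind
    statistic: float
    p_value: float
    alpha: float = ALPHA_LEVEL

    @property
    def decision(self) -> str:
        return "reject" if self.p_value < self.alpha else "fail_to_reject"


# ---------------------------------------------------------------------------
# Channel reliability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReliabilityTable:
    """Per-channel good/total ratios, grouped by cap and layout."""

    table: pd.DataFrame  # columns: cap, layout, channel, n_good, n_total, reliability

    def group_summary(self) -> pd.DataFrame:
        """Grand mean and SD of per-channel reliability per (cap, layout)."""
        return (
            self.table.groupby(["cap", "layout"])["reliability"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )


def channel_reliability(
    ratings: Iterable[tuple[str, str, str, ChannelRating]]
) -> ReliabilityTable:
    """Aggregate (cap, layout, segment, rating) records into reliability ratios.

    Each element is ``(cap, layout_name, segment_kind, ChannelRating)``; the
    reliability of a channel is its number of good ratings divided by its
    total ratings within each (cap, layout) group.
    """
    rows = [
        {
            "cap": cap,
            "layout": layout,
            "channel": r.channel,
            "good": 1 if r.verdict is Verdict.GOOD else 0,
        }
        for cap, layout, _segment, r in ratings
    ]
    if not rows:
        raise InsufficientDataError("no channel ratings supplied")
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["cap", "layout", "channel"])
        .agg(n_good=("good", "sum"), n_total=("good", "count"))
        .reset_index()
    )
    agg["reliability"] = agg["n_good"] / agg["n_total"]
    return ReliabilityTable(table=agg)


# ---------------------------------------------------------------------------
# Agreement metrics
# ---------------------------------------------------------------------------

def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_r needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared deviation between two equally sampled signals."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("rmsd needs equal-length vectors")
    return float(np.sqrt(np.mean((x - y) ** 2)))


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def ks_normality(sample: np.ndarray) -> TestResult:
    """Kolmogorov–Smirnov normality check with estimated moments (Lilliefors).

    The null hypothesis is that the sample is normal with unknown mean and
    variance; the statistic is the supremum ECDF distance from the fitted
    normal CDF, with the Lilliefors small-sample p-value approximation.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 8:
        raise InsufficientDataError("Lilliefors test needs at least 8 observations")
    if np.ptp(sample) == 0:
        raise ValueError("degenerate sample: all values identical")
    stat, p = _lilliefors(sample, dist="norm")
    return TestResult(TestKind.KS_NORMALITY, float(stat), float(p))


def mann_whitney_u(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon–Mann–Whitney U test for equality of distributions.

    The p-value is exact (full null enumeration) when ``len(a)*len(b) <= 400``
    and the pooled sample is tie-free; otherwise the normal approximation
    with midranks, tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return TestResult(TestKind.MANN_WHITNEY_U, float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Metadata and impedance summaries
# ---------------------------------------------------------------------------

def impedance_summary(metadata: Sequence[SubjectMetadata]) -> pd.DataFrame:
    """Per-electrode mean of (start+end)/2 across subjects, per cap.

    Returns a table with per-electrode means plus a ``__grand__`` row holding
    the group grand mean and SD over electrode means.
    """
    rows = []
    for m in metadata:
        if set(m.impedance_start) != set(m.impedance_end):
            missing = set(m.impedance_start) ^ set(m.impedance_end)
            raise ValueError(
                f"{m.subject_id}/{m.cap_type.value}: start/end impedance maps "
                f"disagree on electrodes {sorted(missing)}"
            )
        for lbl in m.impedance_start:
            rows.append(
                {
                    "cap": m.cap_type.value,
                    "channel": lbl,
                    "impedance": 0.5 * (m.impedance_start[lbl] + m.impedance_end[lbl]),
                }
            )
    if not rows:
        raise InsufficientDataError("no impedance records")
    df = pd.DataFrame(rows)
    per_elec = (
        df.groupby(["cap", "channel"])["impedance"].agg(["mean", "std", "count"]).reset_index()
    )
    grand = (
        per_elec.groupby("cap")["mean"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "grand_mean", "std": "grand_sd"})
    )
    per_elec = per_elec.merge(grand, on="cap")
    return per_elec


_META_FIELDS = (
    "prep_time", "acquisition_time",
    "attention_start", "attention_end", "comfort_start", "comfort_end",
)


def metadata_summary(table: pd.DataFrame) -> dict:
    """Grand mean and SD per cap of the session-metadata fields, plus the
    derived dry/gel preparation-time ratio and percent reduction.

    Ratios are rounded to 2 decimals and the reduction to an integer percent
    for reporting; a single-subject group reports SD 0 with a degenerate flag.
    """
    summary: dict = {"per_cap": {}, "degenerate_sd": False}
    for cap, group in table.groupby("cap"):
        entry = {}
        for fld in _META_FIELDS:
            if fld not in group:
                continue
            vals = group[fld].to_numpy(dtype=float)
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            if vals.size == 1:
                summary["degenerate_sd"] = True
            entry[fld] = {"mean": float(vals.mean()), "sd": sd, "n": int(vals.size)}
        summary["per_cap"][str(cap)] = entry
    gel = summary["per_cap"].get("gel")
    dry = summary["per_cap"].get("dry")
    if gel and dry and "prep_time" in gel and "prep_time" in dry:
        ratio, reduction = prep_time_ratio(gel["prep_time"]["mean"], dry["prep_time"]["mean"])
        summary["prep_time_ratio"] = ratio
        summary["prep_time_reduction_pct"] = reduction
    return summary


def prep_time_ratio(gel_mean: float, dry_mean: float) -> tuple[float, int]:
    """Dry/gel preparation-time ratio (2 d.p.) and percent reduction (integer)."""
    if gel_mean <= 0:
        raise ValueError("gel preparation time must be positive")
    ratio = dry_mean / gel_mean
    return round(ratio, 2), int(round(100.0 * (1.0 - ratio)))


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

_REQUIRED_SECTIONS = (
    "metadata_summary",
    "reliability",
    "impedance",
    "comparison_metrics",
    "test_results",
)


@dataclass
class StudyReport:
    sections: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, **self.sections},
            indent=2, sort_keys=True, default=_jsonify,
        )

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(self.to_json())
        rel: pd.DataFrame = self.sections["reliability"]["per_channel"]
        rel.to_csv(directory / "reliability.csv", index=False)
        self.sections["impedance"].to_csv(directory / "impedance.csv", index=False)
        cm: pd.DataFrame = self.sections["comparison_metrics"]
        cm.to_csv(directory / "comparison_metrics.csv", index=False)
        meta = pd.json_normalize(self.sections["metadata_summary"], sep="_")
        meta.to_csv(directory / "metadata_summary.csv", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, Enum):
        return obj.value
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def build_report(sections: Mapping[str, object], config_hash: str, seed: int) -> StudyReport:
    """Assemble the serialized study report; all stages must be present."""
    missing = [k for k in _REQUIRED_SECTIONS if k not in sections or sections[k] is None]
    if missing:
        raise IncompleteReportError(f"missing stage outputs: {missing}")
    from . import __version__

    provenance = {"config_hash": config_hash, "seed": int(seed), "version": __version__}
    return StudyReport(sections=dict(sections), provenance=provenance)


def config_digest(config_obj) -> str:
    """Stable content hash of a (nested) configuration object."""
    blob = json.dumps(config_obj, sort_keys=True, default=_jsonify).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
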