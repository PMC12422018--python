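"""Batch analysis, replicate aggregation and model/data comparison.

Communities are measured in several biological replicates (six in the
motivating experiments); this module runs the per-colony analysis over a
file manifest, excludes outlier replicates with zero bisquare weight,
summarizes sector widths (median/min/max) and strain frequencies
(mean +/- SD), normalizes widths against a reference community, compares
groups (Student t-test for frequencies, Wilcoxon rank-sum for widths) and
tabulates observed versus predicted compositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import (
    AnalysisConfig,
    ColonyGeometry,
    ImageAnalysisError,
    SectorMeasurements,
    analyze_colony,
    detect_outliers,
)

__all__ = [
    "ColonyRecord",
    "ReplicateSet",
    "CommunityReport",
    "run_batch",
    "aggregate",
    "compare",
    "report_predictions",
]

_WIDTH_METRICS = ("sector_width_yellow", "sector_width_blue")


@dataclass
class ColonyRecord:
    """Per-colony outcome within a replicate set (failures keep their slot)."""

    colony_id: str
    file: str
    measurements: SectorMeasurements | None
    geometry: ColonyGeometry | None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class ReplicateSet:
    """All replicate colonies of one community, plus exclusion flags."""

    community_label: str
    colonies: list[ColonyRecord]
    excluded: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.colonies:
            raise ValueError("a replicate set needs at least one colony")

    def values(self, metric: str) -> np.ndarray:
        out = []
        for c in self.colonies:
            if c.failed:
                continue
            v = getattr(c.measurements, metric)
            out.append(v)
        return np.asarray(out, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.colonies:
            row = {"community_label": self.community_label,
                   "colony_id": c.colony_id, "file": c.file, "error": c.error}
            if not c.failed:
                m, g = c.measurements, c.geometry
                row.update({
                    "f_yellow": m.f_yellow,
                    "sector_width_yellow": m.sector_width_yellow,
                    "sector_width_blue": m.sector_width_blue,
                    "F_Y": m.F_Y, "F_B": m.F_B,
                    "a": g.a, "b": g.b, "phi": g.phi,
                    "rho_0": g.rho_0, "l_growth": g.l_growth,
                    "flags": ";".join(m.flags),
                })
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CommunityReport:
    """Replicate summary of one community after outlier exclusion."""

    community_label: str
    n_colonies: int
    n_failed: int
    width_summary: dict[str, dict[str, float]]
    mean_f_yellow: float
    sd_f_yellow: float
    excluded: dict[str, list[str]]
    normalized_width_median: dict[str, float] | None = None
    reference_label: str | None = None

    def to_dict(self) -> dict:
        return {
            "community_label": self.community_label,
            "n_colonies": self.n_colonies,
            "n_failed": self.n_failed,
            "width_summary": self.width_summary,
            "mean_f_yellow": self.mean_f_yellow,
            "sd_f_yellow": self.sd_f_yellow,
            "excluded": self.excluded,
            "normalized_width_median": self.normalized_width_median,
            "reference_label": self.reference_label,
        }


def run_batch(manifest: "pd.DataFrame | str | Path",
              config: AnalysisConfig | None = None) -> dict[str, ReplicateSet]:
    """Analyze every file in a manifest, grouped by community label.

    The manifest needs ``file`` and ``community_label`` columns (an optional
    ``colony_id``).  Per-file failures are recorded on the colony record and
    the batch continues.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        raise ValueError("empty manifest")
    if not {"file", "community_label"} <= set(manifest.columns):
        raise ValueError("manifest needs 'file' and 'community_label' columns")
    out: dict[str, ReplicateSet] = {}
    for label, group in manifest.groupby("community_label", sort=False):
        records = []
        for _, row in group.iterrows():
            cid = str(row.get("colony_id", Path(row["file"]).stem))
            try:
                meas, geom = analyze_colony(row["file"], config)
                records.append(ColonyRecord(cid, str(row["file"]), meas, geom))
            except (ImageAnalysisError, OSError, ValueError) as exc:
                records.append(ColonyRecord(cid, str(row["file"]), None, None,
                                            error=f"{type(exc).__name__}: {exc}"))
        out[str(label)] = ReplicateSet(community_label=str(label),
                                       colonies=records)
    return out


def _excluded_ids(replicates: ReplicateSet, metric: str) -> tuple[np.ndarray, list[str]]:
    """Outlier mask and colony ids excluded for one metric."""
    ok = [c for c in replicates.colonies if not c.failed]
    vals = np.array([getattr(c.measurements, metric) for c in ok], dtype=float)
    finite = np.isfinite(vals)
    mask = np.zeros(len(vals), dtype=bool)
    if finite.sum() >= 3:
        _, excl = detect_outliers(vals[finite])
        mask[np.nonzero(finite)[0]] = excl
    kept = vals[finite & ~mask]
    ids = [c.colony_id for c, m, f in zip(ok, mask, finite) if m and f]
    return kept, ids


def aggregate(replicates: ReplicateSet,
              reference: ReplicateSet | None = None) -> CommunityReport:
    """Summarize a replicate set; optionally normalize widths to a reference.

    Outlier exclusion (zero bisquare weight) is applied per metric before
    any summary; exclusions are listed, never silent.  Width medians are
    divided by the reference community's medians when a reference is given.
    """
    ok = [c for c in replicates.colonies if not c.failed]
    if not ok:
        raise ValueError(f"{replicates.community_label}: all colonies failed")
    excluded: dict[str, list[str]] = {}
    width_summary: dict[str, dict[str, float]] = {}
    for metric in _WIDTH_METRICS:
        kept, ids = _excluded_ids(replicates, metric)
        excluded[metric] = ids
        if kept.size == 0:
            raise ValueError(
                f"{replicates.community_label}: no usable values for {metric}")
        width_summary[metric] = {"median": float(np.median(kept)),
                                 "min": float(kept.min()),
                                 "max": float(kept.max()),
                                 "n": int(kept.size)}
    f_kept, f_ids = _excluded_ids(replicates, "f_yellow")
    excluded["f_yellow"] = f_ids
    if f_kept.size == 0:
        raise ValueError(f"{replicates.community_label}: no usable frequencies")
    mean_f = float(np.mean(f_kept))
    sd_f = float(np.std(f_kept, ddof=1)) if f_kept.size >= 2 else float("nan")
    norm = None
    ref_label = None
    if reference is not None:
        ref_report = aggregate(reference)
        ref_label = reference.community_label
        norm = {}
        for metric in _WIDTH_METRICS:
            ref_med = ref_report.width_summary[metric]["median"]
            norm[metric] = (width_summary[metric]["median"] / ref_med
                            if ref_med > 0 else float("nan"))
    return CommunityReport(
        community_label=replicates.community_label,
        n_colonies=len(replicates.colonies),
        n_failed=sum(c.failed for c in replicates.colonies),
        width_summary=width_summary,
        mean_f_yellow=mean_f, sd_f_yellow=sd_f,
        excluded=excluded,
        normalized_width_median=norm, reference_label=ref_label,
    )


def compare(group_a, group_b, test: str = "t-test") -> dict:
    """Two-sided comparison of two replicate groups.

    ``test`` is ``"t-test"`` (frequencies) or ``"rank-sum"`` (widths).  With
    degenerate (zero) variance in both groups the t statistic is undefined;
    the comparison then falls back to the rank-sum test with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    warning = None
    if test == "t-test":
        if np.var(a) == 0 and np.var(b) == 0:
            warning = "degenerate variance; fell back to rank-sum"
            test = "rank-sum"
        else:
            stat, p = stats.ttest_ind(a, b)
            return {"test": "t-test", "statistic": float(stat),
                    "p_value": float(p), "warning": warning}
    if test == "rank-sum":
        stat, p = stats.ranksums(a, b)
        return {"test": "rank-sum", "statistic": float(stat),
                "p_value": float(p), "warning": warning}
    raise ValueError("test must be 't-test' or 'rank-sum'")


def report_predictions(predicted_f: dict[str, float],
                       observed_f: dict[str, float],
                       reference_label: str = "Ctr") -> pd.DataFrame:
    """Observed-vs-predicted composition table with direction agreement.

    For each community: observed and predicted focal-strain frequency, their
    changes relative to the reference community, and whether the predicted
    direction of change matches the observed one.
    """
    common = [k for k in observed_f if k in predicted_f]
    missing = sorted(set(observed_f) ^ set(predicted_f))
    if missing:
        raise ValueError(f"community labels do not match: {missing}")
    if reference_label not in common:
        raise ValueError(f"reference community {reference_label!r} missing")
    f_obs_ref = observed_f[reference_label]
    f_pred_ref = predicted_f[reference_label]
    rows = []
    for label in common:
        d_obs = observed_f[label] - f_obs_ref
        d_pred = predicted_f[label] - f_pred_ref
        agree = (label == reference_label
                 or d_obs == d_pred == 0.0
                 or math.copysign(1, d_obs) == math.copysign(1, d_pred))
        rows.append({
            "community_label": label,
            "f_observed": observed_f[label],
            "f_predicted": predicted_f[label],
            "delta_f_observed": d_obs,
            "delta_f_predicted": d_pred,
            "residual": predicted_f[label] - observed_f[label],
            "direction_agrees": bool(agree),
        })
    return pd.DataFrame(rows)
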