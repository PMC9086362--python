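"""Aggregation of rod measurements into histograms and statistics.

Lengths are binned in fixed-width bins (default 10 nm) anchored at 0 nm,
left-closed right-open. Descriptive statistics (mean, median, sample SD,
min, max, count) are computed over included records only: records that are
manually excluded, that have no defined length (F < W), or that are
truncated at the image border (configurable) do not contribute.

Manual exclusion of "rogue" records — typically two rods joined side by
side that segment as one object — flips a flag and never deletes data, so
the audit trail of raw measurements is preserved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .measure import RodMeasurement


@dataclass
class LengthReport:
    """10-nm-binned histogram plus descriptive statistics."""

    bin_edges: np.ndarray          # length n_bins + 1, starts at 0
    counts: np.ndarray             # per-bin rod counts
    stats: dict                    # mean, median, sd, min, max, count
    n_excluded: int = 0
    empty: bool = False

    def modal_bin(self) -> tuple[float, float] | None:
        """(left, right) edges of the most populated bin, or None if empty."""
        if self.empty or self.counts.sum() == 0:
            return None
        i = int(np.argmax(self.counts))
        return (float(self.bin_edges[i]), float(self.bin_edges[i + 1]))


@dataclass
class MultimerClassing:
    """Nearest-multiple assignment of rod lengths to a repeat unit."""

    unit_length_nm: float
    assignments: pd.DataFrame  # columns: source_id, object_id, length_nm, k, residual_nm, coerced


def _included_lengths(
    measurements: list[RodMeasurement], include_truncated: bool
) -> tuple[np.ndarray, int]:
    lengths, n_excluded = [], 0
    for m in measurements:
        if m.excluded:
            n_excluded += 1
            continue
        if not m.length_defined:
            continue
        if m.truncated and not include_truncated:
            continue
        lengths.append(m.length_nm)
    return np.asarray(lengths, dtype=float), n_excluded


def build_report_from_lengths(
    lengths, bin_width_nm: float = 10.0, n_excluded: int = 0
) -> LengthReport:
    """Histogram + stats for a plain array of lengths in nm."""
    if bin_width_nm <= 0:
        raise ValueError(f"bin_width_nm must be > 0, got {bin_width_nm}")
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        return LengthReport(
            bin_edges=np.array([0.0, bin_width_nm]),
            counts=np.zeros(1, dtype=int),
            stats={"mean": math.nan, "median": math.nan, "sd": math.nan,
                   "min": math.nan, "max": math.nan, "count": 0},
            n_excluded=n_excluded,
            empty=True,
        )
    n_bins = max(1, int(np.floor(lengths.max() / bin_width_nm)) + 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_nm
    # np.histogram closes the last bin; a length equal to the top edge is
    # impossible here because edges extend strictly beyond the maximum.
    counts, _ = np.histogram(lengths, bins=edges)
    sd = float(np.std(lengths, ddof=1)) if lengths.size > 1 else math.nan
    stats = {
        "mean": float(np.mean(lengths)),
        "median": float(np.median(lengths)),
        "sd": sd,
        "min": float(np.min(lengths)),
        "max": float(np.max(lengths)),
        "count": int(lengths.size),
    }
    return LengthReport(bin_edges=edges, counts=counts, stats=stats,
                        n_excluded=n_excluded)


def build_report(
    measurements: list[RodMeasurement],
    bin_width_nm: float = 10.0,
    include_truncated: bool = False,
) -> LengthReport:
    """Histogram and descriptive statistics over included measurements."""
    lengths, n_excluded = _included_lengths(measurements, include_truncated)
    return build_report_from_lengths(lengths, bin_width_nm, n_excluded)


def exclude_rogue(
    measurements: list[RodMeasurement],
    ids: list[tuple[str, int]],
) -> list[RodMeasurement]:
    """Flag records as manually excluded; idempotent, nothing is deleted.

    ``ids`` is a list of (source_id, object_id) pairs; unknown pairs
    produce a warning and are otherwise ignored.
    """
    wanted = {(str(s), int(o)) for s, o in ids}
    present = {(m.source_id, m.object_id) for m in measurements}
    for missing in sorted(wanted - present):
        warnings.warn(f"exclude_rogue: no measurement with id {missing}", UserWarning)
    return [
        replace(m, excluded=True)
        if (m.source_id, m.object_id) in wanted
        else m
        for m in measurements
    ]


def classify_multimers(
    measurements: list[RodMeasurement],
    unit_length_nm: float,
    include_truncated: bool = False,
) -> MultimerClassing:
    """Assign each rod to the nearest integer multiple of a unit length.

    k = round(L / unit) with ties rounding half-up; k = 0 is coerced to 1
    (flagged) so every rod belongs to at least the monomer class.
    """
    if not unit_length_nm > 0:
        raise ValueError("unit_length_nm must be > 0")
    rows = []
    for m in measurements:
        if m.excluded or not m.length_defined:
            continue
        if m.truncated and not include_truncated:
            continue
        k = int(math.floor(m.length_nm / unit_length_nm + 0.5))
        coerced = k < 1
        k = max(k, 1)
        rows.append({
            "source_id": m.source_id,
            "object_id": m.object_id,
            "length_nm": m.length_nm,
            "k": k,
            "residual_nm": m.length_nm - k * unit_length_nm,
            "coerced": coerced,
        })
    frame = pd.DataFrame(
        rows,
        columns=["source_id", "object_id", "length_nm", "k", "residual_nm", "coerced"],
    )
    return MultimerClassing(unit_length_nm=unit_length_nm, assignments=frame)


def report_to_frames(report: LengthReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-bin table, one-row stats table) for CSV export."""
    bins = pd.DataFrame({
        "bin_left_nm": report.bin_edges[:-1],
        "bin_right_nm": report.bin_edges[1:],
        "count": report.counts,
    })
    stats = pd.DataFrame([{**report.stats, "n_excluded": report.n_excluded}])
    return bins, stats


def write_report_csv(report: LengthReport, bins_path, stats_path) -> None:
    bins, stats = report_to_frames(report)
    bins.to_csv(bins_path, index=False, float_format="%.4f")
    stats.to_csv(stats_path, index=False, float_format="%.4f")


def plot_histogram(report: LengthReport, path, title: str = "") -> None:
    """Save the binned length distribution as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    widths = np.diff(report.bin_edges)
    ax.bar(report.bin_edges[:-1], report.counts, width=widths, align="edge",
           edgecolor="black", linewidth=0.5)
    ax.set_xlabel("rod length (nm)")
    ax.set_ylabel("number of nanorods")
    if title:
        ax.set_title(title)
    if not report.empty:
        s = report.stats
        ax.annotate(
            f"n = {s['count']}\nmean = {s['mean']:.1f} nm\n"
            f"median = {s['median']:.1f} nm\nsd = {s['sd']:.1f} nm",
            xy=(0.98, 0.95), xycoords="axes fraction", ha="right", va="top",
            fontsize=9,
        )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
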