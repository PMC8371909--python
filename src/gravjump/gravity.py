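"""Per-jump gravity summaries and assignment to the nine gravity clusters.

The jump-level gravity is summarized at three discrete time points (150 ms
before ground contact, GC, and PO) and over two intervals (GC to PO and
GC-150 ms to PO).  Cluster assignment uses the mean over the wider interval;
trials whose within-jump excursion from that mean exceeds 0.3 g (above the
0.25 g width of a cluster) are excluded as unstable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .core import EmptyResultError, Trace
from .phases import PhaseMarks

#: Numeric cluster bins, lower-inclusive / upper-exclusive (top bin closed).
CLUSTER_NAMES = (
    "0-0.25", "0.25-0.5", "0.5-0.75", "0.75-1",
    "1-1.25", "1.25-1.5", "1.5-1.75", "1.75-2",
)
REFERENCE_CLUSTER = "1g"


@dataclass
class GravitySummary:
    g_pre150: float
    g_gc: float
    g_po: float
    g_gc_po_mean: float
    g_gc_po_dev: float          # max |sample - mean| over [GC, PO]
    g_pre150_po_mean: float
    g_pre150_po_dev: float      # max |sample - mean| over [GC-150 ms, PO]


@dataclass
class ClusterLabel:
    name: str
    excluded: bool = False
    reason: str = ""


def summarize_gravity(
    gravity_z: Trace,
    marks: PhaseMarks,
    lead_s: float = 0.150,
) -> GravitySummary:
    """Discrete and interval gravity values for one jump.

    Interval means are arithmetic means over the closed sample interval;
    deviations are the maximum absolute excursion from the interval mean.
    """
    t_gc = marks.time("GC")
    t_po = marks.time("PO")
    t_pre = t_gc - lead_s
    if gravity_z.t0 > t_pre + 1e-9 or gravity_z.t_end < t_po - 1e-9:
        raise ValueError(
            f"gravity trace [{gravity_z.t0:.3f}, {gravity_z.t_end:.3f}] s does not "
            f"cover [{t_pre:.3f}, {t_po:.3f}] s"
        )
    seg_gc_po = gravity_z.segment(t_gc, t_po)
    seg_wide = gravity_z.segment(t_pre, t_po)
    m1 = float(np.mean(seg_gc_po))
    m2 = float(np.mean(seg_wide))
    return GravitySummary(
        g_pre150=gravity_z.value_at(t_pre),
        g_gc=gravity_z.value_at(t_gc),
        g_po=gravity_z.value_at(t_po),
        g_gc_po_mean=m1,
        g_gc_po_dev=float(np.max(np.abs(seg_gc_po - m1))),
        g_pre150_po_mean=m2,
        g_pre150_po_dev=float(np.max(np.abs(seg_wide - m2))),
    )


def assign_cluster(
    summary: GravitySummary,
    is_reference: bool = False,
    dev_limit: float = 0.3,
) -> ClusterLabel:
    """Map a gravity summary to a cluster label (exclusion is a value, not an error).

    Reference jumps (ground or steady-flight) take the reserved ``1g`` label;
    everything else is binned on the wide-interval mean into the eight
    0.25 g-wide numeric clusters.
    """
    if summary.g_gc_po_dev > dev_limit or summary.g_pre150_po_dev > dev_limit:
        return ClusterLabel("", excluded=True,
                            reason=f"unstable gravity (excursion > {dev_limit} g)")
    if is_reference:
        return ClusterLabel(REFERENCE_CLUSTER)
    mean = summary.g_pre150_po_mean
    if mean < 0.0 or mean > 2.0:
        return ClusterLabel("", excluded=True, reason="gravity mean out of [0, 2] g")
    idx = min(int(mean / 0.25), len(CLUSTER_NAMES) - 1)  # top bin closes at 2.0
    return ClusterLabel(CLUSTER_NAMES[idx])


def cluster_table(
    labeled: Iterable[tuple[ClusterLabel, GravitySummary]],
) -> pd.DataFrame:
    """Per-cluster n, mean and SD of the wide-interval gravity mean."""
    rows = [
        {"cluster": lab.name, "g_mean": s.g_pre150_po_mean}
        for lab, s in labeled
        if not lab.excluded
    ]
    if not rows:
        raise EmptyResultError("all trials excluded; no clusters to summarize")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("cluster")["g_mean"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)  # n = 1 convention
    return out
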