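"""MM-GBSA binding free-energy aggregation.

Per-frame binding energies are the sum of the molecular-mechanics van der
Waals and electrostatic terms with the generalized-Born polar and
surface-area nonpolar solvation terms; site-level summaries report
component-wise means and the standard error of the mean of the per-frame
totals.  No entropy term is modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import GbsaFrame

__all__ = [
    "GbsaSummary",
    "frame_total",
    "summarize_site",
    "rank_sites",
    "write_gbsa_summaries",
]


@dataclass(frozen=True)
class GbsaSummary:
    site_id: str
    n_frames: int
    mean_vdw: float
    mean_elec: float
    mean_gb: float
    mean_sa: float
    mean_total: float
    sem_total: float | None  # kcal/mol; None with a single frame


def frame_total(frame: GbsaFrame) -> float:
    """Per-frame binding energy: e_vdw + e_elec + g_gb + g_sa (kcal/mol)."""
    return frame.e_vdw + frame.e_elec + frame.g_gb + frame.g_sa


def summarize_site(
    site_id: str, frames: Sequence[GbsaFrame], uncertainty: str = "sem"
) -> GbsaSummary:
    """Component-wise means over frames.

    ``uncertainty`` selects what sem_total reports: "sem" (the default)
    gives sd(totals)/sqrt(n) with the sample standard deviation (ddof=1);
    "sd" gives the sample standard deviation itself.
    """
    if not frames:
        raise ValueError(f"no GBSA frames for site {site_id!r}")
    if uncertainty not in ("sem", "sd"):
        raise ValueError(f"unknown uncertainty mode {uncertainty!r}")
    comps = np.array([[f.e_vdw, f.e_elec, f.g_gb, f.g_sa] for f in frames])
    totals = comps.sum(axis=1)
    means = comps.mean(axis=0)
    n = len(frames)
    if n < 2:
        sem = None
    else:
        sem = float(np.std(totals, ddof=1))
        if uncertainty == "sem":
            sem /= math.sqrt(n)
    return GbsaSummary(
        site_id=site_id,
        n_frames=n,
        mean_vdw=float(means[0]),
        mean_elec=float(means[1]),
        mean_gb=float(means[2]),
        mean_sa=float(means[3]),
        mean_total=float(totals.mean()),
        sem_total=sem,
    )


def rank_sites(summaries: Sequence[GbsaSummary]) -> list[GbsaSummary]:
    """Most negative mean_total (strongest binding) first; ties broken by
    site_id lexicographic order.  Stable."""
    return sorted(summaries, key=lambda s: (s.mean_total, s.site_id))


_HEADER = ["system", "dE_vdw", "dE_elec", "dG_GB", "dG_SA", "dG_binding", "sem"]


def write_gbsa_summaries(
    summaries: Sequence[GbsaSummary], path, *, display: bool = False
) -> None:
    """Tab-delimited summary table in the component order vdW, elec, GB, SA,
    total.  ``display=True`` rounds to 0.1 kcal/mol for human-readable
    output; the default keeps full precision for machine use."""
    fmt = (lambda v: "{:.1f}".format(v)) if display else (lambda v: "{:.10g}".format(v))
    lines = ["\t".join(_HEADER)]
    for s in summaries:
        cells = [
            s.site_id,
            fmt(s.mean_vdw),
            fmt(s.mean_elec),
            fmt(s.mean_gb),
            fmt(s.mean_sa),
            fmt(s.mean_total),
            "NA" if s.sem_total is None else fmt(s.sem_total),
        ]
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
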