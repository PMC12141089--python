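"""End-to-end orchestration: checklists in, trend table out.

Chains the stages — zero-fill, optional shared-checklist collapse,
inclusion filters, grid assignment, cell retention/scoring, optional
region overlay, annual range metrics, effort-corrected trends — as one
in-memory call. The CLI wraps the same stages file-by-file; this module
is what tests and simulation studies use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ebd_io, filtering, gridding, range_metrics, trend_analysis
from .filtering import FilterConfig
from .gridding import GridSpec, RegionSet
from .trend_analysis import KmConversion


@dataclass
class PipelineResult:
    """Artifacts of one full pipeline run."""

    checklists: pd.DataFrame
    kept: pd.DataFrame
    exclusion_report: dict
    retained_cells: set
    cell_years: pd.DataFrame
    summaries: pd.DataFrame
    trends: pd.DataFrame


def analyze(
    events: pd.DataFrame,
    obs: pd.DataFrame,
    filter_cfg: FilterConfig | None = None,
    grid: GridSpec | None = None,
    regions: RegionSet | None = None,
    min_years: int = 5,
    conv: KmConversion | None = None,
    collapse_shared: bool = True,
) -> PipelineResult:
    """Run the whole analysis on canonical event/observation tables.

    ``collapse_shared=False`` keeps every copy of shared (group)
    checklists, for strict replication of workflows that skip the
    collapse.
    """
    filter_cfg = filter_cfg or FilterConfig()
    grid = grid or GridSpec()
    conv = conv or KmConversion()

    checklists = ebd_io.zero_fill(events, obs)
    if collapse_shared:
        checklists = ebd_io.collapse_shared(checklists)
    kept, report = filtering.apply_filters(checklists, filter_cfg)
    kept = gridding.assign_cells(kept, grid)
    raw_cell_years = gridding.summarize_cell_years(kept)
    retained = gridding.retain_cells(raw_cell_years, min_years=min_years)
    cell_years = gridding.score_cell_years(kept, retained)
    if regions is not None:
        cell_years = gridding.assign_region(cell_years, regions, grid)
    summaries = range_metrics.annual_summaries(cell_years, grid, regions)
    trends = trend_analysis.run_all_trends(summaries, conv)
    return PipelineResult(
        checklists=checklists,
        kept=kept,
        exclusion_report=report,
        retained_cells=retained,
        cell_years=cell_years,
        summaries=summaries,
        trends=trends,
    )
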