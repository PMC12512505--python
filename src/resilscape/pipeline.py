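"""End-to-end resilience pipeline: input stack -> classes -> summary.

Runs the full chain on a congruent layer stack: terrain metrics and
landform variety from the DEM; elevation-range residuals, wetland score
and soil richness; moving-window z-scores and the hierarchical
heterogeneity combination; resistance mapping and kernel-weighted local
connectedness; bivariate quartile classification; water masking; and the
zonal percent-area summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from resilscape.connectedness import (
    ResistanceTable,
    default_resistance_table,
    local_connectedness,
    map_resistance,
)
from resilscape.heterogeneity import (
    HeterogeneityComponents,
    RegressionFit,
    combine_heterogeneity,
    elev_range_residuals,
    heterogeneity_components,
    soil_richness,
    wetland_components,
    wetland_score,
)
from resilscape.landform import (
    Taxonomy,
    classify_landforms,
    default_taxonomy,
    landform_variety,
    terrain_metrics,
)
from resilscape.raster_core import Grid, NeighborhoodSpec, ensure_congruent
from resilscape.resilience import (
    QuartileBreaks,
    bivariate_classify,
    mask_water,
    quartile_breaks,
    zonal_summary,
)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable knobs of one pipeline run.

    Window radii are in pixels on the shared grid (defaults assume 90 m
    cells: 5 px ~ 450 m local, 13 px ~ 1170 m regional, 23 px ~ 2070 m
    connectedness, 200 px z-score standardization).
    """

    local_radius_px: int = 5
    regional_radius_px: int = 13
    conn_radius_px: int = 23
    zscore_radius_px: int = 200
    tpi_radius_px: int = 5
    strict_circular: bool = True
    inverse_mode: str = "reciprocal"
    taxonomy: Taxonomy | None = None
    resistance_table: ResistanceTable | None = None


@dataclass(frozen=True)
class PipelineResult:
    landforms: Grid
    variety: Grid
    elev_resid: Grid
    range_fit: RegressionFit
    wet_score: Grid
    soil_rich: Grid
    components: HeterogeneityComponents
    heterogeneity: Grid
    resistance: Grid
    connectedness: Grid
    het_breaks: QuartileBreaks
    conn_breaks: QuartileBreaks
    classes: Grid
    summary: pd.DataFrame


def run_pipeline(
    stack: dict[str, Grid], params: PipelineParams | None = None
) -> PipelineResult:
    """Run the full pipeline on a stack with layers ``dem``, ``wetlands``,
    ``soils``, ``lulc`` and optionally ``water`` and ``zones``."""
    if params is None:
        params = PipelineParams()
    required = ("dem", "wetlands", "soils", "lulc")
    missing = [k for k in required if k not in stack]
    if missing:
        raise KeyError(f"stack is missing layers: {missing}")
    ensure_congruent(*stack.values())

    local_spec = NeighborhoodSpec(radius_px=params.local_radius_px)
    regional_spec = NeighborhoodSpec(radius_px=params.regional_radius_px)
    zscore_spec = NeighborhoodSpec(radius_px=params.zscore_radius_px)
    tpi_spec = NeighborhoodSpec(radius_px=params.tpi_radius_px)

    # heterogeneity branch
    metrics = terrain_metrics(stack["dem"], tpi_spec)
    landforms = classify_landforms(metrics, params.taxonomy or default_taxonomy())
    variety = landform_variety(landforms, local_spec)
    elev_resid, fit = elev_range_residuals(stack["dem"], variety, local_spec)
    ld, rd, patch = wetland_components(stack["wetlands"], local_spec, regional_spec)
    wscore = wetland_score(ld, rd, patch)
    srich = soil_richness(stack["soils"], local_spec)
    comps = heterogeneity_components(
        variety,
        elev_resid,
        wscore,
        srich,
        zscore_spec=zscore_spec,
        strict_circular=params.strict_circular,
    )
    het = combine_heterogeneity(comps)

    # connectedness branch
    table = params.resistance_table or default_resistance_table()
    resist = map_resistance(stack["lulc"], table)
    conn = local_connectedness(
        resist, params.conn_radius_px, inverse_mode=params.inverse_mode
    )

    # bivariate classification + accounting
    hb = quartile_breaks(het)
    cb = quartile_breaks(conn)
    classes = bivariate_classify(het, conn, hb, cb)
    if "water" in stack:
        classes = mask_water(classes, stack["water"])
    if "zones" in stack:
        zones = stack["zones"]
    else:
        zones = classes.with_values(
            classes.values * 0 + 1, nodata_mask=classes.nodata_mask
        )
    summary = zonal_summary(classes, zones)

    return PipelineResult(
        landforms=landforms,
        variety=variety,
        elev_resid=elev_resid,
        range_fit=fit,
        wet_score=wscore,
        soil_rich=srich,
        components=comps,
        heterogeneity=het,
        resistance=resist,
        connectedness=conn,
        het_breaks=hb,
        conn_breaks=cb,
        classes=classes,
        summary=summary,
    )
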