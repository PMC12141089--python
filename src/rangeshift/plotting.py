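"""Optional arrow-map of significant centroid shifts.

A minimal static figure: one dot per region at its final-year detection
centroid, with an arrow showing the direction of any significant
centroid trend (dashed for p < 0.05, solid for p < 0.01). Requires
matplotlib (``pip install rangeshift[plot]``); nothing else in the
package depends on this module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def arrow_plot(summaries: pd.DataFrame, trends: pd.DataFrame, ax=None, scale: float = 8.0):
    """Draw centroid-shift arrows per region onto a matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    last = summaries.sort_values("year").groupby("region").tail(1)
    for _, row in last.iterrows():
        lat, lon = row["det_centroid_lat"], row["det_centroid_lon"]
        if not (np.isfinite(lat) and np.isfinite(lon)):
            continue
        ax.plot(lon, lat, "ko", ms=5)
        sub = trends[(trends.region == row["region"]) & (trends.status == "ok")]
        dlat = dlon = 0.0
        p_best = 1.0
        for _, t in sub.iterrows():
            if t.p_value >= 0.05:
                continue
            p_best = min(p_best, t.p_value)
            if t.metric == "centroid_lat":
                dlat = t.slope * scale
            elif t.metric == "centroid_lon":
                dlon = t.slope * scale
        if dlat or dlon:
            ax.annotate(
                "",
                xy=(lon + dlon, lat + dlat),
                xytext=(lon, lat),
                arrowprops=dict(
                    arrowstyle="-|>",
                    linestyle="-" if p_best < 0.01 else "--",
                    color="black",
                ),
            )
        ax.annotate(str(row["region"]), (lon, lat), textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("Longitude (°)")
    ax.set_ylabel("Latitude (°)")
    return ax
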