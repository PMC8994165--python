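"""Report figures: field composite map and progression report.

Both figures draw one Voronoi tile per test location.  The composite
map fills tiles with a grayscale mapped linearly from the dynamic range
(floor -> black, ceiling -> white), prints the integer total deviation,
and colors tile borders by the TD probability category.  The progression
report shows per-location slopes with sparklines (red where the residual
MAD flag is set), the baseline composite and the permutation S/n
histogram with the observed value and p-value.

The probability-level palette (dark red, red, orange, gold for <0.5%,
<1%, <2%, <5%) is fixed across releases.  Figure generation is
deterministic: no randomness is used.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Polygon as MplPolygon  # noqa: E402

from .norms import CATEGORY_LABELS  # noqa: E402

__all__ = ["CATEGORY_COLORS", "plot_field_composite",
           "plot_progression_report"]

#: Stable border colors per probability category.
CATEGORY_COLORS = {
    "<0.5%": "#a50f15",
    "<1%": "#de2d26",
    "<2%": "#fb6a4a",
    "<5%": "#fec44f",
    "normal": None,
}


def _gray(s: float, floor: float, ceiling: float) -> str:
    v = (s - floor) / (ceiling - floor)
    return str(float(np.clip(v, 0.0, 1.0)))


def _draw_tiles(ax, tess, fills, borders, texts, text_colors=None):
    for i, poly in enumerate(tess.polygons):
        face = fills[i] if fills[i] is not None else "none"
        edge = borders[i] if borders[i] is not None else "0.7"
        lw = 2.0 if borders[i] is not None else 0.5
        ax.add_patch(MplPolygon(poly, closed=True, facecolor=face,
                                edgecolor=edge, linewidth=lw))
        if texts[i] is not None:
            c = "black"
            if text_colors is not None and text_colors[i] is not None:
                c = text_colors[i]
            x, y = tess.points[i]
            ax.text(x, y, texts[i], ha="center", va="center", fontsize=7,
                    color=c)
    b = tess.clip_boundary
    ax.set_xlim(b[:, 0].min() - 1, b[:, 0].max() + 1)
    ax.set_ylim(b[:, 1].min() - 1, b[:, 1].max() + 1)
    ax.set_aspect("equal")
    ax.set_xlabel("x (degrees)")
    ax.set_ylabel("y (degrees)")


def plot_field_composite(
    field, deviation_map, tess, out_path,
    db_range: tuple[float, float] = (0.0, 40.0),
):
    """Grayscale sensitivity + color-coded TD composite map.

    Darker tiles mean lower sensitivity; printed numbers are total
    deviations rounded to integers; colored borders mark significantly
    depressed locations.  Blind-spot tiles stay unfilled.
    """
    floor, ceiling = db_range
    n = len(tess)
    sens = field.sensitivities
    fills, borders, texts = [], [], []
    text_colors = []
    for i in range(n):
        cat = deviation_map.td_category[i]
        if cat is None or not np.isfinite(sens[i]):
            fills.append(None)
            borders.append(None)
            texts.append(None)
            text_colors.append(None)
            continue
        fills.append(_gray(sens[i], floor, ceiling))
        borders.append(CATEGORY_COLORS.get(cat))
        td = deviation_map.td[i]
        texts.append(f"{td:.0f}" if np.isfinite(td) else "")
        text_colors.append(
            "white" if (sens[i] - floor) / (ceiling - floor) < 0.4
            else "black")
    fig, ax = plt.subplots(figsize=(7, 6))
    _draw_tiles(ax, tess, fills, borders, texts, text_colors)
    ax.set_title(
        f"{field.subject_id} {field.eye} {field.date.isoformat()}  "
        f"MD {deviation_map.md:+.2f} dB  GH {deviation_map.general_height:+.2f} dB"
    )
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


def _p_category(p: float) -> str:
    for level, label in zip((0.005, 0.01, 0.02, 0.05), CATEGORY_LABELS):
        if p < level:
            return label
    return "normal"


def plot_progression_report(
    tess, trends, poplr_result, series_values, times,
    baseline_sens, baseline_td, out_path,
    db_range: tuple[float, float] = (0.0, 40.0),
):
    """Three-panel progression report.

    Left: per-location slope tiles with sparklines of the series values
    (red when the residual-MAD flag is set), borders colored by the
    category of the one-sided slope p-value.  Top right: baseline
    composite (grayscale sensitivity, TD numbers).  Bottom right:
    histogram of permutation S/n with the observed value marked and the
    PoPLR p-value annotated.

    ``series_values`` is the (n_visits, n_locations) matrix the
    regressions were run on; ``baseline_sens``/``baseline_td`` come from
    the regression intercepts on sensitivities.
    """
    floor, ceiling = db_range
    n = len(tess)
    fig = plt.figure(figsize=(13, 6))
    ax_main = fig.add_axes([0.05, 0.08, 0.52, 0.84])
    ax_base = fig.add_axes([0.63, 0.52, 0.34, 0.40])
    ax_hist = fig.add_axes([0.63, 0.08, 0.34, 0.33])

    fills = [None] * n
    borders = []
    texts = []
    for i in range(n):
        tr = trends[i]
        if tr is None:
            borders.append(None)
            texts.append(None)
        else:
            borders.append(CATEGORY_COLORS.get(_p_category(tr.p)))
            texts.append(None)
    _draw_tiles(ax_main, tess, fills, borders, texts)
    # sparklines + slope values inside each tile
    tmax = float(times[-1]) if times[-1] > 0 else 1.0
    for i in range(n):
        tr = trends[i]
        if tr is None:
            continue
        x0, y0 = tess.points[i]
        xs = x0 - 2.2 + 4.4 * np.asarray(times) / tmax
        v = series_values[:, i]
        vspan = max(float(np.nanmax(v) - np.nanmin(v)), 1e-9)
        ys = y0 - 0.6 + 2.0 * (v - np.nanmin(v)) / vspan
        ax_main.plot(xs, ys, lw=0.8,
                     color="red" if tr.flagged else "0.3")
        ax_main.text(x0, y0 - 1.9, f"{tr.slope:+.1f}", ha="center",
                     va="center", fontsize=6)
    ax_main.set_title("pointwise linear regression slopes (dB/year)")

    base_fills, base_borders, base_texts, base_tc = [], [], [], []
    for i in range(n):
        s = baseline_sens[i]
        if not np.isfinite(s):
            base_fills.append(None)
            base_borders.append(None)
            base_texts.append(None)
            base_tc.append(None)
            continue
        base_fills.append(_gray(s, floor, ceiling))
        base_borders.append(None)
        td = baseline_td[i]
        base_texts.append(f"{td:.0f}" if np.isfinite(td) else "")
        base_tc.append("white" if (s - floor) / (ceiling - floor) < 0.4
                       else "black")
    _draw_tiles(ax_base, tess, base_fills, base_borders, base_texts,
                base_tc)
    ax_base.set_title("baseline (regression intercepts)")

    s_over_n = poplr_result.permutation_s / poplr_result.n_locations
    obs = poplr_result.s_over_n
    ax_hist.hist(s_over_n, bins=30, color="0.6")
    ax_hist.axvline(obs, color="red", lw=2)
    ax_hist.annotate(
        f"S/n = {obs:.2f}\np = {poplr_result.p_value:.3f}",
        xy=(0.97, 0.95), xycoords="axes fraction", ha="right", va="top",
    )
    ax_hist.set_xlabel("permutation S / n")
    ax_hist.set_ylabel("count")
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
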