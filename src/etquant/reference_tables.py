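"""Built-in per-ear reference measurements (five-ear cadaver dataset).

Per-ear values of the reference balloon-dilation cadaver experiment the
pipeline was designed around: percent air-density increases per ROI kind,
percent lumen-width increases per level, and the three straight-line
distances in pixels.  They serve as fixed inputs for the
``reproduce-tables`` summary (mean / sample SD per column) and as magnitude
anchors for phantom configuration.
"""

from __future__ import annotations

__all__ = [
    "AIR_INCREASE_PCT",
    "WIDTH_INCREASE_PCT",
    "DISTANCES_PX",
    "EAR_IDS",
]

EAR_IDS = ("ear1", "ear2", "ear3", "ear4", "ear5")

#: percent increase in air-density pixel count, per ROI kind
AIR_INCREASE_PCT: dict[str, list[float]] = {
    "small": [20, 33, 68, 100, 98],
    "longest": [6, 23, 50, 74, 68],
    "long": [8, 26, 62, 97, 88],
}

#: percent increase in lumen width at the three measurement levels
WIDTH_INCREASE_PCT: dict[str, list[float]] = {
    "width_np": [3.5, 0, 9, 4.2, 25],
    "width_mid": [57.8, 93.5, 75.6, 53.3, 78.9],
    "width_isthmus": [31.6, 10, 100, 47.2, 0],
}

#: straight-line distances in pixels: total lumen, torus->widest, widest->tip
DISTANCES_PX: dict[str, list[float]] = {
    "distance_total": [67.99, 87.74, 73.37, 75.41, 72.6],
    "distance_torus_to_widest": [50.45, 56.01, 44.24, 37.79, 37.79],
    "distance_widest_to_tip": [20.82, 34.41, 30.16, 38.09, 32.82],
}
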