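"""Built-in reference values for the child/adult cream-cheese mastication study.

These are the published summary measurements for a surface-coloured processed
cream cheese chewed by a panel of 30 children (5–12 y) and 30 adults
(18–65 y): chromameter L*a*b* means for the uncoloured and coloured product,
per-group means ± population SDs of the parameters influencing mastication,
and the in vivo / in vitro bolus red-channel variances and back-extrusion
hardnesses used to select masticator settings.  They serve two roles:

* defaults for the synthetic-data generators (the study conditions), and
* desk-scale inputs for the worked matching example (the raw per-subject
  data are not public; only these summaries are).
"""

from __future__ import annotations

from .colorimetry import LabColor

__all__ = [
    "UNCOLORED_CHEESE_LAB",
    "COLORED_CHEESE_LAB",
    "PANEL_SUMMARY",
    "POOLED_RATIO_MOUTH_PER_QUANTITY",
    "POOLED_SALIVA_RATE",
    "GRID_COMPRESSIONS",
    "GRID_SPEEDS",
    "INVIVO_RED_VARIANCE",
    "INVITRO_RED_VARIANCE",
    "INVIVO_HARDNESS",
    "INVITRO_HARDNESS",
    "TRIANGLE_SESSIONS",
]

# Chromameter means (uncoloured is the reference colour).
UNCOLORED_CHEESE_LAB = LabColor(L=90.81, a=-1.67, b=11.38)
COLORED_CHEESE_LAB = LabColor(L=57.01, a=19.82, b=-2.04)

# Per-group (mean, population SD) of the in vivo parameters influencing
# mastication, n = 30 per group, triplicate measurements averaged per subject.
PANEL_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "child": {
        "mouth_volume": (38.24, 14.19),          # mL
        "quantity_consumed": (4.52, 2.11),       # g
        "ratio_mouth_per_quantity": (10.27, 6.46),  # mL/g
        "mastication_time": (6.92, 3.25),        # s
        "n_compressions": (8.62, 3.78),          # count
        "chewing_frequency": (1.29, 0.23),       # s^-1
        "saliva_volume": (0.28, 0.23),           # mL
        "saliva_rate": (0.05, 0.04),             # mL/s
    },
    "adult": {
        "mouth_volume": (84.75, 17.71),
        "quantity_consumed": (7.39, 2.44),
        "ratio_mouth_per_quantity": (12.68, 4.78),
        "mastication_time": (8.91, 3.31),
        "n_compressions": (10.08, 3.90),
        "chewing_frequency": (1.16, 0.24),
        "saliva_volume": (0.52, 0.41),
        "saliva_rate": (0.06, 0.04),
    },
}

# Pooled-panel means actually used for the transposition (group differences
# on these ratios were not significant, so the overall means were kept).
POOLED_RATIO_MOUTH_PER_QUANTITY = 11.47  # mL/g
POOLED_SALIVA_RATE = 0.05  # mL/s

# Masticator experimental grid.
GRID_COMPRESSIONS = (1, 2, 6, 8, 10, 14, 18)
GRID_SPEEDS = (4, 15)  # rpm

# In vivo red-channel variance (normalised intensity²) per group and
# mastication stage (% of individual chewing time).
INVIVO_RED_VARIANCE: dict[tuple[str, int], float] = {
    ("child", 33): 0.0034,
    ("child", 66): 0.0024,
    ("child", 99): 0.0018,
    ("adult", 33): 0.0024,
    ("adult", 66): 0.0012,
    ("adult", 99): 0.0009,
}

# In vitro red-channel variance of the candidate settings that entered the
# published comparison, keyed by (n_compressions, rpm).
INVITRO_RED_VARIANCE: dict[tuple[int, int], float] = {
    (1, 15): 0.0028,
    (2, 15): 0.0026,
    (6, 4): 0.0022,
    (8, 15): 0.0012,
    (14, 15): 0.0008,
}

# In vivo back-extrusion hardness (N) per group and stage.
INVIVO_HARDNESS: dict[tuple[str, int], float] = {
    ("child", 33): 93.54,
    ("child", 66): 81.50,
    ("child", 99): 71.94,
    ("adult", 33): 107.98,
    ("adult", 66): 75.57,
    ("adult", 99): 54.50,
}

# In vitro hardness (N) of the candidate settings in the published comparison.
INVITRO_HARDNESS: dict[tuple[int, int], float] = {
    (2, 15): 96.82,
    (6, 4): 71.30,
    (1, 15): 112.24,
    (8, 15): 50.83,
}

# Blind triangle-test sessions on uncoloured vs coloured cheese:
# (n_panelists, n_correct).
TRIANGLE_SESSIONS = ((30, 5), (30, 9))
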