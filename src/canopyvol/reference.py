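"""Published reference values from the two-site rice field trial that this
package's synthetic generator emulates.

The original study grew four japonica rice varieties — SJ18 and SJ6
(type A: early-maturing, high-yield, long loose leaves) and LY16 and WYD4
(type B: late-maturing, high-quality, short compact leaves) — at two sites
under five nitrogen rates with three replications, sampling four growth
stages (240 plot-stage samples). Its image dataset is not public, so these
printed results serve two roles here: as default parameters for the
synthetic generator (the CC-CVP curves) and as reference inputs for
bookkeeping computations (feature selection on the reported correlations,
relative model-performance changes).
"""

from __future__ import annotations

#: Per-variety exponential CC-CVP fits, CVP = a * exp(b * CC), from the
#: field trial's regression analysis, with the reported R^2.
CC_CVP_CURVES: dict[str, dict[str, float]] = {
    "SJ18": {"a": 0.2064, "b": 3.6204, "r2": 0.78},
    "SJ6": {"a": 0.1759, "b": 3.7112, "r2": 0.77},
    "LY16": {"a": 0.2158, "b": 3.8165, "r2": 0.86},
    "WYD4": {"a": 0.1653, "b": 3.8709, "r2": 0.85},
}

#: Variety -> type mapping used throughout (A: long/loose, B: short/compact).
VARIETY_TYPES: dict[str, str] = {
    "SJ18": "A",
    "SJ6": "A",
    "LY16": "B",
    "WYD4": "B",
}

#: Reported correlation coefficients between each image feature and CVP,
#: pooled across stages. CC exists only after segmentation.
FEATURE_CVP_CORRELATIONS: dict[str, float] = {
    "INT_before": -0.59,
    "NBI_before": 0.19,
    "NGI_before": 0.61,
    "NRI_before": -0.65,
    "GRRI_before": 0.65,
    "GBRI_before": 0.28,
    "NGRDI_before": 0.70,
    "NGBDI_before": 0.25,
    "EXG_before": 0.50,
    "VDVI_before": 0.61,
    "cc": 0.83,
    "INT_after": -0.54,
    "NBI_after": 0.26,
    "NGI_after": 0.22,
    "NRI_after": -0.50,
    "GRRI_after": 0.39,
    "GBRI_after": -0.05,
    "NGRDI_after": 0.46,
    "NGBDI_after": -0.07,
    "EXG_after": -0.02,
    "VDVI_after": 0.22,
}

#: The ten features the field study selected at |r| >= 0.5 and used as
#: random-forest predictors.
SELECTED_FEATURES: tuple[str, ...] = (
    "INT_before",
    "NGI_before",
    "NRI_before",
    "GRRI_before",
    "NGRDI_before",
    "EXG_before",
    "VDVI_before",
    "cc",
    "INT_after",
    "NRI_after",
)

#: Reported CVP prediction performance of the global (GPM) and per-variety
#: local (LPM) random-forest models.
MODEL_PERFORMANCE: dict[str, dict[str, dict[str, float]]] = {
    "GPM": {
        "modelling": {"r2": 0.89, "rmse": 0.49},
        "validation": {"r2": 0.81, "rmse": 0.66},
    },
    "LPM": {
        "modelling": {"r2": 0.92, "rmse": 0.42},
        "validation": {"r2": 0.92, "rmse": 0.44},
    },
}

#: Yield-level cut points (kg/ha) per variety type: low < first bound,
#: middle in [first, second), high >= second.
YIELD_CUTPOINTS: dict[str, tuple[float, float]] = {
    "A": (7500.0, 8500.0),
    "B": (6500.0, 7500.0),
}
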