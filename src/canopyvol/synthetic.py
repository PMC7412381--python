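"""Synthetic data generation: the two-site rice trial design, plot growth
and yield trajectories, and rendered canopy images with known ground truth.

The generator emulates the field study this package targets: two sites,
each growing one type-A variety (long, loosely packed leaves) and one
type-B variety (short, compact leaves), under five nitrogen rates with
three replications — 30 plots per site, 60 plots, and with four growth
stages 240 plot-stage samples.

Three layers:

* ``simulate_design`` lays out the factorial plot table.
* ``simulate_growth`` / ``simulate_yield`` fill in LAI, PH, CVP and yield.
  LAI and PH follow per-variety stage trajectories that peak at heading,
  scaled by a saturating nitrogen response and multiplicative lognormal
  noise; yield is linear in the whole-period mean CVP plus Gaussian noise.
* ``render_canopy_image`` paints leaf-shaped green ellipses over a soil
  background until the truth-mask cover matches a target. Canopy pixels
  have G - R > 40 and soil pixels |G - R| <= 5, so without shadows a GMR
  threshold of 10 recovers the truth mask exactly. A configurable fraction
  of canopy pixels is darkened below the threshold, emulating the
  bottom-leaf shadows that make measured canopy cover saturate under a
  closing canopy.

Per-sample target cover comes from inverting each variety's exponential
CC-CVP curve (defaults: the published per-variety fits), so synthetic data
live on the same CC-CVP manifold as the field observations. All randomness
flows from one master seed via named substreams.

``generate_dataset`` runs the full chain and, in fast mode, emits feature
vectors directly from a two-component colour mixture (lit canopy + soil,
plus a shadowed-canopy component) instead of rasterising 240 images;
image mode renders every frame and runs the real extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _ellipse

from . import __version__
from .agronomy import STAGES, SAMPLE_COLUMNS, summarize_samples, yield_level
from .errors import RenderError, ValidationError
from .features import ChannelMeans, FeatureVector, compute_all_vis, extract_features
from .imaging import CanopyMask, RGBImage, write_image, write_mask
from .reference import CC_CVP_CURVES

#: Maximum target cover reachable by inverting the CC-CVP link; real canopies
#: never reach full cover in nadir frames.
CC_CLIP = 0.98


@dataclass(frozen=True)
class DesignConfig:
    """Factorial layout of the simulated trial (defaults: the two-site,
    2-variety, 5-N-rate, 3-replicate, 4-stage design)."""

    sites: tuple = (
        ("Fangzheng", (("SJ18", "A"), ("LY16", "B"))),
        ("Wuchang", (("SJ6", "A"), ("WYD4", "B"))),
    )
    n_rates: tuple[float, ...] = (0.0, 79.1, 90.5, 102.3, 115.0)
    replicates: int = 3
    stages: tuple[str, ...] = STAGES

    def __post_init__(self):
        if (
            not self.sites
            or any(not vs for _, vs in self.sites)
            or not self.n_rates
            or self.replicates < 1
            or not self.stages
        ):
            raise ValidationError("every design factor must be non-empty")


@dataclass(frozen=True)
class VarietyGrowth:
    """Growth-curve parameters of one variety.

    ``lai_stage_shape`` / ``ph_stage_shape`` are multipliers per stage
    (tillering, jointing, heading, filling), maximal at heading; ``cc_curve``
    is the (a, b) of CVP = a * exp(b * CC) used to derive target cover.
    """

    lai_max: float
    ph_max: float  # metres
    lai_stage_shape: tuple[float, ...] = (0.35, 0.75, 1.0, 0.85)
    ph_stage_shape: tuple[float, ...] = (0.55, 0.80, 1.0, 0.95)
    cc_curve: tuple[float, float] = (0.2064, 3.6204)


def _default_varieties() -> dict[str, VarietyGrowth]:
    curve = lambda v: (CC_CVP_CURVES[v]["a"], CC_CVP_CURVES[v]["b"])
    return {
        # type A: taller, larger leaf area (long loose leaves)
        "SJ18": VarietyGrowth(lai_max=5.8, ph_max=0.95, cc_curve=curve("SJ18")),
        "SJ6": VarietyGrowth(lai_max=5.6, ph_max=0.92, cc_curve=curve("SJ6")),
        # type B: shorter, more compact canopies, lower yields
        "LY16": VarietyGrowth(lai_max=5.0, ph_max=0.85, cc_curve=curve("LY16")),
        "WYD4": VarietyGrowth(lai_max=4.8, ph_max=0.80, cc_curve=curve("WYD4")),
    }


@dataclass(frozen=True)
class GrowthParams:
    """Statistical structure of the simulated trial.

    The nitrogen response is multiplicative and saturating:
    resp(n) = base + (1 - base) * (n / n_max)^gamma, monotone in n. Yield
    is linear in cvp_avg with type-specific coefficients calibrated so
    type-A plot yields straddle the 7500/8500 kg/ha grouping cut points
    and type-B the 6500/7500 ones.
    """

    varieties: dict[str, VarietyGrowth] = field(default_factory=_default_varieties)
    n_base: float = 0.55
    n_gamma: float = 0.7
    n_max: float = 115.0
    noise_sd: float = 0.1  # lognormal sigma on LAI and PH
    #: variety type -> (intercept kg/ha, slope kg/ha per unit CVP, noise sd)
    yield_models: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"A": (5200.0, 1100.0, 250.0), "B": (5300.0, 950.0, 250.0)}
    )
    shadow_fraction: float = 0.15  # peak shaded fraction of canopy pixels
    cc_noise_sd: float = 0.01  # measurement jitter on extracted cover

    def n_response(self, n_rate: float) -> float:
        frac = min(max(n_rate / self.n_max, 0.0), 1.0)
        return self.n_base + (1.0 - self.n_base) * frac**self.n_gamma


@dataclass(frozen=True)
class RenderSpec:
    """Geometry and palette of one rendered canopy frame.

    Defaults are a 1/10 linear scale of a 1920x1080 smartphone frame. Leaf
    ellipses for type A are long and loose, for type B short and compact.
    Canopy colours keep G - R > 40 and soil |G - R| <= 5 so the GMR
    threshold of 10 separates them; ``shadow_fraction`` of canopy pixels is
    darkened so its GMR falls below 10 while staying in the truth mask.
    """

    width: int = 192
    height: int = 108
    target_cc: float = 0.5
    variety_type: str = "A"
    shadow_fraction: float = 0.0
    seed: int = 0
    #: (major semi-axis range, minor semi-axis range) in pixels per type
    leaf_geometry: dict = field(
        default_factory=lambda: {"A": ((8, 18), (2, 4)), "B": ((4, 9), (2, 4))}
    )

    def __post_init__(self):
        if not 0.0 <= self.target_cc <= 1.0:
            raise ValidationError("target_cc must lie in [0, 1]")
        if not 0.0 <= self.shadow_fraction <= 1.0:
            raise ValidationError("shadow_fraction must lie in [0, 1]")


def simulate_design(config: DesignConfig = DesignConfig()) -> pd.DataFrame:
    """Full factorial plot table crossed with growth stages.

    Deterministic ordering: site, variety, N rate, replicate, stage. LAI,
    PH, CVP and yield columns are present but unfilled.
    """
    rows = []
    for site, variety_list in config.sites:
        for variety, vtype in variety_list:
            for i_n, n_rate in enumerate(config.n_rates):
                for rep in range(1, config.replicates + 1):
                    plot_id = f"{site}-{variety}-N{i_n}-R{rep}"
                    for stage in config.stages:
                        rows.append(
                            {
                                "sample_id": f"{plot_id}-{stage}",
                                "plot_id": plot_id,
                                "site": site,
                                "variety": variety,
                                "variety_type": vtype,
                                "n_rate": n_rate,
                                "replicate": rep,
                                "stage": stage,
                                "lai": np.nan,
                                "ph": np.nan,
                                "cvp": np.nan,
                                "yield_kg_ha": np.nan,
                            }
                        )
    return pd.DataFrame(rows)


def simulate_growth(
    design: pd.DataFrame, params: GrowthParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill LAI, PH and CVP for every stage-sample.

    lai = lai_max * stage shape * N response * lognormal noise, and
    analogously for PH; CVP is their product. With zero noise the CVP
    trajectory is deterministic and peaks at heading.
    """
    missing = set(design["variety"]) - set(params.varieties)
    if missing:
        raise ValidationError(f"no growth parameters for varieties {sorted(missing)}")
    df = design.copy()
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    lai = np.empty(len(df))
    ph = np.empty(len(df))
    for i, row in enumerate(df.itertuples()):
        vp = params.varieties[row.variety]
        si = stage_idx[row.stage]
        resp = params.n_response(row.n_rate)
        noise_l = np.exp(rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 1.0
        noise_p = np.exp(rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 1.0
        lai[i] = vp.lai_max * vp.lai_stage_shape[si] * resp * noise_l
        ph[i] = vp.ph_max * vp.ph_stage_shape[si] * resp * noise_p
    df["lai"] = lai
    df["ph"] = ph
    df["cvp"] = lai * ph
    return df


def simulate_yield(
    samples: pd.DataFrame, params: GrowthParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach a maturity yield to every plot (constant across its stages).

    yield = intercept + slope * cvp_avg + Gaussian noise, truncated at 0,
    with type-specific coefficients.
    """
    df = samples.copy()
    df["yield_kg_ha"] = 0.0  # placeholder so summaries validate
    summaries = summarize_samples(df)
    plot_info = df.drop_duplicates("plot_id").set_index("plot_id")["variety_type"]
    yields = {}
    for row in summaries.itertuples():
        vtype = plot_info[row.plot_id]
        intercept, slope, sd = params.yield_models[vtype]
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        yields[row.plot_id] = max(0.0, intercept + slope * row.cvp_avg + noise)
    df["yield_kg_ha"] = df["plot_id"].map(yields)
    return df


def target_cover(cvp: float, curve: tuple[float, float]) -> float:
    """Invert CVP = a * exp(b * CC) for the cover target, clipped to
    [0, CC_CLIP]."""
    a, b = curve
    if cvp <= 0:
        return 0.0
    return float(np.clip(np.log(cvp / a) / b, 0.0, CC_CLIP))


# -- canopy frame rendering -------------------------------------------------

_SOIL_R = (95, 125)
_SOIL_DELTA = (-5, 5)  # G - R of soil
_SOIL_B = (60, 85)
_CANOPY_R = (40, 90)
_CANOPY_DELTA = (45, 105)  # G - R of lit canopy
_CANOPY_B = (30, 80)
_SHADOW_R = (40, 70)
_SHADOW_DELTA = (0, 8)  # G - R of shadowed canopy: below the threshold


def _fill_truth_mask(spec: RenderSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    n_total = h * w
    n_target = int(round(spec.target_cc * n_total))
    truth = np.zeros((h, w), dtype=bool)
    if n_target == 0:
        return truth
    if n_target == n_total:
        truth[:] = True
        return truth
    (a_lo, a_hi), (b_lo, b_hi) = spec.leaf_geometry[spec.variety_type]
    misses = 0
    max_attempts = 50 * n_total
    attempts = 0
    count = 0
    while count < n_target and misses < 60:
        attempts += 1
        if attempts > max_attempts:
            raise RenderError(
                f"could not reach cover {spec.target_cc} after {attempts} attempts"
            )
        r0 = rng.integers(0, h)
        c0 = rng.integers(0, w)
        rr, cc = _ellipse(
            r0,
            c0,
            rng.integers(a_lo, a_hi + 1),
            rng.integers(b_lo, b_hi + 1),
            shape=(h, w),
            rotation=rng.uniform(0, np.pi),
        )
        new = ~truth[rr, cc]
        if count + int(new.sum()) <= n_target:
            truth[rr, cc] = True
            count += int(new.sum())
            misses = 0
        else:
            misses += 1
    if count < n_target:
        # leaves are now too coarse; top up with single boundary pixels
        flat = np.flatnonzero(~truth.ravel())
        pick = rng.choice(flat, size=n_target - count, replace=False)
        truth.ravel()[pick] = True
    return truth


def render_canopy_image(spec: RenderSpec) -> tuple[RGBImage, CanopyMask]:
    """Render one canopy frame and its ground-truth mask.

    The truth-mask cover matches ``target_cc`` to within one pixel in
    ``width * height`` (well inside 0.01). ``shadow_fraction`` of the
    canopy pixels is darkened below the GMR threshold while remaining in
    the truth mask, so segmentation undercounts shaded canopies.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _fill_truth_mask(spec, rng)
    h, w = truth.shape
    r = rng.integers(*_SOIL_R, size=(h, w), endpoint=True)
    g = r + rng.integers(*_SOIL_DELTA, size=(h, w), endpoint=True)
    b = rng.integers(*_SOIL_B, size=(h, w), endpoint=True)

    n_plant = int(truth.sum())
    if n_plant:
        rc = rng.integers(*_CANOPY_R, size=n_plant, endpoint=True)
        gc = rc + rng.integers(*_CANOPY_DELTA, size=n_plant, endpoint=True)
        bc = rng.integers(*_CANOPY_B, size=n_plant, endpoint=True)
        r[truth], g[truth], b[truth] = rc, gc, bc
        n_shadow = int(round(spec.shadow_fraction * n_plant))
        if n_shadow:
            idx = rng.choice(np.flatnonzero(truth.ravel()), size=n_shadow, replace=False)
            rs = rng.integers(*_SHADOW_R, size=n_shadow, endpoint=True)
            gs = rs + rng.integers(*_SHADOW_DELTA, size=n_shadow, endpoint=True)
            bs = rng.integers(30, 51, size=n_shadow)
            r.ravel()[idx], g.ravel()[idx], b.ravel()[idx] = rs, gs, bs
    pixels = np.stack([r, g, b], axis=-1)
    return RGBImage(np.clip(pixels, 0, 255).astype(np.uint8)), CanopyMask(truth)


# -- fast-mode feature emission ---------------------------------------------


def _emit_features_fast(
    samples: pd.DataFrame, params: GrowthParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Emit per-sample 21-feature vectors without rasterising frames.

    Channel means are modelled as a mixture of lit-canopy, shadowed-canopy
    and soil colour components weighted by the true cover; the shaded
    fraction grows quadratically with cover, so measured cover (the lit
    fraction) saturates under closing canopies exactly as segmentation of
    a rendered frame would.
    """
    rows = []
    for row in samples.itertuples():
        vp = params.varieties[row.variety]
        true_cc = target_cover(row.cvp, vp.cc_curve)
        s_eff = params.shadow_fraction * true_cc**2
        lit = true_cc * (1.0 - s_eff)
        shaded = true_cc * s_eff
        soil = 1.0 - true_cc

        canopy = np.array(
            [
                rng.uniform(55, 75),
                0.0,
                rng.uniform(35, 60),
            ]
        )
        canopy[1] = canopy[0] + rng.uniform(55, 85)
        shadow_col = np.array([rng.uniform(45, 65), 0.0, rng.uniform(30, 50)])
        shadow_col[1] = shadow_col[0] + rng.uniform(0, 8)
        soil_col = np.array([rng.uniform(100, 120), 0.0, rng.uniform(65, 85)])
        soil_col[1] = soil_col[0] + rng.uniform(-5, 5)

        before = lit * canopy + shaded * shadow_col + soil * soil_col
        cc_meas = lit + (rng.normal(0.0, params.cc_noise_sd) if params.cc_noise_sd else 0.0)
        cc_meas = float(np.clip(cc_meas, 0.0, 1.0))

        vi_before = compute_all_vis(
            ChannelMeans(before[0], before[1], before[2], n_pixels=192 * 108)
        )
        if cc_meas > 0:
            vi_after = compute_all_vis(
                ChannelMeans(canopy[0], canopy[1], canopy[2], n_pixels=192 * 108)
            )
        else:
            vi_after = {k: np.nan for k in vi_before}
        fv = FeatureVector(
            image_id=row.sample_id, cc=cc_meas, vi_before=vi_before, vi_after=vi_after
        )
        rows.append({"sample_id": row.sample_id, **fv.as_dict()})
    return pd.DataFrame(rows)


def _emit_features_images(
    samples: pd.DataFrame,
    params: GrowthParams,
    rng: np.random.Generator,
    scale: float = 0.1,
    threshold: int = 10,
    outdir=None,
) -> pd.DataFrame:
    """Render one frame per sample and run the real feature extraction."""
    from pathlib import Path

    w, h = max(8, int(round(1920 * scale))), max(8, int(round(1080 * scale)))
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for row in samples.itertuples():
        vp = params.varieties[row.variety]
        true_cc = target_cover(row.cvp, vp.cc_curve)
        spec = RenderSpec(
            width=w,
            height=h,
            target_cc=true_cc,
            variety_type=row.variety_type,
            shadow_fraction=params.shadow_fraction * true_cc,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth = render_canopy_image(spec)
        if outdir is not None:
            write_image(image, outdir / "images" / f"{row.sample_id}.png")
            write_mask(truth, outdir / "masks" / f"{row.sample_id}.png")
        fv = extract_features(image, threshold=threshold, image_id=row.sample_id)
        rows.append({"sample_id": row.sample_id, **fv.as_dict()})
    return pd.DataFrame(rows)


def generate_dataset(
    config: DesignConfig = DesignConfig(),
    params: GrowthParams = GrowthParams(),
    seed: int = 0,
    mode: str = "fast",
    scale: float = 0.1,
    threshold: int = 10,
    outdir=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """End-to-end synthetic dataset: design -> growth -> yield -> features.

    Returns (samples, features, manifest). ``mode='fast'`` emits feature
    vectors directly; ``mode='images'`` renders a frame per sample (at
    ``scale`` times the full 1920x1080 resolution) and extracts features
    from it. When ``outdir`` is given, samples.csv, features.csv and
    manifest.json (plus images/ and masks/ in image mode) are written
    there. Regenerating from the manifest seed reproduces the outputs.
    """
    if mode not in ("fast", "images"):
        raise ValidationError(f"mode must be 'fast' or 'images', got {mode!r}")
    ss = np.random.SeedSequence(seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(("growth", "yield", "render"), ss.spawn(3))
    }
    design = simulate_design(config)
    samples = simulate_growth(design, params, streams["growth"])
    samples = simulate_yield(samples, params, streams["yield"])
    samples["yield_level"] = [
        yield_level(y, t) for y, t in zip(samples["yield_kg_ha"], samples["variety_type"])
    ]
    if mode == "fast":
        features = _emit_features_fast(samples, params, streams["render"])
    else:
        features = _emit_features_images(
            samples, params, streams["render"], scale=scale, threshold=threshold, outdir=outdir
        )
    manifest = {
        "seed": seed,
        "mode": mode,
        "scale": scale,
        "threshold": threshold,
        "n_plots": int(samples["plot_id"].nunique()),
        "n_samples": int(len(samples)),
        "version": __version__,
        "design": {
            "sites": [[s, [list(v) for v in vs]] for s, vs in config.sites],
            "n_rates": list(config.n_rates),
            "replicates": config.replicates,
            "stages": list(config.stages),
        },
        "growth_params": {
            "n_base": params.n_base,
            "n_gamma": params.n_gamma,
            "n_max": params.n_max,
            "noise_sd": params.noise_sd,
            "shadow_fraction": params.shadow_fraction,
            "cc_noise_sd": params.cc_noise_sd,
            "varieties": {v: asdict(vp) for v, vp in params.varieties.items()},
            "yield_models": {k: list(v) for k, v in params.yield_models.items()},
        },
    }
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        samples[["sample_id", *SAMPLE_COLUMNS, "yield_level"]].to_csv(
            outdir / "samples.csv", index=False
        )
        features.to_csv(outdir / "features.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return samples, features, manifest
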