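"""Synthetic screening plates with known ground truth.

Forward model of a QD-imaging screening well: an inhibitor at concentration
x leaves a fraction ``level(x)`` of the control aggregate density; the well
image contains ``n ~ Poisson(level * lambda_max)`` Gaussian puncta (isotropic
width ``psf_sigma``) at uniform positions on a constant background, plus
Gaussian read noise, clipped to the bit depth.

The latent aggregate load follows an asymmetric logistic in concentration,

    level(x) = floor_frac + (1 - floor_frac) / (1 + (x/c)^hill_b)^asym_g .

Because puncta placement is Poisson, the image variance is proportional to
the aggregate load (Campbell's theorem), so the measured SD statistic scales
as sqrt(level): the expected SD readout of this load curve is itself an
asymmetric logistic with asymmetry ``asym_g / 2``.  ``ec50_true`` is defined
on the readout scale - it is the concentration at which the *expected
normalized SD* is halfway between its plateaus, i.e. exactly what the
fitting stage estimates.  ``c`` is therefore chosen as
``ec50_to_c(ec50_true, hill_b, asym_g / 2)``; with floor_frac = 0 the latent
load at ec50_true is 1/4 while the SD readout is 1/2 of control.

Everything here is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import MANIFEST_COLUMNS, WellImage, write_image, write_manifest, score_wells
from .dose_response import ec50_to_c, fit_series, normalize

__all__ = [
    "SampleTruth",
    "ImagingModel",
    "ThTTruth",
    "aggregation_level",
    "render_well",
    "make_plate",
    "write_plate",
    "write_truth",
    "read_truth",
    "simulate_tht",
    "simulate_viability",
    "recovery_harness",
]


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth dose-response of one synthetic sample.

    ``ec50_true`` is the half-max concentration of the expected normalized
    SD readout (see module docstring); ``hill_b``/``asym_g`` are the slope
    and asymmetry of the latent load curve; ``floor_frac`` is the fraction
    of control aggregate density remaining at full inhibition (0 = complete
    inhibition, 1 = inert sample).
    """

    sample_id: str
    ec50_true: float
    hill_b: float = 1.5
    asym_g: float = 1.0
    floor_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ec50_true <= 0:
            raise ValueError("ec50_true must be > 0")
        if self.hill_b <= 0 or self.asym_g <= 0:
            raise ValueError("hill_b and asym_g must be > 0")
        if not 0.0 <= self.floor_frac <= 1.0:
            raise ValueError("floor_frac must be within [0, 1]")


@dataclass(frozen=True)
class ImagingModel:
    """Forward imaging model for one well (defaults sized for a 16-bit
    camera; the image must be at least 432 x 432 so the analysis crop is
    always defined)."""

    image_shape: tuple[int, int] = (1000, 1000)
    bit_depth: int = 16
    background_level: float = 500.0
    lambda_max: float = 1500.0
    psf_sigma: float = 3.0
    puncta_amplitude_mean: float = 2000.0
    puncta_amplitude_sd: float = 400.0
    noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.lambda_max < 0:
            raise ValueError("lambda_max must be >= 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if min(self.image_shape) < 432:
            raise ValueError("image_shape must be at least 432 x 432")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class ThTTruth:
    """Ground truth for thioflavin-T aggregation kinetics: a logistic
    fluorescence rise to ``f_max`` with rate ``rate_k`` (1/h) and midpoint
    ``t_half`` (h), attenuated by ``inhibition_fn(conc)`` in [0, 1]."""

    f_max: float
    rate_k: float
    t_half: float
    inhibition_fn: Callable[[float], float]

    def __post_init__(self) -> None:
        if self.f_max < 0:
            raise ValueError("f_max must be >= 0")
        if self.rate_k <= 0:
            raise ValueError("rate_k must be > 0")


# ---------------------------------------------------------------------------

def aggregation_level(conc: float, truth: SampleTruth) -> float:
    """Fraction of control aggregate density remaining at concentration conc."""
    conc = float(conc)
    if not math.isfinite(conc) or conc < 0:
        raise ValueError(f"concentration must be finite and >= 0, got {conc}")
    # SD readout ~ sqrt(load) halves the asymmetry, hence asym_g / 2 here:
    # this places the half-max of the expected SD response at ec50_true.
    c = ec50_to_c(truth.ec50_true, truth.hill_b, truth.asym_g / 2.0)
    core = 1.0 / (1.0 + (conc / c) ** truth.hill_b) ** truth.asym_g
    return truth.floor_frac + (1.0 - truth.floor_frac) * core


def render_well(level: float, model: ImagingModel,
                seed: int | np.random.SeedSequence = 0, well_id: str = "") -> WellImage:
    """Render one well image at a given aggregation level (in [0, 1])."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level must be within [0, 1], got {level}")
    rng = np.random.default_rng(seed)
    h, w = model.image_shape
    img = np.full((h, w), float(model.background_level))
    n = int(rng.poisson(level * model.lambda_max))
    if n:
        rows = rng.uniform(0, h, n)
        cols = rng.uniform(0, w, n)
        amps = np.clip(rng.normal(model.puncta_amplitude_mean,
                                  model.puncta_amplitude_sd, n), 0.0, None)
        rad = int(math.ceil(4.0 * model.psf_sigma))
        two_s2 = 2.0 * model.psf_sigma ** 2
        for r, c, amp in zip(rows, cols, amps):
            r0, r1 = max(int(r) - rad, 0), min(int(r) + rad + 1, h)
            c0, c1 = max(int(c) - rad, 0), min(int(c) + rad + 1, w)
            gr = np.exp(-((np.arange(r0, r1) - r) ** 2) / two_s2)
            gc = np.exp(-((np.arange(c0, c1) - c) ** 2) / two_s2)
            img[r0:r1, c0:c1] += amp * np.outer(gr, gc)
    if model.noise_sd > 0:
        img += rng.normal(0.0, model.noise_sd, (h, w))
    maxval = 2 ** model.bit_depth - 1
    img = np.clip(np.rint(img), 0, maxval)
    dtype = np.uint8 if model.bit_depth == 8 else np.uint16
    return WellImage(img.astype(dtype), bit_depth=model.bit_depth,
                     channel_tag="gray", well_id=well_id)


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic per-well seed derived from the top-level seed."""
    return int(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key))
               .generate_state(1)[0])


def make_plate(truths: Sequence[SampleTruth], concs: Sequence[float], n_reps: int,
               model: ImagingModel | None = None, seed: int = 0,
               n_controls: int = 3, n_blanks: int = 3
               ) -> tuple[pd.DataFrame, dict[str, WellImage]]:
    """Generate one synthetic plate: images for every (sample, conc, rep)
    plus aggregation-control wells (level 1) and blanks (level 0).

    Returns the manifest (one row per well, image paths relative to the
    eventual plate directory) and a dict of in-memory images keyed by
    well id.
    """
    model = model or ImagingModel()
    ids = [t.sample_id for t in truths]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample_id in truths: {sorted(ids)}")
    concs = [float(c) for c in concs]
    if not concs:
        raise ValueError("concs must be non-empty")
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    rows: list[dict] = []
    images: dict[str, WellImage] = {}
    idx = 0

    def add_well(well_id: str, sample_id: str, conc: float, rep: int, role: str, level: float):
        nonlocal idx
        images[well_id] = render_well(level, model, _child_seed(seed, idx), well_id)
        rows.append(dict(image_path=f"{well_id}.tif", well_id=well_id, sample_id=sample_id,
                         conc_ug_ml=conc, replicate=rep, role=role))
        idx += 1

    for truth in truths:
        for ci, conc in enumerate(concs):
            level = aggregation_level(conc, truth)
            for rep in range(1, n_reps + 1):
                add_well(f"{truth.sample_id}_c{ci:02d}_r{rep}", truth.sample_id,
                         conc, rep, "test", level)
    for k in range(1, n_controls + 1):
        add_well(f"abeta_control_r{k}", "abeta_control", 0.0, k, "abeta_control", 1.0)
    for k in range(1, n_blanks + 1):
        add_well(f"blank_r{k}", "blank", 0.0, k, "blank", 0.0)

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return manifest, images


def write_truth(path: str | Path, truths: Sequence[SampleTruth],
                model: ImagingModel, seed: int, concs: Sequence[float],
                n_reps: int) -> Path:
    import yaml

    doc = {
        "seed": int(seed),
        "concs_ug_ml": [float(c) for c in concs],
        "n_reps": int(n_reps),
        "imaging_model": {**asdict(model), "image_shape": list(model.image_shape)},
        "truths": [asdict(t) for t in truths],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_truth(path: str | Path) -> dict:
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    doc["truths"] = [SampleTruth(**t) for t in doc["truths"]]
    im = dict(doc["imaging_model"])
    im["image_shape"] = tuple(im["image_shape"])
    doc["imaging_model"] = ImagingModel(**im)
    return doc


def write_plate(outdir: str | Path, manifest: pd.DataFrame,
                images: Mapping[str, WellImage], truths: Sequence[SampleTruth] | None = None,
                model: ImagingModel | None = None, seed: int = 0,
                concs: Sequence[float] = (), n_reps: int = 0) -> Path:
    """Persist a plate: TIFFs, manifest.csv and (when given) truth.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for row in manifest.itertuples(index=False):
        write_image(images[row.well_id], outdir / row.image_path)
    write_manifest(manifest, outdir / "manifest.csv")
    if truths is not None:
        write_truth(outdir / "truth.yaml", truths, model or ImagingModel(),
                    seed, concs, n_reps)
    return outdir


# ---------------------------------------------------------------------------
# orthogonal assays

def simulate_tht(truth: ThTTruth, concs: Sequence[float], times: Sequence[float],
                 noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Simulate ThT fluorescence time courses over a 24 h window.

    Returns a wide table: ``time_h`` plus one ``conc_<x>`` column per
    concentration; trace(t) = (1 - inhibition) * f_max logistic + noise.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0 or times[-1] > 24:
        raise ValueError("times must lie within [0, 24] h")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"time_h": times})
    for conc in concs:
        inh = float(np.clip(truth.inhibition_fn(float(conc)), 0.0, 1.0))
        trace = (1.0 - inh) * truth.f_max / (1.0 + np.exp(-truth.rate_k * (times - truth.t_half)))
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, times.size)
        out[f"conc_{conc:g}"] = trace
    return out


def simulate_viability(group_means: Mapping[str, float], n_reps: int,
                       noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Simulate MTT absorbances: per-group Gaussian replicates around the
    configured means.  Long format: group, replicate, absorbance."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    for group, mean in group_means.items():
        if mean < 0:
            raise ValueError(f"group {group!r} has negative mean absorbance {mean}")
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean in group_means.items():
        values = np.full(n_reps, float(mean))
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, n_reps)
        for rep, v in enumerate(values, start=1):
            rows.append(dict(group=group, replicate=rep, absorbance=float(v)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter-recovery harness

def default_dilution_series(top: float = 100.0, n_points: int = 7,
                            factor: float = 2.0) -> list[float]:
    """7-point 2-fold dilution series topping at 100 ug/mL, ascending."""
    return sorted(top / factor ** k for k in range(n_points))


def recovery_harness(n_runs: int = 20, ec50_truths: Sequence[float] = (2.0, 10.0, 40.0),
                     seed: int = 0, model: ImagingModel | None = None,
                     concs: Sequence[float] | None = None, n_reps: int = 3,
                     include_null: bool = True, rel_tol: float = 0.25) -> pd.DataFrame:
    """Run the full pipeline on seeded synthetic plates and compare the
    estimated EC50s with truth.

    Each run renders a plate (one sample per true EC50, plus an inert
    zero-effect sample when ``include_null``), scores it with the imaging
    stage, normalizes against the plate's controls and fits per replicate.
    Returns one row per (run, sample) with the estimate, the ND flag and
    whether the estimate fell within ``rel_tol`` of truth.
    """
    model = model or ImagingModel()
    concs = list(concs) if concs is not None else default_dilution_series()
    records = []
    for run in range(n_runs):
        truths = [SampleTruth(f"s{j + 1:02d}", float(e)) for j, e in enumerate(ec50_truths)]
        if include_null:
            truths.append(SampleTruth("null", 1000.0, floor_frac=1.0))
        run_seed = _child_seed(seed, 9001, run)
        manifest, images = make_plate(truths, concs, n_reps, model, seed=run_seed)
        scores = score_wells(manifest, images)
        series = normalize(scores)
        for truth in truths:
            _, res = fit_series(series[truth.sample_id], mode="per_replicate")
            rel_err = (res.ec50_mean - truth.ec50_true) / truth.ec50_true
            records.append(dict(
                run=run, sample_id=truth.sample_id, ec50_true=truth.ec50_true,
                is_null=truth.floor_frac >= 1.0, ec50_est=res.ec50_mean,
                ec50_sd=res.ec50_sd, nd=res.nd_flag,
                rel_err=rel_err if not res.nd_flag else float("nan"),
                within_tol=bool(not res.nd_flag and np.isfinite(rel_err)
                                and abs(rel_err) <= rel_tol),
            ))
    return pd.DataFrame(records)
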