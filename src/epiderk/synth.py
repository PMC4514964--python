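"""Synthetic ROI tables and partition profiles for the analysis pipeline.

The original confocal image data behind this analysis were never
deposited, so this module generates tabular samples with the statistical
structure the pipeline assumes: three patients, the study's panel of
targets and subcellular compartments, smooth depth-dependent intensity
trends plus per-patient offsets and Gaussian noise.  Sample positions are
drawn uniformly on the layer-normalized ordinate u in [0, 3); boundary
distances d1, d2 are back-computed from u and a nominal layer thickness so
that the conditioning module's round trip recovers u exactly.

Three trend sources are available:

``piecewise_catalog``
    Monotone-rise-then-drop shapes in model depth, qualitatively matching
    the measured phospho-protein profiles (gradual increase over the
    spinous/granular layers, decline in the transitional layer); CaM peaks
    at the basal/spinous boundary instead.
``model_forward``
    Steady-state spatial profiles of the cascade model itself, mapped to
    the matching target/compartment (nuclear phospho-Raf-1, which the
    model does not represent, reuses the cytoplasmic Raf-1 curve).
``flat``
    No spatial trend (for calibration/null experiments).

With ``scramble=True`` intensities are permuted across positions within
each patient/target/compartment, destroying spatial conditioning while
preserving every marginal distribution — the null the permutation test is
calibrated against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import CascadeParameters, cam_input, spatial_profile
from .conditioning import PartitionProfile, to_model_depth
from .exceptions import ConfigError

__all__ = ["SynthConfig", "PANEL", "synth_roi_table", "synth_profiles_from_model"]

#: target/compartment panel of the study: phospho-Raf-1, phospho-MEK-1/2 and
#: phospho-ERK-1/2 in cytoplasm and nucleus; calmodulin at the plasma membrane.
PANEL = (
    ("pRaf1", "cytoplasm"),
    ("pRaf1", "nucleus"),
    ("pMEK", "cytoplasm"),
    ("pMEK", "nucleus"),
    ("pERK", "cytoplasm"),
    ("pERK", "nucleus"),
    ("CaM", "plasma_membrane"),
)

# (peak depth, drop fraction) of the rise-then-drop catalog trends; the
# phospho-kinases rise over the spinous/granular layers and drop in the
# transitional layer (strongly for Raf/MEK, mildly for ERK); membrane CaM
# peaks at the basal/spinous boundary and decays superficially.
_CATALOG = {
    ("pRaf1", "cytoplasm"): (5.5, 0.9),
    ("pRaf1", "nucleus"): (5.5, 0.5),
    ("pMEK", "cytoplasm"): (5.5, 0.9),
    ("pMEK", "nucleus"): (5.0, 0.9),
    ("pERK", "cytoplasm"): (5.5, 0.3),
    ("pERK", "nucleus"): (5.5, 0.2),
    ("CaM", "plasma_membrane"): (1.0, 0.8),
}
_Z_LO, _Z_HI = -1.2, 1.2

_MODEL_SPECIES = {
    ("pRaf1", "cytoplasm"): "rafc",
    ("pRaf1", "nucleus"): "rafc",  # no nuclear Raf species in the model
    ("pMEK", "cytoplasm"): "mekc",
    ("pMEK", "nucleus"): "mekn",
    ("pERK", "cytoplasm"): "erkc",
    ("pERK", "nucleus"): "erkn",
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic ROI-table generator.

    Defaults emulate the study design: 3 patients, the full 7-series
    panel, modest measurement noise in z-score units and per-patient
    intensity offsets (each labeling experiment has its own scale).  The
    per-target sample count per patient is not reported for the original
    study; 300 gives dense coverage of all 28 fine partitions.
    """

    seed: int = 0
    n_patients: int = 3
    samples_per_patient: int = 300
    noise_sd: float = 0.1
    patient_offset_sd: float = 0.2
    trend_source: str = "piecewise_catalog"
    scramble: bool = False
    layer_thickness: float = 30.0
    heteroscedastic: bool = False
    targets: tuple = PANEL

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.samples_per_patient < 1:
            raise ConfigError("patient and sample counts must be positive")
        if self.noise_sd < 0 or self.patient_offset_sd < 0:
            raise ConfigError("noise and offset SDs must be nonnegative")
        if self.trend_source not in ("model_forward", "piecewise_catalog", "flat"):
            raise ConfigError(f"unknown trend_source {self.trend_source!r}")
        if self.layer_thickness <= 0:
            raise ConfigError("layer_thickness must be positive")


def _catalog_trend(d: np.ndarray, peak: float, drop: float) -> np.ndarray:
    """Rise linearly to the peak depth, then drop a fraction of the range."""
    rise = _Z_LO + (_Z_HI - _Z_LO) * np.minimum(d / peak, 1.0)
    fall = np.maximum(d - peak, 0.0) / (7.0 - peak) * drop * (_Z_HI - _Z_LO)
    return rise - fall


def _trend_functions(config: SynthConfig, params: CascadeParameters | None):
    """One trend callable (of u) per target/compartment in the panel."""
    trends = {}
    if config.trend_source == "flat":
        for key in config.targets:
            trends[key] = lambda u: np.zeros_like(np.asarray(u, dtype=float))
    elif config.trend_source == "piecewise_catalog":
        for key in config.targets:
            peak, drop = _CATALOG[key]
            trends[key] = (
                lambda u, pk=peak, dr=drop:
                _catalog_trend(np.asarray(to_model_depth(u)), pk, dr)
            )
    else:  # model_forward
        p = params if params is not None else CascadeParameters()
        profile = spatial_profile(p, step=0.5)
        for key in config.targets:
            if key == ("CaM", "plasma_membrane"):
                trends[key] = lambda u, pp=p: np.asarray(
                    cam_input(to_model_depth(u), pp.b_cam, pp.a_cam)
                )
            else:
                curve = profile.species(_MODEL_SPECIES[key])
                trends[key] = (
                    lambda u, c=curve, dd=profile.depths:
                    np.interp(np.asarray(to_model_depth(u)), dd, c)
                )
    return trends


def synth_roi_table(
    config: SynthConfig, params: CascadeParameters | None = None
) -> pd.DataFrame:
    """Generate a synthetic ROI sample table.

    Returns a DataFrame with columns ``patient, target, compartment,
    layer_index, d1, d2, intensity``.  Positions u are uniform on [0, 3);
    layer_index = floor(u); d1 = frac * T and d2 = (1 - frac) * T for the
    nominal layer thickness T, so conditioning recovers u exactly.
    Intensity = trend(u) + patient offset + Gaussian noise (optionally
    heteroscedastic, with SD growing linearly by 50 % from the deep to the
    superficial surface).  Byte-identical output under a fixed seed.
    """
    # separate stream for scrambling so positions/intensities are identical
    # between scrambled and unscrambled tables generated from the same seed
    rng = np.random.default_rng([config.seed, 0])
    scrambler = np.random.default_rng([config.seed, 1])
    trends = _trend_functions(config, params)
    frames = []
    for ip in range(config.n_patients):
        patient = f"patient{ip + 1}"
        offset = rng.normal(0.0, config.patient_offset_sd)
        for target, compartment in config.targets:
            m = config.samples_per_patient
            u = rng.uniform(0.0, 3.0, size=m)
            layer = np.floor(u).astype(int)
            frac = u - layer
            sd = config.noise_sd * (
                1.0 + 0.5 * u / 3.0 if config.heteroscedastic else 1.0
            )
            intensity = trends[(target, compartment)](u) + offset + rng.normal(
                0.0, 1.0, size=m
            ) * sd
            if config.scramble:
                intensity = scrambler.permutation(intensity)
            frames.append(
                pd.DataFrame(
                    {
                        "patient": patient,
                        "target": target,
                        "compartment": compartment,
                        "layer_index": layer,
                        "d1": frac * config.layer_thickness,
                        "d2": (1.0 - frac) * config.layer_thickness,
                        "intensity": intensity,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def synth_profiles_from_model(
    params: CascadeParameters,
    gain: float | tuple[float, float] = 1.0,
    offset: float | tuple[float, float] = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    standardize: bool = False,
) -> tuple[PartitionProfile, PartitionProfile]:
    """Forward-generate phospho-ERK partition profiles from the model.

    Solves the cascade to steady state at the 7 coarse partition centers
    (d = 0.5, 1.5, ..., 6.5) and returns cytoplasmic and nuclear
    phospho-ERK profiles mapped through ``gain * x + offset`` with
    additive Gaussian noise — the forward counterpart of
    :func:`epiderk.fitting.fit_inputs`.  ``gain``/``offset`` may be
    scalars or per-species (cytoplasmic, nuclear) pairs.

    With ``standardize=True`` each species' noise-free curve is first
    mapped to mean 0, SD 1 — emulating the per-experiment z-scoring of
    the real intensity data, so that ``noise_sd`` is measurement noise
    relative to each profile's own spatial variation (the nuclear
    phospho-ERK steady-state curve spans a far smaller absolute range
    than the cytoplasmic one).
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    centers = np.arange(7) + 0.5
    profile = spatial_profile(params, depths=centers)
    gains = np.broadcast_to(np.asarray(gain, dtype=float), (2,))
    offsets = np.broadcast_to(np.asarray(offset, dtype=float), (2,))
    out = []
    for i, (species, (target, compartment)) in enumerate((
        ("erkc", ("pERK", "cytoplasm")),
        ("erkn", ("pERK", "nucleus")),
    )):
        curve = profile.species(species)
        if standardize:
            sd = curve.std()
            if sd > 0:
                curve = (curve - curve.mean()) / sd
        vals = gains[i] * curve + offsets[i]
        vals = vals + rng.normal(0.0, noise_sd, size=vals.size)
        out.append(
            PartitionProfile(
                scheme="coarse7",
                values=vals,
                counts=np.ones(7, dtype=int),
                target=target,
                compartment=compartment,
            )
        )
    return out[0], out[1]
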