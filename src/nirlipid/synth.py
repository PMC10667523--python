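"""Synthetic diet-structured livers: compositions and raw NIR frames.

The generator emulates the statistical structure the analysis assumes so
that the whole pipeline (reflectance correction, SNV, kernel-regression
calibration, per-pixel mapping) can run without instrument data:

* five default diet groups (ND, HFD, HCD, 2% LA, 12% LA) whose mean
  fatty-acid compositions are solved in closed form so their pooled HCL
  and DS equal the published per-group liver means, with Dirichlet
  sampling around each mean emulating lobe-to-lobe variability;
* a Beer-Lambert-style band model in which each CH functional group
  absorbs as a Gaussian overtone band (CH3 ~1150 nm, CH2 ~1175 nm,
  CH ~1190 nm) scaled by the pooled group count and the total lipid
  content, on top of a per-sample linear scatter baseline and a water
  edge rising above ~1350 nm;
* raw/dark/white camera frames on the instrument's 760-1885 nm, 2.2 nm
  grid, with shot-like and readout noise and isolated single-band spike
  artifacts.

Every draw is controlled by an integer seed; identical specs give
bit-identical cubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    FattyAcid,
    FattyAcidComposition,
    composition_profile,
    count_functional_groups,
    parse_fatty_acid,
)
from .preprocess import (
    HyperspectralCube,
    SampleSpectrum,
    sample_spectrum_from_frames,
)

__all__ = [
    "DietProfile",
    "GaussianBand",
    "BandModel",
    "NoiseModel",
    "Region",
    "SceneSpec",
    "instrument_wavelengths",
    "profile_from_group_means",
    "default_diet_profiles",
    "sample_composition",
    "absorption_spectrum",
    "render_cube",
    "simulate_study",
    "elliptical_mask",
    "tumor_scene",
]

#: Instrument wavelength grid: 512 bands from 760 nm at 2.2 nm spacing.
GRID_START_NM = 760.0
GRID_STEP_NM = 2.2
GRID_BANDS = 512


def instrument_wavelengths(
    start: float = GRID_START_NM,
    step: float = GRID_STEP_NM,
    n_bands: int = GRID_BANDS,
) -> np.ndarray:
    return start + step * np.arange(n_bands)


@dataclass(frozen=True)
class DietProfile:
    """A diet group's composition template and lipid level.

    ``concentration`` is the Dirichlet dispersion: draws are
    Dirichlet(concentration * mean_fractions); larger means tighter
    around the template (infinity returns the template itself).
    """

    name: str
    mean_fractions: FattyAcidComposition
    lipid_mean: float
    lipid_sd: float
    concentration: float = 150.0

    def __post_init__(self) -> None:
        if self.lipid_mean <= 0:
            raise ValueError("lipid_mean must be positive (mg/g)")
        if not (self.concentration > 0):
            raise ValueError("concentration must be > 0")


@dataclass(frozen=True)
class GaussianBand:
    center_nm: float
    width_nm: float
    weight: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.weight * np.exp(
            -0.5 * ((wavelengths - self.center_nm) / self.width_nm) ** 2
        )


@dataclass(frozen=True)
class BandModel:
    """Per-functional-group overtone bands plus a water edge.

    The CH2 second overtone sits near 1175 nm, CH3 near 1150 nm and the
    CH band near 1190 nm; the weak CH3 weight reflects that a straight
    chain carries a single methyl group whose absorption is easily
    swamped by neighbours.  Water is modelled only as a rising edge
    above ~1350 nm so the 1000-1400 nm crop has something to cut.
    """

    ch3: GaussianBand = GaussianBand(1150.0, 12.0, 0.25)
    ch2: GaussianBand = GaussianBand(1175.0, 12.0, 1.0)
    ch: GaussianBand = GaussianBand(1190.0, 12.0, 1.0)
    water_edge_nm: float = 1430.0
    water_width_nm: float = 35.0
    water_weight: float = 0.6
    lipid_scale: float = 0.02  # absorbance units per (mg/g / 100) per group count

    def water(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (wavelengths - self.water_edge_nm) / self.water_width_nm
        return self.water_weight / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: multiplicative shot-like, additive readout (counts),
    and a per-(pixel, band) rate of isolated positive spike artifacts."""

    shot: float = 0.003
    readout: float = 2.0
    spike_rate: float = 2e-4
    spike_amplitude: float = 0.2  # fraction of the white level; >= 10 sigma

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(shot=0.0, readout=0.0, spike_rate=0.0)


@dataclass(frozen=True)
class Region:
    name: str
    mask: np.ndarray
    profile: DietProfile


@dataclass(frozen=True)
class SceneSpec:
    """One simulated acquisition: image geometry, disjoint tissue regions
    with their diet profiles, noise levels and the master seed."""

    height: int
    width: int
    regions: tuple[Region, ...]
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    baseline_offset_range: tuple[float, float] = (0.10, 0.30)
    baseline_slope_range: tuple[float, float] = (-0.05, 0.05)
    lipid_pixel_cv: float = 0.04
    wavelengths: np.ndarray = field(default_factory=instrument_wavelengths)

    def __post_init__(self) -> None:
        total = np.zeros((self.height, self.width), dtype=int)
        for r in self.regions:
            if r.mask.shape != (self.height, self.width):
                raise ValueError(f"region {r.name!r} mask does not fit the image")
            total += r.mask.astype(int)
        if (total > 1).any():
            raise ValueError("regions must be disjoint")

    @property
    def tissue_mask(self) -> np.ndarray:
        mask = np.zeros((self.height, self.width), dtype=bool)
        for r in self.regions:
            mask |= r.mask
        return mask


# ---------------------------------------------------------------------------
# Diet profiles solved from published group means

# Per-group (HCL, DS, lipid mean, lipid SD mg/g) liver statistics.
GROUP_MEANS: dict[str, tuple[float, float, float, float]] = {
    "ND": (17.72, 0.77, 66.2, 20.2),
    "HFD": (17.56, 0.79, 135.0, 54.2),
    "HCD": (17.83, 0.75, 174.2, 35.8),
    "LA2": (17.22, 0.83, 80.4, 27.8),
    "LA12": (17.54, 0.81, 65.2, 24.2),
}

# Diet-specific minor fatty acids and the oleic (18:1) fraction; the major
# 16:0 / 18:2 / 18:3 fractions are solved from the HCL and DS targets.
_MINORS: dict[str, tuple[dict[str, float], float]] = {
    "ND": ({"14:0": 0.02, "16:1": 0.03, "18:0": 0.05, "20:4": 0.05, "22:6": 0.03}, 0.12),
    "HFD": ({"14:0": 0.02, "16:1": 0.04, "18:0": 0.04, "20:4": 0.04, "22:6": 0.02}, 0.18),
    "HCD": ({"14:0": 0.01, "16:1": 0.03, "18:0": 0.05, "20:4": 0.06, "22:6": 0.03}, 0.10),
    "LA2": ({"14:0": 0.08, "16:1": 0.05, "18:0": 0.05, "20:4": 0.02, "22:6": 0.01}, 0.16),
    "LA12": ({"14:0": 0.03, "16:1": 0.03, "18:0": 0.04, "20:4": 0.03, "22:6": 0.02}, 0.14),
}


def profile_from_group_means(
    name: str,
    hcl: float,
    ds: float,
    lipid_mean: float,
    lipid_sd: float,
    *,
    minors: Mapping[str, float] | None = None,
    oleic_fraction: float = 0.14,
    concentration: float = 150.0,
) -> DietProfile:
    """Build a mean composition whose pooled HCL and DS equal the targets.

    The palmitic (16:0) fraction follows from the HCL target (pooled HCL
    is the molar-weighted mean carbon number) and the 18:2 / 18:3 split
    from the DS target, given fixed minor fatty acids and an oleic
    fraction.  Raises if the targets are unreachable with those minors.
    """
    minors = dict(minors if minors is not None else _MINORS.get(name, _MINORS["ND"])[0])
    hclm = nm = dm = 0.0
    for sh, f in minors.items():
        fa = parse_fatty_acid(sh)
        g = count_functional_groups(fa)
        hclm += f * fa.carbons
        nm += f * g.n_ch2
        dm += f * (g.n_ch + g.n_ch2)
    main = 1.0 - sum(minors.values())
    a = (18.0 * main + hclm - hcl) / 2.0  # 16:0 fraction
    b = oleic_fraction
    m2 = main - a - b  # 18:2 + 18:3
    denom = dm + 14.0 * a + 16.0 * (main - a)
    e = (nm + 14.0 * a + 14.0 * b + 12.0 * m2 - ds * denom) / 2.0  # 18:3
    c = m2 - e  # 18:2
    fracs = dict(minors)
    fracs.update({"16:0": a, "18:1": b, "18:2": c, "18:3": e})
    if min(fracs.values()) < 0:
        raise ValueError(
            f"HCL={hcl}, DS={ds} unreachable with the given minors for {name!r}"
        )
    comp = FattyAcidComposition.from_dict(fracs)
    return DietProfile(
        name=name,
        mean_fractions=comp,
        lipid_mean=lipid_mean,
        lipid_sd=lipid_sd,
        concentration=concentration,
    )


def default_diet_profiles(concentration: float = 150.0) -> dict[str, DietProfile]:
    """The five default diet groups, solved from the published group means."""
    out: dict[str, DietProfile] = {}
    for name, (hcl, ds, lm, ls) in GROUP_MEANS.items():
        minors, oleic = _MINORS[name]
        out[name] = profile_from_group_means(
            name, hcl, ds, lm, ls,
            minors=minors, oleic_fraction=oleic, concentration=concentration,
        )
    return out


# ---------------------------------------------------------------------------
# Sampling and spectra

def sample_composition(
    profile: DietProfile,
    seed_or_rng: int | np.random.Generator,
) -> FattyAcidComposition:
    """One lobe's composition: Dirichlet around the template mean, with
    total lipid drawn truncated-normal(lipid_mean, lipid_sd) at zero."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    mean = profile.mean_fractions.fractions
    if np.isinf(profile.concentration):
        fracs = mean.copy()
    else:
        alpha = profile.concentration * mean
        if not np.all(np.isfinite(alpha)):
            raise ValueError("non-finite Dirichlet parameters")
        fracs = rng.dirichlet(alpha)
    lipid = rng.normal(profile.lipid_mean, profile.lipid_sd)
    while lipid <= 0:
        lipid = rng.normal(profile.lipid_mean, profile.lipid_sd)
    entries = tuple(
        (fa, float(f))
        for fa, f in zip(profile.mean_fractions.fatty_acids, fracs / fracs.sum())
    )
    return FattyAcidComposition(entries=entries, total_lipid=float(lipid))


def absorption_spectrum(
    comp: FattyAcidComposition,
    lipid_mg_per_g: float,
    bands: BandModel,
    wavelengths: np.ndarray,
    baseline: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Noise-free absorbance of a tissue of given composition and lipid.

    Each functional group's Gaussian band is scaled by its molar-pooled
    count per molecule and by ``lipid_scale * lipid / 100``; a water edge
    and a linear scatter baseline (offset, slope over the grid) add on.
    Non-negative everywhere by construction.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength axis must be strictly increasing")
    groups = [count_functional_groups(fa) for fa in comp.fatty_acids]
    f = comp.fractions
    ch3_bar = float(f @ [g.n_ch3 for g in groups])
    ch2_bar = float(f @ [g.n_ch2 for g in groups])
    ch_bar = float(f @ [g.n_ch for g in groups])
    amp = bands.lipid_scale * lipid_mg_per_g / 100.0
    spectrum = amp * (
        ch3_bar * bands.ch3.profile(wl)
        + ch2_bar * bands.ch2.profile(wl)
        + ch_bar * bands.ch.profile(wl)
    )
    spectrum += bands.water(wl)
    offset, slope = baseline
    t = (wl - wl.mean()) / (wl[-1] - wl[0] if wl.size > 1 else 1.0)
    spectrum += offset + slope * t
    return np.maximum(spectrum, 0.0)


#: Background (non-tissue) absorbance: a dim, spectrally flat support.
_BACKGROUND_ABSORBANCE = 1.7


def render_cube(
    scene: SceneSpec,
    bands: BandModel = BandModel(),
) -> tuple[HyperspectralCube, HyperspectralCube, HyperspectralCube]:
    """Render a scene into (raw, dark, white) frames.

    The white frame is a smooth lamp profile over a dark level of 100
    counts; raw = dark + (white - dark) * 10^(-A) plus shot/readout noise
    and spike artifacts, so that reflectance correction inverts the model
    exactly when noise is zero.
    """
    rng = np.random.default_rng(scene.seed)
    wl = scene.wavelengths
    h, w, nb = scene.height, scene.width, wl.size
    dark_level = 100.0
    lamp = 3000.0 * (1.0 - 0.3 * ((wl - 1300.0) / 600.0) ** 2)
    dark = np.full((h, w, nb), dark_level)
    white = dark + lamp  # white frame records dark current plus lamp signal

    absorbance = np.full((h, w, nb), _BACKGROUND_ABSORBANCE)
    for region in scene.regions:
        comp = sample_composition(region.profile, rng)
        offset = rng.uniform(*scene.baseline_offset_range)
        slope = rng.uniform(*scene.baseline_slope_range)
        base = absorption_spectrum(
            comp, comp.total_lipid, bands, wl, baseline=(offset, slope)
        )
        lipid_jitter = 1.0 + scene.lipid_pixel_cv * rng.standard_normal(
            (h, w)
        )
        water_and_baseline = bands.water(wl) + offset + slope * (
            (wl - wl.mean()) / (wl[-1] - wl[0])
        )
        lipid_part = base - water_and_baseline
        idx = np.where(region.mask)
        absorbance[idx] = (
            water_and_baseline[None, :]
            + np.clip(lipid_jitter[idx], 0.5, 1.5)[:, None] * lipid_part[None, :]
        )

    signal = lamp * np.power(10.0, -absorbance)
    raw = dark_level + signal
    if scene.noise.shot > 0:
        raw = dark_level + signal * (
            1.0 + scene.noise.shot * rng.standard_normal(raw.shape)
        )
    if scene.noise.readout > 0:
        raw = raw + scene.noise.readout * rng.standard_normal(raw.shape)
    if scene.noise.spike_rate > 0:
        spikes = rng.random(raw.shape) < scene.noise.spike_rate
        raw = raw + spikes * scene.noise.spike_amplitude * (white)
    make = lambda arr, role: HyperspectralCube(arr, wl, role)
    return make(raw, "raw"), make(dark, "dark"), make(white, "white")


def elliptical_mask(
    height: int, width: int,
    center: tuple[float, float] | None = None,
    radii: tuple[float, float] | None = None,
) -> np.ndarray:
    cy, cx = center if center else ((height - 1) / 2, (width - 1) / 2)
    ry, rx = radii if radii else (0.42 * height, 0.42 * width)
    y, x = np.mgrid[0:height, 0:width]
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def single_lobe_scene(
    profile: DietProfile,
    seed: int,
    height: int = 12,
    width: int = 12,
    noise: NoiseModel = NoiseModel(),
) -> SceneSpec:
    """A small one-region scene: one lobe filling most of the frame."""
    mask = elliptical_mask(height, width)
    return SceneSpec(
        height=height,
        width=width,
        regions=(Region(profile.name, mask, profile),),
        noise=noise,
        seed=seed,
    )


def tumor_scene(
    seed: int,
    height: int = 24,
    width: int = 24,
    noise: NoiseModel = NoiseModel(),
    normal_profile: DietProfile | None = None,
    tumor_profile: DietProfile | None = None,
) -> SceneSpec:
    """A lobe with an embedded tumor region: the tumor profile carries
    more linoleic acid (lower DS) and more total lipid than the
    surrounding tissue, the contrast seen in tumor-bearing livers."""
    if normal_profile is None:
        normal_profile = profile_from_group_means(
            "normal", hcl=17.54, ds=0.81, lipid_mean=115.0, lipid_sd=10.0,
            minors=_MINORS["LA12"][0], oleic_fraction=_MINORS["LA12"][1],
        )
    if tumor_profile is None:
        # low oleic leaves room for the dietary 18:2/18:3 driving DS down
        tumor_profile = profile_from_group_means(
            "tumor", hcl=17.54, ds=0.74, lipid_mean=150.0, lipid_sd=10.0,
            minors=_MINORS["LA12"][0], oleic_fraction=0.03,
        )
    lobe = elliptical_mask(height, width)
    tumor = elliptical_mask(
        height, width,
        center=(0.38 * height, 0.62 * width),
        radii=(0.16 * height, 0.16 * width),
    )
    tumor &= lobe
    normal = lobe & ~tumor
    return SceneSpec(
        height=height,
        width=width,
        regions=(
            Region("normal", normal, normal_profile),
            Region("tumor", tumor, tumor_profile),
        ),
        noise=noise,
        seed=seed,
    )


def simulate_study(
    n_per_diet: int = 20,
    profiles: Mapping[str, DietProfile] | None = None,
    bands: BandModel = BandModel(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    lobe_shape: tuple[int, int] = (12, 12),
) -> tuple[list[SampleSpectrum], pd.DataFrame]:
    """Simulate a whole calibration study and preprocess every lobe.

    For each diet profile, ``n_per_diet`` lobes are drawn, rendered as
    raw/dark/white frames and pushed through the per-sample preprocessing
    chain.  Returns the SNV sample spectra and a ground-truth table
    (sample id, diet, lipid mg/g, pooled HCL and DS of the drawn
    composition) for calibration and recovery checks.
    """
    if profiles is None:
        profiles = default_diet_profiles()
    rng = np.random.default_rng(seed)
    spectra: list[SampleSpectrum] = []
    rows = []
    for name, profile in profiles.items():
        for k in range(n_per_diet):
            sample_seed = int(rng.integers(0, 2**31 - 1))
            comp = sample_composition(profile, rng)
            truth = composition_profile(comp)
            # freeze the drawn lobe so the renderer reproduces it exactly
            fixed = DietProfile(
                name=profile.name,
                mean_fractions=comp,
                lipid_mean=comp.total_lipid,
                lipid_sd=0.0,
                concentration=np.inf,
            )
            scene = single_lobe_scene(
                fixed, seed=sample_seed,
                height=lobe_shape[0], width=lobe_shape[1], noise=noise,
            )
            raw, dark, white = render_cube(scene, bands)
            sid = f"{name}-{k:03d}"
            spec = sample_spectrum_from_frames(
                raw, dark, white, roi=scene.tissue_mask, sample_id=sid
            )
            spec.extras.update(diet=name)
            spectra.append(spec)
            rows.append(
                {
                    "sample_id": sid,
                    "diet": name,
                    "total_lipid": comp.total_lipid,
                    "hcl": truth.hcl,
                    "ds": truth.ds,
                }
            )
    return spectra, pd.DataFrame(rows)
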