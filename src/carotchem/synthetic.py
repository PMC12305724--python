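"""Seeded synthetic cohorts: metabolite tables, FT-NIR spectra, extracts.

The real study material (461 field samples with triplicate FT-NIR scans
and UPLC-MS/MS reference concentrations) is not publicly deposited, so
this module emulates its statistical structure from the published
summary parameters, making every downstream stage testable end to end.

Three coupled generators:

``generate_metabolite_profiles``
    Draws per-sample concentrations for the seven binary root-color
    phenotype groups.  Total anthocyanin follows a group-specific
    log-normal law; total cyanidin mass is split into acylated (AcA) vs
    non-acylated (NAA) fractions by a Beta draw, then within-AcA
    (Cy3XSGG/Cy3XFGG/Cy3XCGG) by a Dirichlet draw and within-NAA
    (Cy3XG/Cy3XGG) by a second Beta draw.  Total phenolic acids share a
    latent Gaussian factor with anthocyanin so the cohort-level
    PHEN-ACN correlation has realistic strength.

``simulate_spectra``
    Beer-Lambert forward model: each analyte contributes a fixed
    superposition of Gaussian absorption bands (placed inside the
    wavenumber windows that analyte's calibration model uses), a shared
    sample-matrix component dominates the raw absorbance (~10:1), and a
    multiplicative-slope + additive-baseline scatter model plus white
    noise corrupts each replicate scan.

``simulate_extracts``
    Maps puree pigment concentrations through per-analyte extraction
    efficiencies to steeped-extract concentrations and A420/A520/A700
    absorbances (Cy3XSGG carrying the largest A520 response).

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from carotchem.composition import ACYLATED, NON_ACYLATED, PIGMENTS
from carotchem.spectra import SpectraSet, default_grid

__all__ = [
    "PhenotypeGroupParams",
    "PureComponentSpectrum",
    "ScatterNoiseModel",
    "ExtractSimParams",
    "DEFAULT_GROUPS",
    "default_groups",
    "purple_groups",
    "default_pure_components",
    "generate_metabolite_profiles",
    "simulate_pure_spectra",
    "simulate_spectra",
    "simulate_extracts",
    "ANALYTES",
]

#: The ten modeled responses.
ANALYTES = [
    "Total_ACN", "Total_AcA", "Total_PHEN",
    "Cy3XSGG", "Cy3XFGG", "Cy3XCGG", "Cy3XG", "Cy3XGG",
    "3CQA", "CA",
]

#: Concentrations (ug/100 g dw) at or below this are reported as 0
#: (below the detection threshold of the reference UPLC assay).
DETECTION_FLOOR = 0.02


@dataclass(frozen=True)
class PhenotypeGroupParams:
    """Concentration law for one binary root-color phenotype group.

    Total anthocyanin is log-normal with mean ``acn_mean`` (ug/100 g dw)
    and log-scale spread ``acn_sigma``; the acylated fraction of the
    cyanidin pool is Beta(mean*kappa, (1-mean)*kappa).  ``phen_link`` is
    the loading of the shared latent factor tying total phenolic acids
    to total anthocyanin within the group.
    """

    code: str
    n_samples: int
    acn_mean: float
    acn_sigma: float
    phen_mean: float
    phen_sigma: float
    acyl_mean: float          # mean AcA/(AcA+NAA) fraction
    acyl_kappa: float         # Beta concentration of the AcA/NAA split
    naa_split_mean: float     # mean Cy3XG share of the NAA pool
    naa_split_kappa: float
    aca_shape: tuple[float, float, float]  # Dirichlet shapes (Cy3XSGG, Cy3XFGG, Cy3XCGG)
    phen_shape: tuple[float, float, float] = (52.3, 3.6, 4.1)  # (3CQA, CA, other)
    phen_link: float = 0.35

    def __post_init__(self) -> None:
        from carotchem.phenotype import parse_code

        parse_code(self.code)  # raises on malformed codes
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        for name in ("acn_mean", "acn_sigma", "phen_mean", "phen_sigma",
                     "acyl_kappa", "naa_split_kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.acyl_mean < 1 or not 0 < self.naa_split_mean < 1:
            raise ValueError("split means must lie strictly in (0, 1)")
        if any(s <= 0 for s in self.aca_shape) or any(s <= 0 for s in self.phen_shape):
            raise ValueError("Dirichlet shapes must be positive")
        if not -1 <= self.phen_link <= 1:
            raise ValueError("phen_link must be a correlation in [-1, 1]")


# Within-AcA Dirichlet: mean shares ~ (0.502, 0.473, 0.025) for
# sinapoyl/feruloyl/coumaroyl, low concentration (kappa ~ 3) so individual
# samples range from feruloyl- to sinapoyl-dominated, as observed across
# purple carrot germplasm.  The NAA Beta split is likewise diffuse: some
# genotypes carry no detectable Cy3XG at all.
_ACA_SHAPE = (1.2562, 1.1814, 0.0624)

# Shape parameters below were tuned once (scripts/tune_generator.py) so
# the cohort-level compositional correlations emerge at their published
# strengths; the printed group means enter directly as acn_mean/acyl_mean.
DEFAULT_GROUPS: list[PhenotypeGroupParams] = [
    PhenotypeGroupParams(
        code=":1111", n_samples=60, acn_mean=1799.7, acn_sigma=0.62,
        phen_mean=290.0, phen_sigma=0.45, acyl_mean=0.695, acyl_kappa=22.0,
        naa_split_mean=0.86, naa_split_kappa=1.6, aca_shape=_ACA_SHAPE,
        phen_link=0.35,
    ),
    PhenotypeGroupParams(
        code=":1110", n_samples=25, acn_mean=1100.0, acn_sigma=0.60,
        phen_mean=200.0, phen_sigma=0.45, acyl_mean=0.78, acyl_kappa=20.0,
        naa_split_mean=0.86, naa_split_kappa=1.6, aca_shape=_ACA_SHAPE,
        phen_link=0.35,
    ),
    PhenotypeGroupParams(
        code=":1101", n_samples=20, acn_mean=900.0, acn_sigma=0.60,
        phen_mean=308.2, phen_sigma=0.45, acyl_mean=0.80, acyl_kappa=20.0,
        naa_split_mean=0.86, naa_split_kappa=1.6, aca_shape=_ACA_SHAPE,
        phen_link=0.35,
    ),
    PhenotypeGroupParams(
        code=":1100", n_samples=25, acn_mean=500.0, acn_sigma=0.60,
        phen_mean=190.0, phen_sigma=0.45, acyl_mean=0.85, acyl_kappa=20.0,
        naa_split_mean=0.86, naa_split_kappa=1.6, aca_shape=_ACA_SHAPE,
        phen_link=0.35,
    ),
    PhenotypeGroupParams(
        code=":1001", n_samples=10, acn_mean=250.0, acn_sigma=0.60,
        phen_mean=160.0, phen_sigma=0.45, acyl_mean=0.90, acyl_kappa=24.0,
        naa_split_mean=0.86, naa_split_kappa=1.6, aca_shape=_ACA_SHAPE,
        phen_link=0.35,
    ),
    PhenotypeGroupParams(
        code=":1000", n_samples=25, acn_mean=120.0, acn_sigma=0.60,
        phen_mean=69.0, phen_sigma=0.45, acyl_mean=0.946, acyl_kappa=30.0,
        naa_split_mean=0.86, naa_split_kappa=1.6, aca_shape=_ACA_SHAPE,
        phen_link=0.35,
    ),
    PhenotypeGroupParams(
        code=":0000", n_samples=296, acn_mean=0.5, acn_sigma=1.0,
        phen_mean=165.0, phen_sigma=0.45, acyl_mean=0.60, acyl_kappa=10.0,
        naa_split_mean=0.86, naa_split_kappa=1.6, aca_shape=_ACA_SHAPE,
        phen_link=0.35,
    ),
]


def default_groups(n_scale: float = 1.0) -> list[PhenotypeGroupParams]:
    """Copy of the default seven-group cohort (optionally rescaled sizes)."""
    if n_scale == 1.0:
        return list(DEFAULT_GROUPS)
    return [
        replace(g, n_samples=max(1, round(g.n_samples * n_scale)))
        for g in DEFAULT_GROUPS
    ]


def purple_groups() -> list[PhenotypeGroupParams]:
    """The six purple phenotype groups (165 samples by default)."""
    return [g for g in DEFAULT_GROUPS if g.code != ":0000"]


def generate_metabolite_profiles(
    groups: list[PhenotypeGroupParams] | None = None,
    seed: int = 0,
    detection_floor: float = DETECTION_FLOOR,
) -> pd.DataFrame:
    """Draw a per-sample metabolite table for the given phenotype groups.

    Returns one row per sample with the five cyanidin glycosides, their
    totals (Total_AcA, Total_NAA, Total_ACN), the phenolic acids (3CQA,
    CA, PHEN_other, Total_PHEN), and the phenotype code.  Component
    concentrations at or below ``detection_floor`` are reported as 0.
    Deterministic given (groups, seed).
    """
    if groups is None:
        groups = DEFAULT_GROUPS
    rng = np.random.default_rng(seed)
    frames = []
    for g in groups:
        n = g.n_samples
        if n == 0:
            continue
        z = rng.standard_normal(n)                       # shared latent factor
        z_indep = rng.standard_normal(n)
        acn = g.acn_mean * np.exp(g.acn_sigma * z - 0.5 * g.acn_sigma**2)
        rho = g.phen_link
        z_phen = rho * z + np.sqrt(1.0 - rho**2) * z_indep
        phen = g.phen_mean * np.exp(g.phen_sigma * z_phen - 0.5 * g.phen_sigma**2)

        a = rng.beta(g.acyl_mean * g.acyl_kappa, (1 - g.acyl_mean) * g.acyl_kappa, n)
        aca_split = rng.dirichlet(np.asarray(g.aca_shape), n)      # (n, 3) S/F/C
        w = rng.beta(
            g.naa_split_mean * g.naa_split_kappa,
            (1 - g.naa_split_mean) * g.naa_split_kappa,
            n,
        )
        phen_split = rng.dirichlet(np.asarray(g.phen_shape), n)    # 3CQA/CA/other

        comp = pd.DataFrame(
            {
                "sample_id": [f"{g.code[1:]}_{i:03d}" for i in range(n)],
                "phenotype": g.code,
                "Cy3XSGG": acn * a * aca_split[:, 0],
                "Cy3XFGG": acn * a * aca_split[:, 1],
                "Cy3XCGG": acn * a * aca_split[:, 2],
                "Cy3XG": acn * (1 - a) * w,
                "Cy3XGG": acn * (1 - a) * (1 - w),
                "3CQA": phen * phen_split[:, 0],
                "CA": phen * phen_split[:, 1],
                "PHEN_other": phen * phen_split[:, 2],
            }
        )
        frames.append(comp)
    if not frames:
        raise ValueError("no samples requested (all group sizes zero)")
    table = pd.concat(frames, ignore_index=True)
    # below-detection components report as zero
    conc_cols = PIGMENTS + ["3CQA", "CA", "PHEN_other"]
    values = table[conc_cols].to_numpy()
    values[values <= detection_floor] = 0.0
    table[conc_cols] = values
    table["Total_AcA"] = table[ACYLATED].sum(axis=1)
    table["Total_NAA"] = table[NON_ACYLATED].sum(axis=1)
    table["Total_ACN"] = table["Total_AcA"] + table["Total_NAA"]
    table["Total_PHEN"] = table[["3CQA", "CA", "PHEN_other"]].sum(axis=1)
    return table


# ---------------------------------------------------------------------------
# spectra

@dataclass(frozen=True)
class PureComponentSpectrum:
    """Unit-concentration absorption spectrum of one analyte.

    ``bands`` is a list of (center cm^-1, width cm^-1, amplitude)
    Gaussian bands; the spectrum is their superposition.
    """

    analyte: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for center, width, amp in self.bands:
            if width <= 0:
                raise ValueError(f"{self.analyte}: band width must be positive")
            if amp < 0:
                raise ValueError(f"{self.analyte}: band amplitude must be >= 0")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        out = np.zeros_like(grid)
        for center, width, amp in self.bands:
            if not grid[0] <= center <= grid[-1]:
                raise ValueError(
                    f"{self.analyte}: band center {center} cm^-1 outside grid "
                    f"[{grid[0]}, {grid[-1]}]"
                )
            out += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
        return out


# Per-unit-concentration amplitude scales.  Pigments are quantified in
# ug/100 g dw up to ~4500, phenolic acids up to ~700; the scales below put
# a typical fully-purple sample's analyte signal near 0.04 absorbance
# against a matrix signal near 0.45 (~1:10).
_PIG_AMP = 2.5e-5
_PHEN_AMP = 1.0e-4
# caffeic acid sits at ~20x lower concentration than chlorogenic acid, so
# its per-unit absorptivity is set higher to keep its spectral signature
# above the instrument noise floor (distinct absorptivities per analyte
# are the physical norm under Beer-Lambert mixing)
_CA_AMP = 3.0e-4

def default_pure_components() -> list[PureComponentSpectrum]:
    """Default band sets.

    Each analyte's bands sit inside the wavenumber windows its
    calibration model retains (anthocyanins in 8925-12490 and 4482-7159
    cm^-1, Cy3XSGG around 9820-10715 and 4482-6264 cm^-1, etc.); the
    shared 'matrix' component carries broad water/carbohydrate bands
    common to every sample.
    """
    a, b, c = _PIG_AMP, _PHEN_AMP, _CA_AMP
    return [
        PureComponentSpectrum("Cy3XSGG", (
            (10150.0, 180.0, 1.0 * a), (10550.0, 140.0, 0.6 * a),
            (5050.0, 200.0, 0.8 * a), (5950.0, 160.0, 0.5 * a),
        )),
        PureComponentSpectrum("Cy3XFGG", (
            (9300.0, 170.0, 1.0 * a), (11850.0, 150.0, 0.5 * a),
            (7600.0, 140.0, 0.7 * a), (5800.0, 150.0, 0.4 * a),
        )),
        PureComponentSpectrum("Cy3XCGG", (
            (12050.0, 160.0, 1.0 * a), (8500.0, 200.0, 0.6 * a),
            (4900.0, 150.0, 0.7 * a),
        )),
        PureComponentSpectrum("Cy3XG", (
            (11700.0, 150.0, 1.0 * a), (9900.0, 180.0, 0.7 * a),
            (8600.0, 160.0, 0.5 * a),
        )),
        PureComponentSpectrum("Cy3XGG", (
            (12300.0, 130.0, 1.0 * a), (9100.0, 170.0, 0.8 * a),
            (8200.0, 150.0, 0.4 * a),
        )),
        PureComponentSpectrum("3CQA", (
            (7200.0, 200.0, 1.0 * b), (8900.0, 180.0, 0.6 * b),
            (3900.0, 140.0, 0.9 * b),
        )),
        PureComponentSpectrum("CA", (
            (9150.0, 130.0, 1.0 * c), (7650.0, 120.0, 0.5 * c),
            (5500.0, 180.0, 0.7 * c), (4900.0, 150.0, 0.3 * c),
        )),
        PureComponentSpectrum("PHEN_other", (
            (6500.0, 250.0, 1.0 * b), (4300.0, 200.0, 0.6 * b),
        )),
        # water / carbohydrate matrix, concentration 1 for every sample
        PureComponentSpectrum("matrix", (
            (5155.0, 220.0, 0.45), (6900.0, 260.0, 0.36),
            (4400.0, 200.0, 0.40), (8300.0, 500.0, 0.22),
            (10300.0, 600.0, 0.13),
        )),
    ]


def simulate_pure_spectra(
    components: list[PureComponentSpectrum] | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Evaluate unit-concentration spectra: one row per analyte."""
    if components is None:
        components = default_pure_components()
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    rows = {c.analyte: c.evaluate(grid) for c in components}
    return pd.DataFrame.from_dict(rows, orient="index", columns=grid)


@dataclass(frozen=True)
class ScatterNoiseModel:
    """Scatter and noise corrupting each replicate scan.

    absorbance = slope * (mixture + baseline) + white noise, with
    baseline(v) = offset + tilt * (v - grid midpoint).  ``replicate_jitter``
    is an extra relative slope/offset spread between replicate scans of
    the same sample.
    """

    slope_sd: float = 0.05
    baseline_offset: float = 0.02
    baseline_offset_sd: float = 0.01
    tilt_sd: float = 1e-6        # absorbance per cm^-1
    noise_sd: float = 1e-3       # white noise, absorbance units
    replicate_jitter: float = 0.01

    def __post_init__(self) -> None:
        for name in ("slope_sd", "baseline_offset_sd", "tilt_sd", "noise_sd",
                     "replicate_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def off(cls) -> "ScatterNoiseModel":
        """Identity scatter and zero noise (exact Beer-Lambert limit)."""
        return cls(slope_sd=0.0, baseline_offset=0.0, baseline_offset_sd=0.0,
                   tilt_sd=0.0, noise_sd=0.0, replicate_jitter=0.0)


def simulate_spectra(
    profiles: pd.DataFrame,
    pure: pd.DataFrame | None = None,
    scatter: ScatterNoiseModel | None = None,
    replicates: int = 3,
    seed: int = 0,
) -> SpectraSet:
    """Beer-Lambert mixture spectra with scatter and noise, per replicate.

    ``pure`` rows are analyte names matching columns of ``profiles``; a
    row named 'matrix' gets unit concentration for every sample.  Each of
    the ``replicates`` scans of a sample shares the sample's concentrations
    and differs only in its scatter/noise draws.  Negative absorbances are
    clipped to 0 (a warning reports how many points were clipped).
    """
    if pure is None:
        pure = simulate_pure_spectra()
    if scatter is None:
        scatter = ScatterNoiseModel()
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = np.asarray(pure.columns, dtype=float)
    analytes = [a for a in pure.index if a != "matrix"]
    missing = [a for a in analytes if a not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack concentration columns for {missing}")
    conc = profiles[analytes].to_numpy(dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative concentrations")
    E = pure.loc[analytes].to_numpy(dtype=float)          # (k, p)
    mix = conc @ E                                        # (n, p)
    if "matrix" in pure.index:
        mix = mix + pure.loc["matrix"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    n, p = mix.shape
    v_mid = 0.5 * (grid[0] + grid[-1])
    rows, sample_ids, rep_ids = [], [], []
    ids = (
        profiles["sample_id"].to_numpy()
        if "sample_id" in profiles
        else np.array([f"s{i:03d}" for i in range(n)])
    )
    n_clipped = 0
    for i in range(n):
        slope_i = 1.0 + scatter.slope_sd * rng.standard_normal()
        offset_i = scatter.baseline_offset + scatter.baseline_offset_sd * rng.standard_normal()
        tilt_i = scatter.tilt_sd * rng.standard_normal()
        for r in range(replicates):
            jit = scatter.replicate_jitter
            slope = slope_i * (1.0 + jit * rng.standard_normal())
            offset = offset_i + jit * scatter.baseline_offset * rng.standard_normal()
            slope = max(slope, 0.05)  # slope draws must stay positive
            baseline = offset + tilt_i * (grid - v_mid)
            scan = slope * (mix[i] + baseline) + scatter.noise_sd * rng.standard_normal(p)
            neg = scan < 0
            if neg.any():
                n_clipped += int(neg.sum())
                scan = np.where(neg, 0.0, scan)
            rows.append(scan)
            sample_ids.append(ids[i])
            rep_ids.append(r + 1)
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} negative absorbance points to 0", stacklevel=2)
    return SpectraSet(
        wavenumbers=grid,
        absorbance=np.vstack(rows),
        sample_ids=np.asarray(sample_ids),
        replicate_ids=np.asarray(rep_ids),
    )


# ---------------------------------------------------------------------------
# extracts

@dataclass(frozen=True)
class ExtractSimParams:
    """Steeping-extraction and colorimetry response parameters.

    Efficiencies are percent of the puree concentration recovered in the
    color extract; absorbance coefficients map extract concentrations
    (ug/100 g dw) to A420/A520 responses.  The sinapoyl pigment Cy3XSGG
    carries the largest A520 coefficient, reflecting its dominant
    contribution to color density.
    """

    efficiency_mean: dict[str, float] = field(default_factory=lambda: {
        "Cy3XGG": 98.0, "Cy3XFGG": 82.3, "Cy3XSGG": 79.0,
        "Cy3XCGG": 78.0, "Cy3XG": 85.0,
    })
    efficiency_sd: float = 4.0
    a520_coef: dict[str, float] = field(default_factory=lambda: {
        "Cy3XSGG": 0.035, "Cy3XFGG": 0.016, "Cy3XCGG": 0.020,
        "Cy3XG": 0.018, "Cy3XGG": 0.018,
    })
    a420_ratio: float = 0.3125   # pigment A420 response relative to A520
    browning_a420: float = 0.5   # mean browning contribution to A420 (absorbance)
    a700_turbidity: float = 0.01
    absorbance_noise_sd: float = 0.005
    solids_fraction: float = 10.0  # percent, extracts normalised to 10 % solids

    def __post_init__(self) -> None:
        for name, val in self.efficiency_mean.items():
            if val < 0:
                raise ValueError(f"negative mean efficiency for {name}")
        if any(v < 0 for v in self.a520_coef.values()):
            raise ValueError("absorbance coefficients must be >= 0")

    @classmethod
    def off_noise(cls, **kwargs) -> "ExtractSimParams":
        """Noise-free variant (deterministic efficiencies and absorbances)."""
        return cls(efficiency_sd=0.0, absorbance_noise_sd=0.0, browning_a420=0.0,
                   **kwargs)


def simulate_extracts(
    profiles: pd.DataFrame,
    params: ExtractSimParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate steeped color extracts for each sample in ``profiles``.

    Returns a table with puree/extract concentrations per pigment, the
    realised extraction efficiencies, the A420/A520/A700 absorbance
    triple, and derived color density (CD) and hue.  Negative efficiency
    draws are clipped to 0 with a warning.
    """
    from carotchem.composition import color_density, hue as hue_fn

    if params is None:
        params = ExtractSimParams()
    missing = [p for p in PIGMENTS if p not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack pigment columns {missing}")
    rng = np.random.default_rng(seed)
    n = len(profiles)
    out = pd.DataFrame(index=profiles.index)
    if "sample_id" in profiles:
        out["sample_id"] = profiles["sample_id"]
    if "phenotype" in profiles:
        out["phenotype"] = profiles["phenotype"]
    a520 = np.zeros(n)
    clipped = 0
    for pigment in PIGMENTS:
        puree = profiles[pigment].to_numpy(dtype=float)
        eff = params.efficiency_mean[pigment] + params.efficiency_sd * rng.standard_normal(n)
        neg = eff < 0
        if neg.any():
            clipped += int(neg.sum())
            eff = np.where(neg, 0.0, eff)
        extract = puree * eff / 100.0
        out[f"puree_{pigment}"] = puree
        out[f"extract_{pigment}"] = extract
        out[f"eff_{pigment}"] = eff
        a520 += params.a520_coef[pigment] * extract
    if clipped:
        warnings.warn(f"clipped {clipped} negative efficiency draws to 0", stacklevel=2)
    a700 = params.a700_turbidity + params.absorbance_noise_sd * np.abs(rng.standard_normal(n))
    browning = params.browning_a420 * np.exp(0.3 * rng.standard_normal(n)) if (
        params.browning_a420 > 0
    ) else np.zeros(n)
    a420 = params.a420_ratio * a520 + browning + a700
    a520 = a520 + a700 + params.absorbance_noise_sd * rng.standard_normal(n)
    a520 = np.clip(a520, 0.0, None)
    a420 = np.clip(a420 + params.absorbance_noise_sd * rng.standard_normal(n), 0.0, None)
    out["A420"], out["A520"], out["A700"] = a420, a520, a700
    out["solids_fraction"] = params.solids_fraction
    out["CD"] = color_density(a420, a520, a700)
    out["hue"] = hue_fn(a420, a520, a700)
    return out
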