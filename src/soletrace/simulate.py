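"""Synthetic genotypes and otolith outlines with known population structure.

The generator emulates a three-subunit (SW / NE / UK) sampling design with
unbalanced sample sizes, weak genetic differentiation and subtle, confounded
otolith-shape differences, so that every downstream stage of the pipeline can
be exercised and validated without any field data.

Genotypes follow the Balding-Nichols island model: each locus has an ancestral
allele frequency p drawn uniformly from ``maf_range``; each subunit draws its
own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst_target`` (the
beta parameterization whose expected Weir-Cockerham F_ST equals F; at F = 0
the subunit frequency is p itself); individual genotypes are Binomial(2, p_sub)
alternate-allele counts.

Otolith outlines are synthesized directly in elliptical-Fourier space: the
first harmonic is an ellipse with a sole-like axis ratio (default 1.35), fixed
low-order harmonic bumps give the outline its characteristic asymmetry, and a
high-harmonic "roughness" band perturbs the perimeter. Covariates act through
two channels:

* elongation (the first-harmonic axis ratio) — moved by sex and by the
  ``ellipticity`` entry of ``shape_effects``; drives ellipticity and roundness;
* perimeter roughness (high-harmonic amplitude) — moved by subunit
  (``circularity`` entry of ``shape_effects``), side and year; drives
  circularity and the form coefficient while leaving rectangularity,
  ellipticity and roundness essentially untouched.

Otolith size scales allometrically with fish length (``allometry_slope``, mm
of otolith length per cm of fish). Left otoliths are exact mirrors of the
right ones apart from the side effect, so left/right pairs are
mirror-consistent when ``side_effect`` is zero.

All randomness flows from a single seed through named substreams (genotypes,
metadata, shapes), so partial outputs are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .contour import Contour
from .popgen import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_otoliths",
    "default_config",
]

SUBUNITS = ("SW", "NE", "UK")

# fixed low-order harmonic bumps (relative to the semi-major axis) that make
# the base outline sole-like rather than a plain ellipse
_BASE_BUMPS: dict[int, tuple[float, float, float, float]] = {
    2: (0.015, 0.005, -0.010, 0.050),
    3: (0.040, 0.000, 0.000, 0.015),
    4: (0.010, 0.000, 0.000, 0.012),
    5: (0.008, 0.003, 0.000, 0.008),
    6: (0.005, 0.000, 0.000, 0.005),
}
# perimeter roughness lives in two harmonic bands; covariates shift wobble
# energy from the low band to the high band (same radial amplitude, higher
# frequency -> longer perimeter), so circularity and form coefficient respond
# while the extent/area indices do not
_ROUGH_LOW = (7, 8, 9, 10)
_ROUGH_HIGH = (13, 14, 15, 16)
# the high band is slightly de-rated: at equal radial amplitude a higher-
# frequency wobble has more peaks and inflates the max-extent measures (L0,
# l0); de-rating equalizes the expected extents so the mixing weight moves
# perimeter-based indices only
_HIGH_BAND_DERATE = 0.85

_STREAMS = {"genotypes": 0, "metadata": 1, "shapes": 2}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[name])))


@dataclass
class SimulationConfig:
    """Generating parameters for the synthetic study.

    Defaults emulate the study conditions: the 2017 genetic sampling design
    (47 SW / 31 NE / 42 UK fish, 2902 SNP loci, global F_ST around 0.0045)
    and shape effects that make circularity and the form coefficient differ
    between SW and NE while rectangularity does not.
    """

    n_per_subunit: dict[str, int] = field(
        default_factory=lambda: {"SW": 47, "NE": 31, "UK": 42}
    )
    n_loci: int = 2902
    fst_target: float = 0.0045
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    # per-index, per-subunit additive effects; "circularity" entries shift the
    # roughness frequency mix (0 = all low band, 1 = all high band),
    # "ellipticity" entries shift the elongation channel
    shape_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "circularity": {"SW": 0.15, "NE": 0.0, "UK": 0.075},
        }
    )
    allometry_slope: float = 0.05  # mm otolith length per cm fish length
    sex_effect: float = 0.015  # elongation shift, M vs F
    side_effect: float = 0.05  # roughness-mix shift, L vs R
    year_effect: float = 0.03  # roughness-mix shift per year step
    noise_sd: float = 0.002  # sd of per-otolith harmonic-amplitude jitter
    length_range: tuple[float, float] = (25.0, 40.0)
    axis_ratio: float = 1.35
    axis_ratio_cv: float = 0.03
    roughness: float = 0.025  # radial roughness amplitude per band harmonic
    roughness_mix: float = 0.3  # baseline low/high band mixing weight
    roughness_mix_sd: float = 0.08  # per-otolith jitter of the mixing weight
    l0_intercept: float = 2.5  # mm otolith length at zero fish length
    l0_noise_cv: float = 0.01  # residual CV of otolith length around allometry
    years: tuple[int, ...] = (2016, 2017, 2018)
    contour_points: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_subunit:
            raise ValueError("n_per_subunit must not be empty")
        for sub, n in self.n_per_subunit.items():
            if n < 1:
                raise ValueError(f"sample count for {sub} must be >= 1, got {n}")
        if not 0.0 <= self.fst_target <= 0.5:
            raise ValueError("fst_target must be in [0, 0.5]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie within (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def default_config(**overrides) -> SimulationConfig:
    """The study-condition defaults, with keyword overrides."""
    return SimulationConfig(**overrides)


@dataclass
class SimulatedDataset:
    """Genotypes, contours and metadata produced by one simulation run."""

    genotypes: GenotypeMatrix
    contours: list[Contour]
    metadata: pd.DataFrame  # fish-level: fish_id, subunit, year, length_cm, sex
    otolith_table: pd.DataFrame  # otolith-level rows (adds otolith_id, side)
    truth: dict


def _sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    rng = _stream(config.seed, "metadata")
    rows = []
    for sub in config.n_per_subunit:
        n = config.n_per_subunit[sub]
        lengths = rng.uniform(*config.length_range, size=n)
        sexes = rng.choice(["F", "M"], size=n)
        years = rng.choice(config.years, size=n)
        for i in range(n):
            rows.append(
                {
                    "fish_id": f"{sub}{i:03d}",
                    "subunit": sub,
                    "year": int(years[i]),
                    "length_cm": float(lengths[i]),
                    "sex": str(sexes[i]),
                }
            )
    return pd.DataFrame(rows)


def simulate_genotypes(
    config: SimulationConfig, metadata: pd.DataFrame | None = None
) -> GenotypeMatrix:
    """Balding-Nichols genotypes for the configured sampling design."""
    if metadata is None:
        metadata = _sample_metadata(config)
    rng = _stream(config.seed, "genotypes")
    F = config.fst_target
    p_anc = rng.uniform(*config.maf_range, size=config.n_loci)
    subunits = list(config.n_per_subunit)
    if F > 0:
        shape1 = p_anc * (1.0 - F) / F
        shape2 = (1.0 - p_anc) * (1.0 - F) / F
        p_sub = {s: rng.beta(shape1, shape2) for s in subunits}
    else:
        p_sub = {s: p_anc for s in subunits}
    blocks = []
    for s in subunits:
        n = config.n_per_subunit[s]
        blocks.append(rng.binomial(2, p_sub[s][None, :], size=(n, config.n_loci)))
    geno = np.concatenate(blocks, axis=0).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = np.nan
    return GenotypeMatrix(
        genotypes=geno,
        sample_ids=list(metadata["fish_id"]),
        locus_ids=[f"snp{j:05d}" for j in range(config.n_loci)],
        subunits=np.asarray(metadata["subunit"]),
        years=np.asarray(metadata["year"]),
    )


def _effect(config: SimulationConfig, index: str, sub: str) -> float:
    return float(config.shape_effects.get(index, {}).get(sub, 0.0))


def _build_coeffs(
    config: SimulationConfig,
    rng: np.random.Generator,
    semi_major: float,
    ratio: float,
    rough_mix: float,
) -> np.ndarray:
    """Per-otolith EFD coefficient array (right-side frame), in mm.

    ``rough_mix`` in [0, 1] splits the (fixed) radial roughness amplitude
    between the low and high harmonic bands: sqrt(1 - w) on the low band and
    sqrt(w) on the high band, keeping total wobble energy constant.
    """
    k_gen = max(_ROUGH_HIGH)
    coeffs = np.zeros((k_gen, 4))
    coeffs[0] = (1.0, 0.0, 0.0, 1.0 / ratio)
    for k, bump in _BASE_BUMPS.items():
        coeffs[k - 1] = np.asarray(bump) + rng.normal(0.0, config.noise_sd, size=4)
    w = float(np.clip(rough_mix, 0.0, 1.0))
    bands = (
        (_ROUGH_LOW, np.sqrt(1.0 - w)),
        (_ROUGH_HIGH, _HIGH_BAND_DERATE * np.sqrt(w)),
    )
    for band, weight in bands:
        for k in band:
            direction = rng.normal(size=4)
            direction /= np.linalg.norm(direction)
            amp = max(config.roughness + rng.normal(0.0, config.noise_sd), 0.0)
            coeffs[k - 1] = weight * amp * direction
    return coeffs * semi_major


def _feret(pts: np.ndarray) -> float:
    from scipy.spatial import ConvexHull

    hull = pts[ConvexHull(pts).vertices]
    d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _synthesize(coeffs: np.ndarray, n_points: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    k = np.arange(1, coeffs.shape[0] + 1)[:, None]
    cos_kt = np.cos(2.0 * np.pi * k * t)
    sin_kt = np.sin(2.0 * np.pi * k * t)
    a, b, c, d = coeffs.T
    return np.column_stack([a @ cos_kt + b @ sin_kt, c @ cos_kt + d @ sin_kt])


def simulate_otoliths(config: SimulationConfig) -> SimulatedDataset:
    """Full synthetic dataset: metadata, genotypes and paired otolith contours."""
    metadata = _sample_metadata(config)
    genotypes = simulate_genotypes(config, metadata)
    rng = _stream(config.seed, "shapes")
    mean_len = float(np.mean(config.length_range))
    year_mid = config.years[len(config.years) // 2]
    contours: list[Contour] = []
    oto_rows = []
    for row in metadata.itertuples(index=False):
        L0_target = config.l0_intercept + config.allometry_slope * row.length_cm
        semi_major = L0_target / 2.0
        elong = (
            config.axis_ratio_cv * config.axis_ratio * rng.normal()
            + _effect(config, "ellipticity", row.subunit)
            + (config.sex_effect if row.sex == "M" else 0.0)
        )
        ratio = max(config.axis_ratio + elong, 1.01)
        mix_base = (
            config.roughness_mix
            + _effect(config, "circularity", row.subunit)
            + config.year_effect * (row.year - year_mid)
            + config.roughness_mix_sd * rng.normal()
        )
        for side in ("R", "L"):
            mix = mix_base + (config.side_effect if side == "L" else 0.0)
            oid = f"{row.fish_id}_{side}"
            for attempt in range(6):
                if side == "L" and config.side_effect == 0.0 and attempt == 0:
                    # exact mirror of the right otolith
                    contour = contours[-1].mirrored()
                    contour.otolith_id = oid
                else:
                    coeffs = _build_coeffs(config, rng, semi_major, ratio, mix)
                    pts = _synthesize(coeffs, config.contour_points)
                    # pin the realized otolith length to the allometric target
                    # (harmonic bumps inflate the Feret length otherwise)
                    target = L0_target * (1.0 + config.l0_noise_cv * rng.normal())
                    pts *= target / _feret(pts)
                    if side == "L":
                        pts[:, 0] *= -1.0
                        pts = pts[::-1]
                    contour = Contour(
                        points=pts, otolith_id=oid, fish_id=row.fish_id, side=side
                    )
                if contour.is_simple():
                    break
            else:
                raise RuntimeError(
                    f"could not generate a simple outline for {oid} after retries"
                )
            contours.append(contour)
            oto_rows.append(
                {
                    "otolith_id": oid,
                    "fish_id": row.fish_id,
                    "subunit": row.subunit,
                    "year": row.year,
                    "length_cm": row.length_cm,
                    "sex": row.sex,
                    "side": side,
                }
            )
    truth = {"config": asdict(config)}
    return SimulatedDataset(
        genotypes=genotypes,
        contours=contours,
        metadata=metadata,
        otolith_table=pd.DataFrame(oto_rows),
        truth=truth,
    )
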