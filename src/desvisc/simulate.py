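"""Synthetic sigma-profiles and viscosity datasets.

Real sigma-profiles and the curated experimental viscosity table are
external inputs; this module generates stand-ins with the statistical
structure the model assumes, so the whole pipeline is testable
end-to-end and the generating law can serve as an oracle in
parameter-recovery studies.

Profiles are sums of a few Gaussian peaks on the 31-point +/-0.03 grid:
every compound carries a nonpolar peak near sigma = 0; hydrogen-bond
donors add a peak on the negative (donor) side beyond -0.0075, acceptors
on the positive side.  The choline-chloride-like salt gets a strong
acceptor peak (the chloride); cosolvents are small water-like molecules
with modest donor and acceptor peaks.

Viscosities follow a Vogel-Fulcher-Tammann-like law in the mixture
descriptors,

    log10 eta = A(S) + B(S) / (T - T0(S)),

with A, B, T0 affine in S1..S8 and coefficients drawn once per
configuration (recorded as the ground truth).  Temperature raises
mobility, so eta falls with T; cosolvents have small descriptor areas,
which pulls B down on dilution and reproduces the strong viscosity drop
on adding water.  Noise is multiplicative lognormal on eta, i.e.
additive Gaussian on log10 eta — the modelling scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import json
import numpy as np

from .data import Dataset, ViscosityRecord
from .errors import GenerationError, ValidationError
from .profiles import (
    DescriptorVector,
    MixtureSpec,
    SigmaProfile,
    default_region_scheme,
    discretize_profile,
    mix_descriptors,
    ratio_to_fractions,
)

__all__ = [
    "GeneratorConfig",
    "ViscosityLaw",
    "gen_sigma_profiles",
    "gen_viscosity_dataset",
    "synthetic_profile",
    "SIGMA_GRID_31",
]

SIGMA_GRID_31 = np.linspace(-0.03, 0.03, 31)

_RATIO_CYCLE = ((1.0, 2.0), (1.0, 3.0), (1.0, 1.0), (1.0, 4.0))


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic benchmark.

    The defaults emulate a realistic choline-chloride viscosity study:
    20 pure DES systems plus 45 DES + cosolvent systems on a
    9-temperature grid (283.15-363.15 K), most systems covering a
    low-to-moderate dilution window and every fifth extending to deep
    dilution — 1557 records, with multiplicative noise of 0.02 decades
    on the viscosity and the response spanning the 0.3862-4722 mPa*s
    window of the experimental databases.
    """

    seed: int = 0
    n_hbd: int = 10
    n_cosolvents: int = 3
    n_pure_systems: int = 20
    n_cosolvent_systems: int = 45
    temperatures: tuple[float, ...] = tuple(
        283.15 + 10.0 * i for i in range(9)
    )
    cosolvent_fractions: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    #: every n-th cosolvent system covers the full dilution grid; the
    #: rest stop before the last two (deep-dilution) fractions
    deep_dilution_every: int = 5
    noise_sigma: float = 0.02  # std of the additive noise on log10(eta)
    n_points: int | None = None  # optional deterministic cap on the size
    n_grid_points: int = 31
    #: target span of noiseless log10(eta); the drawn law is affinely
    #: recalibrated so the generated values cover exactly this range
    #: (default: the 0.3862-4722 mPa*s window of the experimental database)
    log_eta_range: tuple[float, float] = (-0.4132, 3.6742)
    # ranges the affine law coefficients are drawn from (see ViscosityLaw)
    a0_range: tuple[float, float] = (-2.2, -1.8)
    a_coef_range: tuple[float, float] = (-0.002, 0.006)
    b0_range: tuple[float, float] = (120.0, 180.0)
    b_coef_range: tuple[float, float] = (1.5, 4.5)
    t0_range: tuple[float, float] = (140.0, 160.0)
    t0_coef_range: tuple[float, float] = (0.0, 0.1)
    b_min: float = 50.0
    t0_margin: float = 40.0  # T0 capped at min(T) - margin

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be nonnegative")
        if self.n_hbd < 1 or self.n_cosolvents < 1:
            raise ValidationError("need at least one HBD and one cosolvent")
        if not self.temperatures:
            raise ValidationError("temperature grid must be nonempty")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=(int(self.seed), stream))
        )


# ---------------------------------------------------------------------------
# sigma-profiles


def _gauss_peaks(
    grid: np.ndarray, peaks: Sequence[tuple[float, float, float]]
) -> np.ndarray:
    """Sum of Gaussians given as (center, sd, area) triples."""
    y = np.zeros_like(grid)
    for center, sd, area in peaks:
        height = area / (sd * np.sqrt(2.0 * np.pi))
        y += height * np.exp(-0.5 * ((grid - center) / sd) ** 2)
    return y


def synthetic_profile(
    kind: str,
    compound_id: str,
    rng: np.random.Generator | int | None = None,
    grid: np.ndarray | None = None,
) -> SigmaProfile:
    """One profile from a named template.

    Kinds: ``nonpolar`` (single peak near sigma = 0), ``donor_rich``
    (nonpolar + strong donor-side peak), ``acceptor_rich`` and
    ``water_like`` (small donor + acceptor peaks).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if grid is None:
        grid = SIGMA_GRID_31
    u = rng.uniform
    if kind == "nonpolar":
        peaks = [(u(-0.002, 0.002), u(0.003, 0.0045), u(80.0, 160.0))]
    elif kind == "donor_rich":
        peaks = [
            (u(-0.002, 0.002), u(0.003, 0.0045), u(60.0, 140.0)),
            (u(-0.018, -0.012), u(0.002, 0.003), u(30.0, 70.0)),
            (u(0.010, 0.016), u(0.002, 0.003), u(10.0, 40.0)),
        ]
    elif kind == "acceptor_rich":
        peaks = [
            (u(-0.002, 0.002), u(0.003, 0.0045), u(60.0, 120.0)),
            (u(0.012, 0.018), u(0.002, 0.003), u(40.0, 80.0)),
            (u(-0.012, -0.008), u(0.002, 0.003), u(5.0, 25.0)),
        ]
    elif kind == "water_like":
        peaks = [
            (u(-0.017, -0.013), u(0.002, 0.003), u(12.0, 25.0)),
            (u(0.013, 0.017), u(0.002, 0.003), u(12.0, 25.0)),
            (u(-0.002, 0.002), u(0.0025, 0.004), u(5.0, 15.0)),
        ]
    else:
        raise ValidationError(f"unknown profile template {kind!r}")
    return SigmaProfile(
        compound_id=compound_id,
        sigma_grid=grid,
        area_density=_gauss_peaks(grid, peaks),
    )


def gen_sigma_profiles(config: GeneratorConfig) -> dict[str, SigmaProfile]:
    """Profiles for one salt ("hba"), ``n_hbd`` donors ("hbd01"..) and
    ``n_cosolvents`` cosolvents ("cos01"..); fully reproducible from the
    config seed."""
    rng = config._rng(0)
    grid = np.linspace(-0.03, 0.03, config.n_grid_points)
    profiles: dict[str, SigmaProfile] = {}
    # choline-chloride-like salt: nonpolar body + strong chloride acceptor
    u = rng.uniform
    salt_peaks = [
        (u(-0.002, 0.002), u(0.0035, 0.0045), u(80.0, 110.0)),
        (u(0.014, 0.018), u(0.002, 0.0028), u(55.0, 80.0)),
        (u(-0.012, -0.008), u(0.002, 0.003), u(10.0, 25.0)),
    ]
    profiles["hba"] = SigmaProfile(
        compound_id="hba",
        sigma_grid=grid,
        area_density=_gauss_peaks(grid, salt_peaks),
    )
    for i in range(config.n_hbd):
        kind = "donor_rich" if i % 3 != 2 else "acceptor_rich"
        profiles[f"hbd{i + 1:02d}"] = synthetic_profile(
            kind, f"hbd{i + 1:02d}", rng, grid
        )
    for i in range(config.n_cosolvents):
        profiles[f"cos{i + 1:02d}"] = synthetic_profile(
            "water_like", f"cos{i + 1:02d}", rng, grid
        )
    return profiles


# ---------------------------------------------------------------------------
# viscosity law and dataset


@dataclass
class ViscosityLaw:
    """Recorded ground truth: log10 eta = A(S) + B(S) / (T - T0(S))."""

    a0: float
    a: np.ndarray
    b0: float
    b: np.ndarray
    t00: float
    t0c: np.ndarray
    b_min: float
    t0_cap: float

    def params(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        A = self.a0 + s @ self.a
        B = np.maximum(self.b0 + s @ self.b, self.b_min)
        T0 = np.minimum(self.t00 + s @ self.t0c, self.t0_cap)
        return A, B, T0

    def recalibrated(
        self, observed: tuple[float, float], target: tuple[float, float]
    ) -> "ViscosityLaw":
        """Affine remap of the response so values spanning ``observed``
        span ``target`` instead; the map folds exactly into (A, B) since
        c0 + c1 * (A + B/(T - T0)) is again of VFT form."""
        lo, hi = observed
        if hi - lo < 1e-12:
            raise GenerationError("degenerate response span; cannot calibrate")
        c1 = (target[1] - target[0]) / (hi - lo)
        c0 = target[0] - c1 * lo
        return ViscosityLaw(
            a0=c0 + c1 * self.a0, a=c1 * self.a,
            b0=c1 * self.b0, b=c1 * self.b,
            t00=self.t00, t0c=self.t0c,
            b_min=c1 * self.b_min, t0_cap=self.t0_cap,
        )

    def log_eta(self, s: np.ndarray, T: float | np.ndarray) -> np.ndarray:
        A, B, T0 = self.params(s)
        T = np.asarray(T, dtype=float)
        if np.any(T <= T0):
            raise GenerationError(
                "temperature at or below the Vogel temperature T0"
            )
        return A + B / (T - T0)

    def to_json(self, path: str) -> None:
        doc = {
            "a0": self.a0, "a": self.a.tolist(),
            "b0": self.b0, "b": self.b.tolist(),
            "t00": self.t00, "t0c": self.t0c.tolist(),
            "b_min": self.b_min, "t0_cap": self.t0_cap,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ViscosityLaw":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            a0=doc["a0"], a=np.asarray(doc["a"]),
            b0=doc["b0"], b=np.asarray(doc["b"]),
            t00=doc["t00"], t0c=np.asarray(doc["t0c"]),
            b_min=doc["b_min"], t0_cap=doc["t0_cap"],
        )


def _draw_law(config: GeneratorConfig) -> ViscosityLaw:
    rng = config._rng(1)
    return ViscosityLaw(
        a0=rng.uniform(*config.a0_range),
        a=rng.uniform(*config.a_coef_range, size=8),
        b0=rng.uniform(*config.b0_range),
        b=rng.uniform(*config.b_coef_range, size=8),
        t00=rng.uniform(*config.t0_range),
        t0c=rng.uniform(*config.t0_coef_range, size=8),
        b_min=config.b_min,
        t0_cap=min(config.temperatures) - config.t0_margin,
    )


def gen_viscosity_dataset(
    config: GeneratorConfig,
    profiles: Mapping[str, SigmaProfile] | None = None,
) -> tuple[Dataset, ViscosityLaw]:
    """Generate a labelled-composition viscosity dataset plus its law.

    Returns the dataset with the feature matrix already attached (the
    descriptors are known exactly here) and the ground-truth law for
    oracle use.  The system grid cycles donors, molar ratios and
    cosolvents; pure systems are measured at every temperature and
    cosolvent systems additionally at every dilution of the fraction
    grid.  With ``noise_sigma = 0`` every record lies exactly on the law.
    """
    if profiles is None:
        profiles = gen_sigma_profiles(config)
    scheme = default_region_scheme()
    pure = {
        cid: discretize_profile(p, scheme) for cid, p in profiles.items()
    }
    noise_rng = config._rng(2)

    hbd_ids = [f"hbd{i + 1:02d}" for i in range(config.n_hbd)]
    cos_ids = [f"cos{i + 1:02d}" for i in range(config.n_cosolvents)]

    # enumerate the full measurement grid first
    grid: list[tuple[str, MixtureSpec, float]] = []
    for i in range(config.n_pure_systems):
        hbd = hbd_ids[i % len(hbd_ids)]
        parts = _RATIO_CYCLE[i % len(_RATIO_CYCLE)]
        mixture = ratio_to_fractions(
            parts[0], parts[1], 0.0, hba_id="hba", hbd_id=hbd
        )
        sid = f"SYN{i + 1:02d}"
        for T in config.temperatures:
            grid.append((sid, mixture, T))
    # each system covers its own dilution window, as in real studies:
    # most stop at moderate cosolvent content, only every few-th extends
    # to the deep-dilution (water-like viscosity) regime
    fracs = config.cosolvent_fractions
    shallow = fracs[: max(len(fracs) - 2, 1)]
    for i in range(config.n_cosolvent_systems):
        hbd = hbd_ids[(i * 2 + 1) % len(hbd_ids)]
        cos = cos_ids[i % len(cos_ids)]
        parts = _RATIO_CYCLE[(i + 1) % len(_RATIO_CYCLE)]
        sid = f"SYN{config.n_pure_systems + i + 1:02d}c"
        deep = i % config.deep_dilution_every == 0
        for frac in (fracs if deep else shallow):
            mixture = ratio_to_fractions(
                parts[0], parts[1], frac,
                hba_id="hba", hbd_id=hbd, cosolvent_id=cos,
            )
            for T in config.temperatures:
                grid.append((sid, mixture, T))

    feats = np.empty((len(grid), 9))
    for k, (_, mixture, T) in enumerate(grid):
        d = mix_descriptors(pure, mixture)
        feats[k, :8] = d.s
        feats[k, 8] = T

    # draw the law, then recalibrate it so the noiseless response spans
    # exactly the configured log-viscosity window
    law = _draw_law(config)
    raw = law.log_eta(feats[:, :8], feats[:, 8])
    law = law.recalibrated(
        (float(raw.min()), float(raw.max())), config.log_eta_range
    )
    log_eta = law.log_eta(feats[:, :8], feats[:, 8])
    if config.noise_sigma > 0:
        log_eta = log_eta + noise_rng.normal(
            0.0, config.noise_sigma, size=log_eta.shape
        )

    records = [
        ViscosityRecord(
            system_id=sid,
            mixture=mixture,
            temperature=T,
            viscosity=float(10.0 ** log_eta[k]),
            source="synthetic",
        )
        for k, (sid, mixture, T) in enumerate(grid)
    ]
    if config.n_points is not None:
        records = records[: config.n_points]
        feats = feats[: config.n_points]
    dataset = Dataset(records=records, features=np.asarray(feats))
    return dataset, law
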