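"""Sigma-profile handling and molecular descriptors.

A sigma-profile is the histogram of screening charge density over a
molecule's COSMO cavity surface: at each charge density ``sigma`` (e/A^2)
the curve ``p(sigma)*A`` gives the surface area (A^2) carrying that charge.
Profiles are consumed as two-column text files in the open LVPP-database
dialect; the quantum-chemistry step that produces them is out of scope.

The descriptors used for property modelling are the areas S1..S8 under
the profile in eight contiguous charge-density regions spanning, from the
negative to the positive end of the sigma axis: strong hydrogen-bond donor
(S1, S2), weak donor (S3), nonpolar (S4, S5), weak acceptor (S6) and
strong acceptor (S7, S8).  The negative-sigma end is the donor side: an
H(delta+) atom induces negative screening charge on the cavity.  Mixture
descriptors are mole-fraction weighted averages of the pure-component
descriptors.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "SigmaProfile",
    "RegionScheme",
    "DescriptorVector",
    "Component",
    "MixtureSpec",
    "DEFAULT_REGION_LABELS",
    "default_region_scheme",
    "parse_sigma_profile",
    "write_sigma_profile",
    "discretize_profile",
    "mix_descriptors",
    "ratio_to_fractions",
    "descriptor_table",
]

#: Canonical interpretation of the eight regions, donor side first.
DEFAULT_REGION_LABELS: tuple[str, ...] = (
    "strong HBD",
    "strong HBD",
    "weak HBD",
    "nonpolar",
    "nonpolar",
    "weak HBA",
    "strong HBA",
    "strong HBA",
)

#: Conventional half-span of the sigma grid (e/A^2).
SIGMA_SPAN = 0.03

_BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class SigmaProfile:
    """One compound's discrete sigma-profile curve.

    Parameters
    ----------
    compound_id : str
        Identifier used to look the compound up in mixtures.
    sigma_grid : ndarray
        Strictly increasing screening charge densities (e/A^2).
    area_density : ndarray
        ``p(sigma)*A`` values (A^2), same length, nonnegative.
    """

    compound_id: str
    sigma_grid: np.ndarray
    area_density: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.sigma_grid, dtype=float)
        dens = np.asarray(self.area_density, dtype=float)
        object.__setattr__(self, "sigma_grid", grid)
        object.__setattr__(self, "area_density", dens)
        if grid.ndim != 1 or dens.ndim != 1 or grid.size != dens.size:
            raise ValidationError(
                f"{self.compound_id}: grid and area-density columns must be "
                f"1-D and of equal length (got {grid.shape} vs {dens.shape})"
            )
        if grid.size < 4:
            raise ValidationError(
                f"{self.compound_id}: at least 4 grid points required"
            )
        if not np.all(np.diff(grid) > 0):
            raise ValidationError(
                f"{self.compound_id}: sigma grid must be strictly increasing"
            )
        if np.any(dens < 0):
            raise ValidationError(
                f"{self.compound_id}: negative area density"
            )

    @property
    def n_points(self) -> int:
        return int(self.sigma_grid.size)

    def total_area(self) -> float:
        """Trapezoidal area under the whole profile."""
        return float(np.trapezoid(self.area_density, self.sigma_grid))


@dataclass(frozen=True)
class RegionScheme:
    """Partition of the sigma axis into eight labelled regions.

    ``boundaries`` holds the 9 ordered edges; region ``i`` (0-based) spans
    ``[boundaries[i], boundaries[i + 1]]``.
    """

    boundaries: np.ndarray
    labels: tuple[str, ...] = DEFAULT_REGION_LABELS

    def __post_init__(self) -> None:
        edges = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", edges)
        if edges.ndim != 1 or edges.size != len(self.labels) + 1:
            raise ValidationError(
                f"expected {len(self.labels) + 1} boundaries for "
                f"{len(self.labels)} regions, got {edges.size}"
            )
        if not np.all(np.diff(edges) > 0):
            raise ValidationError("region boundaries must be strictly increasing")

    @property
    def n_regions(self) -> int:
        return len(self.labels)


def default_region_scheme(span: float = SIGMA_SPAN) -> RegionScheme:
    """Eight equal-width regions over ``[-span, +span]``.

    The default width 0.0075 e/A^2 places the conventional hydrogen-bond
    threshold |sigma| ~ 0.0075-0.0082 at the S3/S4 and S5/S6 edges, so the
    equal-width partition reproduces the usual grouping of the eight
    regions into donor / nonpolar / acceptor bands.
    """
    return RegionScheme(boundaries=np.linspace(-span, span, 9))


@dataclass
class DescriptorVector:
    """The eight region areas S1..S8 plus (optionally) a temperature.

    The network's nine inputs are ``(S1, ..., S8, T)``; the temperature is
    attached only once the descriptor is paired with an observation.
    """

    s: np.ndarray
    temperature: float | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        self.s = s
        if s.shape != (8,):
            raise ValidationError(f"expected 8 region areas, got shape {s.shape}")
        if np.any(s < -1e-12):
            raise ValidationError("region areas must be nonnegative")

    def with_temperature(self, temperature: float) -> "DescriptorVector":
        return DescriptorVector(self.s.copy(), float(temperature))

    def as_features(self) -> np.ndarray:
        """Return the 9-vector ``(S1..S8, T)`` consumed by the model."""
        if self.temperature is None:
            raise ValidationError("temperature not attached to descriptor")
        return np.append(self.s, self.temperature)

    def total(self) -> float:
        return float(self.s.sum())


@dataclass(frozen=True)
class Component:
    """One mixture constituent: compound id, mole fraction and its role."""

    compound_id: str
    mole_fraction: float
    role: str  # "hba" | "hbd" | "cosolvent"


_ROLES = {"hba", "hbd", "cosolvent"}


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of a DES (optionally diluted by a cosolvent).

    Mole fractions must be nonnegative and sum to one; exactly one
    component is the hydrogen-bond acceptor salt and at least one is a
    donor, matching the choline-chloride systems this model targets.
    """

    components: tuple[Component, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValidationError("mixture has no components")
        for c in comps:
            if c.role not in _ROLES:
                raise ValidationError(f"unknown component role {c.role!r}")
            if c.mole_fraction < 0:
                raise ValidationError(
                    f"negative mole fraction for {c.compound_id}"
                )
        total = sum(c.mole_fraction for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"mole fractions sum to {total!r}, expected 1 within 1e-9"
            )
        n_hba = sum(1 for c in comps if c.role == "hba")
        n_hbd = sum(1 for c in comps if c.role == "hbd")
        if n_hba != 1:
            raise ValidationError(f"expected exactly one HBA, got {n_hba}")
        if n_hbd < 1:
            raise ValidationError("expected at least one HBD")

    def fractions(self) -> dict[str, float]:
        return {c.compound_id: c.mole_fraction for c in self.components}

    def component_by_role(self, role: str) -> Component | None:
        for c in self.components:
            if c.role == role:
                return c
        return None


# ---------------------------------------------------------------------------
# parsing / writing


def parse_sigma_profile(
    source: Union[str, IO[str]],
    compound_id: str | None = None,
) -> SigmaProfile:
    """Read a two-column sigma-profile text file (LVPP dialect).

    Lines starting with ``#`` and blank lines are ignored; the remaining
    rows hold two whitespace- or comma-separated numbers
    ``sigma  p(sigma)*A``.  Rows may appear in any order; the grid is
    sorted ascending.  Typical profiles have 31-61 points; other counts
    are accepted with a warning since the integration is grid-agnostic.
    """
    if hasattr(source, "read"):
        stream: IO[str] = source  # type: ignore[assignment]
        name = compound_id or getattr(source, "name", "<stream>")
    else:
        stream = open(source, "r", encoding="utf-8")
        name = compound_id or _stem(str(source))
    sigmas: list[float] = []
    dens: list[float] = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(
                    f"{name}: line {lineno}: expected 2 columns, got "
                    f"{len(parts)}: {line!r}"
                )
            try:
                sigmas.append(float(parts[0]))
                dens.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(
                    f"{name}: line {lineno}: malformed number in {line!r}"
                ) from exc
    finally:
        if stream is not source:
            stream.close()
    if not sigmas:
        raise ParseError(f"{name}: no data rows found")
    order = np.argsort(sigmas, kind="stable")
    grid = np.asarray(sigmas, dtype=float)[order]
    values = np.asarray(dens, dtype=float)[order]
    profile = SigmaProfile(compound_id=name, sigma_grid=grid, area_density=values)
    if not 31 <= profile.n_points <= 61:
        warnings.warn(
            f"{name}: {profile.n_points} grid points (typical profiles "
            "have 31-61)",
            stacklevel=2,
        )
    return profile


def _stem(path: str) -> str:
    base = path.replace("\\", "/").rsplit("/", 1)[-1]
    return base.rsplit(".", 1)[0] if "." in base else base


def write_sigma_profile(profile: SigmaProfile, target: Union[str, IO[str]]) -> None:
    """Write a profile in the same two-column dialect ``parse`` accepts."""
    lines = [f"# sigma-profile for {profile.compound_id}", "# sigma  p(sigma)*A"]
    for s, a in zip(profile.sigma_grid, profile.area_density):
        lines.append(f"{float(s)!r} {float(a)!r}")
    text = "\n".join(lines) + "\n"
    if hasattr(target, "write"):
        target.write(text)  # type: ignore[union-attr]
    else:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# discretization and mixing


def discretize_profile(
    profile: SigmaProfile, scheme: RegionScheme | None = None
) -> DescriptorVector:
    """Integrate the profile over each region by the trapezoidal rule.

    Region edges that fall between grid points contribute linearly
    interpolated area-density values, so the eight areas always sum to the
    trapezoidal integral over the full scheme span (the partition is
    exhaustive and non-overlapping).
    """
    if scheme is None:
        scheme = default_region_scheme()
    grid = profile.sigma_grid
    edges = scheme.boundaries
    if edges[0] < grid[0] - _BOUNDARY_TOL or edges[-1] > grid[-1] + _BOUNDARY_TOL:
        raise ValidationError(
            f"{profile.compound_id}: region scheme "
            f"[{edges[0]}, {edges[-1]}] extends beyond the profile grid "
            f"[{grid[0]}, {grid[-1]}]"
        )
    areas = np.empty(scheme.n_regions)
    for i in range(scheme.n_regions):
        lo = max(edges[i], grid[0])
        hi = min(edges[i + 1], grid[-1])
        inner = grid[(grid > lo) & (grid < hi)]
        xs = np.concatenate(([lo], inner, [hi]))
        ys = np.interp(xs, grid, profile.area_density)
        areas[i] = np.trapezoid(ys, xs)
    return DescriptorVector(s=areas)


def mix_descriptors(
    pure: Mapping[str, DescriptorVector], mixture: MixtureSpec
) -> DescriptorVector:
    """Mole-fraction weighted average of the pure-component descriptors.

    ``S_i(mix) = sum_j x_j * S_i^j`` for i = 1..8 — the conventional
    mixing rule for sigma-profile areas of multicomponent solvents.
    """
    missing = [c.compound_id for c in mixture.components if c.compound_id not in pure]
    if missing:
        raise KeyError(
            f"no descriptors for mixture component(s): {', '.join(missing)}"
        )
    s = np.zeros(8)
    for c in mixture.components:
        s += c.mole_fraction * pure[c.compound_id].s
    return DescriptorVector(s=s)


def ratio_to_fractions(
    hba_parts: float,
    hbd_parts: float,
    cosolvent_fraction: float = 0.0,
    *,
    hba_id: str = "ChCl",
    hbd_id: str = "HBD",
    cosolvent_id: str | None = None,
) -> MixtureSpec:
    """Turn an ``HBA:HBD (1:n)`` molar ratio plus a cosolvent mole fraction
    into explicit mole fractions.

    The HBA:HBD parts are normalized among themselves, then rescaled by
    ``1 - cosolvent_fraction`` so the three fractions sum to one.
    """
    if hba_parts <= 0 or hbd_parts <= 0:
        raise ValidationError("HBA and HBD parts must be positive")
    if not 0.0 <= cosolvent_fraction < 1.0:
        raise ValidationError("cosolvent fraction must lie in [0, 1)")
    des_total = hba_parts + hbd_parts
    scale = 1.0 - cosolvent_fraction
    comps = [
        Component(hba_id, scale * hba_parts / des_total, "hba"),
        Component(hbd_id, scale * hbd_parts / des_total, "hbd"),
    ]
    if cosolvent_fraction > 0.0:
        if cosolvent_id is None:
            cosolvent_id = "cosolvent"
        comps.append(Component(cosolvent_id, cosolvent_fraction, "cosolvent"))
    return MixtureSpec(components=tuple(comps))


def descriptor_table(pure: Mapping[str, DescriptorVector]) -> pd.DataFrame:
    """Tabulate descriptors as one row per compound, columns S1..S8."""
    rows = {cid: d.s for cid, d in pure.items()}
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"S{i}" for i in range(1, 9)]
    )
    df.index.name = "compound_id"
    return df.sort_index()
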