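"""Elemental compositions and bulk radiological properties of mixtures.

A dosimetric medium is described by its elemental mass fractions and bulk
density.  From these the quantities that drive charged-particle energy loss
follow: the mean ratio ⟨Z/A⟩, the electron density, the effective atomic
number Z_eff, and the mean excitation energy I obtained by Bragg additivity.

The package targets an alcohol-based liquid scintillator (AbLS): a 7:3
mixture of 2-ethoxyethanol (C4H10O2) and water with a measured bulk density
of 0.945 g/cm³.  The PPO / bis-MSB fluors are present only at the g/L level
and are neglected in the composition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

N_AVOGADRO = 6.02214076e23  # 1/mol

__all__ = [
    "ElementSpec",
    "MaterialComposition",
    "ELEMENTS",
    "parse_formula",
    "formula_mass_fractions",
    "compose_mixture",
    "effective_atomic_number",
    "mean_excitation_energy",
    "electron_density",
    "mean_z_over_a",
    "water",
    "abls",
    "material_from_yaml",
    "material_to_yaml",
    "FormulaParseError",
]

# Densities (g/cm³) used for the default AbLS volume-basis mixing rule.
ETHOXYETHANOL_DENSITY = 0.930
WATER_DENSITY = 0.998
ABLS_DENSITY = 0.945  # measured bulk density of the mixed scintillator


class FormulaParseError(ValueError):
    """A molecular formula contains an unknown or malformed element symbol."""


@dataclass(frozen=True)
class ElementSpec:
    """Atomic data for one element.

    ``i_elem`` is the mean excitation energy (eV) recommended for use in the
    Bragg additivity rule for condensed compounds (ICRU report 37 convention),
    which is why oxygen carries 106 eV rather than the 95 eV gas-phase value.
    """

    symbol: str
    Z: int
    A: float  # g/mol
    i_elem: float  # eV

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError("Z must be >= 1")
        if self.A <= 0 or self.i_elem <= 0:
            raise ValueError("A and i_elem must be positive")


ELEMENTS: dict[str, ElementSpec] = {
    "H": ElementSpec("H", 1, 1.008, 19.2),
    "C": ElementSpec("C", 6, 12.011, 81.0),
    "N": ElementSpec("N", 7, 14.007, 82.0),
    "O": ElementSpec("O", 8, 15.999, 106.0),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple molecular formula like ``C4H10O2`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaParseError(f"malformed formula {formula!r} at position {pos}")
        pos = match.end()
        sym, num = match.groups()
        if sym not in ELEMENTS:
            raise FormulaParseError(f"unknown element symbol {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise FormulaParseError(f"malformed formula {formula!r}")
    return counts


def formula_mass_fractions(formula: str) -> dict[str, float]:
    """Elemental mass fractions of a pure compound."""
    counts = parse_formula(formula)
    masses = {sym: n * ELEMENTS[sym].A for sym, n in counts.items()}
    total = sum(masses.values())
    return {sym: m / total for sym, m in masses.items()}


@dataclass
class MaterialComposition:
    """Elemental mass fractions plus bulk density of a medium."""

    mass_fractions: dict[str, float]
    density: float  # g/cm³
    name: str = "material"

    def __post_init__(self) -> None:
        if not self.mass_fractions:
            raise ValueError("composition must contain at least one element")
        if self.density <= 0:
            raise ValueError("density must be positive")
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {total}, not 1")
        for sym, w in self.mass_fractions.items():
            if sym not in ELEMENTS:
                raise FormulaParseError(f"unknown element symbol {sym!r}")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"mass fraction of {sym} out of [0, 1]: {w}")

    @property
    def elements(self) -> list[ElementSpec]:
        return [ELEMENTS[sym] for sym in self.mass_fractions]


def compose_mixture(
    components: list[tuple[str, float]],
    basis: str = "mass",
    component_densities: list[float] | None = None,
    final_density: float | None = None,
    name: str = "mixture",
) -> MaterialComposition:
    """Combine pure compounds into a mixture.

    Parameters
    ----------
    components
        ``(molecular_formula, proportion)`` pairs.  Proportions are relative
        masses (``basis="mass"``) or relative volumes (``basis="volume"``).
    component_densities
        Per-component densities in g/cm³; required for the volume basis and
        for estimating the mixture density when ``final_density`` is omitted.
    final_density
        Measured bulk density, which overrides the ideal-mixing estimate.
    """
    if basis not in ("mass", "volume"):
        raise ValueError(f"basis must be 'mass' or 'volume', got {basis!r}")
    if not components:
        raise ValueError("at least one component is required")
    for _, prop in components:
        if prop <= 0:
            raise ValueError(f"proportions must be positive, got {prop}")
    if basis == "volume" and component_densities is None:
        raise ValueError("volume basis requires component_densities")

    if basis == "volume":
        masses = [p * rho for (_, p), rho in zip(components, component_densities)]
    else:
        masses = [p for _, p in components]
    total_mass = sum(masses)

    fractions: dict[str, float] = {}
    for (formula, _), m in zip(components, masses):
        for sym, w in formula_mass_fractions(formula).items():
            fractions[sym] = fractions.get(sym, 0.0) + w * m / total_mass
    # renormalise away accumulated round-off so the invariant holds exactly
    s = sum(fractions.values())
    fractions = {sym: w / s for sym, w in fractions.items()}

    if final_density is None:
        if component_densities is None:
            raise ValueError("need component_densities or final_density")
        volume = sum(m / rho for m, rho in zip(masses, component_densities))
        final_density = total_mass / volume

    return MaterialComposition(fractions, final_density, name=name)


def mean_z_over_a(comp: MaterialComposition) -> float:
    """Mass-weighted ⟨Z/A⟩ in mol/g."""
    return sum(w * ELEMENTS[s].Z / ELEMENTS[s].A for s, w in comp.mass_fractions.items())


def electron_density(comp: MaterialComposition) -> float:
    """Electrons per gram: N_A · Σ w_i Z_i / A_i."""
    return N_AVOGADRO * mean_z_over_a(comp)


def _electron_fractions(comp: MaterialComposition) -> dict[str, float]:
    contrib = {s: w * ELEMENTS[s].Z / ELEMENTS[s].A for s, w in comp.mass_fractions.items()}
    total = sum(contrib.values())
    return {s: c / total for s, c in contrib.items()}


def effective_atomic_number(comp: MaterialComposition, exponent: float = 2.94) -> float:
    """Power-law effective atomic number (Σ α_i Z_i^m)^(1/m).

    α_i are electron-number fractions (α_i ∝ w_i Z_i / A_i).  The default
    exponent m = 2.94 is the Mayneord convention for photoelectric-dominated
    photon interactions, the usual choice when quoting a single Z_eff for a
    tissue substitute.
    """
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    alpha = _electron_fractions(comp)
    s = sum(a * ELEMENTS[sym].Z ** exponent for sym, a in alpha.items())
    return s ** (1.0 / exponent)


def mean_excitation_energy(comp: MaterialComposition) -> float:
    """Mean excitation energy I (eV) by Bragg additivity.

    ln I = Σ (w_i Z_i/A_i · ln I_i) / Σ (w_i Z_i/A_i)
    """
    import math

    alpha = _electron_fractions(comp)
    ln_i = sum(a * math.log(ELEMENTS[sym].i_elem) for sym, a in alpha.items())
    return math.exp(ln_i)


def water(name: str = "water") -> MaterialComposition:
    """Pure water at 0.998 g/cm³."""
    return MaterialComposition(formula_mass_fractions("H2O"), WATER_DENSITY, name=name)


def abls(
    basis: str = "volume",
    ratio: tuple[float, float] = (7.0, 3.0),
    density: float = ABLS_DENSITY,
) -> MaterialComposition:
    """The alcohol-based liquid scintillator.

    2-ethoxyethanol and water mixed 7:3.  The ratio is interpreted on a
    volume basis by default (the common lab convention for solvent recipes),
    using component densities 0.930 and 0.998 g/cm³, and the bulk density is
    pinned to the measured 0.945 g/cm³.
    """
    return compose_mixture(
        [("C4H10O2", ratio[0]), ("H2O", ratio[1])],
        basis=basis,
        component_densities=[ETHOXYETHANOL_DENSITY, WATER_DENSITY],
        final_density=density,
        name="AbLS",
    )


# ---------------------------------------------------------------------------
# YAML interchange


def material_to_yaml(comp: MaterialComposition, path) -> None:
    doc = {
        "name": comp.name,
        "density": float(comp.density),
        "mass_fractions": {s: float(w) for s, w in comp.mass_fractions.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def material_from_yaml(path) -> MaterialComposition:
    """Load a material definition.

    Two YAML layouts are accepted: explicit ``mass_fractions``, or a recipe
    with ``components`` (formula/proportion pairs), ``basis``, optional
    ``component_densities`` and ``density``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    name = doc.get("name", "material")
    if "mass_fractions" in doc:
        return MaterialComposition(dict(doc["mass_fractions"]), float(doc["density"]), name=name)
    comps = [(c["formula"], float(c["proportion"])) for c in doc["components"]]
    dens = doc.get("component_densities")
    return compose_mixture(
        comps,
        basis=doc.get("basis", "mass"),
        component_densities=[float(d) for d in dens] if dens else None,
        final_density=float(doc["density"]) if "density" in doc else None,
        name=name,
    )
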