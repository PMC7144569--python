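"""Registry of endogenous-fluorophore band components.

Serum autofluorescence under 310 or 366 nm excitation is decomposed into
bands for retinol, three fluorescing free fatty acids (arachidonic,
linoleic, oleic), a protein emission tail below 420 nm, an unassigned
auxiliary band near 440 nm, a negative hemoglobin re-absorption band
near 410 nm (hemolysis artifact, relevant under 310 nm excitation), and
a flavin band near 560 nm seen only in ischemia/reperfusion samples
under 366 nm excitation.

Each component carries the starting (peak, FWHM) of its band — for the
four fluorophores these are the values measured on the pure compounds in
ethanol — together with fit bounds and a role that controls its sign and
when it is enabled.  The registry round-trips through a YAML config so a
user can adjust starting values or bounds without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .lineshape import ShapeSpec

__all__ = [
    "ComponentSpec",
    "Bounds",
    "get_components",
    "load_library",
    "save_library",
    "FLUOROPHORES",
    "COMPONENT_NAMES",
]

FLUOROPHORES = ("retinol", "arachidonic_acid", "linoleic_acid", "oleic_acid")

COMPONENT_NAMES = FLUOROPHORES + (
    "proteins",
    "undefined_440",
    "hemoglobin_neg",
    "flavin_560",
)

_ROLES = ("fluorophore", "tail", "auxiliary", "negative")

# starting (peak nm, FWHM nm) of the pure-compound emission bands,
# keyed by excitation wavelength
_FLUOROPHORE_STARTS = {
    310: {
        "retinol": (490.0, 112.0),
        "arachidonic_acid": (425.0, 120.0),
        "oleic_acid": (370.0, 85.0),
        "linoleic_acid": (417.0, 92.0),
    },
    366: {
        "retinol": (490.0, 112.0),
        "arachidonic_acid": (470.0, 93.0),
        "oleic_acid": (462.0, 90.0),
        "linoleic_acid": (428.0, 73.0),
    },
}

#: default asymmetry ratio for library components (fit-adjustable)
DEFAULT_RHO = 0.3

_RHO_BOUNDS = (0.0, 1.5)
_AMP_MAX = 1e6

# starting FWHM for the minor bands (not derived from pure compounds;
# the fit is expected to adapt them within wide bounds)
_MINOR_FWHM = {
    "proteins": 80.0,
    "undefined_440": 60.0,
    "hemoglobin_neg": 30.0,
    "flavin_560": 60.0,
}
_MINOR_FWHM_BOUNDS = (20.0, 150.0)

#: half-width (nm) of the peak-position bounds around the start for the
#: four fluorophores in reference-stage fits
PEAK_HALF_WINDOW = 10.0


@dataclass
class Bounds:
    """Fit bounds for one component's observable parameters."""

    peak_lambda: tuple[float, float]
    fwhm: tuple[float, float]
    asymmetry_rho: tuple[float, float] = _RHO_BOUNDS
    amplitude: tuple[float, float] = (0.0, _AMP_MAX)

    def __post_init__(self) -> None:
        for name in ("peak_lambda", "fwhm", "asymmetry_rho", "amplitude"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"bounds.{name}: lower {lo} > upper {hi}")


@dataclass
class ComponentSpec:
    """One named band component with starting shape, bounds and role."""

    name: str
    role: str
    shape: ShapeSpec
    bounds: Bounds
    excitation: int
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.name not in COMPONENT_NAMES:
            raise ValueError(f"unknown component name {self.name!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.excitation not in (310, 366):
            raise ValueError(f"unsupported excitation {self.excitation} nm")
        amp_lo, amp_hi = self.bounds.amplitude
        if self.role == "negative":
            if amp_hi > 0:
                raise ValueError(
                    f"{self.name}: negative-role amplitude upper bound must be <= 0"
                )
        elif amp_lo < 0:
            raise ValueError(
                f"{self.name}: amplitude lower bound must be >= 0 for role {self.role}"
            )


def _fluorophore(name: str, excitation: int) -> ComponentSpec:
    peak, fwhm = _FLUOROPHORE_STARTS[excitation][name]
    return ComponentSpec(
        name=name,
        role="fluorophore",
        shape=ShapeSpec(peak, fwhm, DEFAULT_RHO),
        bounds=Bounds(
            peak_lambda=(peak - PEAK_HALF_WINDOW, peak + PEAK_HALF_WINDOW),
            fwhm=(0.75 * fwhm, 1.25 * fwhm),
        ),
        excitation=excitation,
    )


def _minor(name: str, role: str, peak: float, excitation: int,
           peak_bounds: tuple[float, float], enabled: bool = True) -> ComponentSpec:
    amp = (-_AMP_MAX, 0.0) if role == "negative" else (0.0, _AMP_MAX)
    return ComponentSpec(
        name=name,
        role=role,
        shape=ShapeSpec(peak, _MINOR_FWHM[name], DEFAULT_RHO),
        bounds=Bounds(peak_lambda=peak_bounds, fwhm=_MINOR_FWHM_BOUNDS, amplitude=amp),
        excitation=excitation,
        enabled=enabled,
    )


def get_components(excitation: int, treatment_context: str = "control",
                   include_hemoglobin_at_366: bool = False) -> list[ComponentSpec]:
    """Default component set for one excitation wavelength.

    Parameters
    ----------
    excitation:
        310 or 366 (nm).
    treatment_context:
        ``"control"`` or ``"ir"``; the flavin band near 560 nm is only
        enabled for ischemia/reperfusion samples under 366 nm excitation,
        where it appears in measured spectra.
    include_hemoglobin_at_366:
        The hemoglobin compensation band is tied to the emission
        distortion around 410 nm seen under 310 nm excitation; it is off
        at 366 nm unless explicitly requested.
    """
    if excitation not in (310, 366):
        raise ValueError(f"unsupported excitation {excitation} nm (use 310 or 366)")
    if treatment_context not in ("control", "ir"):
        raise ValueError(f"treatment_context must be 'control' or 'ir', got {treatment_context!r}")

    comps = [_fluorophore(n, excitation) for n in
             ("retinol", "arachidonic_acid", "linoleic_acid", "oleic_acid")]
    # protein emission tail: peak constrained below 420 nm, width free
    comps.append(_minor("proteins", "tail", 400.0, excitation, (370.0, 419.0)))
    comps.append(_minor("undefined_440", "auxiliary", 440.0, excitation, (430.0, 450.0)))
    comps.append(
        _minor(
            "hemoglobin_neg", "negative", 410.0, excitation, (400.0, 420.0),
            enabled=(excitation == 310) or include_hemoglobin_at_366,
        )
    )
    if excitation == 366 and treatment_context == "ir":
        comps.append(_minor("flavin_560", "auxiliary", 560.0, excitation, (545.0, 575.0)))
    return [c for c in comps if c.enabled]


# ---------------------------------------------------------------------------
# YAML round-trip

def _spec_to_dict(c: ComponentSpec) -> dict:
    return {
        "name": c.name,
        "role": c.role,
        "peak_lambda": c.shape.peak_lambda,
        "fwhm": c.shape.fwhm,
        "rho": c.shape.asymmetry_rho,
        "bounds": asdict(c.bounds),
        "enabled": c.enabled,
    }


def save_library(specs: list[ComponentSpec], config_path) -> None:
    """Write a component registry to a YAML config."""
    if not specs:
        raise ValueError("empty component list")
    excitations = {c.excitation for c in specs}
    if len(excitations) != 1:
        raise ValueError("all components in one library must share an excitation")
    doc = {
        "excitation": specs[0].excitation,
        "components": [_spec_to_dict(c) for c in specs],
    }
    Path(config_path).write_text(yaml.safe_dump(doc, sort_keys=False))


class LibraryConfigError(ValueError):
    """Malformed component-library config; message carries the field path."""


def load_library(config_path) -> list[ComponentSpec]:
    """Read a component registry from a YAML config written by
    :func:`save_library` (or hand-edited)."""
    try:
        doc = yaml.safe_load(Path(config_path).read_text())
    except yaml.YAMLError as exc:
        raise LibraryConfigError(f"{config_path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or "components" not in doc or "excitation" not in doc:
        raise LibraryConfigError(f"{config_path}: expected keys 'excitation' and 'components'")
    excitation = doc["excitation"]
    specs = []
    seen = set()
    for i, entry in enumerate(doc["components"]):
        path = f"components[{i}]"
        try:
            name = entry["name"]
            if name in seen:
                raise LibraryConfigError(f"{path}.name: duplicate component {name!r}")
            seen.add(name)
            spec = ComponentSpec(
                name=name,
                role=entry["role"],
                shape=ShapeSpec(entry["peak_lambda"], entry["fwhm"], entry["rho"]),
                bounds=Bounds(**{k: tuple(v) for k, v in entry["bounds"].items()}),
                excitation=excitation,
                enabled=bool(entry.get("enabled", True)),
            )
        except LibraryConfigError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise LibraryConfigError(f"{path}: {exc}") from exc
        specs.append(spec)
    return specs
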