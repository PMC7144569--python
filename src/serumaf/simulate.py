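"""Synthetic serum-autofluorescence cohort generator.

Emulates the sham vs ischemia/reperfusion (I/R) serum study design so
that the whole pipeline — normalization, band fitting, quantification,
group statistics — can be exercised end to end without measured data.

Each treatment group × excitation wavelength carries a
:class:`GroupProfile`: mean ± SD percentage composition over the library
components (defaults are the published group means, with SD = SE·√n for
n = 7 animals per group), a mean total integrated area on the measured
scale (defaults are the sums of the published absolute-contribution
rows), a hemoglobin re-absorption dip depth (310 nm excitation), a
flavin band share (I/R groups at 366 nm), and an additive noise level
on the peak-normalized scale.

A sample is drawn by sampling its composition (truncated-normal
percentages renormalized to 100), building one GMG band per component
from the library shapes with a small per-sample peak jitter, scaling the
summed curve to a lognormally drawn total area, and adding Gaussian
noise.  The exact composition actually realized within the analysis
window is returned as ground truth for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .library import DEFAULT_RHO, get_components
from .lineshape import ShapeSpec, gmg_value, solve_band
from .spectra import ANALYSIS_WINDOW, Spectrum, write_spectra

__all__ = [
    "GroupProfile",
    "default_profiles",
    "generate_spectrum",
    "generate_cohort",
    "generate_truth_cohort",
    "GRID",
]

#: emission grid (nm): 390–630 at 1 nm, as recorded
GRID = np.arange(390.0, 630.0 + 1e-9, 1.0)

_N_REFERENCE = 7  # animals per group behind the published mean ± SE

# Published group compositions, percent of overall fitted area,
# (mean, SE) per component; cells reported only as "<= 5%" are assigned
# 2.0 ± 0.5.  The remainder to 100 (minus any flavin share) goes to the
# unassigned 440 nm band.
_SMALL = (2.0, 0.5)

_PERCENT_TABLE = {
    310: {
        "sham": {
            "retinol": (44.26, 1.95), "arachidonic_acid": (25.13, 1.12),
            "linoleic_acid": _SMALL, "oleic_acid": (7.93, 0.39),
            "proteins": (12.48, 0.60),
        },
        "ir_60_60": {
            "retinol": (31.39, 0.84), "arachidonic_acid": (38.93, 1.04),
            "linoleic_acid": _SMALL, "oleic_acid": (8.86, 0.23),
            "proteins": (8.20, 0.21),
        },
        "ir_60_120": {
            "retinol": (29.09, 3.63), "arachidonic_acid": (39.16, 4.95),
            "linoleic_acid": _SMALL, "oleic_acid": (8.56, 0.90),
            "proteins": (10.24, 1.45),
        },
    },
    366: {
        "sham": {
            "retinol": (33.43, 2.68), "arachidonic_acid": (20.22, 1.52),
            "linoleic_acid": (23.32, 1.86), "oleic_acid": (12.88, 1.03),
            "proteins": _SMALL,
        },
        "ir_60_60": {
            "retinol": (24.03, 1.35), "arachidonic_acid": (26.50, 1.49),
            "linoleic_acid": (27.47, 1.55), "oleic_acid": (16.97, 0.67),
            "proteins": _SMALL,
        },
        "ir_60_120": {
            "retinol": (23.76, 3.34), "arachidonic_acid": (27.17, 3.82),
            "linoleic_acid": (27.02, 3.93), "oleic_acid": (16.97, 2.38),
            "proteins": _SMALL,
        },
    },
}

# Total measured area per group (a.u.·nm over 390–600 nm): sum of the
# published absolute component contributions for that group row.
_TOTAL_AREA = {
    310: {"sham": 39284.20, "ir_60_60": 57836.14, "ir_60_120": 50453.79},
    366: {"sham": 16218.19, "ir_60_60": 24444.97, "ir_60_120": 20402.38},
}


@dataclass
class GroupProfile:
    """Statistical recipe for one treatment group at one excitation."""

    group: str
    excitation: int
    component_percent_mean: dict[str, float]
    component_percent_sd: dict[str, float]
    total_area_mean: float
    total_area_cv: float = 0.15
    flavin_percent: float = 0.0       # I/R groups at 366 nm
    flavin_percent_sd: float = 0.5
    hemoglobin_depth: float = 0.0     # dip depth, % of spectrum peak (310 nm)
    noise_sd: float = 0.5             # a.u. on the peak-normalized scale
    peak_jitter: float = 2.0          # per-sample band-peak jitter (± nm)

    def __post_init__(self) -> None:
        total = sum(self.component_percent_mean.values()) + self.flavin_percent
        if total > 100.0 + 1e-9:
            raise ValueError(
                f"{self.group}/{self.excitation}: percent means sum to {total:.2f} > 100"
            )
        if any(sd < 0 for sd in self.component_percent_sd.values()):
            raise ValueError("percent SDs must be >= 0")

    @property
    def undefined_percent(self) -> float:
        """Remainder to 100 assigned to the unassigned 440 nm band."""
        return 100.0 - sum(self.component_percent_mean.values()) - self.flavin_percent


def default_profiles(excitation: int, n_reference: int = _N_REFERENCE
                     ) -> dict[str, GroupProfile]:
    """Default sham / I/R 60-60 / I/R 60-120 profiles for one excitation."""
    if excitation not in _PERCENT_TABLE:
        raise ValueError(f"unsupported excitation {excitation} nm")
    out = {}
    for group, cells in _PERCENT_TABLE[excitation].items():
        means = {c: m for c, (m, _) in cells.items()}
        sds = {c: se * np.sqrt(n_reference) for c, (_, se) in cells.items()}
        out[group] = GroupProfile(
            group=group,
            excitation=excitation,
            component_percent_mean=means,
            component_percent_sd=sds,
            total_area_mean=_TOTAL_AREA[excitation][group],
            flavin_percent=(3.0 if excitation == 366 and group != "sham" else 0.0),
            hemoglobin_depth=(5.0 if excitation == 310 else 0.0),
        )
    return out


def _draw_composition(profile: GroupProfile, rng: np.random.Generator
                      ) -> dict[str, float]:
    """Truncated-normal composition draw, renormalized to sum to 100."""
    means = dict(profile.component_percent_mean)
    sds = dict(profile.component_percent_sd)
    means["undefined_440"] = profile.undefined_percent
    sds["undefined_440"] = 0.5
    if profile.flavin_percent > 0:
        means["flavin_560"] = profile.flavin_percent
        sds["flavin_560"] = profile.flavin_percent_sd
    comp = {}
    for name in means:
        comp[name] = max(0.0, rng.normal(means[name], sds[name]))
    total = sum(comp.values())
    if total <= 0:
        raise RuntimeError("degenerate composition draw")
    return {k: 100.0 * v / total for k, v in comp.items()}


def _component_shapes(profile: GroupProfile) -> dict[str, ShapeSpec]:
    ctx = "control" if profile.group == "sham" else "ir"
    return {c.name: c.shape for c in get_components(profile.excitation, ctx)}


def generate_spectrum(profile: GroupProfile, sample_id: str, seed
                      ) -> tuple[Spectrum, dict]:
    """Draw one synthetic serum emission spectrum plus its ground truth.

    Returns ``(spectrum, truth)`` where ``truth`` holds the drawn
    composition, the composition actually realized inside the analysis
    window (``percent_*``, what a perfect fit would recover), the
    per-component absolute contributions and the total area.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    comp = _draw_composition(profile, rng)
    shapes = _component_shapes(profile)

    total_area = profile.total_area_mean
    if profile.total_area_cv > 0:
        s = np.sqrt(np.log1p(profile.total_area_cv**2))
        total_area *= np.exp(rng.normal(-0.5 * s * s, s))

    curve = np.zeros_like(GRID)
    window_areas = {}
    jitters = {}
    lo, hi = ANALYSIS_WINDOW
    wmask = (GRID >= lo) & (GRID <= hi)
    for name, pct in comp.items():
        shape = shapes.get(name)
        if shape is None:  # component not in this excitation's library
            continue
        jitter = rng.uniform(-profile.peak_jitter, profile.peak_jitter)
        band = solve_band(
            ShapeSpec(shape.peak_lambda + jitter, shape.fwhm, DEFAULT_RHO),
            amplitude=pct,
        )
        vals = gmg_value(band, GRID)
        curve += vals
        window_areas[name] = float(np.trapezoid(vals[wmask], GRID[wmask]))
        jitters[name] = jitter

    # hemoglobin re-absorption dip, subtracted as a fraction of the peak
    if profile.hemoglobin_depth > 0:
        dip_shape = ShapeSpec(410.0 + rng.uniform(-profile.peak_jitter,
                                                  profile.peak_jitter),
                              30.0, DEFAULT_RHO)
        dip = solve_band(dip_shape, amplitude=1.0)
        unit = gmg_value(dip, GRID)
        depth = profile.hemoglobin_depth / 100.0 * curve.max()
        scale = -depth / unit.max()
        curve += scale * unit
        window_areas["hemoglobin_neg"] = float(
            np.trapezoid(scale * unit[wmask], GRID[wmask]))

    # scale so the analysis-window integral equals the drawn total area
    cur_area = float(np.trapezoid(curve[wmask], GRID[wmask]))
    k = total_area / cur_area
    curve *= k
    window_areas = {n: a * k for n, a in window_areas.items()}

    if profile.noise_sd > 0:
        noise = rng.normal(0.0, profile.noise_sd * curve.max() / 100.0, GRID.size)
        curve = curve + noise

    pos_total = sum(a for a in window_areas.values() if a > 0)
    truth = {
        "sample_id": sample_id,
        "group": profile.group,
        "excitation": profile.excitation,
        "total_area": total_area,
    }
    for name, a in window_areas.items():
        truth[f"percent_{name}"] = 100.0 * a / pos_total
        truth[f"absolute_{name}"] = a / pos_total * total_area
    for name, pct in comp.items():
        truth[f"drawn_percent_{name}"] = pct
    for name, j in jitters.items():
        truth[f"peak_jitter_{name}"] = j

    spectrum = Spectrum(
        wavelengths=GRID.copy(),
        intensities=curve,
        excitation=profile.excitation,
        sample_id=sample_id,
        group=profile.group,
    )
    return spectrum, truth


def generate_truth_cohort(profiles, n_per_group: int, seed: int) -> pd.DataFrame:
    """Draw cohort compositions and total areas without rendering spectra.

    Samples the same statistical model as :func:`generate_spectrum`
    (truncated-normal percentages renormalized to 100, lognormal total
    area) and returns per-sample ``drawn_percent_*`` and ``absolute_*``
    columns, where ``absolute = drawn_percent / 100 × total_area``.
    Used for replicate-level power studies of the group statistics,
    where rendering and re-fitting thousands of spectra would only add
    estimation noise on top of the same sampling distribution.
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    rows = []
    children = np.random.SeedSequence(seed).spawn(len(profiles) * n_per_group)
    i = 0
    for profile in profiles:
        for j in range(n_per_group):
            rng = np.random.default_rng(children[i])
            comp = _draw_composition(profile, rng)
            total_area = profile.total_area_mean
            if profile.total_area_cv > 0:
                s = np.sqrt(np.log1p(profile.total_area_cv**2))
                total_area *= np.exp(rng.normal(-0.5 * s * s, s))
            row = {"sample_id": f"{profile.group}_{j + 1:02d}",
                   "group": profile.group,
                   "excitation": profile.excitation,
                   "total_area": total_area}
            for name, pct in comp.items():
                row[f"drawn_percent_{name}"] = pct
                row[f"absolute_{name}"] = pct / 100.0 * total_area
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)


def generate_cohort(profiles, n_per_group: int, seed: int,
                    out_dir=None) -> tuple[list[Spectrum], pd.DataFrame]:
    """Generate a full cohort: ``n_per_group`` samples per profile.

    Per-sample seeds are spawned from the master seed with
    ``numpy.random.SeedSequence`` in a fixed (profile, sample) order, so
    the cohort is reproducible sample by sample.  If ``out_dir`` is
    given, writes ``spectra.csv`` (long format) and ``truth.csv``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    children = np.random.SeedSequence(seed).spawn(len(profiles) * n_per_group)
    spectra, rows = [], []
    i = 0
    for profile in profiles:
        for j in range(n_per_group):
            sid = f"{profile.group}_{profile.excitation}nm_{j + 1:02d}"
            spec, truth = generate_spectrum(profile, sid, children[i])
            spectra.append(spec)
            rows.append(truth)
            i += 1
    truth_df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spectra(spectra, out / "spectra.csv")
        truth_df.to_csv(out / "truth.csv", index=False)
    return spectra, truth_df
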