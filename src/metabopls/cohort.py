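"""Synthetic two-group ¹H NMR cohorts with known discriminatory metabolites.

This module generates 600 MHz-like 1D frequency-domain proton spectra of
serum and urine for a case/control (COPD vs. healthy) design.  Each
metabolite is described by one or more idealized first-order multiplets
(singlet, doublet, triplet, quartet, doublet-of-doublets, generic
multiplet) rendered as sums of Lorentzian lines.  Per-sample metabolite
concentrations are drawn log-normally around a group-dependent median, so
every simulated cohort carries an exact ground truth: which metabolites
differ between groups, in which direction, and by how much.

The built-in libraries emulate the composition of real biofluid spectra:
serum is dominated by broad lipoprotein envelopes (HDL/VLDL methyl and
methylene resonances) plus amino acids, glucose and lactate; urine by
creatinine, citrate, TMAO, hippurate, α-ketoglutarate and related organic
acids, with a TSP chemical-shift reference singlet at 0.00 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "LINE_RATIOS",
    "MultipletDef",
    "MetaboliteSpec",
    "CohortConfig",
    "Spectrum",
    "CohortDataset",
    "build_library",
    "render_spectrum",
    "simulate_cohort",
    "library_to_yaml",
    "library_from_yaml",
]

# Idealized first-order intensity ratios of the multiplet lines.
LINE_RATIOS: dict[str, tuple[int, ...]] = {
    "s": (1,),
    "d": (1, 1),
    "t": (1, 2, 1),
    "q": (1, 3, 3, 1),
    "dd": (1, 1, 1, 1),
    "m": (1, 1, 1, 1, 1),
}

GROUPS = ("copd", "control")
FLUIDS = ("serum", "urine")


@dataclass(frozen=True)
class MultipletDef:
    """One multiplet of a metabolite.

    Parameters
    ----------
    center : float
        Chemical shift of the multiplet midpoint, ppm.
    multiplicity : str
        One of ``s, d, t, q, dd, m``.
    j_spacing : float
        Spacing between adjacent lines in ppm.  The default 0.012 ppm
        corresponds to a ~7 Hz coupling at 600 MHz.
    rel_area : float
        Weight of this multiplet within its metabolite (typically the
        number of contributing protons).
    fwhm : float or None
        Per-multiplet Lorentzian full width at half maximum in ppm;
        ``None`` uses the cohort-level default.  Broad values (~0.03 ppm)
        mimic macromolecule/lipoprotein envelopes.
    """

    center: float
    multiplicity: str = "s"
    j_spacing: float = 0.012
    rel_area: float = 1.0
    fwhm: float | None = None

    def __post_init__(self) -> None:
        if self.multiplicity not in LINE_RATIOS:
            raise ValueError(
                f"unknown multiplicity {self.multiplicity!r}; "
                f"expected one of {sorted(LINE_RATIOS)}"
            )
        if self.multiplicity != "s" and self.j_spacing <= 0:
            raise ValueError("j_spacing must be > 0 for non-singlet multiplets")
        if self.rel_area <= 0:
            raise ValueError("rel_area must be > 0")
        if self.fwhm is not None and self.fwhm <= 0:
            raise ValueError("fwhm override must be > 0")

    @property
    def line_ratios(self) -> tuple[int, ...]:
        return LINE_RATIOS[self.multiplicity]

    def line_offsets(self) -> np.ndarray:
        """Line positions relative to the multiplet center, ppm."""
        n = len(self.line_ratios)
        return (np.arange(n) - (n - 1) / 2.0) * self.j_spacing


@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite: its multiplets plus cohort-level abundance model.

    ``group_log2_effect`` is the log2 fold change of the COPD median
    concentration relative to the control median; a negative value means
    the metabolite is higher in healthy controls.  ``cv_within_group`` is
    the within-group coefficient of variation of concentration (the SD of
    log-concentration is ``sqrt(log(1 + cv^2))``).
    """

    name: str
    multiplets: tuple[MultipletDef, ...]
    base_abundance: float
    group_log2_effect: float = 0.0
    cv_within_group: float = 0.25

    def __post_init__(self) -> None:
        if self.base_abundance <= 0:
            raise ValueError(f"{self.name}: base_abundance must be > 0")
        if self.cv_within_group < 0:
            raise ValueError(f"{self.name}: cv_within_group must be >= 0")
        if not self.multiplets:
            raise ValueError(f"{self.name}: needs at least one multiplet")


@dataclass(frozen=True)
class CohortConfig:
    """Acquisition-window and noise settings for a simulated cohort.

    Defaults reproduce the study design this simulator emulates: 32 COPD
    patients versus 21 healthy controls, a 600 MHz acquisition window wide
    enough for both the serum (9.0–0.5 ppm) and urine (10.0–0.5 ppm)
    integration regions plus the TSP reference at 0 ppm.
    """

    fluid: str
    n_copd: int = 32
    n_control: int = 21
    ppm_min: float = -0.5
    ppm_max: float = 10.5
    points: int = 32768
    lorentz_fwhm: float = 0.002
    shift_jitter_sd: float = 0.001
    noise_sd: float = 5.0
    baseline_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise ValueError(f"unsupported fluid {self.fluid!r}; expected one of {FLUIDS}")
        if self.n_copd < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if self.points < 2:
            raise ValueError("points must be >= 2")
        for name in ("lorentz_fwhm",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("shift_jitter_sd", "noise_sd", "baseline_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Spectrum:
    """One sample's (ppm, intensity) trace.

    The ppm axis is stored strictly descending (high → low), the NMR
    plotting convention; ascending input is flipped on construction.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    fluid: str = "serum"
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError(
                f"axis length {self.ppm.size} != intensity length {self.intensity.size}"
            )
        d = np.diff(self.ppm)
        if d.size and np.all(d > 0):  # ascending input: flip to convention
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif d.size and not np.all(d < 0):
            raise ValueError("ppm axis must be strictly monotone")
        if self.group not in GROUPS + ("unknown",):
            raise ValueError(f"unknown group {self.group!r}")
        if self.fluid not in FLUIDS:
            raise ValueError(f"unsupported fluid {self.fluid!r}")

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.ppm.copy(), self.intensity.copy(), self.sample_id, self.fluid, self.group
        )


@dataclass
class CohortDataset:
    """Simulated cohort plus its generative ground truth.

    ``truth`` maps metabolite name to ``(group_log2_effect, drawn
    concentrations)`` with the concentration array aligned with
    ``spectra``.
    """

    spectra: list[Spectrum]
    truth: dict[str, tuple[float, np.ndarray]]

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.spectra]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]


def _m(center, mult="s", rel=1.0, j=0.012, fwhm=None) -> MultipletDef:
    return MultipletDef(center, mult, j_spacing=j, rel_area=rel, fwhm=fwhm)


_BROAD = 0.03  # FWHM (ppm) for lipoprotein/macromolecule envelopes


def _serum_library(effect: float) -> list[MetaboliteSpec]:
    # Discriminatory species: r > 0 in the reference coefficient table means
    # higher in controls, i.e. a negative COPD log2 effect.
    down, up = -effect, +effect
    return [
        # --- discriminators ---
        MetaboliteSpec("alanine", (_m(1.48, "d", 3),), 8.0, down),
        MetaboliteSpec("glycerophosphocholine", (_m(3.36, "s", 9),), 6.0, up),
        MetaboliteSpec("isoleucine", (_m(0.94, "t", 3), _m(1.01, "d", 3)), 5.0, down),
        MetaboliteSpec("hdl_lipid", (_m(0.84, "m", 10, fwhm=_BROAD),), 30.0, down),
        MetaboliteSpec("leucine", (_m(0.96, "d", 6),), 8.0, down),
        # --- background (no group effect) ---
        MetaboliteSpec("vldl_ch3", (_m(0.88, "m", 8, fwhm=_BROAD),), 40.0),
        MetaboliteSpec("vldl_ch2", (_m(1.29, "m", 20, fwhm=_BROAD),), 50.0),
        MetaboliteSpec("lipid_ch2_co", (_m(1.57, "m", 4, fwhm=_BROAD), _m(2.23, "m", 4, fwhm=_BROAD)), 18.0),
        MetaboliteSpec("lipid_unsat", (_m(2.02, "m", 4, fwhm=_BROAD), _m(5.31, "m", 2, fwhm=_BROAD)), 12.0),
        MetaboliteSpec("nac_glycoprotein", (_m(2.04, "s", 3, fwhm=0.008),), 12.0),
        MetaboliteSpec(
            "glucose",
            (
                _m(3.40, "t", 1),
                _m(3.46, "m", 1),
                _m(3.53, "dd", 1),
                _m(3.72, "dd", 1),
                _m(3.89, "dd", 1),
                _m(5.23, "d", 0.4),
            ),
            60.0,
        ),
        MetaboliteSpec("lactate", (_m(1.33, "d", 3), _m(4.13, "q", 1)), 25.0),
        MetaboliteSpec("valine", (_m(0.98, "d", 3), _m(1.04, "d", 3)), 6.0),
        MetaboliteSpec("glutamine", (_m(2.14, "m", 2), _m(2.45, "m", 2)), 8.0),
        MetaboliteSpec("glutamate", (_m(2.08, "m", 2), _m(2.35, "m", 2)), 7.0),
        MetaboliteSpec("glycine", (_m(3.56, "s", 2),), 10.0),
        MetaboliteSpec("lysine", (_m(1.72, "m", 2), _m(3.02, "t", 2)), 8.0),
        MetaboliteSpec("creatine", (_m(3.03, "s", 3), _m(3.93, "s", 2)), 6.0),
        MetaboliteSpec("acetate", (_m(1.92, "s", 3),), 4.0),
        MetaboliteSpec("phenylalanine", (_m(7.32, "d", 2), _m(7.37, "t", 1), _m(7.42, "m", 2)), 3.0),
        MetaboliteSpec("tyrosine", (_m(6.89, "d", 2), _m(7.19, "d", 2)), 3.0),
        MetaboliteSpec("histidine", (_m(7.06, "s", 1), _m(7.77, "s", 1)), 2.0),
        MetaboliteSpec("formate", (_m(8.46, "s", 1),), 1.0),
    ]


def _urine_library(effect: float) -> list[MetaboliteSpec]:
    down, up = -effect, +effect
    return [
        # --- discriminators ---
        MetaboliteSpec(
            "1-methylnicotinamide",
            (_m(8.02, "t", 1), _m(8.09, "s", 1), _m(8.85, "d", 1), _m(9.13, "s", 1)),
            6.0,
            down,
        ),
        MetaboliteSpec("acetate", (_m(1.93, "s", 3),), 12.0, up),
        MetaboliteSpec("acetoacetate", (_m(2.28, "s", 3),), 6.0, up),
        MetaboliteSpec("acetone", (_m(2.23, "s", 6),), 5.0, up),
        MetaboliteSpec("carnosine", (_m(7.03, "s", 1), _m(7.86, "s", 1)), 4.0, up),
        MetaboliteSpec("creatinine", (_m(3.05, "s", 3), _m(4.06, "s", 2)), 100.0, down),
        MetaboliteSpec("lactate", (_m(1.33, "d", 3), _m(4.13, "q", 1)), 15.0, down),
        MetaboliteSpec(
            "m-hydroxyphenylacetate",
            (_m(3.72, "s", 2), _m(6.67, "d", 1), _m(6.86, "d", 1), _m(7.28, "t", 1)),
            8.0,
            up,
        ),
        MetaboliteSpec(
            "phenylacetylglycine",
            (_m(7.32, "d", 2), _m(7.36, "t", 1), _m(7.42, "dd", 2)),
            7.0,
            up,
        ),
        MetaboliteSpec("pyruvate", (_m(2.35, "s", 3),), 8.0, up),
        MetaboliteSpec("alpha-ketoglutarate", (_m(2.45, "t", 2), _m(3.01, "t", 2)), 20.0, up),
        # --- background (no group effect) ---
        MetaboliteSpec("tsp", (_m(0.00, "s", 9),), 15.0, 0.0, cv_within_group=0.0),
        MetaboliteSpec("citrate", (_m(2.54, "d", 2, j=0.026), _m(2.66, "d", 2, j=0.026)), 40.0),
        MetaboliteSpec(
            "hippurate",
            (_m(3.97, "d", 2), _m(7.55, "t", 2), _m(7.64, "t", 1), _m(7.83, "d", 2)),
            30.0,
        ),
        MetaboliteSpec("trimethylamine-n-oxide", (_m(3.27, "s", 9),), 35.0),
        MetaboliteSpec("taurine", (_m(3.26, "t", 2), _m(3.43, "t", 2)), 18.0),
        MetaboliteSpec("glycine", (_m(3.56, "s", 2),), 25.0),
        MetaboliteSpec("succinate", (_m(2.41, "s", 4),), 8.0),
        MetaboliteSpec("dimethylamine", (_m(2.72, "s", 6),), 10.0),
        MetaboliteSpec("choline", (_m(3.20, "s", 9),), 6.0),
        MetaboliteSpec("allantoin", (_m(5.39, "s", 1),), 12.0),
        MetaboliteSpec("formate", (_m(8.46, "s", 1),), 3.0),
    ]


def build_library(fluid: str, effect_magnitude: float = 0.5) -> list[MetaboliteSpec]:
    """Metabolite library for one biofluid.

    Parameters
    ----------
    fluid : {"serum", "urine"}
    effect_magnitude : float
        |log2 fold change| applied to the discriminatory metabolites; the
        sign pattern (which species go up or down in COPD) is fixed by the
        library.  Set to 0 for a null cohort with no true group effect.

    Returns
    -------
    list of MetaboliteSpec
    """
    if effect_magnitude < 0:
        raise ValueError("effect_magnitude must be >= 0")
    if fluid == "serum":
        return _serum_library(effect_magnitude)
    if fluid == "urine":
        return _urine_library(effect_magnitude)
    raise ValueError(f"unsupported fluid {fluid!r}; expected one of {FLUIDS}")


def render_spectrum(
    concentrations: Mapping[str, float],
    library: Sequence[MetaboliteSpec],
    config: CohortConfig,
    rng: np.random.Generator,
    sample_id: str = "",
    group: str = "unknown",
) -> Spectrum:
    """Render one spectrum from metabolite amounts.

    Each multiplet line is a Lorentzian whose *area* equals
    ``amount * rel_area * ratio / sum(ratios)``, so integrated intensity is
    linear in concentration.  A single chemical-shift jitter per metabolite
    (SD ``config.shift_jitter_sd``) emulates pH/ionic-strength positional
    variability; i.i.d. Gaussian noise and an optional smooth non-negative
    quadratic baseline are added on top.
    """
    by_name = {m.name: m for m in library}
    unknown = sorted(set(concentrations) - set(by_name))
    if unknown:
        raise ValueError(f"unknown metabolite(s): {', '.join(unknown)}")
    for name, amount in concentrations.items():
        if amount < 0:
            raise ValueError(f"negative amount for {name}: {amount}")

    ppm = np.linspace(config.ppm_max, config.ppm_min, config.points)
    intensity = np.zeros_like(ppm)
    # Iterate the library (not the dict) so rng consumption is deterministic.
    for met in library:
        jitter = rng.normal(0.0, config.shift_jitter_sd)
        amount = float(concentrations.get(met.name, 0.0))
        if amount == 0.0:
            continue
        for mp in met.multiplets:
            fwhm = mp.fwhm if mp.fwhm is not None else config.lorentz_fwhm
            hw = fwhm / 2.0
            ratios = np.asarray(mp.line_ratios, dtype=float)
            areas = amount * mp.rel_area * ratios / ratios.sum()
            for offset, area in zip(mp.line_offsets(), areas):
                pos = mp.center + offset + jitter
                height = 2.0 * area / (np.pi * fwhm)
                intensity += height * hw * hw / ((ppm - pos) ** 2 + hw * hw)
    if config.baseline_amplitude > 0:
        c = rng.uniform(0.0, 1.0, 3)
        u = (ppm - config.ppm_min) / (config.ppm_max - config.ppm_min)
        intensity += config.baseline_amplitude * (c[0] + c[1] * u + c[2] * u * u)
    intensity += rng.normal(0.0, config.noise_sd, config.points)
    return Spectrum(ppm, intensity, sample_id=sample_id, fluid=config.fluid, group=group)


def simulate_cohort(
    config: CohortConfig, library: Sequence[MetaboliteSpec] | None = None
) -> CohortDataset:
    """Simulate a full two-group cohort.

    Concentrations are drawn log-normally: for metabolite *m* in sample *i*
    of group *g*, ``c = base * 2**(effect * [g == copd]) * exp(eps)`` with
    ``eps ~ N(0, sqrt(log(1 + cv^2)))``.  Bit-reproducible for a fixed
    ``config.seed``.
    """
    if library is None:
        library = build_library(config.fluid)
    rng = np.random.default_rng(config.seed)
    n = config.n_copd + config.n_control
    groups = ["copd"] * config.n_copd + ["control"] * config.n_control
    ids = [f"{config.fluid}-copd-{i + 1:03d}" for i in range(config.n_copd)] + [
        f"{config.fluid}-ctrl-{i + 1:03d}" for i in range(config.n_control)
    ]
    conc = {m.name: np.empty(n) for m in library}
    spectra: list[Spectrum] = []
    for i, (sid, grp) in enumerate(zip(ids, groups)):
        amounts: dict[str, float] = {}
        for met in library:
            sigma = float(np.sqrt(np.log1p(met.cv_within_group**2)))
            median = met.base_abundance * 2.0 ** (
                met.group_log2_effect if grp == "copd" else 0.0
            )
            c = median * float(np.exp(rng.normal(0.0, sigma)))
            amounts[met.name] = c
            conc[met.name][i] = c
        spectra.append(
            render_spectrum(amounts, library, config, rng, sample_id=sid, group=grp)
        )
    truth = {m.name: (m.group_log2_effect, conc[m.name]) for m in library}
    return CohortDataset(spectra, truth)


# ---------------------------------------------------------------------------
# library serialization (structured text, one record per metabolite)

def library_to_yaml(library: Sequence[MetaboliteSpec], path) -> None:
    records = []
    for m in library:
        records.append(
            {
                "name": m.name,
                "base_abundance": float(m.base_abundance),
                "group_log2_effect": float(m.group_log2_effect),
                "cv_within_group": float(m.cv_within_group),
                "multiplets": [
                    {
                        "center": float(mp.center),
                        "multiplicity": mp.multiplicity,
                        "j_spacing": float(mp.j_spacing),
                        "rel_area": float(mp.rel_area),
                        **({"fwhm": float(mp.fwhm)} if mp.fwhm is not None else {}),
                    }
                    for mp in m.multiplets
                ],
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump(records, fh, sort_keys=False)


def library_from_yaml(path) -> list[MetaboliteSpec]:
    with open(path) as fh:
        records = yaml.safe_load(fh)
    out = []
    for rec in records:
        mps = tuple(
            MultipletDef(
                mp["center"],
                mp.get("multiplicity", "s"),
                j_spacing=mp.get("j_spacing", 0.012),
                rel_area=mp.get("rel_area", 1.0),
                fwhm=mp.get("fwhm"),
            )
            for mp in rec["multiplets"]
        )
        out.append(
            MetaboliteSpec(
                rec["name"],
                mps,
                rec["base_abundance"],
                rec.get("group_log2_effect", 0.0),
                rec.get("cv_within_group", 0.25),
            )
        )
    return out
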