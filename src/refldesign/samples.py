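"""Parametric sample models for design search.

Each model owns a set of named :class:`~refldesign.reflectivity.Parameter`
objects and can build a concrete :class:`~refldesign.reflectivity.Sample`
at the current parameter values, optionally against a given bulk solvent
contrast.  The bundled models are:

* a solid-supported lipid bilayer reparameterized by the water contrast
  SLD (hydrogenous- or deuterated-tail variants), with optional
  deposited underlayers between the native oxide and the bilayer;
* a lipid monolayer at the air/water interface parameterized by area
  per molecule (APM), with hydrogenous and chain-deuterated variants
  and a kinetic degradation series of increasing APM;
* a YAG / YIG / Pt magnetic heterostructure with a thin induced-moment
  slab in the platinum cap.

Default structural values are synthetic, literature-typical placeholders
(every value is overridable); the design-search behaviour of the models,
not any particular fitted value, is the supported surface.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .reflectivity import Layer, Parameter, ReflectivityError, Sample

AVOGADRO = 6.02214076e23  # mol⁻¹
MAGNETIC_CONVERSION_LENGTH = 2.699e-5  # Å per Bohr magneton (neutron-moment coupling)

# bound coherent scattering lengths, fm
COHERENT_B = {"H": -3.7390, "D": 6.6710, "O": 5.8030, "Si": 4.1491}

H2O_SLD = -0.56  # 1e-6 Å⁻², pure H2O
D2O_SLD = 6.36  # 1e-6 Å⁻², pure D2O
SMW_SLD = 2.07  # silicon-matched water
GOLD_SLD = 4.7
PERMALLOY_SLD = 8.4

CONTRAST_BOUNDS = (H2O_SLD, D2O_SLD)


class SampleError(ValueError):
    pass


def compound_sld(total_b_fm: float, molar_mass: float, mass_density: float) -> float:
    """SLD (1e-6 Å⁻²) of a compound from Σb, molar mass (g/mol) and density (g/cm³).

    SLD = Σb · n with n the molecular number density; 1 fm = 1e-5 Å and
    n [Å⁻³] = ρ N_A / M · 1e-24.
    """
    n_per_a3 = mass_density * AVOGADRO / molar_mass * 1e-24
    return total_b_fm * 1e-5 * n_per_a3 * 1e6


def water_sld(d2o_fraction: float) -> float:
    """Solvent SLD (1e-6 Å⁻²) of an H2O/D2O mixture, linear in volume fraction."""
    if not 0.0 <= d2o_fraction <= 1.0:
        raise SampleError("d2o_fraction must lie in [0, 1]")
    return (1.0 - d2o_fraction) * H2O_SLD + d2o_fraction * D2O_SLD


def surface_excess(apm: float, molar_mass: float) -> float:
    """Surface excess Γ (mg m⁻²) of a monolayer with the given area per molecule.

    Γ = M / (N_A · APM · 1e-20), i.e. M/(6.022·APM) with M in g/mol and
    APM in Å²; strictly decreasing in APM.
    """
    if apm <= 0:
        raise SampleError("area per molecule must be > 0")
    return molar_mass * 1e23 / (AVOGADRO * apm)


def moment_to_magnetic_sld(moment: float, number_density: float) -> float:
    """Magnetic SLD (1e-6 Å⁻²) of ``moment`` μB per atom at ``number_density`` Å⁻³."""
    if number_density <= 0:
        raise SampleError("number density must be > 0")
    return MAGNETIC_CONVERSION_LENGTH * moment * number_density * 1e6


class ParametricModel:
    """Base class: a bag of parameters plus a Sample builder."""

    name = "model"

    def __init__(self) -> None:
        self.parameters: list[Parameter] = []

    def param(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(f"{self.name}: no parameter named {name!r}")

    def varying_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters if p.varying]

    def build(self, contrast_sld: float | None = None) -> Sample:  # pragma: no cover
        raise NotImplementedError

    def copy(self) -> "ParametricModel":
        return copy.deepcopy(self)


@dataclass
class Underlayer:
    """A deposited film between the native oxide and the bilayer.

    Roughness is fixed at 2 Å and hydration at 0 — underlayers are grown
    films, characterized before the soft-matter deposition.
    """

    sld: float
    thickness: float
    roughness: float = 2.0
    hydration: float = 0.0

    SLD_BOUNDS = (1.0, 9.0)
    THICKNESS_BOUNDS = (0.0, 500.0)

    def __post_init__(self) -> None:
        lo, hi = self.SLD_BOUNDS
        if not lo <= self.sld <= hi:
            raise SampleError(f"underlayer SLD {self.sld} outside [{lo}, {hi}] (1e-6 Å⁻²)")
        lo, hi = self.THICKNESS_BOUNDS
        if not lo <= self.thickness <= hi:
            raise SampleError(f"underlayer thickness {self.thickness} outside [{lo}, {hi}] Å")


class ContrastBilayer(ParametricModel):
    """Solid-supported lipid bilayer against a variable water contrast.

    Stack (superphase → substrate): Si | SiO2 | [underlayers] |
    inner headgroups | tailgroups | outer headgroups | water.  The
    neutron beam arrives through the silicon block; the backing medium
    is the bulk water, whose SLD is the free contrast variable.  All
    molecular volumes are held fixed, so changing the contrast only
    re-mixes hydrated layers.

    Defaults are synthetic placeholders typical of a PC bilayer on
    silicon.  ``deuterated_tails`` swaps the tailgroup SLD only
    (volumes fixed).
    """

    def __init__(self, deuterated_tails: bool = False, solvent_sld: float = D2O_SLD):
        super().__init__()
        self.name = "bilayer_d_tail" if deuterated_tails else "bilayer_h_tail"
        self.deuterated_tails = deuterated_tails
        self.solvent_sld = solvent_sld
        self.underlayers: list[Underlayer] = []
        self.sio2_sld = 3.47
        self.sio2_thickness = 14.7
        self.si_roughness = 3.0
        self.head_sld = 1.88
        self.tail_sld = 5.90 if deuterated_tails else -0.37
        self.scale = 1.0
        self.background = 2e-6
        self.parameters = [
            Parameter("sio2_hydration", 0.245, (0.0, 0.6)),
            Parameter("bilayer_roughness", 4.0, (1.0, 10.0)),
            Parameter("head_thickness", 9.6, (5.0, 15.0)),
            Parameter("tail_thickness", 25.0, (15.0, 35.0)),
            Parameter("head_hydration", 0.39, (0.0, 0.8)),
            Parameter("tail_hydration", 0.10, (0.0, 0.5)),
        ]
        # excluded from the information objective once underlayers are added
        self._underlayer_exclusions = ("sio2_hydration", "bilayer_roughness")

    def varying_parameters(self) -> list[Parameter]:
        params = super().varying_parameters()
        if self.underlayers:
            params = [p for p in params if p.name not in self._underlayer_exclusions]
        return params

    def build(self, contrast_sld: float | None = None) -> Sample:
        solvent = self.solvent_sld if contrast_sld is None else contrast_sld
        v = {p.name: p.value for p in self.parameters}
        sio2_hydration = 0.0 if self.underlayers else v["sio2_hydration"]
        layers = [
            Layer(
                self.sio2_thickness,
                self.sio2_sld,
                roughness=self.si_roughness,
                hydration=sio2_hydration,
                name="sio2",
            )
        ]
        for i, ul in enumerate(self.underlayers):
            layers.append(
                Layer(
                    ul.thickness,
                    ul.sld,
                    roughness=ul.roughness,
                    hydration=ul.hydration,
                    name=f"underlayer_{i + 1}",
                )
            )
        # with underlayers present the oxide/bilayer interface is replaced by
        # the (fixed, 2 Å) underlayer/bilayer interface
        inner_roughness = 2.0 if self.underlayers else v["bilayer_roughness"]
        layers += [
            Layer(
                v["head_thickness"],
                self.head_sld,
                roughness=inner_roughness,
                hydration=v["head_hydration"],
                name="inner_heads",
            ),
            Layer(
                v["tail_thickness"],
                self.tail_sld,
                roughness=v["bilayer_roughness"],
                hydration=v["tail_hydration"],
                name="tails",
            ),
            Layer(
                v["head_thickness"],
                self.head_sld,
                roughness=v["bilayer_roughness"],
                hydration=v["head_hydration"],
                name="outer_heads",
            ),
        ]
        return Sample(
            superphase_sld=SMW_SLD,  # silicon block
            layers=layers,
            substrate_sld=solvent,
            solvent_sld=solvent,
            scale=self.scale,
            background=self.background,
            substrate_roughness=v["bilayer_roughness"],
            substrate_tracks_solvent=True,
            name=self.name,
        )


def with_underlayer(bilayer: ContrastBilayer, underlayers: list[Underlayer]) -> ContrastBilayer:
    """Return a copy of the bilayer with deposited underlayers.

    Underlayers sit between the SiO2 and the inner headgroups.  Their
    own parameters are nuisance quantities and never enter the
    information objective; in addition the oxide hydration is pinned to
    0 and the oxide hydration + oxide/bilayer roughness parameters are
    dropped from the varying set.
    """
    if len(underlayers) > 3:
        raise SampleError("at most 3 underlayers supported")
    out = bilayer.copy()
    out.underlayers = list(underlayers)
    return out


class APMMonolayer(ParametricModel):
    """Lipid monolayer at the air/water interface, parameterized by APM.

    Two slabs: tailgroups towards air (coverage fraction V_tails/(APM·τ_t),
    remainder air) and hydrated headgroups against the water (coverage
    V_head/(APM·τ_h), remainder solvent).  Increasing APM thins the
    surface excess.  Scattering lengths in fm, volumes in Å³; defaults
    are synthetic placeholders typical of DPPG.
    """

    APM_BOUNDS = (40.0, 1000.0)

    def __init__(self, deuterated_tails: bool = False, solvent_sld: float = 0.0):
        super().__init__()
        self.name = "monolayer_ddppg" if deuterated_tails else "monolayer_hdppg"
        self.deuterated_tails = deuterated_tails
        self.solvent_sld = solvent_sld
        self.tail_b = 613.0 if deuterated_tails else -32.4  # fm, C30(H/D)62
        self.tail_volume = 772.0  # Å³
        self.tail_thickness = 16.0  # Å
        self.head_b = 60.2  # fm
        self.head_volume = 289.0  # Å³
        self.head_thickness = 8.0  # Å
        self.roughness = 3.5
        self.scale = 1.0
        self.background = 5e-6
        self.parameters = [Parameter("apm", 54.1, self.APM_BOUNDS)]

    @property
    def apm(self) -> float:
        return self.param("apm").value

    @apm.setter
    def apm(self, value: float) -> None:
        self.param("apm").value = value

    def volume_fractions(self) -> tuple[float, float]:
        apm = self.apm
        phi_t = self.tail_volume / (apm * self.tail_thickness)
        phi_h = self.head_volume / (apm * self.head_thickness)
        if not (0 < phi_t <= 1 and 0 < phi_h <= 1):
            raise SampleError(f"APM {apm} gives non-physical coverage fractions")
        return phi_t, phi_h

    def build(self, contrast_sld: float | None = None) -> Sample:
        solvent = self.solvent_sld if contrast_sld is None else contrast_sld
        phi_t, phi_h = self.volume_fractions()
        tail_sld_dry = 10.0 * self.tail_b / self.tail_volume  # fm/Å³ → 1e-6 Å⁻²
        head_sld_dry = 10.0 * self.head_b / self.head_volume
        layers = [
            # tail defects are filled by air (SLD 0), not solvent
            Layer(self.tail_thickness, phi_t * tail_sld_dry, roughness=self.roughness, name="tails"),
            Layer(
                self.head_thickness,
                head_sld_dry,
                roughness=self.roughness,
                hydration=1.0 - phi_h,
                name="heads",
            ),
        ]
        return Sample(
            superphase_sld=0.0,  # air
            layers=layers,
            substrate_sld=solvent,
            solvent_sld=solvent,
            scale=self.scale,
            background=self.background,
            substrate_roughness=self.roughness,
            substrate_tracks_solvent=True,
            name=self.name,
        )


def kinetic_series(
    monolayer: APMMonolayer, apm_start: float, apm_end: float, n_steps: int
) -> list[APMMonolayer]:
    """Snapshots of a degrading monolayer over a linear APM grid.

    Returns ``n_steps`` independent model copies with APM increasing
    monotonically from ``apm_start`` to ``apm_end`` inclusive.
    """
    if not apm_start < apm_end:
        raise SampleError("apm_start must be < apm_end")
    if n_steps < 2:
        raise SampleError("n_steps must be >= 2")
    out = []
    for apm in np.linspace(apm_start, apm_end, n_steps):
        snap = monolayer.copy()
        snap.apm = float(apm)
        out.append(snap)
    return out


class MagneticStack(ParametricModel):
    """Air | Pt | YIG | YAG heterostructure with an induced Pt moment.

    A thin magnetized platinum sub-slab of fixed 21 Å sits at the Pt/YIG
    interface; its magnetic SLD is the quantity of interest.  When the
    platinum cap is thickened, the moment is constrained to stay inside
    the 21 Å sub-slab, so the total moment (magnetic SLD × magnetized
    thickness) never grows with cap thickness.  Structural defaults are
    synthetic placeholders.
    """

    YIG_BOUNDS = (400.0, 900.0)
    PT_BOUNDS = (20.0, 100.0)
    MAGNETIZED_THICKNESS = 21.0  # Å

    def __init__(self, pt_thickness: float = 21.0, yig_thickness: float = 700.0):
        super().__init__()
        self.name = "yig_pt"
        self.pt_thickness = pt_thickness
        self.yig_thickness = yig_thickness
        self.pt_sld = 6.36
        self.yig_sld = 5.84
        self.yag_sld = 5.40
        self.pt_roughness = 3.0
        self.yig_roughness = 4.0
        self.yag_roughness = 4.0
        self.scale = 1.0
        self.background = 5e-7
        self.parameters = [Parameter("pt_magnetic_sld", 0.0164, (0.0, 0.1))]

    def build(self, contrast_sld: float | None = None) -> Sample:
        if contrast_sld is not None:
            raise SampleError("the magnetic stack has no solvent contrast")
        msld = self.param("pt_magnetic_sld").value
        mag_t = min(self.pt_thickness, self.MAGNETIZED_THICKNESS)
        layers = []
        cap = self.pt_thickness - mag_t
        if cap > 0:
            layers.append(Layer(cap, self.pt_sld, roughness=self.pt_roughness, name="pt_cap"))
        layers.append(
            Layer(
                mag_t,
                self.pt_sld,
                magnetic_sld=msld,
                roughness=self.pt_roughness if cap == 0 else 0.0,
                name="pt_magnetized",
            )
        )
        layers.append(Layer(self.yig_thickness, self.yig_sld, roughness=self.yig_roughness, name="yig"))
        return Sample(
            superphase_sld=0.0,
            layers=layers,
            substrate_sld=self.yag_sld,
            scale=self.scale,
            background=self.background,
            substrate_roughness=self.yag_roughness,
            name=self.name,
        )

    def total_moment(self) -> float:
        """Magnetic SLD × magnetized thickness (1e-6 Å⁻¹): conserved vs cap thickness."""
        return self.param("pt_magnetic_sld").value * min(
            self.pt_thickness, self.MAGNETIZED_THICKNESS
        )


BUILTIN_SAMPLES = {
    "bilayer_h_tail": lambda: ContrastBilayer(deuterated_tails=False),
    "bilayer_d_tail": lambda: ContrastBilayer(deuterated_tails=True),
    "monolayer_hdppg": lambda: APMMonolayer(deuterated_tails=False),
    "monolayer_ddppg": lambda: APMMonolayer(deuterated_tails=True),
    "yig_pt": lambda: MagneticStack(),
}


def get_sample(name: str) -> ParametricModel:
    try:
        return BUILTIN_SAMPLES[name]()
    except KeyError:
        raise SampleError(
            f"unknown builtin sample {name!r}; available: {sorted(BUILTIN_SAMPLES)}"
        ) from None
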