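"""Parameter definitions for the whole-body iron model.

The model distinguishes *estimable kinetic parameters* (48 of them; these are
the coordinates seen by the fitting machinery) from *structural constants*
(promoter weights, the SMAD half-saturation constant, the normal dietary iron
influx, the chronic LPS source) that are fixed by experimental design or by a
previously calibrated promoter model and are never optimized.

Units
-----
Time is measured in hours throughout; the tracer loss rate ``r_loss`` is the
single exception (1/day, matching how whole-body iron loss rates are usually
quoted).  Iron pools are whole-animal masses in ``µg`` standardized to a 25 g
mouse.  Molecular species (Fpn mRNA/protein, hepcidin, BMP6, IL6) live in
internal model units; comparison with arbitrary-unit measurements goes through
the observation-map scaling parameters.  Dietary iron content is expressed as
a fold of the normal diet (``Fe_food = 1`` is the 200 ppm reference chow).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "KINETIC_PARAM_NAMES",
    "ParameterSet",
    "PromoterParams",
    "reference_parameters",
    "DEFAULT_BOUNDS_DECADES",
]

#: The 48 kinetic parameters estimated from data, grouped by subsystem.
KINETIC_PARAM_NAMES: tuple[str, ...] = (
    # serum -> organ import rates (1/h)
    "v_liver", "v_spleen", "v_duo", "v_bm", "v_other",
    # organ -> serum Fpn-mediated export rates (1/(h * Fpn unit))
    "u_liver", "u_spleen", "u_duo", "u_other",
    # erythroid fluxes (1/h)
    "v_RBC", "v_splBM", "v_splRBC",
    # iron loss rates (enterocyte shedding, skin desquamation; 1/h)
    "l_duo", "l_other",
    # saturable duodenal uptake (µg/h and dietary-iron units)
    "V_duo", "K_duo",
    # NTBI uptake into liver and ferritin storage cap
    "v_NTBI", "K_NTBI", "Fe_max",
    # Fpn mRNA transcription (per organ) and shared decay / LPS inhibition
    "a_liver", "a_spleen", "a_duo", "a_other", "d_mRNA", "K_LPS",
    # Fpn translation (per organ) and shared IRE constant
    "b_liver", "b_spleen", "b_duo", "b_other", "K_IRE",
    # Fpn protein degradation: basal (shared) and hepcidin-mediated (per organ)
    "k1", "k2_liver", "k2_duo", "k2_spleen", "k2_rest",
    # hepcidin synthesis / degradation
    "s_hep", "d_hep",
    # LPS decay and IL6/STAT3 cascade
    "d_LPS", "s_IL6", "K_IL6", "d_IL6", "s_STAT", "K_STAT", "d_STAT",
    # BMP6 synthesis (saturating in liver iron) and decay
    "s_BMP6", "K_BMP6", "d_BMP6",
    # whole-body tracer loss rate (1/day)
    "r_loss",
)

assert len(KINETIC_PARAM_NAMES) == 48


@dataclass(frozen=True)
class PromoterParams:
    """Thermodynamic state-ensemble weights of the hepcidin promoter.

    ``q_S``/``q_T`` are binding weights of SMAD and STAT3, ``w_*`` the
    fold-activation of the singly and doubly bound states, ``omega`` the
    binding cooperativity.  Basal activity (S = T = 0) is exactly 1.
    """

    q_S: float = 1.0
    q_T: float = 1.2
    w_S: float = 100.0
    w_T: float = 25.0
    w_ST: float = 150.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        for name in ("q_S", "q_T", "w_S", "w_T", "w_ST", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"promoter parameter {name} must be >= 0")


@dataclass
class ParameterSet:
    """All constants of the whole-body model.

    The 48 fields named in :data:`KINETIC_PARAM_NAMES` are the estimable
    kinetic parameters; everything after them is structural.  Knockout and
    clamp perturbations act by mutating copies of this object (see
    :mod:`ferroflux.perturb`).
    """

    # -- estimable kinetic parameters (values are the synthetic reference set,
    #    see reference_parameters below) --
    v_liver: float = 0.18
    v_spleen: float = 0.10
    v_duo: float = 0.05
    v_bm: float = 2.0
    v_other: float = 0.90
    u_liver: float = 0.013230769230769231
    u_spleen: float = 0.35
    u_duo: float = 0.5555555555555556
    u_other: float = 0.0015555555555555516
    v_RBC: float = 0.80
    v_splBM: float = 0.20
    v_splRBC: float = 0.0037647058823529413
    l_duo: float = 1.4777777777777776
    l_other: float = 0.010444444444444449
    V_duo: float = 36.0
    K_duo: float = 5.0
    v_NTBI: float = 1.0
    K_NTBI: float = 6.0
    Fe_max: float = 1500.0
    a_liver: float = 0.35
    a_spleen: float = 0.35
    a_duo: float = 0.35
    a_other: float = 0.35
    d_mRNA: float = 0.35
    K_LPS: float = 0.02
    b_liver: float = 0.09792307692307692
    b_spleen: float = 0.14
    b_duo: float = 0.8666666666666667
    b_other: float = 0.07093333333333335
    K_IRE: float = 2.0
    k1: float = 0.02
    k2_liver: float = 0.075
    k2_duo: float = 0.50
    k2_spleen: float = 0.10
    k2_rest: float = 0.05
    s_hep: float = 0.012363636363636365
    d_hep: float = 0.068
    d_LPS: float = 0.30
    s_IL6: float = 1.0
    K_IL6: float = 0.10
    d_IL6: float = 0.70
    s_STAT: float = 0.70
    K_STAT: float = 0.50
    d_STAT: float = 0.35
    s_BMP6: float = 32.76923076923077
    K_BMP6: float = 1000.0
    d_BMP6: float = 2.0
    r_loss: float = 0.005

    # -- structural constants --
    Fe_food: float = 1.0          # dietary iron, fold of the 200 ppm diet
    s_LPS: float = 0.0            # chronic LPS source (µg/g/h); 0 = none
    K_SMAD: float = 20.0          # BMP6 half-saturation of SMAD activity
    promoter: PromoterParams = field(default_factory=PromoterParams)
    smad_ko: bool = False         # SMAD activity forced to 0 (SMAD4-KO)
    ntbi_mode: str = "saturating"  # "saturating" | "threshold"
    Tf_cap: float = 8.0           # serum transferrin capacity (threshold mode)
    linear_uptake: bool = False   # replace MM uptake by a linear law (Fig-7 variant)
    clamps: tuple[str, ...] = ()  # state names whose derivatives are zeroed

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for name in KINETIC_PARAM_NAMES:
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"kinetic parameter {name} must be >= 0, got {value}")
        for name in ("K_duo", "K_NTBI", "K_LPS", "K_IRE", "K_IL6", "K_STAT",
                     "K_BMP6", "K_SMAD"):
            if getattr(self, name) <= 0:
                raise ValueError(f"saturation constant {name} must be > 0")
        if self.ntbi_mode not in ("saturating", "threshold"):
            raise ValueError(f"unknown ntbi_mode {self.ntbi_mode!r}")

    # ------------------------------------------------------------------
    def kinetic_values(self) -> dict[str, float]:
        """Mapping of the 48 estimable parameters to their current values."""
        return {name: getattr(self, name) for name in KINETIC_PARAM_NAMES}

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields changed (validated)."""
        return dataclasses.replace(self, **changes)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.kinetic_values().items())


def reference_parameters() -> ParameterSet:
    """The packaged reference parameter set.

    This is a *synthetic* calibration: a hand-tuned parameter set for a 25 g
    mouse on a 200 ppm diet, adjusted so that the model reproduces the
    characteristic systemic behaviours of murine iron metabolism (fast plasma
    iron turnover, ~40 µg/day dietary absorption, liver-dominant iron loading
    under a 2% carbonyl-iron diet, LPS-induced hypoferremia with recovery by
    72 h, anemia under chronic inflammation, homeostatic buffering of serum
    iron against dietary changes).  It plays the role of a fitted reference
    model for simulation studies and is the default starting point of the
    calibration machinery.
    """
    return ParameterSet()


#: Default multi-start search box: this many decades around the reference
#: value, in log10 space, for every estimable parameter.
DEFAULT_BOUNDS_DECADES: float = 3.0
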