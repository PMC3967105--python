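"""Growth environment for all flux-balance computations.

The environment fixes the exchange bounds of the model (substrate and
oxygen uptake, freely diffusing small molecules), the non-growth ATP
maintenance requirement, the minimum growth rate a designed strain must
sustain, and the small forced production flux used by the shadow-price
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Conventional COBRA "effectively unbounded" flux, mmol/gDW/h.  Kept
#: finite so that big-M reformulations of the bilevel knockout problem
#: are well posed.
BIG = 1000.0

#: Metabolites allowed to diffuse freely across the membrane (BiGG ids),
#: following the convention of the iAF1260 reconstruction.
DEFAULT_FREE_EXCHANGES = (
    "EX_co2_e",
    "EX_h2o_e",
    "EX_h_e",
    "EX_nh4_e",
    "EX_pi_e",
    "EX_so4_e",
    "EX_k_e",
    "EX_na1_e",
    "EX_cl_e",
    "EX_mg2_e",
    "EX_ca2_e",
    "EX_cobalt2_e",
    "EX_cu2_e",
    "EX_fe2_e",
    "EX_fe3_e",
    "EX_mn2_e",
    "EX_mobd_e",
    "EX_tungs_e",
    "EX_zn2_e",
)


@dataclass
class EnvironmentConfig:
    """Environmental and scoring parameters.

    Parameters
    ----------
    gur :
        Maximum glucose uptake rate (mmol/gDW/h).  Default 10.
    our :
        Maximum oxygen uptake rate (mmol/gDW/h).  Default 5, a
        microaerobic condition under which fermentative by-product
        routes carry flux and knockout coupling is strongest.
    ngam :
        Non-growth-associated ATP maintenance, imposed as a flux
        equality on the ATP hydrolysis reaction (mmol/gDW/h).
        Default 8.39.
    min_growth :
        Minimum biomass production rate (1/h) a knockout strain must
        sustain; enforced in the scoring LP.  Default 0.05.
    b_target :
        Small forced target production flux whose dual value is the
        screening score (mmol/gDW/h).  Default 1e-5.
    glucose_exchange, oxygen_exchange :
        Ids of the substrate and oxygen exchange reactions.
    atp_maintenance :
        Id of the ATP maintenance reaction, or ``None`` if the model
        has none (toy models).
    free_exchanges :
        Exchange reaction ids opened in both directions.
    """

    gur: float = 10.0
    our: float = 5.0
    ngam: float = 8.39
    min_growth: float = 0.05
    b_target: float = 1e-5
    glucose_exchange: str = "EX_glc__D_e"
    oxygen_exchange: str = "EX_o2_e"
    atp_maintenance: str | None = "ATPM"
    free_exchanges: tuple[str, ...] = field(default=DEFAULT_FREE_EXCHANGES)

    def __post_init__(self) -> None:
        if not self.gur > 0:
            raise ValueError("gur must be positive")
        if self.our < 0:
            raise ValueError("our must be non-negative")
        if self.ngam < 0:
            raise ValueError("ngam must be non-negative")
        if self.min_growth < 0:
            raise ValueError("min_growth must be non-negative")
        if not 0 < self.b_target < self.gur:
            raise ValueError("b_target must satisfy 0 < b_target << gur")
        self.free_exchanges = tuple(self.free_exchanges)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["free_exchanges"] = list(self.free_exchanges)
        return d
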