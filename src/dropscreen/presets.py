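"""Canonical screening configurations used by the analysis scripts and tests.

These encode the study conditions of the platform: BG-11/AD7 reference
medium concentrations, the standard 1D nitrate ramp (440 droplets, 0-50 mM)
and the 11x11 2D nitrogen-phosphorus grid, together with synthetic growth
parameter sets that produce a unimodal 1D dose response (peak bracketed
between the Monod constant and the inhibition threshold) and a
Liebig-limited 2D response surface.
"""

from __future__ import annotations

from .gradient_design import Effector, ScreeningPlan
from .synthetic_trace import EffectorResponse, GrowthParams, OpticsModel

__all__ = [
    "BG11_NANO3_MM",
    "BG11_K2HPO4_MM",
    "AD7_NANO3_MM",
    "AD7_KH2PO4_MM",
    "REDFIELD_C_N_P",
    "nitrate_1d_plan",
    "nitrate_growth_params",
    "np_2d_plan",
    "np_growth_params",
    "default_optics",
]

# Reference medium compositions (mM)
BG11_NANO3_MM = 17.6
BG11_K2HPO4_MM = 0.175
AD7_NANO3_MM = 12.0
AD7_KH2PO4_MM = 0.37

#: Redfield molar ratio of phytoplankton biomass, C:N:P
REDFIELD_C_N_P = (106, 16, 1)


def nitrate_1d_plan(n_droplets: int = 440) -> ScreeningPlan:
    """1D NaNO3 ramp 0-50 mM from a 2x (100 mM) stock, 440 droplets."""
    return ScreeningPlan(
        effectors=(Effector("NaNO3", stock_mM=100.0),),
        dimensionality=1,
        n_droplets=n_droplets,
    )


def nitrate_growth_params() -> GrowthParams:
    """Unimodal nitrate response peaking near 10 mM (between the Monod
    half-saturation of 4 mM and the inhibition threshold of 16 mM)."""
    return GrowthParams(
        max_rate_per_day=1.2,
        carrying_capacity_per_nl=2000.0,
        lag_days=0.5,
        responses={
            "NaNO3": EffectorResponse(
                half_saturation_mM=4.0,
                inhibition_threshold_mM=16.0,
                inhibition_steepness_per_mM=0.5,
            )
        },
    )


def np_2d_plan(droplets_per_step: int = 8, n_steps: int = 11) -> ScreeningPlan:
    """11x11 NaNO3 x K2HPO4 grid, 0-30 mM N and 0-0.5 mM P (4x stocks)."""
    return ScreeningPlan(
        effectors=(
            Effector("NaNO3", stock_mM=120.0),
            Effector("K2HPO4", stock_mM=2.0),
        ),
        dimensionality=2,
        n_steps=n_steps,
        droplets_per_step=droplets_per_step,
    )


def np_growth_params() -> GrowthParams:
    """Liebig co-limitation by N and P: growth follows the scarcer nutrient,
    neither inhibitory inside the screened window."""
    return GrowthParams(
        max_rate_per_day=1.2,
        carrying_capacity_per_nl=2000.0,
        lag_days=0.5,
        responses={
            "NaNO3": EffectorResponse(
                half_saturation_mM=4.0,
                inhibition_threshold_mM=60.0,
                inhibition_steepness_per_mM=0.3,
            ),
            "K2HPO4": EffectorResponse(
                half_saturation_mM=0.08,
                inhibition_threshold_mM=2.0,
                inhibition_steepness_per_mM=5.0,
            ),
        },
    )


def default_optics() -> OpticsModel:
    return OpticsModel()
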