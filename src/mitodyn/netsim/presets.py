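"""Condition presets for the simulator.

The presets encode the experimental arms as parameter bundles:

* ``control`` / ``mtSOD1`` -- healthy network: well connected at t=0,
  slow balanced remodeling.
* ``g93a`` / ``mtSOD1G93A`` -- mutant: more edges missing at t=0 and a
  raised fission rate, so the network degrades toward a shattered
  steady state during the recording; ``mtSOD1G93A`` additionally
  carries tracer-protein aggregates with local depolarization.
* ``fccp`` -- partial depolarization: potential reduced by 19%
  everywhere and fusion slowed.
* ``mdivi1`` -- the mutant arm with the fission rate reduced 4-fold
  (fission-inhibitor treatment); all other parameters identical to
  ``mtSOD1G93A``.

Numerical values are calibrated so that the ground-truth migration of
the default geometry reproduces the target early rate (~3.7
m-steps/min) and late rate (~0.47 m-steps/min) in the control arm and
the qualitative ordering control ~ mtSOD1 > fccp > mtSOD1G93A ~ g93a,
with mdivi1 restored close to control in the late phase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .model import SimParams

__all__ = ["ConditionPreset", "PRESETS", "get_preset", "PRESET_NAMES"]


@dataclass(frozen=True)
class ConditionPreset:
    name: str
    params: SimParams


_CONTROL = SimParams(
    d_intra=14.0,
    k_fus=0.08,
    k_fis=0.07,
    p_frag0=0.32,
)

_G93A = SimParams(
    d_intra=14.0,
    k_fus=0.08,
    k_fis=0.35,
    p_frag0=0.45,
)

_FCCP = replace(
    _CONTROL,
    k_fus=0.035,
    p_frag0=0.40,
    global_depol=0.19,
)

_MT_SOD1G93A = replace(
    _G93A,
    aggregate_density=2.0,
    depol_at_aggregate=0.5,
)

_MDIVI1 = replace(_MT_SOD1G93A, k_fis=_MT_SOD1G93A.k_fis / 4.0)

PRESETS: dict[str, ConditionPreset] = {
    "control": ConditionPreset("control", _CONTROL),
    "mtSOD1": ConditionPreset("mtSOD1", _CONTROL),
    "g93a": ConditionPreset("g93a", _G93A),
    "mtSOD1G93A": ConditionPreset("mtSOD1G93A", _MT_SOD1G93A),
    "fccp": ConditionPreset("fccp", _FCCP),
    "mdivi1": ConditionPreset("mdivi1", _MDIVI1),
}

PRESET_NAMES = tuple(PRESETS)


def get_preset(name: str) -> ConditionPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {', '.join(PRESETS)}"
        ) from None
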