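"""Perturbation parameters for the single-cell model.

The baseline cell is a mouse left-ventricular epicardial (apical) myocyte.
All perturbations used by the scan protocols are expressed as dimensionless
multipliers on maximal K+ conductances, a multiplier on the Na_v channel
re-opening rate (the IF_Na -> O_Na Markov transition, which generates the
late Na+ current), and an additive voltage shift of L-type Ca2+ channel
activation (mimicking the channel agonist FPL 64176).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: scan-able K+ conductances, keyed by the short current id used in protocols
K_CURRENT_IDS = ("Ktof", "Ktos", "Kur", "Kss", "K1", "Kr", "Ks")

#: default stimulus amplitude in pA/pF: 1.5x the baseline excitation
#: threshold of a 1 ms rectangular pulse, determined once by bisection
#: (see :func:`epicard.simulate.find_threshold`) and held fixed for all
#: perturbations.
DEFAULT_STIM_AMPLITUDE = 30.36


@dataclass(frozen=True)
class ModelParameters:
    """Perturbation set applied on top of the baseline myocyte model.

    With every ``scale_*`` at 1, ``k_reopen_scale`` at 1 and
    ``dV_half_CaL`` at 0 the model is the unmodified baseline.

    Attributes
    ----------
    scale_gKtof, scale_gKtos, scale_gKur, scale_gKss, scale_gK1,
    scale_gKr, scale_gKs : float
        Dimensionless multipliers on the respective maximal K+
        conductances. Must be positive.
    k_reopen_scale : float
        Multiplier on the single IF_Na -> O_Na transition rate of the Na_v
        Markov scheme (late Na+ current modulation). Must be positive.
    dV_half_CaL : float
        Additive shift (mV, <= 0 for the agonist mimic) applied to the
        voltage-dependence of I_CaL *activation*; inactivation untouched.
    stim_amplitude : float
        Stimulus current density magnitude (pA/pF), applied as an inward
        (depolarizing) rectangular pulse.
    stim_duration : float
        Stimulus pulse width (ms).
    cycle_length : float
        Pacing cycle length (ms).
    cell_variant : str
        Fixed tag; only the LV epicardial variant is implemented.
    """

    scale_gKtof: float = 1.0
    scale_gKtos: float = 1.0
    scale_gKur: float = 1.0
    scale_gKss: float = 1.0
    scale_gK1: float = 1.0
    scale_gKr: float = 1.0
    scale_gKs: float = 1.0
    k_reopen_scale: float = 1.0
    dV_half_CaL: float = 0.0
    stim_amplitude: float = DEFAULT_STIM_AMPLITUDE
    stim_duration: float = 1.0
    cycle_length: float = 200.0
    cell_variant: str = "LV epicardial"

    def __post_init__(self) -> None:
        for cid in K_CURRENT_IDS:
            value = getattr(self, f"scale_g{cid}")
            if not value > 0:
                raise ValueError(f"scale_g{cid} must be positive, got {value}")
        if not self.k_reopen_scale > 0:
            raise ValueError(
                f"k_reopen_scale must be positive, got {self.k_reopen_scale}"
            )
        if self.cell_variant != "LV epicardial":
            raise ValueError("only the 'LV epicardial' cell variant is implemented")

    # -- perturbation transforms -------------------------------------------
    def with_scale(self, current_id: str, factor: float) -> "ModelParameters":
        """Return a copy with the named K+ conductance multiplier set.

        ``current_id`` must be one of ``K_CURRENT_IDS``; ``factor`` must be
        positive. Only the named multiplier changes.
        """
        if current_id not in K_CURRENT_IDS:
            raise ValueError(
                f"unknown current id {current_id!r}; expected one of {K_CURRENT_IDS}"
            )
        if not factor > 0:
            raise ValueError(f"conductance factor must be positive, got {factor}")
        return dataclasses.replace(self, **{f"scale_g{current_id}": float(factor)})

    def with_k_reopen(self, factor: float) -> "ModelParameters":
        """Return a copy with the Na_v re-opening rate multiplier set."""
        if not factor > 0:
            raise ValueError(f"k_reopen_scale must be positive, got {factor}")
        return dataclasses.replace(self, k_reopen_scale=float(factor))

    def with_caL_shift(self, dV: float) -> "ModelParameters":
        """Return a copy with the I_CaL activation voltage-dependence shifted.

        The activation rate expressions are evaluated at ``V - dV``; a
        negative ``dV`` therefore moves activation to more negative
        potentials (a -15 mV shift mimics FPL 64176).
        """
        return dataclasses.replace(self, dV_half_CaL=float(dV))

    @property
    def is_baseline(self) -> bool:
        return self == ModelParameters(
            stim_amplitude=self.stim_amplitude,
            stim_duration=self.stim_duration,
            cycle_length=self.cycle_length,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def apply_scales(
    params: ModelParameters, current_id: str, factor: float
) -> ModelParameters:
    """Functional alias for :meth:`ModelParameters.with_scale`."""
    return params.with_scale(current_id, factor)


def shift_caL_activation(params: ModelParameters, dV: float) -> ModelParameters:
    """Functional alias for :meth:`ModelParameters.with_caL_shift`."""
    return params.with_caL_shift(dV)
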